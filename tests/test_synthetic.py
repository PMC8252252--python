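"""Generator contracts: balanced design, behavior model, templates, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonogo_erp import synthetic as syn
from gonogo_erp.events import GO, NOGO, TrialEvent
from gonogo_erp.montage import CHANNELS


class TestTrialSequence:
    def test_default_protocol_counts_are_exact(self):
        events = syn.generate_trial_sequence(3, 80, 0.70, (0.5, 1.5), 0.5, seed=7)
        n_go = sum(e.condition == GO for e in events)
        assert n_go == 168
        assert len(events) - n_go == 72
        # per-block balance
        for b in range(3):
            block = [e for e in events if e.block_index == b]
            assert sum(e.condition == GO for e in block) == 56

    def test_degenerate_all_go(self):
        events = syn.generate_trial_sequence(1, 10, 1.0, (0.5, 1.5), 0.5, seed=0)
        assert len(events) == 10
        assert all(e.condition == GO for e in events)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_onset_gaps_stay_in_jitter_band(self, seed):
        events = syn.generate_trial_sequence(1, 30, 0.7, (0.5, 1.5), 0.5, seed=seed)
        onsets = np.array([e.onset_s for e in events])
        gaps = np.diff(onsets) - 0.5  # remove stimulus duration
        assert np.all(gaps >= 0.5) and np.all(gaps <= 1.5)

    def test_non_integer_split_rejected(self):
        with pytest.raises(ValueError, match="not an\\s+integer"):
            syn.generate_trial_sequence(1, 10, 0.75, (0.5, 1.5), 0.5, seed=0)

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_trial_sequence(0, 80, 0.7, (0.5, 1.5), 0.5, seed=0)

    def test_seed_determinism(self):
        a = syn.generate_trial_sequence(3, 80, 0.7, (0.5, 1.5), 0.5, seed=42)
        b = syn.generate_trial_sequence(3, 80, 0.7, (0.5, 1.5), 0.5, seed=42)
        assert a == b


class TestBehavior:
    def test_rt_mean_matches_configured_moments(self, icd_profile):
        """ICD session-1 Go responses average ~483.9 ms over many draws."""
        events = [TrialEvent(1.0 + 2.0 * i, GO, 0) for i in range(10_000)]
        annotated = syn.simulate_behavior(events, icd_profile, 1, seed=0)
        rts = np.array([e.rt_ms for e in annotated if e.pressed])
        # truncation at 0 is negligible at mean/SD 483.9/93.8
        assert abs(rts.mean() - 483.9) < 3 * 93.8 / np.sqrt(len(rts))

    def test_zero_error_probabilities(self, icd_profile):
        prof = icd_profile
        beh = {s: syn.SessionBehavior(400.0, 50.0, 0.0, 0.0) for s in (1, 2)}
        prof = syn.SubjectProfile(prof.subject_id, prof.group, prof.quip_rs,
                                  prof.components, beh, prof.attenuation_slope)
        events = syn.generate_trial_sequence(1, 40, 0.7, (0.5, 1.5), 0.5, seed=1)
        annotated = syn.simulate_behavior(events, prof, 1, seed=2)
        assert all(e.pressed for e in annotated if e.condition == GO)
        assert not any(e.pressed for e in annotated if e.condition == NOGO)
        assert not any(e.is_error for e in annotated)

    def test_error_flags_respect_task_semantics(self, icd_profile):
        events = syn.generate_trial_sequence(3, 80, 0.7, (0.5, 1.5), 0.5, seed=5)
        annotated = syn.simulate_behavior(events, icd_profile, 2, seed=6)
        for ev in annotated:
            if ev.condition == NOGO:
                assert ev.error_type != "SE"
            if ev.condition == GO:
                assert ev.error_type != "CE"
            assert (ev.rt_ms is not None) == bool(ev.pressed)


class TestComponentWaveform:
    def test_peak_value_is_amplitude(self):
        t = np.arange(0, 1000, 4.0)
        w = syn.erp_component_waveform(-2.0, 340.0, 40.0, t)
        assert w[np.where(t == 340.0)[0][0]] == pytest.approx(-2.0)

    def test_zero_amplitude_gives_zero_waveform(self):
        w = syn.erp_component_waveform(0.0, 340.0, 40.0, np.arange(0, 1000, 4.0))
        assert np.all(w == 0)

    def test_value_at_one_width_matches_gaussian_closed_form(self):
        t = np.array([300.0, 340.0, 380.0])
        w = syn.erp_component_waveform(-2.0, 340.0, 40.0, t)
        expected = -2.0 * np.exp(-0.5)
        assert w[0] == pytest.approx(expected, rel=1e-12)
        assert w[2] == pytest.approx(expected, rel=1e-12)

    def test_compact_support_beyond_four_widths(self):
        t = np.arange(0, 1000, 1.0)
        w = syn.erp_component_waveform(3.0, 500.0, 50.0, t)
        assert np.all(w[t < 500 - 4 * 50] == 0)
        assert np.all(w[t > 500 + 4 * 50] == 0)

    def test_empty_time_axis_rejected(self):
        with pytest.raises(ValueError):
            syn.erp_component_waveform(1.0, 100.0, 10.0, np.array([]))


def _noiseless_config(**kwargs):
    import dataclasses
    return syn.CohortConfig(
        noise=syn.NoiseConfig(1.0, 0.0),
        blink=dataclasses.replace(syn.BlinkConfig(), rate_per_min=0.0),
        **kwargs,
    )


class TestRecording:
    def test_noiseless_nogo_average_has_n2_trough_at_configured_latency(self, icd_profile):
        import dataclasses
        # zero P3 so its rising flank cannot displace the N2 trough
        comps = dict(icd_profile.components)
        comps["P3"] = dataclasses.replace(comps["P3"], amplitude_uv=0.0)
        icd_profile = dataclasses.replace(icd_profile, components=comps)
        events = syn.generate_trial_sequence(1, 20, 0.5, (0.5, 1.5), 0.5, seed=1)
        events = syn.simulate_behavior(events, icd_profile, 1, seed=2)
        rec = syn.simulate_recording(events, icd_profile, 1, _noiseless_config(), seed=3)
        fs = rec.fs_hz
        cz = rec.channel("Cz")
        nogo = [e for e in events if e.condition == NOGO]
        epochs = np.stack([
            cz[int(round(e.onset_s * fs)): int(round(e.onset_s * fs)) + int(fs)]
            for e in nogo
        ])
        avg = epochs.mean(axis=0)
        t_ms = np.arange(avg.size) / fs * 1000.0
        window = (t_ms >= 200) & (t_ms <= 400)
        t_min = t_ms[window][np.argmin(avg[window])]
        assert abs(t_min - icd_profile.components["N2"].latency_ms) <= 1000.0 / fs

    def test_go_trials_carry_no_component(self, icd_profile):
        events = [TrialEvent(1.0 + 2.0 * i, GO, 0) for i in range(10)]
        events = syn.simulate_behavior(events, icd_profile, 1, seed=2)
        rec = syn.simulate_recording(events, icd_profile, 1, _noiseless_config(), seed=3)
        assert np.allclose(rec.data, 0.0)

    def test_blink_topography_ratio_front_vs_posterior(self, icd_profile):
        events = syn.simulate_behavior(
            syn.generate_trial_sequence(1, 10, 0.5, (0.5, 1.5), 0.5, seed=1),
            icd_profile, 1, seed=2,
        )
        import dataclasses
        config = syn.CohortConfig(
            noise=syn.NoiseConfig(1.0, 0.0),
            blink=dataclasses.replace(syn.BlinkConfig(), rate_per_min=60.0),
        )
        # suppress components to isolate the blink mixture
        comps = {k: dataclasses.replace(v, amplitude_uv=0.0)
                 for k, v in icd_profile.components.items()}
        prof = dataclasses.replace(icd_profile, components=comps)
        rec = syn.simulate_recording(events, prof, 1, config, seed=3)
        fz_amp = np.abs(rec.channel("Fz")).max()
        cpz_amp = np.abs(rec.channel("CPz")).max()
        topo = config.blink.topography
        expected = topo[CHANNELS.index("Fz")] / topo[CHANNELS.index("CPz")]
        assert fz_amp / cpz_amp == pytest.approx(expected, rel=1e-6)

    def test_recording_reproducible_given_seed(self, icd_profile):
        events = syn.simulate_behavior(
            syn.generate_trial_sequence(1, 10, 0.5, (0.5, 1.5), 0.5, seed=1),
            icd_profile, 1, seed=2,
        )
        config = syn.CohortConfig()
        a = syn.simulate_recording(events, icd_profile, 1, config, seed=9)
        b = syn.simulate_recording(events, icd_profile, 1, config, seed=9)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_default_group_sizes(self):
        cohort = syn.simulate_cohort(seed=0)
        groups = [s.profile.group for s in cohort.subjects]
        assert groups.count("HC") == 23
        assert groups.count("PD") == 20
        assert groups.count("ICD") == 9

    def test_attenuation_applies_only_to_icd_session2(self):
        cohort = syn.simulate_cohort(seed=1)
        for sub in cohort.subjects:
            p = sub.profile
            a1 = p.session_amplitude("N2", 1)
            a2 = p.session_amplitude("N2", 2)
            if p.group == "ICD" and p.quip_rs > 0:
                assert abs(a2) < abs(a1)
            else:
                assert a1 == a2

    def test_zero_slope_removes_builtin_session_effect(self):
        import dataclasses
        cfg = dataclasses.replace(syn.CohortConfig(), attenuation_slope=0.0)
        cohort = syn.simulate_cohort(cfg)
        for sub in cohort.subjects:
            for comp in ("N2", "P3"):
                assert sub.profile.session_amplitude(comp, 1) == \
                    sub.profile.session_amplitude(comp, 2)

    def test_negative_slope_builds_positive_delta_quip_correlation(self):
        """Ground-truth ΔN2 (signed, session2-session1) correlates with
        QUIP-RS in the direction the attenuation model implies, in >= 90%
        of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = syn.CohortConfig(group_sizes={"HC": 0, "PD": 20, "ICD": 9},
                                   attenuation_slope=-0.02, seed=seed)
            cohort = syn.simulate_cohort(cfg)
            delta = np.array([
                s.profile.session_amplitude("N2", 2) - s.profile.session_amplitude("N2", 1)
                for s in cohort.subjects
            ])
            quip = np.array([s.profile.quip_rs for s in cohort.subjects])
            # N2 is negative; attenuation moves it toward zero, so the signed
            # delta grows with QUIP-RS
            if np.corrcoef(delta, quip)[0, 1] > 0:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_cohort_determinism(self):
        a = syn.simulate_cohort(seed=7)
        b = syn.simulate_cohort(seed=7)
        ev_a, rec_a = a.subjects[5].realize_session(2)
        ev_b, rec_b = b.subjects[5].realize_session(2)
        assert ev_a == ev_b
        assert np.array_equal(rec_a.data, rec_b.data)

    def test_duplicate_subject_ids_rejected(self, icd_profile):
        with pytest.raises(ValueError, match="duplicate"):
            syn.simulate_cohort(profiles=[icd_profile, icd_profile])
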