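"""Filtering, epoching, artifact rejection, ICA cleanup, retention rule."""

import numpy as np
import pytest
import scipy.signal
import scipy.stats

from gonogo_erp import preprocess, synthetic as syn
from gonogo_erp.montage import CHANNELS
from gonogo_erp.recording import Recording

from conftest import bandlimited_noise_epochs, make_epochset

FS = 250.0


def _rec(data, fs=FS):
    return Recording("sub-01", 1, data, list(CHANNELS), fs)


def _analytic_filtfilt_gain(freq_hz: float) -> float:
    """Oracle: squared magnitude of the Butterworth band-pass at freq."""
    sos = preprocess.design_bandpass(1.0, 30.0, FS)
    w, h = scipy.signal.sosfreqz(sos, worN=[freq_hz], fs=FS)
    return float(np.abs(h[0]) ** 2)  # forward-backward squares the response


class TestBandpass:
    def _measure_gain(self, freq_hz: float) -> float:
        t = np.arange(int(20 * FS)) / FS
        sig = np.sin(2 * np.pi * freq_hz * t)
        out = preprocess.bandpass_filter(_rec(np.tile(sig, (8, 1)))).data[0]
        core = slice(int(5 * FS), int(15 * FS))  # avoid edge transients
        return np.abs(out[core]).max()

    def test_midband_gain_matches_analytic_response(self):
        gain = self._measure_gain(10.0)
        assert gain == pytest.approx(_analytic_filtfilt_gain(10.0), rel=0.01)
        assert abs(gain - 1.0) < 0.05

    def test_dc_is_removed(self):
        out = preprocess.bandpass_filter(_rec(np.full((8, 5000), 57.0))).data
        assert np.abs(out[:, 1000:-1000]).max() < 1e-6

    def test_45hz_attenuated_at_least_20db(self):
        gain = self._measure_gain(45.0)
        assert 20 * np.log10(gain) < -20
        assert gain == pytest.approx(_analytic_filtfilt_gain(45.0), rel=0.05)

    def test_too_short_signal_errors_with_advice(self):
        with pytest.raises(ValueError, match="pad"):
            preprocess.bandpass_filter(_rec(np.zeros((8, 10))))

    def test_zero_phase_preserves_peak_latency(self, rng):
        """A template's extremum must not shift by more than one sample."""
        t_ms = np.arange(0, 2000, 1000.0 / FS)
        wave = syn.erp_component_waveform(-5.0, 1000.0, 45.0, t_ms)
        rec = _rec(np.tile(wave, (8, 1)))
        out = preprocess.bandpass_filter(rec).data[0]
        assert abs(np.argmin(out) - np.argmin(wave)) <= 1


class TestExtractEpochs:
    def test_epoch_has_300_samples_at_250hz(self, annotated_small_session):
        events, recording, _ = annotated_small_session
        filtered = preprocess.bandpass_filter(recording)
        epochs = preprocess.extract_epochs(filtered, events)
        assert epochs.data.shape[2] == 300
        assert epochs.times_ms[0] == -200.0
        assert epochs.times_ms[-1] == pytest.approx(996.0)

    def test_baseline_mean_is_zero_after_correction(self, annotated_small_session):
        events, recording, _ = annotated_small_session
        epochs = preprocess.extract_epochs(recording, events)
        base = epochs.data[epochs.retained][:, :, epochs.baseline_mask]
        scale = np.abs(epochs.data).max()
        assert np.abs(base.mean(axis=2)).max() < 1e-9 * max(scale, 1.0)

    def test_event_too_close_to_start_flagged_edge(self):
        from gonogo_erp.events import TrialEvent
        rec = _rec(np.zeros((8, 1000)))
        events = [TrialEvent(0.1, "Go", 0), TrialEvent(2.0, "Go", 0)]
        epochs = preprocess.extract_epochs(rec, events)
        assert not epochs.retained[0]
        assert epochs.rejection_reason[0] == "edge"
        assert epochs.retained[1]

    def test_zero_usable_events_errors(self):
        from gonogo_erp.events import TrialEvent
        rec = _rec(np.zeros((8, 100)))
        with pytest.raises(ValueError):
            preprocess.extract_epochs(rec, [TrialEvent(0.01, "Go", 0)])


class TestKurtosisRejection:
    def test_spiked_epoch_is_rejected_and_its_kurtosis_extreme(self, rng):
        data = bandlimited_noise_epochs(rng, 40)
        sd = data.std()
        data[7, :, 150] += 20 * sd  # single-sample spike on every channel
        epochs = make_epochset(data)
        # moment-formula oracle: the spiked epoch's excess kurtosis is huge
        x = data[7, 0]
        m2 = np.mean((x - x.mean()) ** 2)
        m4 = np.mean((x - x.mean()) ** 4)
        assert m4 / m2**2 - 3 > 30
        out = preprocess.reject_by_kurtosis(epochs)
        assert not out.retained[7]
        assert out.rejection_reason[7] == "kurtosis"
        assert out.retained.sum() >= 35  # clean epochs largely kept

    def test_identical_epochs_trigger_degenerate_branch(self, rng):
        one = bandlimited_noise_epochs(rng, 1)
        data = np.repeat(one, 12, axis=0)
        epochs = make_epochset(data)
        with pytest.warns(UserWarning, match="zero variance"):
            out = preprocess.reject_by_kurtosis(epochs)
        assert out.retained.all()

    def test_raw_mode_uses_absolute_threshold(self, rng):
        data = bandlimited_noise_epochs(rng, 20)
        epochs = make_epochset(data)
        out = preprocess.reject_by_kurtosis(epochs, z_threshold=4.0, mode="raw")
        # band-limited noise has near-zero excess kurtosis: nothing over 4
        assert out.retained.all()

    def test_needs_at_least_8_epochs(self, rng):
        epochs = make_epochset(bandlimited_noise_epochs(rng, 5))
        with pytest.raises(ValueError, match="8"):
            preprocess.reject_by_kurtosis(epochs)


class TestBehaviorRejection:
    def test_error_trials_removed_and_clean_kept(self, icd_profile):
        events = syn.generate_trial_sequence(1, 40, 0.7, (0.5, 1.5), 0.5, seed=3)
        annotated = []
        from gonogo_erp.events import GO
        for i, ev in enumerate(events):
            if ev.condition == GO:
                annotated.append(ev.annotate(pressed=(i % 5 != 0), rt_ms=400.0))
            else:
                annotated.append(ev.annotate(pressed=(i % 7 == 0), rt_ms=300.0))
        data = np.zeros((40, 8, 300))
        epochs = make_epochset(data)
        out = preprocess.reject_by_behavior(epochs, annotated)
        for i, ev in enumerate(annotated):
            if ev.is_error:
                assert not out.retained[i]
                assert out.rejection_reason[i] == "behavior"
            else:
                assert out.retained[i]

    def test_all_correct_leaves_mask_unchanged(self, rng):
        from gonogo_erp.events import TrialEvent
        events = [TrialEvent(1.0 + i, "Go", 0).annotate(True, 400.0) for i in range(10)]
        epochs = make_epochset(bandlimited_noise_epochs(rng, 10),
                               conditions=np.array(["Go"] * 10, dtype=object))
        out = preprocess.reject_by_behavior(epochs, events)
        assert out.retained.all()

    def test_count_mismatch_errors(self, rng):
        from gonogo_erp.events import TrialEvent
        epochs = make_epochset(bandlimited_noise_epochs(rng, 4))
        with pytest.raises(ValueError, match="match"):
            preprocess.reject_by_behavior(epochs, [TrialEvent(1.0, "Go", 0)])

    def test_earlier_reasons_are_never_overwritten(self, rng):
        from gonogo_erp.events import TrialEvent
        events = [TrialEvent(1.0 + i, "Go", 0).annotate(False) for i in range(10)]
        epochs = make_epochset(bandlimited_noise_epochs(rng, 10),
                               conditions=np.array(["Go"] * 10, dtype=object))
        epochs.reject([2], "kurtosis")
        out = preprocess.reject_by_behavior(epochs, events)
        assert out.rejection_reason[2] == "kurtosis"  # SE too, but kurtosis came first
        assert out.rejection_reason[3] == "behavior"
        assert not out.retained.any()


class TestOcularRemoval:
    def test_nothing_flagged_reconstruction_is_identity(self, rng):
        data = bandlimited_noise_epochs(rng, 60)
        epochs = make_epochset(data)
        out = preprocess.remove_ocular_components(
            epochs, frontal_ratio_threshold=1e9  # impossible to flag
        )
        assert out.ica_report.flagged == []
        rel = np.abs(out.data - data).max() / np.abs(data).max()
        assert rel < 1e-6

    def test_blink_component_removed_drops_frontal_correlation(self, rng):
        """Criterion: frontal correlation with the blink course falls from
        > 0.6 to < 0.2 once the flagged component is projected out."""
        n_tr, n_t = 64, 300
        clean = bandlimited_noise_epochs(rng, n_tr, n_t)
        blink = syn.blink_waveform(300.0, FS)
        topo = np.asarray(syn.BlinkConfig().topography)
        course = np.zeros((n_tr, n_t))
        for i in rng.choice(n_tr, 24, replace=False):
            s = rng.integers(0, n_t - blink.size)
            course[i, s:s + blink.size] = 150.0 * blink
        epochs = make_epochset(clean + topo[None, :, None] * course[:, None, :])

        def fz_corr(ep):
            return abs(np.corrcoef(ep.data[:, 1, :].ravel(), course.ravel())[0, 1])

        assert fz_corr(epochs) > 0.6
        out = preprocess.remove_ocular_components(epochs, seed=1)
        assert len(out.ica_report.flagged) >= 1
        assert fz_corr(out) < 0.2

    def test_flagged_count_bounded_by_channel_count(self, rng):
        epochs = make_epochset(bandlimited_noise_epochs(rng, 40))
        out = preprocess.remove_ocular_components(epochs, seed=2)
        assert 0 <= len(out.ica_report.flagged) <= 8

    def test_rejects_zscored_input(self, rng):
        epochs = make_epochset(bandlimited_noise_epochs(rng, 10), units="zscore")
        with pytest.raises(ValueError, match="microvolt"):
            preprocess.remove_ocular_components(epochs)


class TestRetention:
    def test_no_rejection_gives_full_retention(self, rng):
        epochs = make_epochset(bandlimited_noise_epochs(rng, 10))
        summary = preprocess.retention_summary(epochs)
        assert summary.fraction == 1.0 and not summary.excluded

    def test_240_trials_24_rejected_is_90_percent(self, rng):
        epochs = make_epochset(np.zeros((240, 8, 10)))
        epochs.reject(np.arange(24), "kurtosis")
        summary = preprocess.retention_summary(epochs)
        assert summary.fraction == pytest.approx(0.90)
        assert not summary.excluded

    def test_below_80_percent_sets_exclusion_flag(self, rng):
        epochs = make_epochset(np.zeros((100, 8, 10)))
        epochs.reject(np.arange(21), "behavior")
        assert preprocess.retention_summary(epochs).excluded

    def test_empty_epochset_errors(self):
        epochs = make_epochset(np.zeros((0, 8, 10)))
        with pytest.raises(ValueError):
            preprocess.retention_summary(epochs)


class TestMonotoneRejection:
    def test_stages_only_shrink_the_retained_set(self, annotated_small_session):
        events, recording, _ = annotated_small_session
        filtered = preprocess.bandpass_filter(recording)
        e1 = preprocess.extract_epochs(filtered, events)
        e2 = preprocess.reject_by_kurtosis(e1)
        e3 = preprocess.reject_by_behavior(e2, events)
        assert set(np.flatnonzero(e2.retained)) <= set(np.flatnonzero(e1.retained))
        assert set(np.flatnonzero(e3.retained)) <= set(np.flatnonzero(e2.retained))
        # reasons persist
        for i in np.flatnonzero(~e2.retained):
            assert e3.rejection_reason[i] == e2.rejection_reason[i]
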