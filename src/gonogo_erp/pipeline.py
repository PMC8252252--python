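"""End-to-end orchestration: simulate/load → preprocess → score → infer.

A :class:`RunConfig` (YAML-backed, strictly validated) carries every
tunable with the study defaults: 1–30 Hz band, −200…1000 ms epochs,
kurtosis threshold 4, N2 200–500 ms / P3 400–700 ms windows, 20,000
permutations, 80% retention rule.  ``run_full_pipeline`` produces the
report bundle: per-session retention and rejection logs, the peak
table, behavioral summaries and contrasts, between-session and
between-group permutation results per component, a latency table, the
peak-change–vs–QUIP-RS association, optional figures, and a provenance
block (config hash, seed, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, analysis, erp, io as gio, stats, synthetic
from .events import GO, NOGO, TrialEvent
from .montage import CHANNELS
from .recording import Recording

MIDLINE_CHANNELS = ("Fz", "FCz", "Cz")


# ---------------------------------------------------------------------------
# configuration


def _strict(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where} config")


@dataclass(frozen=True)
class SimulateConfig:
    group_sizes: dict = field(default_factory=lambda: {"HC": 23, "PD": 20, "ICD": 9})
    attenuation_slope: float = -0.02
    noise_rms_uv: float = 10.0
    noise_exponent: float = 1.0
    blink_rate_per_min: float = 15.0
    blink_amplitude_uv: float = 150.0
    n_blocks: int = 3
    trials_per_block: int = 80
    go_fraction: float = 0.70
    jitter_range_s: tuple[float, float] = (0.5, 1.5)
    stimulus_duration_s: float = 0.5

    def to_cohort_config(self, seed: int) -> synthetic.CohortConfig:
        return synthetic.CohortConfig(
            group_sizes=dict(self.group_sizes),
            protocol=synthetic.ProtocolConfig(
                self.n_blocks, self.trials_per_block, self.go_fraction,
                tuple(self.jitter_range_s), self.stimulus_duration_s,
            ),
            noise=synthetic.NoiseConfig(self.noise_exponent, self.noise_rms_uv),
            blink=dataclasses.replace(
                synthetic.BlinkConfig(),
                rate_per_min=self.blink_rate_per_min,
                amplitude_uv=self.blink_amplitude_uv,
            ),
            attenuation_slope=self.attenuation_slope,
            seed=seed,
        )


@dataclass(frozen=True)
class StatsConfig:
    n_permutations: int = stats.DEFAULT_N_PERMUTATIONS
    alpha: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class ReportConfig:
    make_figures: bool = True


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    input_manifest: Optional[str] = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocessing: analysis.PreprocessParams = field(default_factory=analysis.PreprocessParams)
    components: tuple[erp.ComponentSpec, ...] = erp.DEFAULT_COMPONENTS
    stats: StatsConfig = field(default_factory=StatsConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        _strict(raw, {"out_dir", "seed", "input_manifest", "simulate",
                      "preprocessing", "components", "stats", "report"}, "top-level")
        sim_raw = dict(raw.get("simulate") or {})
        _strict(sim_raw, {f.name for f in dataclasses.fields(SimulateConfig)}, "simulate")
        pre_raw = dict(raw.get("preprocessing") or {})
        _strict(pre_raw, {f.name for f in dataclasses.fields(analysis.PreprocessParams)},
                "preprocessing")
        for key in ("window_ms", "baseline_ms"):
            if key in pre_raw:
                pre_raw[key] = tuple(pre_raw[key])
        stats_raw = dict(raw.get("stats") or {})
        _strict(stats_raw, {f.name for f in dataclasses.fields(StatsConfig)}, "stats")
        rep_raw = dict(raw.get("report") or {})
        _strict(rep_raw, {f.name for f in dataclasses.fields(ReportConfig)}, "report")
        comps = raw.get("components")
        if comps is None:
            components = erp.DEFAULT_COMPONENTS
        else:
            components = tuple(
                erp.ComponentSpec(
                    c["name"], tuple(c["search_window_ms"]), c["polarity"]
                )
                for c in comps
            )
        return RunConfig(
            out_dir=raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
            input_manifest=raw.get("input_manifest"),
            simulate=SimulateConfig(**sim_raw),
            preprocessing=analysis.PreprocessParams(**pre_raw),
            components=components,
            stats=StatsConfig(**stats_raw),
            report=ReportConfig(**rep_raw),
        )

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return RunConfig.from_dict(yaml.safe_load(path.read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["components"] = [dataclasses.asdict(c) for c in self.components]
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort export / loading


def export_cohort(cohort: synthetic.Cohort, out_dir: str | Path) -> Path:
    """Write every session as EDF + events TSV plus a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sub in cohort.subjects:
        prof = sub.profile
        sessions: dict[int, dict[str, str]] = {}
        for session in (1, 2):
            events, recording = sub.realize_session(session)
            stem = f"{prof.subject_id}_ses-{session}"
            gio.write_recording(recording, out_dir / f"{stem}_eeg.edf")
            gio.write_events(
                events, out_dir / f"{stem}_events.tsv",
                stimulus_duration_s=cohort.config.protocol.stimulus_duration_s,
            )
            sessions[session] = {
                "eeg": f"{stem}_eeg.edf",
                "events": f"{stem}_events.tsv",
            }
        entries.append(gio.ManifestEntry(prof.subject_id, prof.group, prof.quip_rs, sessions))
    manifest = gio.CohortManifest(seed=cohort.config.seed, entries=entries)
    return gio.write_cohort_manifest(manifest, out_dir / "manifest.json")


@dataclass(frozen=True)
class SessionInput:
    subject_id: str
    group: str
    quip_rs: float
    session: int
    events: tuple[TrialEvent, ...]
    recording: Recording


def _iter_sessions(config: RunConfig) -> Iterator[SessionInput]:
    if config.input_manifest:
        manifest_path = Path(config.input_manifest)
        manifest = gio.read_cohort_manifest(manifest_path)
        for entry in manifest.entries:
            for session, files in sorted(entry.sessions.items()):
                rec = gio.read_recording(manifest_path.parent / files["eeg"])
                events = gio.read_events(manifest_path.parent / files["events"])
                yield SessionInput(entry.subject_id, entry.group, entry.quip_rs,
                                   session, tuple(events), rec)
    else:
        cohort = synthetic.simulate_cohort(
            config.simulate.to_cohort_config(config.seed)
        )
        for sub in cohort.subjects:
            for session in (1, 2):
                events, rec = sub.realize_session(session)
                yield SessionInput(sub.profile.subject_id, sub.profile.group,
                                   sub.profile.quip_rs, session, tuple(events), rec)


# ---------------------------------------------------------------------------
# statistics over the peak table


def _paired_matrices(peaks: pd.DataFrame, component: str, group: str):
    m1, subs1 = analysis.peak_matrix(peaks, component, 1, group)
    m2, subs2 = analysis.peak_matrix(peaks, component, 2, group)
    if subs1 != subs2:
        raise ValueError(f"subject sets differ between sessions for {group}/{component}")
    return m1, m2, subs1


def run_stats(
    peaks: pd.DataFrame,
    behavior: pd.DataFrame,
    quip_by_subject: dict[str, float],
    components: Sequence[erp.ComponentSpec] = erp.DEFAULT_COMPONENTS,
    stats_config: StatsConfig = StatsConfig(),
) -> dict:
    """All inferential results from the tidy peak/behavior tables."""
    groups = [g for g in ("HC", "PD", "ICD") if (peaks.group == g).any()]
    seed_seq = np.random.SeedSequence(stats_config.seed)
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in seed_seq.spawn(200))
    results: dict = {"channels": list(CHANNELS), "n_permutations": stats_config.n_permutations,
                     "alpha": stats_config.alpha}

    def perm_to_dict(res: stats.PermutationResult) -> dict:
        return {
            "statistic": res.statistic_name,
            "observed": res.observed,
            "raw_p": res.raw_p,
            "fwe_p": res.fwe_p,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
        }

    between_session: dict = {}
    between_group: dict = {}
    for spec in components:
        comp = spec.name
        deltas: dict[str, np.ndarray] = {}
        for group in groups:
            m1, m2, subs = _paired_matrices(peaks, comp, group)
            if len(subs) < 2:
                continue
            res = stats.paired_session_permutation(
                m1, m2, n_perm=stats_config.n_permutations, seed=int(next(seeds))
            )
            between_session.setdefault(comp, {})[group] = perm_to_dict(res)
            deltas[group] = m2 - m1
        tested = [g for g in groups if g in deltas]
        for i, ga in enumerate(tested):
            for gb in tested[i + 1:]:
                res = stats.group_permutation(
                    deltas[ga], deltas[gb],
                    n_perm=stats_config.n_permutations, seed=int(next(seeds)),
                )
                between_group.setdefault(comp, {})[f"{ga}_vs_{gb}"] = perm_to_dict(res)
    results["between_session"] = between_session
    results["between_group_delta"] = between_group

    # behavioral contrasts (paired t for HC/PD, signed-rank for ICD)
    behavioral: dict = {}
    for group in groups:
        gb = behavior[behavior.group == group].sort_values(["subject", "session"])
        by_measure = {}
        for measure in ("rt_mean_ms", "se_count", "ce_count", "total_errors"):
            pivot = gb.pivot(index="subject", columns="session", values=measure).dropna()
            if len(pivot) < 2:
                continue
            res = stats.behavioral_contrast(pivot[1].to_numpy(), pivot[2].to_numpy(), group)
            by_measure[measure] = dataclasses.asdict(res)
        behavioral[group] = by_measure
    results["behavioral"] = behavioral

    # QUIP-RS across groups (Kruskal-Wallis + pairwise rank-sum)
    quip_by_group = {
        g: [quip_by_subject[s] for s in peaks[peaks.group == g].subject.unique()]
        for g in groups
    }
    if all(len(v) >= 2 for v in quip_by_group.values()) and len(groups) >= 2:
        demo = stats.demographics_comparison(quip_by_group)
        results["quip_rs_comparison"] = {
            "kruskal_h": demo.kruskal_h,
            "kruskal_p": demo.kruskal_p,
            "pairwise_p": {f"{a}_vs_{b}": p for (a, b), p in demo.pairwise_p.items()},
        }

    # latency table (mean ± SD per group/session/component at the midline)
    lat = peaks[peaks.channel.isin(MIDLINE_CHANNELS)]
    latency_table = (
        lat.groupby(["group", "component", "channel", "session"])["latency_ms"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .to_dict(orient="records")
    )
    results["latency_table"] = latency_table

    # peak-change vs QUIP-RS association, pooled over the treated groups
    association: dict = {}
    treated = [g for g in ("PD", "ICD") if g in groups]
    spec_by_name = {s.name: s for s in components}
    for comp, spec in spec_by_name.items():
        association[comp] = {}
        for channel in MIDLINE_CHANNELS:
            rows = []
            for group in treated:
                sel = peaks[(peaks.component == comp) & (peaks.channel == channel)
                            & (peaks.group == group)]
                pivot = sel.pivot(index="subject", columns="session", values="amplitude_z")
                pivot = pivot.dropna()
                sign = -1.0 if spec.polarity == "negative" else 1.0
                for subject, row in pivot.iterrows():
                    rows.append((subject, sign * (row[2] - row[1])))
            if len(rows) < 3:
                continue
            delta = np.array([r[1] for r in rows])
            quip = np.array([quip_by_subject[r[0]] for r in rows])
            if np.ptp(quip) == 0:
                continue
            res = stats.association_with_icd(delta, quip)
            association[comp][channel] = dataclasses.asdict(res)
    results["association"] = association
    return results


# ---------------------------------------------------------------------------
# the full pipeline


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load → preprocess → score → infer → report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    peak_frames: list[pd.DataFrame] = []
    retention_rows: list[dict] = []
    behavior_rows: list[dict] = []
    quip_by_subject: dict[str, float] = {}
    excluded_subjects: set[str] = set()
    figure_material: dict[str, analysis.SessionResult] = {}
    pending: dict[str, list[pd.DataFrame]] = {}

    for item in _iter_sessions(config):
        quip_by_subject[item.subject_id] = item.quip_rs
        try:
            epochs, summary = analysis.process_session(
                item.recording, list(item.events), config.preprocessing
            )
        except Exception as exc:  # noqa: BLE001 - stage name + subject propagated
            raise RuntimeError(
                f"preprocessing failed for {item.subject_id} session {item.session}: {exc}"
            ) from exc
        retention_rows.append({
            "subject": item.subject_id, "group": item.group, "session": item.session,
            "n_total": summary.n_total, "n_retained": summary.n_retained,
            "fraction": summary.fraction, "excluded": summary.excluded,
        })
        behavior_rows.append({
            "subject": item.subject_id, "group": item.group, "session": item.session,
            **analysis.behavior_summary(list(item.events)),
        })
        epochs.rejection_log().to_csv(
            out_dir / f"{item.subject_id}_ses-{item.session}_rejection.tsv",
            sep="\t", index=False,
        )
        if summary.excluded:
            excluded_subjects.add(item.subject_id)
            continue
        try:
            scored = analysis.score_session(epochs, config.components)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"peak scoring failed for {item.subject_id} session {item.session}: {exc}"
            ) from exc
        pending.setdefault(item.subject_id, []).append(
            analysis.peaks_to_frame(scored.peaks, item.subject_id, item.group, item.session)
        )
        if config.report.make_figures and item.group not in figure_material and item.session == 1:
            figure_material[item.group] = scored
    for subject, frames in pending.items():
        if subject not in excluded_subjects and len(frames) == 2:
            peak_frames.extend(frames)

    peaks = pd.concat(peak_frames, ignore_index=True) if peak_frames else pd.DataFrame(
        columns=gio.PEAK_COLUMNS[:5] + ["amplitude_z", "latency_ms"]
    )
    retention = pd.DataFrame(retention_rows)
    behavior = pd.DataFrame(behavior_rows)

    gio.write_peak_table(peaks, out_dir / "peaks.csv")
    retention.to_csv(out_dir / "retention.tsv", sep="\t", index=False)
    behavior.to_csv(out_dir / "behavior.csv", index=False)

    results = run_stats(
        peaks, behavior, quip_by_subject,
        components=config.components, stats_config=config.stats,
    ) if not peaks.empty else {}
    results["excluded_subjects"] = sorted(excluded_subjects)
    results["mean_retention"] = float(retention.fraction.mean()) if len(retention) else np.nan
    results["provenance"] = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    gio.write_results_json(results, out_dir / "results.json")
    (out_dir / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    if config.report.make_figures and figure_material:
        _write_figures(figure_material, out_dir / "figures")
    return results


def _write_figures(material: dict[str, analysis.SessionResult], fig_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from . import viz

    fig_dir.mkdir(parents=True, exist_ok=True)
    for group, scored in material.items():
        nogo = scored.profiles.get(NOGO)
        go_profile = None
        try:
            go_profile = erp.average_erp(scored.epochs, GO)
        except ValueError:
            pass
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        profiles = [p for p in (go_profile, nogo) if p is not None]
        viz.plot_erp_profiles(axes[0], profiles, "Cz")
        image = erp.erp_image(scored.epochs, "Cz", NOGO, smoothing_width=10)
        viz.plot_erp_image(axes[1], image, scored.epochs.times_ms, f"{group} NoGo at Cz")
        if nogo is not None:
            n2_vals = {
                ch: erp.find_peak(nogo, ch, erp.N2).amplitude for ch in CHANNELS
            }
            viz.plot_topomap(axes[2], n2_vals, f"{group} N2 amplitude (z)")
        fig.tight_layout()
        fig.savefig(fig_dir / f"{group}_overview.svg")
        plt.close(fig)
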