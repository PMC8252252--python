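"""Synthetic Go/NoGo EEG cohorts with the structure the analysis assumes.

The generator emulates a two-session Go/NoGo study of three groups —
healthy controls (HC), Parkinson's disease (PD) and PD with impulse
control disorder (ICD) — in which both patient groups receive a dopamine
agonist between sessions but only the ICD group's NoGo-locked N2/P3
peaks attenuate in session 2, proportionally to the subject's QUIP-RS
impulse-control score.  Every default is a study condition:

* protocol: 3 blocks x 80 trials, 70% Go, onset-to-onset gap =
  stimulus duration (0.5 s) + uniform jitter in [0.5, 1.5] s, so one
  session yields exactly 168 Go and 72 NoGo trials;
* components: a negative N2 bump (~340 ms) and a positive P3 bump
  (~520 ms), fronto-central midline maxima, added only on NoGo trials;
* background: independent pink (1/f) noise per channel plus stochastic
  blink artifacts with frontal topography;
* behavior: group/session reaction-time and error-probability tables.

Amplitudes are in microvolts throughout; z-units only appear after the
per-epoch baseline standardization downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import scipy.fft

from .events import GO, NOGO, TrialEvent, validate_sequence
from .montage import CHANNELS, DEFAULT_FS_HZ
from .recording import Recording

GROUPS = ("HC", "PD", "ICD")

# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class ProtocolConfig:
    """Go/NoGo presentation schedule."""

    n_blocks: int = 3
    trials_per_block: int = 80
    go_fraction: float = 0.70
    jitter_range_s: tuple[float, float] = (0.5, 1.5)
    stimulus_duration_s: float = 0.5

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("protocol must contain at least one block and one trial")
        if not 0.0 < self.go_fraction <= 1.0:
            raise ValueError("go_fraction must lie in (0, 1]")
        lo, hi = self.jitter_range_s
        if lo > hi:
            raise ValueError("jitter range low must be <= high")
        if self.stimulus_duration_s <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    """Pink background noise: power spectrum ~ 1/f**exponent."""

    exponent: float = 1.0
    rms_uv: float = 10.0


@dataclass(frozen=True)
class BlinkConfig:
    """Ocular artifact model: biphasic low-frequency bumps, frontal-weighted."""

    rate_per_min: float = 15.0
    amplitude_uv: float = 150.0
    duration_ms: float = 300.0
    #: per-channel mixing weights in montage order (F3 Fz F4 FCz C3 Cz C4 CPz)
    topography: tuple[float, ...] = (1.0, 1.0, 1.0, 0.6, 0.25, 0.25, 0.25, 0.1)


@dataclass(frozen=True)
class ComponentParams:
    """One ERP component template for one subject.

    ``amplitude_uv`` is signed (negative for N2, positive for P3) and is
    the value of the waveform at ``latency_ms``; ``topography`` scales it
    per channel in montage order, with fronto-central midline maxima.
    """

    amplitude_uv: float
    latency_ms: float
    width_ms: float
    topography: tuple[float, ...]

    def validate(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("component width must be positive")
        if len(self.topography) != len(CHANNELS):
            raise ValueError("topography must have one weight per montage channel")
        if any(not 0.0 <= w <= 1.0 for w in self.topography):
            raise ValueError("topographic weights must lie in [0, 1]")


@dataclass(frozen=True)
class SessionBehavior:
    rt_mean_ms: float
    rt_sd_ms: float
    p_se: float  # miss probability on Go trials
    p_ce: float  # false-press probability on NoGo trials

    def validate(self) -> None:
        if self.rt_sd_ms < 0:
            raise ValueError("RT standard deviation must be >= 0")
        for p in (self.p_se, self.p_ce):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str
    quip_rs: float
    components: dict[str, ComponentParams]  # keys "N2", "P3"
    behavior: dict[int, SessionBehavior]  # keys 1, 2
    #: amplitude change per QUIP-RS point applied to session-2 component
    #: magnitudes, ICD group only; negative values model deterioration.
    attenuation_slope: float = 0.0

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.quip_rs < 0:
            raise ValueError("QUIP-RS score must be >= 0")
        for comp in self.components.values():
            comp.validate()
        for beh in self.behavior.values():
            beh.validate()

    def session_amplitude(self, component: str, session: int) -> float:
        """Signed template amplitude for *component* in *session*.

        Attenuation applies only to the ICD group in session 2: the
        magnitude is scaled by ``max(0, 1 + attenuation_slope * quip_rs)``.
        """
        amp = self.components[component].amplitude_uv
        if self.group == "ICD" and session == 2:
            amp *= max(0.0, 1.0 + self.attenuation_slope * self.quip_rs)
        return amp


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 23, "PD": 20, "ICD": 9}
    )
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    blink: BlinkConfig = field(default_factory=BlinkConfig)
    attenuation_slope: float = -0.02
    fs_hz: float = DEFAULT_FS_HZ
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be >= 0")
        self.protocol.validate()
        if self.noise.rms_uv < 0 or self.blink.rate_per_min < 0:
            raise ValueError("noise RMS and blink rate must be >= 0")


# ---------------------------------------------------------------------------
# group-level default tables (microvolts, milliseconds, probabilities)

#: Session-wise behavior per group.  Reaction-time moments follow the
#: reported group trajectories (ICD speeds up ~9 ms after treatment, PD
#: slows ~8 ms, HC speeds up ~4 ms); SE/CE probabilities are mean error
#: counts divided by the 168 Go / 72 NoGo trials of a session.
DEFAULT_BEHAVIOR: dict[str, dict[int, SessionBehavior]] = {
    "HC": {
        1: SessionBehavior(430.0, 80.0, 0.48 / 168, 1.04 / 72),
        2: SessionBehavior(426.0, 80.0, 1.35 / 168, 0.91 / 72),
    },
    "PD": {
        1: SessionBehavior(520.0, 100.0, 2.50 / 168, 3.45 / 72),
        2: SessionBehavior(528.0, 100.0, 2.35 / 168, 2.85 / 72),
    },
    "ICD": {
        1: SessionBehavior(483.9, 93.8, 0.78 / 168, 1.22 / 72),
        2: SessionBehavior(474.5, 104.7, 2.11 / 168, 2.11 / 72),
    },
}

#: Topographies: midline fronto-central maxima; P3 additionally spreads
#: laterally toward F3/F4.
N2_TOPOGRAPHY = (0.60, 1.00, 0.60, 1.00, 0.55, 0.90, 0.55, 0.50)
P3_TOPOGRAPHY = (0.75, 0.90, 0.75, 1.00, 0.60, 1.00, 0.60, 0.70)

#: Population moments for subject-level component parameters:
#: (mean amplitude uV, amplitude SD, mean latency ms, latency SD, width ms).
COMPONENT_POPULATION = {
    "N2": (-4.0, 1.0, 340.0, 30.0, 45.0),
    "P3": (5.0, 1.25, 520.0, 50.0, 70.0),
}

#: Patient groups show weaker peaks than controls.
GROUP_AMPLITUDE_SCALE = {"HC": 1.0, "PD": 0.75, "ICD": 0.75}

#: Latencies are kept inside the peak search windows (N2 200-500 ms,
#: P3 400-700 ms) with margin for the template width.
LATENCY_CLIP = {"N2": (250.0, 450.0), "P3": (450.0, 650.0)}

#: QUIP-RS population moments (mean, SD) for truncated-normal sampling;
#: controls are asymptomatic.
QUIP_MOMENTS = {"HC": (0.0, 0.0), "PD": (0.45, 1.15), "ICD": (16.00, 12.32)}


# ---------------------------------------------------------------------------
# operations


def generate_trial_sequence(
    n_blocks: int,
    trials_per_block: int,
    go_fraction: float,
    jitter_range_s: Sequence[float],
    stimulus_duration_s: float,
    seed: int | np.random.Generator,
) -> list[TrialEvent]:
    """Generate a balanced, shuffled Go/NoGo stimulus schedule.

    Each block contains exactly ``round(go_fraction * trials_per_block)``
    Go trials in uniformly shuffled order.  Consecutive onsets are spaced
    by ``stimulus_duration_s`` plus a uniform jitter drawn from
    ``jitter_range_s``; the first stimulus starts one full gap after
    recording start so the pre-stimulus baseline always exists.

    Raises
    ------
    ValueError
        If the balanced split is not an integer number of trials, or the
        protocol is empty or the jitter range inverted.
    """
    proto = ProtocolConfig(
        n_blocks, trials_per_block, go_fraction,
        (float(jitter_range_s[0]), float(jitter_range_s[1])), stimulus_duration_s,
    )
    proto.validate()
    n_go_f = go_fraction * trials_per_block
    n_go = round(n_go_f)
    if abs(n_go_f - n_go) > 1e-9:
        raise ValueError(
            f"go_fraction {go_fraction} x {trials_per_block} trials/block is not an "
            f"integer; the balanced design requires an exact Go/NoGo split"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = proto.jitter_range_s

    events: list[TrialEvent] = []
    t = 0.0
    for block in range(n_blocks):
        conditions = np.array([GO] * n_go + [NOGO] * (trials_per_block - n_go))
        rng.shuffle(conditions)
        for cond in conditions:
            t += stimulus_duration_s + rng.uniform(lo, hi)
            events.append(TrialEvent(onset_s=t, condition=str(cond), block_index=block))
    return validate_sequence(events)


def simulate_behavior(
    events: Iterable[TrialEvent],
    profile: SubjectProfile,
    session: int,
    seed: int | np.random.Generator,
) -> list[TrialEvent]:
    """Annotate a stimulus schedule with presses, RTs and error flags.

    Go trials are pressed with probability ``1 - p_se`` and the RT is
    drawn from a normal truncated at zero with the profile's session
    moments; NoGo trials are pressed with probability ``p_ce``.
    """
    beh = profile.behavior[session]
    beh.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[TrialEvent] = []
    for ev in events:
        if ev.annotated:
            raise ValueError("events are already annotated")
        if ev.condition == GO:
            pressed = rng.uniform() >= beh.p_se
        else:
            pressed = rng.uniform() < beh.p_ce
        rt = _truncated_normal_rt(rng, beh.rt_mean_ms, beh.rt_sd_ms) if pressed else None
        out.append(ev.annotate(pressed=pressed, rt_ms=rt))
    return out


def _truncated_normal_rt(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from N(mean, sd) truncated to (0, inf) by rejection."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate RT distribution with non-positive mean")
        return mean
    while True:
        rt = rng.normal(mean, sd)
        if rt > 0:
            return rt


def erp_component_waveform(
    amplitude: float,
    latency_ms: float,
    width_ms: float,
    times_ms: np.ndarray,
) -> np.ndarray:
    """Gaussian-bump component template on a time axis.

    The waveform equals *amplitude* at ``latency_ms``, decays
    symmetrically with scale ``width_ms`` and is exactly zero beyond
    four widths from the peak.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.size == 0:
        raise ValueError("empty time axis")
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    u = (times_ms - latency_ms) / width_ms
    wave = amplitude * np.exp(-0.5 * u**2)
    wave[np.abs(u) > 4.0] = 0.0
    return wave


def pink_noise(
    n_samples: int,
    fs_hz: float,
    exponent: float,
    rms_uv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f**exponent noise of a given RMS amplitude, one channel."""
    return _pink_noise_block(1, n_samples, fs_hz, exponent, rms_uv, rng)[0]


def _pink_noise_block(
    n_channels: int,
    n_samples: int,
    fs_hz: float,
    exponent: float,
    rms_uv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent pink-noise channels in one batched FFT."""
    if rms_uv == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    # pad to a fast FFT length, shape the spectrum, then truncate
    n_fft = scipy.fft.next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, n_fft))
    spectrum = scipy.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs_hz)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    noise = scipy.fft.irfft(spectrum * shaping[None, :], n=n_fft, axis=1)[:, :n_samples]
    noise *= rms_uv / np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
    return noise


def blink_waveform(duration_ms: float, fs_hz: float) -> np.ndarray:
    """Biphasic low-frequency blink bump (unit peak amplitude)."""
    n = max(int(round(duration_ms / 1000.0 * fs_hz)), 3)
    t = np.linspace(0.0, 1.0, n)
    main = np.exp(-0.5 * ((t - 0.4) / 0.16) ** 2)
    rebound = -0.25 * np.exp(-0.5 * ((t - 0.78) / 0.14) ** 2)
    wave = main + rebound
    return wave / np.max(np.abs(wave))


def simulate_recording(
    events: Sequence[TrialEvent],
    profile: SubjectProfile,
    session: int,
    config: CohortConfig,
    seed: int | np.random.Generator,
) -> Recording:
    """Render one continuous 8-channel session in microvolts.

    Output = pink background noise + N2/P3 templates on every NoGo trial
    (scaled per channel by the component topography and, for ICD session
    2, attenuated in proportion to QUIP-RS) + blink artifacts at the
    configured rate with frontal weighting.  The recording extends 1.5 s
    past the last stimulus onset.
    """
    config.validate()
    profile.validate()
    events = validate_sequence(events)
    if not events:
        raise ValueError("cannot simulate a recording without events")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = config.fs_hz
    n_channels = len(CHANNELS)
    duration_s = events[-1].onset_s + 1.5
    n_samples = int(np.ceil(duration_s * fs))

    data = _pink_noise_block(
        n_channels, n_samples, fs, config.noise.exponent, config.noise.rms_uv, rng
    )

    # NoGo-locked ERP components
    template_t = np.arange(0, int(round(1.0 * fs))) / fs * 1000.0  # 0..1000 ms
    for name in ("N2", "P3"):
        comp = profile.components[name]
        amp = profile.session_amplitude(name, session)
        wave = erp_component_waveform(amp, comp.latency_ms, comp.width_ms, template_t)
        topo = np.asarray(comp.topography)
        for ev in events:
            if ev.condition != NOGO:
                continue
            start = int(round(ev.onset_s * fs))
            stop = start + wave.size
            if stop > n_samples:
                raise ValueError("event response extends beyond the requested duration")
            data[:, start:stop] += topo[:, None] * wave[None, :]

    # blink artifacts: Poisson arrivals, frontal topography
    if config.blink.rate_per_min > 0 and config.blink.amplitude_uv > 0:
        blink = blink_waveform(config.blink.duration_ms, fs)
        topo = np.asarray(config.blink.topography)
        n_blinks = rng.poisson(config.blink.rate_per_min * duration_s / 60.0)
        starts = np.sort(rng.integers(0, max(n_samples - blink.size, 1), size=n_blinks))
        for start in starts:
            stop = start + blink.size
            scale = config.blink.amplitude_uv * rng.uniform(0.7, 1.3)
            data[:, start:stop] += topo[:, None] * (scale * blink)[None, :]

    return Recording(
        subject_id=profile.subject_id,
        session=session,
        channel_labels=list(CHANNELS),
        fs_hz=fs,
        data=data,
        reference_note="synthetic; linked-earlobe reference emulation",
    )


# ---------------------------------------------------------------------------
# cohort assembly


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return max(mean, 0.0)
    while True:
        x = rng.normal(mean, sd)
        if x >= 0:
            return x


def default_profile(
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    attenuation_slope: float,
    quip_rs: Optional[float] = None,
) -> SubjectProfile:
    """Draw one subject's parameters from the group-level population model."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if quip_rs is None:
        quip_rs = _truncated_normal(rng, *QUIP_MOMENTS[group])
    components = {}
    for name, (amp_mu, amp_sd, lat_mu, lat_sd, width) in COMPONENT_POPULATION.items():
        scale = GROUP_AMPLITUDE_SCALE[group]
        amp = rng.normal(amp_mu * scale, amp_sd)
        # keep the component's polarity: N2 stays negative, P3 positive
        if amp_mu < 0:
            amp = min(amp, -0.5)
        else:
            amp = max(amp, 0.5)
        lat = float(np.clip(rng.normal(lat_mu, lat_sd), *LATENCY_CLIP[name]))
        topo = N2_TOPOGRAPHY if name == "N2" else P3_TOPOGRAPHY
        components[name] = ComponentParams(amp, lat, width, topo)
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        quip_rs=float(quip_rs),
        components=components,
        behavior={s: DEFAULT_BEHAVIOR[group][s] for s in (1, 2)},
        attenuation_slope=attenuation_slope if group == "ICD" else 0.0,
    )


@dataclass
class SubjectRecord:
    """One cohort member: profile plus deterministic per-session seeds.

    Recordings are rendered lazily (a full cohort held eagerly would be
    hundreds of megabytes); ``realize_session`` is deterministic given
    the cohort seed.
    """

    profile: SubjectProfile
    session_seeds: dict[int, np.random.SeedSequence]
    config: CohortConfig

    def realize_session(self, session: int) -> tuple[list[TrialEvent], Recording]:
        ss = self.session_seeds[session]
        ev_rng, beh_rng, rec_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
        p = self.config.protocol
        events = generate_trial_sequence(
            p.n_blocks, p.trials_per_block, p.go_fraction,
            p.jitter_range_s, p.stimulus_duration_s, ev_rng,
        )
        events = simulate_behavior(events, self.profile, session, beh_rng)
        recording = simulate_recording(events, self.profile, session, self.config, rec_rng)
        return events, recording


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectRecord]

    def __len__(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.profile.group == group]


def simulate_cohort(
    config: CohortConfig | None = None,
    profiles: Optional[Sequence[SubjectProfile]] = None,
    profile_generator: Optional[Callable[[str, str, np.random.Generator], SubjectProfile]] = None,
    seed: Optional[int] = None,
) -> Cohort:
    """Assemble a two-session cohort (HC/PD/ICD by default).

    Profiles may be supplied explicitly, produced by a custom
    ``profile_generator(subject_id, group, rng)``, or drawn from the
    default population model.  Only ICD subjects carry a nonzero
    attenuation slope, so only their session-2 peaks differ from
    session 1 in expectation.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    root = np.random.SeedSequence(config.seed)
    profile_ss, session_ss = root.spawn(2)
    profile_rng = np.random.default_rng(profile_ss)

    if profiles is None:
        profiles = []
        for group in GROUPS:
            for i in range(config.group_sizes.get(group, 0)):
                sid = f"sub-{group}{i + 1:02d}"
                if profile_generator is not None:
                    prof = profile_generator(sid, group, profile_rng)
                else:
                    prof = default_profile(sid, group, profile_rng, config.attenuation_slope)
                profiles.append(prof)
    seen: set[str] = set()
    for prof in profiles:
        prof.validate()
        if prof.subject_id in seen:
            raise ValueError(f"duplicate subject_id {prof.subject_id!r}")
        seen.add(prof.subject_id)

    subject_seeds = session_ss.spawn(len(profiles))
    subjects = []
    for prof, ss in zip(profiles, subject_seeds):
        s1, s2 = ss.spawn(2)
        subjects.append(SubjectRecord(prof, {1: s1, 2: s2}, config))
    return Cohort(config=config, subjects=subjects)
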