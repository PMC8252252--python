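# Methods

This package implements a complete analysis chain for two-session
Go/NoGo EEG studies of impulse control, together with a synthetic
cohort generator that reproduces the statistical structure such a study
assumes. Everything below is the package's own account of what it
computes and why; all empirical statements are reproduced by the test
suite or by `scripts/acceptance.py`.

## The study design being modeled

Three groups perform a visual Go/NoGo task twice: healthy controls
(HC), Parkinson's disease patients (PD), and PD patients with a
dopamine-agonist-induced impulse control disorder (ICD). Both patient
groups receive their dopamine agonist between the sessions. The working
hypothesis is that successful NoGo inhibition elicits a fronto-central
N2 (negative, ~200–400 ms) and P3 (positive, ~400–600 ms), and that in
the ICD group — and only there — these peaks weaken in session 2, in
proportion to the QUIP-RS impulse-control score.

A session is three 80-trial blocks with 70 % Go trials, so exactly
168 Go and 72 NoGo stimuli. Trials are spaced by the stimulus duration
plus a uniform 0.5–1.5 s jitter. EEG is recorded from eight
fronto-central electrodes (F3, Fz, F4, FCz, C3, Cz, C4, CPz) at 250 Hz.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions.

* **Trial schedule** — per-block exact balancing (56 Go / 24 NoGo)
  in uniformly shuffled order, rather than Bernoulli draws, because the
  design prescribes exact totals. Onset-to-onset gap = stimulus
  duration (0.5 s, a convention: display duration is not part of the
  design) + uniform jitter.
* **Behavior** — Go trials are pressed with probability 1 − P(SE) and
  the reaction time is drawn from a normal truncated at zero (only
  mean ± SD are meaningful inputs); NoGo trials are pressed with
  probability P(CE). The group/session RT moments and error
  probabilities follow the published group trajectories (e.g. ICD Go RT
  483.9 ± 93.8 ms in session 1, 474.5 ± 104.7 ms in session 2; error
  probabilities are mean error counts divided by 168 Go or 72 NoGo
  trials).
* **ERP components** — Gaussian bumps (compactly supported at ±4
  widths) added on NoGo trials only. Population defaults: N2 amplitude
  −4 µV (SD 1), latency 340 ms (SD 30, clipped into the search window),
  width 45 ms; P3 +5 µV (SD 1.25), latency 520 ms (SD 50), width 70 ms.
  Patient groups carry a 0.75 amplitude scale relative to HC.
  Topographic weights have fronto-central midline maxima; P3 spreads
  laterally toward F3/F4.
* **Treatment effect** — for ICD subjects in session 2 the component
  magnitude is multiplied by `max(0, 1 + slope · QUIP-RS)`. The default
  slope is −0.02 per QUIP-RS point, chosen a priori so that, with ~65
  retained NoGo trials per session (average-noise SD ≈ 0.12 z) and the
  ICD QUIP-RS spread (16.0 ± 12.3 vs. PD 0.45 ± 1.15), the pooled
  PD+ICD Δpeak–QUIP-RS correlation lands in the moderate regime
  (|r| ≈ 0.3–0.5) reported for real cohorts of this size. HC and PD
  subjects have slope 0 — with `attenuation_slope = 0` the generator
  contains *no* session effect anywhere, which is what makes the
  type-I-error checks meaningful.
* **QUIP-RS scores** — truncated normals at 0 with the group moments
  above; HC is fixed at 0.
* **Background** — independent 1/f (pink) noise per channel, RMS
  10 µV, plus Poisson blink artifacts (15/min, 150 µV) with a biphasic
  ~300 ms template and frontal topography (F3/Fz/F4 weight 1.0 falling
  to 0.1 at CPz). There is no volume-conduction head model and no
  cross-channel noise correlation; consequences are discussed under
  Limitations.

Recordings are rendered lazily per subject-session (an eager default
cohort would hold hundreds of megabytes); everything is deterministic
given the cohort seed via spawned seed sequences.

## Preprocessing

1. **Band-pass 1–30 Hz** — 4th-order Butterworth applied
   forward-backward (zero phase). The zero-phase realization is a
   design choice: peak *latencies* are measurands here, and a causal
   filter would bias them by its group delay. The property suite checks
   that a template's extremum moves by at most one sample.
2. **Epoching** — −200 to 1000 ms around stimulus onset, half-open
   sample window (300 samples at 250 Hz), baseline subtraction of the
   pre-stimulus mean. Events too close to the recording edge are
   flagged (`edge`), never silently dropped.
3. **Kurtosis rejection** — per channel, the excess kurtosis of each
   epoch is z-scored across epochs and the epoch is rejected when any
   channel exceeds z = 4 (`kurtosis`). This is the standardized-measure
   convention of the common EEG toolboxes; a raw-kurtosis threshold is
   available via `mode="raw"`. The deterministic rule replaces manual
   visual inspection, which cannot be reproduced.
4. **Behavioral rejection** — epochs whose trial carries an SE (missed
   Go press) or CE (NoGo press) are discarded (`behavior`).
5. **Ocular ICA** — extended-infomax ICA (via MNE) on the concatenated
   retained epochs, as many components as channels. A component is
   flagged as ocular when its scalp pattern is frontal-dominant (mean
   |weight| at F3/Fz/F4 > 2× the mean at C3/Cz/C4/CPz) *and* more than
   60 % of its source power lies below 5 Hz. Flagged components are
   zeroed and the rest back-projected. The automated rule replaces
   expert component inspection; both thresholds are configurable.
   As in real pipelines, zeroing an ocular component also discards
   whatever ERP variance it carries, so frontal (Fz) peak amplitudes
   come out slightly attenuated relative to a blink-free analysis.
   Numerical notes: the fit runs on decimated data (~20 k samples),
   with the decimation factor capped so the effective rate stays above
   twice the 30 Hz passband — stronger decimation aliases the sources
   toward Gaussianity and infomax stalls. Infomax anneals up to its
   iteration cap as normal termination; a divergence (non-finite
   unmixing matrix) raises an error suggesting a different seed.
6. **Retention rule** — a subject-session retaining < 80 % of its
   epochs is excluded from group analysis.

Rejection is monotone and auditable: each stage can only shrink the
retained set, a reason is never overwritten, and per-stage logs are
written as TSV.

## ERP quantification

Each retained epoch is z-standardized against its own pre-stimulus
baseline (subtract the baseline mean, divide by the baseline SD, per
channel; a pooled-channel SD is available as a config option). Epochs
with a zero-variance baseline cannot be standardized and are excluded
with reason `baseline` — this is why the noiseless peak-recovery check
operates in microvolts: with zero noise every baseline is constant and
z-scaling is undefined, while peak finding itself is unit-agnostic.

Condition averages are pointwise means over retained epochs. Peaks are
scored as the extremum *sample* in the search window — N2: minimum in
200–500 ms; P3: maximum in 400–700 ms — window endpoints inclusive,
ties broken to the earliest time. A window-edge extremum is accepted:
the measurand is the maximal deflection, and the edge rule keeps the
score deterministic. ERP images are trial × time rasters smoothed by a
10-trial centered moving average, truncated at the raster edges.

Between-session contrasts use Δ = session 2 − session 1 per
subject/channel/component on the signed amplitude. For the
impulse-score association the amplitude is first rectified into the
component's polarity direction (N2 magnitude = −amplitude), so that
*deterioration of either component is a negative Δ* and a negative
attenuation slope yields a negative correlation — one sign convention
throughout.

## Inference

* **Within group, between sessions** — per-channel paired t statistics;
  the null distribution is built by sign-flipping whole per-subject
  difference rows (20,000 permutations by default), which preserves the
  cross-channel correlation structure.
* **Between groups** — pooled-variance two-sample t per channel; null
  by shuffling whole-subject group labels.
* **P-values** — add-one two-sided: p = (1 + #{|T*| ≥ |T|}) / (n_perm
  + 1), floored at 1/(n_perm + 1); a permutation reproducing the
  observed assignment counts as a tie despite float-summation noise
  (a relative tolerance of 1e−10 on |T|). Family-wise error over the
  eight channels is controlled with the max-|T| permutation
  distribution — the standard strong-control choice for multichannel
  ERP; fwe_p ≥ raw_p channel-wise by construction. The t statistic
  (rather than the raw mean difference) is the default because it is
  variance-stabilizing; zero-variance channels yield p = 1 with a
  warning.
* **Behavioral contrasts** — paired t for HC/PD, Wilcoxon signed-rank
  (exact null when feasible, zeros dropped) for the small ICD group.
* **Across groups** — Kruskal–Wallis with tie correction plus pairwise
  rank-sum p-values, uncorrected (the convention for small feasibility
  cohorts).
* **Association** — Pearson r with the t-transform p and the
  least-squares line, pooled over the treated PD + ICD subjects
  (n = 29 at the default design); a per-group analysis is a one-line
  variation on the same function.

## Problem sizes in the verification suite

The acceptance checks run at sizes chosen to give stable Monte-Carlo
estimates on a single CPU: 500 null datasets × 2,000 permutations for
calibration; 50,000 permutations against the 2⁵ and C(8,4) exhaustive
enumerations; 100 simulated cohorts for the association-sign and
null-false-positive checks (the acceptance script uses 40); the
association cohorts are generated blink-free and analyzed without the
ICA stage — there is nothing ocular to remove, and every other stage
(filter, epoch, reject, z-score, average, score) runs. The full
pipeline including ICA runs on the complete 52-subject default cohort
in the acceptance script.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of a real study:
exact trial counts, group sizes, score distributions, NoGo-locked
components with subject variability, blinks, and a dose-dependent
session-2 attenuation confined to one group. It does not model volume
conduction, correlated background EEG across channels, non-stationary
artifacts (drift, movement, electrode pops), latency *shifts* under
treatment, or any pharmacokinetics. Passing tests therefore demonstrate
that the pipeline measures what the model puts in — calibrated error
rates, faithful peak recovery, effective ocular cleanup — not that real
patient effects of a given size would be detected; statements about
real cohorts require real recordings.

## Other numerical choices and degenerate inputs

* EDF storage is 16-bit with a ±1000 µV physical range (quantization
  step ≈ 0.031 µV) and a symmetric digital range so 0 µV is exact; the
  final 1-s record is zero-padded and the true sample count kept in the
  reserved header field so round trips restore length exactly.
* Kurtosis z-scoring needs ≥ 8 retained epochs; a zero-variance
  kurtosis spread disables rejection on that channel with a warning.
* The balanced design requires `go_fraction × trials_per_block` to be
  an integer; anything else is rejected with an explicit message.
* Identical paired vectors yield t = 0, p = 1 rather than NaN;
  all-zero signed-rank differences yield p = 1 with a warning; constant
  QUIP-RS vectors make the correlation undefined and raise.
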