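"""Permutation inference and classical contrasts for peak measures.

Between-session effects within a group are tested by sign-flip
permutation of per-subject difference vectors (whole-subject flips, so
the cross-channel correlation structure is preserved); between-group
effects by whole-subject group-label shuffles.  The test statistic is a
t-statistic (paired or two-sample); the family-wise error rate over the
channel set is controlled with the max-|T| permutation distribution.
P-values use the add-one formula ``(1 + #{|T*| >= |T|}) / (n_perm + 1)``,
so the smallest achievable p is ``1/(n_perm + 1)`` and the estimate is
valid (never anti-conservative) under exchangeability.

Behavioral and demographic contrasts delegate to the classical tests:
paired t for the larger (HC/PD) groups, Wilcoxon signed-rank for the
small ICD group, Kruskal–Wallis plus pairwise rank-sum across groups,
and Pearson/least-squares for the peak-change–vs–QUIP-RS association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

DEFAULT_N_PERMUTATIONS = 20_000


@dataclass
class PermutationResult:
    statistic_name: str
    observed: np.ndarray  # per channel
    raw_p: np.ndarray
    fwe_p: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.fwe_p + 1e-12 < self.raw_p):
            raise AssertionError("FWE-corrected p-values must dominate raw p-values")


@dataclass
class AssociationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def _paired_t(mean: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    """t = mean / (sd/sqrt(n)) from the mean and raw sum of squares."""
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return t


def _finalize(
    name: str,
    t_obs: np.ndarray,
    t_null: np.ndarray,
    n_perm: int,
    seed: int,
    undefined: np.ndarray,
) -> PermutationResult:
    """Add-one raw p per channel and max-|T| FWE p across channels."""
    abs_obs = np.abs(t_obs)
    abs_null = np.abs(t_null)  # (n_perm, n_channels)
    # a permutation reproducing the observed assignment must count as a tie
    # despite float-summation noise
    thresh = abs_obs * (1.0 - 1e-10) - 1e-12
    raw = (1 + (abs_null >= thresh[None, :]).sum(axis=0)) / (n_perm + 1)
    max_null = np.nanmax(np.where(np.isfinite(abs_null), abs_null, 0.0), axis=1)
    fwe = (1 + (max_null[:, None] >= thresh[None, :]).sum(axis=0)) / (n_perm + 1)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} channel(s) have zero-variance data; "
            f"their statistic is undefined and p set to 1",
            stacklevel=3,
        )
        t_obs = np.where(undefined, 0.0, t_obs)
        raw = np.where(undefined, 1.0, raw)
        fwe = np.where(undefined, 1.0, fwe)
    fwe = np.maximum(fwe, raw)
    return PermutationResult(
        statistic_name=name,
        observed=np.asarray(t_obs, dtype=float),
        raw_p=raw,
        fwe_p=fwe,
        n_permutations=n_perm,
        seed=seed,
    )


def paired_session_permutation(
    measures_s1: np.ndarray,
    measures_s2: np.ndarray,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> PermutationResult:
    """Sign-flip permutation test of session 2 − session 1 differences.

    Parameters are subjects x channels matrices with identical subject
    order.  The observed statistic is the per-channel paired t; the null
    is built by flipping the sign of whole per-subject difference rows.
    """
    d = np.asarray(measures_s2, dtype=float) - np.asarray(measures_s1, dtype=float)
    if d.ndim == 1:
        d = d[:, None]  # single channel
    n, n_ch = d.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    ss = (d**2).sum(axis=0)
    undefined = ss - n * d.mean(axis=0) ** 2 <= 1e-300
    t_obs = _paired_t(d.mean(axis=0), ss, n)

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1  # ±1
    mean_null = flips @ d / n  # (n_perm, n_ch); sum of squares is flip-invariant
    t_null = _paired_t(mean_null, ss[None, :], n)
    return _finalize("paired_t_signflip", t_obs, t_null, n_perm, seed, undefined)


def _two_sample_t(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column."""
    na, nb = x_a.shape[0], x_b.shape[0]
    ma, mb = x_a.mean(axis=0), x_b.mean(axis=0)
    va = x_a.var(axis=0, ddof=1)
    vb = x_b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def group_permutation(
    measures_a: np.ndarray,
    measures_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> PermutationResult:
    """Label-shuffle permutation test of a between-group difference.

    Whole subject rows are permuted between the two groups; the observed
    statistic is the pooled-variance two-sample t per channel.
    """
    a = np.atleast_2d(np.asarray(measures_a, dtype=float))
    b = np.atleast_2d(np.asarray(measures_b, dtype=float))
    if np.asarray(measures_a).ndim == 1:
        a, b = a.T, b.T
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the channel set")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    pooled = np.vstack([a, b])
    undefined = pooled.var(axis=0) <= 1e-300
    t_obs = _two_sample_t(a, b)

    rng = np.random.default_rng(seed)
    t_null = np.empty((n_perm, a.shape[1]))
    order = np.arange(na + nb)
    for i in range(n_perm):
        perm = rng.permutation(order)
        t_null[i] = _two_sample_t(pooled[perm[:na]], pooled[perm[na:]])
    return _finalize("two_sample_t_shuffle", t_obs, t_null, n_perm, seed, undefined)


# ---------------------------------------------------------------------------
# classical contrasts


@dataclass
class ContrastResult:
    test_name: str
    statistic: float
    p: float
    n: int


def behavioral_contrast(values_s1, values_s2, group: str) -> ContrastResult:
    """Between-session behavioral contrast with the group-size rule.

    HC and PD use the paired-sample t-test; the small ICD group uses the
    Wilcoxon signed-rank test (exact null when feasible, zero
    differences dropped).  Two-sided throughout.
    """
    x = np.asarray(values_s1, dtype=float)
    y = np.asarray(values_s2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    if group in ("HC", "PD"):
        if np.allclose(x, y):
            return ContrastResult("paired_t", 0.0, 1.0, x.size)
        res = scipy.stats.ttest_rel(y, x)
        return ContrastResult("paired_t", float(res.statistic), float(res.pvalue), x.size)
    if group == "ICD":
        d = y - x
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; signed-rank p set to 1", stacklevel=2)
            return ContrastResult("wilcoxon_signed_rank", 0.0, 1.0, x.size)
        nz = np.count_nonzero(d)
        method = "exact" if nz <= 25 else "auto"
        res = scipy.stats.wilcoxon(y, x, zero_method="wilcox", method=method)
        return ContrastResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), x.size)
    raise ValueError(f"unknown group {group!r}")


@dataclass
class DemographicsResult:
    kruskal_h: float
    kruskal_p: float
    pairwise_p: dict  # (group_i, group_j) -> rank-sum p, uncorrected


def demographics_comparison(values_by_group: dict) -> DemographicsResult:
    """Kruskal–Wallis across the three groups plus pairwise rank-sum tests.

    Pairwise p-values are uncorrected, matching how small feasibility
    cohorts are conventionally reported.
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    for g, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")
    if all(np.array_equal(samples[0], s) for s in samples[1:]) and all(
        np.ptp(s) == 0 for s in samples
    ):
        h, p = 0.0, 1.0
    else:
        h, p = scipy.stats.kruskal(*samples)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            stat = scipy.stats.ranksums(samples[i], samples[j])
            pairwise[(names[i], names[j])] = float(stat.pvalue)
    return DemographicsResult(float(h), float(p), pairwise)


def association_with_icd(delta_peaks, quip_scores) -> AssociationResult:
    """Pearson correlation and least-squares line between per-subject
    peak-magnitude changes and QUIP-RS impulse-control scores."""
    x = np.asarray(quip_scores, dtype=float)
    y = np.asarray(delta_peaks, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("delta_peaks and quip_scores must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 subjects for the association")
    if np.ptp(x) == 0:
        raise ValueError("QUIP-RS scores are constant; correlation undefined")
    lr = scipy.stats.linregress(x, y)
    return AssociationResult(
        r=float(lr.rvalue),
        p=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=x.size,
    )
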