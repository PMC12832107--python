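"""Allelic-choice skew, passage stability, compensation and cis-coupling.

These are the downstream statistics applied to a focal monoallelic gene
once per-clone states are known: how strongly the allelic choice is skewed
toward one parental allele (fold bias plus an exact binomial test of the
balanced-choice null), whether the allelic ratio drifts over passages,
whether monoallelic clones over- or under-express the gene relative to
bi-allelic clones (Welch t), and whether a neighboring gene's allelic
ratio moves inversely with the focal gene's (Pearson r / R^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SkewResult",
    "CouplingResult",
    "allelic_fold_bias",
    "balance_test",
    "skew_summary",
    "stability_drift",
    "compensation_test",
    "cis_coupling",
    "allelic_expression_difference",
    "ar_distribution_shift",
]


@dataclass(frozen=True)
class SkewResult:
    """Skew of the allelic choice across monoallelic clones.

    ``fold_bias`` is the ratio of the majority to the minority allele count
    (inf when one allele is never chosen); ``p_balance`` is the two-sided
    exact binomial p-value under a fair (p = 0.5) allelic choice.
    """

    n_mono_cast: int
    n_mono_129: int
    fold_bias: float
    favored_allele: str  # "CAST" | "129" | "NONE"
    p_balance: float


@dataclass(frozen=True)
class CouplingResult:
    """Pearson correlation between a focal and a neighbor gene's ARs."""

    r: float
    r_squared: float
    n: int


def allelic_fold_bias(n_mono_cast: int, n_mono_129: int) -> tuple[float, str]:
    """Fold bias max/min of the two monoallelic clone counts and its direction.

    (56, 4) -> (14.0, "CAST"); a zero minority count yields inf.
    """
    if n_mono_cast < 0 or n_mono_129 < 0:
        raise ValueError("clone counts must be non-negative")
    if n_mono_cast == 0 and n_mono_129 == 0:
        raise ValueError("fold bias undefined: no monoallelic clones")
    if n_mono_cast == n_mono_129:
        return 1.0, "NONE"
    hi, lo = max(n_mono_cast, n_mono_129), min(n_mono_cast, n_mono_129)
    fold = math.inf if lo == 0 else hi / lo
    return fold, "CAST" if n_mono_cast > n_mono_129 else "129"


def balance_test(n_mono_cast: int, n_mono_129: int) -> float:
    """Two-sided exact binomial p-value for a balanced allelic choice.

    Tests the observed CAST/129 split of monoallelic clones against
    Binomial(n, 0.5); p = 1 for an even split.
    """
    n = n_mono_cast + n_mono_129
    if n_mono_cast < 0 or n_mono_129 < 0:
        raise ValueError("clone counts must be non-negative")
    if n < 1:
        raise ValueError("balance test undefined: no monoallelic clones")
    return float(stats.binomtest(n_mono_cast, n, p=0.5, alternative="two-sided").pvalue)


def skew_summary(n_mono_cast: int, n_mono_129: int) -> SkewResult:
    """Fold bias and balance test bundled for one gene."""
    fold, favored = allelic_fold_bias(n_mono_cast, n_mono_129)
    return SkewResult(
        n_mono_cast=n_mono_cast,
        n_mono_129=n_mono_129,
        fold_bias=fold,
        favored_allele=favored,
        p_balance=balance_test(n_mono_cast, n_mono_129),
    )


def stability_drift(series: list[tuple[float, float]]) -> tuple[float, float]:
    """Drift of a clone's AR over passages.

    ``series`` is ordered (passage, AR) pairs with strictly increasing
    passage numbers.  Returns the maximum absolute change from the first
    time point and the least-squares slope of AR on passage number.
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    passages = np.asarray([p for p, _ in series], dtype=float)
    ars = np.asarray([a for _, a in series], dtype=float)
    if not np.all(np.diff(passages) > 0):
        raise ValueError("passages must be strictly increasing")
    max_abs_change = float(np.max(np.abs(ars - ars[0])))
    slope = float(stats.linregress(passages, ars).slope)
    return max_abs_change, slope


def compensation_test(expr_mono, expr_bi) -> tuple[float, float, float]:
    """Does the single active allele compensate (or over-compensate)?

    Compares total expression in monoallelic versus bi-allelic clones.
    Returns (mean difference mono - bi, Welch t statistic, two-sided p).
    A positive difference is the over-compensation pattern (one active
    allele yielding *more* transcript than two); a negative difference is
    the naive dosage pattern.
    """
    a = np.asarray(expr_mono, dtype=float)
    b = np.asarray(expr_bi, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(t), float(p)


def cis_coupling(ar_focal, ar_neighbor) -> CouplingResult:
    """Pearson correlation between paired per-clone ARs of two genes.

    Clones with an undetermined (NaN) AR in either gene are dropped
    pairwise; at least three determined pairs are required.  Zero variance
    in either vector yields NaN markers.
    """
    x = np.asarray(ar_focal, dtype=float)
    y = np.asarray(ar_neighbor, dtype=float)
    if x.shape != y.shape:
        raise ValueError("AR vectors must be paired over the same clones")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need >= 3 determined AR pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CouplingResult(r=float("nan"), r_squared=float("nan"), n=n)
    r = float(stats.pearsonr(x, y).statistic)
    return CouplingResult(r=r, r_squared=r * r, n=n)


def allelic_expression_difference(cast_tpm, tpm_129):
    """Per-clone allele-specific expression difference, CAST TPM - 129 TPM."""
    c = np.asarray(cast_tpm, dtype=float)
    m = np.asarray(tpm_129, dtype=float)
    if (c < 0).any() or (m < 0).any():
        raise ValueError("abundances must be non-negative")
    return c - m


def ar_distribution_shift(group_a, group_b) -> tuple[float, float, float]:
    """Shift of the AR distribution between two conditions.

    Returns (mean of a, mean of b, two-sided Welch t p-value).  Used for
    comparisons such as control versus factor-overexpression populations,
    where losing a genetic skew moves the mean AR toward 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    _, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), float(b.mean()), float(p)
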