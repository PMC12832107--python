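"""Allelic-ratio statistic and per-clone allelic states.

The allelic ratio (AR) of a gene in an F1-hybrid clonal line is

    AR = reads_129 / (cast_reads + reads_129) - 0.5

so AR = -0.5 means exclusive CAST expression, 0 means balanced bi-allelic
expression and +0.5 means exclusive 129 expression.  A clone's state is
called monoallelic when |AR| reaches the configured cutoff (inclusive), and
undetermined when too few informative (SNP-overlapping) reads support the
ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "AlleleState",
    "AllelicCounts",
    "AllelicRatio",
    "Thresholds",
    "allelic_ratio",
    "allelic_ratio_array",
    "classify_clone_state",
    "classify_states_array",
    "expression_filter",
]


class AlleleState(str, Enum):
    """Per-gene, per-clone allelic call."""

    MONO_CAST = "MONO_CAST"
    MONO_129 = "MONO_129"
    BIALLELIC = "BIALLELIC"
    UNDETERMINED = "UNDETERMINED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AllelicCounts:
    """Allele-resolved read counts for one gene in one clone.

    Parameters
    ----------
    cast_reads
        Reads assigned to the CAST (paternal-strain) allele.
    reads_129
        Reads assigned to the 129 (maternal-strain) allele.
    total_tpm
        Allele-agnostic abundance of the gene in the clone (TPM scale).
    """

    cast_reads: int
    reads_129: int
    total_tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.cast_reads < 0 or self.reads_129 < 0:
            raise ValueError(
                f"allele read counts must be non-negative, got "
                f"cast={self.cast_reads}, 129={self.reads_129}"
            )
        if self.total_tpm < 0:
            raise ValueError(f"total_tpm must be non-negative, got {self.total_tpm}")

    @property
    def informative_reads(self) -> int:
        return self.cast_reads + self.reads_129


@dataclass(frozen=True)
class AllelicRatio:
    """An allelic ratio together with the read support behind it.

    ``value`` is NaN when the ratio is undetermined (informative reads below
    the configured minimum); otherwise it lies in [-0.5, +0.5].
    """

    value: float
    informative_reads: int

    @property
    def determined(self) -> bool:
        return not math.isnan(self.value)


@dataclass
class Thresholds:
    """All tunable cutoffs of the monoallelic-expression pipeline.

    Defaults follow the clonal-panel study design: a gene-clone pair is
    monoallelic at |AR| >= 0.3, a gene is ME when monoallelic in >= 40% of
    determined clones, genes are expressed at mean TPM strictly greater
    than 5, and an AR needs at least 10 informative reads.  Per-gene cutoff
    overrides support genes whose AR distribution separates better at other
    cutoffs (the Pvt1-style +/-0.2 case).
    """

    ar_cutoff_pos: float = 0.3
    ar_cutoff_neg: float = -0.3
    me_fraction_cutoff: float = 0.4
    min_mean_tpm: float = 5.0
    min_informative_reads: int = 10
    per_gene_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.ar_cutoff_pos <= 0.5):
            raise ValueError(f"ar_cutoff_pos must be in (0, 0.5], got {self.ar_cutoff_pos}")
        if not (-0.5 <= self.ar_cutoff_neg < 0.0):
            raise ValueError(f"ar_cutoff_neg must be in [-0.5, 0), got {self.ar_cutoff_neg}")
        if not (0.0 < self.me_fraction_cutoff <= 1.0):
            raise ValueError(
                f"me_fraction_cutoff must be in (0, 1], got {self.me_fraction_cutoff}"
            )
        if self.min_mean_tpm < 0:
            raise ValueError(f"min_mean_tpm must be >= 0, got {self.min_mean_tpm}")
        if self.min_informative_reads < 1:
            raise ValueError(
                f"min_informative_reads must be >= 1, got {self.min_informative_reads}"
            )
        for gene, (pos, neg) in self.per_gene_overrides.items():
            if not (0.0 < pos <= 0.5) or not (-0.5 <= neg < 0.0):
                raise ValueError(f"invalid per-gene override for {gene!r}: ({pos}, {neg})")

    def cutoffs_for(self, gene: str | None) -> tuple[float, float]:
        """Return ``(positive, negative)`` AR cutoffs, honoring overrides."""
        if gene is not None and gene in self.per_gene_overrides:
            return self.per_gene_overrides[gene]
        return self.ar_cutoff_pos, self.ar_cutoff_neg

    def to_dict(self) -> dict:
        return {
            "ar_cutoff_pos": self.ar_cutoff_pos,
            "ar_cutoff_neg": self.ar_cutoff_neg,
            "me_fraction_cutoff": self.me_fraction_cutoff,
            "min_mean_tpm": self.min_mean_tpm,
            "min_informative_reads": self.min_informative_reads,
            "per_gene_overrides": {g: list(v) for g, v in self.per_gene_overrides.items()},
        }


def allelic_ratio(counts: AllelicCounts, min_informative_reads: int = 10) -> AllelicRatio:
    """Compute the allelic ratio of one gene in one clone.

    AR = reads_129 / (cast_reads + reads_129) - 0.5; positive values
    indicate 129 bias, negative values CAST bias.  Undetermined (NaN) when
    fewer than ``min_informative_reads`` allele-assigned reads are present.
    """
    if min_informative_reads < 1:
        raise ValueError("min_informative_reads must be >= 1")
    n = counts.informative_reads
    if n < min_informative_reads:
        return AllelicRatio(value=float("nan"), informative_reads=n)
    return AllelicRatio(value=counts.reads_129 / n - 0.5, informative_reads=n)


def allelic_ratio_array(
    cast_reads: np.ndarray, reads_129: np.ndarray, min_informative_reads: int = 10
) -> np.ndarray:
    """Vectorized allelic ratio; NaN where informative reads are below floor."""
    cast_reads = np.asarray(cast_reads, dtype=float)
    reads_129 = np.asarray(reads_129, dtype=float)
    if (cast_reads < 0).any() or (reads_129 < 0).any():
        raise ValueError("allele read counts must be non-negative")
    total = cast_reads + reads_129
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = np.where(total >= min_informative_reads, reads_129 / total - 0.5, np.nan)
    return ar


def classify_clone_state(
    ar: AllelicRatio, th: Thresholds, gene: str | None = None
) -> AlleleState:
    """Call a clone monoallelic / bi-allelic / undetermined from its AR.

    Cutoffs are inclusive: AR >= positive cutoff is MONO_129, AR <= negative
    cutoff is MONO_CAST.  Per-gene overrides in ``th`` take precedence.
    """
    if not ar.determined:
        return AlleleState.UNDETERMINED
    pos, neg = th.cutoffs_for(gene)
    if ar.value >= pos:
        return AlleleState.MONO_129
    if ar.value <= neg:
        return AlleleState.MONO_CAST
    return AlleleState.BIALLELIC


def classify_states_array(ar: np.ndarray, pos: float, neg: float) -> np.ndarray:
    """Vectorized state call: array of AlleleState values from AR values."""
    ar = np.asarray(ar, dtype=float)
    out = np.full(ar.shape, AlleleState.BIALLELIC, dtype=object)
    out[np.isnan(ar)] = AlleleState.UNDETERMINED
    with np.errstate(invalid="ignore"):
        out[ar >= pos] = AlleleState.MONO_129
        out[ar <= neg] = AlleleState.MONO_CAST
    return out


def expression_filter(panel, th: Thresholds) -> list[str]:
    """Genes whose mean total TPM across all clones strictly exceeds the floor.

    The strict inequality means a gene averaging exactly the floor (default
    5.0 TPM) is excluded.
    """
    if len(panel.clones) == 0:
        raise ValueError("panel has no clones")
    means = panel.tpm.mean(axis=1)
    return [g for g in panel.genes if means[g] > th.min_mean_tpm]
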