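"""Wet-lab readout arithmetic: competition assays and ChIP-qPCR.

Two small quantifications: (1) GFP/RFP fluorescence ratios from a growth
competition between monoallelic (GFP) and bi-allelic (RFP) clonal lines,
summarized per passage across clone combinations; (2) delta-delta-Ct fold
enrichment over input for plasmid ChIP-qPCR, with the input Ct corrected
for its dilution (a 5% input is 2^4.32-fold diluted, so 4.32 cycles are
subtracted).  Targeted-amplicon allelic ratios reuse the core AR formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AllelicCounts, AllelicRatio, allelic_ratio

__all__ = [
    "QpcrMeasurement",
    "gfp_ratio",
    "competition_trajectory",
    "input_correction_cycles",
    "chip_fold_enrichment",
    "amplicon_ar",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One ChIP-qPCR comparison: target and normalizer Ct in sample and input.

    ``input_fraction`` is the fraction of chromatin kept as input (0.05 for
    a 5% input).
    """

    ct_target_sample: float
    ct_target_input: float
    ct_norm_sample: float
    ct_norm_input: float
    input_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("ct_target_sample", "ct_target_input", "ct_norm_sample",
                     "ct_norm_input"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 < self.input_fraction <= 1.0):
            raise ValueError(f"input_fraction must be in (0, 1], got {self.input_fraction}")


def gfp_ratio(n_gfp: float, n_rfp: float) -> float:
    """GFP cells over all fluorescent (GFP + RFP) cells."""
    if n_gfp < 0 or n_rfp < 0:
        raise ValueError("cell counts must be non-negative")
    total = n_gfp + n_rfp
    if total == 0:
        raise ValueError("no fluorescent cells")
    return n_gfp / total


def competition_trajectory(series: pd.DataFrame) -> pd.DataFrame:
    """Per-passage mean and SD of GFP ratios across clone combinations.

    ``series`` needs columns combination, replicate, passage, n_gfp, n_rfp.
    SD uses the sample (n-1) convention and is NaN for a single entry.
    """
    required = {"combination", "replicate", "passage", "n_gfp", "n_rfp"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(series) == 0:
        raise ValueError("empty competition series")
    df = series.copy()
    df["ratio"] = [gfp_ratio(g, r) for g, r in zip(df["n_gfp"], df["n_rfp"])]
    out = (
        df.groupby("passage")["ratio"]
        .agg(mean_ratio="mean", sd_ratio=lambda x: x.std(ddof=1), n="count")
        .reset_index()
        .sort_values("passage", ignore_index=True)
    )
    out["n"] = out["n"].astype(int)
    return out


def input_correction_cycles(input_fraction: float) -> float:
    """Cycles to subtract from an input Ct given its dilution fraction.

    log2(1 / fraction): a 5% input gives 4.32 cycles, an undiluted input 0.
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    return math.log2(1.0 / input_fraction)


def chip_fold_enrichment(m: QpcrMeasurement) -> tuple[float, float]:
    """Fold enrichment of the ChIP sample over dilution-corrected input.

    Delta-delta-Ct with the normalizer applied symmetrically:

        corrected_input = ct_target_input - log2(1/input_fraction)
        dCt_sample = ct_target_sample - ct_norm_sample
        dCt_input  = corrected_input   - ct_norm_input
        log2_fold  = dCt_input - dCt_sample;   fold = 2 ** log2_fold

    Returns (fold, log2_fold); fold is 1 when the sample matches the
    corrected input exactly.
    """
    corrected_input = m.ct_target_input - input_correction_cycles(m.input_fraction)
    dct_sample = m.ct_target_sample - m.ct_norm_sample
    dct_input = corrected_input - m.ct_norm_input
    log2_fold = dct_input - dct_sample
    return 2.0 ** log2_fold, log2_fold


def amplicon_ar(cast_reads: int, reads_129: int, min_informative_reads: int = 10) -> AllelicRatio:
    """Allelic ratio from targeted-amplicon per-allele read counts."""
    return allelic_ratio(
        AllelicCounts(cast_reads=cast_reads, reads_129=reads_129),
        min_informative_reads=min_informative_reads,
    )
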