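"""Gene-level classification of monoallelic expression across a clonal panel.

A gene expressed in the panel is assigned to exactly one group:

* ``X_LINKED`` / ``Y_LINKED`` / ``IMPRINTED`` — by annotation, before any
  random-ME calling (sex-linked and imprinted genes are monoallelic for
  known, non-random reasons);
* ``ARME`` — monoallelic in at least the ME-fraction cutoff of determined
  clones, with *both* alleles represented among the monoallelic clones
  (at least one CAST-monoallelic and one 129-monoallelic clone);
* ``ME_BIAS_CAST`` / ``ME_BIAS_129`` — ME fraction reached but every
  monoallelic clone expresses the same allele (genetically biased aME);
* ``BIALLELIC`` — everything else that is expressed;
* ``UNEXPRESSED`` — failed the mean-TPM expression filter.

Undetermined clones carry no allelic information and are excluded from the
ME-fraction denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import AlleleState, Thresholds, expression_filter
from .panel import ClonePanel

__all__ = [
    "GeneGroup",
    "GeneClass",
    "me_fraction",
    "ar_mean_variance",
    "classify_gene",
    "classify_panel",
    "threshold_sweep",
    "summarize_panel",
    "truncate_percentage",
]

AME_GROUPS = ("ARME", "ME_BIAS_129", "ME_BIAS_CAST")
ANNOTATION_PRECEDENCE = ("X_LINKED", "Y_LINKED", "IMPRINTED")


class GeneGroup(str, Enum):
    BIALLELIC = "BIALLELIC"
    ARME = "ARME"
    ME_BIAS_129 = "ME_BIAS_129"
    ME_BIAS_CAST = "ME_BIAS_CAST"
    X_LINKED = "X_LINKED"
    Y_LINKED = "Y_LINKED"
    IMPRINTED = "IMPRINTED"
    UNEXPRESSED = "UNEXPRESSED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneClass:
    """Cross-clone classification of one gene with summary statistics."""

    gene: str
    group: GeneGroup
    me_fraction: float
    n_mono_cast: int
    n_mono_129: int
    n_biallelic: int
    n_undetermined: int
    ar_mean: float
    ar_variance: float


def me_fraction(states: list[AlleleState]) -> float:
    """Fraction of determined clones in which the gene is monoallelic.

    UNDETERMINED states are excluded from the denominator; raises if no
    state is determined.
    """
    n_mono = sum(1 for s in states if s in (AlleleState.MONO_CAST, AlleleState.MONO_129))
    n_det = n_mono + sum(1 for s in states if s == AlleleState.BIALLELIC)
    if n_det == 0:
        raise ValueError("ME fraction undefined: no determined clone states")
    return n_mono / n_det


def ar_mean_variance(ars) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) variance of determined ARs.

    Variance is NaN with fewer than two determined values; mean is NaN with
    none.
    """
    vals = np.asarray([a for a in np.asarray(ars, dtype=float) if not math.isnan(a)])
    if vals.size == 0:
        return float("nan"), float("nan")
    mean = float(vals.mean())
    var = float(vals.var(ddof=1)) if vals.size >= 2 else float("nan")
    return mean, var


def _tally(states) -> tuple[int, int, int, int]:
    # equality, not identity: states may arrive as plain strings (e.g. out
    # of a pandas object column) and AlleleState is a str Enum.
    states = list(states)
    return (
        sum(1 for s in states if s == AlleleState.MONO_CAST),
        sum(1 for s in states if s == AlleleState.MONO_129),
        sum(1 for s in states if s == AlleleState.BIALLELIC),
        sum(1 for s in states if s == AlleleState.UNDETERMINED),
    )


def classify_gene(
    gene: str,
    states: list[AlleleState],
    annotations: frozenset[str] | set[str],
    th: Thresholds,
    ars=None,
) -> GeneClass:
    """Classify one expressed gene from its per-clone states.

    Annotations take precedence over random-ME calling; among the remaining
    genes the ME-fraction cutoff and the both-alleles rule decide between
    ARME, the two ME_BIAS groups, and BIALLELIC.
    """
    n_cast, n_129, n_bi, n_und = _tally(states)
    n_det = n_cast + n_129 + n_bi
    frac = (n_cast + n_129) / n_det if n_det > 0 else float("nan")
    mean, var = ar_mean_variance(ars) if ars is not None else (float("nan"), float("nan"))

    group = GeneGroup.BIALLELIC
    for cat in ANNOTATION_PRECEDENCE:
        if cat in annotations:
            group = GeneGroup(cat)
            break
    else:
        if n_det > 0 and frac >= th.me_fraction_cutoff:
            if n_cast >= 1 and n_129 >= 1:
                group = GeneGroup.ARME
            elif n_cast >= 1:
                group = GeneGroup.ME_BIAS_CAST
            else:
                group = GeneGroup.ME_BIAS_129

    return GeneClass(
        gene=gene,
        group=group,
        me_fraction=frac,
        n_mono_cast=n_cast,
        n_mono_129=n_129,
        n_biallelic=n_bi,
        n_undetermined=n_und,
        ar_mean=mean,
        ar_variance=var,
    )


def classify_panel(panel: ClonePanel, th: Thresholds) -> pd.DataFrame:
    """Per-gene classification table for every gene in the panel.

    Genes failing the expression filter are kept with group UNEXPRESSED so
    that the output partitions the input gene list.
    """
    expressed = set(expression_filter(panel, th))
    ar = panel.allelic_ratios(th.min_informative_reads)
    states = panel.state_matrix(th)
    records = []
    for gene in panel.genes:
        if gene not in expressed:
            records.append(
                GeneClass(gene, GeneGroup.UNEXPRESSED, float("nan"), 0, 0, 0, 0,
                          float("nan"), float("nan"))
            )
            continue
        records.append(
            classify_gene(
                gene,
                list(states.loc[gene]),
                panel.annotation_of(gene),
                th,
                ars=ar.loc[gene].to_numpy(),
            )
        )
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "group": [str(r.group) for r in records],
            "me_fraction": [r.me_fraction for r in records],
            "n_mono_cast": [r.n_mono_cast for r in records],
            "n_mono_129": [r.n_mono_129 for r in records],
            "n_biallelic": [r.n_biallelic for r in records],
            "n_undetermined": [r.n_undetermined for r in records],
            "ar_mean": [r.ar_mean for r in records],
            "ar_variance": [r.ar_variance for r in records],
        }
    ).set_index("gene")
    return df


def threshold_sweep(
    panel: ClonePanel,
    ar_grid: list[float],
    me_grid: list[float],
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Counts of aME and aRME genes over a grid of AR and ME-fraction cutoffs.

    Each positive AR cutoff is paired with its symmetric negative cutoff.
    Per-gene overrides are intentionally ignored during a sweep (the sweep
    explores global cutoffs).
    """
    if not ar_grid or not me_grid:
        raise ValueError("cutoff grids must be non-empty")
    base = th or Thresholds()
    rows = []
    for ar_c in ar_grid:
        for me_c in me_grid:
            sweep_th = Thresholds(
                ar_cutoff_pos=ar_c,
                ar_cutoff_neg=-ar_c,
                me_fraction_cutoff=me_c,
                min_mean_tpm=base.min_mean_tpm,
                min_informative_reads=base.min_informative_reads,
            )
            table = classify_panel(panel, sweep_th)
            n_ame = int(table["group"].isin(AME_GROUPS).sum())
            n_arme = int((table["group"] == "ARME").sum())
            rows.append((ar_c, me_c, n_ame, n_arme))
    return pd.DataFrame(rows, columns=["ar_cutoff", "me_cutoff", "n_aME", "n_aRME"])


def truncate_percentage(numerator: int, denominator: int) -> tuple[float, float]:
    """Percentage of ``numerator/denominator`` truncated to one decimal,
    plus the full-precision value.

    Truncation (not rounding) matches the reporting style in which
    287/10,318 prints as 2.7% and 638/10,318 as 6.1%.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    full = 100.0 * numerator / denominator
    return math.floor(full * 10.0) / 10.0, full


def summarize_panel(panel: ClonePanel, th: Thresholds) -> tuple[pd.DataFrame, dict]:
    """Classification table plus group tallies and expressed-gene fractions."""
    table = classify_panel(panel, th)
    expressed = table[table["group"] != "UNEXPRESSED"]
    n_expressed = int(len(expressed))
    tallies = {g.value: int((table["group"] == g.value).sum()) for g in GeneGroup}
    percentages = {}
    if n_expressed > 0:
        for g in GeneGroup:
            if g is GeneGroup.UNEXPRESSED:
                continue
            trunc, full = truncate_percentage(tallies[g.value], n_expressed)
            percentages[g.value] = {"truncated": trunc, "full": full}
        n_ame = sum(tallies[g] for g in AME_GROUPS)
        trunc, full = truncate_percentage(n_ame, n_expressed)
        percentages["aME_total"] = {"truncated": trunc, "full": full}
    summary = {
        "n_genes": int(len(table)),
        "n_expressed": n_expressed,
        "n_clones": panel.n_clones,
        "tallies": tallies,
        "n_aME": sum(tallies[g] for g in AME_GROUPS),
        "percent_of_expressed": percentages,
        "thresholds": th.to_dict(),
    }
    return table, summary
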