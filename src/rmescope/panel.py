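"""ClonePanel: genes x clones container of allele-resolved counts.

Holds the CAST-allele and 129-allele read-count matrices, the total-TPM
matrix, per-clone metadata (sex, line, passage) and gene annotations
(X-linked / Y-linked / imprinted).  All downstream analyses operate on this
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlleleState, Thresholds, allelic_ratio_array, classify_states_array

__all__ = ["ANNOTATION_CATEGORIES", "ClonePanel"]

ANNOTATION_CATEGORIES = ("X_LINKED", "Y_LINKED", "IMPRINTED")


@dataclass
class ClonePanel:
    """Allele-resolved expression over a panel of clonal lines.

    Parameters
    ----------
    cast : DataFrame
        CAST-allele read counts, genes as rows, clones as columns.
    r129 : DataFrame
        129-allele read counts, same shape and labels as ``cast``.
    tpm : DataFrame
        Allele-agnostic abundance (TPM), same shape and labels.
    clone_meta : DataFrame, optional
        Indexed by clone, columns ``sex`` ('male'/'female'/'unknown'),
        ``line`` and ``passage``.
    annotations : dict, optional
        gene -> subset of {'X_LINKED', 'Y_LINKED', 'IMPRINTED'}.
    cast_tpm, r129_tpm : DataFrame, optional
        Per-allele abundances; required only for abundance-mode ARs and the
        CAST TPM - 129 TPM analyses.
    """

    cast: pd.DataFrame
    r129: pd.DataFrame
    tpm: pd.DataFrame
    clone_meta: pd.DataFrame | None = None
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    cast_tpm: pd.DataFrame | None = None
    r129_tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, df in self._matrices():
            if df.index.has_duplicates:
                dups = df.index[df.index.duplicated()].unique().tolist()
                raise ValueError(f"duplicate gene identifiers in {name}: {dups}")
            if df.columns.has_duplicates:
                dups = df.columns[df.columns.duplicated()].unique().tolist()
                raise ValueError(f"duplicate clone identifiers in {name}: {dups}")
            if not df.index.equals(self.cast.index) or not df.columns.equals(
                self.cast.columns
            ):
                raise ValueError(
                    f"{name} matrix gene/clone labels do not match the CAST matrix"
                )
        if (self.cast.to_numpy() < 0).any() or (self.r129.to_numpy() < 0).any():
            raise ValueError("allele read counts must be non-negative")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        bad = {
            g: sorted(set(cats) - set(ANNOTATION_CATEGORIES))
            for g, cats in self.annotations.items()
            if set(cats) - set(ANNOTATION_CATEGORIES)
        }
        if bad:
            raise ValueError(f"unknown annotation categories: {bad}")
        self.annotations = {g: frozenset(c) for g, c in self.annotations.items()}

    def _matrices(self):
        out = [("cast", self.cast), ("r129", self.r129), ("tpm", self.tpm)]
        if self.cast_tpm is not None:
            out.append(("cast_tpm", self.cast_tpm))
        if self.r129_tpm is not None:
            out.append(("r129_tpm", self.r129_tpm))
        return out

    @property
    def genes(self) -> list[str]:
        return list(self.cast.index)

    @property
    def clones(self) -> list[str]:
        return list(self.cast.columns)

    @property
    def n_genes(self) -> int:
        return self.cast.shape[0]

    @property
    def n_clones(self) -> int:
        return self.cast.shape[1]

    def has_allele_tpm(self) -> bool:
        return self.cast_tpm is not None and self.r129_tpm is not None

    def allelic_ratios(
        self, min_informative_reads: int = 10, use_abundance: bool = False
    ) -> pd.DataFrame:
        """Genes x clones AR matrix (NaN = undetermined).

        With ``use_abundance`` the ratio is computed from per-allele TPMs
        (panel must carry them); the informative-read floor still applies,
        so low-coverage cells stay undetermined either way.
        """
        ar_counts = allelic_ratio_array(
            self.cast.to_numpy(), self.r129.to_numpy(), min_informative_reads
        )
        if not use_abundance:
            values = ar_counts
        else:
            if not self.has_allele_tpm():
                raise ValueError(
                    "abundance-mode AR requires per-allele TPM matrices on the panel"
                )
            c = self.cast_tpm.to_numpy(dtype=float)
            m = self.r129_tpm.to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                ar_ab = np.where(c + m > 0, m / (c + m) - 0.5, np.nan)
            values = np.where(np.isnan(ar_counts), np.nan, ar_ab)
        return pd.DataFrame(values, index=self.cast.index, columns=self.cast.columns)

    def state_matrix(self, th: Thresholds) -> pd.DataFrame:
        """Genes x clones matrix of AlleleState calls under ``th``."""
        ar = self.allelic_ratios(th.min_informative_reads)
        states = classify_states_array(ar.to_numpy(), th.ar_cutoff_pos, th.ar_cutoff_neg)
        out = pd.DataFrame(states, index=ar.index, columns=ar.columns)
        for gene, (pos, neg) in th.per_gene_overrides.items():
            if gene in out.index:
                row = classify_states_array(ar.loc[gene].to_numpy(), pos, neg)
                out.loc[gene] = row
        return out

    def long_table(self, th: Thresholds) -> pd.DataFrame:
        """Long-format (gene, clone, cast_reads, reads_129, ar, state) table."""
        ar = self.allelic_ratios(th.min_informative_reads)
        states = self.state_matrix(th)
        rows = []
        for gene in self.genes:
            for clone in self.clones:
                rows.append(
                    (
                        gene,
                        clone,
                        int(self.cast.at[gene, clone]),
                        int(self.r129.at[gene, clone]),
                        ar.at[gene, clone],
                        str(states.at[gene, clone]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["gene", "clone", "cast_reads", "reads_129", "ar", "state"]
        )

    def swap_alleles(self) -> "ClonePanel":
        """Panel with the two parental strains relabeled (CAST <-> 129)."""
        return ClonePanel(
            cast=self.r129.copy(),
            r129=self.cast.copy(),
            tpm=self.tpm.copy(),
            clone_meta=None if self.clone_meta is None else self.clone_meta.copy(),
            annotations=dict(self.annotations),
            cast_tpm=None if self.r129_tpm is None else self.r129_tpm.copy(),
            r129_tpm=None if self.cast_tpm is None else self.cast_tpm.copy(),
        )

    def annotation_of(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, frozenset())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClonePanel):
            return NotImplemented
        same = (
            self.cast.equals(other.cast)
            and self.r129.equals(other.r129)
            and self.tpm.equals(other.tpm)
            and self.annotations == other.annotations
        )
        if not same:
            return False
        for a, b in ((self.cast_tpm, other.cast_tpm), (self.r129_tpm, other.r129_tpm)):
            if (a is None) != (b is None):
                return False
            if a is not None and not a.equals(b):
                return False
        if (self.clone_meta is None) != (other.clone_meta is None):
            return False
        if self.clone_meta is not None and not self.clone_meta.equals(other.clone_meta):
            return False
        return True
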