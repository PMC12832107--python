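"""Synthetic clonal panels with known ground truth.

The generator embodies a two-step picture of random monoallelic expression
in F1-hybrid clonal lines: when a clone is founded, each aRME-class gene
either stays bi-allelic or commits (with probability ``f_me``) to
monoallelic expression; if it commits, the silenced allele is chosen
stochastically.  For genetically skewed genes the choice probability
depends on the allele-specific binding affinity of a transcription factor:
the higher-affinity allele tends to be activated first and then silenced,
so stronger 129-promoter affinity skews monoallelic expression toward the
CAST allele.  Raising the factor's expression level washes the genetic
bias out (both alleles are activated regardless of affinity), restoring a
balanced choice.

Bulk sequencing of a clone then averages transcriptional bursting, and the
observed allele-resolved counts are produced by (1) negative-binomial
total read depth, (2) binomial thinning to the informative (SNP-carrying)
reads, and (3) a beta-binomial split of informative reads between alleles
around the clone's true allelic fraction, with intra-clone correlation
``rho`` capturing residual overdispersion.  Monoallelic clones optionally
over- or under-express the gene (transcriptional compensation), and each
skewed focal gene can carry a cis-coupled neighbor whose allelic ratio
responds inversely to the focal gene's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AlleleState
from .panel import ClonePanel

__all__ = [
    "GENE_CLASSES",
    "SimulationParams",
    "TruthLabels",
    "choice_bias",
    "simulate_panel",
    "write_truth",
    "read_truth",
]

GENE_CLASSES = (
    "BIALLELIC",
    "ARME_BALANCED",
    "ARME_SKEWED",
    "AME_ONE_ALLELE",
    "IMPRINTED_LIKE",
    "X_LIKE",
)

#: default gene mix: mostly bi-allelic genes with a minority of ME classes,
#: mirroring the few-percent aME share seen in clonal panels.
DEFAULT_GENE_SPEC = (
    ("BIALLELIC", 120),
    ("ARME_BALANCED", 30),
    ("ARME_SKEWED", 20),
    ("AME_ONE_ALLELE", 15),
    ("IMPRINTED_LIKE", 10),
    ("X_LIKE", 5),
)


@dataclass
class SimulationParams:
    """Generative parameters of a synthetic clonal panel.

    Defaults reproduce the study conditions: a 120-clone panel (74 female,
    46 male), a Pvt1-like skew probability of ~0.933 (the 56:4, 14-fold
    split) for skewed genes at ``tf_level = 0``, ~1000-read depth per gene
    with ~63% of reads informative (one SNP per ~100 bp and ~100 b reads),
    1.5-fold over-compensation in monoallelic clones and a strong inverse
    cis-coupling of the neighbor gene.
    """

    n_clones: int = 120
    gene_spec: tuple[tuple[str, int], ...] = DEFAULT_GENE_SPEC
    f_me: float = 0.6
    affinity_129: float = 2.0
    affinity_cast: float = 1.0
    tf_level: float = 0.0
    kappa: float = 2.639
    mean_expression: float = 100.0
    reads_per_tpm: float = 10.0
    dispersion: float = 0.1
    rho: float = 0.05
    compensation: float = 1.5
    coupling_strength: float = 0.8
    coupling_noise_sd: float = 0.05
    leakage: float = 0.02
    snp_informative_fraction: float = 0.632
    female_fraction: float = 74 / 120
    emit_neighbors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for cls, count in self.gene_spec:
            if cls not in GENE_CLASSES:
                raise ValueError(f"unknown gene class {cls!r}")
            if count < 0:
                raise ValueError(f"gene count for {cls} must be >= 0")
        for name in ("f_me", "rho", "coupling_strength", "snp_informative_fraction",
                     "female_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rho >= 1.0:
            raise ValueError("rho must be < 1")
        if not (0.0 <= self.leakage < 0.5):
            raise ValueError("leakage must be in [0, 0.5)")
        for name in ("affinity_129", "affinity_cast", "tf_level", "kappa",
                     "mean_expression", "reads_per_tpm", "dispersion",
                     "compensation", "coupling_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["gene_spec"] = [list(x) for x in self.gene_spec]
        return d


@dataclass
class TruthLabels:
    """Ground truth emitted alongside a simulated panel.

    ``genes``: per-gene table (true_class, p_cast_me, partner_of).
    ``states``: long per-gene-per-clone table (true_state, true_frac_129).
    ``params``: the full SimulationParams record.
    """

    genes: pd.DataFrame
    states: pd.DataFrame
    params: dict = field(default_factory=dict)


def choice_bias(
    affinity_129: float, affinity_cast: float, tf_level: float, kappa: float
) -> float:
    """Probability that the monoallelically expressed allele is CAST.

    Logistic in the affinity difference, damped by the factor's expression
    level:

        p = 1 / (1 + exp(-kappa * (affinity_129 - affinity_cast) / (1 + tf_level)))

    Equal affinities give 0.5; a higher 129 affinity pushes the choice
    toward CAST (the strongly bound 129 allele fires first and is the one
    silenced); p -> 0.5 as tf_level -> inf, so overexpressing the factor
    erases the genetic skew.
    """
    for name, v in (("affinity_129", affinity_129), ("affinity_cast", affinity_cast),
                    ("tf_level", tf_level), ("kappa", kappa)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    z = kappa * (affinity_129 - affinity_cast) / (1.0 + tf_level)
    return 1.0 / (1.0 + math.exp(-z))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial totals with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial draws with mean p and intra-class correlation rho."""
    n = np.asarray(n)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    if rho <= 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    q = rng.beta(p * conc, (1.0 - p) * conc)
    return rng.binomial(n, q)


def _true_states_for_gene(
    rng: np.random.Generator,
    cls: str,
    params: SimulationParams,
    sexes: np.ndarray,
    fixed_allele: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-clone (state, true 129-allele fraction) plus P(ME allele = CAST)."""
    n = params.n_clones
    lk = params.leakage
    frac = np.full(n, 0.5)
    state = np.full(n, AlleleState.BIALLELIC, dtype=object)

    if cls == "BIALLELIC":
        return state, frac, math.nan

    if cls in ("ARME_BALANCED", "ARME_SKEWED", "AME_ONE_ALLELE"):
        is_me = rng.random(n) < params.f_me
        if cls == "ARME_BALANCED":
            p_cast = 0.5
            cast_me = rng.random(n) < p_cast
        elif cls == "ARME_SKEWED":
            p_cast = choice_bias(
                params.affinity_129, params.affinity_cast, params.tf_level, params.kappa
            )
            cast_me = rng.random(n) < p_cast
        else:
            p_cast = 1.0 if fixed_allele == "CAST" else 0.0
            cast_me = np.full(n, fixed_allele == "CAST")
        state[is_me & cast_me] = AlleleState.MONO_CAST
        state[is_me & ~cast_me] = AlleleState.MONO_129
        frac[is_me & cast_me] = lk
        frac[is_me & ~cast_me] = 1.0 - lk
        return state, frac, p_cast

    if cls == "IMPRINTED_LIKE":
        # fixed parental allele in every clone
        cast_expressed = fixed_allele == "CAST"
        state[:] = AlleleState.MONO_CAST if cast_expressed else AlleleState.MONO_129
        frac[:] = lk if cast_expressed else 1.0 - lk
        return state, frac, math.nan

    if cls == "X_LIKE":
        # female clones: random X-inactivation choice; male clones carry a
        # single (maternal 129) X, so expression is exclusively 129.
        female = sexes == "female"
        cast_active = rng.random(n) < 0.5
        mono_cast = female & cast_active
        state[:] = AlleleState.MONO_129
        state[mono_cast] = AlleleState.MONO_CAST
        frac[:] = 1.0 - lk
        frac[mono_cast] = lk
        return state, frac, math.nan

    raise AssertionError(f"unhandled class {cls}")


def simulate_panel(params: SimulationParams) -> tuple[ClonePanel, TruthLabels]:
    """Draw a clonal panel and its ground truth from the generative model.

    The same seed always yields byte-identical panels.  Skewed genes
    optionally emit a cis-coupled neighbor gene (``neighbor_of_<gene>``)
    whose true AR is ``-coupling_strength`` times the focal gene's, plus
    Gaussian noise, soft-clipped into [-0.5, 0.5].
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_clones
    clones = [f"clone_{i + 1:03d}" for i in range(n)]
    n_female = int(round(params.female_fraction * n))
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))

    gene_rows: list[dict] = []
    state_rows: list[dict] = []
    counts_cast: list[np.ndarray] = []
    counts_129: list[np.ndarray] = []
    tpm_rows: list[np.ndarray] = []
    tpm_cast_rows: list[np.ndarray] = []
    tpm_129_rows: list[np.ndarray] = []
    gene_names: list[str] = []
    annotations: dict[str, frozenset[str]] = {}

    def emit(gene: str, cls: str, frac: np.ndarray, state: np.ndarray,
             p_cast_me: float, compensated: np.ndarray, partner: str | None) -> None:
        mean_tpm = np.full(n, params.mean_expression)
        mean_tpm[compensated] *= params.compensation
        total_reads = _nb_counts(rng, mean_tpm * params.reads_per_tpm, params.dispersion)
        informative = rng.binomial(total_reads, params.snp_informative_fraction)
        r129 = _beta_binomial(rng, informative, frac, params.rho)
        cast = informative - r129
        # TPM split follows the realized read split where reads exist
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_frac = np.where(informative > 0, r129 / np.maximum(informative, 1), frac)
        tpm = mean_tpm * (total_reads / np.maximum(mean_tpm * params.reads_per_tpm, 1e-9))
        gene_names.append(gene)
        counts_cast.append(cast)
        counts_129.append(r129)
        tpm_rows.append(tpm)
        tpm_cast_rows.append(tpm * (1.0 - obs_frac))
        tpm_129_rows.append(tpm * obs_frac)
        gene_rows.append(
            {"gene": gene, "true_class": cls,
             "p_cast_me": p_cast_me, "partner_of": partner or ""}
        )
        for j, clone in enumerate(clones):
            state_rows.append(
                {"gene": gene, "clone": clone,
                 "true_state": str(state[j]), "true_frac_129": float(frac[j])}
            )

    idx = 0
    for cls, count in params.gene_spec:
        for k in range(count):
            idx += 1
            gene = f"{cls.lower()}_{idx:04d}"
            fixed_allele = "CAST" if k % 2 == 0 else "129"
            state, frac, p_cast = _true_states_for_gene(rng, cls, params, sexes, fixed_allele)
            is_me = np.array(
                [s in (AlleleState.MONO_CAST, AlleleState.MONO_129) for s in state]
            )
            compensated = is_me if cls in ("ARME_BALANCED", "ARME_SKEWED", "AME_ONE_ALLELE") else np.zeros(n, bool)
            emit(gene, cls, frac, state, p_cast, compensated, None)
            if cls == "IMPRINTED_LIKE":
                annotations[gene] = frozenset({"IMPRINTED"})
            elif cls == "X_LIKE":
                annotations[gene] = frozenset({"X_LINKED"})

            if cls == "ARME_SKEWED" and params.emit_neighbors:
                focal_ar = frac - 0.5
                nb_ar = -params.coupling_strength * focal_ar + rng.normal(
                    0.0, params.coupling_noise_sd, n
                )
                nb_frac = np.clip(nb_ar + 0.5, params.leakage, 1.0 - params.leakage)
                nb_state = np.full(n, AlleleState.BIALLELIC, dtype=object)
                emit(f"neighbor_of_{gene}", "NEIGHBOR", nb_frac, nb_state,
                     math.nan, np.zeros(n, bool), partner=gene)

    index = pd.Index(gene_names, name="gene")
    cols = pd.Index(clones, name="clone")
    clone_meta = pd.DataFrame(
        {"sex": sexes, "line": ["sim"] * n, "passage": [0] * n}, index=cols
    )
    panel = ClonePanel(
        cast=pd.DataFrame(np.vstack(counts_cast), index=index, columns=cols),
        r129=pd.DataFrame(np.vstack(counts_129), index=index, columns=cols),
        tpm=pd.DataFrame(np.vstack(tpm_rows), index=index, columns=cols),
        clone_meta=clone_meta,
        annotations=annotations,
        cast_tpm=pd.DataFrame(np.vstack(tpm_cast_rows), index=index, columns=cols),
        r129_tpm=pd.DataFrame(np.vstack(tpm_129_rows), index=index, columns=cols),
    )
    truth = TruthLabels(
        genes=pd.DataFrame(gene_rows).set_index("gene"),
        states=pd.DataFrame(state_rows),
        params=params.to_dict(),
    )
    return panel, truth


def write_truth(truth: TruthLabels, out_dir: str | Path) -> None:
    """Write truth tables (TSV) and the parameter record (JSON) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    truth.states.to_csv(out / "truth_states.tsv", sep="\t", index=False)
    with open(out / "truth_params.json", "w") as fh:
        json.dump(truth.params, fh, indent=2, sort_keys=True)


def read_truth(out_dir: str | Path) -> TruthLabels:
    """Read back what :func:`write_truth` wrote."""
    out = Path(out_dir)
    genes = pd.read_csv(out / "truth_genes.tsv", sep="\t", index_col="gene",
                        keep_default_na=False)
    genes["p_cast_me"] = pd.to_numeric(genes["p_cast_me"], errors="coerce")
    states = pd.read_csv(out / "truth_states.tsv", sep="\t")
    with open(out / "truth_params.json") as fh:
        params = json.load(fh)
    return TruthLabels(genes=genes, states=states, params=params)
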