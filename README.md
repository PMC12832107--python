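# rmescope

Detection and characterization of **autosomal random monoallelic expression
(aRME)** from allele-resolved RNA-seq of clonal cell-line panels.

Most autosomal genes are expressed from both alleles, but some genes commit,
clone by clone, to expressing only one — a choice that is stable through cell
division and can carry a genetic skew and a phenotypic consequence. In an
F1-hybrid system (e.g. CAST/EiJ × 129S1 mouse cells), dense strain SNPs let
every informative read be assigned to a parental allele, so a panel of clonal
lines reveals which genes are bi-allelic, which flip between alleles at random
(aRME), and which are monoallelic with a fixed genetic bias (aME). `rmescope`
implements that analysis for people working with allele-resolved clonal-panel
count matrices: quantitative geneticists and genomics analysts studying
allele-specific expression, X-inactivation-like processes or imprinting.

## The statistic and the classification

For a gene in one clone, with allele-assigned read counts `CAST` and `129`,
the **allelic ratio** is

```
AR = 129 / (CAST + 129) − 0.5
```

so AR = −0.5 is exclusive CAST expression, 0 is balance and +0.5 is exclusive
129 expression. A clone with fewer than `min_informative_reads` (default 10)
allele-assigned reads is *undetermined*. Clone states use inclusive cutoffs
(default ±0.3): AR ≥ 0.3 → monoallelic-129, AR ≤ −0.3 → monoallelic-CAST.

Across the panel, genes with mean TPM strictly greater than 5 are classified
into one group each:

- **X_LINKED / Y_LINKED / IMPRINTED** — by annotation list, excluded from
  random-ME calling;
- **ARME** — monoallelic in ≥ 40% of determined clones (the *ME fraction*),
  with at least one CAST-monoallelic *and* one 129-monoallelic clone;
- **ME_BIAS_CAST / ME_BIAS_129** — ME fraction reached, but every monoallelic
  clone uses the same allele;
- **BIALLELIC** otherwise.

Downstream statistics: allelic-choice **fold bias** (majority/minority clone
counts) with a two-sided exact binomial test of the fair-choice null; AR
**stability** over passages (max drift and per-passage slope); transcriptional
**compensation** (Welch t between total expression of monoallelic and
bi-allelic clones); and **cis-coupling** (Pearson r / R² between the per-clone
ARs of a focal gene and a neighbor). A PWM scanner compares transcription-
factor motif strength between allele promoter sequences, and small assay
helpers cover GFP/RFP competition ratios and ΔΔCt ChIP-qPCR fold enrichment
with input-dilution correction (a 5% input ⇒ log2(20) = 4.32 cycles).

A ground-truthed simulator generates whole panels under a two-step allelic-
choice model — per-clone ME commitment with probability `f_me`, then an allele
choice whose skew follows a logistic function of the allele affinity
difference of a transcription factor, damped by that factor's expression
level — with negative-binomial depth, beta-binomial allelic sampling,
compensation, and an inversely coupled neighbor gene.

## Worked example

```python
from rmescope import (SimulationParams, simulate_panel, Thresholds,
                      summarize_panel, skew_summary, cis_coupling)

params = SimulationParams(n_clones=120, seed=42)   # 220 genes, known truth
panel, truth = simulate_panel(params)
th = Thresholds()                                   # ±0.3 AR, 0.4 ME, TPM>5
table, summary = summarize_panel(panel, th)
print(summary["tallies"])
# {'BIALLELIC': 120, 'ARME': 70, 'ME_BIAS_129': 8, 'ME_BIAS_CAST': 7,
#  'X_LINKED': 5, 'Y_LINKED': 0, 'IMPRINTED': 10, 'UNEXPRESSED': 0}

focal = "arme_skewed_0151"                          # a genetically skewed gene
row = table.loc[focal]
res = skew_summary(int(row["n_mono_cast"]), int(row["n_mono_129"]))
print(res.n_mono_cast, res.n_mono_129, res.fold_bias, res.p_balance)
# 77 5 15.4 1.2046380153120002e-17

ar = panel.allelic_ratios(th.min_informative_reads)
c = cis_coupling(ar.loc[focal], ar.loc["neighbor_of_" + focal])
print(round(c.r, 3), round(c.r_squared, 3), c.n)
# -0.888 0.788 120
```

The tallies recover the simulated gene mix (120 bi-allelic, 50 aRME-class,
15 one-allele aME, 10 imprinted-like, 5 X-like, plus 20 coupled neighbors
that are themselves called ARME). The skewed gene is CAST-monoallelic in 77
clones and 129-monoallelic in 5 — a 15.4-fold bias whose exact binomial
p ≈ 10⁻¹⁷ rejects a fair allelic choice — and its neighbor's AR runs
inversely (r = −0.89) because both compete for the same cis-regulatory
contact.

The same pipeline is available from the shell:

```
rmescope simulate --out-dir sim --seed 42
rmescope classify --cast sim/cast_counts.tsv --r129 sim/129_counts.tsv \
         --tpm sim/tpm.tsv --annotations-dir sim --out-dir results
rmescope skew --table results/classification.tsv --gene arme_skewed_0151 \
         --out results/skew.json
```

Every command writes a `manifest.json` with the tool version, full
configuration and its hash.

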