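"""Gene-level classification, threshold sweeps and panel summaries."""

import math

import numpy as np
import pytest

from rmescope import (
    AlleleState,
    Thresholds,
    ar_mean_variance,
    classify_gene,
    classify_panel,
    me_fraction,
    summarize_panel,
    threshold_sweep,
    truncate_percentage,
)
from rmescope.classify import AME_GROUPS, GeneGroup

from conftest import make_panel

M_CAST = AlleleState.MONO_CAST
M_129 = AlleleState.MONO_129
BI = AlleleState.BIALLELIC
UND = AlleleState.UNDETERMINED


class TestMeFraction:
    def test_basic_counts(self):
        states = [M_CAST] * 3 + [M_129] * 2 + [BI] * 5
        assert me_fraction(states) == pytest.approx(0.5)

    def test_all_biallelic(self):
        assert me_fraction([BI] * 8) == 0.0

    def test_undetermined_excluded_from_denominator(self):
        states = [M_CAST] * 4 + [UND] + [BI] * 5
        assert me_fraction(states) == pytest.approx(4 / 9)

    def test_all_undetermined_is_error(self):
        with pytest.raises(ValueError):
            me_fraction([UND, UND])


class TestArMeanVariance:
    def test_constant(self):
        mean, var = ar_mean_variance([0.1, 0.1, 0.1])
        assert mean == pytest.approx(0.1)
        assert var == pytest.approx(0.0)

    def test_sample_variance_two_points(self):
        mean, var = ar_mean_variance([0.5, -0.5])
        assert mean == pytest.approx(0.0)
        assert var == pytest.approx(0.5)  # (0.25 + 0.25) / (2 - 1)

    def test_mean_with_nan_excluded(self):
        mean, _ = ar_mean_variance([0.0, 0.0, 0.0, 0.5])
        assert mean == pytest.approx(0.125)
        mean2, _ = ar_mean_variance([0.0, float("nan"), 0.5])
        assert mean2 == pytest.approx(0.25)

    def test_single_value_variance_undefined(self):
        mean, var = ar_mean_variance([0.2])
        assert mean == pytest.approx(0.2)
        assert math.isnan(var)


class TestClassifyGene:
    def test_arme_requires_both_alleles(self, defaults):
        states = [M_CAST] * 3 + [M_129] * 2 + [BI] * 5
        assert classify_gene("g", states, frozenset(), defaults).group == GeneGroup.ARME

    def test_single_allele_is_biased_not_random(self, defaults):
        states = [M_CAST] * 5 + [BI] * 5
        gc = classify_gene("g", states, frozenset(), defaults)
        assert gc.group == GeneGroup.ME_BIAS_CAST
        states = [M_129] * 5 + [BI] * 5
        assert classify_gene("g", states, frozenset(), defaults).group == GeneGroup.ME_BIAS_129

    def test_all_biallelic(self, defaults):
        gc = classify_gene("g", [BI] * 10, frozenset(), defaults)
        assert gc.group == GeneGroup.BIALLELIC
        assert gc.me_fraction == 0.0

    def test_annotation_precedence_over_me_calling(self, defaults):
        states = [M_129] * 9 + [BI]
        gc = classify_gene("g", states, frozenset({"IMPRINTED"}), defaults)
        assert gc.group == GeneGroup.IMPRINTED
        gc = classify_gene("g", states, frozenset({"X_LINKED"}), defaults)
        assert gc.group == GeneGroup.X_LINKED

    def test_counts_partition_clones(self, defaults):
        states = [M_CAST] * 2 + [M_129] * 3 + [BI] * 4 + [UND]
        gc = classify_gene("g", states, frozenset(), defaults)
        assert (gc.n_mono_cast, gc.n_mono_129, gc.n_biallelic, gc.n_undetermined) == (
            2, 3, 4, 1,
        )
        assert gc.n_mono_cast + gc.n_mono_129 + gc.n_biallelic + gc.n_undetermined == 10


def _brute_force_counts(panel, ar_c, me_c, th):
    """Independent reclassification: recompute every AR and state by hand."""
    n_ame = n_arme = 0
    tpm_mean = panel.tpm.mean(axis=1)
    for gene in panel.genes:
        if not tpm_mean[gene] > th.min_mean_tpm:
            continue
        if panel.annotation_of(gene):
            continue
        n_cast = n_129 = n_bi = 0
        for clone in panel.clones:
            c = panel.cast.at[gene, clone]
            m = panel.r129.at[gene, clone]
            if c + m < th.min_informative_reads:
                continue
            ar = m / (c + m) - 0.5
            if ar >= ar_c:
                n_129 += 1
            elif ar <= -ar_c:
                n_cast += 1
            else:
                n_bi += 1
        det = n_cast + n_129 + n_bi
        if det == 0 or (n_cast + n_129) / det < me_c:
            continue
        n_ame += 1
        if n_cast >= 1 and n_129 >= 1:
            n_arme += 1
    return n_ame, n_arme


class TestThresholdSweep:
    @pytest.fixture()
    def random_panel(self):
        rng = np.random.default_rng(42)
        n_genes, n_clones = 12, 8
        total = rng.integers(20, 200, size=(n_genes, n_clones))
        frac = rng.beta(0.7, 0.7, size=(n_genes, n_clones))
        r129 = rng.binomial(total, frac)
        return make_panel(total - r129, r129)

    def test_matches_brute_force(self, random_panel, defaults):
        ar_grid = [0.2, 0.3, 0.45]
        me_grid = [0.3, 0.4, 0.8]
        table = threshold_sweep(random_panel, ar_grid, me_grid, defaults)
        for _, row in table.iterrows():
            exp_ame, exp_arme = _brute_force_counts(
                random_panel, row["ar_cutoff"], row["me_cutoff"], defaults
            )
            assert (row["n_aME"], row["n_aRME"]) == (exp_ame, exp_arme)

    def test_monotone_in_both_cutoffs(self, random_panel, defaults):
        table = threshold_sweep(
            random_panel, [0.2, 0.3, 0.4, 0.5], [0.2, 0.4, 0.6, 0.8], defaults
        ).set_index(["ar_cutoff", "me_cutoff"])
        for col in ("n_aME", "n_aRME"):
            grid = table[col].unstack()
            assert (grid.diff(axis=0).dropna(how="all") <= 0).all().all()
            assert (grid.diff(axis=1).dropna(axis=1, how="all") <= 0).all().all()

    def test_strict_grid_on_clean_biallelic_panel(self, defaults):
        panel = make_panel([[50] * 6] * 3, [[50] * 6] * 3)
        table = threshold_sweep(panel, [0.5], [0.4], defaults)
        assert table["n_aME"].tolist() == [0]

    def test_single_arme_gene_found_at_defaults(self, defaults):
        cast = [[95, 95, 5, 5, 50, 50], [50] * 6]
        r129 = [[5, 5, 95, 95, 50, 50], [50] * 6]
        panel = make_panel(cast, r129)
        table = threshold_sweep(panel, [0.3], [0.4], defaults)
        assert table["n_aRME"].tolist() == [1]

    def test_empty_grid_rejected(self, random_panel, defaults):
        with pytest.raises(ValueError):
            threshold_sweep(random_panel, [], [0.4], defaults)


class TestSummarizePanel:
    def test_percentages_use_truncation(self):
        assert truncate_percentage(287, 10318)[0] == pytest.approx(2.7)
        assert truncate_percentage(638, 10318)[0] == pytest.approx(6.1)
        assert truncate_percentage(2, 80)[0] == pytest.approx(2.5)
        assert truncate_percentage(0, 80)[0] == 0.0
        # full precision kept alongside
        assert truncate_percentage(287, 10318)[1] == pytest.approx(2.78155, abs=1e-4)

    def test_partition_and_tallies(self, sim_default, defaults):
        panel, _ = sim_default
        table, summary = summarize_panel(panel, defaults)
        assert len(table) == panel.n_genes
        assert sum(summary["tallies"].values()) == panel.n_genes
        n_exp = summary["n_expressed"]
        assert n_exp == int((table["group"] != "UNEXPRESSED").sum())
        assert summary["n_aME"] == int(table["group"].isin(AME_GROUPS).sum())

    def test_arme_rows_satisfy_definition(self, sim_default, defaults):
        panel, _ = sim_default
        table = classify_panel(panel, defaults)
        arme = table[table["group"] == "ARME"]
        assert (arme["me_fraction"] >= defaults.me_fraction_cutoff).all()
        assert (arme["n_mono_cast"] >= 1).all()
        assert (arme["n_mono_129"] >= 1).all()

    def test_strain_swap_symmetry(self, sim_default, defaults):
        """Relabeling parental strains swaps the two ME_BIAS groups only."""
        panel, _ = sim_default
        fwd = classify_panel(panel, defaults)["group"]
        rev = classify_panel(panel.swap_alleles(), defaults)["group"]
        swap = {"ME_BIAS_129": "ME_BIAS_CAST", "ME_BIAS_CAST": "ME_BIAS_129"}
        assert (rev == fwd.map(lambda g: swap.get(g, g))).all()
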