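"""Synthetic clonal-panel generator: determinism, truth, and recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rmescope import (
    SimulationParams,
    Thresholds,
    choice_bias,
    cis_coupling,
    classify_panel,
    compensation_test,
    read_truth,
    simulate_panel,
    write_truth,
)

TRUTH_TO_GROUP = {
    "BIALLELIC": {"BIALLELIC"},
    "ARME_BALANCED": {"ARME"},
    "ARME_SKEWED": {"ARME"},
    "AME_ONE_ALLELE": {"ME_BIAS_CAST", "ME_BIAS_129"},
    "IMPRINTED_LIKE": {"IMPRINTED"},
    "X_LIKE": {"X_LINKED"},
}


class TestChoiceBias:
    def test_equal_affinities_balanced(self):
        for tf in (0.0, 1.0, 100.0):
            assert choice_bias(1.0, 1.0, tf, 5.0) == pytest.approx(0.5)

    def test_higher_129_affinity_favors_cast_me(self):
        p = choice_bias(5.0, 1.0, 0.0, 10.0)
        assert p > 0.99

    def test_tf_overexpression_erases_bias(self):
        low = choice_bias(2.0, 1.0, 0.0, 2.639)
        high = choice_bias(2.0, 1.0, 100.0, 2.639)
        assert abs(high - 0.5) < abs(low - 0.5)
        assert high == pytest.approx(0.5, abs=0.01)

    def test_default_parameters_give_pvt1_like_skew(self):
        p = SimulationParams()
        assert choice_bias(p.affinity_129, p.affinity_cast, p.tf_level, p.kappa) == (
            pytest.approx(56 / 60, abs=0.001)
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            choice_bias(-1.0, 1.0, 0.0, 1.0)


class TestSimulatePanel:
    def test_same_seed_identical(self):
        params = SimulationParams(n_clones=20, seed=99)
        p1, t1 = simulate_panel(params)
        p2, t2 = simulate_panel(params)
        assert p1 == p2
        assert t1.genes.equals(t2.genes)
        assert t1.states.equals(t2.states)

    def test_different_seed_differs(self):
        p1, _ = simulate_panel(SimulationParams(n_clones=20, seed=1))
        p2, _ = simulate_panel(SimulationParams(n_clones=20, seed=2))
        assert not p1.cast.equals(p2.cast)

    def test_truth_counts_match_gene_spec(self, sim_default):
        panel, truth = sim_default
        params = SimulationParams(seed=123)
        counts = truth.genes["true_class"].value_counts().to_dict()
        for cls, n in params.gene_spec:
            assert counts[cls] == n
        assert counts.get("NEIGHBOR", 0) == dict(params.gene_spec)["ARME_SKEWED"]

    def test_biallelic_only_panel_yields_no_ame(self):
        params = SimulationParams(
            n_clones=30,
            gene_spec=(("BIALLELIC", 50),),
            rho=0.0,
            mean_expression=200.0,
            reads_per_tpm=10.0,
            seed=5,
        )
        panel, _ = simulate_panel(params)
        table = classify_panel(panel, Thresholds())
        assert (table["group"] == "BIALLELIC").all()

    def test_balanced_choice_within_binomial_ci(self):
        """CAST-ME share of balanced aRME clones stays inside the exact
        binomial 99% interval around 1/2."""
        params = SimulationParams(
            n_clones=200,
            gene_spec=(("ARME_BALANCED", 1),),
            f_me=1.0,
            leakage=0.0,
            emit_neighbors=False,
            seed=11,
        )
        _, truth = simulate_panel(params)
        states = truth.states["true_state"]
        n_cast = int((states == "MONO_CAST").sum())
        n = int(states.isin(["MONO_CAST", "MONO_129"]).sum())
        assert n == 200
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= n_cast <= hi

    def test_me_rate_approaches_f_me(self):
        params = SimulationParams(
            n_clones=1000,
            gene_spec=(("ARME_BALANCED", 1),),
            f_me=0.6,
            emit_neighbors=False,
            seed=3,
        )
        _, truth = simulate_panel(params)
        rate = truth.states["true_state"].isin(["MONO_CAST", "MONO_129"]).mean()
        assert rate == pytest.approx(0.6, abs=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_clones=0)
        with pytest.raises(ValueError):
            SimulationParams(f_me=1.5)
        with pytest.raises(ValueError):
            SimulationParams(gene_spec=(("NOT_A_CLASS", 3),))
        with pytest.raises(ValueError):
            SimulationParams(rho=1.0)

    def test_male_clones_express_maternal_x(self):
        params = SimulationParams(
            n_clones=40, gene_spec=(("X_LIKE", 2),), female_fraction=0.5, seed=9
        )
        panel, truth = simulate_panel(params)
        males = panel.clone_meta.index[panel.clone_meta["sex"] == "male"]
        male_states = truth.states[truth.states["clone"].isin(males)]["true_state"]
        assert (male_states == "MONO_129").all()


class TestTruthRoundTrip:
    def test_write_read_identity(self, tmp_path, sim_default):
        _, truth = sim_default
        write_truth(truth, tmp_path)
        back = read_truth(tmp_path)
        pd.testing.assert_frame_equal(truth.genes, back.genes, check_dtype=False)
        pd.testing.assert_frame_equal(truth.states, back.states, check_dtype=False)
        assert back.params == truth.params


class TestRecovery:
    def test_class_recovery_on_clean_panel(self, sim_clean):
        """Default thresholds recover >= 95% of true gene classes."""
        params, (panel, truth) = sim_clean
        table = classify_panel(panel, Thresholds())
        merged = table.join(truth.genes)
        scored = merged[merged["true_class"] != "NEIGHBOR"]
        hits = sum(
            row["group"] in TRUTH_TO_GROUP[row["true_class"]]
            for _, row in scored.iterrows()
        )
        assert hits / len(scored) >= 0.95

    def test_compensation_recovered_across_seeds(self):
        """compensation = 1.5 shows up as a significant positive shift in
        nearly all replicate panels."""
        th = Thresholds()
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            params = SimulationParams(
                n_clones=100,
                gene_spec=(("ARME_BALANCED", 1),),
                f_me=0.5,
                compensation=1.5,
                emit_neighbors=False,
                seed=seed,
            )
            panel, _ = simulate_panel(params)
            gene = panel.genes[0]
            states = panel.state_matrix(th).loc[gene]
            tpm = panel.tpm.loc[gene]
            mono = tpm[states.isin(["MONO_CAST", "MONO_129"])]
            bi = tpm[states == "BIALLELIC"]
            diff, _, p = compensation_test(mono, bi)
            if diff > 0 and p < 0.01:
                wins += 1
        assert wins / n_seeds >= 0.9

    def test_coupling_recovered_at_depth(self):
        """Estimated neighbor coupling approaches -coupling_strength."""
        params = SimulationParams(
            n_clones=150,
            gene_spec=(("ARME_SKEWED", 1),),
            f_me=0.6,
            coupling_strength=1.0,
            coupling_noise_sd=0.0,
            rho=0.0,
            mean_expression=500.0,
            reads_per_tpm=20.0,
            seed=21,
        )
        panel, truth = simulate_panel(params)
        focal = truth.genes.index[truth.genes["true_class"] == "ARME_SKEWED"][0]
        neighbor = truth.genes.index[truth.genes["true_class"] == "NEIGHBOR"][0]
        ar = panel.allelic_ratios(10)
        res = cis_coupling(ar.loc[focal].to_numpy(), ar.loc[neighbor].to_numpy())
        assert res.r == pytest.approx(-1.0, abs=0.02)
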