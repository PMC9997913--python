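"""Interaction battery, BH adjustment, hypergeometric enrichment and
stratified grid means."""

import math

import numpy as np
import pandas as pd
import pytest
from conftest import bh_reference, ols_oracle
from scipy import stats

from prcgwas import (
    ConfigError,
    InteractionPair,
    ThicknessCube,
    hypergeometric_overlap,
    interaction_test,
    run_interaction_battery,
    stratified_segment_means,
)
from prcgwas._core import EYES, LAYERS, SEGMENTS


def series(arr, ids=None):
    ids = ids or [f"i{k}" for k in range(len(arr))]
    return pd.Series(np.asarray(arr, dtype=float), index=pd.Index(ids))


class TestInteractionTest:
    def test_noise_free_product_term_exact(self, rng):
        g1 = series(rng.integers(0, 3, 200))
        g2 = series(rng.integers(0, 3, 200), ids=g1.index.tolist())
        y = g1 + g2 + 2.0 * g1 * g2
        res = interaction_test(g1, g2, y)
        assert res["beta_int"] == pytest.approx(2.0, abs=1e-9)

    def test_matches_full_design_oracle(self, rng):
        for _ in range(10):
            n = 60
            g1 = series(rng.integers(0, 3, n))
            g2 = series(rng.integers(0, 3, n), ids=g1.index.tolist())
            C = rng.normal(size=(n, 2))
            cov = pd.DataFrame(C, index=g1.index, columns=["a", "b"])
            y = series(rng.normal(size=n), ids=g1.index.tolist())
            res = interaction_test(g1, g2, y, cov)
            X = np.column_stack([np.ones(n), C, g1, g2, g1 * g2])
            beta, se, p = ols_oracle(y.to_numpy(), X)
            assert res["beta_int"] == pytest.approx(beta[-1], abs=1e-8)
            assert res["se_int"] == pytest.approx(se[-1], abs=1e-8)
            assert res["p"] == pytest.approx(p[-1], abs=1e-8)

    def test_null_interaction_pvalues_uniform(self, rng):
        pvals = []
        n = 800
        for _ in range(300):
            g1 = series(rng.binomial(2, 0.3, n))
            g2 = series(rng.binomial(2, 0.4, n), ids=g1.index.tolist())
            y = 0.3 * g1 + 0.2 * g2 + rng.normal(size=n)
            pvals.append(interaction_test(g1, g2, series(
                y.to_numpy(), ids=g1.index.tolist()), None)["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_interactor_untestable(self):
        g1 = series([1, 1, 1, 1])
        g2 = series([0, 1, 2, 1])
        y = series([1.0, 2.0, 3.0, 2.0])
        assert not interaction_test(g1, g2, y)["testable"]


class TestRunInteractionBattery:
    def test_bh_step_up_hand_trace(self, rng):
        # p = (.01, .02, .03, .04), m=4, FDR .15 -> all four discoveries
        from statsmodels.stats.multitest import multipletests
        reject, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04],
                                        alpha=0.15, method="fdr_bh")
        ref_reject, ref_q = bh_reference([0.01, 0.02, 0.03, 0.04], 0.15)
        assert reject.all() and ref_reject.all()
        assert np.allclose(q, ref_q)

    def test_adjustment_matches_reference_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(100):
            p = rng.uniform(size=rng.integers(3, 40))
            reject, q, _, _ = multipletests(p, alpha=0.15, method="fdr_bh")
            ref_reject, ref_q = bh_reference(p, 0.15)
            assert np.array_equal(reject, ref_reject)
            assert np.allclose(q, ref_q, atol=1e-12)

    def test_unit_pvalues_give_zero_discoveries(self):
        from statsmodels.stats.multitest import multipletests
        reject, q, _, _ = multipletests([1.0] * 6, alpha=0.15,
                                        method="fdr_bh")
        assert not reject.any() and np.allclose(q, 1.0)

    def test_empty_battery_and_untestable_exclusion(self, rng):
        out = run_interaction_battery([], series([1.0, 2.0], ids=["a", "b"]))
        assert out.empty
        n = 50
        ids = [f"i{k}" for k in range(n)]
        const = series(np.ones(n), ids=ids)
        var = series(rng.binomial(2, 0.4, n), ids=ids)
        y = series(rng.normal(size=n), ids=ids)
        pairs = [InteractionPair("const", const, "v", var, "c"),
                 InteractionPair("v", var, "v2",
                                 series(rng.binomial(2, 0.4, n), ids=ids),
                                 "c")]
        out = run_interaction_battery(pairs, y)
        assert not bool(out["TESTABLE"].iloc[0])
        assert np.isnan(out["Q"].iloc[0])
        assert np.isfinite(out["Q"].iloc[1])

    def test_planted_pair_discovered_controlling_fdr(self, rng):
        """One strong planted interaction among null pairs: planted pair
        discovered in >= 80% of replicates, empirical FDR <= 0.15 + MC
        error."""
        n = 1200
        reps = 25
        found = 0
        ratios = []
        for rep in range(reps):
            ids = [f"i{k}" for k in range(n)]
            pairs = []
            g1 = series(rng.binomial(2, 0.3, n), ids=ids)
            g2 = series(rng.binomial(2, 0.3, n), ids=ids)
            y = (0.3 * g1 + 0.3 * g2 + 0.5 * g1 * g2
                 + rng.normal(size=n))
            pairs.append(InteractionPair("p1", g1, "p2", g2, "planted"))
            for k in range(20):
                h1 = series(rng.binomial(2, 0.3, n), ids=ids)
                h2 = series(rng.binomial(2, 0.3, n), ids=ids)
                pairs.append(InteractionPair(f"n{k}a", h1, f"n{k}b", h2,
                                             "null"))
            out = run_interaction_battery(pairs, series(y.to_numpy(),
                                                        ids=ids))
            disc = out[out["DISCOVERY"]]
            v = int((disc["CATEGORY"] == "null").sum())
            ratios.append(v / len(disc) if len(disc) else 0.0)
            found += int((disc["CATEGORY"] == "planted").any())
        assert found >= 0.8 * reps
        # empirical FDR = mean V/R, the expectation BH bounds
        mc_error = 2 * np.std(ratios) / np.sqrt(reps)
        assert np.mean(ratios) <= 0.15 + mc_error

    def test_reduces_to_marginal_model_when_g1_held_out(self, rng):
        """With g1 constant-coded out, the g2 coefficient equals a marginal
        additive fit on g2."""
        n = 300
        g2 = series(rng.binomial(2, 0.4, n))
        y = series(0.5 * g2.to_numpy() + rng.normal(size=n),
                   ids=g2.index.tolist())
        X = np.column_stack([np.ones(n), g2.to_numpy()])
        beta, _, _ = ols_oracle(y.to_numpy(), X)
        g1 = series(np.ones(n), ids=g2.index.tolist())
        res = interaction_test(g1, g2, y)
        assert not res["testable"]


class TestHypergeometricOverlap:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_overlap(0, 4, 5, 20) == 1.0

    def test_exact_enumeration_example(self):
        # N=20, K=5, n=4, k=3: (C(5,3)C(15,1)+C(5,4)C(15,0))/C(20,4)
        expected = (math.comb(5, 3) * math.comb(15, 1)
                    + math.comb(5, 4)) / math.comb(20, 4)
        assert expected == pytest.approx(155 / 4845)
        assert hypergeometric_overlap(3, 4, 5, 20) == pytest.approx(
            expected, rel=1e-12)

    def test_full_overlap_single_term(self):
        for N, K in [(30, 6), (12, 4)]:
            n = k = K
            expected = math.comb(K, n) / math.comb(N, n)
            assert hypergeometric_overlap(k, n, K, N) == pytest.approx(
                expected, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigError):
            hypergeometric_overlap(5, 4, 5, 20)
        with pytest.raises(ConfigError):
            hypergeometric_overlap(1, 30, 5, 20)


class TestStratifiedSegmentMeans:
    def make_cube(self, values, ids):
        return ThicknessCube(values, pd.Index(ids))

    def test_weighted_normalized_means_center_to_zero(self, rng):
        n = 600
        ids = [f"i{k}" for k in range(n)]
        values = rng.normal(70, 4, size=(n, 3, 9, 2))
        ga = series(rng.binomial(2, 0.4, n), ids=ids)
        gb = series(rng.binomial(2, 0.4, n), ids=ids)
        strat = stratified_segment_means(self.make_cube(values, ids), ga,
                                         gb)
        for a in (0, 1, 2):
            block = strat[(strat["GENO_A"] == a) & (strat["N"] > 0)]
            weighted = (block["MEAN_UM"] * block["N"]).sum()
            assert weighted == pytest.approx(0.0, abs=1e-8)

    def test_antisymmetric_interaction_flips_between_strata(self, rng):
        """A planted interaction thinning superior and thickening inferior
        segments reverses sign between partner homozygote strata."""
        n = 3000
        ids = [f"i{k}" for k in range(n)]
        ga = series(rng.binomial(2, 0.5, n), ids=ids)
        gb = series(rng.binomial(2, 0.5, n), ids=ids)
        values = np.full((n, 3, 9, 2), 70.0)
        sup = SEGMENTS.index("IS1")
        inf = SEGMENTS.index("IS3")
        # interaction: for gb=2 vs gb=0, superior thins / inferior thickens
        effect = (gb.to_numpy() - 1.0)
        values[:, 0, sup, :] -= 2.0 * effect[:, None]
        values[:, 0, inf, :] += 2.0 * effect[:, None]
        values += rng.normal(0, 0.5, size=values.shape)
        strat = stratified_segment_means(self.make_cube(values, ids), ga,
                                         gb, layer="ONL")
        for a in (0, 1, 2):
            sup0 = strat.query("GENO_A==@a & GENO_B==0 & SEGMENT=='IS1'")
            sup2 = strat.query("GENO_A==@a & GENO_B==2 & SEGMENT=='IS1'")
            inf0 = strat.query("GENO_A==@a & GENO_B==0 & SEGMENT=='IS3'")
            inf2 = strat.query("GENO_A==@a & GENO_B==2 & SEGMENT=='IS3'")
            assert sup0["MEAN_UM"].iloc[0] > sup2["MEAN_UM"].iloc[0]
            assert inf0["MEAN_UM"].iloc[0] < inf2["MEAN_UM"].iloc[0]

    def test_no_effect_cells_near_zero(self, rng):
        n = 2000
        ids = [f"i{k}" for k in range(n)]
        values = np.full((n, 3, 9, 2), 70.0) + rng.normal(
            0, 1.0, size=(n, 3, 9, 2))
        ga = series(rng.binomial(2, 0.4, n), ids=ids)
        gb = series(rng.binomial(2, 0.4, n), ids=ids)
        strat = stratified_segment_means(self.make_cube(values, ids), ga, gb)
        filled = strat[strat["N"] > 10]
        se = 1.0 / np.sqrt(2 * filled["N"])  # eye-averaged noise SE
        assert (filled["MEAN_UM"].abs() < 5 * se + 0.2).all()

    def test_empty_stratum_marked_missing(self, rng):
        n = 50
        ids = [f"i{k}" for k in range(n)]
        values = np.full((n, 3, 9, 2), 70.0)
        ga = series(np.zeros(n), ids=ids)      # only stratum 0
        gb = series(rng.binomial(2, 0.4, n), ids=ids)
        strat = stratified_segment_means(self.make_cube(values, ids), ga, gb)
        empty = strat[strat["GENO_A"] == 2]
        assert empty["MEAN_UM"].isna().all()
        assert (empty["N"] == 0).all()
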