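"""Association engine: oracle equivalence, meta rule, locus selection,
genomic-inflation diagnostics."""

import numpy as np
import pandas as pd
import pytest
from conftest import ols_oracle

from prcgwas import (
    ConfigError,
    GenotypeMatrix,
    SimConfig,
    compute_lambda_gc,
    meta_min_p,
    run_additive_gwas,
    select_independent_loci,
    simulate_genotypes,
)


def panel_from_dosages(dosages, ids=None, positions=None, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"i{k}" for k in range(n)]
    snps = pd.DataFrame({
        "CHR": chrom if chrom is not None else [1] * m,
        "POS": positions if positions is not None else
        [1_000_000 + j * 10_000 for j in range(m)],
        "ID": [f"s{j}" for j in range(m)],
        "REF": "A", "ALT": "G",
        "AF": np.nanmean(dosages, axis=0) / 2,
    })
    return GenotypeMatrix(dosages, snps, pd.Index(ids))


class TestRunAdditiveGwas:
    def test_noise_free_exact_beta_and_degenerate_flag(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(50, 1)).astype(float)
        g = panel_from_dosages(dos)
        y = pd.Series(3.0 * dos[:, 0] + 5.0, index=g.individuals)
        res = run_additive_gwas(y, g)
        assert res["BETA"].iloc[0] == pytest.approx(3.0, abs=1e-10)
        assert bool(res["degenerate"].iloc[0])

    def test_matches_normal_equations_oracle(self):
        """beta, SE, p equal an independent OLS oracle to 1e-8 on random
        instances with covariates."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, ncov = 50, 3
            dos = rng.integers(0, 3, size=(n, 4)).astype(float)
            g = panel_from_dosages(dos)
            C = rng.normal(size=(n, ncov))
            cov = pd.DataFrame(C, index=g.individuals,
                               columns=[f"c{j}" for j in range(ncov)])
            y = pd.Series(rng.normal(size=n) + dos[:, 0] * 0.3,
                          index=g.individuals)
            res = run_additive_gwas(y, g, cov)
            for j in range(4):
                X = np.column_stack([np.ones(n), C, dos[:, j]])
                beta, se, p = ols_oracle(y.to_numpy(), X)
                assert res["BETA"].iloc[j] == pytest.approx(beta[-1],
                                                            abs=1e-8)
                assert res["SE"].iloc[j] == pytest.approx(se[-1], abs=1e-8)
                assert res["P"].iloc[j] == pytest.approx(p[-1], abs=1e-8)

    def test_planted_effect_recovered_within_3se(self):
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = SimConfig(n_individuals=2000, n_snps=1,
                            maf_range=(0.3, 0.3), seed=100 + rep)
            g = simulate_genotypes(cfg)
            rng = np.random.default_rng(10_000 + rep)
            y = pd.Series(0.5 * g.dosages[:, 0] + rng.normal(size=2000),
                          index=g.individuals)
            res = run_additive_gwas(y, g)
            if abs(res["BETA"].iloc[0] - 0.5) < 3 * res["SE"].iloc[0]:
                hits += 1
        assert hits >= n_rep - 1

    def test_monomorphic_snp_flagged_p_one(self):
        dos = np.column_stack([np.full(30, 2.0),
                               np.random.default_rng(1).integers(
                                   0, 3, 30).astype(float)])
        g = panel_from_dosages(dos)
        y = pd.Series(np.random.default_rng(2).normal(size=30),
                      index=g.individuals)
        res = run_additive_gwas(y, g)
        assert bool(res["monomorphic"].iloc[0])
        assert res["P"].iloc[0] == 1.0
        assert not bool(res["monomorphic"].iloc[1])

    def test_missing_dosage_complete_case_per_snp(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(60, 2)).astype(float)
        dos[:5, 0] = np.nan
        g = panel_from_dosages(dos)
        y = pd.Series(rng.normal(size=60), index=g.individuals)
        res = run_additive_gwas(y, g)
        assert res["N"].iloc[0] == 55
        assert res["N"].iloc[1] == 60
        # complete-case estimate equals oracle on the reduced sample
        ok = ~np.isnan(dos[:, 0])
        X = np.column_stack([np.ones(ok.sum()), dos[ok, 0]])
        beta, se, _ = ols_oracle(y.to_numpy()[ok], X)
        assert res["BETA"].iloc[0] == pytest.approx(beta[-1], abs=1e-8)

    def test_allele_flip_negates_beta_preserves_se_p(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(80, 1)).astype(float)
        g = panel_from_dosages(dos)
        g_flip = panel_from_dosages(2.0 - dos)
        y = pd.Series(rng.normal(size=80) + 0.4 * dos[:, 0],
                      index=g.individuals)
        a = run_additive_gwas(y, g)
        b = run_additive_gwas(y, g_flip)
        assert b["BETA"].iloc[0] == pytest.approx(-a["BETA"].iloc[0],
                                                  abs=1e-10)
        assert b["SE"].iloc[0] == pytest.approx(a["SE"].iloc[0], abs=1e-10)
        assert b["P"].iloc[0] == pytest.approx(a["P"].iloc[0], rel=1e-8)

    def test_underdetermined_raises(self):
        dos = np.ones((3, 1)) + np.arange(3)[:, None]
        g = panel_from_dosages(dos)
        cov = pd.DataFrame(np.eye(3), index=g.individuals,
                           columns=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=g.individuals)
        with pytest.raises(ConfigError):
            run_additive_gwas(y, g, cov)


def assoc_frame(rows):
    return pd.DataFrame(rows, columns=["ID", "CHR", "POS", "P", "BETA",
                                       "SE"])


class TestMetaMinP:
    def test_min_rule_records_source_layer(self):
        onl = assoc_frame([("s1", 1, 100, 1e-9, 0.1, 0.01)])
        is_ = assoc_frame([("s1", 1, 100, 2e-5, 0.1, 0.01)])
        os_ = assoc_frame([("s1", 1, 100, 0.3, 0.1, 0.01)])
        meta = meta_min_p(onl, is_, os_)
        assert meta["P_META"].iloc[0] == 1e-9
        assert meta["SOURCE_LAYER"].iloc[0] == "ONL"

    def test_tie_breaks_to_layer_order(self):
        row = [("s1", 1, 100, 0.01, 0.1, 0.01)]
        meta = meta_min_p(assoc_frame(row), assoc_frame(row),
                          assoc_frame(row))
        assert meta["SOURCE_LAYER"].iloc[0] == "ONL"

    def test_missing_layer_uses_available(self):
        onl = assoc_frame([])
        is_ = assoc_frame([("s1", 1, 100, 0.02, 0.1, 0.01)])
        os_ = assoc_frame([("s1", 1, 100, 0.04, 0.1, 0.01)])
        meta = meta_min_p(onl, is_, os_)
        assert meta["P_META"].iloc[0] == 0.02
        assert meta["SOURCE_LAYER"].iloc[0] == "IS"

    def test_monotone_improving_a_layer_never_worsens_meta(self):
        onl = assoc_frame([("s1", 1, 100, 0.05, 0.1, 0.01)])
        better = assoc_frame([("s1", 1, 100, 0.01, 0.1, 0.01)])
        base = meta_min_p(onl, onl, onl)["P_META"].iloc[0]
        improved = meta_min_p(better, onl, onl)["P_META"].iloc[0]
        assert improved <= base


class TestSelectIndependentLoci:
    def results(self, rows):
        return pd.DataFrame(rows, columns=["ID", "CHR", "POS", "P"])

    def test_greedy_hand_trace(self):
        res = self.results([
            ("a", 1, 10_000_000, 1e-12),
            ("b", 1, 10_800_000, 1e-9),
            ("c", 1, 25_000_000, 1e-10),
        ])
        out = select_independent_loci(res)
        assert list(out["ID"]) == ["a", "c"]
        assert out["locus_group"].nunique() == 2

    def test_different_chromosomes_both_kept(self):
        res = self.results([("a", 1, 100, 1e-9), ("b", 2, 100, 1e-9)])
        out = select_independent_loci(res)
        assert len(out) == 2

    def test_nothing_significant_empty(self):
        res = self.results([("a", 1, 100, 1e-3)])
        assert select_independent_loci(res).empty

    def test_group_labels_within_window(self):
        res = self.results([
            ("a", 1, 10_000_000, 1e-12),
            ("b", 1, 21_000_000, 1e-11),   # 11 Mb away: separate lead
        ])
        out = select_independent_loci(res, group_window=12_000_000)
        assert out["locus_group"].nunique() == 1

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(8)
        rows = [(f"s{j}", int(rng.integers(1, 4)),
                 int(rng.integers(1, 2_000_000_00)),
                 float(10 ** -rng.uniform(6, 15))) for j in range(40)]
        res = self.results(rows)
        out1 = select_independent_loci(res)
        out2 = select_independent_loci(res.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(out1.reset_index(drop=True),
                                      out2.reset_index(drop=True))


class TestLambdaGC:
    def test_null_median_gives_unity(self):
        assert compute_lambda_gc([0.5] * 100) == pytest.approx(1.0,
                                                               abs=1e-3)

    def test_null_gwas_within_band(self):
        # lambda is a sample median: pool several null scans so its Monte
        # Carlo sd (~0.1 at 500 SNPs) shrinks well inside the band
        pvals = []
        for rep in range(6):
            cfg = SimConfig(n_individuals=1000, n_snps=500, seed=21 + rep)
            g = simulate_genotypes(cfg)
            rng = np.random.default_rng(50 + rep)
            y = pd.Series(rng.normal(size=1000), index=g.individuals)
            res = run_additive_gwas(y, g)
            pvals.append(res["P"].to_numpy())
        assert 0.9 <= compute_lambda_gc(np.concatenate(pvals)) <= 1.1

    def test_halving_pvalues_increases_lambda(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=200)
        assert compute_lambda_gc(p / 2) > compute_lambda_gc(p)

    def test_empty_input_raises(self):
        with pytest.raises(ConfigError):
            compute_lambda_gc([])


def test_null_type_i_error_calibrated():
    """Fraction of null SNP tests with p < 0.05 is 0.05 +/- 0.01 over
    >= 10^4 tests."""
    total, sig = 0, 0
    for rep in range(10):
        cfg = SimConfig(n_individuals=500, n_snps=1200, ld_rho=0.0,
                        ld_block_size=1, seed=400 + rep)
        g = simulate_genotypes(cfg)
        rng = np.random.default_rng(500 + rep)
        y = pd.Series(rng.normal(size=500), index=g.individuals)
        res = run_additive_gwas(y, g)
        p = res.loc[~res["monomorphic"], "P"]
        total += len(p)
        sig += int((p < 0.05).sum())
    assert total >= 10_000
    assert abs(sig / total - 0.05) <= 0.01
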