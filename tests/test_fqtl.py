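"""Tests for gene-set z-scoring, the stacked repeated-measures fit, and
genotype-permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from tissueqtl import fqtl
from tissueqtl.fqtl import _SetStatistics, fqtl_fit, fqtl_scan, permutation_fdr, zscore_standardize
from tissueqtl.synthetic_data import SimConfig, simulate_bundle


class TestZscore:
    def test_three_point_example(self):
        z = zscore_standardize(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")))
        np.testing.assert_allclose(z.loc["g"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_rows(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 40))
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        df = pd.DataFrame(x)
        np.testing.assert_allclose(zscore_standardize(df).to_numpy(), x, atol=1e-12)

    def test_constant_gene_dropped_not_errored(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        z = zscore_standardize(df)
        assert list(z.index) == ["ok"]


def _covars(rng, n):
    return rng.integers(1990, 2005, n).astype(float), np.clip(rng.normal(57, 7, n), 40, 80)


class TestFqtlFit:
    def test_orthogonal_dosage_gives_zero_beta(self):
        rng = np.random.default_rng(2)
        n, m = 40, 6
        year, age = _covars(rng, n)
        Z = rng.normal(size=(m, n))
        dosage = rng.binomial(2, 0.4, n).astype(float)
        # orthogonalize dosage against every z-row and the covariates
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), year, age, Z.T]))
        dosage = dosage - Q @ (Q.T @ dosage)
        z = pd.DataFrame(Z, index=[f"g{j}" for j in range(m)])
        beta, t, p, df = fqtl_fit(z, list(z.index), dosage, year, age)
        assert beta == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_shift_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n, m = 60, 10
        year, age = _covars(rng, n)
        dosage = rng.binomial(2, 0.3, n).astype(float)
        Z = np.tile(0.5 * dosage, (m, 1))  # every gene shifted 0.5 per allele
        z = pd.DataFrame(Z, index=[f"g{j}" for j in range(m)])
        beta, t, p, df = fqtl_fit(z, list(z.index), dosage, year, age)
        assert beta == pytest.approx(0.5, abs=1e-10)
        assert df == m * n - 4

    def test_parameter_recovery_under_noise(self):
        from tissueqtl.studies import fqtl_recovery_study

        est = fqtl_recovery_study(range(10), beta3=0.3, set_size=20, n=300)
        assert est["estimate"].mean() == pytest.approx(0.3, abs=0.05)

    def test_collapsed_path_matches_stacked_lstsq(self, small_bundle):
        from tissueqtl.eqtl import select_stratum

        ids = select_stratum(small_bundle.samples, "tumor")
        z = zscore_standardize(small_bundle.expression[ids])
        year = small_bundle.samples.loc[ids, "year_dx"].to_numpy(float)
        age = small_bundle.samples.loc[ids, "age_dx"].to_numpy(float)
        ss = _SetStatistics(z, small_bundle.gene_sets)
        dosage = small_bundle.dosage.loc["rs900003", ids].to_numpy(float)
        beta, t, p, df = ss.stats_for_dosage(year, age, dosage)
        for j, name in enumerate(ss.names):
            b_ref, t_ref, p_ref, df_ref = fqtl_fit(z, small_bundle.gene_sets[name], dosage, year, age)
            assert beta[j] == pytest.approx(b_ref, rel=1e-10, abs=1e-12)
            assert t[j] == pytest.approx(t_ref, rel=1e-10)
            assert df[j] == df_ref

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        n, m = 30, 8
        year, age = _covars(rng, n)
        dosage = rng.binomial(2, 0.3, n).astype(float)
        z = pd.DataFrame(rng.normal(size=(m, n)), index=[f"g{j}" for j in range(m)])
        genes = list(z.index)
        a = fqtl_fit(z, genes, dosage, year, age)
        b = fqtl_fit(z, genes[::-1], dosage, year, age)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_dosage_recoding_flips_beta_sign(self):
        rng = np.random.default_rng(6)
        n, m = 30, 8
        year, age = _covars(rng, n)
        dosage = rng.binomial(2, 0.3, n).astype(float)
        z = pd.DataFrame(rng.normal(size=(m, n)), index=[f"g{j}" for j in range(m)])
        b1, t1, *_ = fqtl_fit(z, list(z.index), dosage, year, age)
        b2, t2, *_ = fqtl_fit(z, list(z.index), 2.0 - dosage, year, age)
        assert b2 == pytest.approx(-b1, rel=1e-10)
        assert t2 == pytest.approx(-t1, rel=1e-10)

    def test_monomorphic_dosage_rejected(self):
        z = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 10)))
        with pytest.raises(ValueError, match="monomorphic"):
            fqtl_fit(z, list(z.index), np.zeros(10), np.ones(10), np.ones(10))


class TestPermutationFdr:
    def test_hand_counted_example(self):
        observed = np.array([3.0, 2.0, 1.0])
        perm = np.array([[0.5, 1.5, 2.5], [0.2, 0.4, 2.6]])
        out = permutation_fdr(observed, perm)
        # at 2.0: mean tail count (1+1)/2 = 1 over 2 observed -> 0.5
        np.testing.assert_allclose(out, [0.0, 0.5, 0.5])

    def test_empty_permutation_tail_gives_zero(self):
        out = permutation_fdr([5.0, 4.0], np.full((10, 2), 1.0))
        np.testing.assert_allclose(out, 0.0)

    def test_null_observed_near_one_at_median(self):
        rng = np.random.default_rng(7)
        observed = np.abs(rng.normal(size=200))
        perm = np.abs(rng.normal(size=(500, 200)))
        out = permutation_fdr(observed, perm)
        med = out[np.argsort(observed)[100]]
        assert med > 0.8

    def test_monotone_in_statistic(self):
        rng = np.random.default_rng(8)
        observed = rng.exponential(size=50)
        perm = rng.exponential(size=(100, 50))
        out = permutation_fdr(observed, perm)
        order = np.argsort(observed)
        assert np.all(np.diff(out[order]) <= 1e-12)

    def test_capped_at_one(self):
        out = permutation_fdr([0.1], np.full((5, 3), 2.0))
        assert out[0] == 1.0


class TestFqtlScan:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        cfg = SimConfig(
            n_subjects=120, paired_fraction=0.0, n_snps=4,
            mafs=[0.2, 0.3, 0.4, 0.5], n_genes=300, n_gene_sets=10,
            gene_set_size_range=(8, 20), noise_sd=1.0,
            planted_fqtl=[("rs900001", "SET004", 0.8)], seed=51,
        )
        return simulate_bundle(cfg)

    def test_planted_set_tops_ranking_with_low_fdr(self, planted):
        rec = fqtl_scan(planted, "tumor", n_permutations=200, seed=1)
        top = rec.sort_values("fdr").iloc[0]
        assert (top["snp"], top["set"]) == ("rs900001", "SET004")
        assert top["fdr"] <= 0.05

    def test_identity_permutation_reproduces_observed(self, planted):
        # permuting dosages with the identity leaves all statistics untouched
        from tissueqtl.eqtl import select_stratum

        ids = select_stratum(planted.samples, "tumor")
        z = zscore_standardize(planted.expression[ids])
        year = planted.samples.loc[ids, "year_dx"].to_numpy(float)
        age = planted.samples.loc[ids, "age_dx"].to_numpy(float)
        ss = _SetStatistics(z, planted.gene_sets)
        d = planted.dosage.loc["rs900001", ids].to_numpy(float)
        t1 = ss.stats_for_dosage(year, age, d)[1]
        t2 = ss.stats_for_dosage(year, age, d[np.arange(len(d))])[1]
        np.testing.assert_array_equal(t1, t2)

    def test_scan_determinism_under_seed(self, planted):
        r1 = fqtl_scan(planted, "tumor", n_permutations=50, seed=9)
        r2 = fqtl_scan(planted, "tumor", n_permutations=50, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_small_sets_skipped(self, planted):
        sets = {"tiny": list(planted.expression.index[:2]), "ok": list(planted.expression.index[:8])}
        rec = fqtl_scan(planted, "tumor", gene_sets=sets, n_permutations=0)
        assert set(rec["set"]) == {"ok"}
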