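import numpy as np
import pytest
from scipy import stats

from famrare import (
    DegenerateDesignError,
    ParameterError,
    chi2min_test,
    cmc_collapse,
    cmc_test,
    compute_pcorr,
    single_marker_test,
    t2_test,
)
from famrare.genotype_geneset import PhenotypeVector
from famrare.pedigree_kinship import KinshipMatrix


def identity_kinship(n):
    return KinshipMatrix([f"S{i + 1}" for i in range(n)], 0.5 * np.eye(n))


def phenotype(y):
    return PhenotypeVector([f"S{i + 1}" for i in range(len(y))], np.asarray(y))


def hotelling_oracle(X, y):
    """Independent Hotelling T2 via np.cov pooled covariance and solve."""
    Xa, Xg = X[y == 1], X[y == 0]
    na, ng = len(Xa), len(Xg)
    S = ((na - 1) * np.cov(Xa, rowvar=False) + (ng - 1) * np.cov(Xg, rowvar=False)) / (
        na + ng - 2
    )
    S = np.atleast_2d(S)
    d = Xa.mean(axis=0) - Xg.mean(axis=0)
    return float(d @ np.linalg.solve((1 / na + 1 / ng) * S, d))


class TestPcorr:
    @pytest.mark.parametrize("n_a,n_g", [(1, 1), (3, 7), (50, 50)])
    def test_identity_kinship_gives_one(self, n_a, n_g):
        y = phenotype([1] * n_a + [0] * n_g)
        assert compute_pcorr(identity_kinship(n_a + n_g), y) == pytest.approx(1.0)

    def test_sib_cases_inflate(self):
        # 2 full-sib cases (phi = 0.25) + 2 unrelated controls -> 1.25
        phi = 0.5 * np.eye(4)
        phi[0, 1] = phi[1, 0] = 0.25
        kin = KinshipMatrix(["S1", "S2", "S3", "S4"], phi)
        y = phenotype([1, 1, 0, 0])
        assert compute_pcorr(kin, y) == pytest.approx(1.25)

    def test_related_case_control_deflates(self):
        # parent-offspring case/control singletons -> (1 + 1 - 2*0.5)/2 = 0.5
        phi = np.array([[0.5, 0.25], [0.25, 0.5]])
        kin = KinshipMatrix(["S1", "S2"], phi)
        y = phenotype([1, 0])
        assert compute_pcorr(kin, y) == pytest.approx(0.5)

    def test_matches_empirical_contrast_variance(self):
        """P_corr equals the variance inflation of the case-control mean
        contrast under exchangeable genotype correlation K."""
        rng = np.random.default_rng(44)
        phi = 0.5 * np.eye(4)
        phi[0, 1] = phi[1, 0] = 0.25
        kin = KinshipMatrix(["S1", "S2", "S3", "S4"], phi)
        y = phenotype([1, 1, 0, 0])
        c = np.array([0.5, 0.5, -0.5, -0.5])
        L = np.linalg.cholesky(kin.k)
        draws = (L @ rng.standard_normal((4, 100_000))).T @ c
        expected = compute_pcorr(kin, y) * (1 / 2 + 1 / 2)
        se = draws.var(ddof=1) * np.sqrt(2 / (len(draws) - 1))
        assert abs(draws.var(ddof=1) - expected) < 3 * se + 3e-3

    def test_all_case_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            compute_pcorr(identity_kinship(3), phenotype([1, 1, 1]))


class TestT2:
    def test_equal_means_give_zero(self):
        X = np.tile(np.array([[0.0], [1.0], [2.0]]), (2, 1))
        y = phenotype([1, 1, 1, 0, 0, 0])
        res = t2_test(X, y, identity_kinship(6))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_single_variant_equals_pooled_z_squared(self):
        rng = np.random.default_rng(45)
        g = rng.integers(0, 3, size=40).astype(float)
        yv = np.array([1] * 15 + [0] * 25)
        res = t2_test(g[:, None], phenotype(yv), identity_kinship(40))
        ga, gg = g[yv == 1], g[yv == 0]
        s2 = (
            ((ga - ga.mean()) ** 2).sum() + ((gg - gg.mean()) ** 2).sum()
        ) / (len(g) - 2)
        z2 = (ga.mean() - gg.mean()) ** 2 / (s2 * (1 / 15 + 1 / 25))
        assert res.statistic == pytest.approx(z2, abs=1e-10)
        assert res.df == 1

    def test_matches_independent_hotelling(self):
        rng = np.random.default_rng(46)
        X = rng.integers(0, 3, size=(60, 5)).astype(float)
        yv = np.array([1] * 25 + [0] * 35)
        res = t2_test(X, phenotype(yv), identity_kinship(60))
        assert res.statistic == pytest.approx(hotelling_oracle(X, yv), abs=1e-10)
        assert res.df == 5
        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.statistic, 5), abs=1e-12
        )

    def test_zero_variance_columns_dropped(self):
        rng = np.random.default_rng(47)
        X = np.column_stack(
            [rng.integers(0, 3, size=30).astype(float), np.zeros(30)]
        )
        res = t2_test(X, phenotype([1] * 10 + [0] * 20), identity_kinship(30))
        assert res.df == 1
        assert "dropped_1_zero_variance" in res.flags

    def test_all_zero_variance_untestable(self):
        X = np.ones((10, 2))
        res = t2_test(X, phenotype([1] * 4 + [0] * 6), identity_kinship(10))
        assert res.df == 0 and res.p_value == 1.0
        assert "untestable" in res.flags

    def test_duplicated_column_uses_pseudo_inverse_rank(self):
        rng = np.random.default_rng(48)
        g = rng.integers(0, 3, size=50).astype(float)
        X = np.column_stack([g, g])
        res = t2_test(X, phenotype([1] * 20 + [0] * 30), identity_kinship(50))
        assert res.df == 1
        assert "rank_deficient" in res.flags

    def test_pcorr_decorrelation_identity(self):
        """For one variant, T2/P_corr equals (c'x)^2 / (s^2 c'Kc): the
        statistic computed against the pedigree-correlated contrast
        variance."""
        rng = np.random.default_rng(49)
        # two families of sibs -> block-diagonal K
        phi = 0.5 * np.eye(6)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4)]:
            phi[i, j] = phi[j, i] = 0.25
        kin = KinshipMatrix([f"S{i + 1}" for i in range(6)], phi)
        yv = np.array([1, 1, 0, 1, 0, 0])
        g = rng.integers(0, 3, size=6).astype(float)
        res = t2_test(g[:, None], phenotype(yv), kin)
        n_a, n_g = 3, 3
        c = np.where(yv == 1, 1 / n_a, -1 / n_g)
        ga, gg = g[yv == 1], g[yv == 0]
        s2 = (((ga - ga.mean()) ** 2).sum() + ((gg - gg.mean()) ** 2).sum()) / 4
        direct = (c @ g) ** 2 / (s2 * (c @ kin.k @ c))
        assert res.statistic == pytest.approx(direct, abs=1e-8)


class TestCMC:
    def test_threshold_below_all_mafs_is_identity(self):
        rng = np.random.default_rng(50)
        X = rng.integers(0, 3, size=(30, 4)).astype(float)
        maf = np.full(4, 0.3)
        np.testing.assert_array_equal(cmc_collapse(X, maf, 0.01), X)

    def test_all_rare_collapse_to_carrier_indicator(self):
        X = np.array([[0, 0, 0], [0, 1, 2], [2, 0, 0]], dtype=float)
        out = cmc_collapse(X, np.array([0.01, 0.02, 0.03]), 0.05)
        np.testing.assert_array_equal(out, [[0.0], [1.0], [1.0]])

    def test_mixed_gene_column_count_and_df(self):
        # 2 common + 3 rare variants -> 2 pass-through columns + 1 super
        # variant, df 3 downstream
        common1 = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2], dtype=float)
        common2 = np.array([0, 0, 1, 1, 2, 2, 0, 0, 1, 1, 2, 2], dtype=float)
        rare = np.zeros((12, 3))
        rare[0, 0] = rare[5, 1] = rare[9, 2] = 1.0
        X = np.column_stack([common1, common2, rare])
        maf = np.array([0.4, 0.3, 0.004, 0.004, 0.004])
        out = cmc_collapse(X, maf, 0.005)
        assert out.shape == (12, 3)
        np.testing.assert_array_equal(
            out[:, 2], rare.sum(axis=1) > 0
        )
        res = cmc_test(
            X,
            phenotype([1, 1, 1, 0, 0, 0] * 2),
            identity_kinship(12),
            maf,
            threshold=0.005,
        )
        assert res.df == 3

    def test_no_rare_equals_t2(self):
        rng = np.random.default_rng(52)
        X = rng.integers(0, 3, size=(40, 3)).astype(float)
        y = phenotype([1] * 15 + [0] * 25)
        kin = identity_kinship(40)
        maf = np.full(3, 0.3)
        assert cmc_test(X, y, kin, maf, 0.005).p_value == pytest.approx(
            t2_test(X, y, kin).p_value, abs=1e-12
        )

    def test_df_never_exceeds_t2_df(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            X = rng.integers(0, 3, size=(30, 6)).astype(float)
            maf = rng.uniform(0.0, 0.5, size=6)
            y = phenotype(rng.permutation([1] * 12 + [0] * 18))
            kin = identity_kinship(30)
            thr = rng.uniform(0.01, 0.5)
            assert cmc_test(X, y, kin, maf, thr).df <= t2_test(X, y, kin).df

    def test_all_rare_matches_contingency_chi2(self):
        """Fully collapsed CMC approaches the 2x2 carrier-table chi2."""
        rng = np.random.default_rng(54)
        n = 600
        carrier = (rng.random(n) < 0.3).astype(float)
        X = carrier[:, None]
        yv = rng.permutation([1] * 250 + [0] * 350)
        res = cmc_test(
            X, phenotype(yv), identity_kinship(n), np.array([0.004]), 0.005
        )
        table = np.array(
            [
                [(carrier[yv == 1] == 1).sum(), (carrier[yv == 1] == 0).sum()],
                [(carrier[yv == 0] == 1).sum(), (carrier[yv == 0] == 0).sum()],
            ]
        )
        chi2_p = stats.chi2_contingency(table, correction=False)[1]
        assert res.p_value == pytest.approx(chi2_p, abs=0.01)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ParameterError):
            cmc_collapse(np.zeros((3, 1)), np.array([0.1]), 0.0)


class TestSingleMarker:
    def test_zero_statistic_case(self):
        # 10/90 vs 10/90 allele counts -> chi2 = 0, p = 1 exactly
        g = np.array([1.0] * 10 + [0.0] * 90 + [1.0] * 10 + [0.0] * 90)
        y = phenotype([1] * 100 + [0] * 100)
        assert single_marker_test(g, y, identity_kinship(200)) == 1.0

    def test_pearson_matches_hand_formula(self):
        # cases 15/85, controls 5/95 minor/major alleles
        g = np.concatenate([np.ones(15), np.zeros(185 // 2)])
        # construct allele counts directly: 100 case alleles needs 50 samples
        g_case = np.array([1.0] * 15 + [0.0] * 35)  # 15 minor / 85 major
        g_ctrl = np.array([1.0] * 5 + [0.0] * 45)  # 5 minor / 95 major
        g = np.concatenate([g_case, g_ctrl])
        y = phenotype([1] * 50 + [0] * 50)
        p = single_marker_test(g, y, identity_kinship(100))
        table = np.array([[15, 85], [5, 95]])
        expected = np.outer(table.sum(1), table.sum(0)) / 200
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-10)

    def test_monomorphic_gives_one(self):
        g = np.zeros(20)
        y = phenotype([1] * 8 + [0] * 12)
        assert single_marker_test(g, y, identity_kinship(20)) == 1.0

    def test_fisher_branch_for_sparse_table(self):
        g = np.array([1.0] + [0.0] * 9 + [0.0] * 10)
        y = phenotype([1] * 10 + [0] * 10)
        p = single_marker_test(g, y, identity_kinship(20))
        table = np.array([[1, 19], [0, 20]])
        assert p == pytest.approx(stats.fisher_exact(table)[1], abs=1e-10)

    def test_pcorr_adjustment_raises_pearson_p(self):
        g_case = np.array([1.0] * 20 + [0.0] * 30)
        g_ctrl = np.array([1.0] * 8 + [0.0] * 42)
        g = np.concatenate([g_case, g_ctrl])
        y = phenotype([1] * 50 + [0] * 50)
        p1 = single_marker_test(g, y, pcorr=1.0)
        p2 = single_marker_test(g, y, pcorr=2.0)
        assert p2 > p1


class TestChi2Min:
    def test_single_variant_equals_single_marker(self):
        rng = np.random.default_rng(55)
        g = rng.integers(0, 2, size=60).astype(float)
        y = phenotype(rng.permutation([1] * 25 + [0] * 35))
        kin = identity_kinship(60)
        res = chi2min_test(g[:, None], y, kin)
        assert res.p_value == pytest.approx(
            single_marker_test(g, y, kin), abs=1e-12
        )
        assert res.df == 1

    def test_takes_minimum_over_variants(self):
        rng = np.random.default_rng(56)
        X = rng.integers(0, 2, size=(80, 5)).astype(float)
        y = phenotype(rng.permutation([1] * 30 + [0] * 50))
        kin = identity_kinship(80)
        res = chi2min_test(X, y, kin)
        singles = [single_marker_test(X[:, j], y, kin) for j in range(5)]
        assert res.p_value == pytest.approx(min(singles), abs=1e-12)

    def test_monomorphic_gene_untestable_p_one(self):
        X = np.zeros((10, 3))
        y = phenotype([1] * 4 + [0] * 6)
        res = chi2min_test(X, y, identity_kinship(10))
        assert res.p_value == 1.0
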