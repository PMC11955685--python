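import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from conngrad.stats import (
    DesignMatrix,
    decode_term_maps,
    design_matrix,
    fdr_bh,
    hotelling_test,
    multivariate_map,
    network_average,
    posthoc_bonferroni,
    univariate_map,
    univariate_test,
)


def two_group_design(n1, n2, covariates=False, rng=None):
    group = np.r_[np.zeros(n1), np.ones(n2)]
    cols = [np.ones(n1 + n2), group]
    names = ["intercept", "group"]
    if covariates:
        cols += [rng.normal(60, 8, n1 + n2), rng.integers(0, 2, n1 + n2).astype(float)]
        names += ["age", "sex"]
    return DesignMatrix(np.column_stack(cols), columns=names)


def classical_t2(y1, y2):
    """Textbook two-sample Hotelling T2: (n1 n2 / n) d' S_pooled^-1 d."""
    n1, n2 = len(y1), len(y2)
    d = y1.mean(0) - y2.mean(0)
    s1 = np.cov(y1, rowvar=False, ddof=1)
    s2 = np.cov(y2, rowvar=False, ddof=1)
    sp = ((n1 - 1) * np.atleast_2d(s1) + (n2 - 1) * np.atleast_2d(s2)) / (n1 + n2 - 2)
    return n1 * n2 / (n1 + n2) * float(d @ np.linalg.solve(sp, d))


class TestHotelling:
    def test_zero_contrast_null_identity(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 3))
        y = np.vstack([base, base])  # identical groups
        x = two_group_design(10, 10)
        t2, f, p = hotelling_test(y, x)
        assert t2 == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_matches_classical_two_sample_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n1, n2, k = rng.integers(8, 15), rng.integers(8, 15), rng.integers(1, 4)
            y1 = rng.normal(size=(n1, k))
            y2 = rng.normal(1.0, 1.0, size=(n2, k))
            t2, _, _ = hotelling_test(np.vstack([y1, y2]), two_group_design(n1, n2))
            assert t2 == pytest.approx(classical_t2(y2, y1), abs=1e-8, rel=1e-8)

    def test_k1_reduces_to_t_squared(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        x = two_group_design(10, 10, covariates=True, rng=rng)
        t2, f, p_multi = hotelling_test(y[:, None], x)
        t, p_uni = univariate_test(y, x)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p_multi == pytest.approx(p_uni, abs=1e-10)

    def test_covariate_adjustment_removes_confound(self):
        # a pure age effect with age balanced against group must not reject
        rng = np.random.default_rng(3)
        n = 40
        x = two_group_design(20, 20, covariates=True, rng=rng)
        age = x.values[:, 2]
        y = np.column_stack([0.5 * age + rng.normal(size=n) for _ in range(3)])
        _, _, p = hotelling_test(y, x)
        assert p > 0.01

    def test_too_few_subjects_rejected(self):
        y = np.zeros((5, 3))
        with pytest.raises(ValueError, match="n_subjects"):
            hotelling_test(y, two_group_design(3, 2))

    def test_singular_covariance_advises(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=20)
        y = np.column_stack([base, base, rng.normal(size=20)])  # collinear responses
        with pytest.raises(ValueError, match="singular"):
            hotelling_test(y, two_group_design(10, 10))


class TestUnivariate:
    def test_normal_equations_fixture(self):
        # 6-subject fixture solved by hand via the normal equations
        x = DesignMatrix(
            np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1.0]]),
            columns=["intercept", "group"],
        )
        y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 10.0])
        # beta = (X'X)^-1 X'y; group effect = 7 - 2 = 5
        xtx_inv = np.linalg.inv(x.values.T @ x.values)
        beta = xtx_inv @ x.values.T @ y
        resid = y - x.values @ beta
        se = np.sqrt(resid @ resid / 4 * xtx_inv[1, 1])
        t_expect = beta[1] / se
        p_expect = 2 * sstats.t.sf(abs(t_expect), 4)
        t, p = univariate_test(y, x)
        assert t == pytest.approx(t_expect, abs=1e-10)
        assert p == pytest.approx(p_expect, abs=1e-10)

    def test_group_swap_flips_sign(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=16)
        x1 = two_group_design(8, 8)
        swapped = x1.values.copy()
        swapped[:, 1] = 1 - swapped[:, 1]
        x2 = DesignMatrix(swapped, columns=x1.columns)
        t1, p1 = univariate_test(y, x1)
        t2, p2 = univariate_test(y, x2)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_variance_response_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            univariate_test(np.full(10, 3.0), two_group_design(5, 5))


class TestFdrAndPosthoc:
    def test_step_up_hand_example(self):
        q = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(fdr_bh([0.2]), [0.2])

    def test_saturation(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_q_ge_p_elementwise(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        assert (fdr_bh(p) >= p - 1e-15).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        p = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(fdr_bh(p)[perm], fdr_bh(p[perm]))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_property_q_bounds_and_monotone_in_p_order(self, p):
        p = np.asarray(p)
        q = fdr_bh(p)
        assert ((q >= p - 1e-12) & (q <= 1 + 1e-12)).all()
        # q preserves the ranking of p
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_posthoc_threshold_arithmetic(self):
        # threshold is exactly 0.05/3 = 0.01666...
        flags = posthoc_bonferroni(np.array([0.0167, 0.0166, 0.0]))
        np.testing.assert_array_equal(flags, [False, True, True])


class TestNetworkAverage:
    def test_constant_gradient(self, region_table):
        n = int(region_table.cortical_mask.sum())
        out = network_average(np.full((n, 3), 2.5), region_table)
        np.testing.assert_allclose(out, 2.5)

    def test_hand_mean(self, region_table):
        cort = region_table.cortical()
        nets = cort.networks
        coords = np.zeros((len(nets), 1))
        vis = np.flatnonzero(nets == "Vis")
        coords[vis[0], 0] = 1.0
        coords[vis[1], 0] = 3.0
        out = network_average(coords, region_table)
        expect = (1.0 + 3.0) / len(vis)
        assert out[0, 0] == pytest.approx(expect)


class TestDecodeTermMaps:
    def test_self_map_ranks_first(self, rng):
        stat = rng.normal(size=10)
        terms = np.vstack([rng.normal(size=10), stat, rng.normal(size=10)])
        out = decode_term_maps(stat, terms, ["a", "self", "b"])
        assert out[0][0] == "self"
        assert out[0][1] == pytest.approx(1.0)

    def test_constant_term_excluded_with_warning(self, rng):
        stat = rng.normal(size=8)
        terms = np.vstack([np.full(8, 2.0), rng.normal(size=8)])
        with pytest.warns(UserWarning, match="constant"):
            out = decode_term_maps(stat, terms, ["flat", "ok"])
        assert [t for t, _ in out] == ["ok"]

    def test_hand_computed_ranking(self):
        stat = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        terms = np.array(
            [
                [0, 1, 2, 3, 4.0],  # r = 1
                [4, 3, 2, 1, 0.0],  # r = -1
                [0, 2, 1, 4, 3.0],  # r = 0.8 by hand
            ]
        )
        out = decode_term_maps(stat, terms, ["up", "down", "mid"], top_n=3)
        assert [t for t, _ in out] == ["up", "mid", "down"]
        assert out[1][1] == pytest.approx(0.8)

    def test_top_n_truncation(self, rng):
        stat = rng.normal(size=12)
        terms = rng.normal(size=(20, 12))
        assert len(decode_term_maps(stat, terms, top_n=15)) == 15


class TestMapWrappers:
    def test_statmap_contract(self, rng):
        scores = rng.normal(size=(24, 5, 3))
        x = two_group_design(12, 12)
        m = multivariate_map(scores, x, [f"u{i}" for i in range(5)])
        assert (m.table["q"] >= m.table["p"] - 1e-15).all()
        assert (m.table["significant"] == (m.table["q"] < 0.05)).all()
        u = univariate_map(scores[:, :, 0], x, [f"u{i}" for i in range(5)])
        assert list(u.table.columns) == ["unit", "statistic", "p", "q", "significant"]

    def test_design_matrix_from_manifest(self, small_cohort):
        d = design_matrix(small_cohort.manifest)
        assert d.columns == ["intercept", "group", "age", "sex"]
        patients = small_cohort.manifest["group"] == "patient"
        np.testing.assert_array_equal(d.values[:, 1], patients.astype(float))
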