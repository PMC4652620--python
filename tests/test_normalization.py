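import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnorm.count_core import CountMatrix
from mirnorm.normalization import (
    METHODS,
    ma_stats,
    normalize,
    normalize_cpm,
    normalize_cyclic_loess,
    normalize_linear_regression,
    normalize_median_ratio,
    normalize_quantile,
    normalize_tmm,
    normalize_total_count,
    normalize_upper_quartile,
)


def make_matrix(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"S{j + 1}" for j in range(rows.shape[1])]
    return CountMatrix(
        pd.DataFrame(rows, index=[f"f{i}" for i in range(rows.shape[0])], columns=samples)
    )


def brute_force_tmm_log2_factor(xk, xr, sk, sr, trim_m=0.30, trim_a=0.05):
    """Independent re-derivation of the weighted trimmed mean of M-values.

    Written from the verbal definition with explicit sorting and loops, kept
    deliberately separate from the vectorized implementation it checks.
    """
    pairs = [(a, b) for a, b in zip(xk, xr) if a > 0 and b > 0]
    M, A, w = [], [], []
    for a, b in pairs:
        m_val = np.log2((a / sk) / (b / sr))
        a_val = 0.5 * np.log2((a / sk) * (b / sr))
        var = (sk - a) / (sk * a) + (sr - b) / (sr * b)
        M.append(m_val)
        A.append(a_val)
        w.append(1.0 / var)
    n = len(M)
    lo_m = int(np.floor(n * trim_m / 2)) + 1
    lo_a = int(np.floor(n * trim_a / 2)) + 1

    def ranks(values):
        order = sorted(range(n), key=lambda i: values[i])
        r = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rm, ra = ranks(M), ranks(A)
    kept = [
        i
        for i in range(n)
        if lo_m <= rm[i] <= n + 1 - lo_m and lo_a <= ra[i] <= n + 1 - lo_a
    ]
    num = sum(w[i] * M[i] for i in kept)
    den = sum(w[i] for i in kept)
    return num / den


class TestCpm:
    def test_arithmetic(self):
        m = make_matrix([[500], [249_500]])
        out, _ = normalize_cpm(m)
        assert out.data.iloc[0, 0] == pytest.approx(2000)

    def test_column_sums_exactly_one_million(self, tiny_matrix):
        out, factors = normalize_cpm(tiny_matrix)
        assert np.allclose(out.data.sum(axis=0), 1e6)
        assert (factors.factors > 0).all()

    def test_already_cpm_scaled_unchanged(self):
        col = np.array([2e5, 3e5, 5e5])
        m = make_matrix(np.column_stack([col, col]))
        out, _ = normalize_cpm(m)
        assert np.allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_proportional_columns_identical_after(self):
        m = make_matrix([[10, 20], [30, 60], [5, 10]])
        out, _ = normalize_cpm(m)
        assert np.allclose(out.data["S1"], out.data["S2"])

    def test_zero_sum_column_rejected(self):
        m = make_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero-sum"):
            normalize_cpm(m)


class TestTotalCount:
    def test_factor_formula(self):
        # sums [100, 200, 400], median baseline 200 -> factors [2, 1, 0.5]
        m = make_matrix([[100, 200, 400]])
        out, factors = normalize_total_count(m)
        assert list(factors.factors) == [2.0, 1.0, 0.5]
        assert factors.reference == "S2"
        assert np.allclose(out.data.sum(axis=0), 200)

    def test_baseline_column_unchanged(self):
        m = make_matrix([[10, 25, 40], [90, 75, 60]])
        out, factors = normalize_total_count(m)
        base = factors.reference
        assert factors.factors[base] == 1.0
        assert np.array_equal(out.data[base], m.data[base])


class TestUpperQuartile:
    def test_identical_columns_factors_one(self, identical_columns):
        out, factors = normalize_upper_quartile(identical_columns)
        assert np.allclose(factors.factors, 1.0)
        assert np.allclose(out.data.to_numpy(), identical_columns.data.to_numpy())

    def test_tripled_column_hand_computed(self):
        rng = np.random.default_rng(5)
        col = rng.integers(1, 100, size=20).astype(float)
        m = make_matrix(np.column_stack([col, 3 * col]))
        out, factors = normalize_upper_quartile(m)
        assert factors.factors["S1"] == pytest.approx(np.sqrt(3))
        assert factors.factors["S2"] == pytest.approx(np.sqrt(3) / 3)
        assert np.allclose(out.data["S1"], out.data["S2"])

    def test_all_zero_feature_ignored_in_quartile(self):
        rng = np.random.default_rng(6)
        base = rng.integers(1, 50, size=(15, 3)).astype(float)
        with_zero = np.vstack([base, np.zeros(3)])
        _, f1 = normalize_upper_quartile(make_matrix(base))
        _, f2 = normalize_upper_quartile(make_matrix(with_zero))
        assert np.allclose(f1.factors.to_numpy(), f2.factors.to_numpy())

    def test_factors_geometric_mean_one(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.integers(0, 500, size=(40, 5)).astype(float))
        _, factors = normalize_upper_quartile(m)
        assert np.exp(np.mean(np.log(factors.factors))) == pytest.approx(1.0, abs=1e-9)


class TestTmm:
    def test_identical_to_reference_factor_one(self, identical_columns):
        _, factors = normalize_tmm(identical_columns)
        assert np.allclose(factors.params["tmm_factors"], 1.0)

    def test_pure_depth_change_factor_one(self):
        rng = np.random.default_rng(8)
        col = rng.integers(1, 200, size=25).astype(float)
        m = make_matrix(np.column_stack([col, 7 * col]))
        _, factors = normalize_tmm(m)
        assert np.allclose(factors.params["tmm_factors"], 1.0, atol=1e-12)

    def test_against_brute_force_oracle(self):
        # 20 features, 4 eight-fold up in sample B, 16 equal
        xa = np.array([100.0] * 20)
        xb = xa.copy()
        xb[:4] *= 8
        m = make_matrix(np.column_stack([xa, xb]))
        _, factors = normalize_tmm(m, reference="S1")
        expected = brute_force_tmm_log2_factor(xb, xa, xb.sum(), xa.sum())
        got = np.log2(factors.params["tmm_factors"]["S2"]) - np.log2(
            factors.params["tmm_factors"]["S1"]
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_against_brute_force_oracle_random(self):
        rng = np.random.default_rng(9)
        xa = rng.integers(1, 1000, size=50).astype(float)
        xb = rng.integers(1, 1000, size=50).astype(float)
        m = make_matrix(np.column_stack([xa, xb]))
        _, factors = normalize_tmm(m, reference="S1")
        expected = brute_force_tmm_log2_factor(xb, xa, xb.sum(), xa.sum())
        got = np.log2(factors.params["tmm_factors"]["S2"]) - np.log2(
            factors.params["tmm_factors"]["S1"]
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_factors_geometric_mean_one(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.integers(0, 300, size=(60, 6)).astype(float))
        _, factors = normalize_tmm(m)
        f = factors.params["tmm_factors"].to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_explicit_reference_matches_dispatch(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.integers(1, 300, size=(30, 3)).astype(float))
        direct = normalize_tmm(m, reference="S2")[1]
        via = normalize(m, "tmm", reference="S2")[1]
        pd.testing.assert_series_equal(direct.factors, via.factors)


class TestMedianRatio:
    def test_hand_computed_size_factors(self):
        m = make_matrix([[100, 200], [50, 100], [10, 20]])
        _, factors = normalize_median_ratio(m)
        sf = factors.params["size_factors"]
        assert sf["S1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["S2"] == pytest.approx(np.sqrt(2))

    def test_identical_columns_size_factors_one(self, identical_columns):
        _, factors = normalize_median_ratio(identical_columns)
        assert np.allclose(factors.params["size_factors"], 1.0)

    def test_scaling_equivariance(self):
        # scaling one column by c rescales every geometric mean by c^(1/n),
        # so the equivariance is relative: factor ratios involving the scaled
        # column grow by exactly c, ratios among the others are unchanged
        rng = np.random.default_rng(12)
        m = make_matrix(rng.integers(1, 500, size=(40, 4)).astype(float))
        _, f0 = normalize_median_ratio(m)
        scaled = CountMatrix(m.data.assign(S3=m.data["S3"] * 10))
        _, f1 = normalize_median_ratio(scaled)
        sf0, sf1 = f0.params["size_factors"], f1.params["size_factors"]
        assert sf1["S3"] / sf1["S1"] == pytest.approx(10 * sf0["S3"] / sf0["S1"])
        assert sf1["S2"] / sf1["S1"] == pytest.approx(sf0["S2"] / sf0["S1"])
        assert sf1["S4"] / sf1["S1"] == pytest.approx(sf0["S4"] / sf0["S1"])
        # and the normalized matrices are identical up to that relabeling
        out0, _ = normalize_median_ratio(m)
        out1, _ = normalize_median_ratio(scaled)
        ratio = out1.data.to_numpy() / out0.data.to_numpy()
        assert np.allclose(ratio, ratio[0, 0])

    def test_no_all_positive_feature_rejected(self):
        m = make_matrix([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="filter"):
            normalize_median_ratio(m)


class TestMaStats:
    def test_arithmetic(self):
        m = make_matrix([[8, 2]])
        s = ma_stats(m, ("S1", "S2"))
        assert s.M.iloc[0] == pytest.approx(2.0)
        assert s.A.iloc[0] == pytest.approx(2.0)

    def test_equal_values_m_zero(self):
        m = make_matrix([[16, 16]])
        s = ma_stats(m, ("S1", "S2"))
        assert s.M.iloc[0] == 0.0
        assert s.A.iloc[0] == pytest.approx(4.0)

    def test_zero_in_either_member_excluded(self):
        m = make_matrix([[0, 5], [4, 4]])
        s = ma_stats(m, ("S1", "S2"), pseudocount=0)
        assert list(s.features) == ["f1"]

    def test_baseline_is_median_profile(self):
        m = make_matrix([[2, 8, 32]])
        s = ma_stats(m, ("S3", "baseline"))
        # median of (2, 8, 32) is 8 -> M = log2(32/8) = 2
        assert s.M.iloc[0] == pytest.approx(2.0)


class TestLinearRegression:
    def test_constant_offset_absorbed(self):
        rng = np.random.default_rng(13)
        base = rng.uniform(10, 1000, size=30)
        m = make_matrix(np.column_stack([base, base, base * 4]))
        out = normalize_linear_regression(m)
        # corrected M ~ 0 -> rebuilt value = geometric mean of sample and baseline
        expected = 2.0 ** (0.5 * np.log2(base * 4 * base))
        assert np.allclose(out.data["S3"], expected, rtol=1e-9)

    def test_identical_to_baseline_unchanged(self, identical_columns):
        out = normalize_linear_regression(identical_columns)
        assert np.allclose(out.data.to_numpy(), identical_columns.data.to_numpy())

    def test_exactly_linear_trend_removed(self):
        # build a sample whose M is exactly linear in its own A coordinate
        # (m = (c0 + c1*log2 g) / (1 - c1/2) solves m = c0 + c1*A with
        # A = log2 g + m/2 when the baseline is g); OLS reproduces the trend
        # exactly, so the corrected sample is the pure 2^A profile
        c0, c1 = 0.3, 0.1
        g = np.geomspace(4, 4096, 24)
        m_exact = (c0 + c1 * np.log2(g)) / (1 - c1 / 2)
        sample = g * 2.0 ** m_exact
        m = make_matrix(np.column_stack([g, g, sample]))
        out = normalize_linear_regression(m)
        a = 0.5 * np.log2(sample * g)
        assert np.allclose(out.data["S3"], 2.0 ** a, rtol=1e-9)


class TestCyclicLoess:
    def test_identical_samples_fixed_point(self, identical_columns):
        out = normalize_cyclic_loess(identical_columns)
        assert np.allclose(
            out.data.to_numpy(), identical_columns.data.to_numpy(), atol=1e-6
        )

    def test_global_shift_removed(self):
        rng = np.random.default_rng(14)
        base = rng.uniform(16, 4096, size=80)
        m = make_matrix(np.column_stack([base, base * 2.0]))
        out = normalize_cyclic_loess(m)
        logged = np.log2(out.data + 1.0)
        median_m = float((logged["S2"] - logged["S1"]).median())
        assert abs(median_m) < 0.05

    def test_intensity_dependent_distortion_removed(self):
        rng = np.random.default_rng(15)
        base = rng.uniform(16, 65_536, size=400)
        a = np.log2(base)
        distort = 2.0 ** (0.8 * np.sin(a / 2.0))
        m = make_matrix(np.column_stack([base, base * distort]))
        out = normalize_cyclic_loess(m)
        logged = np.log2(out.data + 1.0)
        mvals = logged["S2"] - logged["S1"]
        avals = 0.5 * (logged["S2"] + logged["S1"])
        deciles = pd.qcut(avals, 10, labels=False)
        per_decile = mvals.groupby(deciles).median()
        assert float(per_decile.abs().max()) < 0.1

    def test_sparse_pair_skipped_with_warning(self):
        m = make_matrix([[4, 5], [6, 7], [0, 0]])
        with pytest.warns(UserWarning, match="fewer than 10"):
            out = normalize_cyclic_loess(m)
        assert np.allclose(out.data.to_numpy(), m.data.to_numpy(), atol=1e-9)


class TestQuantile:
    def test_hand_sorted_rank_means(self):
        m = make_matrix(np.column_stack([[1, 3, 5], [2, 4, 8]]))
        out = normalize_quantile(m)
        assert np.allclose(np.sort(out.data["S1"]), [1.5, 3.5, 6.5])
        assert np.allclose(np.sort(out.data["S2"]), [1.5, 3.5, 6.5])

    def test_identical_columns_unchanged(self, identical_columns):
        out = normalize_quantile(identical_columns)
        assert np.allclose(out.data.to_numpy(), identical_columns.data.to_numpy())

    def test_tie_rule_enumerated(self):
        # column [0, 0, 7] against [1, 2, 3]: zeros share ranks 1-2
        m = make_matrix(np.column_stack([[0, 0, 7], [1, 2, 3]]))
        out = normalize_quantile(m)
        ref = [(0 + 1) / 2, (0 + 2) / 2, (7 + 3) / 2]  # [0.5, 1.0, 5.0]
        tied = (ref[0] + ref[1]) / 2
        assert out.data["S1"].iloc[0] == pytest.approx(tied)
        assert out.data["S1"].iloc[1] == pytest.approx(tied)
        assert out.data["S1"].iloc[2] == pytest.approx(5.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_sorted_columns_identical_without_ties(self, data):
        n = data.draw(st.integers(min_value=2, max_value=12))
        cols = []
        for _ in range(3):
            col = data.draw(
                st.lists(
                    st.integers(min_value=0, max_value=10_000),
                    min_size=n, max_size=n, unique=True,
                )
            )
            cols.append(col)
        m = make_matrix(np.column_stack(cols))
        out = normalize_quantile(m)
        sorted_cols = np.sort(out.data.to_numpy(), axis=0)
        for j in range(1, sorted_cols.shape[1]):
            assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])


class TestDispatch:
    def test_cpm_identical_to_direct_call(self, tiny_matrix):
        via, f_via = normalize(tiny_matrix, "cpm")
        direct, f_direct = normalize_cpm(tiny_matrix)
        pd.testing.assert_frame_equal(via.data, direct.data)
        pd.testing.assert_series_equal(f_via.factors, f_direct.factors)

    def test_unknown_method_lists_valid_names(self, tiny_matrix):
        with pytest.raises(ValueError, match="rpkm.*cpm"):
            normalize(tiny_matrix, "rpkm")

    def test_none_passthrough_factors_one(self, tiny_matrix):
        out, factors = normalize(tiny_matrix, "none")
        assert np.allclose(out.data.to_numpy(), tiny_matrix.data.to_numpy())
        assert (factors.factors == 1.0).all()

    @pytest.mark.parametrize("method", METHODS)
    def test_shape_nonnegativity_and_identity_fixed_point(self, method, identical_columns):
        out, _ = normalize(identical_columns, method)
        assert out.shape == identical_columns.shape
        assert (out.data.to_numpy() >= 0).all()
        assert np.allclose(
            out.data.to_numpy(), identical_columns.data.to_numpy(), atol=1e-6
        )
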