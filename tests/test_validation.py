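from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cohortval.cohort import CohortError
from cohortval.validation import (
    SingularCovarianceError,
    bandwidth_rule_of_thumb,
    bootstrap_density_band,
    boxplot_stats,
    chi2_reference,
    gaussian_kde_on_grid,
    mahalanobis_quadratic_forms,
    quadratic_forms,
    scatter_pairs,
    spearman_matrices,
    summarize_univariate,
)

from conftest import continuous_cohort


class TestSummarizeUnivariate:
    def test_constant_variable(self):
        real = continuous_cohort(a=[5.0, 5.0, 5.0])
        virtual = continuous_cohort(a=[5.0, 5.0, 5.0])
        table = summarize_univariate(real, virtual, ["a"]).table
        assert (table["mean"] == 5.0).all()
        assert (table["sd"] == 0.0).all()
        assert (table["min"] == 5.0).all() and (table["max"] == 5.0).all()

    def test_hand_computed_summary(self):
        real = continuous_cohort(a=[1.0, 2.0, 3.0, 4.0, 5.0])
        virtual = continuous_cohort(a=[2.0, 2.0, 2.0])
        table = summarize_univariate(real, virtual, ["a"]).table
        row = table[(table.variable == "a") & (table.cohort == "real")].iloc[0]
        assert row["mean"] == 3.0
        assert row["sd"] == pytest.approx(np.sqrt(2.5), abs=1e-12)
        assert row["min"] == 1.0 and row["max"] == 5.0 and row["n"] == 5

    def test_empty_variable_list(self):
        real = continuous_cohort(a=[1.0, 2.0])
        table = summarize_univariate(real, real, []).table
        assert len(table) == 0

    def test_ordering_invariant(self):
        table = summarize_univariate(
            continuous_cohort(a=[1.0, 2.0, 3.0]),
            continuous_cohort(a=[3.0, 1.0, 2.0]),
            ["a"],
        ).table
        assert table["mean"].nunique() == 1

    def test_min_mean_max_invariant(self, rng):
        values = rng.normal(size=40)
        cohort = continuous_cohort(a=values)
        row = summarize_univariate(cohort, cohort, ["a"]).table.iloc[0]
        assert row["min"] <= row["mean"] <= row["max"]
        assert row["sd"] >= 0


class TestBoxplotStats:
    def test_interpolated_median(self):
        box = boxplot_stats(continuous_cohort(a=[1.0, 2.0, 3.0, 4.0]), "a")
        assert box.median == 2.5
        assert box.q1 == 1.75 and box.q3 == 3.25

    def test_all_equal_values(self):
        box = boxplot_stats(continuous_cohort(a=[7.0] * 5), "a")
        assert box.median == box.q1 == box.q3 == 7.0
        assert box.whisker_low == box.whisker_high == 7.0
        assert box.outliers == []

    def test_outlier_beyond_fence(self):
        # q1=1.75, q3=27.25, iqr=25.5 -> upper fence 65.5, so 100 is out
        box = boxplot_stats(continuous_cohort(a=[1.0, 2.0, 3.0, 100.0]), "a")
        assert box.outliers == [100.0]
        assert box.whisker_high == 3.0

    def test_whiskers_within_data_range(self, rng):
        values = rng.standard_t(df=2, size=100)
        box = boxplot_stats(continuous_cohort(a=values), "a")
        assert values.min() <= box.whisker_low <= box.q1
        assert box.q3 <= box.whisker_high <= values.max()
        assert box.q1 <= box.median <= box.q3


class TestScatterPairs:
    def test_pair_count(self):
        cohort = continuous_cohort(a=[1.0, 2.0], b=[3.0, 4.0], c=[5.0, 6.0])
        assert len(scatter_pairs(cohort, cohort, ["a", "b", "c"])) == 3

    def test_point_counts(self):
        cohort = continuous_cohort(a=[1.0, 2.0, 3.0, 4.0], b=[4.0, 3.0, 2.0, 1.0])
        (pair,) = scatter_pairs(cohort, cohort, ["a", "b"])
        assert pair.real.shape == (4, 2)
        assert pair.virtual.shape == (4, 2)

    def test_pairwise_complete(self):
        cohort = continuous_cohort(
            a=[1.0, np.nan, 3.0], b=[1.0, 2.0, 3.0], c=[1.0, 2.0, 3.0]
        )
        pairs = {(p.x, p.y): p for p in scatter_pairs(cohort, cohort, ["a", "b", "c"])}
        assert pairs[("a", "b")].real.shape[0] == 2
        assert pairs[("b", "c")].real.shape[0] == 3

    def test_needs_two_variables(self):
        cohort = continuous_cohort(a=[1.0, 2.0])
        with pytest.raises(CohortError, match="at least 2"):
            scatter_pairs(cohort, cohort, ["a"])


class TestSpearman:
    def test_monotone_pair_is_one(self):
        x = np.linspace(0.0, 3.0, 10)
        cohort = continuous_cohort(a=x, b=np.exp(x))
        result = spearman_matrices(cohort, cohort, ["a", "b"])
        assert result.real_matrix[0, 1] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        # d^2 = {4, 1, 1}: rho = 1 - 6*6 / (3*8) = -0.5
        cohort = continuous_cohort(a=[1.0, 2.0, 3.0], b=[3.0, 1.0, 2.0])
        result = spearman_matrices(cohort, cohort, ["a", "b"])
        assert result.real_matrix[0, 1] == pytest.approx(-0.5)
        assert result.difference_matrix[0, 1] == pytest.approx(0.0)

    def test_unit_diagonal(self, rng):
        cohort = continuous_cohort(
            a=rng.normal(size=10), b=rng.normal(size=10), c=rng.normal(size=10)
        )
        result = spearman_matrices(cohort, cohort, ["a", "b", "c"])
        assert np.allclose(np.diag(result.real_matrix), 1.0)
        assert np.allclose(result.real_matrix, result.real_matrix.T)

    def test_constant_variable_flagged_undefined(self):
        cohort = continuous_cohort(a=[1.0, 1.0, 1.0], b=[1.0, 2.0, 3.0])
        result = spearman_matrices(cohort, cohort, ["a", "b"])
        assert "a" in result.undefined_real
        assert np.isnan(result.real_matrix[0, 1])

    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        cohort = continuous_cohort(a=x, b=y)
        result = spearman_matrices(cohort, cohort, ["a", "b"])
        expected = stats.spearmanr(x, y).statistic
        assert result.real_matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        transform=st.sampled_from(["exp", "cube", "logit-ish"]),
    )
    def test_monotone_transform_invariance(self, seed, transform):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        fn = {
            "exp": np.exp,
            "cube": lambda v: v**3,
            "logit-ish": lambda v: v / (1 + np.abs(v)),
        }[transform]
        base = spearman_matrices(
            continuous_cohort(a=x, b=y), continuous_cohort(a=x, b=y), ["a", "b"]
        ).real_matrix[0, 1]
        mapped = spearman_matrices(
            continuous_cohort(a=fn(x), b=y),
            continuous_cohort(a=fn(x), b=y),
            ["a", "b"],
        ).real_matrix[0, 1]
        assert mapped == pytest.approx(base, abs=1e-12)


class TestQuadraticForms:
    def test_univariate_squared_z_scores(self):
        cohort = continuous_cohort(a=[-1.0, 0.0, 1.0])
        result = quadratic_forms(cohort, cohort, ["a"])
        assert result.d_real.tolist() == pytest.approx([1.0, 0.0, 1.0])
        assert result.d_real.sum() == pytest.approx(1 * (3 - 1))

    def test_sum_identity_random(self, rng):
        for p in range(1, 6):
            n = int(rng.integers(p + 2, 200))
            block = rng.normal(size=(n, p))
            names = [f"v{j}" for j in range(p)]
            d = mahalanobis_quadratic_forms(block, names)
            assert np.all(d >= 0)
            assert d.sum() == pytest.approx(p * (n - 1), rel=1e-8)

    def test_affine_invariance(self, rng):
        n, p = 50, 3
        block = rng.normal(size=(n, p))
        names = ["a", "b", "c"]
        d0 = mahalanobis_quadratic_forms(block, names)
        A = rng.normal(size=(p, p)) + 3 * np.eye(p)
        shift = rng.normal(size=p)
        d1 = mahalanobis_quadratic_forms(block @ A.T + shift, names)
        assert np.allclose(d0, d1, rtol=1e-8)

    def test_identical_cohorts_qq_diagonal(self, rng):
        cohort = continuous_cohort(
            a=rng.normal(size=40), b=rng.normal(size=40)
        )
        result = quadratic_forms(cohort, cohort, ["a", "b"])
        assert np.allclose(result.qq_pairs[:, 0], result.qq_pairs[:, 1])

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=30)
        cohort = continuous_cohort(a=x, b=x.copy(), c=rng.normal(size=30))
        with pytest.raises(SingularCovarianceError) as err:
            quadratic_forms(cohort, cohort, ["a", "b", "c"])
        assert ("a", "b") in err.value.collinear

    def test_n_not_greater_than_p(self):
        cohort = continuous_cohort(a=[1.0, 2.0], b=[2.0, 1.0])
        with pytest.raises(CohortError, match="more than p"):
            quadratic_forms(cohort, cohort, ["a", "b"])

    def test_df_modes(self, rng):
        cohort = continuous_cohort(
            a=rng.normal(size=20), b=rng.normal(size=20), c=rng.normal(size=20)
        )
        assert quadratic_forms(cohort, cohort, ["a", "b", "c"]).df == 2
        assert quadratic_forms(
            cohort, cohort, ["a", "b", "c"], df_mode="classical"
        ).df == 3


class TestChi2Reference:
    def test_df2_median_closed_form(self):
        # chi2(2) is exponential(1/2): median 2*ln(2)
        (q,) = chi2_reference(2, [0.5])
        assert q == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_df1_median_closed_form(self):
        (q,) = chi2_reference(1, [0.5])
        assert q == pytest.approx(stats.norm.ppf(0.75) ** 2, abs=1e-12)

    def test_small_probability_limit(self):
        (q,) = chi2_reference(3, [1e-12])
        assert 0 < q < 1e-3

    def test_invalid_inputs(self):
        with pytest.raises(CohortError):
            chi2_reference(0, [0.5])
        with pytest.raises(CohortError):
            chi2_reference(2, [0.0, 0.5])


class TestDensityBand:
    def test_determinism(self, rng):
        real = continuous_cohort(a=rng.normal(size=120))
        virtual = continuous_cohort(a=rng.normal(size=120))
        r1 = bootstrap_density_band(real, virtual, "a", B=120, seed=42)
        r2 = bootstrap_density_band(real, virtual, "a", B=120, seed=42)
        assert np.array_equal(r1.band_lower, r2.band_lower)
        assert np.array_equal(r1.band_upper, r2.band_upper)
        assert r1.outside_fraction == r2.outside_fraction

    def test_band_orders_and_bounds(self, rng):
        real = continuous_cohort(a=rng.normal(size=100))
        virtual = continuous_cohort(a=rng.normal(size=100))
        result = bootstrap_density_band(real, virtual, "a", B=150, seed=1)
        assert np.all(result.band_lower <= result.band_upper)
        assert np.all(result.density_real >= 0)
        assert 0.0 <= result.outside_fraction <= 1.0
        assert result.p_value == result.outside_fraction

    def test_band_widens_with_level(self, rng):
        real = continuous_cohort(a=rng.normal(size=100))
        virtual = continuous_cohort(a=rng.normal(size=100))
        narrow = bootstrap_density_band(real, virtual, "a", B=150, level=0.90, seed=9)
        wide = bootstrap_density_band(real, virtual, "a", B=150, level=0.99, seed=9)
        assert np.all(wide.band_lower <= narrow.band_lower + 1e-15)
        assert np.all(wide.band_upper >= narrow.band_upper - 1e-15)

    def test_shifted_virtual_flags_deviation(self, rng):
        real = continuous_cohort(a=rng.normal(size=200))
        virtual = continuous_cohort(a=rng.normal(size=200) + 8.0)
        result = bootstrap_density_band(real, virtual, "a", B=120, seed=4)
        assert result.outside_fraction > 0.3
        assert result.deviation_detected

    def test_rejects_small_b_and_small_cohorts(self, rng):
        real = continuous_cohort(a=rng.normal(size=100))
        with pytest.raises(CohortError, match="B must be"):
            bootstrap_density_band(real, real, "a", B=50)
        tiny = continuous_cohort(a=rng.normal(size=5))
        with pytest.raises(CohortError, match="at least 10"):
            bootstrap_density_band(tiny, tiny, "a", B=100)

    def test_kde_integrates_to_one(self, rng):
        values = rng.normal(size=80)
        bw = bandwidth_rule_of_thumb(values)
        grid = np.linspace(values.min() - 5 * bw, values.max() + 5 * bw, 2048)
        dens = gaussian_kde_on_grid(values, bw, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bandwidth_matches_reference_rule(self, rng):
        values = rng.normal(size=64)
        sd = values.std(ddof=1)
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 64 ** (-0.2)
        assert bandwidth_rule_of_thumb(values) == pytest.approx(expected)
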