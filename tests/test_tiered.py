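import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npxfactor.exceptions import DegenerateFitError, ParameterError
from npxfactor.npx_io import MatchedCohort, NPXMatrix
from npxfactor.simulate import SimConfig, gen_matched_cohort
from npxfactor.tiered import (
    TierScheme,
    cooks_distance,
    fit_cohort,
    fit_ols,
    pearson_screen,
    rank_outliers,
    slope_ci,
    tiered_fit,
    variance_diagnostics,
)

from conftest import brute_force_cooks


class TestFitOLS:
    def test_identity_line(self):
        f = fit_ols(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        assert f.slope == pytest.approx(1.0)
        assert f.intercept == pytest.approx(0.0)
        assert f.r2 == pytest.approx(1.0)

    def test_closed_form_example(self):
        # least-squares by hand: Sxy=3, Sxx=5, SSE=3.2, SStot=5
        f = fit_ols(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3]))
        assert f.slope == pytest.approx(0.6)
        assert f.intercept == pytest.approx(1.0)
        assert f.r2 == pytest.approx(0.36)
        assert f.slope_se == pytest.approx(np.sqrt(1.6 / 5))  # s^2=SSE/(n-2)=1.6

    def test_zero_variance_x_raises(self):
        with pytest.raises(DegenerateFitError):
            fit_ols(np.array([1.0, 1, 1, 1]), np.array([1.0, 2, 3, 4]))

    def test_zero_variance_y_flagged(self):
        f = fit_ols(np.array([1.0, 2, 3, 4]), np.array([5.0, 5, 5, 5]))
        assert f.degenerate_y
        assert f.slope == 0.0
        assert f.r2 == 0.0

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(scale=0.5, size=12)
        import statsmodels.api as sm

        ref = sm.OLS(y, sm.add_constant(x)).fit()
        f = fit_ols(x, y)
        assert f.slope == pytest.approx(ref.params[1], rel=1e-10)
        assert f.slope_se == pytest.approx(ref.bse[1], rel=1e-10)
        assert f.r2 == pytest.approx(ref.rsquared, rel=1e-10)


class TestCooksDistance:
    def test_collinear_data_all_zero(self):
        x = np.array([0.0, 1, 2, 3])
        f = fit_ols(x, 2 * x + 1)
        assert np.all(cooks_distance(f) == 0.0)

    def test_displaced_point_has_max_distance(self):
        x = np.array([0.0, 1, 2, 3])
        y = np.array([0.0, 1, 2, 10])
        d = cooks_distance(fit_ols(x, y))
        assert int(np.argmax(d)) == 3
        # leave-one-out refit oracle agrees
        assert np.allclose(d, brute_force_cooks(x, y), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_formula_equals_leave_one_out(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        x = rng.normal(size=n)
        y = 0.9 * x + rng.normal(scale=0.4, size=n)
        f = fit_ols(x, y)
        assert np.allclose(cooks_distance(f), brute_force_cooks(x, y), rtol=1e-10)

    def test_matches_statsmodels_influence(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = 1.1 * x + rng.normal(scale=0.3, size=15)
        import statsmodels.api as sm

        infl = sm.OLS(y, sm.add_constant(x)).fit().get_influence()
        assert np.allclose(cooks_distance(fit_ols(x, y)),
                           infl.cooks_distance[0], rtol=1e-9)


class TestRankOutliers:
    def test_simple(self):
        assert rank_outliers([0.1, 0.9, 0.2], 1) == [1]

    def test_tie_broken_by_input_order(self):
        assert rank_outliers([0.5, 0.9, 0.9, 0.1, 0.9], 2) == [1, 2]

    def test_sample_ids_returned(self):
        assert rank_outliers([0.1, 0.9, 0.2], 1, sample_ids=["a", "b", "c"]) == ["b"]

    def test_k_too_large(self):
        with pytest.raises(ParameterError):
            rank_outliers([0.1, 0.9, 0.2, 0.4], 5)

    def test_topk_matches_sort(self):
        rng = np.random.default_rng(0)
        d = rng.random(19)
        got = rank_outliers(d, 3)
        expect = list(np.argsort(-d)[:3])
        assert got == expect


class TestSlopeCI:
    def test_zero_se_gives_zero(self):
        assert slope_ci(0.0, 10) == 0.0

    def test_t_quantile_example(self):
        # t(0.975, df=2) = 4.3027 times se = sqrt(0.32)
        assert slope_ci(np.sqrt(1.6 / 5), 4, 0.05) == pytest.approx(2.4339, rel=1e-4)

    def test_undefined_below_three(self):
        with pytest.raises(ParameterError):
            slope_ci(0.1, 2)


class TestTieredFit:
    def test_exact_line_is_tier1(self):
        x = np.linspace(0, 5, 19)
        fit = tiered_fit(x, 0.8 * x + 2.0)
        assert fit.tier == 1
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.8)
        assert fit.excluded_samples == []
        assert fit.ci_halfwidth == pytest.approx(0.0, abs=1e-12)

    def test_two_displaced_points_recovered_at_tier2(self):
        x = np.linspace(0, 5, 19)
        y = 0.9 * x + 1.0
        y[4] += 8.0
        y[11] += 8.0
        fit = tiered_fit(x, y, sample_ids=[f"S{i}" for i in range(19)])
        assert fit.tier == 2
        assert sorted(fit.excluded_samples) == ["S11", "S4"]
        assert fit.n_used == 17
        # oracle: refit without the displaced points
        keep = np.array([i for i in range(19) if i not in (4, 11)])
        oracle = fit_ols(x[keep], y[keep])
        assert fit.slope == pytest.approx(oracle.slope, rel=1e-12)
        assert fit.slope == pytest.approx(0.9, abs=1e-9)

    def test_three_displaced_points_fall_to_tier3(self):
        x = np.linspace(0, 5, 19)
        y = 0.9 * x + 1.0
        for i in (3, 9, 15):
            y[i] += 8.0
        fit = tiered_fit(x, y)
        assert fit.tier == 3
        assert fit.n_used == 16
        assert fit.slope == pytest.approx(0.9, abs=1e-9)

    def test_hopeless_data_non_modelable(self):
        rng = np.random.default_rng(0)
        fit = tiered_fit(rng.normal(size=19), rng.normal(size=19))
        assert fit.tier is None
        assert not fit.modelable
        assert fit.n_used == 19  # carries the tier-1 fit

    def test_removal_counts_fraction_vs_fixed(self):
        assert TierScheme().removal_counts(19) == (0, 2, 3)
        assert TierScheme().removal_counts(40) == (0, 4, 6)
        assert TierScheme(fixed_counts=(0, 2, 3)).removal_counts(40) == (0, 2, 3)

    def test_constant_serum_non_modelable(self):
        fit = tiered_fit(np.ones(10), np.arange(10.0))
        assert fit.tier is None
        assert fit.degenerate

    def test_missing_pairs_excluded(self):
        x = np.array([0.0, 1, 2, 3, np.nan, 5])
        y = np.array([0.0, 1, 2, 3, 4, np.nan])
        fit = tiered_fit(x, y)
        assert fit.n_total == 4
        assert fit.tier == 1

    def test_tier_exclusivity_by_recomputation(self):
        """A tier-t protein fails the R2 threshold at every tier above t."""
        cohort, _ = gen_matched_cohort(SimConfig(n_proteins=120, seed=2))
        scheme = TierScheme()
        for protein in cohort.protein_ids:
            x = cohort.serum.values[protein].to_numpy()
            y = cohort.plasma.values[protein].to_numpy()
            fit = tiered_fit(x, y, scheme)
            if fit.tier in (2, 3):
                assert fit_ols(x, y).r2 < scheme.r2_threshold
            if fit.tier == 3:
                d = cooks_distance(fit_ols(x, y))
                keep = np.setdiff1d(np.arange(19), np.argsort(-d, kind="stable")[:2])
                assert fit_ols(x[keep], y[keep]).r2 < scheme.r2_threshold

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(0.2, 5.0), b=st.floats(-10.0, 10.0), seed=st.integers(0, 100))
    def test_location_scale_covariance(self, a, b, seed):
        """Rescaling serum x -> a*x + b divides the slope by a, leaves R2 put."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=19)
        y = 0.9 * x + rng.normal(scale=0.3, size=19)
        f0 = tiered_fit(x, y)
        f1 = tiered_fit(a * x + b, y)
        assert f1.slope == pytest.approx(f0.slope / a, rel=1e-8, abs=1e-10)
        assert f1.r2 == pytest.approx(f0.r2, rel=1e-8)
        assert f1.tier == f0.tier

    def test_deterministic(self, default_cohort):
        cohort, _ = default_cohort
        fits_a = fit_cohort(cohort)
        fits_b = fit_cohort(cohort)
        for a, b in zip(fits_a, fits_b):
            assert (a.protein_id, a.tier, a.slope, a.intercept, a.slope_se,
                    a.r2, a.ci_halfwidth, tuple(a.excluded_samples)) == \
                   (b.protein_id, b.tier, b.slope, b.intercept, b.slope_se,
                    b.r2, b.ci_halfwidth, tuple(b.excluded_samples))


def _tiny_cohort(serum: dict, plasma: dict) -> MatchedCohort:
    s = pd.DataFrame(serum)
    p = pd.DataFrame(plasma)
    idx = [f"S{i}" for i in range(len(s))]
    s.index = idx
    p.index = idx
    return MatchedCohort(
        serum=NPXMatrix(s, medium="serum"), plasma=NPXMatrix(p, medium="plasma"),
        subject_map=[(i, i) for i in idx],
    )


class TestPearsonScreen:
    def test_perfect_and_anticorrelated(self):
        v = [1.0, 2.0, 3.0, 4.0]
        cohort = _tiny_cohort({"A": v, "B": v}, {"A": v, "B": [-x for x in v]})
        screen = pearson_screen(cohort, 0.5)
        assert screen.loc["A", "pearson_r"] == pytest.approx(1.0)
        assert bool(screen.loc["A", "passes"])
        assert screen.loc["B", "pearson_r"] == pytest.approx(-1.0)
        assert not bool(screen.loc["B", "passes"])  # threshold on signed r

    def test_zero_variance_undefined(self):
        cohort = _tiny_cohort({"A": [1.0, 1, 1, 1]}, {"A": [1.0, 2, 3, 4]})
        screen = pearson_screen(cohort, 0.5)
        assert np.isnan(screen.loc["A", "pearson_r"])
        assert not bool(screen.loc["A", "passes"])

    def test_screen_does_not_restrict_fitting(self, default_cohort):
        cohort, _ = default_cohort
        screen = pearson_screen(cohort, 0.5)
        fits = fit_cohort(cohort)
        assert len(fits) == len(screen) == cohort.serum.n_proteins


class TestVarianceDiagnostics:
    def test_constant_protein(self):
        cohort = _tiny_cohort({"A": [1.0, 2, 3, 4]}, {"A": [2.0, 2, 2, 2]})
        diag = variance_diagnostics(cohort, fit_cohort(cohort))
        assert diag.loc["A", "plasma_variance"] == 0.0
        assert not bool(diag.loc["A", "modelable"])

    def test_mean_shift_leaves_fit_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=19)
        y = 0.9 * x + rng.normal(scale=0.3, size=19)
        f0 = tiered_fit(x, y)
        f1 = tiered_fit(x + 7.0, y + 7.0)
        assert f1.tier == f0.tier
        assert f1.r2 == pytest.approx(f0.r2, rel=1e-9)
        assert f1.slope == pytest.approx(f0.slope, rel=1e-9)

    def test_modelable_fraction_higher_in_high_variance_stratum(self, default_cohort):
        cohort, truth = default_cohort
        diag = variance_diagnostics(cohort, fit_cohort(cohort)).join(
            truth[["low_variance"]])
        low = diag[diag.low_variance]["modelable"].mean()
        high = diag[~diag.low_variance]["modelable"].mean()
        assert high > low
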