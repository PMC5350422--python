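import numpy as np
import pytest

from qpar.perturbation import (RegionSpec, mean_fingerprint,
                               perturb_and_predict, perturbation_table,
                               select_regions, select_regions_combined)
from qpar.pls import PLSRegressionNIPALS, fit_pls


class _LinearModel:
    """Minimal affine predictor with a controllable coefficient vector."""

    def __init__(self, coef, intercept=0.0):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = intercept

    def predict(self, X):
        return self.intercept + np.asarray(X, dtype=float) @ self.coef

    def full_coef(self, n):
        assert n == len(self.coef)
        return self.coef.copy()


class TestMeanFingerprint:
    def test_identical_rows(self):
        X = np.tile(np.arange(5.0), (3, 1))
        np.testing.assert_array_equal(mean_fingerprint(X), np.arange(5.0))

    def test_two_row_average(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        np.testing.assert_array_equal(mean_fingerprint(X), [1.0, 1.0])

    def test_panel_shape(self, small_panel):
        fm = small_panel["fm"]
        assert mean_fingerprint(fm).shape == (fm.n_points,)


class TestSelectRegions:
    def test_six_vector_exhaustive_case(self):
        model = _LinearModel([1.0, 1.0, 0.0, 0.0, -2.0, -2.0])
        regions = select_regions(model, 6, 1, 1, 1, min_width=2)
        by_cat = {r.category: (r.start, r.end) for r in regions}
        assert by_cat == {"positive": (0, 2), "zero": (2, 4), "negative": (4, 6)}
        aggs = {r.category: r.aggregate_coefficient for r in regions}
        assert aggs["positive"] == pytest.approx(2.0)
        assert aggs["negative"] == pytest.approx(-4.0)
        assert aggs["zero"] == 0.0

    def test_all_zero_coefficients_error(self):
        model = _LinearModel(np.zeros(10))
        with pytest.raises(ValueError):
            select_regions(model, 10, 1, 0, 0, min_width=2)

    def test_thirteen_regions_on_fitted_models(self, default_panel):
        fm = default_panel["fm"]
        y = default_panel["activities"].values
        pls = fit_pls(fm.X, y, 5)
        from qpar.elastic_net import ENPLSRegressor, lambda1_max
        en = ENPLSRegressor(lambda1=0.015 * lambda1_max(fm.X, y), lambda2=10.0).fit(fm.X, y)
        regions = select_regions_combined(pls, en, fm.n_points, 6, 5, 2)
        assert len(regions) == 13
        cats = [r.category for r in regions]
        assert cats.count("positive") == 6
        assert cats.count("negative") == 5
        assert cats.count("zero") == 2
        intervals = sorted((r.start, r.end) for r in regions)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in
                   zip(intervals, intervals[1:]))

    def test_insufficient_runs_names_category(self):
        model = _LinearModel([1.0] * 6)
        with pytest.raises(ValueError, match="negative"):
            select_regions(model, 6, 1, 1, 0, min_width=2)


class TestPerturbAndPredict:
    def test_zero_coefficient_region_gives_zero(self):
        model = _LinearModel([1.0, 1.0, 0.0, 0.0, -2.0, -2.0])
        region = RegionSpec(1, 2, 4, "zero", 0.0)
        base = np.ones(6)
        for scale in (0.5, 1.0, 2.0):
            assert perturb_and_predict(model, base, region, scale) == 0.0

    def test_zero_increase_gives_zero(self):
        model = _LinearModel([1.0, -1.0, 2.0])
        region = RegionSpec(1, 0, 2, "positive", 0.0)
        assert perturb_and_predict(model, np.ones(3), region, 0.0) == 0.0

    def test_exact_dose_linearity(self, small_panel):
        fm = small_panel["fm"]
        y = small_panel["activities"].values
        m = fit_pls(fm.X, y, 4)
        base = mean_fingerprint(fm)
        region = RegionSpec(1, 50, 90, "positive", 1.0)
        d50 = perturb_and_predict(m, base, region, 0.5)
        d100 = perturb_and_predict(m, base, region, 1.0)
        d200 = perturb_and_predict(m, base, region, 2.0)
        assert d200 == pytest.approx(4 * d50, rel=1e-9)
        assert d200 == pytest.approx(2 * d100, rel=1e-9)

    def test_matches_closed_form(self, small_panel):
        fm = small_panel["fm"]
        y = small_panel["activities"].values
        m = fit_pls(fm.X, y, 3)
        base = mean_fingerprint(fm)
        region = RegionSpec(1, 100, 140, "positive", 1.0)
        delta = perturb_and_predict(m, base, region, 0.5)
        expected = 0.5 * float(m.coef_[100:140] @ base[100:140])
        assert delta == pytest.approx(expected, rel=1e-9)

    def test_additivity_over_disjoint_regions(self, small_panel):
        fm = small_panel["fm"]
        y = small_panel["activities"].values
        m = fit_pls(fm.X, y, 3)
        base = mean_fingerprint(fm)
        r1 = RegionSpec(1, 10, 40, "positive", 1.0)
        r2 = RegionSpec(2, 200, 240, "negative", -1.0)
        both = base.copy()
        both[10:40] *= 1.5
        both[200:240] *= 1.5
        combined = float(m.predict(both[None])[0] - m.predict(base[None])[0])
        assert combined == pytest.approx(
            perturb_and_predict(m, base, r1, 0.5)
            + perturb_and_predict(m, base, r2, 0.5), rel=1e-9)

    def test_sign_concordance(self, small_panel):
        fm = small_panel["fm"]
        y = small_panel["activities"].values
        m = fit_pls(fm.X, y, 3)
        base = np.abs(mean_fingerprint(fm)) + 0.01
        for start in (0, 100, 250):
            region = RegionSpec(1, start, start + 30, "any", 0.0)
            delta = perturb_and_predict(m, base, region, 1.0)
            assert np.sign(delta) == np.sign(m.coef_[start:start + 30] @ base[start:start + 30])

    def test_region_outside_grid_rejected(self):
        model = _LinearModel([1.0, 2.0])
        with pytest.raises(ValueError):
            perturb_and_predict(model, np.ones(2), RegionSpec(1, 0, 5, "positive", 0.0), 1.0)


class TestPerturbationTable:
    def test_zero_region_row_of_zeros(self):
        model = _LinearModel([1.0, 1.0, 0.0, 0.0])
        region = RegionSpec(1, 2, 4, "zero", 0.0)
        table = perturbation_table({"PLS": model}, np.ones(4), [region])
        row = table.iloc[0]
        assert row["delta_50"] == row["delta_100"] == row["delta_200"] == 0.0

    def test_dose_response_ordering_positive_region(self):
        model = _LinearModel([2.0, 2.0, 0.0])
        region = RegionSpec(1, 0, 2, "positive", 4.0)
        table = perturbation_table({"PLS": model}, np.ones(3), [region])
        row = table.iloc[0]
        assert row["delta_50"] < row["delta_100"] < row["delta_200"]

    def test_both_models_present_per_region(self, small_panel):
        fm = small_panel["fm"]
        y = small_panel["activities"].values
        pls = fit_pls(fm.X, y, 3)
        sub = np.arange(50, 150)
        en_like = PLSRegressionNIPALS(n_components=2, variable_subset=sub).fit(fm.X, y)
        regions = [RegionSpec(1, 0, 30, "zero", 0.0),
                   RegionSpec(2, 60, 90, "positive", 1.0)]
        table = perturbation_table({"PLS": pls, "EN-PLS": en_like},
                                   mean_fingerprint(fm), regions, X=fm, y=y)
        assert len(table) == 4
        # region 1 lies outside the restricted model's support -> coefficient 0
        r1_en = table[(table.region_id == 1) & (table.model == "EN-PLS")].iloc[0]
        assert r1_en["coefficient"] == 0.0
        assert r1_en["delta_100"] == 0.0
        assert "pearson_r" in table.columns
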