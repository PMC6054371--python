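import numpy as np
import pandas as pd
import pytest

from rsfpipe.design import _fractions, _gather_window, coverage_proportions
from rsfpipe.flowlines import FlowlineSet
from rsfpipe.predict import selection_probability, project_landscape, selection_curves
from rsfpipe.rasters import LandCoverRaster
from rsfpipe.rsf import FittedRSF


def make_model(beta0=0.0, corn=0.0, wet=0.0, flin=0.0, fquad=0.0,
               dist_mean=500.0, dist_sd=200.0, quad_mean=40_000.0, quad_sd=50_000.0,
               sigma_b=0.0, scheme="H1"):
    beta = {
        "prop_Corn": corn, "prop_Wetland": wet,
        "prop_Rice": 0.0, "prop_Soybeans": 0.0, "prop_OtherCrop": 0.0,
        "prop_OtherNoncrop": 0.0, "prop_Water": 0.0,
        "dist_flow_std": flin, "dist_flow_quad_std": fquad,
    }
    return FittedRSF(
        season="s1", scheme=scheme, beta0=beta0, beta=beta, sigma_b=sigma_b,
        se={}, loglik=-1.0, aic=2.0, n_obs=10, n_groups=2, converged=True,
        boundary=False,
        standardization={"dist_mean": dist_mean, "dist_sd": dist_sd,
                         "quad_mean": quad_mean, "quad_sd": quad_sd},
        reference_category="Fallow",
    )


class TestSelectionProbability:
    def test_all_zero_coefficients_give_half(self):
        m = make_model()
        for P in (0.0, 0.3, 1.0):
            assert selection_probability(m, "Corn", P, 700.0) == pytest.approx(0.5)

    def test_unit_crop_coefficient_at_standardized_zero_distance(self):
        # z = 0 at dist = dist_mean; flowline terms zero anyway
        m = make_model(corn=1.0)
        p = selection_probability(m, "Corn", 1.0, 500.0)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-9)
        assert p == pytest.approx(0.7311, abs=1e-4)

    def test_random_intercept_has_no_effect(self):
        a = make_model(corn=0.7, wet=0.4, sigma_b=0.0)
        b = make_model(corn=0.7, wet=0.4, sigma_b=1.5)
        assert selection_probability(a, "Corn", 0.4, 600.0) == selection_probability(b, "Corn", 0.4, 600.0)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            selection_probability(make_model(), "Maize", 0.5, 100.0)

    def test_missing_standardization_rejected(self):
        m = make_model()
        m.standardization = {}
        with pytest.raises(ValueError):
            selection_probability(m, "Corn", 0.5, 100.0)


@pytest.fixture
def season_table():
    """Minimal table shim exposing the season's raw flowline distances."""
    from rsfpipe.design import UseAvailableTable

    df = pd.DataFrame(
        {
            "individual_id": "a",
            "season": "s1",
            "used": 1,
            "dist_flow_raw": np.linspace(0.0, 900.0, 101),
        }
    )
    return UseAvailableTable(df, {"s1": {}}, "H1", ["Corn"], "Fallow", 100.0)


class TestSelectionCurves:
    def test_monotone_with_sign_of_coefficient_gap(self, season_table):
        for corn, wet in ((1.2, 0.3), (0.1, 0.9)):
            m = make_model(corn=corn, wet=wet)
            curves = selection_curves(m, ["Corn"], season_table)
            for c in curves:
                assert c.slope_sign == np.sign(corn - wet)
                assert np.all(np.diff(c.p_values) * np.sign(corn - wet) > 0)

    def test_p_zero_endpoint_is_pure_wetland(self, season_table):
        m = make_model(corn=1.0, wet=0.5)
        c_corn = selection_curves(m, ["Corn"], season_table)[0]
        m2 = make_model(corn=-2.0, wet=0.5)  # different crop coefficient
        c_other = selection_curves(m2, ["Corn"], season_table)[0]
        assert c_corn.p_values[0] == pytest.approx(c_other.p_values[0])

    def test_three_distance_levels_per_crop_by_default(self, season_table):
        m = make_model(corn=0.5, wet=0.2, flin=-0.3, fquad=0.1)
        curves = selection_curves(m, ["Corn"], season_table)
        assert len(curves) == 3
        assert [c.distance for c in curves] == [0.0, 450.0, 900.0]


class TestProjectLandscape:
    def test_homogeneous_raster_matches_point_evaluation(self, h1_scheme):
        r = LandCoverRaster(np.full((12, 12), 1), 30.0, (0.0, 0.0))  # all corn
        flows = FlowlineSet([np.array([[0.0, -500.0], [360.0, -500.0]])])
        m = make_model(corn=0.8, wet=0.1)
        pred = project_landscape(m, r, flows, h1_scheme)
        expect = selection_probability(m, "Corn", 1.0, 0.0)  # flow terms are zero
        np.testing.assert_allclose(pred.values, expect, atol=1e-12)
        assert np.all((pred.values > 0) & (pred.values < 1))

    def test_window_equals_per_point_rule_at_cells(self, small_landscape, h1_scheme):
        from rsfpipe.rasters import category_fraction_stack

        cats = h1_scheme.categories
        idx = {c: i for i, c in enumerate(cats)}
        stack = category_fraction_stack(
            small_landscape, {c: idx[l] for c, l in h1_scheme.mapping.items()},
            len(cats), 100.0,
        )
        rng = np.random.default_rng(8)
        for _ in range(20):
            i = rng.integers(0, small_landscape.n_rows)
            j = rng.integers(0, small_landscape.n_cols)
            x, y = small_landscape.center_of(i, j)
            fr = coverage_proportions(small_landscape, (float(x), float(y)), 100.0, h1_scheme)
            for c in cats:
                assert stack[idx[c], i, j] == fr[c]

    def test_agrees_with_point_formula_on_two_class_landscape(self, h1_scheme):
        # only corn and wetland present: every window is P corn, 1-P wetland
        rng = np.random.default_rng(3)
        vals = np.where(rng.uniform(size=(20, 20)) < 0.5, 1, 190).astype(np.int64)
        r = LandCoverRaster(vals, 30.0, (0.0, 0.0))
        flows = FlowlineSet([np.array([[0.0, 300.0], [600.0, 300.0]])])
        m = make_model(corn=0.9, wet=0.4, flin=-0.5, fquad=0.2)
        pred = project_landscape(m, r, flows, h1_scheme)
        idx = {c: i for i, c in enumerate(h1_scheme.categories)}
        from rsfpipe.rasters import category_fraction_stack

        stack = category_fraction_stack(
            r, {c: idx[l] for c, l in h1_scheme.mapping.items()}, len(idx), 100.0
        )
        for i in range(0, 20, 5):
            for j in range(0, 20, 5):
                P = stack[idx["Corn"], i, j]
                x, y = r.center_of(i, j)
                d = float(flows.distances([x], [y])[0])
                assert pred.values[i, j] == pytest.approx(
                    selection_probability(m, "Corn", float(P), d), abs=1e-12
                )

    def test_translation_equivariance(self, h1_scheme):
        rng = np.random.default_rng(4)
        vals = rng.choice([1, 190, 61], size=(15, 15)).astype(np.int64)
        flows_a = FlowlineSet([np.array([[0.0, 100.0], [450.0, 250.0]])])
        ra = LandCoverRaster(vals, 30.0, (0.0, 0.0))
        shift = np.array([5000.0, -3000.0])
        rb = LandCoverRaster(vals, 30.0, (5000.0, -3000.0))
        flows_b = FlowlineSet([flows_a.polylines[0] + shift])
        m = make_model(corn=0.6, wet=0.3, flin=-0.4, fquad=0.1)
        pa = project_landscape(m, ra, flows_a, h1_scheme)
        pb = project_landscape(m, rb, flows_b, h1_scheme)
        np.testing.assert_allclose(pa.values, pb.values, atol=1e-12)

    def test_nodata_propagates(self, h1_scheme):
        vals = np.full((10, 10), 1, dtype=np.int64)
        vals[0, 0] = -9999
        r = LandCoverRaster(vals, 30.0, (0.0, 0.0), -9999)
        flows = FlowlineSet([np.array([[0.0, 0.0], [300.0, 0.0]])])
        pred = project_landscape(make_model(corn=0.5), r, flows, h1_scheme)
        assert np.isnan(pred.values[0, 0])
        assert np.isfinite(pred.values[5, 5])
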