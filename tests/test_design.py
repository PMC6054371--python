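import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rsfpipe.design import (
    DEFAULT_SEASONS,
    Season,
    UseAvailableTable,
    assign_seasons,
    build_design_table,
    build_design_tables,
    coverage_proportions,
    default_schemes,
    minimum_convex_polygon,
    sample_available,
)
from rsfpipe.flowlines import FlowlineSet
from rsfpipe.rasters import LandCoverRaster
from rsfpipe.synthetic import TrueModel, simulate_individual
from rsfpipe.tracks import Track


def brute_force_coverage(raster, point, radius, scheme):
    """Independent oracle: full scan of every raster cell center."""
    counts: dict[str, int] = {c: 0 for c in scheme.categories}
    total = 0
    for i in range(raster.n_rows):
        for j in range(raster.n_cols):
            code = int(raster.values[i, j])
            if code == raster.nodata:
                continue
            x, y = raster.center_of(i, j)
            if (x - point[0]) ** 2 + (y - point[1]) ** 2 <= radius**2 + 1e-9:
                counts[scheme.mapping[code]] += 1
                total += 1
    return {c: counts[c] / total for c in scheme.categories}


class TestAssignSeasons:
    def _track_spanning(self, start, end, ind="a"):
        t = np.arange(np.datetime64(start), np.datetime64(end), np.timedelta64(2, "h"))
        rng = np.random.default_rng(0)
        return Track(ind, t.astype("datetime64[ns]"),
                     rng.normal(0, 10, len(t)), rng.normal(0, 10, len(t)))

    def test_april_fix_is_early_growing(self):
        tr = self._track_spanning("2016-02-28T00:00", "2017-02-01T00:00")
        parts = assign_seasons(tr)
        sub, included = parts["early_growing"]
        assert included
        d = sub.dates()
        assert np.datetime64("2016-04-01") in d
        assert d.min() == np.datetime64("2016-03-01")

    def test_season_end_inclusive(self):
        tr = self._track_spanning("2016-02-28T00:00", "2017-02-01T00:00")
        sub, _ = assign_seasons(tr)["early_growing"]
        assert sub.dates().max() == np.datetime64("2016-05-15")

    def test_late_deployment_excluded_until_spanned(self):
        tr = self._track_spanning("2016-06-15T00:00", "2017-02-01T00:00")
        parts = assign_seasons(tr)
        assert not parts["late_growing"][1]  # missed the 16 May start
        assert parts["harvest"][1]

    def test_overlapping_seasons_rejected(self):
        bad = [
            Season("a", dt.date(2016, 1, 1), dt.date(2016, 3, 1)),
            Season("b", dt.date(2016, 3, 1), dt.date(2016, 5, 1)),
        ]
        tr = self._track_spanning("2016-01-01T00:00", "2016-06-01T00:00")
        with pytest.raises(ValueError):
            assign_seasons(tr, bad)


class TestMinimumConvexPolygon:
    def test_unit_square(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        hull = minimum_convex_polygon(pts)
        assert hull.area == pytest.approx(1.0)
        assert len(hull.vertices) == 4

    def test_interior_point_ignored(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.5, 0.5]])
        hull = minimum_convex_polygon(pts)
        assert hull.area == pytest.approx(1.0)
        assert len(hull.vertices) == 4

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 50, (40, 2))
        h1 = minimum_convex_polygon(pts)
        h2 = minimum_convex_polygon(h1.vertices)
        assert h1.area == pytest.approx(h2.area)
        assert len(h1.vertices) == len(h2.vertices)

    @pytest.mark.parametrize(
        "pts",
        [np.array([[0.0, 0.0], [1.0, 1.0]]),
         np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])],
    )
    def test_degenerate_geometry_rejected(self, pts):
        with pytest.raises(ValueError):
            minimum_convex_polygon(pts)


class TestSampleAvailable:
    @pytest.fixture
    def square(self):
        return minimum_convex_polygon(
            np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        )

    def test_zero_points(self, square):
        assert len(sample_available(square, 0, seed=0)) == 0

    def test_containment(self, square):
        pts = sample_available(square, 500, seed=1)
        assert np.all((pts >= 0.0) & (pts <= 1.0))

    def test_uniform_mean(self, square):
        pts = sample_available(square, 10_000, seed=2)
        sd = np.sqrt(1.0 / 12.0)
        assert abs(pts[:, 0].mean() - 0.5) <= 3 * sd / 100.0

    def test_seeded_bit_exact(self, square):
        a = sample_available(square, 100, seed=3)
        b = sample_available(square, 100, seed=3)
        assert np.array_equal(a, b)


class TestCoverageProportions:
    def test_homogeneous_raster(self, h1_scheme):
        r = LandCoverRaster(np.full((20, 20), 5), 30.0, (0.0, 0.0))
        fr = coverage_proportions(r, (300.0, 300.0), 100.0, h1_scheme)
        assert fr["Soybeans"] == 1.0

    def test_half_and_half_matches_enumeration(self, h1_scheme):
        vals = np.full((20, 20), 1)
        vals[:, 10:] = 190  # right half wetland
        r = LandCoverRaster(vals, 30.0, (0.0, 0.0))
        point = (300.0, 300.0)  # on the class boundary
        fr = coverage_proportions(r, point, 100.0, h1_scheme)
        oracle = brute_force_coverage(r, point, 100.0, h1_scheme)
        for cat in h1_scheme.categories:
            assert fr[cat] == oracle[cat]
        assert fr["Corn"] + fr["Wetland"] == 1.0

    def test_random_points_match_enumeration_exactly(self, small_landscape, h1_scheme):
        rng = np.random.default_rng(4)
        ext = small_landscape.extent
        for _ in range(10):
            pt = (rng.uniform(ext[0] + 120, ext[2] - 120),
                  rng.uniform(ext[1] + 120, ext[3] - 120))
            fr = coverage_proportions(small_landscape, pt, 100.0, h1_scheme)
            oracle = brute_force_coverage(small_landscape, pt, 100.0, h1_scheme)
            for cat in h1_scheme.categories:
                assert fr[cat] == oracle[cat]

    def test_nodata_only_buffer_rejected(self, h1_scheme):
        r = LandCoverRaster(np.full((10, 10), -9999), 30.0, (0.0, 0.0))
        with pytest.raises(ValueError):
            coverage_proportions(r, (150.0, 150.0), 100.0, h1_scheme)


@pytest.fixture(scope="module")
def design_inputs(request):
    land = request.getfixturevalue("small_landscape")
    flows = request.getfixturevalue("small_flowlines")
    scheme = request.getfixturevalue("h1_scheme")
    tracks = [
        simulate_individual(
            land, flows, TrueModel(beta_cover={"Wetland": 1.0}), scheme,
            (900.0, 900.0), 600.0, 200, seed=s, individual_id=f"i{s}",
        )
        for s in (1, 2, 3)
    ]
    return land, flows, scheme, {"s1": tracks}


class TestBuildDesignTable:
    def test_one_to_one_ratio_per_individual(self, design_inputs):
        land, flows, scheme, used = design_inputs
        table = build_design_table(used, land, flows, scheme, seed=0)
        counts = table.df.groupby(["individual_id", "used"]).size().unstack()
        assert (counts[0] == counts[1]).all()

    def test_standardized_columns(self, design_inputs):
        land, flows, scheme, used = design_inputs
        table = build_design_table(used, land, flows, scheme, seed=0)
        sub = table.season_frame("s1")
        assert sub["dist_flow_std"].mean() == pytest.approx(0.0, abs=1e-12)
        assert sub["dist_flow_std"].std(ddof=0) == pytest.approx(1.0)
        # quadratic column: standardize((x - xbar)^2), recomputed directly
        raw = sub["dist_flow_raw"].to_numpy()
        quad = (raw - raw.mean()) ** 2
        expect = (quad - quad.mean()) / quad.std(ddof=0)
        np.testing.assert_allclose(sub["dist_flow_quad_std"].to_numpy(), expect, atol=1e-12)
        st = table.standardization["s1"]
        assert st["dist_mean"] == pytest.approx(raw.mean())

    def test_reference_category_excluded_from_predictors(self, design_inputs):
        land, flows, scheme, used = design_inputs
        table = build_design_table(used, land, flows, scheme, seed=0)
        assert "prop_Fallow" not in table.predictor_columns
        assert "prop_Fallow" in table.df.columns

    def test_proportions_conservation(self, design_inputs):
        land, flows, scheme, used = design_inputs
        table = build_design_table(used, land, flows, scheme, seed=0)
        prop_cols = [f"prop_{c}" for c in table.categories]
        sums = table.df[prop_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        nonref = table.df[[c for c in prop_cols if c != "prop_Fallow"]].sum(axis=1)
        assert (nonref <= 1.0 + 1e-9).all()

    def test_same_seed_bit_exact(self, design_inputs):
        land, flows, scheme, used = design_inputs
        a = build_design_table(used, land, flows, scheme, seed=9)
        b = build_design_table(used, land, flows, scheme, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_roundtrip_through_text(self, design_inputs, tmp_path):
        land, flows, scheme, used = design_inputs
        table = build_design_table(used, land, flows, scheme, seed=0)
        path = tmp_path / "table.csv"
        table.write(path)
        back = UseAvailableTable.read(path)
        assert back.scheme_name == table.scheme_name
        assert back.standardization == table.standardization
        pd.testing.assert_frame_equal(back.df, table.df)

    def test_shared_points_across_schemes(self, design_inputs):
        land, flows, scheme, used = design_inputs
        tables = build_design_tables(used, land, flows, default_schemes(), seed=3)
        dists = [t.df["dist_flow_raw"].to_numpy() for t in tables.values()]
        for d in dists[1:]:
            assert np.array_equal(dists[0], d)
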