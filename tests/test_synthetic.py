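import datetime as dt

import numpy as np
import pytest
from scipy import stats

from rsfpipe.design import _fractions, _gather_window
from rsfpipe.rasters import LandCoverRaster
from rsfpipe.synthetic import (
    TrueModel,
    corrupt_track,
    generate_flowlines,
    generate_landscape,
    make_dependent_pair,
    simulate_individual,
)
from rsfpipe.flowlines import FlowlineSet


class TestGenerateLandscape:
    def test_single_class_everywhere(self):
        r = generate_landscape(20, 20, 30.0, {7: 1.0}, patch_scale=2.0, seed=0)
        assert np.all(r.values == 7)

    def test_iid_cells_hit_target_frequency(self):
        r = generate_landscape(200, 200, 30.0, {1: 0.5, 2: 0.5}, patch_scale=0.0, seed=3)
        freq = np.mean(r.values == 1)
        se = np.sqrt(0.25 / r.values.size)
        assert abs(freq - 0.5) <= 3 * se

    def test_same_seed_bit_identical(self):
        a = generate_landscape(50, 40, 30.0, None, 3.0, seed=11)
        b = generate_landscape(50, 40, 30.0, None, 3.0, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_patchiness_increases_with_scale(self):
        # neighbouring-cell agreement should rise with the smoothing scale
        def agreement(r):
            return np.mean(r.values[:, :-1] == r.values[:, 1:])

        smooth = generate_landscape(100, 100, 30.0, {1: 0.5, 2: 0.5}, 5.0, seed=2)
        rough = generate_landscape(100, 100, 30.0, {1: 0.5, 2: 0.5}, 0.0, seed=2)
        assert agreement(smooth) > agreement(rough) + 0.2

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_rows=0, n_cols=5, cell_size=30.0),
            dict(n_rows=5, n_cols=5, cell_size=-1.0),
            dict(n_rows=5, n_cols=5, cell_size=30.0, class_weights={1: 0.7}),
            dict(n_rows=5, n_cols=5, cell_size=30.0, patch_scale=-2.0),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_landscape(seed=0, **kwargs)


class TestGenerateFlowlines:
    def test_zero_lines(self):
        assert len(generate_flowlines((0, 0, 100, 100), 0, seed=0)) == 0

    def test_vertices_inside_extent(self):
        ext = (100.0, -50.0, 700.0, 350.0)
        fl = generate_flowlines(ext, 3, seed=4)
        assert len(fl) == 3
        for line in fl.polylines:
            assert np.all(line[:, 0] >= ext[0]) and np.all(line[:, 0] <= ext[2])
            assert np.all(line[:, 1] >= ext[1]) and np.all(line[:, 1] <= ext[3])

    def test_deterministic(self):
        a = generate_flowlines((0, 0, 100, 100), 4, seed=9)
        b = generate_flowlines((0, 0, 100, 100), 4, seed=9)
        for la, lb in zip(a.polylines, b.polylines):
            assert np.array_equal(la, lb)

    def test_degenerate_extent(self):
        with pytest.raises(ValueError):
            generate_flowlines((0, 0, 0, 100), 1, seed=0)


class TestSimulateIndividual:
    def test_flat_preference_uniform_over_disc(self, h1_scheme):
        land = generate_landscape(80, 80, 30.0, seed=1)
        flows = FlowlineSet([np.array([[0.0, 0.0], [2400.0, 0.0]])])
        center = (1200.0, 1200.0)
        tr = simulate_individual(
            land, flows, TrueModel(), h1_scheme, center, 800.0, 2000, seed=2
        )
        # quadrant counts under uniformity: chi-square GOF not rejected at 1%
        qx = tr.x > center[0]
        qy = tr.y > center[1]
        counts = [
            np.sum(qx & qy), np.sum(qx & ~qy), np.sum(~qx & qy), np.sum(~qx & ~qy)
        ]
        stat, p = stats.chisquare(counts)
        assert p > 0.01

    def test_wetland_preference_shifts_use(self, h1_scheme):
        land = generate_landscape(80, 80, 30.0, patch_scale=4.0, seed=3)
        flows = FlowlineSet([np.array([[0.0, 0.0], [2400.0, 0.0]])])
        center = (1200.0, 1200.0)
        model = TrueModel(beta_cover={"Wetland": 2.0})
        tr = simulate_individual(
            land, flows, model, h1_scheme, center, 800.0, 3000, seed=4
        )
        pts = np.column_stack([tr.x, tr.y])
        codes, within = _gather_window(land, pts, 100.0)
        fr_used = _fractions(codes, within, h1_scheme)
        wet_col = h1_scheme.categories.index("Wetland")
        # disc-wide mean wetland coverage from a flat-preference sample
        flat = simulate_individual(
            land, flows, TrueModel(), h1_scheme, center, 800.0, 3000, seed=5
        )
        fpts = np.column_stack([flat.x, flat.y])
        fc, fw = _gather_window(land, fpts, 100.0)
        fr_flat = _fractions(fc, fw, h1_scheme)
        assert fr_used[:, wet_col].mean() > fr_flat[:, wet_col].mean() + 0.05

    def test_track_length_and_even_hours(self, small_landscape, small_flowlines, h1_scheme):
        tr = simulate_individual(
            small_landscape, small_flowlines, TrueModel(), h1_scheme,
            (900.0, 900.0), 500.0, 1606, seed=6,
        )
        assert len(tr) == 1606
        mins = tr.t.astype("datetime64[m]").astype(np.int64) % 60
        hours = tr.t.astype("datetime64[h]").astype(np.int64) % 2
        assert np.all(mins == 0) and np.all(hours == 0)

    def test_off_raster_disc_rejected(self, small_landscape, small_flowlines, h1_scheme):
        with pytest.raises(ValueError):
            simulate_individual(
                small_landscape, small_flowlines, TrueModel(), h1_scheme,
                (1e7, 1e7), 500.0, 10, seed=0,
            )

    def test_selection_coefficient_recovered_from_strata(self, h1_scheme):
        """sigma_b = 0: empirical log-ratio of use between pure-cover strata
        estimates the true coefficient difference within Monte-Carlo error."""
        # left half corn (1), right half idle cropland (61): pure strata
        vals = np.full((120, 120), 61, dtype=np.int64)
        vals[:, :60] = 1
        land = LandCoverRaster(vals, 30.0, (0.0, 0.0), -9999)
        flows = FlowlineSet([np.array([[0.0, -1e5], [3600.0, -1e5]])])  # far: ~constant
        beta_corn = 0.8
        model = TrueModel(beta_cover={"Corn": beta_corn})
        center, radius, n = (1800.0, 1800.0), 900.0, 8000
        tr = simulate_individual(land, flows, model, h1_scheme, center, radius, n, seed=7)
        # strata: >150 m from the boundary so buffers are pure
        used_corn = np.sum(tr.x < 1800.0 - 150.0)
        used_idle = np.sum(tr.x > 1800.0 + 150.0)
        flat = simulate_individual(land, flows, TrueModel(), h1_scheme, center, radius, n, seed=8)
        avail_corn = np.sum(flat.x < 1800.0 - 150.0)
        avail_idle = np.sum(flat.x > 1800.0 + 150.0)
        est = np.log(used_corn / avail_corn) - np.log(used_idle / avail_idle)
        se = np.sqrt(1 / used_corn + 1 / used_idle + 1 / avail_corn + 1 / avail_idle)
        assert abs(est - beta_corn) < 3.5 * se


class TestCorruptTrack:
    @pytest.fixture
    def clean_track(self, small_landscape, small_flowlines, h1_scheme):
        return simulate_individual(
            small_landscape, small_flowlines, TrueModel(), h1_scheme,
            (900.0, 900.0), 500.0, 300, seed=9,
        )

    def test_zero_rates_identity(self, clean_track):
        out = corrupt_track(clean_track, 0.0, 0.0, seed=0)
        assert np.array_equal(out.t, clean_track.t)
        assert np.array_equal(out.x, clean_track.x)

    def test_spikes_exceed_speed_limit_by_construction(self, clean_track):
        out = corrupt_track(clean_track, 0.05, 0.0, seed=1)
        spike_times = out.meta["spike_times"]
        assert len(spike_times) >= 1
        t_h = out.t.astype("datetime64[s]").astype(np.int64) / 3600.0
        for ts in spike_times:
            i = int(np.searchsorted(out.t, ts))
            d_km = np.hypot(out.x[i] - out.x[i - 1], out.y[i] - out.y[i - 1]) / 1000.0
            assert d_km / (t_h[i] - t_h[i - 1]) > 20.0

    def test_seeded_repeatability(self, clean_track):
        a = corrupt_track(clean_track, 0.03, 0.05, seed=2)
        b = corrupt_track(clean_track, 0.03, 0.05, seed=2)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.x, b.x)

    def test_empty_track_rejected(self, clean_track):
        empty = clean_track.replace(t=clean_track.t[:0], x=clean_track.x[:0], y=clean_track.y[:0])
        with pytest.raises(ValueError):
            corrupt_track(empty, 0.1, 0.0, seed=0)


class TestMakeDependentPair:
    @pytest.fixture
    def base_track(self, small_landscape, small_flowlines, h1_scheme):
        return simulate_individual(
            small_landscape, small_flowlines, TrueModel(), h1_scheme,
            (900.0, 900.0), 600.0, 500, seed=10,
        )

    def test_zero_jitter_perfect_correlation(self, base_track):
        dep = make_dependent_pair(base_track, 0.0, seed=0)
        assert np.corrcoef(base_track.x, dep.x)[0, 1] == pytest.approx(1.0)
        assert np.corrcoef(base_track.y, dep.y)[0, 1] == pytest.approx(1.0)

    def test_small_jitter_flaggable(self, base_track):
        # attenuation: r ~ sd(x) / sqrt(sd(x)^2 + jitter^2); jitter << extent
        dep = make_dependent_pair(base_track, 30.0, seed=1)
        rx = np.corrcoef(base_track.x, dep.x)[0, 1]
        ry = np.corrcoef(base_track.y, dep.y)[0, 1]
        sx = base_track.x.std()
        expected = sx / np.sqrt(sx**2 + 30.0**2)
        assert abs(rx) > 0.5 and abs(ry) > 0.5
        assert rx == pytest.approx(expected, abs=0.05)

    def test_huge_jitter_uncorrelated(self, base_track):
        dep = make_dependent_pair(base_track, 1e5, seed=2)
        rx = np.corrcoef(base_track.x, dep.x)[0, 1]
        ry = np.corrcoef(base_track.y, dep.y)[0, 1]
        assert abs(rx) < 0.3 and abs(ry) < 0.3
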