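"""Synthetic trajectory, grid map and spike generators."""

import numpy as np
import pytest

from gridsep import (
    ArenaSpec,
    GridCellSpec,
    generate_spikes,
    grid_rate,
    make_null_session,
    modulated_rate,
    simulate_session,
    simulate_trajectory,
)
from gridsep.binning import BinningSpec, bin_position_2d


class TestTrajectory:
    def test_zero_duration_gives_empty_trajectory(self):
        s = simulate_trajectory(duration=0.0, seed=0)
        assert s.n_samples == 0

    def test_fixed_seed_reproduces_bitwise(self):
        a = simulate_trajectory(duration=60, seed=7)
        b = simulate_trajectory(duration=60, seed=7)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert not np.array_equal(a.x, simulate_trajectory(duration=60, seed=8).x)

    @pytest.mark.parametrize("bad", [{"duration": -1.0}, {"speed_scale": 0.0}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_trajectory(**bad)

    def test_positions_stay_inside_arena(self):
        arena = ArenaSpec(half_width=75.0)
        s = simulate_trajectory(arena, duration=300, seed=3)
        assert np.all(np.abs(s.x) <= 75.0) and np.all(np.abs(s.y) <= 75.0)

    def test_occupancy_statistics_match_foraging(self):
        """30-min default trajectory: >=80% of samples inside +/-25 cm/s on
        both axes, near-uniform position coverage, velocity unimodal at 0."""
        s = simulate_trajectory(duration=1800, seed=11)
        vx = np.gradient(s.x, s.dt)
        vy = np.gradient(s.y, s.dt)
        inside = np.mean((np.abs(vx) < 25) & (np.abs(vy) < 25))
        assert inside >= 0.80
        H, _, _ = np.histogram2d(s.x, s.y, bins=30, range=[[-75, 75], [-75, 75]])
        assert np.mean(H > 0) > 0.95  # nearly all position bins visited
        assert H.std() / H.mean() < 0.8  # no gross over-concentration
        hist, edges = np.histogram(vx, bins=21, range=(-35, 35))
        assert np.argmax(hist) == 10  # mode at the zero-velocity bin


class TestGridRate:
    def test_peak_rate_at_phase_point(self):
        spec = GridCellSpec(grid_scale=50, phase=(10.0, -5.0), peak_rate=15.0)
        assert grid_rate(spec, 10.0, -5.0) == pytest.approx(15.0)

    def test_nonnegative_on_lattice(self):
        spec = GridCellSpec(grid_scale=40, orientation=17.0)
        g = np.linspace(-75, 75, 30)
        X, Y = np.meshgrid(g, g)
        assert np.all(grid_rate(spec, X, Y) >= 0)

    @pytest.mark.parametrize("scale", [30.0, 50.0, 70.0])
    def test_nearest_field_spacing_matches_grid_scale(self, scale):
        """Brute-force peak search on a dense lattice: the two nearest rate
        maxima are one grid_scale apart."""
        from scipy.ndimage import maximum_filter

        spec = GridCellSpec(grid_scale=scale, orientation=10.0, phase=(3.0, 4.0))
        g = np.arange(-100, 100, 0.5)
        X, Y = np.meshgrid(g, g, indexing="ij")
        R = grid_rate(spec, X, Y)
        peaks = (maximum_filter(R, size=9) == R) & (R > 0.99 * spec.peak_rate)
        px, py = np.nonzero(peaks)
        assert len(px) >= 2
        pts = np.column_stack([g[px], g[py]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        nearest = np.min(np.where(d > 0, d, np.inf), axis=1)
        assert np.min(nearest) == pytest.approx(scale, abs=1.0)


class TestModulatedRate:
    def test_none_is_velocity_independent(self):
        spec = GridCellSpec(modulation="none")
        r1 = modulated_rate(spec, 5.0, 5.0, 0.0, 0.0)
        r2 = modulated_rate(spec, 5.0, 5.0, 20.0, -15.0)
        assert r1 == pytest.approx(r2)

    def test_gain_with_zero_slope_is_identity(self):
        spec = GridCellSpec(modulation="gain", modulation_params={"gain_slope": 0.0})
        x, y = np.array([1.0, 7.0]), np.array([-3.0, 2.0])
        np.testing.assert_allclose(
            modulated_rate(spec, x, y, 15.0, -8.0), grid_rate(spec, x, y)
        )

    def test_gain_factorizes_into_position_times_speed(self):
        spec = GridCellSpec(modulation="gain", modulation_params={"gain_slope": 0.02})
        r = modulated_rate(spec, 3.0, 4.0, 12.0, 16.0)  # speed 20
        assert r == pytest.approx(grid_rate(spec, 3.0, 4.0) * (1 + 0.02 * 20.0))

    def test_shift_evaluates_lagged_position(self):
        """lag 0.5 s at vx=20 cm/s displaces the map 10 cm leftward."""
        spec = GridCellSpec(modulation="shift", modulation_params={"lag": 0.5})
        plain = GridCellSpec()
        x = np.linspace(-40, 40, 9)
        np.testing.assert_allclose(
            modulated_rate(spec, x, 0.0, 20.0, 0.0), grid_rate(plain, x - 10.0, 0.0)
        )

    def test_dropout_suppresses_high_speed_half_plane_only(self):
        spec = GridCellSpec(modulation="dropout")
        slow = modulated_rate(spec, 40.0, 0.0, 2.0, 0.0)
        fast = modulated_rate(spec, 40.0, 0.0, 25.0, 0.0)
        fast_other_side = modulated_rate(spec, -40.0, 0.0, 25.0, 0.0)
        assert fast < 0.5 * slow
        assert fast_other_side > 0.8 * modulated_rate(spec, -40.0, 0.0, 2.0, 0.0)

    def test_unknown_modulation_rejected(self):
        with pytest.raises(ValueError, match="modulation"):
            GridCellSpec(modulation="wobble")


class TestSpikes:
    def test_zero_rate_gives_zero_counts(self):
        assert generate_spikes(np.zeros(100), 0.01, seed=0).sum() == 0

    def test_poisson_mean_within_three_standard_errors(self):
        counts = generate_spikes(np.full(10**6, 10.0), 0.01, seed=5)
        se = np.sqrt(0.1 / 10**6)
        assert abs(counts.mean() - 0.1) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_spikes(np.array([-1.0]), 0.01)

    def test_seeded_reproducibility(self):
        r = np.full(1000, 5.0)
        assert np.array_equal(generate_spikes(r, 0.01, seed=3), generate_spikes(r, 0.01, seed=3))


class TestNullSession:
    def setup_method(self):
        self.spec = BinningSpec()
        self.sess = simulate_trajectory(duration=300, seed=2)

    def test_zero_map_gives_zero_spikes(self):
        r0 = np.zeros((30, 30))
        out = make_null_session(self.sess, r0, self.spec.pos_edges, seed=0)
        assert out.spikes.sum() == 0

    def test_constant_map_total_spikes_within_three_se(self):
        c = 8.0
        r0 = np.full((30, 30), c)
        out = make_null_session(self.sess, r0, self.spec.pos_edges, seed=4)
        expected = c * self.sess.duration
        assert abs(out.spikes.sum() - expected) < 3 * np.sqrt(expected)

    def test_negative_map_rejected(self):
        r0 = np.full((30, 30), -1.0)
        with pytest.raises(ValueError):
            make_null_session(self.sess, r0, self.spec.pos_edges)

    def test_binned_tuning_converges_to_r0_with_duration(self):
        """The null session's empirical position map approaches the
        generating map as occupancy grows (Poisson noise shrinks as
        1/sqrt(time in bin))."""
        cell = GridCellSpec(grid_scale=50, peak_rate=15)
        centers = BinningSpec().pos_centers
        X, Y = np.meshgrid(centers, centers, indexing="ij")
        r0 = grid_rate(cell, X, Y)

        def corr_at(duration):
            sess = simulate_trajectory(duration=duration, seed=9)
            out = make_null_session(sess, r0, self.spec.pos_edges, seed=1)
            rate, _, visits = bin_position_2d(out, BinningSpec())
            well = visits > 0.05 * duration / 9  # scale cut with occupancy
            return np.corrcoef(rate[well], r0[well])[0, 1]

        c_short, c_long = corr_at(300), corr_at(2400)
        assert c_long > c_short
        assert c_long > 0.85


class TestSimulateSession:
    def test_deterministic_and_shapes(self):
        cells = [GridCellSpec(), GridCellSpec(modulation="shift")]
        a = simulate_session(cells, duration=30, seed=5)
        b = simulate_session(cells, duration=30, seed=5)
        assert a.n_cells == 2 and a.n_samples == 3000
        assert np.array_equal(a.spikes, b.spikes)
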