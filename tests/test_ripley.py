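"""Ripley h estimator, envelopes, peak extraction, and null comparisons."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import locquant as lq


REGION = lq.Region.square(5000.0)


def brute_force_h(table, region, distances):
    """Independent all-pairs oracle: direct evaluation of the estimator."""
    xy = table.xy
    n = len(xy)
    D = cdist(xy, xy)
    h = np.empty(len(distances))
    for k, d in enumerate(distances):
        count = np.count_nonzero((D > 0) & (D < d))
        k_hat = region.area() * count / (n * (n - 1))
        h[k] = np.sqrt(k_hat / np.pi) - d
    return h


class TestRipleyH:
    def test_two_point_hand_example(self):
        # two points 10 apart in a window of area 100*pi: h(11) = -1, h(9) = -9
        region = lq.Region(0.0, 100.0 * np.pi, 0.0, 1.0)
        t = lq.LocalizationTable.from_arrays([1.0, 11.0], [0.5, 0.5], 0)
        curve = lq.ripley_h(t, region, distances=np.array([9.0, 11.0]), m=2)
        np.testing.assert_allclose(curve.h, [-9.0, -1.0], rtol=1e-12)

    def test_full_estimator_matches_brute_force(self):
        t = lq.simulate_csr(20.0, REGION, 17)  # ~500 points
        grid = np.arange(10.0, 801.0, 10.0)
        curve = lq.ripley_h(t, REGION, grid, m=None)
        np.testing.assert_allclose(curve.h, brute_force_h(t, REGION, grid), rtol=1e-9)

    def test_subset_estimator_unbiased(self):
        t = lq.simulate_csr(32.0, REGION, 18)  # ~800 points
        grid = np.arange(10.0, 501.0, 10.0)
        full = lq.ripley_h(t, REGION, grid, m=None).h
        H = np.vstack([lq.ripley_h(t, REGION, grid, m=200, seed=s).h
                       for s in range(20)])
        se_mean = H.std(axis=0, ddof=1) / np.sqrt(20)
        assert np.all(np.abs(H.mean(axis=0) - full) < 4 * se_mean + 1e-9)

    def test_duplicated_table_does_not_diverge(self):
        t = lq.simulate_csr(20.0, REGION, 19)
        dup = lq.LocalizationTable.from_arrays(np.tile(t.x, 2), np.tile(t.y, 2), 0)
        grid = np.arange(10.0, 301.0, 10.0)
        h1 = lq.ripley_h(t, REGION, grid, m=None).h
        h2 = lq.ripley_h(dup, REGION, grid, m=None).h
        assert np.isfinite(h2).all()
        np.testing.assert_allclose(h2, h1, atol=0.5)

    def test_translation_and_rotation_invariance(self):
        t = lq.simulate_csr(40.0, REGION, 20)
        grid = np.arange(10.0, 301.0, 10.0)
        base = lq.ripley_h(t, REGION, grid, m=300, seed=1).h
        shifted = lq.LocalizationTable.from_arrays(t.x + 1e4, t.y - 2e3, 0)
        sh_region = lq.Region(1e4, 1e4 + 5000, -2e3, -2e3 + 5000)
        np.testing.assert_allclose(lq.ripley_h(shifted, sh_region, grid, m=300, seed=1).h,
                                   base, atol=1e-9)
        rotated = lq.LocalizationTable.from_arrays(t.y, 5000.0 - t.x, 0)
        np.testing.assert_allclose(lq.ripley_h(rotated, REGION, grid, m=300, seed=1).h,
                                   base, atol=1e-9)

    def test_parameter_validation(self):
        t = lq.simulate_csr(20.0, REGION, 21)
        with pytest.raises(ValueError, match="exceeds"):
            lq.ripley_h(t, REGION, m=t.n + 1)
        with pytest.raises(ValueError, match="at least 2"):
            lq.ripley_h(lq.LocalizationTable.from_arrays([1.0], [1.0], 0), REGION)
        outside = lq.LocalizationTable.from_arrays([-10.0, 100.0], [5.0, 5.0], 0)
        with pytest.raises(ValueError, match="inside"):
            lq.ripley_h(outside, REGION)

    def test_csr_mean_h_near_zero(self):
        """Complete spatial randomness: E[h] ~ 0 (interior test points)."""
        rng = np.random.default_rng(0)
        curves = [lq.ripley_h(lq.simulate_csr(200.0, REGION, rng), REGION,
                              np.arange(10.0, 301.0, 10.0), 400, rng,
                              guard_buffer=True)
                  for _ in range(10)]
        env = lq.ripley_envelope(curves)
        assert np.all(np.abs(env.mean) < 3 * env.se + 1e-9)


class TestEnvelope:
    def test_identical_curves_zero_width(self):
        grid = np.arange(10.0, 101.0, 10.0)
        c = lq.RipleyCurve(grid, np.sin(grid / 30.0), 100, 50, REGION.area())
        env = lq.ripley_envelope([c, c, c])
        np.testing.assert_allclose(env.lower, env.mean)
        np.testing.assert_allclose(env.upper, env.mean)

    def test_mismatched_grids_rejected(self):
        a = lq.RipleyCurve(np.array([10.0, 20.0]), np.zeros(2), 10, 5, 1.0)
        b = lq.RipleyCurve(np.array([10.0, 30.0]), np.zeros(2), 10, 5, 1.0)
        with pytest.raises(ValueError, match="grid"):
            lq.ripley_envelope([a, b])

    def test_needs_two_curves(self):
        a = lq.RipleyCurve(np.array([10.0]), np.zeros(1), 10, 5, 1.0)
        with pytest.raises(ValueError):
            lq.ripley_envelope([a])

    def test_csr_envelope_covers_zero_on_average(self):
        # a 5-replicate t-interval covers 0 at ~95% of grid points when
        # averaged over independent envelopes (single envelopes can miss
        # in correlated runs, which is expected behavior of the interval)
        rng = np.random.default_rng(2)
        grid = np.arange(10.0, 301.0, 10.0)
        coverage = []
        for _ in range(8):
            curves = [lq.ripley_h(lq.simulate_csr(200.0, REGION, rng), REGION,
                                  grid, 400, rng, guard_buffer=True)
                      for _ in range(5)]
            env = lq.ripley_envelope(curves)
            coverage.append(((env.lower <= 0) & (0 <= env.upper)).mean())
        assert np.mean(coverage) >= 0.9


def _envelope_from(grid, mean):
    mean = np.asarray(mean, dtype=float)
    return lq.RipleyEnvelope(np.asarray(grid, dtype=float), mean,
                             mean - 1.0, mean + 1.0, 5)


class TestPeak:
    def test_interior_maximum(self):
        grid = np.arange(10.0, 101.0, 2.0)
        mean = -((grid - 24.0) ** 2)
        pk = lq.peak_distance(_envelope_from(grid, mean), (10.0, 100.0))
        assert pk.distance == 24.0
        assert not pk.at_boundary

    def test_tie_breaks_toward_smaller_d(self):
        grid = np.array([10.0, 20.0, 30.0])
        pk = lq.peak_distance(_envelope_from(grid, [1.0, 5.0, 5.0]))
        assert pk.distance == 20.0

    def test_monotone_curve_flagged_at_boundary(self):
        grid = np.array([10.0, 20.0, 30.0, 40.0])
        pk = lq.peak_distance(_envelope_from(grid, [4.0, 3.0, 2.0, 1.0]))
        assert pk.distance == 10.0
        assert pk.at_boundary

    def test_search_range_outside_grid(self):
        grid = np.array([10.0, 20.0])
        with pytest.raises(ValueError):
            lq.peak_distance(_envelope_from(grid, [0.0, 1.0]), (500.0, 600.0))

    def test_blink_peak_on_neyman_scott(self):
        """Blinking clusters peak near the localization-precision scale."""
        rng = np.random.default_rng(3)
        params = lq.NeymanScottParams.from_localization_density(300.0)
        grid = np.arange(10.0, 201.0, 10.0)
        curves = [lq.ripley_h(lq.simulate_neyman_scott(params, REGION, rng)[0],
                              REGION, grid, 500, rng) for _ in range(5)]
        env = lq.ripley_envelope(curves)
        pk = lq.peak_distance(env, (10.0, 150.0))
        assert 20.0 <= pk.distance <= 30.0
        # and the envelope excludes zero there: blinking is detectable clustering
        k = np.argmin(np.abs(env.distances - pk.distance))
        assert env.lower[k] > 0


class TestComparison:
    GRID = np.arange(10.0, 301.0, 10.0)

    def _csr_envelope(self, rng, n_rep=5, intensity=300.0):
        return lq.ripley_envelope(
            [lq.ripley_h(lq.simulate_csr(intensity, REGION, rng), REGION,
                         self.GRID, 500, rng) for _ in range(n_rep)])

    def test_mismatched_grids_rejected(self):
        a = _envelope_from(self.GRID, np.zeros(self.GRID.size))
        b = _envelope_from(self.GRID + 5.0, np.zeros(self.GRID.size))
        with pytest.raises(ValueError):
            lq.compare_to_nulls(a, a, b)

    def test_csr_against_itself_stays_inside(self):
        rng = np.random.default_rng(4)
        observed = self._csr_envelope(rng)
        csr = self._csr_envelope(rng)
        report = lq.compare_to_nulls(observed, csr, csr)
        assert report.outside_csr.mean() < 0.3  # chance-rate excursions only

    def test_blinking_data_excurses_over_csr_null(self):
        rng = np.random.default_rng(5)
        params = lq.NeymanScottParams.from_localization_density(300.0)
        curves = [lq.ripley_h(lq.simulate_neyman_scott(params, REGION, rng)[0],
                              REGION, self.GRID, 500, rng) for _ in range(5)]
        observed = lq.ripley_envelope(curves)
        csr = self._csr_envelope(rng)
        report = lq.compare_to_nulls(observed, csr, csr)
        flagged = report.distances[report.outside_csr]
        assert {20.0, 30.0} <= set(flagged)  # the blink-peak scale is flagged
        assert report.csr_intervals  # summarized as contiguous intervals

    def test_vesicles_excurse_over_blinking_null(self):
        rng = np.random.default_rng(6)
        vesicle_tables = [lq.simulate_vesicle_field(300.0, 20, 100.0, 100, REGION, rng)
                          for _ in range(5)]
        density = np.mean([t.n for t in vesicle_tables]) / REGION.area_um2()
        observed = lq.ripley_envelope(
            [lq.ripley_h(t, REGION, self.GRID, 500, rng) for t in vesicle_tables])
        _, ns = lq.null_envelopes(density, REGION, self.GRID, 500, 5, rng)
        report = lq.compare_to_nulls(observed, ns, ns)
        large_scale = report.outside_ns[self.GRID > 30.0]
        assert large_scale.any()


class TestModelInterface:
    def test_fit_builds_envelope_and_summary(self):
        rng = np.random.default_rng(7)
        tables = [lq.simulate_csr(100.0, REGION, rng) for _ in range(3)]
        res = lq.RipleyModel(tables, REGION, np.arange(10.0, 201.0, 10.0), 200).fit(0)
        assert res.envelope.n_replicates == 3
        assert "Ripley" in res.summary()

    def test_single_table_degenerate_envelope(self):
        t = lq.simulate_csr(100.0, REGION, 8)
        res = lq.RipleyModel(t, REGION, np.arange(10.0, 101.0, 10.0), 200).fit(0)
        assert res.envelope.n_replicates == 1
        assert np.isnan(res.envelope.lower).all()
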