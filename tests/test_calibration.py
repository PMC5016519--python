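"""Track grouping, radius sweep, precision, and molecular-density arithmetic."""

import numpy as np
import pytest

import locquant as lq
from locquant.calibration import AlignedOffsets
from locquant.simulate import conditional_poisson_mean


REGION = lq.Region.square(5000.0)


def _grid_scene(sigma=8.0, spacing=500.0, blink_mean=5.0, seed=0):
    """Well-separated fluorophores on a grid: grouping truth is unambiguous."""
    rng = np.random.default_rng(seed)
    centers = np.array([(spacing / 2 + i * spacing, spacing / 2 + j * spacing)
                        for i in range(10) for j in range(10)])
    xs, ys, frames, labels = [], [], [], []
    for k, c in enumerate(centers):
        cnt = 1 + rng.poisson(blink_mean - 1)
        pts = c + rng.normal(0, sigma, size=(cnt, 2))
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        frames.append(rng.choice(20_000, size=cnt, replace=False))
        labels.append(np.full(cnt, k))
    table = lq.LocalizationTable.from_arrays(np.concatenate(xs), np.concatenate(ys),
                                             np.concatenate(frames))
    return table, np.concatenate(labels)


class TestGrouping:
    def test_radius_zero_single_tracks(self):
        t = lq.LocalizationTable.from_arrays([0.0, 10.0, 10.0], [0.0, 0.0, 0.0],
                                             [0, 1, 2])
        ts = lq.group_localizations(t, 0.0)
        # the two exactly coincident localizations merge; the other stays alone
        assert sorted(ts.track_lengths.tolist()) == [1, 2]

    def test_threshold_semantics(self):
        t = lq.LocalizationTable.from_arrays([0.0, 30.0], [0.0, 0.0], [0, 1])
        assert lq.group_localizations(t, 50.0).n_tracks == 1
        assert lq.group_localizations(t, 20.0).n_tracks == 2

    def test_max_gap(self):
        t = lq.LocalizationTable.from_arrays([0.0, 0.0], [0.0, 0.0], [0, 10])
        assert lq.group_localizations(t, 5.0, max_gap=5).n_tracks == 2
        assert lq.group_localizations(t, 5.0, max_gap=10).n_tracks == 1

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            lq.group_localizations(lq.LocalizationTable.empty(), -1.0)

    def test_recovers_ground_truth_on_separated_scene(self):
        table, labels = _grid_scene()
        ts = lq.group_localizations(table, 50.0)
        got = ts.labels(table.n)
        # same partition up to label permutation
        for k in range(ts.n_tracks):
            members = labels[got == k]
            assert (members == members[0]).all()
        assert ts.n_tracks == len(set(labels))

    @pytest.mark.parametrize("radius", [0.0, 10.0, 50.0, 160.0])
    def test_partition_property(self, radius):
        table, _ = _grid_scene(seed=1)
        ts = lq.group_localizations(table, radius)
        assert ts.track_lengths.sum() == table.n
        lab = ts.labels(table.n)
        assert (lab >= 0).all()


class TestRadiusSweep:
    def test_isolated_points_constant_one(self):
        t = lq.LocalizationTable.from_arrays([0.0, 1000.0, 2000.0],
                                             [0.0, 0.0, 0.0], [0, 1, 2])
        curve = lq.radius_sweep(t, radii=[10, 50, 160])
        np.testing.assert_allclose(curve.mean_track_length, 1.0)

    def test_empty_table_errors(self):
        with pytest.raises(lq.EmptyInputError):
            lq.radius_sweep(lq.LocalizationTable.empty())

    def test_curve_non_decreasing(self):
        table, _ = _grid_scene(seed=2)
        curve = lq.radius_sweep(table)
        assert (np.diff(curve.mean_track_length) >= -1e-12).all()

    def test_saturates_at_blink_mean(self):
        table, labels = _grid_scene(seed=3)
        curve = lq.radius_sweep(table)
        factor, se = lq.estimate_conversion_factor(curve)
        true_mean = table.n / len(set(labels))
        assert factor == pytest.approx(true_mean, abs=1e-9)


class TestConversionFactor:
    def test_constant_curve_factor_one(self):
        curve = lq.CalibrationCurve(np.array([10.0, 50.0]), np.array([1.0, 1.0]),
                                    np.array([0.0, 0.0]), np.array([5, 5]))
        factor, se = lq.estimate_conversion_factor(curve)
        assert factor == 1.0

    def test_missing_plateau_radius_lists_grid(self):
        curve = lq.CalibrationCurve(np.array([10.0, 20.0]), np.array([1.0, 2.0]),
                                    np.array([0.0, 0.0]), np.array([5, 5]))
        with pytest.raises(ValueError, match="10.*20"):
            lq.estimate_conversion_factor(curve, plateau_radius=50.0)

    def test_window_mean_method(self):
        radii = np.arange(1.0, 161.0)
        vals = np.minimum(radii / 10.0, 4.0)  # saturates at radius 40
        curve = lq.CalibrationCurve(radii, vals, np.zeros_like(vals),
                                    np.full(radii.size, 9))
        factor, _ = lq.estimate_conversion_factor(curve, method="window_mean")
        assert factor == pytest.approx(4.0)


class TestAlignment:
    def test_identical_points_zero_offsets(self):
        t = lq.LocalizationTable.from_arrays([5.0] * 3, [7.0] * 3, [0, 1, 2])
        ts = lq.group_localizations(t, 10.0)
        off = lq.align_tracks(ts, t)
        np.testing.assert_array_equal(off.dx, 0.0)
        np.testing.assert_array_equal(off.dy, 0.0)

    def test_hand_centroid_arithmetic(self):
        t = lq.LocalizationTable.from_arrays([0.0, 2.0, 4.0], [0.0, 0.0, 0.0],
                                             [0, 1, 2])
        ts = lq.group_localizations(t, 10.0)
        off = lq.align_tracks(ts, t)
        np.testing.assert_allclose(sorted(off.dx), [-2.0, 0.0, 2.0])
        np.testing.assert_allclose(off.dy, 0.0)

    def test_no_qualifying_tracks_errors(self):
        t = lq.LocalizationTable.from_arrays([0.0, 1000.0], [0.0, 0.0], [0, 1])
        ts = lq.group_localizations(t, 10.0)
        with pytest.raises(ValueError, match="length"):
            lq.align_tracks(ts, t)

    def test_raw_offsets_shrunk_by_centroid_subtraction(self):
        table, _ = _grid_scene(sigma=8.0, seed=4)
        ts = lq.group_localizations(table, 50.0)
        off = lq.align_tracks(ts, table)
        raw_sd = np.concatenate([off.dx, off.dy]).std()
        assert raw_sd < 8.0  # variance shrunk by factor (L-1)/L per track


class TestPrecision:
    def test_zero_offsets_zero_sigma(self):
        off = AlignedOffsets(np.zeros(20), np.zeros(20), np.full(20, 4), 5)
        assert lq.estimate_precision(off) == (0.0, 0.0)

    def test_plain_gaussian_draws_without_shrinkage(self):
        rng = np.random.default_rng(6)
        draws = rng.normal(0, 5.0, size=(5000, 2))
        sx, sy = lq.estimate_precision(draws)
        assert sx == pytest.approx(5.0, abs=0.2)
        assert sy == pytest.approx(5.0, abs=0.2)

    def test_shrinkage_correction_recovers_sigma(self):
        table, _ = _grid_scene(sigma=8.0, seed=7)
        ts = lq.group_localizations(table, 50.0)
        off = lq.align_tracks(ts, table)
        sx, sy = lq.estimate_precision(off)
        assert sx == pytest.approx(8.0, abs=0.7)
        assert sy == pytest.approx(8.0, abs=0.7)

    def test_histogram_fit_agrees_with_analytic(self):
        table, _ = _grid_scene(sigma=8.0, seed=8)
        ts = lq.group_localizations(table, 50.0)
        off = lq.align_tracks(ts, table)
        ax, ay = lq.estimate_precision(off, method="analytic")
        hx, hy = lq.estimate_precision(off, method="histogram")
        # histogram fit carries no shrinkage correction, so it sits slightly low
        assert hx == pytest.approx(ax, rel=0.15)
        assert hy == pytest.approx(ay, rel=0.15)

    def test_too_few_offsets_error(self):
        with pytest.raises(ValueError, match="10"):
            lq.estimate_precision(np.zeros((5, 2)))


class TestMolecularDensity:
    @pytest.mark.parametrize("density,factor,expected", [
        (350.0, 6.7, 52), (625.0, 5.0, 125), (1520.0, 4.4, 345), (1536.0, 5.5, 279),
    ])
    def test_reference_rows(self, density, factor, expected):
        assert lq.molecular_density(density, factor).rounded == expected

    def test_identity_with_unit_factor(self):
        assert lq.molecular_density(123.4, 1.0).value == pytest.approx(123.4)

    def test_round_trip(self):
        # density a*k with factor k recovers a
        assert lq.molecular_density(52.0 * 6.7, 6.7).value == pytest.approx(52.0)

    def test_error_propagation(self):
        md = lq.molecular_density(350.0, 6.7, density_se=30.0, conversion_se=1.1)
        expected = (350 / 6.7) * np.sqrt((30 / 350) ** 2 + (1.1 / 6.7) ** 2)
        assert md.se == pytest.approx(expected)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            lq.molecular_density(100.0, 0.0)


class TestModelInterface:
    def test_summary_reports_estimates(self, reference_fit):
        text = reference_fit.summary()
        assert "conversion factor" in text
        assert "sigma_x" in text

    def test_results_molecular_density(self, reference_fit):
        md = reference_fit.molecular_density(350.0, density_se=30.0)
        assert md.value == pytest.approx(350.0 / reference_fit.conversion_factor)
        assert md.se is not None
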