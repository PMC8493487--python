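"""Anisotropy maps, axial circular statistics, half-order unwrapping,
and the Stokes-vs-Mueller deviation analysis."""

import numpy as np
import pytest

from mmpol import (
    analyze_stack,
    axial_circular_stats,
    axis_deviation_analysis,
    decompose_matrix,
    deviation_sweep,
    make_anisotropy_map,
    mueller_linear_retarder,
    signed_axial_difference,
    simulate_stack,
    slow_axis_map,
    unwrap_half_order,
)


class TestSlowAxis:
    def test_offset_is_quarter_turn_with_fold(self):
        assert slow_axis_map(0.0) == pytest.approx(np.pi / 2)
        assert slow_axis_map(np.pi / 4) == pytest.approx(-np.pi / 4)

    def test_nan_propagates(self):
        out = slow_axis_map(np.array([0.1, np.nan]))
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_end_to_end_fiber_orientation(self):
        """A scene of fibers (slow axis) at 30 deg maps back to 30 deg."""
        slow = np.deg2rad(30.0)
        M = mueller_linear_retarder(1.0, slow - np.pi / 2)  # fast axis orthogonal
        props = decompose_matrix(M)
        assert slow_axis_map(props.thetaFA) == pytest.approx(slow, abs=1e-12)


class TestAxialStats:
    def test_constant_angles_have_zero_variance(self):
        mean, var = axial_circular_stats(np.full(50, 0.7))
        assert mean == pytest.approx(0.7)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_axes_are_maximally_dispersed(self):
        mean, var = axial_circular_stats(np.array([0.0, np.pi / 2] * 10))
        assert var == pytest.approx(1.0, abs=1e-12)

    def test_small_set_matches_direct_complex_sum(self):
        angles = np.deg2rad([0.0, 10.0, 20.0])
        mean, var = axial_circular_stats(angles)
        z = np.exp(2j * angles).sum()
        assert mean == pytest.approx(np.angle(z) / 2)
        assert mean == pytest.approx(np.deg2rad(10.0))
        assert var == pytest.approx(1 - abs(z) / 3)

    def test_empty_set_is_undefined(self):
        mean, var = axial_circular_stats(np.array([]))
        assert np.isnan(mean) and np.isnan(var)

    def test_variance_bounds_on_random_angles(self, rng):
        for _ in range(20):
            _, var = axial_circular_stats(rng.uniform(-np.pi / 2, np.pi / 2, 30))
            assert 0.0 <= var <= 1.0


class TestAnisotropyMap:
    def test_homogeneous_scene_single_orientation(self):
        table = make_anisotropy_map(np.full((16, 16), 0.3), block_px=4)
        assert len(table) == 16
        assert not table.omitted.any()
        np.testing.assert_allclose(table.mean_axis_rad, 0.3, atol=1e-12)
        np.testing.assert_allclose(table.circ_variance, 0.0, atol=1e-12)

    def test_two_domain_scene_classifies_blocks(self):
        ax = np.zeros((8, 16))
        ax[:, 8:] = np.deg2rad(60.0)
        table = make_anisotropy_map(ax, block_px=8)
        means = table.sort_values("col").mean_axis_rad.to_numpy()
        assert means[0] == pytest.approx(0.0, abs=1e-12)
        assert means[1] == pytest.approx(np.deg2rad(60.0))

    def test_omission_rule_is_exact(self):
        """Blocks are omitted iff their undefined fraction exceeds 25%."""
        ax = np.zeros((8, 24))
        ax[:3, 0:8] = np.nan  # 37.5% undefined -> omitted
        ax[:2, 8:16] = np.nan  # exactly 25% -> kept
        table = make_anisotropy_map(ax, block_px=8).sort_values("col")
        assert list(table.omitted) == [True, False, False]
        assert np.isnan(table.iloc[0].mean_axis_rad)
        n_exceeding = int(np.sum([np.isnan(ax[:, 8 * i : 8 * (i + 1)]).mean() > 0.25 for i in range(3)]))
        assert int(table.omitted.sum()) == n_exceeding

    def test_line_length_is_one_minus_variance(self, rng):
        ax = rng.uniform(-np.pi / 2, np.pi / 2, (8, 8))
        table = make_anisotropy_map(ax, block_px=8)
        assert table.line_length[0] == pytest.approx(1 - table.circ_variance[0])

    def test_block_size_validation(self):
        with pytest.raises(ValueError):
            make_anisotropy_map(np.zeros((4, 4)), block_px=0)


class TestUnwrapHalfOrder:
    def test_first_order_passes_through(self):
        dl, th = unwrap_half_order(0.5, np.deg2rad(10), "first")
        assert dl == pytest.approx(0.5) and th == pytest.approx(np.deg2rad(10))

    def test_wrap_then_unwrap_round_trip(self):
        theta = 0.35
        for x in np.linspace(0.05, np.pi - 0.05, 9):
            delta_true = np.pi + x
            props = decompose_matrix(mueller_linear_retarder(delta_true, theta))
            dl, th = unwrap_half_order(props.deltaL, props.thetaFA, "second")
            assert dl == pytest.approx(delta_true, abs=1e-9)
            assert abs(signed_axial_difference(th, theta)) < 1e-9

    def test_continuity_at_the_pi_boundary(self):
        eps = 1e-6
        dl, _ = unwrap_half_order(np.pi - eps, 0.0, "second")
        assert dl == pytest.approx(np.pi + eps, abs=1e-12)

    def test_per_pixel_order_array(self):
        dl, th = unwrap_half_order(
            np.array([0.5, 0.5]), np.array([0.1, 0.1]), np.array(["first", "second"])
        )
        assert dl[0] == pytest.approx(0.5)
        assert dl[1] == pytest.approx(2 * np.pi - 0.5)
        assert abs(signed_axial_difference(th[1], 0.1 + np.pi / 2)) < 1e-12


class TestDeviationAnalysis:
    def test_no_circular_retardance_means_no_deviation(self):
        M, truth = deviation_sweep(np.zeros(6), deltaL=1.2, theta=0.3, block_px=4)
        est = analyze_stack(simulate_stack(M))
        table, r = axis_deviation_analysis(
            est.thetaFA_S, truth["thetaFA"], truth["deltaC"], block_px=4
        )
        assert np.all(np.abs(table.dropna().deviation_rad) <= 1e-9)
        assert np.isnan(r)  # degenerate: deltaC constant

    def test_deviation_law_slope_and_correlation(self):
        M, truth = deviation_sweep(np.linspace(-1.0, -0.05, 12), deltaL=1.5, block_px=4)
        est = analyze_stack(simulate_stack(M))
        table, r = axis_deviation_analysis(
            est.thetaFA_S, truth["thetaFA"], truth["deltaC"], block_px=4
        )
        good = table.dropna(subset=["deviation_rad"])
        np.testing.assert_allclose(
            good.deviation_rad, -good.deltaC_rad / 2, atol=1e-9
        )
        slope = np.polyfit(good.deltaC_rad, good.deviation_rad, 1)[0]
        assert slope == pytest.approx(-0.5, abs=1e-6)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_noisy_sweep_keeps_strong_negative_correlation(self):
        from mmpol import NoiseSpec

        M, truth = deviation_sweep(np.linspace(-1.0, -0.05, 12), deltaL=1.5, block_px=8)
        stack = simulate_stack(M, noise=NoiseSpec(gaussian_sigma=0.005), seed=42)
        est = analyze_stack(stack)
        _, r = axis_deviation_analysis(
            est.thetaFA_S, truth["thetaFA"], truth["deltaC"], block_px=8
        )
        assert r < -0.9

    def test_too_few_blocks_gives_undefined_r(self):
        M, truth = deviation_sweep(np.array([-0.5, -0.2]), block_px=4)
        est = analyze_stack(simulate_stack(M))
        _, r = axis_deviation_analysis(
            est.thetaFA_S, truth["thetaFA"], truth["deltaC"], block_px=4
        )
        assert np.isnan(r)
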