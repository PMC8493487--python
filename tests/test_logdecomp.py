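"""Logarithm decomposition: classification, logarithm, property extraction."""

import numpy as np
import pytest

from mmpol import (
    Case,
    build_differential,
    classify_eigenvalues,
    decompose_image,
    decompose_matrix,
    extract_properties,
    mueller_from_differential,
    mueller_linear_retarder,
    mueller_log,
    reconstruct_mueller,
    signed_axial_difference,
    simulate_stack,
    split_L,
)


class TestClassify:
    def test_identity_is_real_positive(self):
        assert classify_eigenvalues(np.eye(4)) is Case.REAL_POSITIVE

    def test_retarder_has_complex_pair(self):
        assert classify_eigenvalues(mueller_linear_retarder(1.0, np.deg2rad(20))) is Case.COMPLEX_PAIR

    def test_negative_real_eigenvalues_are_undefined(self):
        assert classify_eigenvalues(np.diag([1.0, 1.0, -1.0, -1.0])) is Case.UNDEFINED

    def test_zero_eigenvalue_is_undefined(self):
        assert classify_eigenvalues(np.diag([1.0, 0.5, 0.2, 0.0])) is Case.UNDEFINED

    def test_half_wave_retardance_is_undefined(self):
        # delta = pi gives a double -1 eigenvalue
        assert classify_eigenvalues(mueller_linear_retarder(np.pi, 0.3)) is Case.UNDEFINED

    def test_nonfinite_matrix_is_undefined(self):
        M = np.eye(4)
        M[2, 2] = np.nan
        assert classify_eigenvalues(M) is Case.UNDEFINED


class TestMuellerLog:
    def test_identity_log_is_zero(self):
        np.testing.assert_allclose(mueller_log(np.eye(4)), np.zeros((4, 4)), atol=1e-12)

    def test_pure_retarder_log_recovers_LB(self):
        L = mueller_log(mueller_linear_retarder(0.8, 0.0))
        expected = build_differential(LB=0.8)
        np.testing.assert_allclose(L, expected, atol=1e-10)

    def test_generator_round_trip(self):
        L = build_differential(LB=0.5, LBp=0.3, CB=-0.4, alpha1=-0.2, alpha2=-0.2, alpha3=-0.2)
        np.testing.assert_allclose(mueller_log(mueller_from_differential(L)), L, atol=1e-8)

    def test_undefined_case_raises(self):
        with pytest.raises(ValueError):
            mueller_log(np.diag([1.0, 1.0, -1.0, -1.0]))


class TestExtractProperties:
    def test_zero_matrices_give_zero_properties_with_nan_axes(self):
        props = extract_properties(np.zeros((4, 4)), np.zeros((4, 4)))
        assert props.defined
        assert props.deltaL == 0 and props.deltaC == 0 and props.DL == 0
        assert props.DC == 0 and props.Delta == 0
        assert np.isnan(props.thetaFA) and np.isnan(props.thetaTA)

    def test_isotropic_alpha_gives_expected_net_depolarization(self):
        # alpha = -0.51 each corresponds to a net depolarization near 0.4,
        # the level of the 1% lipid scattering phantom
        Lu = np.diag([0.0, -0.51, -0.51, -0.51])
        props = extract_properties(np.zeros((4, 4)), Lu)
        assert props.Delta == pytest.approx(1 - np.exp(-0.51), abs=1e-12)
        assert props.Delta == pytest.approx(0.4, abs=0.005)

    def test_linear_birefringence_components_combine(self):
        Lm = build_differential(LB=0.6, LBp=0.6)
        props = extract_properties(Lm, np.zeros((4, 4)))
        assert props.deltaL == pytest.approx(0.8485, abs=1e-4)
        assert props.thetaFA == pytest.approx(np.pi / 8)

    def test_property_ranges_on_random_media(self, random_media):
        for _, M in random_media:
            p = decompose_matrix(M)
            assert p.defined
            assert 0 <= p.deltaL < np.pi
            assert -np.pi <= p.deltaC < np.pi
            assert 0 <= p.DL <= 1 and -1 <= p.DC <= 1
            assert 0 <= p.Delta <= 1
            if np.isfinite(p.thetaFA):
                assert -np.pi / 2 < p.thetaFA <= np.pi / 2


class TestParameterRecovery:
    def test_noiseless_recovery_of_all_seven_properties(self, random_media):
        for L, M in random_media:
            Lm, Lu = split_L(L)
            truth = extract_properties(Lm, Lu)
            est = decompose_matrix(M / M[0, 0])  # as measured: m11-normalized
            assert est.deltaL == pytest.approx(truth.deltaL, abs=1e-6)
            assert est.deltaC == pytest.approx(truth.deltaC, abs=1e-6)
            assert est.DL == pytest.approx(truth.DL, abs=1e-6)
            assert est.DC == pytest.approx(truth.DC, abs=1e-6)
            assert est.Delta == pytest.approx(truth.Delta, abs=1e-6)
            assert abs(signed_axial_difference(est.thetaFA, truth.thetaFA)) < 1e-6
            assert abs(signed_axial_difference(est.thetaTA, truth.thetaTA)) < 1e-6

    def test_wrap_law_for_overrange_retarders(self):
        """Retardance pi + x reads as pi - x with the axis flipped by pi/2."""
        theta = 0.35
        for x in np.linspace(0.1, np.pi - 0.1, 7):
            props = decompose_matrix(mueller_linear_retarder(np.pi + x, theta))
            assert props.defined
            assert props.deltaL == pytest.approx(np.pi - x, abs=1e-8)
            offset = signed_axial_difference(props.thetaFA, theta)
            assert abs(abs(offset) - np.pi / 2) < 1e-8


class TestDecomposeImage:
    def test_identity_image_is_all_zero_and_defined(self):
        maps = decompose_image(np.broadcast_to(np.eye(4), (2, 3, 4, 4)))
        assert not maps.undefined.any()
        np.testing.assert_allclose(maps.deltaL, 0.0, atol=1e-12)
        np.testing.assert_allclose(maps.Delta, 0.0, atol=1e-12)
        np.testing.assert_allclose(maps.deltaT, 0.0, atol=1e-12)

    def test_pi_retardance_pixel_flagged_undefined(self):
        M = np.stack(
            [mueller_linear_retarder(1.0, 0.1), mueller_linear_retarder(np.pi, 0.1)]
        )[np.newaxis]
        maps = decompose_image(M)
        assert not maps.undefined[0, 0]
        assert maps.undefined[0, 1]
        assert np.isnan(maps.deltaL[0, 1])
        assert maps.case[0, 1] == "undefined"

    def test_reconstruction_mask_propagates(self):
        from mmpol import IntensityStack

        stack = simulate_stack(np.broadcast_to(np.eye(4), (1, 2, 4, 4)))
        images = stack.images.copy()
        images[:, 0, 1] = 0.0
        maps = decompose_image(reconstruct_mueller(IntensityStack(images)))
        assert not maps.undefined[0, 0]
        assert maps.undefined[0, 1]

    def test_pericardium_scene_parameters_recovered(self):
        from mmpol import pericardium_scene

        scene = pericardium_scene(n_regions=(2, 2), region_px=6, seed=11)
        maps = decompose_image(reconstruct_mueller(simulate_stack(scene)))
        assert not maps.undefined.any()
        np.testing.assert_allclose(maps.deltaL, scene.deltaL, atol=1e-8)
        np.testing.assert_allclose(maps.deltaC, scene.deltaC, atol=1e-8)
        np.testing.assert_allclose(maps.Delta, scene.Delta, atol=1e-8)
        assert np.nanmax(np.abs(signed_axial_difference(maps.thetaFA, scene.thetaFA))) < 1e-8
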