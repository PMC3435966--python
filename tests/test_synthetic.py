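"""Synthetic scene generator: distortion chain, rendering, presets."""

import numpy as np
import pytest

import tpscolor as tc
from tpscolor.errors import InvalidInputError
from tpscolor.synthetic import CAMERA_LABELS, CONDITION_LABELS


class TestDistort:
    def test_identity_spec_is_identity(self, rng):
        c = rng.uniform(0, 255, (20, 3))
        assert np.allclose(tc.distort(c, tc.DistortionSpec()), c)

    def test_pure_channel_gain(self):
        spec = tc.DistortionSpec(channel_gains=(2.0, 1.0, 1.0))
        out = tc.distort(np.array([100.0, 100.0, 100.0]), spec)
        assert np.allclose(out, [200.0, 100.0, 100.0])

    def test_gamma_on_mid_grey_matches_scalar_evaluation(self):
        spec = tc.DistortionSpec(gamma=(2.2, 2.2, 2.2))
        out = tc.distort(np.array([127.5, 127.5, 127.5]), spec)
        expected = 255.0 * 0.5**2.2
        assert np.allclose(out, expected, atol=1e-9)
        # frozen from direct scalar evaluation of 255 * 0.5**2.2
        assert out[0] == pytest.approx(55.4975984101, abs=1e-6)

    def test_exposure_normalization_prevents_saturation(self):
        spec = tc.DistortionSpec(
            channel_gains=(1.25, 1.0, 0.75), normalize_exposure=True
        )
        corners = np.array(
            [[255.0, 255, 255], [255, 0, 0], [0, 255, 0], [0, 0, 255]]
        )
        out = tc.distort(corners, spec)
        assert out.max() <= 255.0
        # the cast survives normalization: R/B ratio of neutral above 1
        grey = tc.distort(np.array([128.0, 128.0, 128.0]), spec)
        assert grey[0] / grey[2] > 1.0

    def test_noise_is_seed_deterministic(self):
        spec = tc.DistortionSpec(noise_sd=2.0, seed=99)
        c = np.full((50, 3), 128.0)
        assert np.array_equal(tc.distort(c, spec), tc.distort(c, spec))

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidInputError):
            tc.DistortionSpec(channel_gains=(0.0, 1.0, 1.0))
        with pytest.raises(InvalidInputError):
            tc.DistortionSpec(gamma=(1.0, -2.0, 1.0))
        with pytest.raises(InvalidInputError):
            tc.DistortionSpec(mixing_matrix=np.ones((3, 3)))


class TestRenderChecker:
    def test_image_size_and_layout_contract(self, checker24):
        spec = tc.preset_conditions()["S/A"]
        scene = tc.render_checker(checker24, spec, patch_px=16, grid=(4, 6))
        h, w = scene.image.shape
        assert h == 4 * 17 + 1 and w == 6 * 17 + 1
        assert len(scene.layout.regions) == 24

    def test_noiseless_patch_means_equal_distorted_reference(self, tungsten_scene):
        measured = tc.measure_patches(tungsten_scene.image, tungsten_scene.layout)
        expected = tungsten_scene.distorted_patch_rgb
        assert np.abs(measured.rgb_matrix() - expected).max() < 1e-9

    def test_noisy_means_within_clt_bound(self, checker24):
        spec = tc.preset_conditions(noise_sd=2.0, seed=3)["S/A"]
        scene = tc.render_checker(checker24, spec, patch_px=16)
        layout = tc.CheckerLayout(
            checker=scene.layout.checker, regions=scene.layout.regions,
            sampling_margin=0.0,
        )
        measured = tc.measure_patches(scene.image, layout)
        bound = 3 * 2.0 / np.sqrt(16 * 16)
        dev = np.abs(measured.rgb_matrix() - scene.distorted_patch_rgb)
        # clipping can bias patches near the gamut edge; check interior ones
        interior = (scene.distorted_patch_rgb > 10).all(axis=1) & (
            scene.distorted_patch_rgb < 245
        ).all(axis=1)
        assert np.all(dev[interior] < bound)

    def test_same_seed_renders_bit_identical_images(self, checker24):
        spec = tc.preset_conditions(noise_sd=1.5, seed=11)["NE/B"]
        a = tc.render_checker(checker24, spec, patch_px=8)
        b = tc.render_checker(checker24, spec, patch_px=8)
        assert np.array_equal(a.image.pixels, b.image.pixels)

    def test_changing_seed_changes_only_noise(self, checker24):
        base = tc.preset_conditions(noise_sd=1.5, seed=1)["T/A"]
        other = tc.preset_conditions(noise_sd=1.5, seed=2)["T/A"]
        a = tc.render_checker(checker24, base, patch_px=8)
        b = tc.render_checker(checker24, other, patch_px=8)
        assert np.array_equal(a.distorted_patch_rgb, b.distorted_patch_rgb)
        assert not np.array_equal(a.image.pixels, b.image.pixels)

    def test_grid_too_small_rejected(self, checker24):
        with pytest.raises(InvalidInputError):
            tc.render_checker(checker24, tc.DistortionSpec(), grid=(2, 2))


class TestPresets:
    def test_eight_scenarios(self):
        presets = tc.preset_conditions()
        assert len(presets) == len(CONDITION_LABELS) * len(CAMERA_LABELS) == 8

    def test_all_mixing_matrices_invertible(self):
        for spec in tc.preset_conditions().values():
            assert abs(np.linalg.det(spec.mixing_matrix)) > 1e-6

    def test_tungsten_warms_a_neutral_grey(self):
        spec = tc.preset_conditions()["T/A"]
        grey = tc.distort(np.array([128.0, 128.0, 128.0]), spec)
        assert grey[0] / grey[2] > 1.0


class TestFullLoopRecovery:
    def test_noiseless_preset_recovers_holdout_colors(self, rng):
        ref = tc.checker_24()
        spec = tc.preset_conditions()["T/B"]
        measured, ref_rgb, ids = tc.simulate_measurement(ref, spec)
        model = tc.fit(tc.ControlPointSet(measured, ref_rgb, tuple(ids)))
        holdout = tc.sample_holdout_colors(116, rng)
        calibrated = np.clip(model.warp(tc.distort(holdout, spec)), 0, 255)
        errors = tc.delta_rgb_rows(calibrated, holdout)
        assert errors.mean() < 2.0

    def test_affine_distortion_recovered_to_solver_precision(self, rng):
        ref = tc.checker_24()
        spec = tc.DistortionSpec(
            channel_gains=(1.1, 1.0, 0.85),
            mixing_matrix=np.array(
                [[0.95, 0.04, 0.01], [0.03, 0.94, 0.03], [0.02, 0.05, 0.93]]
            ),
            normalize_exposure=True,
        )
        assert spec.is_affine
        measured, ref_rgb, ids = tc.simulate_measurement(ref, spec)
        model = tc.fit(tc.ControlPointSet(measured, ref_rgb, tuple(ids)))
        holdout = tc.sample_holdout_colors(100, rng)
        calibrated = model.warp(tc.distort(holdout, spec))
        assert tc.delta_rgb_rows(np.clip(calibrated, 0, 255), holdout).max() < 1e-6

    def test_error_ordering_with_chart_size(self):
        """Holdout error decreases (weakly) as the chart grows: 7 >= 24 >= 140."""
        sums = {"7": 0.0, "24": 0.0, "140": 0.0}
        for s in range(10):
            r = np.random.default_rng(700 + s)
            spec = tc.random_distortion(r)
            holdout = tc.sample_holdout_colors(116, r)
            distorted = tc.distort(holdout, spec)
            for key in sums:
                chart = tc.get_checker(key)
                measured, ref_rgb, ids = tc.simulate_measurement(chart, spec)
                model = tc.fit(tc.ControlPointSet(measured, ref_rgb, tuple(ids)))
                cal = np.clip(model.warp(distorted), 0, 255)
                sums[key] += tc.delta_rgb_rows(cal, holdout).mean()
        assert sums["7"] >= sums["24"] >= sums["140"]
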