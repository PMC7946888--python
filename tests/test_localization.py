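"""Segmentation, sharpness metric, axial estimates and the in-situ calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mprheo import (
    CalibrationModel,
    DegenerateImageError,
    FormatError,
    InsufficientRangeError,
    NoObjectError,
    OpticalConfig,
    PlaneStack,
    SharpnessProfile,
    apply_calibration,
    center_of_sharpness,
    characterize_plane_spacing,
    fit_calibration,
    otsu_threshold,
    preprocess_for_sharpness,
    render_frame,
    render_zscan,
    sharpest_plane_z,
    sharpness,
    sharpness_profile,
    split_frame,
    track,
    xy_centroid,
)

DZ = 0.88


def make_profile(values, dz=DZ):
    values = np.asarray(values, dtype=float)
    half = (values.size - 1) // 2
    return SharpnessProfile(
        values=values, plane_indices=np.arange(-half, half + 1), plane_spacing=dz
    )


class TestSplitFrame:
    def test_tile_arithmetic_and_reassembly(self, noise_free_config):
        frame = render_frame((0.2, -0.1, 0.5), noise_free_config)
        stack = split_frame(frame, noise_free_config)
        assert stack.sub_images.shape == (9, 64, 64)
        npx = noise_free_config.tile_pixels
        rebuilt = np.block(
            [[stack.sub_images[r * 3 + c] for c in range(3)] for r in range(3)]
        )
        np.testing.assert_array_equal(rebuilt, frame.image)

    def test_layout_permutation_permutes_plane_indices(self, noise_free_config):
        frame = render_frame((0, 0, 0.5), noise_free_config)
        layout = tuple(reversed(noise_free_config.tile_layout))
        permuted_config = OpticalConfig(noise_model="none", tile_layout=layout)
        stack = split_frame(frame, permuted_config)
        np.testing.assert_array_equal(stack.plane_indices, np.asarray(layout))

    def test_shape_mismatch_names_dimensions(self, noise_free_config):
        from mprheo import RawFrame

        bad = RawFrame(image=np.zeros((100, 192), dtype=np.uint16))
        with pytest.raises(FormatError, match=r"\(192, 192\)"):
            split_frame(bad, noise_free_config)


class TestOtsuThreshold:
    def test_separates_two_populations(self):
        values = np.full(1000, 100.0)
        values[:100] = 500.0
        stack = PlaneStack(
            sub_images=values.reshape(10, 10, 10),
            plane_indices=np.arange(10),
            plane_spacing=DZ,
        )
        threshold = otsu_threshold(stack)
        assert 100.0 < threshold < 500.0

    def test_invariant_to_pixel_order(self):
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 1000, size=(9, 16, 16))
        stack = PlaneStack(
            sub_images=pixels, plane_indices=np.arange(-4, 5), plane_spacing=DZ
        )
        shuffled = PlaneStack(
            sub_images=rng.permutation(pixels.ravel()).reshape(9, 16, 16),
            plane_indices=np.arange(-4, 5),
            plane_spacing=DZ,
        )
        assert otsu_threshold(stack) == otsu_threshold(shuffled)

    def test_constant_stack_rejected(self):
        stack = PlaneStack(
            sub_images=np.full((9, 8, 8), 7.0),
            plane_indices=np.arange(-4, 5),
            plane_spacing=DZ,
        )
        with pytest.raises(DegenerateImageError):
            otsu_threshold(stack)

    def test_isolates_bead_on_rendered_frame(self, noise_free_config):
        frame = render_frame((0.3, -0.2, 0.0), noise_free_config)
        stack = split_frame(frame, noise_free_config)
        threshold = otsu_threshold(stack)
        image = stack.plane(0).astype(float)
        rows, cols = np.nonzero(image >= threshold)
        centre = (noise_free_config.tile_pixels - 1) / 2.0
        px = noise_free_config.pixel_size
        dist = np.hypot(
            (rows - centre) * px - (-0.2), (cols - centre) * px - 0.3
        )
        assert dist.max() <= 1.5 * noise_free_config.bead_diameter / 2.0


class TestXYCentroid:
    def test_symmetric_blob_centres_at_zero(self):
        idx = np.arange(33) - 16.0
        blob = np.exp(-(idx[:, None] ** 2 + idx[None, :] ** 2) / 18.0)
        x, y = xy_centroid(blob, threshold=0.01, pixel_size=0.1)
        assert x == pytest.approx(0.0, abs=1e-9)
        assert y == pytest.approx(0.0, abs=1e-9)

    def test_integer_shift_equivariance(self):
        rng = np.random.default_rng(1)
        image = np.zeros((48, 48))
        image[20:28, 18:26] = rng.uniform(1.0, 5.0, size=(8, 8))
        x0, y0 = xy_centroid(image, 0.5, pixel_size=0.2)
        x1, y1 = xy_centroid(np.roll(image, 3, axis=1), 0.5, pixel_size=0.2)
        assert x1 - x0 == pytest.approx(3 * 0.2, abs=1e-12)
        assert y1 == pytest.approx(y0, abs=1e-12)

    def test_recovers_rendered_position(self, noise_free_config):
        frame = render_frame((0.30, -0.20, 0.0), noise_free_config)
        stack = split_frame(frame, noise_free_config)
        threshold = otsu_threshold(stack)
        x, y = xy_centroid(stack.plane(0), threshold, noise_free_config.pixel_size)
        assert x == pytest.approx(0.30, abs=0.02)
        assert y == pytest.approx(-0.20, abs=0.02)

    def test_empty_foreground_rejected(self):
        with pytest.raises(NoObjectError):
            xy_centroid(np.ones((8, 8)), threshold=10.0)


class TestSharpness:
    def test_uniform_image_hand_value(self):
        # 4x4 image of 2s: (16 * (4 - 2)) / 32^2 = 0.03125
        assert sharpness(np.full((4, 4), 2.0)) == pytest.approx(0.03125, rel=1e-12)

    @pytest.mark.parametrize("value", [2.0, 10.0, 400.0])
    def test_single_pixel_closed_form(self, value):
        image = np.zeros((8, 8))
        image[3, 4] = value
        assert sharpness(image) == pytest.approx(1.0 - 1.0 / value, rel=1e-12)

    def test_concentration_increases_sharpness(self):
        # Fixed total intensity: every redistribution onto fewer pixels is sharper.
        total = 64.0
        values = []
        for n_pixels in (16, 8, 4, 2, 1):
            image = np.zeros((8, 8))
            image.ravel()[:n_pixels] = total / n_pixels
            values.append(sharpness(image))
        assert np.all(np.diff(values) > 0)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateImageError):
            sharpness(np.zeros((4, 4)))


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        stack = PlaneStack(
            sub_images=np.full((9, 8, 8), 100.0),
            plane_indices=np.arange(-4, 5),
            plane_spacing=DZ,
        )
        assert preprocess_for_sharpness(stack).sub_images.max() == 0.0

    def test_dark_and_bright_beads_equally_sharp(self):
        background = np.full((16, 16), 100.0)
        bright, dark = background.copy(), background.copy()
        bright[6:10, 6:10] += 50.0
        dark[6:10, 6:10] -= 50.0
        stacks = [
            PlaneStack(
                sub_images=img[None], plane_indices=np.array([0]), plane_spacing=DZ
            )
            for img in (bright, dark)
        ]
        values = [
            sharpness(preprocess_for_sharpness(s).sub_images[0]) for s in stacks
        ]
        assert values[0] == pytest.approx(values[1], rel=1e-12)

    def test_bead_free_tile_has_small_numerator(self, noisy_config):
        frame = render_frame((0, 0, 0), noisy_config, seed=5)
        stack = preprocess_for_sharpness(split_frame(frame, noisy_config))
        bead = stack.plane(0).astype(float)
        rng = np.random.default_rng(5)
        empty = np.abs(
            rng.poisson(noisy_config.background_level, size=bead.shape)
            - noisy_config.background_level
        ).astype(float)
        numerator = lambda img: np.square(img).sum() - img.sum()
        assert numerator(empty) < 0.1 * numerator(bead)


class TestCenterOfSharpness:
    def test_symmetric_profile(self):
        assert center_of_sharpness(
            make_profile([1, 2, 3, 4, 5, 4, 3, 2, 1])
        ) == pytest.approx(0.0, abs=1e-12)

    def test_single_plane_weight(self):
        values = np.zeros(9)
        values[6] = 3.0  # plane n = +2
        assert center_of_sharpness(make_profile(values)) == pytest.approx(2 * DZ)

    def test_two_point_mean(self):
        values = np.zeros(9)
        values[4] = values[5] = 1.0  # planes 0 and +1
        assert center_of_sharpness(make_profile(values)) == pytest.approx(DZ / 2)

    def test_zero_profile_rejected(self):
        with pytest.raises(DegenerateImageError):
            center_of_sharpness(make_profile(np.zeros(9)))


class TestSharpestPlaneZ:
    def test_quarter_step_above(self):
        values = np.array([0, 0, 0, 0.2, 1.0, 0.8, 0.1, 0, 0])
        # sharpest n=0, second n=+1 -> +dz/4 = +0.22 um at dz = 0.88
        assert sharpest_plane_z(make_profile(values)) == pytest.approx(0.22)

    def test_quarter_step_below_mirror(self):
        values = np.array([0, 0, 0.1, 0.8, 1.0, 0.2, 0, 0, 0])
        assert sharpest_plane_z(make_profile(values)) == pytest.approx(-0.22)

    def test_staircase_on_rendered_scan(self, zscan_nf, noise_free_config):
        stage_z, frames = zscan_nf
        z_sp = []
        for frame in frames:
            pre = preprocess_for_sharpness(split_frame(frame, noise_free_config))
            z_sp.append(sharpest_plane_z(sharpness_profile(pre)))
        z_sp = np.asarray(z_sp)
        dz = noise_free_config.plane_spacing
        # every value on the half-spacing lattice {n dz +/- dz/4}
        lattice_pos = z_sp / (dz / 4.0)
        np.testing.assert_allclose(lattice_pos, np.round(lattice_pos), atol=1e-9)
        assert np.all(np.round(lattice_pos).astype(int) % 2 != 0)
        # consecutive distinct values differ by exactly dz/2
        changes = np.diff(z_sp)
        changes = changes[np.abs(changes) > 1e-12]
        np.testing.assert_allclose(changes, dz / 2.0, atol=1e-9)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(z=st.floats(min_value=-1.5, max_value=1.5))
    def test_lattice_invariant_for_rendered_frames(self, z):
        config = OpticalConfig(noise_model="none")
        pre = preprocess_for_sharpness(
            split_frame(render_frame((0, 0, z), config), config)
        )
        z_sp = sharpest_plane_z(sharpness_profile(pre))
        lattice_pos = z_sp / (config.plane_spacing / 4.0)
        assert abs(lattice_pos - round(lattice_pos)) < 1e-9
        assert round(lattice_pos) % 2 != 0


class TestCalibration:
    @staticmethod
    def staircase_series():
        steps = np.array([-0.66, -0.22, 0.22, 0.66])
        z_sp = np.repeat(steps, 6)
        return z_sp / 5.0, z_sp

    def test_constructed_linear_relation(self):
        z_cs, z_sp = self.staircase_series()
        model = fit_calibration(z_cs, z_sp, OpticalConfig(noise_model="none"))
        assert model.gradient == pytest.approx(5.0, abs=1e-6)
        assert model.offset == pytest.approx(0.0, abs=1e-9)
        assert model.n_points == 24

    def test_insufficient_steps_rejected(self):
        z_sp = np.repeat([0.22, 0.66], 12)
        with pytest.raises(InsufficientRangeError):
            fit_calibration(z_sp / 5.0, z_sp, OpticalConfig(noise_model="none"))

    def test_symmetric_noise_leaves_gradient_unbiased(self):
        rng = np.random.default_rng(6)
        config = OpticalConfig(noise_model="none")
        gradients = []
        for _ in range(30):
            z_cs, z_sp = self.staircase_series()
            gradients.append(
                fit_calibration(z_cs + rng.normal(0, 0.01, z_cs.size), z_sp, config).gradient
            )
        assert np.mean(gradients) == pytest.approx(5.0, rel=0.05)

    def test_apply_example_and_linearity(self):
        model = CalibrationModel(
            gradient=5.26, offset=0.0, center=0.0, fit_range=(-1.0, 1.0),
            n_points=24, plane_spacing=DZ,
        )
        assert apply_calibration(0.1, model) == pytest.approx(0.526)
        a, b = 0.07, -0.13
        assert apply_calibration(a, model) + apply_calibration(b, model) - apply_calibration(
            0.0, model
        ) == pytest.approx(apply_calibration(a + b, model))


class TestTrack:
    def test_static_centred_bead(self, noise_free_config):
        frames = [
            render_frame((0, 0, 0), noise_free_config, timestamp=i) for i in range(3)
        ]
        model = CalibrationModel(
            gradient=2.0, offset=0.0, center=0.0, fit_range=(-0.44, 0.44),
            n_points=24, plane_spacing=DZ,
        )
        result = track(frames, noise_free_config, calibration=model)
        np.testing.assert_allclose(result.x, 0.0, atol=1e-6)
        np.testing.assert_allclose(result.y, 0.0, atol=1e-6)
        np.testing.assert_allclose(result.z_rcs, 0.0, atol=1e-6)

    def test_zscan_recovery_gradient_unity(self, zscan_nf, noise_free_config):
        stage_z, frames = zscan_nf
        result = track(frames, noise_free_config, calibration="self")
        mask = np.abs(stage_z) <= 1.0
        gradient = np.polyfit(stage_z[mask], result.z_rcs[mask], 1)[0]
        assert gradient == pytest.approx(1.0, rel=0.02)

    def test_cs_gradient_below_unity_before_rescaling(self, zscan_nf, noise_free_config):
        # Nine planes undersample the sharpness curve, biasing z_cs toward 0.
        stage_z, frames = zscan_nf
        result = track(frames, noise_free_config, calibration="self")
        mask = np.abs(stage_z) <= 1.0
        raw_gradient = np.polyfit(stage_z[mask], result.z_cs[mask], 1)[0]
        assert 0.0 < raw_gradient < 1.0

    def test_cs_monotone_in_central_region(self, zscan_nf, noise_free_config):
        stage_z, frames = zscan_nf
        result = track(frames, noise_free_config, calibration="self")
        mask = np.abs(stage_z) <= 1.0
        assert np.all(np.diff(result.z_cs[mask]) > 0)

    def test_trajectory_recovery_correlates_with_truth(self, water_params, noisy_config):
        from mprheo import render_trajectory_frames

        traj = simulate_from(water_params, 150, seed=8)
        sweep_z = np.arange(-1.8, 1.8 + 1e-9, 0.1)
        sweep = render_zscan(sweep_z, noisy_config, seed=9)
        frames = sweep + render_trajectory_frames(traj, noisy_config, seed=10)
        result = track(
            frames, noisy_config, calibration="self", calibration_frames=len(sweep)
        )
        n0 = len(sweep)
        for estimate, truth in (
            (result.x[n0:], traj.positions[0]),
            (result.y[n0:], traj.positions[1]),
            (result.z_rcs[n0:], traj.positions[2]),
        ):
            assert np.corrcoef(estimate, truth)[0, 1] > 0.99


def simulate_from(params, n_frames, seed):
    from mprheo import simulate_trajectory

    return simulate_trajectory(params, 67.0, n_frames, seed=seed)


class TestPlaneSpacing:
    def test_doubling_spacing_doubles_estimate(self):
        estimates = {}
        for spacing in (0.6, 1.2):
            config = OpticalConfig(noise_model="none", plane_spacing=spacing)
            stage_z = np.arange(-3.0, 3.0 + 1e-9, 0.1)
            frames = render_zscan(stage_z, config)
            estimates[spacing] = characterize_plane_spacing(frames, stage_z, config)
        assert estimates[1.2] == pytest.approx(2 * estimates[0.6], rel=0.02)

    def test_translation_invariance(self, noise_free_config):
        stage_z = np.arange(-3.0, 3.0 + 1e-9, 0.1)
        frames = render_zscan(stage_z, noise_free_config)
        a = characterize_plane_spacing(frames, stage_z, noise_free_config)
        b = characterize_plane_spacing(frames, stage_z + 5.0, noise_free_config)
        assert a == pytest.approx(b, rel=1e-9)

    def test_recovers_configured_spacing(self, noise_free_config):
        stage_z = np.arange(-4.0, 4.0 + 1e-9, 0.05)
        frames = render_zscan(stage_z, noise_free_config)
        estimate = characterize_plane_spacing(frames, stage_z, noise_free_config)
        assert estimate == pytest.approx(noise_free_config.plane_spacing, rel=0.02)

    def test_short_scan_rejected(self, noise_free_config):
        stage_z = np.arange(-0.3, 0.3 + 1e-9, 0.1)
        frames = render_zscan(stage_z, noise_free_config)
        with pytest.warns(UserWarning):
            with pytest.raises(Exception):
                characterize_plane_spacing(frames, stage_z, noise_free_config)
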