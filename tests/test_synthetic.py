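"""Synthetic-data generators: determinism, signal-law consistency, schedules."""

import numpy as np
import pytest

from mechanomap.calibration import DEFAULT_MODEL, DEFAULT_STRAIN_MODEL, stress_from_strain
from mechanomap.errors import CapacityError, ScheduleRangeError, ValidationError
from mechanomap.mrsignal import compute_sbr
from mechanomap.synthetic import (
    LoadingProfile,
    NoiseSpec,
    WarpSpec,
    generate_calibration_phantom,
    generate_cfm_observations,
    generate_registration_scene,
    generate_tumor_timeseries,
    render_session,
)


class TestPhantomGenerator:
    def test_empty_scene_is_pure_background(self):
        volume, scene = generate_calibration_phantom(0, [], seed=1)
        assert scene.n_particles == 0
        assert volume.intensities.mean() == pytest.approx(
            scene.noise.background_mean, rel=0.01
        )

    def test_same_seed_bit_identical(self):
        v1, s1 = generate_calibration_phantom(10, 2.0, seed=123)
        v2, s2 = generate_calibration_phantom(10, 2.0, seed=123)
        assert np.array_equal(v1.intensities, v2.intensities)
        assert np.array_equal(s1.positions_at(0), s2.positions_at(0))

    def test_different_seed_differs(self):
        v1, _ = generate_calibration_phantom(10, 2.0, seed=1)
        v2, _ = generate_calibration_phantom(10, 2.0, seed=2)
        assert not np.array_equal(v1.intensities, v2.intensities)

    def test_capacity_error_names_the_limit(self):
        with pytest.raises(CapacityError):
            generate_calibration_phantom(
                500, 0.0, volume_shape=(20, 40, 40), seed=0
            )

    def test_stress_broadcast_and_validation(self):
        _, scene = generate_calibration_phantom(4, 3.0, seed=0)
        assert np.all(scene.stresses_at(0) == 3.0)
        with pytest.raises(ValidationError):
            generate_calibration_phantom(3, [1.0, 2.0], seed=0)
        with pytest.raises(ValidationError):
            generate_calibration_phantom(2, [1.0, 20.0], seed=0)

    @pytest.mark.parametrize("S", [0.0, 5.0, 10.0, 15.0])
    def test_rendered_contrast_follows_signal_law(self, S):
        # noiseless SBR ratio to the zero-stress design SBR matches the
        # biexponential ratio within 1%
        volume, scene = generate_calibration_phantom(
            8, S, seed=21, noiseless=True
        )
        model, noise = scene.model, scene.noise
        expected = (
            model.a1 * np.exp(-model.b1 * S) + model.a2 * np.exp(-model.b2 * S)
        ) / model.signal_at_zero
        for p in scene.particles:
            sbr = compute_sbr(volume, volume.mm_to_voxel(p.positions[0])).sbr
            assert sbr / noise.sbr0 == pytest.approx(expected, rel=0.01)

    def test_noise_spec_validation(self):
        with pytest.raises(ValidationError):
            NoiseSpec(sigma=-1.0)
        with pytest.raises(ValidationError):
            NoiseSpec(spot_depth=200.0)
        with pytest.raises(ValidationError):
            NoiseSpec(model="poisson")


class TestTumorTimeseries:
    def test_constant_trajectory_zero_delta(self):
        prof = LoadingProfile.constant(2.0, duration_hours=10 * 24)
        _, scene = generate_tumor_timeseries(
            5, [0.0, 3.0, 6.0], prof, seed=2, noiseless=True
        )
        stresses = np.array([p.true_stress for p in scene.particles])
        assert np.all(np.diff(stresses, axis=1) == 0.0)

    def test_zero_growth_static_positions(self):
        _, scene = generate_tumor_timeseries(
            6, [0.0, 2.0, 4.0], np.full((6, 3), 1.0), growth_rate=0.0, seed=3,
            noiseless=True,
        )
        for p in scene.particles:
            assert np.array_equal(p.positions[0], p.positions[1])
            assert np.array_equal(p.positions[0], p.positions[2])

    def test_growth_scales_about_centroid(self):
        _, scene = generate_tumor_timeseries(
            10, [0.0, 1.0], np.full((10, 2), 1.0), growth_rate=0.1, seed=4,
            noiseless=True,
        )
        p0 = scene.positions_at(0)
        p1 = scene.positions_at(1)
        c = p0.mean(axis=0)
        assert np.allclose(p1 - c, 1.1 * (p0 - c), atol=1e-12)

    def test_schedule_range_error(self):
        prof = LoadingProfile.gradual()  # defined over 48 h only
        with pytest.raises(ScheduleRangeError):
            generate_tumor_timeseries(3, [0.0, 5.0], prof, seed=5)

    def test_acute_ramp_rate_exceeds_gradual_max(self):
        gradual = LoadingProfile.gradual()
        acute = LoadingProfile.acute()
        assert acute.max_interval_rate() > gradual.max_interval_rate()
        # both reach the same 5 kPa peak
        assert gradual.stress_at(48.0) == acute.stress_at(49.0) == 5.0

    def test_aggregate_fraction_recorded(self):
        _, scene = generate_tumor_timeseries(
            20, [0.0, 1.0], np.full((20, 2), 1.0), aggregate_fraction=0.25,
            seed=6, noiseless=True,
        )
        assert scene.aggregate_flags.sum() == 5


class TestRegistrationScene:
    def test_identity_warp_zero_jitter_exact(self):
        scene = generate_registration_scene(
            60, 10, warp=WarpSpec(), jitter=0.0, seed=1
        )
        assert np.allclose(scene.source.points, scene.target.points, atol=1e-12)
        assert np.allclose(scene.sensor_source, scene.sensor_target, atol=1e-12)

    def test_zero_vimentin_fraction_all_negative(self):
        scene = generate_registration_scene(
            60, 15, warp=WarpSpec(), vimentin_fraction=0.0, seed=2
        )
        assert np.all(scene.sensor_labels == 0)
        assert scene.labels.labels.max() == 0

    def test_fraction_of_tumor_volume_positive(self):
        scene = generate_registration_scene(
            60, 10, warp=WarpSpec(), vimentin_fraction=0.4, seed=3
        )
        lab = scene.labels.labels
        inside = scene.labels.intensity > 0
        assert np.mean(lab[inside] > 0) == pytest.approx(0.4, abs=0.05)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            generate_registration_scene(60, 10, vimentin_fraction=1.2, seed=0)

    def test_deterministic(self):
        a = generate_registration_scene(50, 8, seed=7)
        b = generate_registration_scene(50, 8, seed=7)
        assert np.array_equal(a.target.points, b.target.points)
        assert np.array_equal(a.labels.labels, b.labels.labels)


class TestCfmObservations:
    def test_zero_stress_zero_strain(self):
        _, scene = generate_calibration_phantom(5, 0.0, seed=8, noiseless=True)
        obs = generate_cfm_observations(scene, optical_noise=0.0)
        assert all(strain == 0.0 for _, _, strain in obs)

    def test_noiseless_round_trip(self):
        _, scene = generate_calibration_phantom(5, 7.0, seed=9, noiseless=True)
        obs = generate_cfm_observations(scene, optical_noise=0.0)
        for _, _, strain in obs:
            assert stress_from_strain(DEFAULT_STRAIN_MODEL, strain) == pytest.approx(
                7.0, abs=1e-8
            )

    def test_strain_monotone_in_stress(self):
        S = np.linspace(0, 15, 16)
        _, scene = generate_calibration_phantom(16, S, seed=10, noiseless=True)
        obs = sorted(generate_cfm_observations(scene, optical_noise=0.0))
        strains = {pid: strain for pid, _, strain in obs}
        ordered = [strains[p.id] for p in sorted(
            scene.particles, key=lambda p: p.true_stress[0]
        )]
        assert np.all(np.diff(ordered) > 0)


class TestRenderSession:
    def test_noise_seed_controls_noise_only(self):
        _, scene = generate_calibration_phantom(5, 1.0, seed=11)
        a = render_session(scene, 0, seed=1)
        b = render_session(scene, 0, seed=1)
        c = render_session(scene, 0, seed=2)
        assert np.array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_linear_depth_variant_renders(self):
        _, scene = generate_calibration_phantom(3, 0.0, seed=12)
        v = render_session(scene, 0, seed=1, depth_model="linear", noiseless=True)
        assert v.intensities.min() < scene.noise.background_mean
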