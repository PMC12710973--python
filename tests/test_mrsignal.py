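"""Dark-spot detection, SBR quantification, and the aggregation filter."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mechanomap.calibration import DEFAULT_MODEL, forward_signal, invert_signal
from mechanomap.errors import BoundaryError, ValidationError
from mechanomap.mrsignal import (
    Detection,
    MRVolume,
    compute_sbr,
    detect_particles,
    filter_aggregates,
    normalize_signal,
    sbr_roi_voxels,
)
from mechanomap.synthetic import NoiseSpec, generate_calibration_phantom, render_session


def volume_with_roi_level(roi_level, background=100.0, shape=(10, 40, 40)):
    """Uniform volume with the 18 SBR ROI voxels set to roi_level."""
    vol = np.full(shape, background)
    roi_idx, _ = sbr_roi_voxels(shape, (5.5, 20.0, 20.0))
    vol[roi_idx[:, 0], roi_idx[:, 1], roi_idx[:, 2]] = roi_level
    return MRVolume(intensities=vol)


class TestComputeSbr:
    def test_uniform_volume_gives_zero(self):
        m = compute_sbr(volume_with_roi_level(100.0), (5.5, 20.0, 20.0))
        assert m.sbr == 0.0
        assert m.roi_mean == m.background_mean == 100.0

    @pytest.mark.parametrize("roi,expected", [(50.0, 1.0), (25.0, 3.0)])
    def test_reciprocal_formula(self, roi, expected):
        m = compute_sbr(volume_with_roi_level(roi), (5.5, 20.0, 20.0))
        assert m.sbr == pytest.approx(expected)

    def test_boundary_raises_named_error(self):
        vol = MRVolume(intensities=np.full((10, 40, 40), 100.0))
        with pytest.raises(BoundaryError, match="background"):
            compute_sbr(vol, (5.5, 3.0, 20.0))
        with pytest.raises(BoundaryError, match="axial"):
            compute_sbr(vol, (9.5, 20.0, 20.0))

    def test_invariant_to_global_rescaling(self):
        volume, scene = generate_calibration_phantom(5, 4.0, seed=3)
        scaled = MRVolume(volume.intensities * 7.5, volume.voxel_size)
        for p in scene.particles:
            c = volume.mm_to_voxel(p.positions[0])
            a = compute_sbr(volume, c).sbr
            b = compute_sbr(scaled, c).sbr
            assert b == pytest.approx(a, rel=1e-12)


class TestDetectParticles:
    def test_noiseless_phantom_full_recall(self):
        volume, scene = generate_calibration_phantom(30, 0.0, seed=0, noiseless=True)
        dets = detect_particles(volume)
        assert len(dets) == 30
        tree = cKDTree(scene.positions_at(0))
        d, _ = tree.query(np.array([x.position_mm for x in dets]))
        assert np.all(d < 0.1)  # within one in-plane voxel of ground truth

    def test_default_noise_precision_recall(self):
        hits, total_det, total_true = 0, 0, 0
        for seed in (1, 2, 3):
            volume, scene = generate_calibration_phantom(30, 0.0, seed=seed)
            dets = detect_particles(volume)
            tree = cKDTree(scene.positions_at(0))
            d, _ = tree.query(np.array([x.position_mm for x in dets]))
            hits += int(np.sum(d < 0.15))
            total_det += len(dets)
            total_true += 30
        assert hits / total_det >= 0.95   # precision
        assert hits / total_true >= 0.95  # recall

    def test_pure_noise_volume_yields_nothing(self):
        volume, _ = generate_calibration_phantom(0, [], seed=9)
        assert detect_particles(volume) == []

    def test_constant_volume_yields_nothing(self):
        vol = MRVolume(intensities=np.full((10, 40, 40), 55.0))
        assert detect_particles(vol) == []

    def test_merged_pair_is_single_aggregate(self):
        # two spots 0.3 mm apart (one spot width, far below the 1 mm
        # separation gate) merge into one detection with an oversize area
        volume, scene = generate_calibration_phantom(1, 0.0, seed=4)
        p = scene.particles[0]
        twin = type(p)(id=1, positions=p.positions + np.array([[0.3, 0.0, 0.0]]),
                       true_stress=p.true_stress)
        scene.particles.append(twin)
        merged = render_session(scene, 0, seed=5)
        dets = detect_particles(merged, min_separation=1.0)
        assert len(dets) == 1
        assert dets[0].is_aggregate

    def test_estimated_stress_on_noiseless_phantom(self):
        # the full measurement chain is unbiased without noise: < 2% error
        stresses = np.linspace(0.5, 15.0, 12)
        vol0, _ = generate_calibration_phantom(12, 0.0, seed=6, noiseless=True)
        ref = float(np.mean([d.sbr for d in detect_particles(vol0)]))
        volume, scene = generate_calibration_phantom(
            12, stresses, seed=6, noiseless=True
        )
        dets = detect_particles(volume)
        tree = cKDTree(scene.positions_at(0))
        for det in dets:
            _, idx = tree.query(det.position_mm)
            S_true = scene.particles[idx].true_stress[0]
            S_est = invert_signal(
                DEFAULT_MODEL, normalize_signal(det.sbr, ref, DEFAULT_MODEL)
            )
            assert S_est == pytest.approx(S_true, rel=0.02, abs=0.02)

    def test_bad_min_contrast_rejected(self):
        vol = MRVolume(intensities=np.full((10, 40, 40), 55.0))
        with pytest.raises(ValidationError):
            detect_particles(vol, min_contrast=1.5)


def make_detection(sbr=1.0, area=5):
    return Detection(
        centroid=np.zeros(3), position_mm=np.zeros(3), roi_mean=50.0,
        background_mean=100.0, sbr=sbr, dark_area_px=area,
        is_aggregate=False, noise_sd=1.0,
    )


class TestFilterAggregates:
    def test_boundary_sbr_exactly_at_threshold_retained(self):
        retained, excluded = filter_aggregates([make_detection(sbr=2.5)])
        assert len(retained) == 1 and not excluded

    def test_over_threshold_excluded(self):
        retained, excluded = filter_aggregates([make_detection(sbr=2.6, area=9)])
        assert len(excluded) == 1 and not retained

    def test_area_boundary(self):
        retained, _ = filter_aggregates([make_detection(area=9)])
        assert len(retained) == 1
        _, excluded = filter_aggregates([make_detection(area=10)])
        assert len(excluded) == 1

    def test_counting_on_mixed_set(self):
        dets = [make_detection(area=16 if i < 3 else 4) for i in range(10)]
        retained, excluded = filter_aggregates(dets)
        assert len(retained) == 7 and len(excluded) == 3

    def test_and_variant_requires_both(self):
        det = make_detection(sbr=2.6, area=5)
        retained, excluded = filter_aggregates([det], combine="and")
        assert len(retained) == 1
        det = make_detection(sbr=2.6, area=16)
        _, excluded = filter_aggregates([det], combine="and")
        assert len(excluded) == 1

    def test_partition_is_exact(self):
        dets = [make_detection(sbr=s) for s in (0.5, 2.5, 2.6, 3.0)]
        retained, excluded = filter_aggregates(dets)
        assert len(retained) + len(excluded) == len(dets)
        assert not (set(map(id, retained)) & set(map(id, excluded)))


class TestNormalizeSignal:
    def test_reference_maps_to_zero_stress_signal(self):
        assert normalize_signal(0.8, 0.8) == pytest.approx(0.9984)

    def test_zero_maps_to_zero(self):
        assert normalize_signal(0.0, 0.8) == 0.0

    def test_half_reference(self):
        assert normalize_signal(0.4, 0.8) == pytest.approx(0.4992)

    def test_invalid_reference(self):
        with pytest.raises(ValidationError):
            normalize_signal(0.5, 0.0)
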