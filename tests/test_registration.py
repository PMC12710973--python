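"""CPD registration, transform application, region assignment and stats."""

import numpy as np
import pytest

from mechanomap.errors import DegenerateCloudError, ValidationError
from mechanomap.registration import (
    LabelVolume,
    PointCloud,
    RegionAssignment,
    assign_regions,
    region_stats,
    register_cpd,
    transform_points,
)
from mechanomap.synthetic import WarpSpec, generate_registration_scene


def rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


@pytest.fixture(scope="module")
def cloud():
    rng = np.random.default_rng(3)
    return PointCloud(rng.uniform(0, 10, (80, 3)), frame_label="mr")


class TestRigidCpd:
    def test_identity_converges_fast(self, cloud):
        res = register_cpd(cloud, cloud, mode="rigid", w=0.0)
        assert res.converged
        assert res.final_sigma2 < 1e-6
        assert np.allclose(res.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(res.registered, cloud.points, atol=1e-6)

    def test_recovers_rotation_translation(self, cloud):
        R = rot_z(10.0)
        t = np.array([3.0, -2.0, 1.0])
        target = PointCloud(cloud.points @ R.T + t)
        res = register_cpd(cloud, target, mode="rigid", w=0.0)
        assert np.allclose(res.rotation, R, atol=1e-3)
        assert np.allclose(res.translation, t, atol=1e-3)
        assert res.scale == pytest.approx(1.0, abs=1e-3)

    def test_equivariance_under_pre_rotation(self, cloud):
        R = rot_z(25.0)
        target = PointCloud(cloud.points @ rot_z(8.0).T + [1.0, 0.5, -0.3])
        res0 = register_cpd(cloud, target, mode="rigid", w=0.0)
        resR = register_cpd(
            PointCloud(cloud.points @ R.T), PointCloud(target.points @ R.T),
            mode="rigid", w=0.0,
        )
        r0 = np.linalg.norm(res0.registered - target.points, axis=1)
        rR = np.linalg.norm(resR.registered - target.points @ R.T, axis=1)
        assert np.allclose(np.sort(r0), np.sort(rR), atol=1e-6)

    def test_collinear_cloud_rejected(self):
        line = PointCloud(np.outer(np.arange(10.0), [1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateCloudError):
            register_cpd(line, line, mode="rigid")

    def test_too_few_points_rejected(self):
        pts = PointCloud(np.random.default_rng(0).uniform(0, 1, (3, 3)))
        with pytest.raises(ValidationError):
            register_cpd(pts, pts, mode="rigid")


@pytest.fixture(scope="module")
def warped_scene():
    return generate_registration_scene(
        300, 30,
        warp=WarpSpec(rotation=(4, -3, 5), translation=(1.5, -1.0, 0.8),
                      scale=1.03, nonrigid_amplitude=0.5,
                      nonrigid_length_scale=5.0),
        jitter=0.03, seed=17,
    )


class TestNonrigidCpd:
    def test_recovers_warp_within_tolerance(self, warped_scene):
        res = register_cpd(warped_scene.source, warped_scene.target, mode="nonrigid")
        sensors = transform_points(res, PointCloud(warped_scene.sensor_source))
        err = np.linalg.norm(sensors.points - warped_scene.sensor_target, axis=1)
        assert np.sqrt(np.mean(err**2)) < 0.2
        assert err.max() < 0.3

    def test_objective_non_increasing(self, warped_scene):
        res = register_cpd(warped_scene.source, warped_scene.target, mode="nonrigid")
        obj = np.array(res.objective_history)
        assert len(obj) >= 2
        assert np.all(np.diff(obj) <= 1e-6 * np.maximum(np.abs(obj[:-1]), 1.0))

    def test_large_lambda_degenerates_to_rigid(self, cloud):
        R = rot_z(6.0)
        target = PointCloud(cloud.points @ R.T + [1.0, -0.5, 0.2])
        stiff = register_cpd(cloud, target, mode="nonrigid", lam=1e6)
        rigid = register_cpd(cloud, target, mode="rigid", w=0.0)
        assert np.allclose(stiff.registered, rigid.registered, atol=1e-3)

    def test_transform_reproduces_registered_cloud(self, warped_scene):
        res = register_cpd(warped_scene.source, warped_scene.target, mode="nonrigid")
        again = transform_points(res, warped_scene.source)
        assert np.allclose(again.points, res.registered, atol=1e-10)


class TestTransformPoints:
    def test_identity_result_leaves_points(self, cloud):
        res = register_cpd(cloud, cloud, mode="rigid", w=0.0)
        out = transform_points(res, cloud)
        assert np.allclose(out.points, cloud.points, atol=1e-6)

    def test_pure_translation_exact(self, cloud):
        t = np.array([5.0, -3.0, 2.0])
        target = PointCloud(cloud.points + t)
        res = register_cpd(cloud, target, mode="rigid", w=0.0)
        assert np.allclose(res.translation, t, atol=1e-4)
        probe = PointCloud(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]]))
        moved = transform_points(res, probe)
        assert np.allclose(moved.points, probe.points + t, atol=1e-3)


def uniform_labels(value, shape=(20, 20, 20)):
    return LabelVolume(
        labels=np.full(shape, value, dtype=np.uint8),
        voxel_size=(0.2, 0.2, 0.2),
    )


class TestAssignRegions:
    def test_point_in_pure_positive_region(self):
        asn = assign_regions(PointCloud([[2.0, 2.0, 2.0]]), uniform_labels(1))
        assert asn[0].region_label == "vimentin_positive"

    def test_all_negative_volume(self):
        asn = assign_regions(PointCloud([[2.0, 2.0, 2.0]]), uniform_labels(0))
        assert asn[0].region_label == "vimentin_negative"

    def test_point_outside_volume_unassigned(self):
        asn = assign_regions(PointCloud([[50.0, 50.0, 50.0]]), uniform_labels(1))
        assert not asn[0].assigned
        assert asn[0].region_label is None

    def test_agreement_with_scene_ground_truth(self):
        scene = generate_registration_scene(
            300, 40, warp=WarpSpec(), jitter=0.0, vimentin_fraction=0.5, seed=23
        )
        asn = assign_regions(PointCloud(scene.sensor_target), scene.labels)
        got = np.array([a.region_label == "vimentin_positive" for a in asn])
        assert np.mean(got == (scene.sensor_labels == 1)) >= 0.95


class TestRegionStats:
    def test_arithmetic(self):
        asn = [
            RegionAssignment(i, np.zeros(3), lab, 0.0, True)
            for i, lab in enumerate(
                ["vimentin_positive"] * 2 + ["vimentin_negative"] * 2
            )
        ]
        df = region_stats(asn, [2.0, 4.0, 6.0, 8.0])
        assert df.loc["vimentin_positive", "mean_kPa"] == pytest.approx(3.0)
        assert df.loc["vimentin_negative", "mean_kPa"] == pytest.approx(7.0)
        assert df.attrs["mean_difference_kPa"] == pytest.approx(4.0)

    def test_empty_group_reported_with_zero_n(self):
        asn = [RegionAssignment(0, np.zeros(3), "vimentin_positive", 0.0, True)]
        df = region_stats(asn, [5.0])
        assert df.loc["vimentin_negative", "n"] == 0
        assert np.isnan(df.loc["vimentin_negative", "mean_kPa"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            region_stats([], [1.0])
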