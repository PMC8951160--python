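import numpy as np
import pytest

import ctcloud as cc
from ctcloud.morphometrics import (
    MorphReport,
    RigidTransform,
    bounding_dimensions,
    change_table,
    icp_align,
    nearest_distances,
    percent_change,
    voxel_volume,
)

# Published scan-year measurements used as worked examples (µm / µm³).
LENGTHS = {"2009": 155606, "2013": 160958, "2015": 152709, "2017": 151768, "2018": 150435, "2019": 149171}
WIDTHS = {"2009": 50014, "2013": 52274, "2015": 50594, "2017": 50348, "2018": 48359, "2019": 50705}
THICKNESSES = {"2009": 25579, "2013": 28810, "2015": 23856, "2017": 23585, "2018": 22689, "2019": 23793}
VOLUMES = {"2009": 70653.6, "2013": 80404.1, "2015": 66382.8, "2017": 65238.9, "2018": 63871.9, "2019": 63289.4}


def reports():
    return [
        MorphReport(length=LENGTHS[y], width=WIDTHS[y], thickness=THICKNESSES[y], volume=VOLUMES[y], label=y)
        for y in LENGTHS
    ]


class TestPercentChange:
    def test_length_2013_vs_2009(self):
        assert percent_change(155606, 160958) == 3.44

    def test_volume_2013_vs_2009(self):
        assert percent_change(70653.6, 80404.1) == 13.80

    def test_identity(self):
        assert percent_change(123.4, 123.4) == 0.0

    def test_index_relation(self):
        pct = percent_change(155606, 160958)
        assert 100 + pct == pytest.approx(103.44)

    def test_nonpositive_reference(self):
        with pytest.raises(ValueError):
            percent_change(0, 5)


class TestChangeTable:
    def test_base_2009_lengths(self):
        table = change_table(reports(), base="2009")
        rows = table.rows[table.rows["quantity"] == "length"].set_index("label")
        for year, expected in [("2013", 3.44), ("2015", -1.86), ("2017", -2.47), ("2018", -3.32)]:
            assert rows.loc[year, "percent"] == expected

    def test_base_2013_thickness_2018(self):
        table = change_table(reports(), base="2013")
        rows = table.rows[table.rows["quantity"] == "thickness"].set_index("label")
        assert rows.loc["2018", "percent"] == -21.25

    def test_base_row_is_index_100(self):
        table = change_table(reports(), base="2013")
        base_rows = table.rows[table.rows["label"] == "2013"]
        assert (base_rows["index"] == 100).all()
        assert (base_rows["percent"] == 0).all()

    def test_unknown_base(self):
        with pytest.raises(ValueError, match="unknown base"):
            change_table(reports(), base="1999")

    def test_self_comparison_all_zero(self):
        import dataclasses

        rep = reports()[0]
        copy = dataclasses.replace(rep, label="copy")
        table = change_table([rep, copy], base=rep.label)
        sub = table.rows[table.rows["label"] == "copy"]
        assert (sub["percent"] == 0).all()


class TestBoundingDimensions:
    CUBE = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float)

    def test_unit_cube(self):
        assert bounding_dimensions(self.CUBE, "pca") == pytest.approx((1, 1, 1), abs=1e-9)
        assert bounding_dimensions(self.CUBE, "axis") == pytest.approx((1, 1, 1), abs=1e-9)

    def test_rotated_cube(self):
        theta = np.deg2rad(45)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rotated = self.CUBE @ rot.T
        assert bounding_dimensions(rotated, "pca") == pytest.approx((1, 1, 1), abs=1e-6)
        assert bounding_dimensions(rotated, "axis") == pytest.approx((np.sqrt(2), np.sqrt(2), 1), abs=1e-9)

    def test_phantom_major_axis(self, small_spec, small_phantom):
        from conftest import mask_points

        _, truth = small_phantom
        pts = mask_points(truth.body_mask, small_spec.spacing)
        length = bounding_dimensions(pts, "pca")[0]
        tol = 2 * max(small_spec.spacing.dx, small_spec.spacing.dy, small_spec.spacing.dz)
        assert abs(length - truth.major_axis_length) <= tol

    def test_degenerate_falls_back(self):
        plane = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="degenerate"):
            dims = bounding_dimensions(plane, "pca")
        assert dims == pytest.approx((1, 1, 0), abs=1e-12)


class TestVoxelVolume:
    def test_eight_unit_voxels(self):
        assert voxel_volume(8, cc.VoxelSpacing(1, 1, 1)) == 8

    def test_zero(self):
        assert voxel_volume(0, cc.VoxelSpacing(2, 3, 4)) == 0

    def test_linearity(self):
        sp = cc.VoxelSpacing(1.5, 2.0, 3.0)
        assert voxel_volume(10, sp) == pytest.approx(10 * voxel_volume(1, sp))
        sp2 = cc.VoxelSpacing(3.0, 2.0, 3.0)
        assert voxel_volume(10, sp2) == pytest.approx(2 * voxel_volume(10, sp))

    def test_negative_count(self):
        with pytest.raises(ValueError):
            voxel_volume(-1, cc.VoxelSpacing(1, 1, 1))


def cloud_of(points):
    return cc.LabeledPointCloud(np.asarray(points, dtype=float), np.zeros(len(points)))


class TestNearestDistances:
    def test_self_zero(self):
        rng = np.random.default_rng(4)
        cloud = cloud_of(rng.uniform(0, 10, (100, 3)))
        field = nearest_distances(cloud, cloud)
        assert field.max == 0.0

    def test_translated_plane_bounds(self):
        xs, ys = np.meshgrid(np.arange(0, 50, 1.0), np.arange(0, 50, 1.0))
        plane = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
        ref = cloud_of(plane + np.array([5.0, 0.0, 0.0]))
        field = nearest_distances(cloud_of(plane), ref)
        assert field.max <= 5.0 + 1e-9
        assert field.max >= 5.0 - 1.0  # grid pitch

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        a = cloud_of(rng.uniform(0, 100, (200, 3)))
        b = cloud_of(rng.uniform(0, 100, (200, 3)))
        field = nearest_distances(a, b)
        brute = np.sqrt(((a.points[:, None, :] - b.points[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        np.testing.assert_allclose(field.distances, brute, atol=1e-9)

    def test_zero_iff_subset(self):
        rng = np.random.default_rng(13)
        ref = cloud_of(rng.uniform(0, 10, (50, 3)))
        subset = cc.LabeledPointCloud(ref.points[:20], np.zeros(20))
        assert nearest_distances(subset, ref).max == 0.0
        outside = cloud_of(ref.points[:20] + 0.5)
        assert nearest_distances(outside, ref).max > 0.0

    def test_empty_reference(self):
        cloud = cloud_of([[0, 0, 0]])
        with pytest.raises(ValueError, match="empty reference"):
            nearest_distances(cloud, cc.LabeledPointCloud(np.empty((0, 3)), np.empty(0)))


def rot_z(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


class TestICP:
    def test_identity_on_same_cloud(self):
        rng = np.random.default_rng(5)
        cloud = cloud_of(rng.uniform(0, 100, (300, 3)))
        result = icp_align(cloud, cloud)
        assert result.rms == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(result.transform.rotation, np.eye(3), atol=1e-9)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 1000, (500, 3)) * np.array([3.0, 1.5, 1.0])
        centre = pts.mean(axis=0)
        fixed_pts = (pts - centre) @ rot_z(5.0).T + centre + np.array([10.0, 5.0, 0.0])
        result = icp_align(cloud_of(pts), cloud_of(fixed_pts))
        assert abs(result.transform.angle_deg - 5.0) < 0.1
        expected_t = centre - rot_z(5.0) @ centre + np.array([10.0, 5.0, 0.0])
        assert np.linalg.norm(result.transform.translation - expected_t) < 0.5

    def test_noise_floor(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1000, (800, 3))
        sigma = 1.0
        jittered = pts + rng.normal(0, sigma, pts.shape)
        result = icp_align(cloud_of(pts), cloud_of(jittered))
        # expected rms approximately sqrt(3)*sigma; accept within 50%
        expected = np.sqrt(3) * sigma
        assert 0.5 * expected < result.rms < 1.5 * expected

    def test_rms_non_increasing(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, (200, 3))
        moved = (pts @ rot_z(20.0).T) + np.array([4.0, -2.0, 1.0])
        result = icp_align(cloud_of(pts), cloud_of(moved), max_iter=30)
        assert all(b <= a + 1e-12 for a, b in zip(result.rms_history, result.rms_history[1:]))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            icp_align(cloud_of([[0, 0, 0]]), cloud_of([[1, 1, 1], [2, 2, 2], [3, 3, 3]]))


class TestRigidTransform:
    def test_det_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_apply(self):
        t = RigidTransform(rot_z(90.0), np.array([1.0, 0.0, 0.0]))
        out = t.apply(np.array([[1.0, 0.0, 0.0]]))
        np.testing.assert_allclose(out, [[1.0, 1.0, 0.0]], atol=1e-12)
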