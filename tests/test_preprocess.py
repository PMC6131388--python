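import dataclasses

import numpy as np
import pytest

from archtrough import (
    PhantomSpec,
    PipelineConfig,
    Volume3D,
    dice,
    generate_phantom,
    normalize_intensity,
    project,
    remove_cervical_vertebrae,
    remove_condyle_caps,
    remove_superior_halfplane,
    reorient_to_frankfort,
)
from archtrough.preprocess import frankfort_point_map
from archtrough.segmentation import DegenerateHistogramError, EmptyMaskWarning


def cube(n=20, spacing=1.0, value=0.0):
    return Volume3D(np.full((n, n, n), value), (spacing,) * 3)


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        data = np.zeros((2, 2, 2))
        data.flat[:3] = [-1000.0, 3000.0, 1000.0]
        out = normalize_intensity(Volume3D(data, (1, 1, 1)))
        assert out.data.flat[0] == 0.0
        assert out.data.flat[1] == 1.0
        assert out.data.flat[2] == pytest.approx(0.5)
        assert out.data.min() == 0.0 and out.data.max() == 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        vol = Volume3D(rng.normal(0, 100, (8, 8, 8)), (1, 1, 1))
        once = normalize_intensity(vol)
        twice = normalize_intensity(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            normalize_intensity(cube(value=7.0))


class TestReorient:
    def test_level_points_are_identity(self):
        rng = np.random.default_rng(1)
        vol = Volume3D(rng.random((10, 10, 10)), (1, 1, 1))
        out = reorient_to_frankfort(vol, (0.0, 8.0, 5.0), (0.0, 2.0, 5.0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_ten_degree_line_becomes_level(self):
        """Transforming the two picked points with the applied rotation must
        level them to well under a voxel."""
        orbit = np.array([0.0, 30.0, 20.0])
        run = 40.0
        meatus = orbit - np.array([0.0, run, run * np.tan(np.radians(10.0))])
        fmap = frankfort_point_map(orbit, meatus)
        dz = fmap(orbit)[2] - fmap(meatus)[2]
        assert abs(dz) < 1e-9

    def test_bright_voxels_level_after_resampling(self):
        vol = Volume3D(np.zeros((40, 60, 60)), (1.0, 1.0, 1.0))
        orbit_idx = (20, 45, 38)
        meatus_idx = (20, 15, 33)  # ~9.5 degree inclination
        vol.data[orbit_idx] = 1.0
        vol.data[meatus_idx] = 1.0
        out = reorient_to_frankfort(vol, (45.0, 38.0), (15.0, 33.0))
        ys, zs = [], []
        for ref in (orbit_idx, meatus_idx):
            region = out.data[:, ref[1] - 6:ref[1] + 7, :]
            k = np.unravel_index(np.argmax(region), region.shape)
            zs.append(k[2])
        assert abs(zs[0] - zs[1]) <= 1  # within one voxel

    def test_pivot_keeps_value(self):
        rng = np.random.default_rng(2)
        vol = Volume3D(rng.random((12, 21, 21)), (1.0, 1.0, 1.0))
        # pivot = midpoint of the two points = voxel (any, 10, 10)
        out = reorient_to_frankfort(vol, (6.0, 14.0), (14.0, 6.0))
        np.testing.assert_allclose(out.data[:, 10, 10], vol.data[:, 10, 10], atol=1e-7)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            reorient_to_frankfort(cube(), (1.0, 2.0), (1.0, 2.0))


class TestProject:
    def test_mean_of_constant(self):
        img = project(cube(value=3.5), "X", "mean")
        assert np.all(img.data == 3.5)
        assert img.axes == ("Y", "Z")

    def test_single_bright_voxel_max(self):
        vol = cube()
        vol.data[4, 7, 9] = 2.0
        img = project(vol, "Z", "max")
        assert img.data[4, 7] == 2.0
        assert np.count_nonzero(img.data) == 1

    @pytest.mark.parametrize("axis,expected", [("X", (7, 9)), ("Y", (5, 9)), ("Z", (5, 7))])
    def test_brick_projections(self, axis, expected):
        vol = Volume3D(np.zeros((12, 14, 16)), (1, 1, 1))
        vol.data[:5, :7, :9] = 1.0
        img = project(vol, axis, "max")
        assert tuple(np.array(np.nonzero(img.data)).max(axis=1) + 1) == expected


class TestHalfplane:
    def test_horizontal_line_count(self):
        vol = cube(20, value=1.0)
        out = remove_superior_halfplane(vol, "X", (0.0, 9.0), (5.0, 9.0))
        # z coords 0..19; strictly above 9 -> 10 slices zeroed
        assert (out.data == 0).sum() == 20 * 20 * 10

    def test_diagonal_line_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        vol = Volume3D(rng.random((20, 20, 20)) + 0.5, (1, 1, 1))
        p1, p2 = (2.0, 3.0), (17.0, 18.0)  # 45-degree line in (y, z)
        out = remove_superior_halfplane(vol, "X", p1, p2)
        kept = np.zeros_like(vol.data, bool)
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    z_line = 3.0 + (j - 2.0)
                    kept[i, j, k] = not (k > z_line)
        np.testing.assert_array_equal(out.data != 0, kept)

    def test_line_above_volume_is_noop(self):
        vol = cube(10, value=2.0)
        out = remove_superior_halfplane(vol, "Y", (0.0, 50.0), (9.0, 50.0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_vertical_line_rejected(self):
        with pytest.raises(ValueError, match="vertical"):
            remove_superior_halfplane(cube(), "X", (3.0, 1.0), (3.0, 8.0))

    def test_removals_commute(self):
        rng = np.random.default_rng(4)
        vol = Volume3D(rng.random((15, 15, 15)), (1, 1, 1))
        a = remove_superior_halfplane(
            remove_superior_halfplane(vol, "X", (1.0, 10.0), (13.0, 4.0)),
            "Y", (2.0, 3.0), (12.0, 12.0))
        b = remove_superior_halfplane(
            remove_superior_halfplane(vol, "Y", (2.0, 3.0), (12.0, 12.0)),
            "X", (1.0, 10.0), (13.0, 4.0))
        np.testing.assert_array_equal(a.data, b.data)

    def test_output_never_exceeds_input(self):
        rng = np.random.default_rng(5)
        vol = Volume3D(rng.random((10, 10, 10)), (1, 1, 1))
        out = remove_superior_halfplane(vol, "Y", (0.0, 4.0), (9.0, 6.0))
        assert np.all(out.data <= vol.data)


class TestVertebraRemoval:
    def test_confounder_phantom_cleaned(self):
        spec = PhantomSpec(include_vertebra=True)
        vol, truth = generate_phantom(spec)
        occl = spec.occlusal_z_mm
        out = remove_cervical_vertebrae(vol, occl)
        mid = (spec.soft_tissue_intensity + spec.bone_intensity) / 2
        assert dice(out.data > mid, truth.mask.data) >= 0.99

    def test_no_confounder_unchanged(self, clean_phantom):
        vol, _ = clean_phantom
        out = remove_cervical_vertebrae(vol, 0.0)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_empty_band_raises(self, clean_phantom):
        vol, _ = clean_phantom
        with pytest.raises(ValueError):
            remove_cervical_vertebrae(vol, -1000.0)

    def test_no_foreground_warns_and_passes_through(self):
        vol = cube(16, value=0.0)
        vol.data += np.linspace(0, 1e-12, 16)[None, None, :]  # non-constant
        with pytest.warns(EmptyMaskWarning):
            out = remove_cervical_vertebrae(vol, 10.0)
        np.testing.assert_array_equal(out.data, vol.data)


class TestCondyleCaps:
    def test_removed_count_matches_ellipse_area(self):
        vol = Volume3D(np.ones((30, 80, 100)), (1.0, 0.5, 0.5))
        cfg = PipelineConfig()
        out, stop_z = remove_condyle_caps(vol, (20.0, 25.0), (20.0, 25.0), cfg)
        removed = (out.data == 0).sum()
        expected = np.pi * 7.5 * 10.5 / (0.5 * 0.5) * 30
        assert abs(removed - expected) / expected < 0.03

    def test_coincident_points_same_as_one(self):
        rng = np.random.default_rng(6)
        vol = Volume3D(rng.random((10, 40, 40)), (1, 1, 1))
        a, _ = remove_condyle_caps(vol, (20.0, 20.0), (20.0, 20.0))
        b, _ = remove_condyle_caps(vol, (20.0, 20.0), (20.0, 20.001))
        assert np.isclose((a.data == 0).sum(), (b.data == 0).sum(), rtol=0.05)

    def test_stop_z_is_inferior_ellipse_edge(self):
        vol = Volume3D(np.ones((10, 40, 40)), (1, 1, 1))
        _, stop_z = remove_condyle_caps(vol, (20.0, 25.0), (18.0, 30.0))
        assert stop_z == pytest.approx(25.0 - 10.5)

    def test_point_outside_volume_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            remove_condyle_caps(cube(10), (200.0, 5.0), (5.0, 5.0))


def test_phantom_preprocess_chain_only_removes(noisy_phantom):
    """Every removal op only zeroes voxels: output <= input voxel-wise."""
    vol, truth = noisy_phantom
    lm = truth.landmarks
    v0 = normalize_intensity(vol)
    v1 = remove_superior_halfplane(v0, "Y", lm["coronal_right"], lm["coronal_left"])
    v2 = remove_superior_halfplane(v1, "X", lm["occlusal_anterior"], lm["occlusal_posterior"])
    v3 = remove_cervical_vertebrae(v2, 0.0)
    v4, _ = remove_condyle_caps(v3, lm["condyle_a"], lm["condyle_b"])
    for a, b in ((v1, v0), (v2, v1), (v3, v2), (v4, v3)):
        assert np.all(a.data <= b.data + 1e-12)
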