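"""Nuclear segmentation, circularity and volumetry."""

import numpy as np
import pytest
from scipy import ndimage, special
from skimage.draw import disk, ellipse

from nucleomech.core_io import Image2D, VoxelGrid
from nucleomech.morphometry import (
    SegmentationParams,
    circularity,
    filter_objects,
    measure_nuclei_stack,
    measure_volumes,
    nuclear_stats,
    segment_nuclei_2d,
    segment_nuclei_3d,
)
from nucleomech.synthetic import _paint_ellipsoid

VS = (0.25, 0.1, 0.1)


def _sphere_stack(radii_centers, shape, amplitude=1000.0):
    canvas = np.zeros(shape)
    for r, c in radii_centers:
        _paint_ellipsoid(canvas, np.asarray(c, float), np.array([r, r, r]),
                         np.eye(3), VS, amplitude)
    return VoxelGrid(canvas, VS)


class TestSegment2D:
    def test_two_discs_two_labels(self):
        img = np.zeros((100, 100))
        rr, cc = disk((30, 30), 12)
        img[rr, cc] = 500.0
        rr, cc = disk((70, 70), 10)
        img[rr, cc] = 500.0
        labels = segment_nuclei_2d(Image2D(img, 0.2), SegmentationParams(min_volume=1.0))
        assert labels.n_objects == 2

    def test_blank_image_no_labels(self):
        with pytest.warns(UserWarning):
            labels = segment_nuclei_2d(Image2D(np.zeros((64, 64))))
        assert labels.n_objects == 0

    def test_disc_grid_centroids(self, rng):
        img = np.zeros((300, 300))
        truth = []
        for gy in range(4):
            for gx in range(5):
                cy, cx = 40 + gy * 70, 30 + gx * 60
                rr, cc = disk((cy, cx), 11)
                img[rr, cc] = 800.0
                truth.append((cy, cx))
        noisy = np.clip(img + rng.normal(0, 20, img.shape), 0, None)
        labels = segment_nuclei_2d(Image2D(noisy, 0.2),
                                   SegmentationParams(min_volume=1.0, surface_smoothing=0.4))
        assert labels.n_objects == 20
        found = ndimage.center_of_mass(labels.labels > 0, labels.labels,
                                       range(1, 21))
        for fc in found:
            assert min(np.hypot(fc[0] - t[0], fc[1] - t[1]) for t in truth) < 1.0


class TestCircularity:
    def test_disc_is_most_circular(self):
        m = np.zeros((120, 120), bool)
        rr, cc = disk((60, 60), 50)
        m[rr, cc] = True
        assert circularity(m) == pytest.approx(1.0, abs=0.02)

    def test_square_matches_crofton_expectation(self):
        # the 4-direction Crofton estimator averages widths over 4 angles;
        # for an axis-aligned square that quadrature gives perimeter
        # pi*(2+sqrt(2))/4 * s = 0.948 * 4s, hence circularity ~0.874
        # rather than the continuum pi/4
        sq = np.zeros((80, 80), bool)
        sq[15:65, 15:65] = True
        # average width over {0,45,90,135} deg = s(1+sqrt(2))/2, so the
        # estimated perimeter is pi*(1+sqrt(2))/2*s ~ 0.948*4s
        expected = 4 * np.pi / (np.pi * (1 + np.sqrt(2)) / 2) ** 2
        assert circularity(sq) == pytest.approx(expected, abs=0.02)

    def test_two_to_one_ellipse(self):
        m = np.zeros((140, 220), bool)
        rr, cc = ellipse(70, 110, 50, 100)
        m[rr, cc] = True
        circumference = 4 * 100 * special.ellipe(0.75)
        expected = 4 * np.pi * (np.pi * 100 * 50) / circumference**2  # ~0.84
        assert circularity(m) == pytest.approx(expected, abs=0.02)

    def test_scale_invariance(self):
        m = np.zeros((70, 110), bool)
        rr, cc = ellipse(35, 55, 25, 50)
        m[rr, cc] = True
        up = np.zeros((140, 220), bool)  # same shape rasterized at 2x
        rr, cc = ellipse(70, 110, 50, 100)
        up[rr, cc] = True
        assert abs(circularity(m) - circularity(up, 0.5)) < 0.02

    def test_shape_ordering(self):
        md = np.zeros((130, 130), bool)
        rr, cc = disk((65, 65), 55)
        md[rr, cc] = True
        sq = np.zeros((110, 110), bool)
        sq[15:95, 15:95] = True
        el = np.zeros((90, 220), bool)
        rr, cc = ellipse(45, 110, 33, 99)
        el[rr, cc] = True
        assert circularity(md) > circularity(sq) > circularity(el)

    def test_tiny_component_rejected(self):
        m = np.zeros((10, 10), bool)
        m[4:6, 4:6] = True
        with pytest.raises(ValueError, match="9 px"):
            circularity(m)

    def test_multi_component_rejected(self):
        m = np.zeros((20, 20), bool)
        m[2:6, 2:6] = True
        m[12:16, 12:16] = True
        with pytest.raises(ValueError, match="connected"):
            circularity(m)


class TestSegment3D:
    def test_single_ellipsoid_one_label(self):
        canvas = np.zeros((60, 120, 120))
        _paint_ellipsoid(canvas, np.array([7.5, 6.0, 6.0]),
                         np.array([3.0, 4.0, 3.5]), np.eye(3), VS, 1000.0)
        labels = segment_nuclei_3d(VoxelGrid(canvas, VS))
        assert labels.n_objects == 1

    def test_touching_spheres_split(self):
        grid = _sphere_stack([(3.0, (7.5, 7.0, 4.5)), (3.0, (7.5, 7.0, 9.5))],
                             (60, 140, 140))
        labels = segment_nuclei_3d(
            grid, SegmentationParams(threshold_mode=500.0, seed_point_diameter=4.0))
        assert labels.n_objects == 2

    def test_voxel_conservation_under_split(self):
        grid = _sphere_stack([(3.0, (7.5, 7.0, 4.5)), (3.0, (7.5, 7.0, 9.5))],
                             (60, 140, 140))
        params = SegmentationParams(threshold_mode=500.0, seed_point_diameter=4.0)
        labels = segment_nuclei_3d(grid, params)
        fg = (ndimage.gaussian_filter(
            grid.voxels, tuple(params.surface_smoothing / s for s in VS)) > 500.0)
        fg = ndimage.binary_fill_holes(fg)
        assert (labels.labels > 0).sum() == fg.sum()

    def test_unresolved_merge_flagged(self):
        grid = _sphere_stack([(3.0, (7.5, 7.0, 5.25)), (3.0, (7.5, 7.0, 8.75))],
                             (60, 140, 140))
        labels = segment_nuclei_3d(
            grid, SegmentationParams(threshold_mode=500.0, seed_point_diameter=6.0))
        flags = filter_objects(labels)
        assert labels.n_objects == 1
        assert "unresolved_merge" in flags[1]

    def test_border_touching_flagged_interior_clean(self):
        canvas = np.zeros((40, 100, 100))
        _paint_ellipsoid(canvas, np.array([5.0, 5.0, 0.5]),  # clipped at x=0
                         np.array([3.0, 3.0, 3.0]), np.eye(3), VS, 1000.0)
        _paint_ellipsoid(canvas, np.array([5.0, 6.0, 6.5]),
                         np.array([2.5, 2.5, 2.5]), np.eye(3), VS, 1000.0)
        labels = segment_nuclei_3d(VoxelGrid(canvas, VS),
                                   SegmentationParams(threshold_mode=500.0))
        flags = filter_objects(labels)
        flagsets = sorted(flags.values(), key=len)
        assert flagsets[0] == frozenset()
        assert "border_touching" in flagsets[1]


class TestVolumes:
    def test_digitized_sphere_closed_form(self):
        r = 3.68
        grid = _sphere_stack([(r, (7.5, 6.0, 6.0))], (60, 120, 120))
        labels = segment_nuclei_3d(grid, SegmentationParams(threshold_mode=500.0))
        vol = measure_volumes(labels)[0].volume
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)

    def test_ellipsoid_closed_form(self):
        canvas = np.zeros((60, 120, 120))
        _paint_ellipsoid(canvas, np.array([7.5, 6.0, 6.0]),
                         np.array([3.1, 4.0, 4.0]), np.eye(3), VS, 1000.0)
        labels = segment_nuclei_3d(VoxelGrid(canvas, VS),
                                   SegmentationParams(threshold_mode=500.0))
        vol = measure_volumes(labels)[0].volume
        assert vol == pytest.approx(4 / 3 * np.pi * 4.0 * 4.0 * 3.1, rel=0.05)

    def test_error_shrinks_with_radius(self):
        errs = []
        for r in (2.0, 3.0, 4.0, 6.0):
            pad = r + 1.5
            shape = (int(2 * pad / 0.25) + 4, int(2 * pad / 0.1) + 4, int(2 * pad / 0.1) + 4)
            grid = _sphere_stack([(r, (pad, pad, pad))], shape)
            labels = segment_nuclei_3d(grid, SegmentationParams(threshold_mode=500.0))
            vol = measure_volumes(labels)[0].volume
            errs.append(abs(vol - 4 / 3 * np.pi * r**3) / (4 / 3 * np.pi * r**3))
        assert all(e < 0.05 for e in errs)
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_empty_map(self):
        from nucleomech.morphometry import LabelMap

        assert measure_volumes(LabelMap(np.zeros((4, 8, 8), dtype=np.int32), VS)) == []


class TestStats:
    def _meas(self, volumes):
        from nucleomech.morphometry import NucleusMeasurement

        return [NucleusMeasurement(label=i + 1, volume=v) for i, v in enumerate(volumes)]

    def test_mean_and_sd(self):
        s = nuclear_stats(self._meas([200.0, 210.0, 220.0]))
        assert s["mean"] == pytest.approx(210.0)
        assert s["sd"] == pytest.approx(10.0)
        assert s["n"] == 3

    def test_identical_groups_null(self):
        a = self._meas([200.0, 210.0, 220.0, 230.0])
        s = nuclear_stats(a, other=self._meas([200.0, 210.0, 220.0, 230.0]))
        assert s["comparison"]["p"] == pytest.approx(1.0)

    def test_flagged_objects_excluded(self):
        from nucleomech.morphometry import NucleusMeasurement

        ms = self._meas([100.0, 120.0]) + [
            NucleusMeasurement(label=3, volume=9000.0, flags=frozenset({"border_touching"}))
        ]
        assert nuclear_stats(ms)["n"] == 2

    def test_too_few_objects(self):
        with pytest.raises(ValueError, match="at least 2"):
            nuclear_stats(self._meas([100.0]))


def test_measure_nuclei_stack_end_to_end():
    grid = _sphere_stack([(3.0, (7.5, 4.0, 4.0)), (2.5, (7.5, 10.0, 10.0))],
                         (60, 140, 140))
    ms = measure_nuclei_stack(grid, SegmentationParams(threshold_mode=500.0))
    assert len(ms) == 2
    vols = sorted(m.volume for m in ms)
    assert vols[0] == pytest.approx(4 / 3 * np.pi * 2.5**3, rel=0.05)
    assert vols[1] == pytest.approx(4 / 3 * np.pi * 3.0**3, rel=0.05)
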