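"""Polygon-stack tracing, rasterization and volume measurement."""

import numpy as np
import pytest
from scipy import ndimage

from repli3d import VoxelGrid, build_mask, trace_polygons, volume
from repli3d.segmentation import (
    NuclearMask,
    PolygonStack,
    load_polygons_csv,
    save_polygons_csv,
)

VS = (0.2, 0.07, 0.07)


def square(y0, x0, side):
    return np.array([(y0, x0), (y0, x0 + side), (y0 + side, x0 + side), (y0 + side, x0)], float)


def circle(cy, cx, r, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([cy + r * np.sin(t), cx + r * np.cos(t)], axis=1)


def synthetic_ellipsoid(shape=(40, 60, 60), vs=VS, semi=(3.0, 1.6, 1.6), value=1000.0):
    nz, ny, nx = shape
    z = (np.arange(nz) + 0.5) * vs[0] - nz * vs[0] / 2
    y = (np.arange(ny) + 0.5) * vs[1] - ny * vs[1] / 2
    x = (np.arange(nx) + 0.5) * vs[2] - nx * vs[2] / 2
    q = (
        (z / semi[0])[:, None, None] ** 2
        + (y / semi[1])[None, :, None] ** 2
        + (x / semi[2])[None, None, :] ** 2
    )
    return VoxelGrid(np.where(q <= 1.0, value, 0.0), vs), semi


class TestPolygonStack:
    def test_requires_contiguous_planes(self):
        with pytest.raises(ValueError, match="contiguous"):
            PolygonStack(entries=[(2, square(0, 0, 9)), (3, square(0, 0, 9)), (5, square(0, 0, 9))])

    def test_requires_three_vertices(self):
        with pytest.raises(ValueError, match="n>=3"):
            PolygonStack(entries=[(0, np.array([(0.0, 0.0), (1.0, 1.0)]))])

    def test_rejects_self_intersecting_polygon(self):
        bowtie = np.array([(0, 0), (2, 2), (0, 2), (2, 0)], float)
        with pytest.raises(ValueError, match="self-intersecting"):
            PolygonStack(entries=[(0, bowtie)])

    def test_csv_roundtrip(self, tmp_path):
        stack = PolygonStack(entries=[(3, square(1, 2, 8)), (4, circle(5, 5, 3))])
        path = save_polygons_csv(stack, tmp_path / "polys.csv")
        back = load_polygons_csv(path)
        assert [z for z, _ in back.entries] == [3, 4]
        np.testing.assert_allclose(back.entries[0][1], stack.entries[0][1])


class TestBuildMask:
    def test_square_prism_counts_exactly(self):
        # a 10x10-voxel square on 5 planes rasterizes to 500 voxels
        # (vertices on voxel centers; boundary centers count as inside)
        stack = PolygonStack(entries=[(z, square(3, 3, 9)) for z in range(2, 7)])
        mask = build_mask(stack, (10, 20, 20), VS)
        assert mask.n_voxels == 500

    def test_sphere_volume_within_3_percent(self):
        r = 20.0
        entries = []
        for z in range(-19, 20):
            rz = np.sqrt(r**2 - z**2)
            if rz < 1:
                continue
            entries.append((z + 25, circle(24.5, 24.5, rz, n=128)))
        stack = PolygonStack(entries=entries)
        mask = build_mask(stack, (50, 50, 50), (1.0, 1.0, 1.0))
        analytic = 4.0 / 3.0 * np.pi * r**3
        assert abs(mask.n_voxels - analytic) / analytic < 0.03

    def test_out_of_bounds_vertices_rejected(self):
        stack = PolygonStack(entries=[(0, square(3, 3, 9))])
        with pytest.raises(ValueError, match="outside the grid"):
            build_mask(stack, (2, 8, 8), VS)

    def test_mask_must_be_single_component(self):
        # NuclearMask itself enforces 26-connectivity
        m = np.zeros((3, 5, 5), bool)
        m[0, 0, 0] = True
        m[2, 4, 4] = True
        with pytest.raises(ValueError, match="single 26-connected"):
            NuclearMask(mask=m, voxel_size=VS)


class TestVolume:
    def test_thousand_voxels(self):
        stack = PolygonStack(entries=[(z, square(0, 0, 9)) for z in range(10)])
        mask = build_mask(stack, (10, 12, 12), VS)
        assert mask.n_voxels == 1000
        assert volume(mask) == pytest.approx(1000 * 0.2 * 0.07 * 0.07)

    def test_single_voxel_volume(self):
        m = np.zeros((1, 1, 1), bool)
        m[0, 0, 0] = True
        assert volume(NuclearMask(mask=m, voxel_size=VS)) == pytest.approx(0.2 * 0.07 * 0.07)

    def test_translation_invariance_and_dilation_monotonicity(self):
        base = PolygonStack(entries=[(z, square(2, 2, 7)) for z in range(1, 5)])
        shifted = PolygonStack(entries=[(z, square(5, 6, 7)) for z in range(2, 6)])
        shape = (10, 20, 20)
        v1 = volume(build_mask(base, shape, VS))
        v2 = volume(build_mask(shifted, shape, VS))
        assert v1 == pytest.approx(v2)
        m = build_mask(base, shape, VS)
        dilated = NuclearMask(ndimage.binary_dilation(m.mask), VS)
        assert volume(dilated) > v1


class TestTracePolygons:
    def test_all_zero_image_rejected(self):
        g = VoxelGrid(np.zeros((6, 10, 10)), VS)
        with pytest.raises(ValueError, match="no foreground"):
            trace_polygons(g)

    def test_ellipsoid_slice_areas_match_analytic(self):
        g, semi = synthetic_ellipsoid()
        stack = trace_polygons(g, smooth_sigma_um=0.1, min_area_um2=0.3)
        vs = g.voxel_size
        nz = g.shape[0]
        pixel_area = vs[1] * vs[2]
        checked = 0
        for idx, (z, _) in enumerate(stack.entries):
            zc = (z + 0.5) * vs[0] - nz * vs[0] / 2
            frac = 1 - (zc / semi[0]) ** 2
            if frac < 0.35:  # polar caps are discretization-dominated
                continue
            analytic = np.pi * semi[1] * semi[2] * frac
            traced = stack.polygon_area(idx) * pixel_area
            assert abs(traced - analytic) / analytic < 0.05
            checked += 1
        assert checked >= 10

    def test_ellipsoid_volume_recovery(self):
        g, semi = synthetic_ellipsoid()
        stack = trace_polygons(g, smooth_sigma_um=0.1, min_area_um2=0.3)
        mask = build_mask(stack, g.shape, g.voxel_size)
        analytic = 4.0 / 3.0 * np.pi * np.prod(semi)
        assert abs(volume(mask) - analytic) / analytic < 0.05

    def test_volume_error_shrinks_with_resolution(self):
        # discretization convergence: doubling resolution reduces error
        errs = []
        for shape, vs in (((20, 30, 30), (0.4, 0.14, 0.14)), ((40, 60, 60), VS)):
            g, semi = synthetic_ellipsoid(shape=shape, vs=vs)
            stack = trace_polygons(g, smooth_sigma_um=0.1, min_area_um2=0.3)
            mask = build_mask(stack, g.shape, g.voxel_size)
            analytic = 4.0 / 3.0 * np.pi * np.prod(semi)
            errs.append(abs(volume(mask) - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_generator_fixture_volume_within_10_percent_of_truth(self):
        # full-resolution fixture: discretization bias at the fast profile
        # is larger by construction
        from repli3d import make_nucleus
        from repli3d.presets import load_default_presets

        img = make_nucleus(load_default_presets("full")["E"], seed=11)
        stack = trace_polygons(img.channels["DAPI"])
        mask = build_mask(stack, img.shape, img.voxel_size)
        truth_voxels = img.truth["nucleus"].sum()
        assert abs(mask.n_voxels - truth_voxels) / truth_voxels < 0.10
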