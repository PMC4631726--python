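"""Raster containers, TIFF round-trips and projection conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repli3d import (
    NucleusImage,
    VoxelGrid,
    average_projection,
    one_micron_window,
    read_stack,
    sequential_projections,
    write_stack,
)


class TestVoxelGrid:
    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError, match="nonnegative"):
            VoxelGrid(-np.ones((2, 2, 2)), (0.2, 0.07, 0.07))

    def test_rejects_nonpositive_voxel_size(self):
        with pytest.raises(ValueError, match="positive"):
            VoxelGrid(np.ones((2, 2, 2)), (0.2, 0.0, 0.07))

    def test_rejects_wrong_rank(self):
        with pytest.raises(ValueError, match="3D"):
            VoxelGrid(np.ones((2, 2)), (0.2, 0.07, 0.07))

    def test_voxel_center_coordinates(self, small_grid):
        # voxel (k, j, i) sits at ((k+0.5)dz, (j+0.5)dy, (i+0.5)dx)
        np.testing.assert_allclose(small_grid.axis_centers_um(0), [0.1, 0.3])
        np.testing.assert_allclose(small_grid.axis_centers_um(2)[0], 0.035)


class TestNucleusImage:
    def test_requires_matching_shapes(self):
        a = VoxelGrid(np.ones((2, 2, 2)), (0.2, 0.07, 0.07))
        b = VoxelGrid(np.ones((2, 2, 3)), (0.2, 0.07, 0.07))
        with pytest.raises(ValueError, match="share shape"):
            NucleusImage(channels={"DAPI": a, "EDU": b})

    def test_rejects_empty_channel_map(self):
        with pytest.raises(ValueError, match="at least one channel"):
            NucleusImage(channels={})

    def test_truth_containment_enforced(self):
        a = VoxelGrid(np.ones((2, 2, 2)), (0.2, 0.07, 0.07))
        nucleus = np.zeros((2, 2, 2), bool)
        nucleus[0, 0, 0] = True
        nucleolus = np.zeros((2, 2, 2), bool)
        nucleolus[1, 1, 1] = True  # outside the nucleus
        with pytest.raises(ValueError, match="outside the nucleus"):
            NucleusImage(channels={"DAPI": a}, truth={"nucleus": nucleus, "nucleolus": nucleolus})


class TestStackIO:
    def test_known_constant_channels_recovered(self, tmp_path):
        # 2-channel 4x4x4 stack of known constants round-trips exactly
        vs = (0.2, 0.07, 0.07)
        img = NucleusImage(
            channels={
                "DAPI": VoxelGrid(np.full((4, 4, 4), 5.0), vs),
                "EDU": VoxelGrid(np.full((4, 4, 4), 7.0), vs),
            },
            meta={"stage": "E"},
        )
        path = write_stack(img, tmp_path / "const.tif")
        back = read_stack(path)
        np.testing.assert_array_equal(back.channels["DAPI"].data, 5.0)
        np.testing.assert_array_equal(back.channels["EDU"].data, 7.0)
        assert back.voxel_size == vs
        assert back.meta["stage"] == "E"

    def test_generator_image_roundtrips_bit_exactly(self, tmp_path, fast_early_nucleus):
        path = write_stack(fast_early_nucleus, tmp_path / "nuc.tif")
        back = read_stack(path)
        for name, grid in fast_early_nucleus.channels.items():
            np.testing.assert_array_equal(back.channels[name].data, grid.data)
        for name, mask in fast_early_nucleus.truth.items():
            np.testing.assert_array_equal(back.truth[name], mask)
        assert back.meta["seed"] == fast_early_nucleus.meta["seed"]

    def test_page_count_divisibility_enforced(self, tmp_path):
        import tifffile

        path = tmp_path / "bad.tif"
        tifffile.imwrite(path, np.zeros((10, 4, 4), np.uint16))
        with pytest.raises(ValueError, match="not divisible"):
            read_stack(path, channels=["A", "B", "C"], voxel_size=(0.2, 0.07, 0.07))

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_stack(tmp_path / "absent.tif")

    def test_nonpositive_voxel_size_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "vs.tif"
        tifffile.imwrite(path, np.zeros((2, 4, 4), np.uint16))
        with pytest.raises(ValueError, match="positive"):
            read_stack(path, channels=["A", "B"], voxel_size=(0.0, 0.07, 0.07))


class TestProjections:
    def test_constant_stack_projects_to_constant(self):
        g = VoxelGrid(np.full((6, 3, 3), 4.0), (0.2, 0.07, 0.07))
        np.testing.assert_array_equal(average_projection(g, 1, 3), 4.0)

    def test_two_plane_hand_mean(self):
        data = np.stack([np.zeros((2, 2)), np.full((2, 2), 2.0)])
        g = VoxelGrid(data, (0.2, 0.07, 0.07))
        np.testing.assert_array_equal(average_projection(g, 0, 2), 1.0)

    def test_out_of_range_window_rejected(self):
        g = VoxelGrid(np.ones((4, 2, 2)), (0.2, 0.07, 0.07))
        with pytest.raises(ValueError, match="out of range"):
            average_projection(g, 2, 3)

    def test_full_range_equals_direct_mean(self, rng):
        data = rng.random((7, 5, 4))
        g = VoxelGrid(data, (0.2, 0.07, 0.07))
        np.testing.assert_allclose(average_projection(g, 0, 7), data.mean(axis=0), rtol=1e-12)

    @pytest.mark.parametrize("dz,expected", [(0.2, 5), (0.25, 4), (0.35, 3), (0.5, 3), (0.1, 5)])
    def test_one_micron_window_plane_counts(self, dz, expected):
        # the 1-um projection convention spans 3-5 planes depending on z step
        g = VoxelGrid(np.ones((10, 2, 2)), (dz, 0.07, 0.07))
        assert one_micron_window(g) == expected

    def test_sequential_even_split(self):
        g = VoxelGrid(np.ones((10, 2, 2)), (0.2, 0.07, 0.07))
        projs = sequential_projections(g)
        assert len(projs) == 5

    def test_sequential_rejects_short_stacks(self):
        g = VoxelGrid(np.ones((4, 2, 2)), (0.2, 0.07, 0.07))
        with pytest.raises(ValueError, match=">=5 planes"):
            sequential_projections(g)

    def test_constant_stack_gives_five_identical_images(self):
        g = VoxelGrid(np.full((13, 2, 2), 3.0), (0.2, 0.07, 0.07))
        for p in sequential_projections(g):
            np.testing.assert_array_equal(p, 3.0)

    @given(nz=st.integers(min_value=5, max_value=60))
    @settings(deadline=None, max_examples=30)
    def test_sequential_partition_property(self, nz):
        # five contiguous runs, sizes differing by <=1, covering each plane once
        data = np.arange(nz, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        g = VoxelGrid(data, (0.2, 0.07, 0.07))
        projs = sequential_projections(g)
        # recover run sizes from the projected plane-index means
        sizes = []
        covered = []
        pos = 0
        for p in projs:
            mean_idx = p[0, 0]
            run = [k for k in range(pos, nz)]
            # find the contiguous run starting at pos whose mean equals mean_idx
            for length in range(1, nz - pos + 1):
                if abs(np.mean(run[:length]) - mean_idx) < 1e-9:
                    sizes.append(length)
                    covered.extend(run[:length])
                    pos += length
                    break
        assert pos == nz and covered == list(range(nz))
        assert max(sizes) - min(sizes) <= 1
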