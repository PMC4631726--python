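"""Generator determinism, ground-truth structure and population plumbing."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from repli3d import (
    PopulationConfig,
    StagePreset,
    derive_seed,
    make_nucleus,
    make_population,
    measure_nucleus,
)
from repli3d.presets import structural_preset
from repli3d.synthetic_nuclei import _fit_ellipsoid_axes


class TestPresetValidation:
    def test_coupling_bounds_enforced(self):
        with pytest.raises(ValueError, match="coupling"):
            dataclasses.replace(structural_preset("E"), coupling=1.3)

    def test_late_presets_cannot_have_puncta(self):
        with pytest.raises(ValueError, match="zero intranucleolar puncta"):
            dataclasses.replace(structural_preset("L"), intranucleolar_puncta_count=2)

    def test_roundtrip_through_dict(self):
        p = structural_preset("M")
        q = StagePreset.from_dict(p.to_dict())
        assert q == p

    def test_scaled_profile_halves_grid(self):
        p = structural_preset("E")
        q = p.scaled(2)
        assert q.grid_shape == tuple(int(np.ceil(s / 2)) for s in p.grid_shape)
        assert q.voxel_size_um == tuple(2 * v for v in p.voxel_size_um)


class TestEllipsoidFit:
    def test_free_fit_preserves_volume(self):
        axes = _fit_ellipsoid_axes(500.0, np.array([10.0, 10.0, 10.0]), np.array([1.25, 1.0, 1.0]))
        assert 4 / 3 * np.pi * np.prod(axes) == pytest.approx(500.0)
        assert axes[0] / axes[1] == pytest.approx(1.25)

    def test_clamped_fit_preserves_volume_within_limits(self):
        limits = np.array([7.0, 5.0, 5.0])
        axes = _fit_ellipsoid_axes(700.0, limits, np.array([1.0, 1.0, 1.0]))
        assert np.all(axes <= limits + 1e-9)
        assert 4 / 3 * np.pi * np.prod(axes) == pytest.approx(700.0)

    def test_impossible_volume_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            _fit_ellipsoid_axes(3000.0, np.array([6.0, 5.0, 5.0]), np.array([1.0, 1.0, 1.0]))


class TestMakeNucleus:
    def test_deterministic_for_fixed_seed(self, fast_early_preset):
        a = make_nucleus(fast_early_preset, 21)
        b = make_nucleus(fast_early_preset, 21)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name].data, b.channels[name].data)

    def test_distinct_seeds_differ(self, fast_early_preset):
        a = make_nucleus(fast_early_preset, 21)
        b = make_nucleus(fast_early_preset, 22)
        assert not np.array_equal(a.channels["DAPI"].data, b.channels["DAPI"].data)

    def test_truth_masks_contained_in_nucleus(self, fast_early_nucleus):
        t = fast_early_nucleus.truth
        assert not np.any(t["nucleolus"] & ~t["nucleus"])
        assert not np.any(t["knobs"] & ~t["nucleus"])
        assert not np.any(t["fibers"] & ~t["nucleus"])
        assert not np.any(t["knobs"] & t["nucleolus"])

    def test_dapi_dark_nucleolus(self, fast_early_nucleus):
        dapi = fast_early_nucleus.channels["DAPI"].data
        t = fast_early_nucleus.truth
        nucleoplasm = t["nucleus"] & ~t["nucleolus"]
        assert dapi[t["nucleolus"]].mean() < 0.5 * dapi[nucleoplasm].mean()

    def test_knob_placement_failure_raises(self):
        p = dataclasses.replace(
            structural_preset("E").scaled(2),
            target_volume_um3=30.0,
            volume_sd_um3=0.0,
            knob_radii_um=(1.5, 1.5),
        )
        with pytest.raises(ValueError, match="knob"):
            make_nucleus(p, 0)

    def test_negative_seed_rejected(self, fast_early_preset):
        with pytest.raises(ValueError, match="seed"):
            make_nucleus(fast_early_preset, -1)

    def test_fish_channel_renders_knob_truth(self, fast_early_preset):
        p = dataclasses.replace(fast_early_preset, render_fish=True)
        img = make_nucleus(p, 5)
        fish = img.channels["KNOB_FISH"].data
        t = img.truth
        assert fish[t["knobs"]].mean() > 5 * fish[t["nucleus"] & ~t["knobs"]].mean()


class TestCouplingMonotonicity:
    def test_population_r_increases_with_coupling(self, fast_early_preset):
        # expected masked Pearson r is monotone nondecreasing in coupling
        means = []
        for c in (0.0, 0.4, 0.8, 1.0):
            p = dataclasses.replace(fast_early_preset, coupling=c, com_displacement_um=0.0)
            rs = [measure_nucleus(make_nucleus(p, s)).pearson_r for s in (1, 2, 3)]
            means.append(np.mean(rs))
        assert all(b > a for a, b in zip(means[:-1], means[1:]))

    def test_zero_displacement_gives_near_zero_offset(self, fast_early_preset):
        p = dataclasses.replace(fast_early_preset, com_displacement_um=0.0)
        offs = [measure_nucleus(make_nucleus(p, s)).com_offset_um for s in (1, 2)]
        assert np.mean(offs) < 0.1

    def test_displacement_recovered_by_measurement(self, fast_early_preset):
        p = dataclasses.replace(fast_early_preset, com_displacement_um=0.4)
        offs = [measure_nucleus(make_nucleus(p, s)).com_offset_um for s in (1, 2)]
        assert 0.25 < np.mean(offs) < 0.5


class TestSeedDerivation:
    def test_stable_across_calls(self):
        assert derive_seed(7, 0, 0) == derive_seed(7, 0, 0)
        assert derive_seed(7, 0, 0) != derive_seed(7, 0, 1)
        assert derive_seed(7, 0, 0) != derive_seed(8, 0, 0)

    def test_below_2_pow_31(self):
        for i in range(50):
            assert 0 <= derive_seed(123, 1, i) < 2**31


class TestMakePopulation:
    def test_counts_and_manifest(self, fast_early_preset, tmp_path):
        mid = dataclasses.replace(fast_early_preset, stage="M", edu_mode="on_fiber")
        cfg = PopulationConfig(
            groups=[(fast_early_preset, 2), (mid, 2)], master_seed=7, output_dir=str(tmp_path)
        )
        paths, manifest = make_population(cfg, write=True)
        assert len(paths) == 4
        assert len(manifest) == 4
        assert (tmp_path / "manifest.csv").exists()
        assert sorted(manifest["stage"].unique()) == ["E", "M"]

    def test_byte_identical_reruns(self, fast_early_preset, tmp_path):
        cfg1 = PopulationConfig(groups=[(fast_early_preset, 2)], master_seed=7, output_dir=str(tmp_path / "a"))
        cfg2 = PopulationConfig(groups=[(fast_early_preset, 2)], master_seed=7, output_dir=str(tmp_path / "b"))
        paths1, _ = make_population(cfg1, write=True)
        paths2, _ = make_population(cfg2, write=True)
        for p1, p2 in zip(paths1, paths2):
            assert p1.read_bytes() == p2.read_bytes()

    def test_group_size_must_be_positive(self, fast_early_preset):
        with pytest.raises(ValueError, match="group sizes"):
            PopulationConfig(groups=[(fast_early_preset, 0)], master_seed=0)

    def test_default_reference_group_sizes(self):
        from repli3d.presets import REFERENCE_GROUPS

        assert [g["n"] for g in REFERENCE_GROUPS.values()] == [44, 61, 36, 45, 44, 52]
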