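"""Shipped substage presets and the default six-group study configuration.

Six presets — early/middle/late S for the mitotic cycle (root zone
0-1 mm, DNA content 2C-4C) and for the endocycle (zone 1-3 mm, 4C-8C) —
are frozen in ``presets/default_presets.yaml``.  Their structural
parameters encode the substage cytology (EdU placement mode, puncta,
knobs); their calibration parameters (``volume_factor``, ``coupling``,
``com_displacement_um``) were fitted once with
:func:`repli3d.synthetic_nuclei.calibrate_preset` against the published
per-group means (volume, Pearson r, COM offset; late-S groups have
published volumes only) and are shipped frozen, so every fresh
generation run reproduces those group statistics through the full
measurement pipeline.

``REFERENCE_GROUPS`` records the published group means, standard
deviations and sizes that the calibration targeted; it is the single
source of truth for group sizes (44, 61, 36, 45, 44, 52) and for the
calibration script.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .synthetic_nuclei import PopulationConfig, StagePreset

__all__ = [
    "REFERENCE_GROUPS",
    "structural_preset",
    "load_default_presets",
    "save_presets",
    "load_presets",
    "default_population_config",
]

#: Published per-group reference statistics (PBS-buffer groups): n,
#: mean (sd) volume in µm³, Pearson r and COM offset in µm.  Late-S
#: groups report volume only.
REFERENCE_GROUPS: dict[str, dict] = {
    "E": {"cycle": "mitotic", "n": 44, "volume": (448.0, 44.0), "r": (0.77, 0.045), "com": (0.27, 0.075)},
    "M": {"cycle": "mitotic", "n": 61, "volume": (605.0, 61.0), "r": (0.88, 0.035), "com": (0.21, 0.010)},
    "L": {"cycle": "mitotic", "n": 36, "volume": (637.0, 83.0), "r": None, "com": None},
    "En-E": {"cycle": "endocycle", "n": 45, "volume": (742.0, 58.0), "r": (0.78, 0.035), "com": (0.50, 0.027)},
    "En-M": {"cycle": "endocycle", "n": 44, "volume": (826.0, 72.0), "r": (0.85, 0.040), "com": (0.46, 0.025)},
    "En-L": {"cycle": "endocycle", "n": 52, "volume": (861.0, 36.0), "r": None, "com": None},
}

_STAGE_MODE = {
    "E": "inter_fiber",
    "M": "on_fiber",
    "L": "heterochromatin",
    "En-E": "inter_fiber",
    "En-M": "on_fiber",
    "En-L": "heterochromatin",
}


def structural_preset(stage: str) -> StagePreset:
    """Uncalibrated preset carrying the substage's structural parameters.

    The starting point for calibration: geometry from the published
    group volume, EdU mode from the substage, no intranucleolar puncta
    in late S, default coupling/displacement of zero.
    """
    ref = REFERENCE_GROUPS[stage]
    mode = _STAGE_MODE[stage]
    vol_mean, vol_sd = ref["volume"]
    late = mode == "heterochromatin"
    # Field of view sized to the group: the largest admissible volume
    # draw (+2 sigma, plus calibration headroom) must fit an ellipsoid
    # inside the field with the segmentation margin.
    import numpy as np

    max_draw = vol_mean * np.exp(2.0 * vol_sd / vol_mean) * 1.10
    grid = (80, 168, 168)
    vs = (0.2, 0.07, 0.07)
    margin = 0.55
    half = np.array([g * v for g, v in zip(grid, vs)]) / 2 - margin
    if max_draw > 4.0 / 3.0 * np.pi * np.prod(half):
        grid = (88, 176, 176)
    return StagePreset(
        stage=stage,
        cycle=ref["cycle"],
        target_volume_um3=vol_mean,
        volume_sd_um3=vol_sd,
        edu_mode=mode,
        grid_shape=grid,
        n_foci=150 if late else 1500,
        intranucleolar_puncta_count=0 if late else 4,
    )


def save_presets(presets: dict[str, StagePreset], path: str | Path) -> Path:
    path = Path(path)
    payload = {name: p.to_dict() for name, p in presets.items()}
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_presets(path: str | Path) -> dict[str, StagePreset]:
    payload = yaml.safe_load(Path(path).read_text())
    return {name: StagePreset.from_dict(d) for name, d in payload.items()}


def load_default_presets(profile: str = "full") -> dict[str, StagePreset]:
    """Load the frozen calibrated presets shipped with the package.

    ``profile='fast'`` returns half-resolution copies (voxel size
    doubled, grid halved) for quick runs; calibration and the reference
    statistics apply to the full profile.
    """
    ref = resources.files("repli3d") / "presets" / "default_presets.yaml"
    presets = {name: StagePreset.from_dict(d) for name, d in yaml.safe_load(ref.read_text()).items()}
    if profile == "full":
        return presets
    if profile == "fast":
        return {name: p.scaled(2) for name, p in presets.items()}
    raise ValueError(f"unknown profile {profile!r}")


def default_population_config(
    master_seed: int = 0,
    profile: str = "full",
    output_dir: str | None = None,
    size_scale: float = 1.0,
) -> PopulationConfig:
    """The default six-group study: published group sizes per substage.

    ``profile='fast'`` also halves group sizes (a documented scaled-down
    profile); ``size_scale`` rescales group sizes explicitly (minimum 2
    per group).
    """
    presets = load_default_presets(profile)
    if profile == "fast":
        size_scale = size_scale * 0.5
    groups = []
    for stage, ref in REFERENCE_GROUPS.items():
        n = max(int(round(ref["n"] * size_scale)), 2)
        groups.append((presets[stage], n))
    return PopulationConfig(groups=groups, master_seed=master_seed, output_dir=output_dir)
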