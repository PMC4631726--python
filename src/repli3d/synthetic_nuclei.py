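"""Synthetic 3D nucleus generator for S-phase replication cytology.

Renders substage-labeled two-channel (DAPI, EdU) image stacks of single
maize-like root-tip nuclei, with ground-truth masks, so the whole
measurement pipeline can be exercised without microscope data.  The
structural prior is a mini-domain picture of the interphase nucleoplasm:
DAPI-bright "thick fibers" ~0.3 µm wide built from persistent 3D random
walks (locally compacted repetitive chromatin) embedded in a dim diffuse
nucleoplasm of low-density genic chromatin, plus a DAPI-dark spherical
nucleolus and a small number of very bright heterochromatic knobs (two
large, two small by default, matching the B73 knob complement visible
by DAPI).

EdU placement encodes the substage:

* ``inter_fiber`` (early S): foci land preferentially on low-DAPI
  nucleoplasm between fibers and away from knobs; faint intranucleolar
  puncta.
* ``on_fiber`` (middle S): foci probability follows DAPI intensity
  (excluding knobs), so label coincides with the bright fibers;
  faint intranucleolar puncta persist.

In both modes the ``coupling`` parameter is the fraction of total EdU
signal placed on high-DAPI (chromatin) voxels as a continuous
DAPI-tracking component; the measured DAPI x EdU correlation is
monotone nondecreasing in it.
* ``heterochromatin`` (late S): patchy label across knob voxels plus
  sparse bright nucleoplasmic foci; no intranucleolar label.

Both channels are blurred with an anisotropic Gaussian PSF and carry
signal-dependent shot noise (Gaussian approximation to Poisson, valid
at camera-count intensities) plus additive background.  Output
intensities are integer counts, so stacks round-trip bit-exactly
through the TIFF writer.

A small displacement parameter (``com_displacement_um``) shifts the
EdU placement field's center of intensity away from the DAPI center by
a controlled physical distance in a random direction; together with
``coupling`` and the ellipsoid scale it is the physical knob that
:func:`calibrate_preset` tunes so that measured population statistics
match published group means.  Calibration adjusts only these physical
parameters — never the statistics themselves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import lfilter

from .voxel_core import NucleusImage, VoxelGrid

__all__ = [
    "StagePreset",
    "PopulationConfig",
    "make_nucleus",
    "iter_population",
    "make_population",
    "calibrate_preset",
    "derive_seed",
]

#: Default full-resolution grid (z, y, x) and voxel size (dz, dy, dx) µm.
DEFAULT_GRID_SHAPE = (80, 168, 168)
DEFAULT_VOXEL_SIZE = (0.2, 0.07, 0.07)

_EDU_MODES = ("inter_fiber", "on_fiber", "heterochromatin")


@dataclass
class StagePreset:
    """Full parameterization of one substage's synthetic nuclei.

    Geometry is in physical µm; intensities are relative amplitudes
    later scaled to camera counts.  ``volume_factor``, ``coupling`` and
    ``com_displacement_um`` are the calibration degrees of freedom.
    """

    stage: str
    cycle: str  # "mitotic" | "endocycle"
    target_volume_um3: float
    volume_sd_um3: float
    edu_mode: str

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    # ellipsoid geometry
    volume_factor: float = 1.0
    z_aspect: float = 1.25
    axis_jitter: float = 0.05
    center_jitter_um: float = 0.15

    # nucleolus and knobs
    nucleolus_radius_fraction: float = 0.24
    knob_radii_um: tuple[float, ...] = (0.55, 0.55, 0.35, 0.35)
    knob_intensity: float = 2.2

    # fiber texture
    fiber_n_walks: int = 48
    fiber_step_um: float = 0.06
    fiber_persistence: float = 0.85
    fiber_thickness_um: float = 0.30
    fiber_volume_fraction: float = 0.30
    fiber_amplitude: float = 1.5
    dapi_diffuse: float = 0.85

    # EdU placement
    coupling: float = 0.0
    com_displacement_um: float = 0.0
    n_foci: int = 1500
    focus_sigma_um: float = 0.10
    foci_amp_sigma: float = 0.5
    edu_diffuse_fraction: float = 0.12
    intranucleolar_puncta_count: int = 4
    intranucleolar_puncta_amplitude: float = 0.6
    knob_margin_um: float = 0.15  # EdU exclusion zone around knobs (early/middle)

    # optics and detection
    psf_sigma_um: tuple[float, float, float] = (0.30, 0.13, 0.13)  # (z, y, x)
    dapi_mean_counts: float = 1200.0
    edu_mean_counts: float = 350.0
    noise_gain: float = 2.0
    noise_read_sd: float = 4.0
    background: float = 20.0

    render_fish: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.edu_mode not in _EDU_MODES:
            raise ValueError(f"edu_mode must be one of {_EDU_MODES}, got {self.edu_mode!r}")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must lie in [0, 1], got {self.coupling}")
        if self.target_volume_um3 <= 0 or self.volume_sd_um3 < 0:
            raise ValueError("target volume must be positive and its sd nonnegative")
        if any(r <= 0 for r in self.knob_radii_um):
            raise ValueError("knob radii must be positive")
        if not 0 < self.nucleolus_radius_fraction < 0.6:
            raise ValueError("nucleolus_radius_fraction out of range")
        if self.edu_mode == "heterochromatin" and self.intranucleolar_puncta_count != 0:
            raise ValueError("late-S (heterochromatin) presets must have zero intranucleolar puncta")
        if self.com_displacement_um < 0:
            raise ValueError("com_displacement_um must be nonnegative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "voxel_size_um", "knob_radii_um", "psf_sigma_um"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StagePreset":
        d = dict(d)
        for key in ("grid_shape", "voxel_size_um", "knob_radii_um", "psf_sigma_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def scaled(self, factor: int = 2) -> "StagePreset":
        """Coarser-resolution copy (voxel size × factor, grid / factor)."""
        return dataclasses.replace(
            self,
            grid_shape=tuple(int(np.ceil(s / factor)) for s in self.grid_shape),
            voxel_size_um=tuple(v * factor for v in self.voxel_size_um),
        )


@dataclass
class PopulationConfig:
    """A list of (preset, group size) pairs plus the master seed."""

    groups: list[tuple[StagePreset, int]]
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("population needs at least one group")
        for _, n in self.groups:
            if n < 1:
                raise ValueError("group sizes must be >= 1")


def derive_seed(master_seed: int, group_index: int, nucleus_index: int) -> int:
    """Stable per-nucleus seed from (master seed, group, nucleus index)."""
    ss = np.random.SeedSequence([int(master_seed), int(group_index), int(nucleus_index)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# geometry helpers


def _fit_ellipsoid_axes(target_volume: float, limits: np.ndarray, ratios: np.ndarray) -> np.ndarray:
    """Semi-axes (az, ay, ax) of volume ``target_volume`` within ``limits``.

    Starts from the requested axis ratios and clamps any axis exceeding
    its half-field limit, re-inflating the others to preserve volume.
    """
    r = ratios.astype(float).copy()
    v_scaled = 3.0 * target_volume / (4.0 * np.pi)
    clamped = np.zeros(3, dtype=bool)
    axes = np.empty(3)
    for _ in range(3):
        free = ~clamped
        prod_clamped = np.prod(limits[clamped]) if clamped.any() else 1.0
        if not free.any():
            break
        t = (v_scaled / (prod_clamped * np.prod(r[free]))) ** (1.0 / free.sum())
        axes[clamped] = limits[clamped]
        axes[free] = t * r[free]
        over = axes > limits + 1e-9
        if not over.any():
            return axes
        clamped |= over
    if v_scaled <= np.prod(limits) + 1e-9:
        return limits.copy()
    raise ValueError(
        f"nucleus of volume {target_volume:.0f} um^3 cannot fit the grid (half-field {limits} um)"
    )


def _sphere_mask(coords: tuple[np.ndarray, np.ndarray, np.ndarray], center: np.ndarray, radius: float) -> np.ndarray:
    """Boolean sphere rasterized only inside its bounding window (fast path)."""
    z, y, x = coords
    out = np.zeros((z.size, y.size, x.size), dtype=bool)
    sel = []
    for ax, c in zip((z, y, x), center):
        idx = np.nonzero(np.abs(ax - c) <= radius)[0]
        if idx.size == 0:
            return out
        sel.append(slice(idx[0], idx[-1] + 1))
    sz, sy, sx = sel
    out[sz, sy, sx] = (
        (z[sz] - center[0])[:, None, None] ** 2
        + (y[sy] - center[1])[None, :, None] ** 2
        + (x[sx] - center[2])[None, None, :] ** 2
    ) <= radius**2
    return out


def _anisotropic_ball(radius_um: float, voxel_size: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = voxel_size
    rz = int(radius_um / dz)
    ry = int(radius_um / dy)
    rx = int(radius_um / dx)
    zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2 <= radius_um**2 + 1e-12


def _field_com(weights: np.ndarray, coords: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Intensity-weighted center (z, y, x µm) of a nonnegative field."""
    z, y, x = coords
    total = weights.sum(dtype=np.float64)
    cz = (weights.sum(axis=(1, 2), dtype=np.float64) @ z) / total
    cy = (weights.sum(axis=(0, 2), dtype=np.float64) @ y) / total
    cx = (weights.sum(axis=(0, 1), dtype=np.float64) @ x) / total
    return np.array([cz, cy, cx])


def _pin_field_com(
    weights: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    target: np.ndarray,
    n_iter: int = 3,
) -> np.ndarray:
    """Tilt a nonnegative field so its center of intensity hits ``target``.

    Applies multiplicative linear ramps ``1 + sum_k k_ax (x_ax - c_ax)``
    (clipped at 0.05 to stay nonnegative); each iteration moves the
    center by ~Cov(x, ramp)/mean, converging in a few steps for the
    sub-µm displacements used here.
    """
    z, y, x = coords
    w = weights
    for _ in range(n_iter):
        c = _field_com(w, coords)
        delta = target - c
        if np.linalg.norm(delta) < 1e-4:
            break
        total = w.sum(dtype=np.float64)
        var = np.array(
            [
                (w.sum(axis=(1, 2), dtype=np.float64) @ (z - c[0]) ** 2) / total,
                (w.sum(axis=(0, 2), dtype=np.float64) @ (y - c[1]) ** 2) / total,
                (w.sum(axis=(0, 1), dtype=np.float64) @ (x - c[2]) ** 2) / total,
            ]
        )
        k = (delta / np.maximum(var, 1e-6)).astype(np.float32)
        rz = (k[0] * (z - c[0])).astype(np.float32)[:, None, None]
        ry = (k[1] * (y - c[1])).astype(np.float32)[None, :, None]
        rx = (k[2] * (x - c[2])).astype(np.float32)[None, None, :]
        ramp = (1.0 + rz) + ry + rx
        np.clip(ramp, 0.05, None, out=ramp)
        w = w * ramp
    return w


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _fiber_points(
    rng: np.random.Generator,
    axes: np.ndarray,
    center: np.ndarray,
    nucleolus_center: np.ndarray,
    nucleolus_radius: float,
    total_length_um: float,
    n_walks: int,
    step_um: float,
    persistence: float,
) -> np.ndarray:
    """Sample points along persistent 3D random-walk fibers inside the nucleus.

    Walk increments are an AR(1)-correlated Gaussian sequence normalized
    to unit steps; paths are folded radially back into the ellipsoid
    (scaled coordinates) and pushed out of the nucleolus, so fibers fill
    the nucleoplasm without leaving it.
    """
    n_steps = max(int(np.ceil(total_length_um / step_um / n_walks)), 8)
    pts = []
    for _ in range(n_walks):
        g = rng.standard_normal((n_steps, 3))
        v = lfilter([1.0], [1.0, -persistence], g, axis=0)
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        dirs = v / np.maximum(norms, 1e-9)
        # start in scaled coordinates, biased toward the interior
        q0 = rng.standard_normal(3)
        q0 *= rng.uniform(0.0, 0.8) / np.linalg.norm(q0)
        pos = q0 * axes + np.cumsum(step_um * dirs, axis=0)
        q = pos / axes
        r = np.linalg.norm(q, axis=1)
        # triangle-wave fold of the scaled radius into [0, 0.96]
        rmax = 0.96
        folded = rmax * (1.0 - np.abs(1.0 - np.mod(r / rmax, 2.0)))
        scale = np.where(r > 1e-9, folded / np.maximum(r, 1e-9), 1.0)
        q = q * scale[:, None]
        p = center + q * axes
        # push points out of the nucleolus
        dn = p - nucleolus_center
        d = np.linalg.norm(dn, axis=1)
        inside = d < nucleolus_radius
        if inside.any():
            dsafe = np.maximum(d[inside], 1e-9)
            p[inside] = nucleolus_center + dn[inside] / dsafe[:, None] * (
                2 * nucleolus_radius - d[inside]
            )[:, None]
        pts.append(p)
    return np.concatenate(pts, axis=0)


# ---------------------------------------------------------------------------
# main generator


def make_nucleus(preset: StagePreset, seed: int) -> NucleusImage:
    """Render one synthetic nucleus; deterministic for fixed (preset, seed)."""
    preset.validate()
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = preset.grid_shape
    dz, dy, dx = preset.voxel_size_um
    zc = (np.arange(nz) + 0.5) * dz
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx
    coords = (zc, yc, xc)
    field_half = np.array([nz * dz, ny * dy, nx * dx]) / 2.0

    # --- nuclear envelope -------------------------------------------------
    sd_rel = preset.volume_sd_um3 / preset.target_volume_um3
    draw = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    vol_draw = preset.target_volume_um3 * np.exp(sd_rel * draw - 0.5 * sd_rel**2)
    vol = vol_draw * preset.volume_factor
    ratios = np.array([preset.z_aspect, 1.0, 1.0]) * np.exp(
        rng.normal(0.0, preset.axis_jitter, size=3)
    )
    margin = 0.4 + preset.center_jitter_um
    axes = _fit_ellipsoid_axes(vol, field_half - margin, ratios)
    center = field_half + rng.uniform(-preset.center_jitter_um, preset.center_jitter_um, size=3)
    qz = ((zc - center[0]) / axes[0]) ** 2
    qy = ((yc - center[1]) / axes[1]) ** 2
    qx = ((xc - center[2]) / axes[2]) ** 2
    nucleus = (qz[:, None, None] + qy[None, :, None] + qx[None, None, :]) <= 1.0

    # --- nucleolus ---------------------------------------------------------
    r_equiv = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_nucleolus = preset.nucleolus_radius_fraction * r_equiv
    for _ in range(100):
        off = rng.uniform(-0.35, 0.35, size=3) * axes
        cand = center + off
        if np.sum(((cand - center) / (axes - r_nucleolus - 0.1)) ** 2) <= 1.0:
            nucleolus_center = cand
            break
    else:
        nucleolus_center = center.copy()
    nucleolus = _sphere_mask(coords, nucleolus_center, r_nucleolus) & nucleus

    # --- knobs -------------------------------------------------------------
    knob_centers: list[np.ndarray] = []
    knob_radii: list[float] = []
    knobs = np.zeros_like(nucleus)
    for radius in preset.knob_radii_um:
        placed = False
        for _ in range(200):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            rad = rng.uniform(0.2, 0.85) ** (1.0 / 3.0)
            cand = center + u * rad * (axes - radius - 0.1)
            if np.sum(((cand - center) / (axes - radius - 0.05)) ** 2) > 1.0:
                continue
            if np.linalg.norm(cand - nucleolus_center) < r_nucleolus + radius + 0.1:
                continue
            if any(
                np.linalg.norm(cand - kc) < kr + radius + 0.1
                for kc, kr in zip(knob_centers, knob_radii)
            ):
                continue
            knob_centers.append(cand)
            knob_radii.append(radius)
            knobs |= _sphere_mask(coords, cand, radius)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"failed to place a knob of radius {radius} um inside the nucleus after 200 tries"
            )
    knobs &= nucleus

    # --- fiber texture -----------------------------------------------------
    nucleoplasm = nucleus & ~nucleolus
    voxel_vol = dz * dy * dx
    nucleoplasm_vol = nucleoplasm.sum() * voxel_vol
    fiber_xsec = np.pi * (preset.fiber_thickness_um / 2.0) ** 2
    total_length = preset.fiber_volume_fraction * nucleoplasm_vol / fiber_xsec
    pts = _fiber_points(
        rng,
        axes,
        center,
        nucleolus_center,
        r_nucleolus,
        total_length,
        preset.fiber_n_walks,
        preset.fiber_step_um,
        preset.fiber_persistence,
    )
    idx = np.floor(pts / np.array([dz, dy, dx])).astype(int)
    np.clip(idx[:, 0], 0, nz - 1, out=idx[:, 0])
    np.clip(idx[:, 1], 0, ny - 1, out=idx[:, 1])
    np.clip(idx[:, 2], 0, nx - 1, out=idx[:, 2])
    counts = np.zeros((nz, ny, nx), dtype=np.float32)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    counts *= nucleoplasm & ~knobs
    fiber_sigma = preset.fiber_thickness_um / 2.355  # FWHM -> sigma
    fiber_density = ndimage.gaussian_filter(
        counts, sigma=(fiber_sigma / dz, fiber_sigma / dy, fiber_sigma / dx)
    )
    fibers = ndimage.binary_dilation(
        counts > 0, structure=_anisotropic_ball(preset.fiber_thickness_um / 2.0, (dz, dy, dx))
    ) & nucleoplasm & ~knobs
    fiber_mean = fiber_density[fibers].mean() if fibers.any() else 1.0
    fiber_tex = fiber_density / max(fiber_mean, 1e-9) * preset.fiber_amplitude

    # --- DAPI channel (pre-blur) -------------------------------------------
    dapi_pre = np.zeros((nz, ny, nx), dtype=np.float32)
    dapi_pre[nucleoplasm] = preset.dapi_diffuse
    dapi_pre += fiber_tex.astype(np.float32) * nucleoplasm
    dapi_pre[knobs] = preset.knob_intensity * (1.0 + 0.1 * rng.standard_normal(int(knobs.sum())))
    dapi_pre[nucleolus] = 0.0
    np.clip(dapi_pre, 0.0, None, out=dapi_pre)

    # --- EdU channel (pre-blur) --------------------------------------------
    # EdU exclusion zone around each knob: the margin grows with the
    # per-axis PSF width so post-blur leakage into the knob interior
    # stays at noise level despite the anisotropic (z-elongated) PSF.
    psf_arr = np.array(preset.psf_sigma_um)
    excl_margin = preset.knob_margin_um + 1.5 * psf_arr
    knob_excl = np.zeros_like(knobs)
    for kc, kr in zip(knob_centers, knob_radii):
        semi = kr + excl_margin
        win = _sphere_mask(coords, kc, float(semi.max()))
        qz2 = ((zc - kc[0]) / semi[0]) ** 2
        qy2 = ((yc - kc[1]) / semi[1]) ** 2
        qx2 = ((xc - kc[2]) / semi[2]) ** 2
        knob_excl |= win & (
            (qz2[:, None, None] + qy2[None, :, None] + qx2[None, None, :]) <= 1.0
        )
    dnorm = dapi_pre / max(np.quantile(dapi_pre[nucleoplasm], 0.99), 1e-9)
    dnorm = np.clip(dnorm, 0.0, 1.0)
    edu_pre = np.zeros((nz, ny, nx), dtype=np.float32)

    open_np = nucleoplasm & ~knob_excl
    flat_open = np.flatnonzero(open_np.ravel())

    def _deposit(flat_indices: np.ndarray, amps: np.ndarray) -> None:
        np.add.at(edu_pre.ravel(), flat_indices, amps.astype(np.float32))

    n_foci = preset.n_foci
    amps_all = np.exp(rng.normal(0.0, preset.foci_amp_sigma, size=n_foci))
    if preset.edu_mode in ("inter_fiber", "on_fiber"):
        if preset.edu_mode == "inter_fiber":
            w = (1.0 - dnorm).ravel()[flat_open]
        else:
            w = dnorm.ravel()[flat_open]
        w = np.clip(w, 1e-6, None)
        w /= w.sum()
        _deposit(rng.choice(flat_open, size=n_foci, p=w), amps_all)
    else:  # heterochromatin (late S)
        flat_knob = np.flatnonzero((knobs & nucleus).ravel())
        n_knob = int(round(0.7 * n_foci))
        n_np = n_foci - n_knob
        if flat_knob.size == 0:
            raise ValueError("late-S preset requires knob voxels for EdU placement")
        parts = [rng.choice(flat_knob, size=n_knob)]
        if n_np > 0:
            parts.append(rng.choice(flat_open, size=n_np))
        _deposit(np.concatenate(parts), amps_all)

    # faint intranucleolar puncta (early/middle only)
    if preset.intranucleolar_puncta_count > 0:
        interior = ndimage.binary_erosion(nucleolus, iterations=1)
        flat_nucleolus = np.flatnonzero((interior if interior.any() else nucleolus).ravel())
        picks = rng.choice(flat_nucleolus, size=preset.intranucleolar_puncta_count)
        mean_amp = amps_all.mean()
        _deposit(picks, np.full(picks.size, preset.intranucleolar_puncta_amplitude * mean_amp))

    # diffuse nucleoplasmic haze (a constant fraction of total signal)
    if preset.edu_diffuse_fraction > 0:
        total = float(edu_pre.sum())
        haze = preset.edu_diffuse_fraction * total / max(open_np.sum(), 1)
        edu_pre[open_np] += haze

    # enforce the knob-exclusion invariant before blur (early/middle)
    edu_cont = None
    if preset.edu_mode in ("inter_fiber", "on_fiber"):
        edu_pre[knob_excl] = 0.0
        # `coupling` is the fraction of total EdU signal placed on
        # chromatin (high-DAPI) voxels: a continuous component that
        # tracks DAPI density, blended with the focal component.
        if preset.coupling > 0:
            # continuous component tracks the unclipped DAPI density
            chromatin = np.where(open_np, dapi_pre, 0.0).astype(np.float32)
            c_sum = float(chromatin.sum())
            e_sum = float(edu_pre.sum())
            if c_sum > 0 and e_sum > 0:
                edu_cont = (preset.coupling * e_sum / c_sum) * chromatin
                edu_pre = (1.0 - preset.coupling) * edu_pre

    # --- COM displacement --------------------------------------------------
    com_dapi = _field_com(dapi_pre, coords)
    direction = _random_unit(rng)
    target_com = com_dapi + preset.com_displacement_um * direction
    if edu_pre.sum() > 0:
        edu_pre = _pin_field_com(edu_pre, coords, target_com)
    if edu_cont is not None:
        edu_cont = _pin_field_com(edu_cont, coords, target_com)

    # --- optics and detection ----------------------------------------------
    # Focal label carries the physical focus size on top of the PSF; the
    # continuous chromatin-tracking label sees the PSF only.
    psf = np.array(preset.psf_sigma_um)
    focus = np.array([preset.focus_sigma_um] * 3)
    edu_sigma = np.sqrt(psf**2 + focus**2)
    dapi_img = ndimage.gaussian_filter(dapi_pre, sigma=(psf[0] / dz, psf[1] / dy, psf[2] / dx))
    edu_img = ndimage.gaussian_filter(
        edu_pre, sigma=(edu_sigma[0] / dz, edu_sigma[1] / dy, edu_sigma[2] / dx)
    )
    if edu_cont is not None:
        edu_img = edu_img + ndimage.gaussian_filter(
            edu_cont, sigma=(psf[0] / dz, psf[1] / dy, psf[2] / dx)
        )
    dapi_img *= preset.dapi_mean_counts / max(float(dapi_img[nucleus].mean()), 1e-9)
    edu_img *= preset.edu_mean_counts / max(float(edu_img[nucleus].mean()), 1e-9)
    channels = {}
    for name, img_arr in (("DAPI", dapi_img), ("EDU", edu_img)):
        sig = img_arr.astype(np.float32, copy=False) + np.float32(preset.background)
        sd = np.sqrt(np.float32(preset.noise_gain) * sig + np.float32(preset.noise_read_sd**2))
        sd *= rng.standard_normal(sig.shape, dtype=np.float32)
        sig += sd
        np.round(sig, out=sig)
        np.clip(sig, 0.0, 65535.0, out=sig)
        channels[name] = VoxelGrid(sig, (dz, dy, dx))

    if preset.render_fish:
        fish = ndimage.gaussian_filter(
            (knobs.astype(np.float32)) * 1000.0, sigma=(psf[0] / dz, psf[1] / dy, psf[2] / dx)
        )
        channels["KNOB_FISH"] = VoxelGrid(np.round(fish + preset.background), (dz, dy, dx))

    truth = {
        "nucleus": nucleus,
        "nucleolus": nucleolus,
        "knobs": knobs,
        "fibers": fibers,
    }
    meta = {
        "stage": preset.stage,
        "cycle": preset.cycle,
        "seed": int(seed),
        "provenance": "repli3d.synthetic_nuclei",
        "analytic_volume_um3": float(vol),
    }
    return NucleusImage(channels=channels, truth=truth, meta=meta)


# ---------------------------------------------------------------------------
# populations


def iter_population(config: PopulationConfig):
    """Yield (NucleusImage, manifest row dict) for every nucleus in turn."""
    for g_idx, (preset, n) in enumerate(config.groups):
        for i in range(n):
            seed = derive_seed(config.master_seed, g_idx, i)
            try:
                img = make_nucleus(preset, seed)
            except Exception as exc:  # annotate with position
                raise RuntimeError(
                    f"nucleus {i} of group {g_idx} ({preset.stage}/{preset.cycle}): {exc}"
                ) from exc
            row = {
                "group_index": g_idx,
                "nucleus_index": i,
                "stage": preset.stage,
                "cycle": preset.cycle,
                "seed": seed,
            }
            yield img, row


def make_population(config: PopulationConfig, write: bool | None = None):
    """Materialize a population; optionally write TIFF+sidecar files.

    Returns ``(images, manifest)`` where ``manifest`` is a DataFrame
    with one row per nucleus (file, stage, cycle, seed).  When
    ``config.output_dir`` is set (or ``write=True``) stacks are written
    and ``images`` holds file paths instead of in-memory images.
    """
    import pandas as pd

    from .voxel_core import write_stack

    if write is None:
        write = config.output_dir is not None
    if write and config.output_dir is None:
        raise ValueError("write=True requires an output_dir")
    out = []
    rows = []
    for img, row in iter_population(config):
        if write:
            from pathlib import Path

            fname = f"nucleus_{row['group_index']:02d}_{row['nucleus_index']:03d}.tif"
            path = Path(config.output_dir) / fname
            write_stack(img, path)
            row["file"] = str(path)
            out.append(path)
        else:
            row["file"] = ""
            out.append(img)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if write:
        from pathlib import Path

        manifest.to_csv(Path(config.output_dir) / "manifest.csv", index=False)
    return out, manifest


# ---------------------------------------------------------------------------
# calibration


def _population_means(
    preset: StagePreset, n: int, seed_base: int, **measure_kwargs
) -> dict[str, float]:
    from .colocalization import measure_nucleus

    vols, rs, offs = [], [], []
    for i in range(n):
        img = make_nucleus(preset, derive_seed(seed_base, 0, i))
        m = measure_nucleus(img, **measure_kwargs)
        vols.append(m.volume_um3)
        rs.append(m.pearson_r)
        offs.append(m.com_offset_um)
    return {
        "volume_um3": float(np.mean(vols)),
        "pearson_r": float(np.mean(rs)),
        "com_offset_um": float(np.mean(offs)),
    }


def calibrate_preset(
    base: StagePreset,
    target_volume_um3: float | None = None,
    target_r: float | None = None,
    target_com_offset_um: float | None = None,
    n_cal: int = 12,
    seed: int = 1000,
    tol_volume_rel: float = 0.01,
    tol_r: float = 0.008,
    tol_com_um: float = 0.01,
    max_iter: int = 8,
) -> tuple[StagePreset, dict]:
    """Tune physical preset parameters to hit measured population targets.

    Adjusts, in order: ``volume_factor`` (fixed-point on the measured
    mean volume), ``coupling`` (bisection; expected Pearson r is
    monotone nondecreasing in coupling) and ``com_displacement_um``
    (bisection on the measured mean COM offset).  Every evaluation
    generates and *measures* ``n_cal`` fresh nuclei through the full
    tracing pipeline, so the calibration absorbs segmentation and blur
    biases.  Returns the frozen preset and a calibration report.
    """
    if target_r is not None and not 0.0 < target_r < 1.0:
        raise ValueError("target_r must lie strictly between 0 and 1")
    preset = dataclasses.replace(base)
    report: dict = {"steps": []}

    if target_volume_um3 is not None:
        for it in range(4):
            got = _population_means(preset, n_cal, seed + it)["volume_um3"]
            report["steps"].append({"param": "volume_factor", "value": preset.volume_factor, "measured": got})
            if abs(got - target_volume_um3) / target_volume_um3 <= tol_volume_rel:
                break
            preset = dataclasses.replace(
                preset, volume_factor=preset.volume_factor * target_volume_um3 / got
            )

    if target_com_offset_um is not None:
        lo, hi = 0.0, max(1.5 * target_com_offset_um, 0.3)
        got_lo = _population_means(dataclasses.replace(preset, com_displacement_um=lo), n_cal, seed + 20)[
            "com_offset_um"
        ]
        if got_lo > target_com_offset_um + tol_com_um:
            raise ValueError(
                f"target COM offset {target_com_offset_um} um below the measurement floor {got_lo:.3f} um"
            )
        got_hi = _population_means(dataclasses.replace(preset, com_displacement_um=hi), n_cal, seed + 20)[
            "com_offset_um"
        ]
        while got_hi < target_com_offset_um and hi < 3.0:
            hi *= 1.5
            got_hi = _population_means(
                dataclasses.replace(preset, com_displacement_um=hi), n_cal, seed + 20
            )["com_offset_um"]
        if got_hi < target_com_offset_um:
            raise ValueError(f"target COM offset {target_com_offset_um} um unreachable (max {got_hi:.3f})")
        best = hi
        for it in range(max_iter):
            mid = 0.5 * (lo + hi)
            got = _population_means(
                dataclasses.replace(preset, com_displacement_um=mid), n_cal, seed + 20
            )["com_offset_um"]
            report["steps"].append({"param": "com_displacement_um", "value": mid, "measured": got})
            best = mid
            if abs(got - target_com_offset_um) <= tol_com_um:
                break
            if got < target_com_offset_um:
                lo = mid
            else:
                hi = mid
        preset = dataclasses.replace(preset, com_displacement_um=best)

    if target_r is not None:
        lo, hi = 0.0, 1.0
        r_lo = _population_means(dataclasses.replace(preset, coupling=lo), n_cal, seed + 10)["pearson_r"]
        r_hi = _population_means(dataclasses.replace(preset, coupling=hi), n_cal, seed + 10)["pearson_r"]
        if not (min(r_lo, r_hi) - tol_r <= target_r <= max(r_lo, r_hi) + tol_r):
            raise ValueError(
                f"target r={target_r} unreachable: coupling in [0,1] spans r=[{r_lo:.3f}, {r_hi:.3f}]"
            )
        for it in range(max_iter):
            mid = 0.5 * (lo + hi)
            got = _population_means(dataclasses.replace(preset, coupling=mid), n_cal, seed + 10)["pearson_r"]
            report["steps"].append({"param": "coupling", "value": mid, "measured": got})
            if abs(got - target_r) <= tol_r:
                break
            if (got < target_r) == (r_lo < r_hi):
                lo = mid
            else:
                hi = mid
        preset = dataclasses.replace(preset, coupling=0.5 * (lo + hi) if abs(got - target_r) > tol_r else mid)

    report["final"] = _population_means(preset, n_cal, seed + 30)
    report["targets"] = {
        "volume_um3": target_volume_um3,
        "pearson_r": target_r,
        "com_offset_um": target_com_offset_um,
    }
    return preset, report
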