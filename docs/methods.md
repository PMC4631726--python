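# Methods

## Scope and rationale

`repli3d` reconstructs, end to end, the quantitative image-analysis
workflow used to substage S-phase nuclei from pulse-labeled plant root
tips: per-optical-section polygon tracing of the nuclear boundary on
the DAPI channel, assembly into a closed 3D mask, nuclear volume,
voxel-wise Pearson correlation of DAPI vs EdU/A-488, per-channel
centers of intensity and their Euclidean offset, and mean (±sd) group
summaries per substage. Because the original microscope stacks cannot
be re-imaged, the package ships a synthetic-nucleus generator whose
six substage presets were calibrated once — by adjusting *physical*
generator parameters only — so that the full measurement pipeline, run
on freshly seeded populations, recovers the published group means.
Acceptance is therefore parameter recovery through the pipeline, never
a lookup.

## The synthetic nucleus model

One nucleus is rendered on a `(z, y, x)` voxel grid (default
168×168×80 voxels for mitotic presets, 176×176×88 for the larger
endocycling nuclei) at 0.07 × 0.07 × 0.2 µm voxel pitch, the typical
sampling of 60×/1.4 NA wide-field optical sectioning.

**Envelope.** The nucleus is an ellipsoid whose volume is drawn from a
lognormal law with the group's published mean and sd (draws truncated
at ±2σ), mildly prolate along z (axis ratio 1.25 with 5% jitter) and
clamped so the shape plus a 0.4 µm segmentation margin fits the field;
a calibrated `volume_factor` absorbs the small systematic bias of the
tracing step. Larger fields for endocycle groups are required: an
endocycle late-S volume draw at +2σ cannot fit the mitotic field.

**Nucleolus and knobs.** One DAPI-dark spherical nucleolus (radius
0.24 of the equivalent nuclear radius) is placed interior; four
heterochromatic knobs (two of 0.55 µm and two of 0.35 µm radius,
matching the B73 knob complement visible by DAPI) are placed as
non-overlapping spheres avoiding the nucleolus, at 2.2× the mean
nucleoplasm intensity.

**Chromatin fibers.** The DAPI texture implements a mini-domain
picture of the maize nucleoplasm: ~0.3 µm "thick fibers" of locally
compacted repetitive chromatin embedded in a dim diffuse nucleoplasm
of low-density genic chromatin. Fibers are persistent 3D random walks
(AR(1)-correlated unit steps of 0.06 µm, persistence 0.85), folded
radially back into the ellipsoid and out of the nucleolus, rasterized
and smoothed to a 0.3 µm FWHM; total walk length is set so fibers
occupy ~30% of the nucleoplasm. The diffuse floor is 0.85 against a
fiber-mean amplitude of 1.5. That contrast was chosen jointly with
the COM mechanism: creating a genuine 0.2–0.5 µm channel offset
necessarily modulates the EdU field across the nucleus and costs
correlation in proportion to E[DAPI²]/Var(DAPI), so the texture
variance must be large enough that the published (r, offset) pairs —
in particular r = 0.85 together with a 0.46 µm offset — are jointly
reachable. The floor stays high enough that the whole-stack intensity
histogram separates background from nucleus cleanly, which is what
makes the global-Otsu tracing step stable.

**EdU placement.** Substage presets differ in where label goes:

* *early S* (`inter_fiber`): 1500 foci sampled with probability
  ∝ (1 − normalized DAPI) over the nucleoplasm, excluding knobs, plus
  faint intranucleolar puncta (4 per nucleus);
* *middle S* (`on_fiber`): foci sampled ∝ normalized DAPI (knobs
  excluded), puncta persist;
* *late S* (`heterochromatin`): 70% of 150 bright foci on knob voxels,
  the rest sparse in the nucleoplasm, no intranucleolar label.

A `coupling ∈ [0, 1]` parameter is the fraction of total EdU signal
contributed by a *continuous* component proportional to the DAPI
density (knobs and nucleolus excluded). This is the package's reading
of "fraction of EdU signal placed on high-DAPI voxels": a purely focal
field cannot reach the published middle-S correlation of 0.88 no
matter where the foci sit, because a spiky field does not track smooth
texture voxel-wise; real stacks, in which label at this resolution is
the superposition of thousands of unresolved forks, are much closer to
the continuous limit. Measured masked Pearson r is monotone
nondecreasing in `coupling` (checked empirically across a coupling
grid), spanning ≈ −0.1 to ≈ 0.92, which brackets both published
values.

Around each knob an exclusion shell (0.15 µm plus 1.5 PSF sigmas per
axis) keeps early/middle EdU out; without the PSF-scaled term the
z-elongated blur leaks enough signal into knob interiors to violate
the "knobs unlabeled before late S" property the presets must satisfy.

**COM displacement.** The published early-vs-middle contrast includes
a systematic offset between the DAPI and EdU centers of intensity
(0.2–0.5 µm). The generator pins the pre-blur EdU field's center of
intensity exactly onto `DAPI COM + d·u` (`u` a random unit vector per
nucleus, `d = com_displacement_um`) by iterated multiplicative linear
ramps clipped at 0.05. Pinning, rather than a loose placement bias,
is needed because the published middle-S offset sd is ±0.010 µm: only
a near-deterministic per-nucleus offset lets a calibrated mean land
inside such a band. A side effect is that the synthetic per-nucleus
offset spread (and likewise the Pearson-r spread) is considerably
*smaller* than the published sds; the calibration targets means, and
the package makes no claim about reproducing published dispersions.

**Optics and detection.** Both channels are blurred with an
anisotropic Gaussian PSF (σ = 0.13/0.13/0.30 µm in x/y/z) standing in
for a deconvolved wide-field system; focal EdU additionally carries a
0.10 µm focus size. Channels are scaled to mean in-nucleus counts
(DAPI 1200, EdU 350) on top of a 20-count background, then perturbed
by Gaussian noise of variance `2·signal + 4²` — a Poisson (shot)
approximation valid at camera-count intensities — and rounded to
integer counts, which is what makes TIFF round-trips bit-exact.

## Segmentation

Manual per-section contour tracing is replaced by a deterministic
tracer with identical outputs contracts: 3D Gaussian smoothing
(0.15 µm), one *global* Otsu threshold for the whole stack (per-slice
thresholds flicker at the dim poles), the largest 26-connected
component, per-slice hole-filled outer contours simplified with a
0.25 px tolerance, and end-slices below 1 µm² dropped (contiguity
preserved). Polygons are rasterized by the voxel-center
inside-or-on-boundary rule (Shapely point queries), making volumes
orientation-independent and bit-reproducible; volume is voxel count ×
voxel volume. Externally traced polygon stacks can be supplied via
the CSV serialization (`z, vertex_index, y, x`) and enter the same
`build_mask` path.

On noise-free analytic ellipsoids the traced volume converges on the
analytic value as resolution doubles and is within 3–5% at full
resolution; on generator fixtures the traced volume is within 10% of
the ground-truth mask. The residual bias is absorbed by the
calibrated `volume_factor`, so *measured* group means match targets.

## Metrics conventions

* Pearson r is computed over masked (traced-object) voxels by default;
  an unmasked whole-crop variant exists but inflates r through the
  common dark background and is not used for calibration.
* Centers of intensity are raw-intensity-weighted voxel-center
  positions within the traced object; no background subtraction is
  applied anywhere, matching the absence of any stated correction in
  the source workflow.
* Knob enrichment = mean EdU over knob voxels / mean EdU over the
  remaining nucleus. With generator fixtures the ground-truth knob
  mask is used; on truth-free data knobs are estimated as ≥98th
  percentile DAPI blobs, opened at 0.1 µm and filtered at 0.1 µm³
  (configuration, not biology; the estimate's provenance is flagged in
  the output).
* Group spreads are sample standard deviations (n−1); the "±" of the
  reference table is assumed to be an sd, not an SEM, and the output
  records that assumption (`sd_is` column).
* The early-vs-middle significance test is Welch's two-sample t
  (group variances are unequal in the reference table); Mann-Whitney U
  is available by flag. No multiple-testing correction is applied:
  only the planned early-vs-middle contrast per cycle is run.

## Calibration

`calibrate_preset` tunes, in order: `volume_factor` (fixed-point
iteration on the measured mean volume), `com_displacement_um`
(bisection on the measured mean offset), then `coupling` (bisection on
the measured mean r). The order matters: the COM ramp tilts the EdU
field and measurably lowers r, so coupling must be calibrated with the
displacement frozen. Every evaluation generates and *measures* 12
fresh nuclei through the full tracing pipeline, so calibration absorbs
segmentation and blur biases; tolerances are 1% (volume), 0.01 µm
(offset) and 0.008 (r). The six calibrated presets are frozen in
`src/repli3d/presets/default_presets.yaml`; `scripts/calibrate_defaults.py`
reproduces them. Late-S groups have published volumes only, so their
presets calibrate volume alone and their r/COM outputs are reported
but not validated.

## Flow simulation

The gating companion simulates the bivariate (DNA content × EdU)
population per root zone as a finite mixture: the meristematic zone
holds G1 (2C), G2 (4C) and labeled S (uniform 2C–4C); the 1–3 mm zone
adds an endocycle arc (4C and 8C gaps, labeled endo-S uniform 4C–8C);
the 3–5 mm zone is mostly unlabeled with ≤5% S events. Mixture
weights are fixed design choices — the source only constrains them
qualitatively — and DNA content carries a 4% measurement CV; EdU
intensities are lognormal (unlabeled autofluorescence ~30, labeled
~500 a.u.). Gates are declared, not extracted from a figure: the
cycle's DNA interval is split into three equal-width windows sharing
an EdU threshold at the 99.5th percentile of the unlabeled events.
Event-level EdU during S is a constant mean with lognormal noise;
pulse-length effects are not modeled, since only gate topology matters
downstream.

## Problem sizes and runtime

The default study is 282 nuclei (44/61/36/45/44/52) at full
resolution, ~1 s per nucleus to generate and measure on one core; the
test suite runs the full default study once and reuses it across
acceptance checks. A `fast` profile (voxel pitch doubled, grid and
group sizes halved) is used for unit tests and quick CLI runs; its
measured absolute values shift slightly with resolution, so all
calibration and recovery claims refer to the full profile. The type-I
error check draws 200 two-sample replicates by randomly splitting a
36-nucleus single-preset pool, an exchangeable resampling scheme that
avoids generating thousands of nuclei.

## What the synthetic data does and does not show

The generator reproduces: stage-dependent volumes, the DAPI-dark
nucleolus with faint early/middle intranucleolar puncta, bright
late-replicating knobs excluded from early/middle label, fiber-like
DAPI texture, substage-specific DAPI×EdU correlation and COM offsets,
and PSF+shot-noise image statistics. It does not model: optical
aberrations or vendor PSFs, fixation/buffer effects, chromatic shift,
FISH photochemistry (FISH channels are blurred renderings of
ground-truth masks), per-focus biology (counts/sizes are free
parameters), or realistic inter-nucleus dispersion of r and COM
offset (see above). Passing tests therefore demonstrate that the
*measurement pipeline* is correct and that the generator realizes the
intended study conditions — not that maize chromatin behaves as the
generator assumes.

## Degenerate inputs and numerical choices

All-zero or constant stacks are rejected ("no foreground"); constant
channels make Pearson r undefined and raise; empty knob masks and
empty rasterizations raise. Polygon stacks must be simple, ≥3
vertices, contiguous in z. Masks must be single 26-connected
components. Seeds derive from `SeedSequence([master, group, index])`
(platform-stable, < 2³¹). Identical-value groups report sd exactly 0.
Intensities are float32 internally, stored as uint16 with a
documented per-channel scale.
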