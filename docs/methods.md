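# Methods

## Estimation model

The package treats a color Doppler frame as a velocity measurement device:
each chromatic pixel encodes the axial blood velocity through the
scanner's color lookup table (LUT), scaled by the Nyquist velocity, while
grayscale pixels render the vessel wall, whose velocity is zero by the
no-slip condition. Near-wall shear rate is estimated with a one-sided
two-layer difference,

    γ_w ≈ (V_fast − V_slow) / d,

where V_slow and V_fast are the speeds (magnitudes) at the first and
second flow pixel in from the wall and d is the radial layer spacing (the
axial pixel spacing after the vessel is rotated horizontal). Wall shear
stress is τ_w = μ γ_w with Newtonian viscosity μ. Speeds enter as
magnitudes because the stencil measures the gradient of speed parallel to
the wall; flow direction (toward/away from the probe) is carried as a
separate per-column diagnostic so that reversed-flow columns remain
identifiable.

All internal quantities are CGS — cm, cm/s, poise, dyne/cm² — with
conversions confined to the I/O boundary (DICOM pixel spacing arrives in
mm and is divided by 10 exactly).

### Assumptions

* Laminar, locally unidirectional flow along a straight, near-horizontal
  vessel segment; "radial" is the image vertical after rotation.
* The scanner has already applied Doppler-angle correction at acquisition
  (a fixed beam-to-vessel angle); an optional divide-by-cos(θ) flag exists
  for uncorrected data, default off.
* Acquisition was alias-free (speed range covering the flow). The decoder
  never unwraps aliased velocities — silent unwrapping would fabricate
  data — but flags frames in which more than 1% of decodable flow pixels
  sit within one LUT step of ±v_nyquist.

### Error structure of the two-layer stencil

For a parabolic profile with pixel centers at half-integer offsets from
the wall, the two-layer difference evaluates the derivative one layer in
from the wall, giving a multiplicative bias of exactly (1 − d/R): a 10%
low bias at d = R/10 shrinking to 1% at d = R/100. On top of this sits
LUT quantization noise of at most one velocity step per layer, i.e. a
shear-rate error bounded by (v_nyquist/levels)/d. The acceptance-grade
convergence checks therefore use the high-resolution built-in map (below),
for which the quantization term is two orders of magnitude below the
discretization bias at every spacing tested.

A second-order one-sided stencil ((−3f₀ + 4f₁ − f₂)/2d) and a variant that
anchors V_slow = 0 at the gray wall pixel itself are available behind
flags for sensitivity studies; the two-layer difference is the default
because it is the method under study.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| μ (viscosity) | 0.03 | poise | 3 cP, the conventional whole-blood value |
| chroma_tol | 20 | 8-bit counts | flow/gray separation; phantom walls (gray 150) and LUT colors (chroma ≥ 128) separate with wide margin |
| lum_min | 40 | 8-bit counts | wall-gray vs dark background floor |
| min_lumen_px | 5 | pixels | rejects speckle runs masquerading as lumen |
| max_rgb_dist | 60 | RGB distance | flow pixels farther from every LUT color are logged and dropped |
| v_nyquist | from file/config | cm/s | mandatory calibration; scanner overlays are never parsed (OCR of on-screen annotations is out of scope) |

Rotation interpolates decoded velocities, never RGB values: interpolating
colors through a nonlinear LUT corrupts velocities. Bilinear weights are
restricted to valid source pixels, and an output pixel stays invalid when
less than half its interpolation weight comes from valid sources. A 0°
rotation is the exact identity. The flow-axis estimator uses the
second-moment eigen-axis of the flow-pixel cloud; a nearly isotropic cloud
(eigenvalue ratio < 1.2) returns 0° with a warning rather than an error,
since circular ROI crops occur in practice.

Wall detection retains a column only when its longest contiguous flow run
is at least min_lumen_px long *and* bordered by a grayscale pixel on both
sides; runs touching the image edge are dropped. Columns lacking two valid
flow layers on either wall are excluded from the shear map, so maps
contain finite values only.

## Built-in colormaps

The scanner palette of any given machine is proprietary; the package ships
two documented conventions rather than a claim about any vendor:

* `red-blue-brightness` — 128 levels per sign, forward flow as a red
  brightness ramp up to (255, 0, 0) at the Nyquist limit, reverse flow
  mirrored in blue. This is the realistic-scale default for the CLI and
  for round-trip examples; its velocity step (v_nyquist/128) limits
  end-to-end shear accuracy to a few percent.
* `red-blue-fine` — 16384 levels per sign; the dominant channel carries
  the coarse brightness ramp and the green channel 128 fine sub-levels.
  This is a test instrument: its step is chosen from the quantization
  analysis above so that color discretization is negligible next to the
  spatial discretization under study in convergence tests.

Custom maps load from JSON. Validation enforces strictly increasing
velocities, distinct colors, and chromaticity of every entry (chroma above
the classification tolerance), which guarantees flow pixels can never
collide with wall grays.

Decoding is nearest-neighbor in RGB space (exact round trip on LUT
colors, by construction); interpolated inversion is deliberately not the
default because it would break the exactness guarantee the tests rely on.

## Synthetic data

### Flow phantom

`generate_poiseuille_frame` renders u(r) = u_M (1 − r²/R²) over a
horizontal lumen of 2R/spacing pixel rows, encodes each pixel-center
velocity through the chosen LUT, paints grayscale wall bands and black
background, and returns the true wall rows plus the analytic stress
2 μ u_M / R. Defaults (u_M = 20 cm/s, R = 0.3 cm, 30 µm pixels, speed
range 25 cm/s, noise-free) represent a small-animal carotid on a
high-frequency linear probe. Optional seeded Gaussian velocity noise is
added before encoding.

A plaque option narrows the lumen over a column range with a smooth
cosine bump; lesion columns carry a locally reduced centerline velocity,
u_M,local = u_M (R_local/R)², so their analytic stress
2 μ u_M,local / R_local falls with narrowing. This deliberately emulates
the low-WSS phenotype observed over atherosclerotic wall segments
(disturbed, separation-prone flow) rather than conserving volumetric flow
— a mass-conserving stenosis would instead raise local WSS, which is not
the regime the diagnostic question concerns.

What the phantom does *not* emulate: speckle texture, pulsatile velocity
profiles, curved centerlines, wall motion, and vendor post-processing
(persistence, write priority). Passing phantom tests therefore
demonstrates correctness of the decoding/segmentation/differencing chain
and its convergence behavior, not robustness to the full noise structure
of clinical frames.

### Cohort simulator

`generate_cohort` draws per-animal weekly WSS, IMT, total cholesterol and
LDL values independently from per-week, per-group normal distributions
(the published group summaries serve as defaults), truncated at zero by
resampling rather than clipping so the distribution stays continuous.
The design is 40 experimental + 20 control animals with 8 + 4 sacrificed
after each even week; experimental stage labels follow the histology
timeline (normal through week 5, fatty streaks weeks 6–7, fibrous plaques
weeks 8–9, dense fibrous plaques week 10; weeks 7 and 9 inherit the
preceding biweekly histology finding). Controls are always normal.

Variables are drawn independently — only marginal summaries are published,
and inventing a covariance structure would be worse than omitting one; a
correlation hook exists but defaults to identity. Consequences: the
simulator reproduces per-week marginal means/SDs and the resulting
t-test/ROC behavior, but not within-animal longitudinal correlation, so it
cannot support mixed-model or trajectory analyses.

One distribution is materially affected by truncation: the control-group
LDL summary (0.41 ± 0.67 mmol/L) places roughly 27% of its normal mass
below zero, so the realized positive-only draws necessarily have a higher
mean and smaller SD than the nominal parameters. Large-sample convergence
to the nominal summaries holds (and is tested) for every other
variable/group; for control LDL it cannot, by construction.

## Statistics

Welch's unequal-variance t-test is the group-comparison default because
the published group SDs differ by up to a factor of six; the pooled
variant is behind a flag. Degenerate inputs: two zero-variance samples
with equal means give p = 1 by convention; with different means the test
is refused. P-values are reported unadjusted — comparisons are per-week,
and no multiplicity correction is applied, deliberately.

ROC curves group tied scores at one threshold. The AUC is accumulated
from integer pair counts, making it *exactly* the Mann–Whitney
probability (positives scoring more disease-like than negatives, ties
half) and exactly the trapezoidal area under the empirical curve — the
test suite verifies this identity against a brute-force pairwise oracle
and against an independent library implementation. The disease direction
default is low_positive (a case is called diseased when its score is at
or below the threshold), matching the biology of falling WSS; calls at
exactly the threshold count as positive, fixing tie semantics so
operating-point statements are reproducible. Youden's J selects operating
thresholds, with ties broken toward higher sensitivity.

The published operating points of the motivating study (thresholds 1.443
and 1.198 dyne/cm² with their sensitivities/specificities and AUCs) derive
from unpublished per-animal measurements and are not recoverable from
summary statistics; the package therefore treats them as illustrative
inputs (e.g. in the CLI examples), not as recoverable ground truth, and
validates the ROC machinery by exactness properties instead.

## Numerical choices

* Two-layer stencil bias is (1 − d/R) on parabolic flow; convergence
  tests use spacings R/10, R/25, R/50, R/100 with n = 24–128 columns,
  sizes at which the full suite runs in seconds on one CPU.
* Linearity of τ in μ and in velocity scale is algebraically exact;
  bitwise-exact assertions use power-of-two scale factors (IEEE scaling
  by 2 is lossless, arbitrary factors round in the last ulp).
* The two Poiseuille forms agree to machine precision under
  Q = π R² u_M / 2; the centerline form is implemented as 2 μ u_M / R,
  the only dimensionally consistent version compatible with the
  flow-rate form.
* Time aggregation across frames is the arithmetic mean of per-frame
  spatial means; both the per-frame values and their average are
  reported, since space-only and space-time averages answer different
  questions.
* The exported WSS surface collapses the two walls per column with max by
  default so the grid's peak equals the summary's maximum stress;
  mean/upper/lower variants are available.
* Large-sample cohort checks run at n = 10,000 with 1% tolerance on
  means; SD checks use 3% (the sampling error of an SD at that n is
  ~0.7%, so a 1% band would be a coin flip, not a check).

## Known limitations

* Nearest-neighbor decoding assumes frames were rendered through the
  declared LUT; heavily compressed or post-processed clinical images may
  decode with many unmatched pixels (the decode report counts them).
* Per-column wall detection assumes a roughly horizontal vessel after
  rotation; strongly curved segments violate the per-column lumen model.
* The estimator reads the *axial* velocity component; out-of-plane flow
  is invisible to it, as to all single-plane color Doppler.
* No confidence intervals on AUC, no survival or longitudinal models —
  the statistics layer covers exactly the study design it serves.
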