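# Methods

## The measurement model

`siderseg` measures the volume of cortical superficial siderosis as the
volume of the voxel set produced by a fixed, deterministic pipeline applied
to a susceptibility-weighted magnitude volume plus a small set of
rater-supplied inputs (seed clicks and false-positive edits). The pipeline
is: per-slice 2D vesselness enhancement of dark tubular structures →
global threshold → seeded 3D 6-neighborhood region growing → explicit edit
operations → voxel counting. Everything that affects the output is either
an image, a recorded parameter, or a recorded rater action, so a run is
exactly reproducible from its provenance record; the only irreducible
variability in practice is the human input, which is what the agreement
statistics quantify.

All computation is lattice-based: voxel coordinates are 0-based array
indices, world/affine coordinates are carried as metadata only, and no
stage resamples. Grid consistency (shape and spacing) is enforced at every
module boundary.

## Vesselness stage

The filter is the standard two-eigenvalue single-scale 2D vesselness
evaluated on the Gaussian-smoothed Hessian of each slice, with the
dark-polarity gate λ₂ > 0 (intensity minima across the structure). Choices
that matter:

- **Scale σ = 1 in-plane voxel**, the regime matched to cSS bands of
  roughly 1–3 voxel thickness. σ is specified in voxel units, not mm:
  filtering is two-dimensional, so through-plane anisotropy is irrelevant.
- **Slice axis**: 2D filtering runs perpendicular to the through-plane
  axis, which defaults to the axis of coarsest spacing (1 mm on a
  0.6 × 0.6 × 1 mm grid, i.e. the acquisition slice direction) and can be
  overridden; the NIfTI header does not record the acquisition orientation
  reliably.
- **β = 0.5**, the conventional blobness sensitivity.
- **c**: when unset, resolved per slice as half the maximum Hessian
  Frobenius norm of that slice — the conventional automatic structureness
  normalisation. A fixed c can be supplied instead (and is what the
  contrast-monotonicity property is stated against, since auto-c
  normalises global contrast away).
- **γ = 2 scale normalisation** (second derivatives multiplied by σ²).
  With a single scale this only rescales the effective c, but it keeps c
  commensurable if σ is changed.
- **Threshold 0.30 on the normalised score.** Calibrated against the
  analytic noise-free response of dark bands at σ = 1 with auto-c: band
  interiors score ≈ 0.75–0.87, the edge rows of a 3-voxel band ≈ 0.47, and
  the first row outside any band has λ₂ < 0 and scores exactly 0. A cut at
  0.30 therefore captures the full 1–3 voxel regime with a symmetric
  margin in both directions; it is exposed as a flag because the optimal
  cut depends on sequence and post-processing.
- **Numerical details**: Gaussian derivatives use mirror-reflected
  boundaries (no spurious edge ridges), a wide kernel truncation (8σ), and
  the slice mean is subtracted first, which makes the response exactly
  invariant to a global intensity offset — a constant slice yields an
  identically zero map even with truncated kernels.

## Region growing and edits

Growth is restricted to the thresholded vesselness mask; the grown result
is exactly the union over seeds of the 6-connected (faces-only) candidate
components containing each seed, so it is deterministic, order-independent
in the seed list, monotone in seeds, and always a subset of the candidate
mask. Connectivity is lattice adjacency regardless of anisotropic spacing.
Seeds falling outside the candidate mask warn and contribute nothing;
`strict_seeds` turns that into an error, and `snap_radius` instead snaps
such a seed to the nearest candidate voxel within a given radius (ties
break toward the lexicographically smallest coordinate).

False-positive correction is modelled as explicit edit operations —
component labels (components are labelled 1..n by descending size, ties by
smallest lexicographic voxel), voxel lists, and exclusion masks — rather
than an interactive GUI, so the inspect-and-correct step is reproducible
and logged. Exclusion masks are also the mechanical support for excluding
siderosis contiguous with a lobar hemorrhage; the radiological judgement
itself is out of scope. Edits only ever remove voxels and are idempotent.

Volume arithmetic is exact by construction: mm³ = count × dx·dy·dz, mL =
mm³/1000. NIfTI stores spacing as float32, so spacings are canonicalised
to six significant digits at read time; without this a 0.6 mm spacing
would round-trip as 0.60000002 and contaminate the volume arithmetic.

## Agreement statistics

The unit of agreement analysis is the per-subject volume (two sessions or
two raters), with voxel-level agreement summarised separately:

- Pearson r with the two-sided t-transform p (n − 2 df), and r² reported
  as r squared (the paired-plot quantity).
- **ICC(A,1)**: two-way random effects, absolute agreement, single
  measures — the only ICC form consistent with two raters rating each
  subject once. From the two-way mean squares (MSR subjects, MSC raters,
  MSE error), ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)); the
  95% CI and the p-value use the standard F-based procedure. Absolute
  agreement penalises systematic offsets: y = x + c has r = 1 but
  ICC < 1. The implementation is authored here because the available
  library rounds the CI to two decimals; its point estimate is
  cross-checked against pingouin in the tests.
- **Bland-Altman**: differences are session 1 − session 2; limits are
  mean ± 1.96 × sample SD (n − 1). Per-subject (mean, difference)
  coordinates are returned for plotting.
- **Dice** 2|A∩B|/(|A|+|B|) per subject, summarised as mean ± SD (the ±
  is explicitly SD). Dice of two empty masks is undefined and returns a
  flagged NaN rather than an arbitrary 0 or 1, so cohort means cannot be
  silently corrupted.

Degenerate inputs raise explicit errors: zero-variance series for Pearson,
fewer than 3 subjects or constant identical ratings for ICC.

## The phantom generator

The generator emulates the inputs the pipeline consumes, not MR physics.
A phantom is a bright uniform parenchyma (default 100) on the
0.6 × 0.6 × 1 mm grid (default 128 × 128 × 40 voxels, a cropped cortical
field of view) containing:

- **Sulcal bands** — the cSS ground truth. Each synthetic sulcus is a wall
  running through-plane: within a slice it traces a straight dark segment
  of 1–3 voxel thickness, and its row position drifts sinusoidally across
  slices (amplitude 2 voxels, wavelength 20 slices, phases decorrelated by
  the golden angle). The drift never exceeds one row per slice, so every
  band is a single 6-connected 3D component reachable from one seed. The
  through-plane fold was a deliberate design choice: a sinusoid folded
  *within* the slice plane rasterises into staircase steps whose corner
  voxels the σ = 1 filter structurally cannot score (they sit inside
  locally 4-voxel-wide fills), capping noise-free recovery around 85–95%;
  folding through-plane is equally faithful to sulcal anatomy (sulci cut
  across axial slices), exercises the 3D grower, and leaves the in-slice
  cross-section exactly in the 1–3 voxel regime. In-plane curvature
  robustness of the filter is exercised separately with oblique
  smooth-profile tubes in the tests.
- **Band intensity**: a crisp drop of 60 below background (sharp edges,
  as partial-volume-limited siderosis bands effectively present at this
  resolution). Default noise SD 5 gives contrast-to-noise 12.
- **Veins** — straight in-plane dark tubes (drop 45, thickness 1) placed
  in a reserved margin away from the ribbon: genuine filter targets that
  must be removed by edits, never touching the bands.
- **Noise** — additive Gaussian, an adequate approximation of magnitude
  noise at 3T SWI SNR. No Rician floor, no phase data, no susceptibility
  dipoles, no hemorrhages.

Severity is parameterised by total band volume, the quantity the tool
measures. The cohort planner fills whole sulci first (thickness cycling
2, 1, 3), then trims the last band by slices and columns, landing within a
few voxels above each target; default cohorts span 0.5–15 mL, bracketing
the severity spread reported for patients with severe multifocal cSS. All
generators are pure functions of their spec and seed.

### The simulated rater

A rating session mirrors the semi-automatic workflow: the rater seeds every
visible dark tubular structure (the suggested cSS seeds, displaced
uniformly within a jitter ball and snapped back to the nearest candidate
voxel — a rater always clicks on visible candidate voxels), grows with a
slightly perturbed threshold, then removes each grown vein component
during visual correction, forgetting each with the edit-omission
probability. With zero perturbation the session reproduces the unperturbed
pipeline exactly. Defaults: jitter radius 2 voxels, threshold jitter
±0.05, omission 0.1.

## What passing tests do and do not show

The phantom experiments demonstrate that the pipeline recovers known
ground truth under its design conditions (thin dark bands at
contrast-to-noise ≥ 5 on a clean background) and that the reliability
machinery reproduces the qualitative signature of semi-automatic
segmentation — near-perfect volume agreement (ICC > 0.99) alongside
imperfect voxel overlap (Dice < 1). They do not show performance on real
SWI: real cortex has texture, vessels interdigitate with sulci, siderosis
contrast varies with field strength, sequence and post-processing, and
human seed placement varies far more than the simulated jitter. The
simulated between-session Dice (≈ 0.99) is accordingly much higher than
what trained raters achieve on patients (reported around 0.75), because
the phantom's candidate mask is nearly unambiguous. Thresholds calibrated
here should be re-calibrated per acquisition protocol before any clinical
use.

## Problem sizes

Default experiment sizes were chosen so the whole suite runs interactively:
a 128 × 128 × 40 grid (≈ 0.65 M voxels), 20-phantom cohorts, 100 random
masks for the region-growing oracle, 50 random series for the statistics
oracles, 10 000 samples for the Bland-Altman coverage check. The full test
suite runs in about half a minute; the acceptance script in under 20
seconds.
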