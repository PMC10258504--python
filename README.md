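# siderseg

Semi-automatic segmentation and quantification of **cortical superficial
siderosis (cSS)** on susceptibility-weighted MRI (SWI).

cSS — hemosiderin deposited in the subpial space, typically after convexity
subarachnoid hemorrhage in cerebral amyloid angiopathy (CAA) — appears on
SWI as a thin hypointense band following the outer layer of the cortex.
Clinically it is scored on a coarse 0–4 visual multifocality scale, which
saturates in severe disease and is blind to subtle progression. `siderseg`
implements the quantitative alternative: measure the *volume* of cSS with a
semi-automatic pipeline, and provide the statistical machinery to assess
how reproducible that measurement is within and between raters.

The package is aimed at neuroimaging researchers; it is a library first
(`import siderseg`) with a thin `siderseg` command-line wrapper, and it
ships a synthetic phantom generator so the entire pipeline and the full
agreement analysis run end-to-end with known ground truth and no data
downloads.

## The pipeline

1. **Vesselness enhancement** — every slice along the through-plane axis is
   filtered with a single-scale 2D Hessian vesselness at σ = 1 in-plane
   voxel. With eigenvalues |λ₁| ≤ |λ₂| of the Gaussian-smoothed Hessian
   (γ = 2 scale-normalised), the dark-polarity score is

   V = exp(−R_b² / 2β²) · (1 − exp(−S² / 2c²)),  λ₂ > 0, else 0,

   where R_b = λ₁/λ₂ (blobness), S = √(λ₁² + λ₂²) (structureness),
   β = 0.5, and c defaults to half the maximum Hessian Frobenius norm of
   the slice. The λ₂ > 0 gate selects *hypointense* tubular structures —
   cSS bands, but also cortical veins.
2. **Thresholding** — scores above a cut-off (default 0.30) form the
   candidate mask.
3. **Seeded 3D region growing** — from rater-placed seed voxels, membership
   spreads through face-adjacent (6-neighborhood) candidate voxels; the
   result is exactly the union of candidate components containing seeds.
4. **False-positive editing** — veins and other confounders are removed by
   explicit, logged edit operations (component labels, voxel lists,
   exclusion masks — e.g. around a lobar hemorrhage).
5. **Quantification** — volume = voxel count × voxel volume; at the
   0.6 × 0.6 × 1 mm acquisition grid, 1000 voxels = 0.36 mL.

Agreement between rating sessions is assessed on the volume level with
Pearson r (and r²), the two-way random-effects absolute-agreement
single-measures intraclass correlation ICC(A,1) with F-based 95% CI, and
Bland-Altman limits of agreement (mean difference ± 1.96 SD), and on the
voxel level with the Dice similarity coefficient
DSC = 2|A∩B| / (|A|+|B|).

## Worked example

`examples/segment_phantom.py` builds a phantom with two dark sulcal bands
plus vein confounders and segments it:

```
true cSS volume      : 7.004 mL
measured cSS volume  : 6.945 mL
voxels segmented     : 19292
connected components : 2
volume error         : -0.84 %
```

The measured volume lands within one percent of the exact ground truth:
the thresholded vesselness response covers the bands almost exactly, and
region growing keeps only the two seeded structures while the veins stay
out. `examples/rater_agreement.py` runs two simulated rating sessions over
a 12-phantom cohort:

```
n subjects      : 12
Pearson r       : 0.9996  (r^2 = 0.9993)
ICC(A,1)        : 0.9995  95% CI (0.9984, 0.9999)
Bland-Altman    : -0.046 mL (LoA -0.322 to +0.230)
Dice            : 0.987 +- 0.022 (SD)
```

Note the characteristic dissociation of semi-automatic segmentation: the
total volume is almost perfectly reproducible (ICC ≈ 1) even though the
sessions do not select exactly the same voxels (Dice < 1).
`examples/longitudinal_change.py` shows the follow-up use case: measured
volume change separates progressing from stable subjects.

## Command line

```sh
siderseg phantom --rng-seed 3 -o vol.nii.gz --truth truth.nii.gz --seeds seeds.csv
siderseg vesselness vol.nii.gz --threshold 0.3 -o map.nii.gz --mask candidate.nii.gz
siderseg segment vol.nii.gz --seeds seeds.csv --edits edits.json -o mask.nii.gz --report report.json
siderseg volume mask.nii.gz
siderseg agree session1.csv session2.csv --masks manifest.csv -o agreement.json
siderseg change baseline.csv followup.csv
siderseg cohort -n 20 -o cohort_dir
siderseg replay mask.nii.gz.provenance.json
```

Volumes and masks are NIfTI-1; seeds are CSV (`i,j,k`, 0-based voxel
indices) or JSON; volume tables are CSV (`subject_id,volume_ml`); reports
are JSON. Every output gets a `*.provenance.json` sidecar with all resolved
parameters, and `siderseg replay` reproduces a run from its sidecar alone.

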