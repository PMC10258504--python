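"""Synthetic SWI-like phantoms with exact cSS ground truth.

Real inputs to the segmentation tool are susceptibility-weighted volumes in
which superficial siderosis forms a hypointense band of roughly 1-3 voxel
thickness following the folded cortical ribbon, alongside confounding dark
tubular structures (cortical veins). No such data ship with the package, so
this module generates the study conditions synthetically:

* a bright uniform background (parenchyma);
* a set of synthetic *sulci* — sulcal walls running through-plane, so that
  each slice shows a straight dark in-plane segment whose position drifts
  sinusoidally from slice to slice (the folded ribbon) — of which a chosen
  subset carries a dark *band* of given thickness and contrast (the cSS
  ground truth);
* straight dark *veins* placed in a reserved region away from the ribbon,
  acting as false-positive confounders exactly as veins do on real SWI;
* additive Gaussian noise (an adequate approximation of magnitude noise at
  the SNR of 3T SWI).

Bands are rasterised with column-bridging fills so every band is a single
6-connected component: one seed per band suffices for region growing.
Severity is parameterised by total band volume, the quantity the tool
measures; :func:`generate_cohort` produces cohorts whose true volumes span
a requested range. All generators are pure functions of their spec and
seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import SeedSet, SegmentationMask, SwiVolume
from .segmentation import (
    EditSet,
    VolumeReport,
    apply_edits,
    connected_components_6n,
    quantify_volume,
    region_grow_6n,
)
from .vesselness import VesselnessParams, threshold_map, vesselness_volume

__all__ = [
    "BandSpec",
    "VeinSpec",
    "PhantomSpec",
    "PhantomTruth",
    "RaterPerturbation",
    "generate_phantom",
    "generate_cohort",
    "simulate_rater",
]

_GOLDEN_ANGLE = 2.399963229728653  # decorrelates sulcus fold phases


@dataclass(frozen=True)
class BandSpec:
    """One hypointense sulcal band (a cSS ground-truth element).

    ``extent`` is the fraction of the sulcus (its slice span) the band
    covers. ``n_slices`` / ``last_slice_cols`` override ``extent`` with an
    explicit slice count and a column truncation of the topmost slice; the
    cohort planner uses them for fine volume control.
    """

    sulcus: int
    thickness: int = 2
    contrast: float = 60.0
    extent: float = 1.0
    n_slices: int | None = None
    last_slice_cols: int | None = None

    def __post_init__(self):
        if self.thickness < 1:
            raise ValueError("band thickness must be >= 1 voxel")
        if not 0.0 < self.extent <= 1.0:
            raise ValueError("band extent fraction must lie in (0, 1]")
        if not self.contrast > 0:
            raise ValueError("band intensity drop (contrast) must be > 0")


@dataclass(frozen=True)
class VeinSpec:
    """Straight in-plane dark tubes acting as false-positive confounders."""

    count: int = 3
    contrast: float = 45.0
    thickness: int = 1
    length: int = 40
    n_slices: int = 6


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic SWI volume.

    Defaults copy the acquisition grid of high-resolution 3T SWI
    (0.6 x 0.6 x 1 mm voxels) on a cropped cortical field of view, with
    band contrast 60 over noise SD 5 (contrast-to-noise 12).
    """

    shape: tuple[int, int, int] = (128, 128, 40)
    spacing: tuple[float, float, float] = (0.6, 0.6, 1.0)
    background: float = 100.0
    n_sulci: int = 8
    fold_amplitude: float = 2.0
    fold_wavelength: float = 20.0
    css_bands: tuple[BandSpec, ...] = (BandSpec(sulcus=0),)
    veins: VeinSpec = field(default_factory=VeinSpec)
    noise_sigma: float = 5.0
    rng_seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.shape):
            raise ValueError("phantom grid must be at least 8 voxels per axis")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_sulci < 1:
            raise ValueError("need at least one sulcus")
        if self.fold_amplitude * 2 * math.pi / self.fold_wavelength > 1.0:
            raise ValueError(
                "fold too steep: through-plane drift must stay below one "
                "row per slice to keep bands 6-connected"
            )
        gap = self._sulcus_gap()
        for b in self.css_bands:
            if not 0 <= b.sulcus < self.n_sulci:
                raise ValueError(f"band names sulcus {b.sulcus}, have {self.n_sulci}")
            if b.thickness + 2 * self.fold_amplitude >= gap:
                raise ValueError(
                    f"band thickness {b.thickness} does not fit the fold "
                    f"geometry (sulcus gap {gap:.1f} voxels)"
                )

    def _sulcus_offsets(self) -> np.ndarray:
        ny = self.shape[1]
        lo, hi = 16, ny - 12
        if self.n_sulci == 1:
            return np.array([(lo + hi) / 2.0])
        return np.linspace(lo, hi, self.n_sulci)

    def _sulcus_gap(self) -> float:
        off = self._sulcus_offsets()
        return float(off[1] - off[0]) if len(off) > 1 else float(self.shape[1])

    def centerline(self, sulcus: int) -> np.ndarray:
        """Row coordinate of the sulcal wall per slice (float, length nz).

        The wall is straight within each slice and drifts sinusoidally
        through-plane — the in-slice trace of a folded sulcus cutting
        across the slice stack. The drift per slice never exceeds one
        voxel row, which keeps every band 6-connected across slices.
        """
        nz = self.shape[2]
        z = np.arange(nz)
        phase = (sulcus * _GOLDEN_ANGLE) % (2 * math.pi)
        return (
            self._sulcus_offsets()[sulcus]
            + self.fold_amplitude
            * np.sin(2 * math.pi * z / self.fold_wavelength + phase)
        )


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom."""

    css_mask: SegmentationMask
    vein_mask: SegmentationMask
    true_volume_ml: float
    suggested_seeds: SeedSet

    def __post_init__(self):
        vox = self.css_mask.voxel_volume_mm3
        expect = self.css_mask.count() * vox / 1000.0
        if not math.isclose(self.true_volume_ml, expect, rel_tol=0, abs_tol=1e-12):
            raise ValueError("true_volume_ml inconsistent with css_mask")
        for s in self.suggested_seeds:
            if not self.css_mask.data[s]:
                raise ValueError(f"suggested seed {s} lies outside the truth mask")


def _band_rows(spec: PhantomSpec, band: BandSpec):
    """Per-slice row intervals of one band.

    Returns a list of (row_lo, row_hi) per slice. Within a slice the band
    is a straight horizontal segment of ``thickness`` rows centred on the
    rounded sulcal wall position. The drift between consecutive slices is
    at most one row, so for thickness >= 2 the intervals of neighbouring
    slices overlap and the band is 6-connected by itself; thickness-1
    slices additionally include the previous slice's row at drift steps
    (a brief 2-row segment) to bridge the diagonal.
    """
    yc = np.rint(spec.centerline(band.sulcus)).astype(int)
    h_lo = (band.thickness - 1) // 2
    h_hi = band.thickness // 2
    ny = spec.shape[1]
    rows = []
    for z in range(len(yc)):
        if band.thickness == 1 and z > 0:
            lo = min(yc[z], yc[z - 1]) - h_lo
            hi = max(yc[z], yc[z - 1]) + h_hi
        else:
            lo, hi = yc[z] - h_lo, yc[z] + h_hi
        rows.append((max(lo, 0), min(hi, ny - 1)))
    return rows


def _band_voxels(spec: PhantomSpec, band: BandSpec):
    """3D boolean mask of one band plus its suggested seed voxel."""
    nx, ny, nz = spec.shape
    rows = _band_rows(spec, band)
    if band.n_slices is not None:
        n_slices = band.n_slices
    else:
        n_slices = max(1, round(band.extent * nz))
    if not 1 <= n_slices <= nz:
        raise ValueError(f"band covers {n_slices} slices but grid has {nz}")
    vol = np.zeros(spec.shape, dtype=bool)
    for z in range(n_slices):
        lo, hi = rows[z]
        vol[:, lo : hi + 1, z] = True
    if band.last_slice_cols is not None and band.last_slice_cols < nx:
        vol[band.last_slice_cols :, :, n_slices - 1] = False
    # seed: wall voxel at mid-column of the bottom (always full) slice
    x_mid = nx // 2
    yc0 = int(np.rint(spec.centerline(band.sulcus)[0]))
    seed = (x_mid, yc0, 0)
    assert vol[seed], "wall-center seed must lie inside the band"
    return vol, seed


def _vein_voxels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Veins as straight in-plane tubes in the reserved top-row margin."""
    nx, ny, nz = spec.shape
    v = spec.veins
    mask = np.zeros(spec.shape, dtype=bool)
    for i in range(v.count):
        y = 4 + 3 * (i % 3)
        x0 = int(rng.integers(0, max(1, nx - v.length)))
        z0 = int(rng.integers(0, max(1, nz - v.n_slices)))
        mask[x0 : x0 + v.length, y : y + v.thickness, z0 : z0 + v.n_slices] = True
    return mask


def generate_phantom(spec: PhantomSpec):
    """Build one phantom volume and its exact ground truth.

    Deterministic given ``spec`` (including ``rng_seed``): the band
    geometry is purely parametric, the vein placement and the noise field
    are drawn from the seeded generator.
    """
    rng = np.random.default_rng(spec.rng_seed)
    css = np.zeros(spec.shape, dtype=bool)
    seeds, labels = [], []
    for idx, band in enumerate(spec.css_bands):
        voxels, seed = _band_voxels(spec, band)
        css |= voxels
        seeds.append(seed)
        labels.append(f"band-{idx}")
    veins = _vein_voxels(spec, rng)

    data = np.full(spec.shape, spec.background, dtype=np.float64)
    for band in spec.css_bands:
        voxels, _ = _band_voxels(spec, band)
        data[voxels] = spec.background - band.contrast
    data[veins] = spec.background - spec.veins.contrast
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    volume = SwiVolume(
        data=data, spacing=spec.spacing, slice_axis=2,
        meta={"source": "phantom", "rng_seed": spec.rng_seed},
    )
    css_mask = SegmentationMask(data=css, spacing=spec.spacing, slice_axis=2)
    truth = PhantomTruth(
        css_mask=css_mask,
        vein_mask=SegmentationMask(data=veins, spacing=spec.spacing, slice_axis=2),
        true_volume_ml=css_mask.count() * css_mask.voxel_volume_mm3 / 1000.0,
        suggested_seeds=SeedSet(seeds=seeds, labels=labels),
    )
    return volume, truth


_THICKNESS_CYCLE = (2, 1, 3)  # covers the 1-3 voxel regime across a cohort


def plan_bands(base_spec: PhantomSpec, target_ml: float) -> tuple[BandSpec, ...]:
    """Choose bands whose total voxel count reaches ``target_ml``.

    Whole sulci are filled first (thickness cycling through 2, 1, 3); the
    final band is trimmed to a slice count and a column cut so the achieved
    volume lands within a few voxels above the target.
    """
    vox_mm3 = float(np.prod(base_spec.spacing))
    target_vox = math.ceil(target_ml * 1000.0 / vox_mm3)
    nx, _, nz = base_spec.shape
    bands: list[BandSpec] = []
    remaining = target_vox
    for s in range(base_spec.n_sulci):
        if remaining <= 0:
            break
        band = BandSpec(sulcus=s, thickness=_THICKNESS_CYCLE[s % 3])
        rows = _band_rows(base_spec, band)
        slice_counts = np.array([nx * (hi - lo + 1) for lo, hi in rows])
        total = int(slice_counts.sum())
        if remaining >= total:
            bands.append(replace(band, extent=1.0))
            remaining -= total
            continue
        cum = np.cumsum(slice_counts)
        n_slices = int(np.searchsorted(cum, remaining) + 1)
        covered = int(cum[n_slices - 2]) if n_slices > 1 else 0
        rem = remaining - covered
        rows_last = rows[n_slices - 1][1] - rows[n_slices - 1][0] + 1
        n_cols = math.ceil(rem / rows_last)
        if n_cols >= nx:
            bands.append(replace(band, n_slices=n_slices))
        else:
            bands.append(
                replace(band, n_slices=n_slices, last_slice_cols=n_cols)
            )
        remaining = 0
    if remaining > 0:
        raise ValueError(
            f"target volume {target_ml} mL exceeds what the fold geometry "
            f"of this grid can carry"
        )
    return tuple(bands)


def generate_cohort(
    n: int = 20,
    severity_range: tuple[float, float] = (0.5, 15.0),
    base_spec: PhantomSpec | None = None,
    rng_seed: int = 0,
):
    """A cohort of phantoms whose true volumes span ``severity_range`` (mL).

    Targets are spaced linearly across the range (kept a small margin below
    the upper end so the few-voxel planner overshoot never exceeds it).
    Per-phantom noise/vein seeds derive deterministically from ``rng_seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    lo, hi = severity_range
    if not 0 < lo < hi:
        raise ValueError("severity range must satisfy 0 < low < high")
    hi_eff = hi - min(0.05, 0.1 * (hi - lo))
    targets = np.linspace(lo, hi_eff, n) if n > 1 else np.array([0.5 * (lo + hi_eff)])
    child_seeds = np.random.default_rng(rng_seed).integers(0, 2**31 - 1, size=n)
    cohort = []
    for i in range(n):
        spec = replace(
            base_spec,
            css_bands=plan_bands(base_spec, float(targets[i])),
            rng_seed=int(child_seeds[i]),
        )
        cohort.append(generate_phantom(spec))
    return cohort


@dataclass(frozen=True)
class RaterPerturbation:
    """How a simulated rating session deviates from the ideal run.

    seed_jitter
        Max per-axis displacement (voxels) of each placed seed; jittered
        seeds snap back to the nearest candidate voxel within the same
        radius, modelling a rater who always clicks on visible candidate
        voxels near the intended spot.
    threshold_jitter
        Half-width of the uniform perturbation of the vesselness threshold.
    edit_omission
        Probability that an individual vein false positive is *not*
        removed during visual correction.
    """

    seed_jitter: int = 2
    threshold_jitter: float = 0.05
    edit_omission: float = 0.1

    def __post_init__(self):
        if self.seed_jitter < 0 or self.threshold_jitter < 0:
            raise ValueError("jitters must be >= 0")
        if not 0.0 <= self.edit_omission <= 1.0:
            raise ValueError("edit_omission must be a probability")


def simulate_rater(
    truth: PhantomTruth,
    volume: SwiVolume,
    params: VesselnessParams | None = None,
    perturbation: RaterPerturbation | None = None,
    rng_seed: int = 0,
) -> tuple[SegmentationMask, VolumeReport]:
    """One simulated rating session through the real pipeline.

    The session mirrors the semi-automatic workflow: the rater seeds every
    visible dark tubular structure (the suggested cSS seeds, jittered, plus
    the vein confounders), grows the mask, then removes each grown vein
    component during visual correction — omitting each with probability
    ``edit_omission``. Deterministic given ``rng_seed``; with zero
    perturbation it reproduces the unperturbed pipeline exactly.
    """
    if params is None:
        params = VesselnessParams()
    if perturbation is None:
        perturbation = RaterPerturbation()
    rng = np.random.default_rng(rng_seed)
    shape = volume.shape

    band_seeds = []
    r = perturbation.seed_jitter
    for s in truth.suggested_seeds:
        if r > 0:
            # uniform over integer offsets within the Euclidean jitter ball,
            # so the displaced click stays within snapping range of the
            # intended (candidate) voxel
            while True:
                off = rng.integers(-r, r + 1, size=3)
                if (off**2).sum() <= r**2:
                    break
            s = tuple(
                int(np.clip(c + o, 0, n - 1)) for c, o, n in zip(s, off, shape)
            )
        band_seeds.append(s)

    threshold = params.threshold
    if perturbation.threshold_jitter > 0:
        threshold = float(
            np.clip(
                threshold + rng.uniform(-perturbation.threshold_jitter,
                                        perturbation.threshold_jitter),
                0.0, 1.0,
            )
        )

    vein_comps = connected_components_6n(truth.vein_mask)
    vein_reprs = [
        tuple(int(c) for c in vein_comps.voxels_of(lab)[0])
        for lab in range(1, vein_comps.n + 1)
    ]

    vmap = vesselness_volume(volume, params)
    candidate = threshold_map(vmap, threshold)
    all_seeds = SeedSet(seeds=band_seeds + vein_reprs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # jittered seeds may need snapping
        grown = region_grow_6n(
            candidate, all_seeds,
            snap_radius=max(1, perturbation.seed_jitter),
        )

    comps = connected_components_6n(grown)
    remove: list[int] = []
    for lab in range(1, vein_comps.n + 1):
        omit = (
            perturbation.edit_omission > 0
            and rng.uniform() < perturbation.edit_omission
        )
        if omit:
            continue
        vein_voxels = vein_comps.voxels_of(lab)
        labels_here = np.unique(comps.labels[tuple(vein_voxels.T)])
        remove.extend(int(l) for l in labels_here if l > 0)
    remove = sorted(set(remove))
    final = apply_edits(grown, EditSet(remove_components=remove))
    return final, quantify_volume(final)
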