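"""Reliability and agreement statistics for paired segmentations and volumes.

Two raters (or one rater on two occasions) each produce a cSS volume per
subject plus a voxel mask. Agreement is assessed on two levels:

* volume level — Pearson r (with r^2), the two-way random-effects
  absolute-agreement single-measures intraclass correlation ICC(A,1) with
  its 95% F-based confidence interval, and Bland-Altman limits of agreement
  (mean difference +/- 1.96 SD of the paired differences);
* voxel level — the Dice similarity coefficient
  DSC = 2 |A ∩ B| / (|A| + |B|) per subject, summarised as mean +/- SD.

Absolute agreement penalises systematic offsets between raters: for
``y = x + c`` with ``c != 0`` the Pearson r is 1 while ICC(A,1) < 1.

The difference direction throughout is ``x - y`` (session 1 - session 2,
or rater 1 - rater 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .io import SegmentationMask, check_same_grid

__all__ = [
    "RatingSeries",
    "AgreementReport",
    "BlandAltmanResult",
    "IccResult",
    "BothEmptyDiceWarning",
    "dice",
    "pearson",
    "icc_absolute_agreement",
    "bland_altman",
    "agreement_report",
    "volume_change",
]


class BothEmptyDiceWarning(UserWarning):
    """Dice of two empty masks is undefined; NaN is returned."""


@dataclass
class RatingSeries:
    """Per-subject cSS volumes from one rating session."""

    subject_ids: list[str]
    volumes_ml: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        if len(self.subject_ids) != len(self.volumes_ml):
            raise ValueError("subject_ids and volumes_ml must be co-indexed")
        if not np.isfinite(self.volumes_ml).all():
            raise ValueError("volumes must be finite")
        if (self.volumes_ml < 0).any():
            raise ValueError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.subject_ids)


def _paired(x: RatingSeries, y: RatingSeries):
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if x.subject_ids != y.subject_ids:
        raise ValueError("series must be co-indexed by identical subject ids")
    return x.volumes_ml, y.volumes_ml


def dice(a: SegmentationMask, b: SegmentationMask) -> float:
    """Dice similarity coefficient ``2 |A ∩ B| / (|A| + |B|)``.

    Symmetric and in [0, 1]. When both masks are empty the coefficient is
    undefined; NaN is returned with a :class:`BothEmptyDiceWarning` rather
    than an arbitrary 0 or 1, so cohort means are not silently corrupted.
    """
    check_same_grid(a, b, what="dice operand")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        warnings.warn(
            "Dice of two empty masks is undefined (both-empty)",
            BothEmptyDiceWarning,
            stacklevel=2,
        )
        return float("nan")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def pearson(x: RatingSeries, y: RatingSeries):
    """Sample Pearson correlation with two-sided p (t transform, n-2 df).

    Returns ``(r, p, r_squared)``; ``r_squared`` is ``r**2``, the quantity
    shown in paired correlation plots of two-session volumes.
    """
    xs, ys = _paired(x, y)
    if len(xs) < 3:
        raise ValueError("Pearson correlation with a p-value needs n >= 3")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance in a series: correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), float(r) ** 2


class IccResult(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float
    p: float


def _two_way_mean_squares(xs: np.ndarray, ys: np.ndarray):
    """Row/column/error mean squares of the n x 2 two-way layout."""
    data = np.column_stack([xs, ys])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc_absolute_agreement(
    x: RatingSeries, y: RatingSeries, alpha: float = 0.05
) -> IccResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    With n subjects and k = 2 raters,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    from the two-way mean squares (MSR rows/subjects, MSC columns/raters,
    MSE error). The confidence interval and the p-value (H0: ICC = 0,
    F = MSR/MSE on (n-1, (n-1)(k-1)) df) follow the standard F-based
    procedure for this ICC form.
    """
    xs, ys = _paired(x, y)
    n = len(xs)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    n, k, msr, msc, mse = _two_way_mean_squares(xs, ys)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise ValueError(
            "all ratings identical and constant: ICC undefined (no variance)"
        )
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # perfect agreement: degenerate F's, interval collapses
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, p=0.0)

    f_obs = msr / mse if mse > 0 else np.inf
    p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))

    # Satterthwaite df for the absolute-agreement interval
    r = icc
    if r >= 1.0:
        return IccResult(icc=float(icc), ci_low=1.0, ci_high=1.0, p=p)
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return IccResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high), p=p)


class BlandAltmanResult(NamedTuple):
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(x: RatingSeries, y: RatingSeries) -> BlandAltmanResult:
    """Bland-Altman limits of agreement for paired volume measurements.

    Differences are ``d_i = x_i - y_i``; limits are ``mean(d) +/- 1.96 sd(d)``
    with the sample SD (n-1 denominator). The per-subject (mean, diff)
    coordinates are returned for plotting.
    """
    xs, ys = _paired(x, y)
    if len(xs) < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    diffs = xs - ys
    means = 0.5 * (xs + ys)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        means=means,
        diffs=diffs,
    )


@dataclass
class AgreementReport:
    """Aggregated paired-series agreement statistics."""

    n: int
    pearson_r: float
    pearson_p: float
    r_squared: float
    icc: float
    icc_ci95: tuple[float, float]
    icc_p: float
    ba_mean_diff: float
    ba_sd_diff: float
    ba_loa: tuple[float, float]
    diff_direction: str = "x - y (session1 - session2)"
    mean_dsc: float | None = None
    sd_dsc: float | None = None
    per_subject_dsc: list[float] | None = None

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "r_squared": self.r_squared,
            "icc": self.icc,
            "icc_ci95": list(self.icc_ci95),
            "icc_p": self.icc_p,
            "ba_mean_diff": self.ba_mean_diff,
            "ba_sd_diff": self.ba_sd_diff,
            "ba_loa": list(self.ba_loa),
            "diff_direction": self.diff_direction,
        }
        if self.mean_dsc is not None:
            out["mean_dsc"] = self.mean_dsc
            out["sd_dsc"] = self.sd_dsc
            out["per_subject_dsc"] = self.per_subject_dsc
        return out


def agreement_report(
    x: RatingSeries,
    y: RatingSeries,
    masks_x: Sequence[SegmentationMask] | None = None,
    masks_y: Sequence[SegmentationMask] | None = None,
) -> AgreementReport:
    """Full reproducibility analysis over two rating sessions.

    When co-indexed mask lists are supplied, per-subject Dice coefficients
    are added with their mean and sample SD (SD is what the +/- denotes).
    """
    _paired(x, y)
    r, p, r2 = pearson(x, y)
    icc = icc_absolute_agreement(x, y)
    ba = bland_altman(x, y)
    report = AgreementReport(
        n=len(x),
        pearson_r=r,
        pearson_p=p,
        r_squared=r2,
        icc=icc.icc,
        icc_ci95=(icc.ci_low, icc.ci_high),
        icc_p=icc.p,
        ba_mean_diff=ba.mean_diff,
        ba_sd_diff=ba.sd_diff,
        ba_loa=(ba.loa_low, ba.loa_high),
    )
    if masks_x is not None or masks_y is not None:
        if masks_x is None or masks_y is None or len(masks_x) != len(masks_y):
            raise ValueError("mask lists must both be given and co-indexed")
        if len(masks_x) != len(x):
            raise ValueError("mask lists must be co-indexed with the series")
        dscs = [dice(a, b) for a, b in zip(masks_x, masks_y)]
        arr = np.asarray(dscs, dtype=float)
        report.per_subject_dsc = [float(d) for d in dscs]
        report.mean_dsc = float(np.nanmean(arr))
        report.sd_dsc = float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else 0.0
    return report


def volume_change(baseline: RatingSeries, followup: RatingSeries):
    """Per-subject longitudinal change: ``delta = followup - baseline``.

    Returns a list of dicts with ``delta_ml`` and ``delta_percent``
    (relative to baseline; flagged undefined when baseline is 0).
    """
    if baseline.subject_ids != followup.subject_ids:
        raise ValueError("baseline and follow-up must pair identical subject ids")
    out = []
    for sid, b, f in zip(baseline.subject_ids, baseline.volumes_ml, followup.volumes_ml):
        delta = float(f - b)
        entry = {"subject_id": sid, "baseline_ml": float(b), "followup_ml": float(f),
                 "delta_ml": delta}
        if b == 0:
            entry["delta_percent"] = None
            entry["percent_undefined"] = True
        else:
            entry["delta_percent"] = 100.0 * delta / float(b)
            entry["percent_undefined"] = False
        out.append(entry)
    return out
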