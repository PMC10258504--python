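"""Agreement statistics against independent from-the-definition oracles."""

import math

import numpy as np
import pytest

from siderseg import (
    RatingSeries,
    SegmentationMask,
    agreement_report,
    bland_altman,
    dice,
    icc_absolute_agreement,
    pearson,
    volume_change,
)
from siderseg.metrics import BothEmptyDiceWarning


def _mask_of(coords, shape=(4, 4, 4)):
    data = np.zeros(shape, bool)
    for c in coords:
        data[c] = True
    return SegmentationMask(data, spacing=(1, 1, 1))


def _series(values, ids=None):
    values = list(values)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return RatingSeries(ids, np.asarray(values, float))


# ---------------------------------------------------------------- oracles

def oracle_pearson(x, y):
    """Pearson r from explicit covariance/variance sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def oracle_icc_a1(x, y):
    """ICC(A,1) from explicit two-way ANOVA sums of squares (loops)."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = sum(data[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(data[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(data[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def oracle_loa(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    m = d.sum() / len(d)
    sd = math.sqrt(((d - m) ** 2).sum() / (len(d) - 1))
    return m - 1.96 * sd, m + 1.96 * sd


# ------------------------------------------------------------------ dice

class TestDice:
    def test_identical_masks_score_one(self):
        m = _mask_of([(0, 0, 0), (1, 1, 1)])
        assert dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        assert dice(_mask_of([(0, 0, 0)]), _mask_of([(1, 1, 1)])) == 0.0

    def test_half_overlap_case(self):
        a = _mask_of([(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)])
        b = _mask_of([(0, 0, 2), (0, 0, 3), (0, 1, 0), (0, 1, 1)])
        assert dice(a, b) == pytest.approx(2 * 2 / (4 + 4))

    def test_symmetry_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = SegmentationMask(rng.random((5, 5, 5)) < 0.4, spacing=(1, 1, 1))
            b = SegmentationMask(rng.random((5, 5, 5)) < 0.4, spacing=(1, 1, 1))
            d = dice(a, b)
            assert d == dice(b, a) and 0.0 <= d <= 1.0

    def test_both_empty_is_flagged_nan(self):
        empty = _mask_of([])
        with pytest.warns(BothEmptyDiceWarning):
            assert math.isnan(dice(empty, empty))


# --------------------------------------------------------------- pearson

class TestPearson:
    def test_perfect_positive_relation(self):
        x = _series([1, 2, 3, 4])
        r, p, r2 = pearson(x, x)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        x = _series([1, 2, 3, 4])
        y = _series([4, 3, 2, 1])
        assert pearson(x, y)[0] == pytest.approx(-1.0)

    def test_fixed_series_matches_definition_oracle(self):
        xv = [2.7, 5.1, 8.0, 11.4, 13.2, 14.3]
        yv = [2.9, 4.8, 8.4, 11.0, 13.5, 14.1]
        r, _, r2 = pearson(_series(xv), _series(yv))
        assert r == pytest.approx(oracle_pearson(xv, yv), abs=1e-12)
        assert r2 == pytest.approx(r * r, abs=1e-15)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(_series([1, 1, 1]), _series([1, 2, 3]))


# ------------------------------------------------------------------- icc

class TestIcc:
    def test_identical_nonconstant_series_gives_one(self):
        x = _series([1.0, 2.0, 5.0, 9.0])
        res = icc_absolute_agreement(x, x)
        assert res.icc == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_constant_shift_penalised_while_pearson_is_not(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            base = rng.uniform(1, 10, size=8)
            x = _series(base)
            y = _series(base + 2.0)
            assert icc_absolute_agreement(x, y).icc < 1.0
            assert pearson(x, y)[0] == pytest.approx(1.0)

    def test_five_subject_table_matches_anova_oracle(self):
        xv = [9.1, 4.2, 7.7, 10.3, 6.0]
        yv = [8.8, 4.9, 7.2, 10.9, 6.3]
        res = icc_absolute_agreement(_series(xv), _series(yv))
        assert res.icc == pytest.approx(oracle_icc_a1(xv, yv), abs=1e-10)

    def test_matches_pingouin_estimate(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        xv = rng.uniform(0.5, 15, size=12)
        yv = xv + rng.normal(0, 0.4, size=12)
        res = icc_absolute_agreement(_series(xv), _series(yv))
        df = pd.DataFrame(
            {
                "s": list(range(12)) * 2,
                "r": ["a"] * 12 + ["b"] * 12,
                "v": np.r_[xv, yv],
            }
        )
        tab = pingouin.intraclass_corr(df, targets="s", raters="r", ratings="v")
        row = tab[tab["Type"] == "ICC2"]
        if row.empty:
            row = tab[tab["Type"] == "ICC(A,1)"]
        assert res.icc == pytest.approx(float(row["ICC"].iloc[0]), abs=1e-8)
        lo, hi = row["CI95"].iloc[0] if "CI95" in row else row["CI95%"].iloc[0]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)
        assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        xv = rng.uniform(0.5, 15, size=10)
        yv = xv + rng.normal(0, 1.0, size=10)
        res = icc_absolute_agreement(_series(xv), _series(yv))
        assert res.ci_low <= res.icc <= res.ci_high <= 1.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(_series([1, 2]), _series([1, 2]))

    def test_constant_identical_data_is_degenerate(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(_series([3, 3, 3]), _series([3, 3, 3]))


# ---------------------------------------------------------- bland-altman

class TestBlandAltman:
    def test_identical_series_zero_limits(self):
        x = _series([1, 2, 3])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.sd_diff == 0
        assert ba.loa_low == ba.loa_high == 0

    def test_constant_offset(self):
        x = _series([3, 4, 5])
        y = _series([1, 2, 3])
        ba = bland_altman(x, y)
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.sd_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_four_pair_series_matches_hand_computation(self):
        xv, yv = [2.0, 5.5, 9.1, 12.0], [2.4, 5.0, 9.9, 11.4]
        ba = bland_altman(_series(xv), _series(yv))
        lo, hi = oracle_loa(xv, yv)
        assert ba.loa_low == pytest.approx(lo, abs=1e-12)
        assert ba.loa_high == pytest.approx(hi, abs=1e-12)

    def test_limits_cover_about_95pct_of_normal_differences(self):
        rng = np.random.default_rng(4)
        n = 10_000
        base = rng.uniform(5, 15, size=n)
        diffs = rng.normal(0.0, 0.5, size=n)
        x = _series(base + diffs)
        y = _series(base)
        ba = bland_altman(x, y)
        inside = ((ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high)).mean()
        assert 0.94 <= inside <= 0.96


# -------------------------------------------------------------- reports

class TestAgreementReport:
    def test_identical_sessions_perfect_agreement(self):
        x = _series([1.0, 4.0, 9.0])
        masks = [_mask_of([(0, 0, 0)]), _mask_of([(1, 1, 1)]), _mask_of([(2, 2, 2)])]
        rep = agreement_report(x, x, masks, masks)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.icc == 1.0
        assert rep.mean_dsc == 1.0
        assert rep.ba_loa == (0.0, 0.0)

    def test_statistics_recomputed_by_oracles_after_swap(self):
        xv = [2.7, 5.1, 8.0, 11.4, 14.3]
        yv = [2.9, 4.8, 8.4, 11.0, 14.1]
        # swap one pair between sessions
        xv2, yv2 = list(xv), list(yv)
        xv2[2], yv2[2] = yv[2], xv[2]
        rep = agreement_report(_series(xv2), _series(yv2))
        assert rep.pearson_r == pytest.approx(oracle_pearson(xv2, yv2), abs=1e-10)
        assert rep.icc == pytest.approx(oracle_icc_a1(xv2, yv2), abs=1e-10)
        assert rep.ba_loa == pytest.approx(oracle_loa(xv2, yv2), abs=1e-10)

    def test_masks_omitted_means_no_dsc_fields(self):
        x = _series([1.0, 2.0, 3.0])
        y = _series([1.1, 2.1, 3.3])
        rep = agreement_report(x, y)
        assert rep.mean_dsc is None
        assert "mean_dsc" not in rep.to_dict()


class TestVolumeChange:
    def test_identical_series_all_zero(self):
        x = _series([1, 2, 3])
        assert all(d["delta_ml"] == 0 for d in volume_change(x, x))

    def test_fifty_percent_increase(self):
        out = volume_change(_series([2.0]), _series([3.0]))
        assert out[0]["delta_ml"] == pytest.approx(1.0)
        assert out[0]["delta_percent"] == pytest.approx(50.0)

    def test_zero_baseline_flagged(self):
        out = volume_change(_series([0.0]), _series([1.0]))
        assert out[0]["percent_undefined"] and out[0]["delta_ml"] == 1.0

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError):
            volume_change(_series([1], ids=["a"]), _series([1], ids=["b"]))
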