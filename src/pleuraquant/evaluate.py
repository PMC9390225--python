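"""Agreement and diagnostic-accuracy statistics.

Covers everything the pipeline reports: Dice overlap of segmentations,
confusion-matrix diagnostics (sensitivity, specificity, PPV, NPV with
Wilson 95% CIs), ICC(2,1) absolute-agreement intraclass correlation with
F-distribution CI bounds, Bland-Altman bias and limits of agreement, and
Pearson correlation of paired volumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io import LabelMask
from .features import volume_ml, PLEURA

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "AgreementReport",
    "dice",
    "confusion_metrics",
    "icc",
    "bland_altman",
    "volume_agreement",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.625 -> 0.63), matching reported tables."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fn + self.tn + self.fp == 0:
            raise ValueError("confusion matrix is empty")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _ratio_with_ci(num: int, den: int, alpha: float = 0.05):
    if den == 0:
        return float("nan"), (float("nan"), float("nan"))
    est = num / den
    lo, hi = proportion_confint(num, den, alpha=alpha, method="wilson")
    return est, (float(lo), float(hi))


def confusion_metrics(cm: ConfusionMatrix, digits: int = 2) -> dict:
    """Sensitivity/specificity/PPV/NPV with Wilson 95% CIs.

    Point estimates and CI bounds are rounded half-up to ``digits``
    decimals; a zero denominator yields NaN for that statistic only.
    """
    raw = {
        "sensitivity": _ratio_with_ci(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio_with_ci(cm.tn, cm.tn + cm.fp),
        "ppv": _ratio_with_ci(cm.tp, cm.tp + cm.fp),
        "npv": _ratio_with_ci(cm.tn, cm.tn + cm.fn),
    }
    out = {}
    for name, (est, (lo, hi)) in raw.items():
        out[name] = round_half_up(est, digits)
        out[f"{name}_ci"] = (round_half_up(lo, digits), round_half_up(hi, digits))
    return out


def icc(measurements: np.ndarray, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is an (n cases x k raters) array with no missing
    cells. Returns ``(estimate, (lower, upper))`` with the CI from the
    standard F-distribution bounds. Zero total variance is perfect
    agreement by convention (ICC 1.0, degenerate-data warning).
    """
    y = np.asarray(measurements, dtype=float)
    if y.ndim != 2 or y.shape[0] < 3 or y.shape[1] < 2:
        raise ValueError("need an (n >= 3) x (k >= 2) measurement matrix")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    n, k = y.shape
    if np.ptp(y) == 0:
        warnings.warn("zero total variance; ICC defined as 1.0")
        return 1.0, (float("nan"), float("nan"))
    gm = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sst = np.sum((y - gm) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # Shrout-Fleiss F-based bounds for ICC(2,1)
    a = k * est / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    return float(est), (float(lower), float(upper))


def bland_altman(a, b):
    """Bias and 95% limits of agreement of paired measurements.

    bias = mean(a - b); limits = bias +/- 1.96 * sd(a - b) (sample sd).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurement lengths differ")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass
class AgreementReport:
    dice_values: list
    volume_diff_ml: list
    icc_estimate: float
    icc_ci: tuple
    ba_bias: float
    ba_limits: tuple
    pearson_r: float

    def to_dict(self) -> dict:
        return {
            "dice_median": float(np.median(self.dice_values)),
            "dice_mean": float(np.mean(self.dice_values)),
            "abs_volume_diff_mean_ml": float(np.mean(np.abs(self.volume_diff_ml))),
            "abs_volume_diff_median_ml": float(np.median(np.abs(self.volume_diff_ml))),
            "icc": self.icc_estimate,
            "icc_ci": list(self.icc_ci),
            "bland_altman_bias_ml": self.ba_bias,
            "bland_altman_limits_ml": list(self.ba_limits),
            "pearson_r": self.pearson_r,
        }


def volume_agreement(pred_masks, ref_masks, label: int = PLEURA) -> AgreementReport:
    """Per-case Dice and volume agreement between two sets of segmentations.

    Accepts paired lists of :class:`LabelMask` (or boolean arrays plus a
    common spacing via tuples ``(array, spacing)``).
    """
    if len(pred_masks) != len(ref_masks):
        raise ValueError("prediction/reference counts differ")

    def unpack(m):
        if isinstance(m, LabelMask):
            return m.region(label), m.spacing
        arr, spacing = m
        return np.asarray(arr, dtype=bool), spacing

    dices, vp, vr = [], [], []
    for p, r in zip(pred_masks, ref_masks):
        pa, ps = unpack(p)
        ra, rs = unpack(r)
        if pa.shape != ra.shape or not np.allclose(ps, rs):
            raise ValueError("paired masks must share grid and spacing")
        dices.append(dice(pa, ra))
        vp.append(volume_ml(pa, ps))
        vr.append(volume_ml(ra, rs))
    vp, vr = np.asarray(vp), np.asarray(vr)
    diffs = (vp - vr).tolist()
    est, ci = icc(np.column_stack([vp, vr]))
    bias, limits = bland_altman(vp, vr)
    if np.ptp(vp) == 0 or np.ptp(vr) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(vp, vr)[0])
    return AgreementReport(
        dice_values=dices, volume_diff_ml=diffs, icc_estimate=est, icc_ci=ci,
        ba_bias=bias, ba_limits=limits, pearson_r=r,
    )
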