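"""Confusion matrices and likelihood-ratio evaluation.

For each analysis cell a 2x2 table is built (prediction vs dichotomous truth),
a Haldane-Anscombe correction (+0.5 to every cell) is applied unconditionally
— rescuing zero cells and adding conservatism — and the positive likelihood
ratio

    pLR = sensitivity / false-positive rate = [TP/(TP+FN)] / [FP/(FP+TN)]

is reported with a 95% confidence interval from the standard log-method:

    exp( ln pLR  +/-  z * sqrt( 1/TP - 1/(TP+FN) + 1/FP - 1/(FP+TN) ) )

with z the exact 97.5th normal quantile (1.959964; the two-decimal 1.96
shifts a handful of extreme upper bounds by one final digit).

The negative likelihood ratio is reported in the orientation the source study
prints, [TN/(TN+FP)] / [FN/(FN+TP)] — specificity over false-negative rate —
which is the reciprocal of the conventional nLR; values above 1 therefore
indicate information toward benignity.

Likelihood ratios map onto the points-based Bayesian formulation of the
ACMG/AMP framework (prior-odds constant 350, very-strong = 8 points):
points = 8 * ln(LR) / ln(350); supporting/moderate/strong thresholds at
1/2/4 points.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

Z_95 = 1.959963984540054  # exact 97.5th percentile of the standard normal
PRIOR_ODDS = 350.0
POINTS_VERY_STRONG = 8.0


def round1(value: float) -> float:
    """Round half-up to 1 decimal, as the study tables print LRs."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: float
    fn: float
    fp: float
    tn: float
    corrected: bool = False

    def __post_init__(self):
        for cell in (self.tp, self.fn, self.fp, self.tn):
            if cell < 0:
                raise ValidationError("confusion-matrix cells must be non-negative")
        if self.corrected:
            for cell in (self.tp, self.fn, self.fp, self.tn):
                if (cell - 0.5) != int(cell - 0.5):
                    raise ValidationError(
                        "corrected cells must be integer + 0.5 exactly"
                    )

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.fp + self.tn

    def cells(self) -> tuple:
        return (self.tp, self.fn, self.fp, self.tn)


def haldane_anscombe(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Add 0.5 to every cell; refuses to correct twice."""
    if cm.corrected:
        raise ValidationError("confusion matrix already corrected")
    return ConfusionMatrix(
        cm.tp + 0.5, cm.fn + 0.5, cm.fp + 0.5, cm.tn + 0.5, corrected=True
    )


class Strength(str, enum.Enum):
    NONE = "NONE"
    SUPPORTING = "SUPPORTING"
    MODERATE = "MODERATE"
    STRONG = "STRONG"
    VERY_STRONG = "VERY_STRONG"


class LrKind(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class LikelihoodRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    kind: LrKind
    evidence_points: Optional[float] = None

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError("confidence interval must contain the estimate")

    def rounded(self) -> tuple:
        return (round1(self.estimate), round1(self.ci_low), round1(self.ci_high))


def _log_method_ci(estimate: float, tp, fn, fp, tn) -> tuple:
    se = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    return (
        estimate * math.exp(-Z_95 * se),
        estimate * math.exp(Z_95 * se),
    )


def _require_corrected(cm: ConfusionMatrix) -> ConfusionMatrix:
    if not cm.corrected:
        raise ValidationError("apply the Haldane-Anscombe correction first")
    return cm


def positive_lr(cm: ConfusionMatrix) -> LikelihoodRatioResult:
    """pLR with 95% CI on a corrected matrix."""
    tp, fn, fp, tn = _require_corrected(cm).cells()
    estimate = (tp / (tp + fn)) / (fp / (fp + tn))
    low, high = _log_method_ci(estimate, tp, fn, fp, tn)
    points, _ = evidence_points(estimate)
    return LikelihoodRatioResult(estimate, low, high, LrKind.POSITIVE, points)


def negative_lr(cm: ConfusionMatrix) -> LikelihoodRatioResult:
    """Printed-orientation nLR (specificity / FN rate) with 95% CI."""
    tp, fn, fp, tn = _require_corrected(cm).cells()
    estimate = (tn / (tn + fp)) / (fn / (fn + tp))
    # same log-method with the roles of the cells swapped (TN<->TP, FN<->FP)
    low, high = _log_method_ci(estimate, tn, fp, fn, tp)
    return LikelihoodRatioResult(estimate, low, high, LrKind.NEGATIVE)


def evidence_points(plr: float) -> tuple:
    """Evidence points and strength label for a positive likelihood ratio."""
    if plr <= 0:
        raise ValidationError("likelihood ratio must be positive")
    points = POINTS_VERY_STRONG * math.log(plr) / math.log(PRIOR_ODDS)
    if points < 1:
        label = Strength.NONE
    elif points < 2:
        label = Strength.SUPPORTING
    elif points < 4:
        label = Strength.MODERATE
    elif points < 8:
        label = Strength.STRONG
    else:
        label = Strength.VERY_STRONG
    return points, label


# --------------------------------------------------------------------------
# From prediction tables to result tables
# --------------------------------------------------------------------------


def build_confusion(predictions: pd.DataFrame, band: Optional[str] = None) -> ConfusionMatrix:
    """Uncorrected 2x2 from prediction rows.

    For binary rules the rows' ``prediction`` column is used directly.  For a
    banded cell, membership in ``band`` counts as a DEL prediction and
    membership in the baseline band as TOL; rows in the other band are
    excluded, so band rows for one tool share their FN/TN cells.
    """
    if band is None:
        pred = predictions["prediction"]
        keep = pd.Series(True, index=predictions.index)
    else:
        keep = predictions["band"].isin([band, "baseline"])
        pred = predictions["band"].map(lambda b: "DEL" if b == band else "TOL")
    truth = predictions["truth"]
    if not set(truth[keep]) <= {"DEL", "TOL"}:
        raise ValidationError("truth labels must be dichotomous DEL/TOL")
    tp = int(((pred == "DEL") & (truth == "DEL") & keep).sum())
    fn = int(((pred == "TOL") & (truth == "DEL") & keep).sum())
    fp = int(((pred == "DEL") & (truth == "TOL") & keep).sum())
    tn = int(((pred == "TOL") & (truth == "TOL") & keep).sum())
    return ConfusionMatrix(tp, fn, fp, tn)


def _result_row(scope, label, tool, cm: ConfusionMatrix) -> dict:
    corrected = haldane_anscombe(cm)
    plr = positive_lr(corrected)
    nlr = negative_lr(corrected)
    points, strength = evidence_points(plr.estimate)
    return {
        "scope": scope,
        "analysis": label,
        "tool": tool,
        "tp": int(cm.tp),
        "fn": int(cm.fn),
        "fp": int(cm.fp),
        "tn": int(cm.tn),
        "plr": plr.estimate,
        "plr_ci_low": plr.ci_low,
        "plr_ci_high": plr.ci_high,
        "nlr": nlr.estimate,
        "nlr_ci_low": nlr.ci_low,
        "nlr_ci_high": nlr.ci_high,
        "evidence_points": round(points, 2),
        "strength": strength.value,
    }


def evaluate_all(predictions: pd.DataFrame, scopes: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """One result row per (scope, rule or band, tool).

    ``scopes`` defaults to every gene present plus a combined scope when more
    than one gene is present.  Empty cells are skipped with a warning row
    (all-zero matrix rows would be meaningless even after correction).
    """
    genes = sorted(predictions["gene"].unique())
    if scopes is None:
        scopes = list(genes) + (["combined"] if len(genes) > 1 else [])
    rows = []
    for scope in scopes:
        in_scope = (
            predictions
            if scope == "combined"
            else predictions[predictions["gene"] == scope]
        )
        binary = in_scope[in_scope["kind"] == "definition"]
        for (defn, tool), cell in binary.groupby(["definition", "tool"], sort=True):
            rows.append(_result_row(scope, defn, tool, build_confusion(cell)))
        banded = in_scope[in_scope["kind"] == "band"]
        for tool, cell in banded.groupby("tool", sort=True):
            for band in ("x", "y"):
                rows.append(
                    _result_row(scope, f"band_{band}", tool, build_confusion(cell, band=band))
                )
    return pd.DataFrame(rows)
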