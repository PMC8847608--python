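"""Frame- and bout-level evaluation of predicted grooming tracks.

The confusion matrix follows the report layout used throughout: rows are the
human label and columns the predicted label, both in the order body (2),
face (1), not grooming (0).  Metrics are computed as exact rationals and
rounded only for display (one decimal for percentages, three for macro-F1).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np

from .labels import BODY, FACIAL, NOT_GROOMING, LabelTrack, as_track, extract_bouts

#: row/column order of the confusion matrix (body, face, not grooming)
CLASS_ORDER = (BODY, FACIAL, NOT_GROOMING)
CLASS_NAMES = {BODY: "body", FACIAL: "face", NOT_GROOMING: "not"}

_POS = {cls: i for i, cls in enumerate(CLASS_ORDER)}


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is empty (e.g. class absent)."""


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 human-vs-predicted frame counts in body/face/not order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, cls: int) -> np.ndarray:
        return self.counts[_POS[cls]]

    def col(self, cls: int) -> np.ndarray:
        return self.counts[:, _POS[cls]]

    def diagonal(self, cls: int) -> int:
        return int(self.counts[_POS[cls], _POS[cls]])


def confusion(truth: LabelTrack, pred: LabelTrack) -> ConfusionMatrix3:
    """Tally frames into the 3x3 human-row x predicted-column matrix."""
    truth, pred = as_track(truth), as_track(pred)
    if len(truth) != len(pred):
        raise ValueError(f"track length mismatch: {len(truth)} vs {len(pred)}")
    counts = np.zeros((3, 3), dtype=np.int64)
    for i, ti in enumerate(CLASS_ORDER):
        mask = truth.values == ti
        for j, pj in enumerate(CLASS_ORDER):
            counts[i, j] = int(np.count_nonzero(pred.values[mask] == pj))
    return ConfusionMatrix3(counts)


def sensitivity(m: ConfusionMatrix3, cls: int) -> Fraction:
    """Per-class recall as a percentage (exact rational)."""
    denom = int(m.row(cls).sum())
    if denom == 0:
        raise UndefinedMetricError(f"no human-labeled frames of class {cls}")
    return Fraction(100 * m.diagonal(cls), denom)


def ppr(m: ConfusionMatrix3, cls: int) -> Fraction:
    """Per-class positive predictive rate (precision) as a percentage."""
    denom = int(m.col(cls).sum())
    if denom == 0:
        raise UndefinedMetricError(f"no predicted frames of class {cls}")
    return Fraction(100 * m.diagonal(cls), denom)


def accuracy(m: ConfusionMatrix3) -> Fraction:
    """Fraction of correctly predicted frames, as a percentage."""
    if m.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return Fraction(100 * int(np.trace(m.counts)), m.total)


def macro_f1(m: ConfusionMatrix3) -> Fraction:
    """Unweighted mean over body/face/not of the class-wise F1 (fraction in [0, 1]).

    A class's F1 is taken as 0 when its precision+recall denominator is 0.
    """
    f1s = []
    for cls in CLASS_ORDER:
        if int(m.row(cls).sum()) == 0:
            raise UndefinedMetricError(f"class {cls} absent from truth")
        tp = m.diagonal(cls)
        denom = int(m.row(cls).sum()) + int(m.col(cls).sum())  # 2tp+fp+fn
        f1s.append(Fraction(2 * tp, denom) if denom else Fraction(0))
    return sum(f1s, Fraction(0)) / 3


def round_pct(x: Fraction | float, ndigits: int = 1) -> float:
    """Round half-up to ``ndigits`` decimals, as printed in reports."""
    d = Decimal(x.numerator) / Decimal(x.denominator) if isinstance(x, Fraction) else Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def bout_correlation(truth_counts, pred_counts) -> float:
    """Pearson correlation between per-video truth and predicted bout counts."""
    x = np.asarray(truth_counts, dtype=np.float64)
    y = np.asarray(pred_counts, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bout-count vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 videos for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("zero variance in bout counts")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class ErrorBreakdown:
    """Mutually exclusive, exhaustive partition of discrepant frames."""

    boundary: int
    oversight: int
    false_detection: int

    @property
    def total(self) -> int:
        return self.boundary + self.oversight + self.false_detection


def classify_errors(truth: LabelTrack, pred: LabelTrack) -> ErrorBreakdown:
    """Partition frames where truth != pred into the three-way error taxonomy.

    A human bout with zero overlap with predicted grooming is an *oversight*
    (all its frames); a predicted bout with zero overlap with human grooming
    is a *false detection*; every remaining discrepant frame is a *boundary*
    error.
    """
    truth, pred = as_track(truth), as_track(pred)
    if len(truth) != len(pred):
        raise ValueError(f"track length mismatch: {len(truth)} vs {len(pred)}")
    t, p = truth.values, pred.values
    discrepant = t != p
    truth_groom = t != NOT_GROOMING
    pred_groom = p != NOT_GROOMING

    oversight = np.zeros(len(t), dtype=bool)
    for bout in extract_bouts(truth):
        if not pred_groom[bout.start:bout.end].any():
            oversight[bout.start:bout.end] = True
    false_det = np.zeros(len(t), dtype=bool)
    for bout in extract_bouts(pred):
        if not truth_groom[bout.start:bout.end].any():
            false_det[bout.start:bout.end] = True

    n_over = int(np.count_nonzero(oversight & discrepant))
    n_false = int(np.count_nonzero(false_det & discrepant))
    n_boundary = int(np.count_nonzero(discrepant)) - n_over - n_false
    return ErrorBreakdown(boundary=n_boundary, oversight=n_over, false_detection=n_false)


def report(truth: LabelTrack, pred: LabelTrack) -> dict:
    """Machine-readable evaluation report for one truth/prediction pair."""
    m = confusion(truth, pred)
    per_class = {}
    for cls in CLASS_ORDER:
        entry = {}
        try:
            entry["sensitivity_pct"] = round_pct(sensitivity(m, cls))
        except UndefinedMetricError:
            entry["sensitivity_pct"] = None
        try:
            entry["ppr_pct"] = round_pct(ppr(m, cls))
        except UndefinedMetricError:
            entry["ppr_pct"] = None
        per_class[CLASS_NAMES[cls]] = entry
    try:
        mf1 = round_pct(macro_f1(m), 3)
    except UndefinedMetricError:
        mf1 = None
    errors = classify_errors(truth, pred)
    return {
        "confusion_matrix": m.counts.tolist(),
        "class_order": [CLASS_NAMES[c] for c in CLASS_ORDER],
        "per_class": per_class,
        "accuracy_pct": round_pct(accuracy(m)),
        "macro_f1": mf1,
        "n_frames": m.total,
        "bouts_truth": len(extract_bouts(truth)),
        "bouts_pred": len(extract_bouts(pred)),
        "errors": {
            "boundary": errors.boundary,
            "oversight": errors.oversight,
            "false_detection": errors.false_detection,
        },
    }


def format_report(rep: dict) -> str:
    """Render a report dict as the human-readable text table."""
    lines = []
    order = rep["class_order"]
    lines.append("confusion matrix (rows: human, cols: predicted; order: " + ", ".join(order) + ")")
    for name, row in zip(order, rep["confusion_matrix"]):
        lines.append(f"  {name:>5}  " + "  ".join(f"{v:>8d}" for v in row))
    for name in order:
        pc = rep["per_class"][name]
        sens = "n/a" if pc["sensitivity_pct"] is None else f"{pc['sensitivity_pct']:.1f}%"
        prec = "n/a" if pc["ppr_pct"] is None else f"{pc['ppr_pct']:.1f}%"
        lines.append(f"{name:>5}: sensitivity {sens:>6}, PPR {prec:>6}")
    lines.append(f"accuracy: {rep['accuracy_pct']:.1f}%")
    if rep["macro_f1"] is not None:
        lines.append(f"macro F1: {rep['macro_f1']:.3f}")
    lines.append(f"bouts: truth {rep['bouts_truth']}, predicted {rep['bouts_pred']}")
    e = rep["errors"]
    lines.append(
        f"errors: boundary {e['boundary']}, oversight {e['oversight']}, "
        f"false detection {e['false_detection']}"
    )
    return "\n".join(lines)
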