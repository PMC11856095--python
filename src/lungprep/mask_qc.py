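"""Segmentation agreement metrics and mask quality control.

Agreement metrics (IoU, Dice, precision/recall/specificity, IoU loss) compare
a predicted mask against a reference; the QC battery additionally scores a
single mask on lung coverage (PLC, percent of image area) and left-right
symmetry, raises threshold flags, and combines everything into a weighted
quality score.

Degenerate-case conventions (both fixed and logged): IoU and Dice of two
empty masks are 1; any 0/0 ratio in precision/recall/specificity is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import BinaryMask

logger = logging.getLogger(__name__)


class Flag:
    LOW_IOU = "LOW_IOU"
    ASYMMETRIC = "ASYMMETRIC"
    PLC_OUT_OF_RANGE = "PLC_OUT_OF_RANGE"


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class QCMetrics:
    iou: float
    dice: float
    precision: float
    recall: float
    specificity: float
    iou_loss: float


@dataclass
class QCConfig:
    iou_min: float = 0.85
    asym_max: float = 0.5
    plc_min: float = 5.0  # percent
    plc_max: float = 50.0  # percent
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # (iou, sym, plc)

    def validate(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValidationError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")
        if self.plc_min > self.plc_max:
            raise ValidationError("plc_min must be <= plc_max")


@dataclass
class QCReport:
    metrics: QCMetrics | None
    plc: float
    asymmetry: float
    weighted_score: float
    flags: list[str] = field(default_factory=list)


def _check_shapes(pred: BinaryMask, truth: BinaryMask) -> None:
    if pred.pixels.shape != truth.pixels.shape:
        raise ValidationError(
            f"mask shapes differ: {pred.pixels.shape} vs {truth.pixels.shape}"
        )


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    _check_shapes(pred, truth)
    p = pred.as_bool()
    g = truth.as_bool()
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=p.size - tp - fp - fn)


def iou(pred: BinaryMask, truth: BinaryMask) -> float:
    """Intersection over union; 1 when both masks are empty."""
    _check_shapes(pred, truth)
    p = pred.as_bool()
    g = truth.as_bool()
    union = int(np.count_nonzero(p | g))
    if union == 0:
        logger.warning("IoU of two empty masks: returning 1 by convention")
        return 1.0
    return int(np.count_nonzero(p & g)) / union


def dice(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice coefficient 2|P∩G|/(|P|+|G|); 1 when both masks are empty."""
    _check_shapes(pred, truth)
    p = pred.as_bool()
    g = truth.as_bool()
    denom = int(np.count_nonzero(p)) + int(np.count_nonzero(g))
    if denom == 0:
        logger.warning("Dice of two empty masks: returning 1 by convention")
        return 1.0
    return 2 * int(np.count_nonzero(p & g)) / denom


def iou_loss(pred: BinaryMask, truth: BinaryMask) -> float:
    return 1.0 - iou(pred, truth)


def _safe_ratio(num: int, den: int) -> float:
    if den == 0:
        logger.warning("0/0 ratio: returning 1 by convention")
        return 1.0
    return num / den


def precision_recall_specificity(c: ConfusionCounts) -> tuple[float, float, float]:
    precision = _safe_ratio(c.tp, c.tp + c.fp)
    recall = _safe_ratio(c.tp, c.tp + c.fn)
    specificity = _safe_ratio(c.tn, c.tn + c.fp)
    return precision, recall, specificity


def plc(mask: BinaryMask) -> float:
    """Percentage of lung coverage: foreground area as percent of all pixels."""
    return 100.0 * int(np.count_nonzero(mask.pixels)) / mask.pixels.size


def asymmetry(mask: BinaryMask) -> float:
    """Relative left/right area difference, split at the vertical midline.

    ``|A_L - A_R| / max(A_L, A_R)``; 0 when both halves are empty.  Columns
    below ``W // 2`` form the left half (the middle column of an odd-width
    image belongs to the right half).
    """
    w = mask.pixels.shape[1]
    a_left = int(np.count_nonzero(mask.pixels[:, : w // 2]))
    a_right = int(np.count_nonzero(mask.pixels[:, w // 2 :]))
    biggest = max(a_left, a_right)
    if biggest == 0:
        return 0.0
    return abs(a_left - a_right) / biggest


def weighted_quality_score(
    iou_val: float, asym: float, plc_val: float, cfg: QCConfig | None = None
) -> float:
    """Linear combination of IoU, (1 - asymmetry), and a binary PLC in-range term."""
    cfg = cfg or QCConfig()
    cfg.validate()
    w_iou, w_sym, w_plc = cfg.weights
    plc_component = 1.0 if cfg.plc_min <= plc_val <= cfg.plc_max else 0.0
    return w_iou * iou_val + w_sym * (1.0 - asym) + w_plc * plc_component


def qc_mask(
    pred: BinaryMask,
    truth: BinaryMask | None = None,
    cfg: QCConfig | None = None,
) -> QCReport:
    """Full QC battery for one mask (agreement metrics only with a reference)."""
    cfg = cfg or QCConfig()
    cfg.validate()

    metrics: QCMetrics | None = None
    if truth is not None:
        _check_shapes(pred, truth)
        c = confusion(pred, truth)
        p, r, s = precision_recall_specificity(c)
        iou_val = iou(pred, truth)
        metrics = QCMetrics(
            iou=iou_val,
            dice=dice(pred, truth),
            precision=p,
            recall=r,
            specificity=s,
            iou_loss=1.0 - iou_val,
        )
    else:
        logger.info("no reference mask: weighted score uses IoU placeholder 1.0")
        iou_val = 1.0

    plc_val = plc(pred)
    asym = asymmetry(pred)
    flags: list[str] = []
    if metrics is not None and metrics.iou < cfg.iou_min:
        flags.append(Flag.LOW_IOU)
    if asym > cfg.asym_max:
        flags.append(Flag.ASYMMETRIC)
    if plc_val < cfg.plc_min or plc_val > cfg.plc_max:
        flags.append(Flag.PLC_OUT_OF_RANGE)
    return QCReport(
        metrics=metrics,
        plc=plc_val,
        asymmetry=asym,
        weighted_score=weighted_quality_score(iou_val, asym, plc_val, cfg),
        flags=flags,
    )
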