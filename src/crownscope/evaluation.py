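"""Detection and regression accuracy protocol for crown extraction.

Predicted and reference crowns are matched one-to-one by intersection over
union (IoU, in percent); a pair is accepted only when IoU strictly exceeds
the threshold (default 50%).  Accepted pairs are TP, unmatched predictions
FP, unmatched references FN, from which

    P  = TP / (TP + FP) x 100
    R  = TP / (TP + FN) x 100
    F1 = 2 P R / (P + R)

Crown width / projection area / height agreement over the matched pairs is
summarized by R^2, RMSE and relative RMSE (RMSE over the reference mean, in
percent).  Note the R^2 here is, by default, computed with the residual sum
normalized by the spread of the *estimates* around their own mean
(``1 - sum (y_i - x_i)^2 / sum (y_i - ybar)^2``); pass ``conventional=True``
for the textbook reference-centered form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .crown_metrics import CrownInstance, extract_crown_instances, filter_border_crowns
from .errors import DimensionError, UndefinedMetricError

__all__ = [
    "DetectionCounts",
    "DetectionMetrics",
    "RegressionPairs",
    "RegressionMetrics",
    "compute_iou",
    "match_crowns",
    "detection_metrics",
    "regression_metrics",
    "evaluate_run",
    "EvaluationReport",
]


@dataclass
class DetectionCounts:
    """TP/FP/FN tallies and the IoU of every accepted match."""

    tp: int
    fp: int
    fn: int
    matched_ious: list[float] = field(default_factory=list)
    n_reference: int = 0
    n_predicted: int = 0
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    #: matches holds (predicted label, reference label, IoU %) triples


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float


@dataclass
class RegressionPairs:
    """Paired reference (x) and predicted (y) crown measurements."""

    reference: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        if self.reference.shape != self.predicted.shape:
            raise DimensionError(
                f"reference ({self.reference.shape}) and predicted "
                f"({self.predicted.shape}) lengths differ"
            )

    @property
    def n(self) -> int:
        return int(self.reference.size)


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    rrmse: float  # percent


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Conventional half-up rounding for report presentation.

    Report tables round halves away from zero (84.375 -> 84.38), unlike
    Python's built-in banker's rounding.
    """
    if not np.isfinite(value):
        return float(value)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def compute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Region IoU in percent: |A ∩ B| / |A ∪ B| x 100.

    Raises :class:`UndefinedMetricError` when both regions are empty.
    """
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise DimensionError(f"region shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise UndefinedMetricError("IoU undefined: both regions empty")
    return 100.0 * np.count_nonzero(a & b) / union


def _instance_iou(p: CrownInstance, r: CrownInstance) -> float:
    """IoU (percent) between two instances via bounding-box intersection."""
    pr0, pc0 = p.slice_[0].start, p.slice_[1].start
    rr0, rc0 = r.slice_[0].start, r.slice_[1].start
    pr1, pc1 = pr0 + p.pixels.shape[0], pc0 + p.pixels.shape[1]
    rr1, rc1 = rr0 + r.pixels.shape[0], rc0 + r.pixels.shape[1]
    ir0, ic0 = max(pr0, rr0), max(pc0, rc0)
    ir1, ic1 = min(pr1, rr1), min(pc1, rc1)
    if ir0 >= ir1 or ic0 >= ic1:
        inter = 0
    else:
        pa = p.pixels[ir0 - pr0 : ir1 - pr0, ic0 - pc0 : ic1 - pc0]
        rb = r.pixels[ir0 - rr0 : ir1 - rr0, ic0 - rc0 : ic1 - rc0]
        inter = int(np.count_nonzero(pa & rb))
    union = p.pixel_count + r.pixel_count - inter
    return 100.0 * inter / union if union else 0.0


def match_crowns(
    predicted: list[CrownInstance],
    reference: list[CrownInstance],
    iou_threshold: float = 50.0,
) -> DetectionCounts:
    """One-to-one crown matching by greedy descending IoU.

    Candidate pairs with IoU strictly above ``iou_threshold`` (percent) are
    accepted in descending IoU order, each instance used at most once; ties
    break toward the smaller predicted, then reference, label id.
    """
    cands: list[tuple[float, int, int]] = []
    for i, p in enumerate(predicted):
        for j, r in enumerate(reference):
            iou = _instance_iou(p, r)
            if iou > iou_threshold:
                cands.append((iou, i, j))
    cands.sort(key=lambda t: (-t[0], predicted[t[1]].label, reference[t[2]].label))
    used_p: set[int] = set()
    used_r: set[int] = set()
    counts = DetectionCounts(
        tp=0, fp=0, fn=0, n_reference=len(reference), n_predicted=len(predicted)
    )
    for iou, i, j in cands:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        counts.tp += 1
        counts.matched_ious.append(iou)
        counts.matches.append((predicted[i].label, reference[j].label, iou))
    counts.fp = len(predicted) - counts.tp
    counts.fn = len(reference) - counts.tp
    return counts


def detection_metrics(counts: DetectionCounts) -> DetectionMetrics:
    """Precision, recall and F1 in percent from TP/FP/FN tallies.

    A zero denominator leaves the corresponding metric NaN (with a
    warning); it is undefined, never reported as 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp > 0:
        precision = 100.0 * tp / (tp + fp)
    else:
        warnings.warn("precision undefined: no predictions", stacklevel=2)
        precision = float("nan")
    if tp + fn > 0:
        recall = 100.0 * tp / (tp + fn)
    else:
        warnings.warn("recall undefined: no reference crowns", stacklevel=2)
        recall = float("nan")
    if np.isnan(precision) or np.isnan(recall):
        f1 = float("nan")
    else:
        # algebraically 2PR/(P+R); this form is exact on integer counts
        f1 = 200.0 * tp / (2 * tp + fp + fn)
    return DetectionMetrics(precision=precision, recall=recall, f1=f1)


def regression_metrics(
    pairs: RegressionPairs | tuple, conventional: bool = False
) -> RegressionMetrics:
    """R^2, RMSE and rRMSE (%) between reference x and predicted y.

    Default R^2 normalizes the residual sum by the spread of the estimates
    around their own mean; ``conventional=True`` uses the reference-centered
    denominator instead.
    """
    if not isinstance(pairs, RegressionPairs):
        pairs = RegressionPairs(*pairs)
    x, y, n = pairs.reference, pairs.predicted, pairs.n
    if n < 2:
        raise UndefinedMetricError(f"need >= 2 pairs for R^2, got {n}")
    sse = float(np.sum((y - x) ** 2))
    denom = float(np.sum((x - x.mean()) ** 2)) if conventional else float(
        np.sum((y - y.mean()) ** 2)
    )
    if sse == 0.0:
        r2 = 1.0
    elif denom == 0.0:
        raise UndefinedMetricError("R^2 undefined: zero variance denominator")
    else:
        r2 = 1.0 - sse / denom
    rmse = float(np.sqrt(sse / n))
    xbar = float(x.mean())
    if xbar == 0.0:
        raise UndefinedMetricError("rRMSE undefined: reference mean is 0")
    rrmse = 100.0 * rmse / xbar
    return RegressionMetrics(r2=r2, rmse=rmse, rrmse=rrmse)


@dataclass
class EvaluationReport:
    """Full per-run report: detection block plus regression blocks."""

    counts: DetectionCounts
    detection: DetectionMetrics
    mean_matched_iou: float
    pooled_pixel_iou: float
    regression: dict[str, RegressionMetrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n_predicted": self.counts.n_predicted,
            "n_reference": self.counts.n_reference,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "mean_matched_iou_percent": round_half_up(self.mean_matched_iou),
            "pooled_pixel_iou_percent": round_half_up(self.pooled_pixel_iou),
            "precision_percent": round_half_up(self.detection.precision),
            "recall_percent": round_half_up(self.detection.recall),
            "f1_percent": round_half_up(self.detection.f1),
        }
        for name, m in self.regression.items():
            out[f"r2_{name}"] = round_half_up(m.r2, 4)
            out[f"rmse_{name}"] = round_half_up(m.rmse, 4)
            out[f"rrmse_{name}_percent"] = round_half_up(m.rrmse)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=True)


def _instances_mask(instances: list[CrownInstance], shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for inst in instances:
        mask[inst.slice_][inst.pixels] = True
    return mask


def evaluate_run(
    pred_mask: np.ndarray,
    ref_instances: list[CrownInstance],
    ref_metrics: pd.DataFrame | None = None,
    resolution: float = 0.01532703,
    iou_threshold: float = 50.0,
    min_crown_pixels: int = 50,
    chm: np.ndarray | None = None,
    exclude_border: bool = True,
) -> EvaluationReport:
    """Run the full accuracy protocol on one predicted mask.

    Predicted instances are extracted from ``pred_mask``, border-clipped
    crowns are dropped on both sides (their shapes are incomplete), crowns
    are matched one-to-one, and detection metrics computed.  If
    ``ref_metrics`` is given (a frame indexed by reference label with any
    of the columns ``cw_mean_m``, ``cpa_m2``, ``height_m``) regression
    metrics over the matched pairs are added for each available quantity;
    otherwise the reference instances' own measurements are used.  With no
    matched pairs the regression block is omitted with a warning.
    """
    predicted = extract_crown_instances(
        pred_mask, resolution=resolution, min_crown_pixels=min_crown_pixels,
        chm=chm,
    )
    if exclude_border:
        predicted = filter_border_crowns(predicted)
        ref_instances = filter_border_crowns(ref_instances)
    counts = match_crowns(predicted, ref_instances, iou_threshold)
    det = detection_metrics(counts)
    mean_iou = float(np.mean(counts.matched_ious)) if counts.matched_ious else float("nan")
    ref_mask = _instances_mask(ref_instances, np.asarray(pred_mask).shape)
    try:
        pooled = compute_iou(np.asarray(pred_mask) > 0, ref_mask)
    except UndefinedMetricError:
        pooled = float("nan")
    report = EvaluationReport(
        counts=counts, detection=det, mean_matched_iou=mean_iou,
        pooled_pixel_iou=pooled,
    )
    if not counts.matches:
        warnings.warn("no matched pairs; regression block omitted", stacklevel=2)
        return report

    pred_by_label = {p.label: p for p in predicted}
    ref_by_label = {r.label: r for r in ref_instances}
    quantities = {
        "cw_m": ("cw_mean_m", "cw_mean"),
        "cpa_m2": ("cpa_m2", "cpa"),
        "height_m": ("height_m", "height"),
    }
    for name, (col, attr) in quantities.items():
        xs, ys = [], []
        for p_lab, r_lab, _ in counts.matches:
            y_val = getattr(pred_by_label[p_lab], attr)
            if ref_metrics is not None:
                if col not in ref_metrics.columns or r_lab not in ref_metrics.index:
                    x_val = None
                else:
                    x_val = ref_metrics.loc[r_lab, col]
            else:
                x_val = getattr(ref_by_label[r_lab], attr)
            if x_val is not None and y_val is not None and np.isfinite([x_val, y_val]).all():
                xs.append(float(x_val))
                ys.append(float(y_val))
        if len(xs) >= 2:
            try:
                report.regression[name] = regression_metrics(
                    RegressionPairs(xs, ys)
                )
            except UndefinedMetricError as exc:
                warnings.warn(f"{name}: {exc}", stacklevel=2)
    return report
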