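"""Prediction benchmarking: confusion counts, sensitivity/specificity, ROC.

Conventions:

* a true NES counts as detected (TP) when at least one prediction overlaps
  its range by at least ``min_overlap`` residues (default 8, most of a motif
  core); extra predictions on the same NES do not add TPs;
* a prediction contributing no detection is a false positive — calls from
  regions other than the true NES ranges;
* for ROC curves the false-positive *rate* is normalised the way sequence
  scanners are usually benchmarked against consensus matching: only false
  calls whose window matches the traditional consensus count, divided by the
  number of traditional-consensus matches in negative territory (a plain
  per-prediction normalisation is available via ``fpr_mode="window"``);
* AUC is the trapezoid over ROC points sorted by FPR, anchored at (0,0) and
  (1,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import match_traditional
from .scanner import NesPrediction
from .train import AnnotatedDataset


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    tn: int = 0
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    protein_level_fp_fraction: float = float("nan")
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def match_predictions(
    preds: list[NesPrediction],
    truth: AnnotatedDataset,
    min_overlap: int = 8,
) -> tuple[int, int, int]:
    """Site-level (tp, fp, fn) of predictions against annotated ranges."""
    ranges = truth.ranges_by_id()
    detected: dict[str, set[int]] = {seq_id: set() for seq_id in ranges}
    fp = 0
    for pred in preds:
        if pred.sequence_id not in ranges:
            raise KeyError(f"prediction on unknown sequence id {pred.sequence_id!r}")
        hit = False
        for idx, (start, end, _) in enumerate(ranges[pred.sequence_id]):
            if _overlap(pred.start, pred.end, start, end) >= min_overlap:
                detected[pred.sequence_id].add(idx)
                hit = True
        if not hit:
            fp += 1
    tp = sum(len(v) for v in detected.values())
    total = sum(len(v) for v in ranges.values())
    return tp, fp, total - tp


def evaluate(
    preds: list[NesPrediction],
    truth: AnnotatedDataset,
    negatives: AnnotatedDataset | None = None,
    min_overlap: int = 8,
) -> EvaluationResult:
    """Confusion counts plus sensitivity/specificity.

    When a negative dataset is given, each negative record is one unit: tn
    counts negative proteins with no prediction, and the protein-level FP
    fraction is the share of negative proteins with at least one call.
    """
    truth_ids = set(truth.ranges_by_id())
    neg_ids = {rec.id for rec, _ in negatives.records} if negatives else set()
    pos_preds = [p for p in preds if p.sequence_id in truth_ids]
    neg_preds = [p for p in preds if p.sequence_id in neg_ids]
    stray = [
        p.sequence_id for p in preds if p.sequence_id not in truth_ids | neg_ids
    ]
    if stray:
        raise KeyError(f"predictions on unknown sequence ids {sorted(set(stray))}")
    tp, fp, fn = match_predictions(pos_preds, truth, min_overlap=min_overlap)
    result = EvaluationResult(tp=tp, fp=fp, fn=fn)
    if tp + fn > 0:
        result.sensitivity = tp / (tp + fn)
    if negatives is not None and negatives.records:
        called = {p.sequence_id for p in neg_preds}
        n_units = len(negatives.records)
        result.fp = fp + len(neg_preds)
        result.tn = n_units - len(called)
        result.specificity = result.tn / n_units
        result.protein_level_fp_fraction = len(called) / n_units
    return result


def _negative_consensus_count(
    truth: AnnotatedDataset, negatives: AnnotatedDataset | None
) -> int:
    """Traditional-consensus matches lying in negative territory."""
    count = 0
    for rec, ranges in truth.records:
        for m in match_traditional(rec.residues):
            if all(_overlap(m.start, m.end, s, e) == 0 for s, e, _ in ranges):
                count += 1
    if negatives is not None:
        for rec, _ in negatives.records:
            count += len(match_traditional(rec.residues))
    return count


def roc_auc(
    preds: list[NesPrediction],
    truth: AnnotatedDataset,
    negatives: AnnotatedDataset | None = None,
    thresholds: list[float] | None = None,
    min_overlap: int = 8,
    fpr_mode: str = "consensus",
) -> EvaluationResult:
    """ROC over a threshold sweep of already-scored predictions.

    ``preds`` should come from an unthresholded scan.  TPR is the detected
    fraction of true NESs; FPR follows ``fpr_mode``:

    * ``"consensus"`` — false calls matching the traditional consensus,
      divided by the consensus-match count in negative territory;
    * ``"window"`` — all false calls divided by their total at the loosest
      threshold.
    """
    if fpr_mode not in ("consensus", "window"):
        raise ValueError(f"fpr_mode {fpr_mode!r}")
    ranges = truth.ranges_by_id()
    total_true = sum(len(v) for v in ranges.values())
    if total_true == 0:
        raise ValueError("truth dataset has no annotated ranges")

    if fpr_mode == "consensus":
        denom = _negative_consensus_count(truth, negatives)
        if denom == 0:
            raise ValueError(
                "no traditional-consensus matches in negative territory; "
                "use fpr_mode='window' or supply negative sequences with "
                "consensus-matching content"
            )
    else:
        denom = None

    scored = []
    for pred in preds:
        is_tp = pred.sequence_id in ranges and any(
            _overlap(pred.start, pred.end, s, e) >= min_overlap
            for s, e, _ in ranges[pred.sequence_id]
        )
        counts_as_fp = not is_tp
        if counts_as_fp and fpr_mode == "consensus":
            counts_as_fp = bool(match_traditional(pred.window))
        scored.append((pred, is_tp, counts_as_fp))

    if thresholds is None:
        values = sorted({p.adjusted_score for p in preds})
        thresholds = values + [max(values) + 1.0] if values else [0.0]
    if denom is None:
        denom = max(1, sum(1 for _, _, f in scored if f))

    points = []
    for t in thresholds:
        kept = [(p, is_tp, f) for p, is_tp, f in scored if p.adjusted_score >= t]
        detected: set[tuple[str, int]] = set()
        for pred, is_tp, _ in kept:
            if not is_tp:
                continue
            for idx, (s, e, _) in enumerate(ranges[pred.sequence_id]):
                if _overlap(pred.start, pred.end, s, e) >= min_overlap:
                    detected.add((pred.sequence_id, idx))
        tpr = len(detected) / total_true
        fp = sum(1 for _, _, f in kept if f)
        points.append((fp / denom, tpr))

    points.extend([(0.0, 0.0), (1.0, 1.0)])
    points = sorted(set(points))
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))

    result = EvaluationResult(tp=0, fp=0, fn=0, roc=points, auc=auc)
    tp, fp, fn = match_predictions(
        [p for p in preds if p.sequence_id in ranges], truth, min_overlap=min_overlap
    )
    result.tp, result.fp, result.fn = tp, fp, fn
    if tp + fn:
        result.sensitivity = tp / (tp + fn)
    return result
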