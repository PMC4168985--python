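"""Profile optimization against annotated training sequences.

Measured activity profiles describe isolated NES peptides; scanning whole
proteins with them over-calls hydrophobic decoys.  Training nudges profile
cells so that thresholded predictions separate annotated true NESs from
negative territory.

The procedure is greedy coordinate ascent on the training objective

    objective = -(lambda_fn * FN + lambda_fp * FP)

with FN/FP counted by the evaluator at the configured threshold (flank
adjustment active).  Epochs visit every free (profile, position, residue)
cell in a seeded-shuffled order; each cell is tried at +/-step within
bounds.  The error count alone offers no gradient — a false positive
sitting several score units above threshold cannot be removed by any single
step — so moves are ranked lexicographically: a move is kept when it
strictly improves the objective, or leaves it unchanged while strictly
shrinking a continuous violation term (hinge excess of false-positive
windows above threshold plus hinge deficit of undetected true NESs below
it, measured on an unmerged, unthresholded scan).  The logged objective
sequence is therefore still non-decreasing.  Training stops at
``max_epochs`` or after a full epoch with no accepted move.  Identical seed and inputs give identical output.  False negatives
cost more than false positives by default (lambda_fn=2 vs lambda_fp=1):
the operating regime trades a slight sensitivity loss for large
false-positive reductions, and the asymmetry keeps the trade in that
direction.

Cells on the template diagonal (S[i, template[i]]) are always frozen so the
template-identity normalisation survives training; ``freeze_conserved``
optionally also freezes every conserved-position cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord
from .profiles import AA_INDEX, ActivityProfile, NesClass
from .scanner import ScanConfig, scan_sequences

#: (start, end, class) with 1-based inclusive coordinates
NesRange = tuple[int, int, NesClass | None]


@dataclass
class AnnotatedDataset:
    """Sequences with true NES ranges (positives) or none (negatives)."""

    records: list[tuple[SequenceRecord, list[NesRange]]]
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity {self.polarity!r}")
        for rec, ranges in self.records:
            for start, end, _ in ranges:
                if not 1 <= start <= end <= len(rec):
                    raise ValueError(
                        f"{rec.id}: range {start}-{end} outside 1..{len(rec)}"
                    )

    @property
    def sequences(self) -> list[SequenceRecord]:
        return [rec for rec, _ in self.records]

    def ranges_by_id(self) -> dict[str, list[NesRange]]:
        return {rec.id: ranges for rec, ranges in self.records}


@dataclass(frozen=True)
class TrainingConfig:
    threshold: float = 2.0
    lambda_fp: float = 1.0
    lambda_fn: float = 2.0
    step: float = 1.0
    bounds: tuple[float, float] = (-10.0, 15.0)
    max_epochs: int = 20
    seed: int = 0
    freeze_conserved: bool = False
    min_overlap: int = 8

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")


def objective(
    profiles: list[ActivityProfile],
    pos: AnnotatedDataset,
    neg: AnnotatedDataset,
    config: TrainingConfig = TrainingConfig(),
    scan_config: ScanConfig | None = None,
) -> float:
    """Negative weighted error count; higher is better, 0 is perfect."""
    from .evaluate import match_predictions

    scan_config = _training_scan_config(scan_config, config)
    preds_pos = scan_sequences(pos.sequences, profiles, scan_config)
    tp, fp_pos, fn = match_predictions(preds_pos, pos, min_overlap=config.min_overlap)
    preds_neg = scan_sequences(neg.sequences, profiles, scan_config)
    fp = fp_pos + len(preds_neg)
    return -(config.lambda_fn * fn + config.lambda_fp * fp)


def _training_scan_config(scan_config: ScanConfig | None, config: TrainingConfig) -> ScanConfig:
    from dataclasses import replace

    base = scan_config if scan_config is not None else ScanConfig()
    return replace(base, threshold=config.threshold)


def _violation(
    profiles: list[ActivityProfile],
    pos: AnnotatedDataset,
    neg: AnnotatedDataset,
    config: TrainingConfig,
    scan_config: ScanConfig | None,
) -> float:
    """Continuous surrogate of the error count.

    Sum of (adjusted score - threshold) over false-call windows above
    threshold, plus (threshold - best adjusted score) over true NESs whose
    best-overlapping window sits below it; windows touching a true range at
    all are not counted as false calls (they merge into the true call).
    """
    from dataclasses import replace

    base = scan_config if scan_config is not None else ScanConfig()
    sweep = replace(base, threshold=-1e9, merge_overlaps=False)
    excess = 0.0
    deficit = 0.0
    ranges = pos.ranges_by_id()
    for dataset in (pos, neg):
        truth = ranges if dataset is pos else {}
        for rec in dataset.sequences:
            rec_ranges = truth.get(rec.id, [])
            best = [-1e9] * len(rec_ranges)
            for pred in scan_sequences([rec], profiles, sweep):
                overlaps = False
                for idx, (s, e, _) in enumerate(rec_ranges):
                    ov = min(pred.end, e) - max(pred.start, s) + 1
                    if ov > 0:
                        overlaps = True
                        if ov >= config.min_overlap:
                            best[idx] = max(best[idx], pred.adjusted_score)
                if not overlaps and pred.adjusted_score > config.threshold:
                    excess += pred.adjusted_score - config.threshold
            for b in best:
                if b < config.threshold:
                    deficit += config.threshold - max(b, config.threshold - 100.0)
    return config.lambda_fp * excess + config.lambda_fn * deficit


@dataclass
class TrainingLog:
    """Objective trajectory: initial value then one entry per epoch."""

    objectives: list[float] = field(default_factory=list)
    accepted_moves: list[int] = field(default_factory=list)


def optimize_profiles(
    profiles: list[ActivityProfile],
    pos: AnnotatedDataset,
    neg: AnnotatedDataset,
    config: TrainingConfig = TrainingConfig(),
    scan_config: ScanConfig | None = None,
) -> tuple[list[ActivityProfile], TrainingLog]:
    """Greedy coordinate ascent over profile cells; see module docstring."""
    profiles = [pr.copy() for pr in profiles]
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    current = objective(profiles, pos, neg, config, scan_config)
    log = TrainingLog(objectives=[current])

    cells = []
    for pi, profile in enumerate(profiles):
        frozen_cols = {i - 1: AA_INDEX[profile.template[i - 1]] for i in range(1, profile.length + 1)}
        for i in range(profile.length):
            for k in range(20):
                if frozen_cols.get(i) == k:
                    continue  # template diagonal anchors the normalisation
                if config.freeze_conserved and (i + 1) in profile.conserved_positions:
                    continue
                cells.append((pi, i, k))

    current_violation = _violation(profiles, pos, neg, config, scan_config)
    for _ in range(config.max_epochs):
        order = rng.permutation(len(cells))
        accepted = 0
        for idx in order:
            pi, i, k = cells[idx]
            base = profiles[pi].matrix[i, k]
            best_value = base
            best_obj, best_violation = current, current_violation
            for direction in (config.step, -config.step):
                candidate = base + direction
                if not lo <= candidate <= hi:
                    continue
                profiles[pi].matrix[i, k] = candidate
                trial = objective(profiles, pos, neg, config, scan_config)
                trial_violation = _violation(profiles, pos, neg, config, scan_config)
                better = trial > best_obj or (
                    trial == best_obj and trial_violation < best_violation - 1e-9
                )
                if better:
                    best_value = candidate
                    best_obj, best_violation = trial, trial_violation
            profiles[pi].matrix[i, k] = best_value
            if best_value != base:
                current, current_violation = best_obj, best_violation
                accepted += 1
        log.objectives.append(current)
        log.accepted_moves.append(accepted)
        if accepted == 0:
            break
    return profiles, log


def read_annotations(
    path, sequences: list[SequenceRecord]
) -> tuple[AnnotatedDataset, AnnotatedDataset]:
    """Read the tab-separated annotation format.

    Columns: sequence_id, start, end, class, polarity.  Negative sequences
    without ranges use NA for start/end/class.  Returns the positive and
    negative datasets over the given sequences.
    """
    by_id = {rec.id: rec for rec in sequences}
    pos_ranges: dict[str, list[NesRange]] = {}
    neg_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(f)}")
            seq_id, start, end, cls, polarity = f
            if seq_id not in by_id:
                raise KeyError(f"{path}:{lineno}: unknown sequence id {seq_id!r}")
            if polarity == "negative" and start == "NA":
                neg_ids.add(seq_id)
                continue
            rng_tuple = (
                int(start),
                int(end),
                None if cls == "NA" else NesClass(cls),
            )
            if polarity == "positive":
                pos_ranges.setdefault(seq_id, []).append(rng_tuple)
            else:
                neg_ids.add(seq_id)
    pos = AnnotatedDataset(
        records=[(by_id[i], pos_ranges[i]) for i in pos_ranges], polarity="positive"
    )
    neg = AnnotatedDataset(
        records=[(by_id[i], []) for i in sorted(neg_ids)], polarity="negative"
    )
    return pos, neg


def write_annotations(path, pos: AnnotatedDataset, neg: AnnotatedDataset | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("#sequence_id\tstart\tend\tclass\tpolarity\n")
        for rec, ranges in pos.records:
            for start, end, cls in ranges:
                cls_str = cls.value if cls is not None else "NA"
                fh.write(f"{rec.id}\t{start}\t{end}\t{cls_str}\tpositive\n")
        if neg is not None:
            for rec, _ in neg.records:
                fh.write(f"{rec.id}\tNA\tNA\tNA\tnegative\n")
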