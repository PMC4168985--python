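"""Scikit-learn-style estimators wrapping the scanner, trainer and matchers.

``NesScanner`` is a detector: ``fit`` optionally optimises the activity
profiles against annotated sequences (greedy coordinate ascent on the
weighted error count), ``predict`` scans sequences and returns per-sequence
NES predictions.  ``ConsensusMatcher`` is the stateless consensus-pattern
counterpart.  Both follow the sklearn parameter contract
(``get_params``/``set_params``/``clone``); X is a list of protein sequences
(strings or :class:`~nescan.io.SequenceRecord`), y a list of true-NES range
lists (empty list = negative sequence).
"""

from __future__ import annotations

from dataclasses import replace

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import consensus as consensus_mod
from .defaults import default_profiles
from .evaluate import evaluate
from .io import SequenceRecord
from .profiles import ActivityProfile, NesClass
from .scanner import ScanConfig, scan_protein
from .train import AnnotatedDataset, TrainingConfig, optimize_profiles


def _as_records(X) -> list[SequenceRecord]:
    records = []
    for i, x in enumerate(X):
        if isinstance(x, SequenceRecord):
            records.append(x)
        elif isinstance(x, str):
            records.append(SequenceRecord(id=f"seq_{i}", residues=x.upper()))
        else:
            raise TypeError(f"X[{i}]: expected str or SequenceRecord, got {type(x)}")
    return records


def _as_ranges(y, records):
    datasets: list[tuple[SequenceRecord, list]] = []
    if len(y) != len(records):
        raise ValueError(f"len(y)={len(y)} != len(X)={len(records)}")
    for rec, ranges in zip(records, y):
        parsed = []
        for r in ranges:
            if len(r) == 2:
                start, end = r
                cls = None
            else:
                start, end, cls = r
                if isinstance(cls, str):
                    cls = NesClass(cls)
            parsed.append((int(start), int(end), cls))
        datasets.append((rec, parsed))
    return datasets


class NesScanner(BaseEstimator):
    """Activity-profile NES detector.

    Parameters
    ----------
    profiles
        Activity profiles to scan with; ``None`` uses the bundled synthetic
        set.
    threshold
        Minimum adjusted score for a call.
    enabled_classes
        Class ids scanned (profile must be present for each).
    max_epochs
        Training epochs in :meth:`fit` when annotations are supplied;
        0 disables optimisation (profiles are adopted as-is).
    """

    def __init__(
        self,
        profiles: list[ActivityProfile] | None = None,
        threshold: float = 2.0,
        enabled_classes: tuple[str, ...] = ("1a3", "1b", "1c", "2"),
        include_class_1d: bool = False,
        apply_penalty: bool = True,
        apply_flank_adjustment: bool = True,
        merge_overlaps: bool = True,
        penalty_value: float = -7.0,
        penalty_rate_threshold: float = 0.4,
        min_overlap: int = 8,
        lambda_fp: float = 1.0,
        lambda_fn: float = 2.0,
        step: float = 1.0,
        max_epochs: int = 0,
        random_state: int = 0,
    ):
        self.profiles = profiles
        self.threshold = threshold
        self.enabled_classes = enabled_classes
        self.include_class_1d = include_class_1d
        self.apply_penalty = apply_penalty
        self.apply_flank_adjustment = apply_flank_adjustment
        self.merge_overlaps = merge_overlaps
        self.penalty_value = penalty_value
        self.penalty_rate_threshold = penalty_rate_threshold
        self.min_overlap = min_overlap
        self.lambda_fp = lambda_fp
        self.lambda_fn = lambda_fn
        self.step = step
        self.max_epochs = max_epochs
        self.random_state = random_state

    def _scan_config(self) -> ScanConfig:
        return ScanConfig(
            enabled_classes=frozenset(NesClass(c) for c in self.enabled_classes),
            threshold=self.threshold,
            penalty_value=self.penalty_value,
            penalty_rate_threshold=self.penalty_rate_threshold,
            apply_penalty=self.apply_penalty,
            apply_flank_adjustment=self.apply_flank_adjustment,
            include_class_1d=self.include_class_1d,
            merge_overlaps=self.merge_overlaps,
        )

    def fit(self, X, y=None):
        """Adopt (and optionally optimise) the activity profiles.

        With annotations ``y`` and ``max_epochs > 0``, profiles are trained
        by coordinate ascent; otherwise they are copied unchanged.
        """
        base = self.profiles if self.profiles is not None else default_profiles()
        records = _as_records(X)
        self.profiles_ = [pr.copy() for pr in base]
        self.training_log_ = None
        if y is not None and self.max_epochs > 0:
            annotated = _as_ranges(y, records)
            pos = AnnotatedDataset(
                records=[(r, rg) for r, rg in annotated if rg], polarity="positive"
            )
            neg = AnnotatedDataset(
                records=[(r, []) for r, rg in annotated if not rg],
                polarity="negative",
            )
            config = TrainingConfig(
                threshold=self.threshold,
                lambda_fp=self.lambda_fp,
                lambda_fn=self.lambda_fn,
                step=self.step,
                max_epochs=self.max_epochs,
                seed=self.random_state,
                min_overlap=self.min_overlap,
            )
            self.profiles_, self.training_log_ = optimize_profiles(
                self.profiles_, pos, neg, config, self._scan_config()
            )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Per-sequence lists of :class:`~nescan.scanner.NesPrediction`."""
        check_is_fitted(self, "profiles_")
        config = self._scan_config()
        return [scan_protein(rec, self.profiles_, config) for rec in _as_records(X)]

    def score(self, X, y):
        """Site-level sensitivity of predictions against annotations."""
        check_is_fitted(self, "profiles_")
        records = _as_records(X)
        annotated = _as_ranges(y, records)
        pos = AnnotatedDataset(
            records=[(r, rg) for r, rg in annotated if rg], polarity="positive"
        )
        neg = AnnotatedDataset(
            records=[(r, []) for r, rg in annotated if not rg], polarity="negative"
        )
        preds = [p for sub in self.predict(X) for p in sub]
        result = evaluate(preds, pos, neg if neg.records else None, self.min_overlap)
        return result.sensitivity


class ConsensusMatcher(BaseEstimator):
    """Consensus-pattern NES matcher (traditional or improved dialect)."""

    def __init__(
        self,
        dialect: str = "traditional",
        nes_class: str | None = None,
        strict: bool = False,
    ):
        self.dialect = dialect
        self.nes_class = nes_class
        self.strict = strict

    def fit(self, X=None, y=None):
        if self.dialect not in ("traditional", "improved"):
            raise ValueError(f"dialect {self.dialect!r}")
        if self.dialect == "improved" and self.nes_class is None:
            raise ValueError("improved dialect needs nes_class")
        self.dialect_ = self.dialect
        return self

    def predict(self, X):
        """Per-sequence lists of :class:`~nescan.consensus.ConsensusMatch`."""
        check_is_fitted(self, "dialect_")
        out = []
        for rec in _as_records(X):
            if self.dialect_ == "traditional":
                matches = consensus_mod.match_traditional(rec.residues)
            else:
                matches = consensus_mod.match_improved(
                    rec.residues, NesClass(self.nes_class), strict=self.strict
                )
            out.append([replace(m, sequence_id=rec.id) for m in matches])
        return out
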