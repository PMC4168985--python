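"""Sliding-window NES scanning.

The scanner slides a window over the protein (shift 1), scores every window
against every enabled class profile with the additive Ts rule, penalises
windows whose spacer positions are hydrophobic-rich (membrane spans and
buried cores mimic NES cores but not their context), multiplies positive
scores by the flank likelihood ratios, thresholds, and merges overlapping
same-class calls keeping the best-scoring window.

Windows abutting the N-terminus that are shorter than the profile are scored
with the leading profile positions dropped (profile start p = 2..4, window
lengths L-1..L-3), so for the canonical 14-column profiles the N-terminal
region is scanned with 11-13 residue windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .flanks import (
    DEFAULT_HPR_TABLE,
    DEFAULT_NC_TABLE,
    FlankFeatures,
    LikelihoodTable,
    flank_features,
)
from .io import SequenceRecord
from .profiles import AA_INDEX, PHI, ActivityProfile, NesClass, compute_ts

logger = logging.getLogger(__name__)

#: deepest N-terminal profile truncation (profile start position)
MAX_PROFILE_START = 4

#: report order for classes at equal start coordinate
CLASS_ORDER = {
    NesClass.CLASS_1A3: 0,
    NesClass.CLASS_1B: 1,
    NesClass.CLASS_1C: 2,
    NesClass.CLASS_2: 3,
    NesClass.CLASS_1A: 4,
    NesClass.CLASS_1D: 5,
    NesClass.CLASS_3: 6,
}

DEFAULT_CLASSES = frozenset(
    {NesClass.CLASS_1A3, NesClass.CLASS_1B, NesClass.CLASS_1C, NesClass.CLASS_2}
)


@dataclass(frozen=True)
class NesPrediction:
    """A scored candidate NES (1-based inclusive coordinates)."""

    sequence_id: str
    nes_class: NesClass | None
    start: int
    end: int
    window: str
    raw_score: float
    penalty: float
    spacer_hydrophobicity_rate: float
    flank: FlankFeatures | None
    multiplier: float
    adjusted_score: float


@dataclass(frozen=True)
class ScanConfig:
    """Scanner settings; defaults are the tool's operating point."""

    enabled_classes: frozenset[NesClass] = DEFAULT_CLASSES
    threshold: float = 2.0
    window_size: int = 14
    min_n_terminal_window: int = 11
    shift: int = 1
    penalty_value: float = -7.0
    penalty_rate_threshold: float = 0.4
    hydrophobic_set: frozenset[str] = frozenset(PHI)
    apply_penalty: bool = True
    apply_flank_adjustment: bool = True
    include_class_1d: bool = False
    merge_overlaps: bool = True
    hpr_table: LikelihoodTable = DEFAULT_HPR_TABLE
    nc_table: LikelihoodTable = DEFAULT_NC_TABLE

    def __post_init__(self) -> None:
        if self.shift < 1:
            raise ValueError("shift must be >= 1")
        if not 0 < self.penalty_rate_threshold <= 1:
            raise ValueError("penalty_rate_threshold must be in (0, 1]")

    def active_classes(self) -> frozenset[NesClass]:
        classes = set(self.enabled_classes)
        if self.include_class_1d:
            classes.add(NesClass.CLASS_1D)
        return frozenset(classes)


def spacer_hydrophobicity(
    window: str,
    profile: ActivityProfile,
    hydrophobic_set: frozenset[str] = frozenset(PHI),
    p: int = 1,
) -> float:
    """Fraction of the profile's spacer positions holding a hydrophobic residue.

    The window is aligned to profile positions p..L; spacer positions are all
    profile positions not conserved.  Raises when the profile (after
    truncation) has no spacer positions.
    """
    spacers = [i for i in profile.spacer_positions if i >= p]
    if not spacers:
        raise ValueError("profile has no spacer positions")
    count = sum(1 for i in spacers if window[i - p] in hydrophobic_set)
    return count / len(spacers)


def apply_penalty(raw_score: float, rate: float, config: ScanConfig = ScanConfig()) -> float:
    """Add the hydrophobicity penalty when the spacer rate reaches threshold."""
    if rate >= config.penalty_rate_threshold:
        return raw_score + config.penalty_value
    return raw_score


def _profile_arrays(profile: ActivityProfile) -> tuple[np.ndarray, np.ndarray]:
    """Delta matrix (L, 21) with an all-zero X column, and spacer offsets."""
    delta = np.zeros((profile.length, 21))
    delta[:, :20] = profile.matrix - profile.st
    spacer_offsets = np.array([i - 1 for i in profile.spacer_positions], dtype=int)
    return delta, spacer_offsets


def _encode(residues: str) -> np.ndarray:
    return np.array([AA_INDEX.get(aa, 20) for aa in residues], dtype=int)


def scan_protein(
    seq: SequenceRecord,
    profiles: Sequence[ActivityProfile],
    config: ScanConfig = ScanConfig(),
) -> list[NesPrediction]:
    """Scan one protein against the enabled class profiles.

    Returns predictions with adjusted score >= threshold, merged per class
    when configured, sorted by (start, class).  Sequences too short for even
    the most truncated window yield an empty list with a warning.
    """
    active = config.active_classes()
    chosen = [pr for pr in profiles if pr.nes_class in active]
    n = len(seq)
    enc = _encode(seq.residues)
    hydro = np.array([aa in config.hydrophobic_set for aa in seq.residues], dtype=float)

    predictions: list[NesPrediction] = []
    min_len = min((pr.length for pr in chosen), default=0) - (MAX_PROFILE_START - 1)
    if chosen and n < max(1, min_len):
        logger.warning(
            "%s: length %d shorter than the shortest scannable window; no scan",
            seq.id,
            n,
        )
        return []

    for profile in chosen:
        delta, spacer_offsets = _profile_arrays(profile)
        L = profile.length
        # full-length windows, profile start p=1
        if n >= L:
            starts = np.arange(0, n - L + 1, config.shift)
            win_idx = starts[:, None] + np.arange(L)[None, :]
            raw = profile.st + delta[np.arange(L)[None, :], enc[win_idx]].sum(axis=1)
            rates = hydro[win_idx[:, spacer_offsets]].mean(axis=1)
            for s, r, rate in zip(starts, raw, rates):
                predictions.extend(
                    _finalize(seq, profile, int(s) + 1, int(s) + L, float(r), float(rate), config)
                )
        # N-terminally truncated windows anchored at residue 1
        for p in range(2, MAX_PROFILE_START + 1):
            wlen = L - p + 1
            if wlen < 1 or n < wlen:
                continue
            window = seq.residues[:wlen]
            raw_score = compute_ts(window, profile, p=p)
            spacers = [i for i in profile.spacer_positions if i >= p]
            if spacers:
                rate = sum(
                    1 for i in spacers if window[i - p] in config.hydrophobic_set
                ) / len(spacers)
            else:
                rate = 0.0
            predictions.extend(
                _finalize(seq, profile, 1, wlen, raw_score, rate, config)
            )

    if config.merge_overlaps:
        predictions = merge_predictions(predictions)
    predictions.sort(key=lambda pr: (pr.start, CLASS_ORDER.get(pr.nes_class, 99)))
    return predictions


def _finalize(
    seq: SequenceRecord,
    profile: ActivityProfile,
    start: int,
    end: int,
    raw_score: float,
    rate: float,
    config: ScanConfig,
) -> list[NesPrediction]:
    penalty = 0.0
    if config.apply_penalty and rate >= config.penalty_rate_threshold:
        penalty = config.penalty_value
    penalized = raw_score + penalty
    flank: FlankFeatures | None = None
    multiplier = 1.0
    if penalized > 0 and config.apply_flank_adjustment:
        flank = flank_features(
            seq.residues, start, end, config.hpr_table, config.nc_table
        )
        multiplier = flank.multiplier
        adjusted = penalized * multiplier
    else:
        adjusted = penalized
    if adjusted < config.threshold:
        return []
    return [
        NesPrediction(
            sequence_id=seq.id,
            nes_class=profile.nes_class,
            start=start,
            end=end,
            window=seq.residues[start - 1 : end],
            raw_score=raw_score,
            penalty=penalty,
            spacer_hydrophobicity_rate=rate,
            flank=flank,
            multiplier=multiplier,
            adjusted_score=adjusted,
        )
    ]


def merge_predictions(predictions: Iterable[NesPrediction]) -> list[NesPrediction]:
    """Collapse overlapping same-class predictions to the best window.

    Within each (sequence, class), overlapping calls form chains; each chain
    keeps its maximum-adjusted-score member, ties broken by smaller start.
    Cross-class overlaps are all reported.
    """
    by_key: dict[tuple[str, NesClass | None], list[NesPrediction]] = {}
    for pred in predictions:
        by_key.setdefault((pred.sequence_id, pred.nes_class), []).append(pred)
    merged: list[NesPrediction] = []
    for group in by_key.values():
        group.sort(key=lambda pr: (pr.start, pr.end))
        chain: list[NesPrediction] = []
        chain_end = -1
        for pred in group:
            if chain and pred.start > chain_end:
                merged.append(_best(chain))
                chain = []
                chain_end = -1
            chain.append(pred)
            chain_end = max(chain_end, pred.end)
        if chain:
            merged.append(_best(chain))
    merged.sort(key=lambda pr: (pr.sequence_id, pr.start, CLASS_ORDER.get(pr.nes_class, 99)))
    return merged


def _best(chain: list[NesPrediction]) -> NesPrediction:
    return max(
        chain,
        key=lambda pr: (
            pr.adjusted_score,
            -pr.start,
            -CLASS_ORDER.get(pr.nes_class, 99),
        ),
    )


def scan_sequences(
    records: Iterable[SequenceRecord],
    profiles: Sequence[ActivityProfile],
    config: ScanConfig = ScanConfig(),
) -> list[NesPrediction]:
    """Scan a collection of proteins; concatenated per-sequence results."""
    out: list[NesPrediction] = []
    for rec in records:
        out.extend(scan_protein(rec, profiles, config))
    return out
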