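"""Deterministic synthetic data: toy profiles and proteomes with planted NESs.

The generator emulates, at the statistical level, the kinds of sequences the
scanner is meant to separate: proteins carrying a genuine class-consensus
NES in a polar, acidic context, and decoy proteins whose hydrophobic
segments mimic an NES core (membrane spans, buried cores) without the
context.  Everything is driven by one seeded generator, so identical
configurations give byte-identical FASTA and annotations.

What it does **not** emulate: real proteome residue composition (background
is uniform by default), disorder/structure, or correlated positions within
motifs — passing tests on this data show the machinery is correct, not that
real-proteome error rates are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import consensus
from .flanks import HPR_HYDROPHOBIC, HPR_POLAR, compute_hpr, compute_nc
from .io import SequenceRecord
from .profiles import AA_INDEX, AMINO_ACIDS, PHI, ActivityProfile, NesClass, compute_ts
from .train import AnnotatedDataset

#: designed template sequences (14 columns); class 1b and 1c templates and
#: their standard scores follow the published profile set, the others are
#: synthetic stand-ins satisfying their class consensus
DEFAULT_TEMPLATES: dict[NesClass, tuple[str, tuple[int, ...], float]] = {
    NesClass.CLASS_1A: ("SNELAQKLAGLDLN", (4, 8, 11, 13), 8.0),
    NesClass.CLASS_1A3: ("LNELAQKLAGLDLN", (1, 4, 8, 11, 13), 8.0),
    NesClass.CLASS_1B: ("PSSELAKLAGLDLN", (5, 8, 11, 13), 4.0),
    NesClass.CLASS_1C: ("SELAEKLQAGLDLN", (3, 7, 11, 13), 8.0),
    NesClass.CLASS_1D: ("SEQLAELQAGLDLN", (4, 7, 11, 13), 5.0),
    NesClass.CLASS_2: ("SEQLELSELELNSD", (4, 6, 9, 11), 3.0),
    NesClass.CLASS_3: ("SELAELQAGLDELN", (3, 6, 10, 13), 6.0),
}

#: improved-consensus class used to validate a planted motif of each class
_VALIDATION_CLASS = {
    NesClass.CLASS_1A3: NesClass.CLASS_1A,  # validate the four-Phi core
}

REJECTION_CAP = 10_000


def make_toy_profile(
    nes_class: NesClass,
    st: float | None = None,
    seed: int = 0,
    template: str | None = None,
    conserved_positions: tuple[int, ...] | None = None,
) -> ActivityProfile:
    """A synthetic activity profile with realistic cell structure.

    Template cells score ``st``; non-hydrophobic residues at conserved
    positions score at most ``st - 3``; proline in the spacer acts as a
    strong repressor (at most ``st - 4``, it abolishes activity in the
    assayed profiles); all other cells sit in ``[st - 2, st + 1]``.
    """
    default_template, default_phi, default_st = DEFAULT_TEMPLATES[nes_class]
    template = template or default_template
    conserved = conserved_positions or default_phi
    st = default_st if st is None else float(st)
    rng = np.random.default_rng(seed)
    L = len(template)
    matrix = np.round(rng.uniform(st - 2, st + 1, size=(L, 20)), 2)
    conserved_set = set(conserved)
    for i in range(L):
        for k, aa in enumerate(AMINO_ACIDS):
            if (i + 1) in conserved_set and aa not in PHI:
                matrix[i, k] = round(rng.uniform(st - 6, st - 3), 2)
            elif (i + 1) not in conserved_set and aa == "P":
                matrix[i, k] = round(rng.uniform(st - 7, st - 4), 2)
        matrix[i, AA_INDEX[template[i]]] = st
    return ActivityProfile(
        nes_class=nes_class,
        template=template,
        st=st,
        matrix=matrix,
        conserved_positions=tuple(conserved),
    )


@dataclass(frozen=True)
class FixtureConfig:
    """Synthetic proteome settings.

    Positive proteins carry ``planted_per_protein`` template-grade NESs
    (classes cycled from ``planted_classes``) with flanks synthesised into
    the requested HPR/NC bins; decoy proteins carry an NES-shaped segment
    whose spacers were made hydrophobic (scoring above threshold before the
    penalty, below it after) plus optional plain hydrophobic stretches.
    """

    n_proteins: int = 10
    n_decoy_proteins: int = 5
    min_length: int = 120
    max_length: int = 200
    planted_classes: tuple[NesClass, ...] = (
        NesClass.CLASS_1C,
        NesClass.CLASS_1B,
        NesClass.CLASS_2,
        NesClass.CLASS_1A3,
    )
    planted_per_protein: int = 1
    #: target HPR bin (lo, hi] for the N-flank of planted NESs
    target_hpr_bin: tuple[float | None, float | None] = (None, 30.0)
    #: target NC bin (lo, hi] for the C-flank of planted NESs
    target_nc_bin: tuple[float | None, float | None] = (None, -4.0)
    decoy_segments: int = 1
    decoy_length: int = 14
    decoy_hydrophobic_fraction: float = 0.8
    #: decoy raw-score window (above threshold, within penalty reach)
    decoy_score_range: tuple[float, float] = (2.5, 8.5)
    background_frequencies: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        need = 14 + 2 * 25
        if self.min_length < need:
            raise ValueError(
                f"min_length {self.min_length} cannot hold a planted NES with "
                f"25-residue flanks (need >= {need})"
            )
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")


def _background(rng: np.random.Generator, n: int, freqs: tuple[float, ...] | None) -> str:
    p = None if freqs is None else np.asarray(freqs) / np.sum(freqs)
    idx = rng.choice(20, size=n, p=p)
    return "".join(AMINO_ACIDS[k] for k in idx)


def _in_bin(value: float, lo: float | None, hi: float | None) -> bool:
    return (lo is None or value > lo) and (hi is None or value <= hi)


def _sample_hpr_flank(rng: np.random.Generator, lo, hi) -> str:
    """Rejection-sample a 25-mer whose HPR lands in (lo, hi]."""
    target = ((0 if lo is None else lo) + (100 if hi is None else hi)) / 2
    hydro, polar = sorted(HPR_HYDROPHOBIC), sorted(HPR_POLAR)
    for _ in range(REJECTION_CAP):
        flank = "".join(
            hydro[rng.integers(len(hydro))]
            if rng.random() < target / 100
            else polar[rng.integers(len(polar))]
            for _ in range(25)
        )
        value = compute_hpr(flank)
        if value is not None and _in_bin(value, lo, hi):
            return flank
    raise RuntimeError(f"could not synthesise an N-flank with HPR in ({lo}, {hi}]")


def _sample_nc_flank(rng: np.random.Generator, lo, hi) -> str:
    """Rejection-sample a 25-mer whose net charge lands in (lo, hi]."""
    target = ((-12 if lo is None else lo) + (12 if hi is None else hi)) / 2
    p_acid = min(0.45, max(0.05, 0.2 - target / 50))
    p_base = min(0.45, max(0.05, 0.2 + target / 50))
    neutral = sorted(set("STNQGAY") )
    for _ in range(REJECTION_CAP):
        residues = []
        for _ in range(25):
            u = rng.random()
            if u < p_acid:
                residues.append("DE"[rng.integers(2)])
            elif u < p_acid + p_base:
                residues.append("KR"[rng.integers(2)])
            else:
                residues.append(neutral[rng.integers(len(neutral))])
        flank = "".join(residues)
        if _in_bin(compute_nc(flank), lo, hi):
            return flank
    raise RuntimeError(f"could not synthesise a C-flank with NC in ({lo}, {hi}]")


def _make_decoy_segment(
    rng: np.random.Generator,
    profile: ActivityProfile,
    score_range: tuple[float, float],
) -> str:
    """Template with hydrophobic spacer substitutions.

    Enough spacers are substituted to trip the hydrophobicity penalty
    (rate >= 0.4); residue choices are rejection-sampled until the raw Ts
    lies in ``score_range`` — called without the penalty, suppressed with it.
    """
    spacers = profile.spacer_positions
    k = max(1, int(np.ceil(0.4 * len(spacers))) + 1)
    phi = sorted(PHI)
    lo, hi = score_range
    for _ in range(REJECTION_CAP):
        chosen = rng.choice(len(spacers), size=k, replace=False)
        window = list(profile.template)
        for c in chosen:
            window[spacers[c] - 1] = phi[rng.integers(len(phi))]
        window = "".join(window)
        if lo <= compute_ts(window, profile) <= hi:
            return window
    raise RuntimeError(
        f"could not build a decoy segment scoring in [{lo}, {hi}] for class "
        f"{profile.nes_class.value}"
    )


def _plain_hydrophobic_stretch(rng: np.random.Generator, length: int, fraction: float) -> str:
    phi = sorted(PHI)
    polar = sorted(HPR_POLAR)
    return "".join(
        phi[rng.integers(len(phi))] if rng.random() < fraction else polar[rng.integers(len(polar))]
        for _ in range(length)
    )


def generate_proteome(
    config: FixtureConfig,
    profiles: dict[NesClass, ActivityProfile] | None = None,
) -> tuple[list[SequenceRecord], AnnotatedDataset, AnnotatedDataset]:
    """Synthesise a proteome with annotated positives and decoy negatives.

    Every planted NES is re-validated against its class's improved
    consensus before emission.  Returns (records, positives, negatives).
    """
    if profiles is None:
        from .defaults import default_profiles

        profiles = {pr.nes_class: pr for pr in default_profiles()}
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    pos_records = []
    neg_records = []

    for n in range(config.n_proteins):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        residues = list(_background(rng, length, config.background_frequencies))
        ranges = []
        slots = _placement_slots(rng, length, config.planted_per_protein)
        for slot, _ in zip(slots, range(config.planted_per_protein)):
            nes_class = config.planted_classes[
                (n * config.planted_per_protein + len(ranges)) % len(config.planted_classes)
            ]
            template, _, _ = DEFAULT_TEMPLATES[nes_class]
            _validate_planted(template, nes_class)
            start = slot  # 1-based
            residues[start - 1 : start - 1 + len(template)] = template
            n_flank = _sample_hpr_flank(rng, *config.target_hpr_bin)
            residues[start - 26 : start - 1] = n_flank
            c_flank = _sample_nc_flank(rng, *config.target_nc_bin)
            end = start + len(template) - 1
            residues[end : end + 25] = c_flank
            ranges.append((start, end, nes_class))
        rec = SequenceRecord(id=f"pos_{n + 1:04d}", residues="".join(residues))
        records.append(rec)
        pos_records.append((rec, ranges))

    decoy_profile = profiles[NesClass.CLASS_1C]
    for n in range(config.n_decoy_proteins):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        residues = list(_background(rng, length, config.background_frequencies))
        start = _placement_slots(rng, length, 1)[0]
        segment = _make_decoy_segment(rng, decoy_profile, config.decoy_score_range)
        residues[start - 1 : start - 1 + len(segment)] = segment
        # neutral flanks keep the decoy's call dependent on the penalty alone
        residues[start - 26 : start - 1] = _sample_hpr_flank(rng, 50, 60)
        end = start + len(segment) - 1
        residues[end : end + 25] = _sample_nc_flank(rng, -4, 0)
        occupied = [(start - 25, end + 25)]
        for slot in _stretch_slots(
            rng, length, config.decoy_segments, config.decoy_length, occupied
        ):
            stretch = _plain_hydrophobic_stretch(
                rng, config.decoy_length, config.decoy_hydrophobic_fraction
            )
            residues[slot - 1 : slot - 1 + len(stretch)] = stretch
        rec = SequenceRecord(id=f"neg_{n + 1:04d}", residues="".join(residues))
        records.append(rec)
        neg_records.append((rec, []))

    positives = AnnotatedDataset(records=pos_records, polarity="positive")
    negatives = AnnotatedDataset(records=neg_records, polarity="negative")
    return records, positives, negatives


def _placement_slots(rng: np.random.Generator, length: int, count: int) -> list[int]:
    """Non-overlapping 1-based start slots with >=26 residues on each side."""
    lo, hi = 27, length - 14 - 25
    if hi < lo:
        raise ValueError(f"protein of length {length} cannot host a planted segment")
    slots: list[int] = []
    for _ in range(REJECTION_CAP):
        if len(slots) == count:
            break
        cand = int(rng.integers(lo, hi + 1))
        if all(abs(cand - s) >= 64 for s in slots):
            slots.append(cand)
    if len(slots) < count:
        raise ValueError(
            f"could not place {count} segments in a protein of length {length}"
        )
    return slots


def _stretch_slots(
    rng: np.random.Generator,
    length: int,
    count: int,
    seg_length: int,
    occupied: list[tuple[int, int]],
) -> list[int]:
    """Start slots for plain stretches avoiding already-occupied intervals."""
    slots: list[int] = []
    intervals = list(occupied)
    for _ in range(REJECTION_CAP):
        if len(slots) == count:
            break
        cand = int(rng.integers(1, length - seg_length + 2))
        span = (cand, cand + seg_length - 1)
        if all(span[1] < lo or span[0] > hi for lo, hi in intervals):
            slots.append(cand)
            intervals.append(span)
    if len(slots) < count:
        raise ValueError(
            f"could not place {count} decoy stretches in a protein of length {length}"
        )
    return slots


def _validate_planted(template: str, nes_class: NesClass) -> None:
    check_class = _VALIDATION_CLASS.get(nes_class, nes_class)
    if not consensus.match_improved(template, check_class):
        raise AssertionError(
            f"planted template {template!r} fails the class {check_class.value} "
            "improved consensus"
        )
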