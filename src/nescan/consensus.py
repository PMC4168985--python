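"""Consensus-pattern matching for leucine-rich NESs.

Two dialects:

* **traditional** — the classical consensus Phi-X(2,3)-Phi-X(2,3)-Phi-X-Phi
  with Phi in {L,I,V,M,F} and X any residue; one pattern, class-agnostic.
* **improved** — per-class patterns with fixed Phi spacing, proline excluded
  from marked spacer positions, weak hydrophobics {C,W,A,T} allowed at no
  more than one conserved position, and candidates rejected when a stretch
  of more than four consecutive hydrophobic residues covers the second and
  third conserved positions (such stretches mark buried/membrane segments,
  not export signals).

Matching is by explicit enumeration of starts and spacer-length choices —
the pattern alphabet is tiny and enumeration keeps every overlapping match.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles import PHI, WEAK_PHI, NesClass

ANY = "X"
NOT_P = "^P"

#: spacer specs per improved-dialect class: one tuple of position constraints
#: per inter-Phi gap
IMPROVED_SPACERS: dict[NesClass, tuple[tuple[str, ...], ...]] = {
    NesClass.CLASS_1A: ((ANY, ANY, NOT_P), (NOT_P, NOT_P), (NOT_P,)),
    NesClass.CLASS_1B: ((ANY, NOT_P), (NOT_P, NOT_P), (NOT_P,)),
    NesClass.CLASS_1C: ((ANY, ANY, NOT_P), (NOT_P, NOT_P, NOT_P), (NOT_P,)),
    NesClass.CLASS_1D: ((ANY, NOT_P), (NOT_P, NOT_P, NOT_P), (NOT_P,)),
    NesClass.CLASS_2: ((NOT_P,), (NOT_P, NOT_P), (NOT_P,)),
    NesClass.CLASS_3: ((ANY, NOT_P), (NOT_P, NOT_P, NOT_P), (NOT_P, NOT_P)),
}

#: maximum weak-hydrophobic residues allowed at conserved positions
WEAK_QUOTA = 1

#: hydrophobic runs longer than this covering Phi2..Phi3 disqualify a match
MAX_HYDROPHOBIC_RUN = 4


@dataclass(frozen=True)
class ConsensusMatch:
    """A consensus hit with 1-based inclusive coordinates."""

    start: int
    end: int
    matched: str
    nes_class: NesClass | None = None
    sequence_id: str | None = None


def match_traditional(seq: str) -> list[ConsensusMatch]:
    """All matches of the classical consensus; overlapping starts reported,
    distinct (start, end) spans deduplicated."""
    hits: set[tuple[int, int]] = set()
    n = len(seq)
    for start in range(n):
        for g1 in (2, 3):
            for g2 in (2, 3):
                offsets = (0, g1 + 1, g1 + g2 + 2, g1 + g2 + 4)
                end = start + offsets[-1]
                if end >= n:
                    continue
                if all(seq[start + o] in PHI for o in offsets):
                    hits.add((start + 1, end + 1))
    return [
        ConsensusMatch(start=s, end=e, matched=seq[s - 1 : e])
        for s, e in sorted(hits)
    ]


def match_improved(
    seq: str,
    nes_class: NesClass,
    strict: bool = False,
    hydrophobic_set: frozenset[str] = frozenset(PHI),
) -> list[ConsensusMatch]:
    """All matches of a class's improved consensus pattern.

    ``strict`` additionally bars weak hydrophobics from the last two
    conserved positions (the refinement proposed for C-terminal pockets).
    """
    if nes_class not in IMPROVED_SPACERS:
        raise ValueError(f"no improved consensus for class {nes_class}")
    spacers = IMPROVED_SPACERS[nes_class]
    offsets = [0]
    constraints: list[str | None] = [None]  # None marks a conserved position
    for gap in spacers:
        constraints.extend(gap)
        offsets.append(offsets[-1] + len(gap) + 1)
        constraints.append(None)
    span = offsets[-1] + 1
    phi_offsets = tuple(offsets)

    hits = []
    n = len(seq)
    for start in range(n - span + 1):
        window = seq[start : start + span]
        if _matches_improved(window, phi_offsets, constraints, strict, hydrophobic_set):
            hits.append(
                ConsensusMatch(
                    start=start + 1,
                    end=start + span,
                    matched=window,
                    nes_class=nes_class,
                )
            )
    return hits


def _matches_improved(
    window: str,
    phi_offsets: tuple[int, ...],
    constraints: list[str | None],
    strict: bool,
    hydrophobic_set: frozenset[str],
) -> bool:
    weak_used = 0
    for o, c in enumerate(constraints):
        aa = window[o]
        if c is None:
            if aa in PHI:
                continue
            if aa in WEAK_PHI:
                if strict and o in phi_offsets[-2:]:
                    return False
                weak_used += 1
                if weak_used > WEAK_QUOTA:
                    return False
                continue
            return False
        if c == NOT_P and aa == "P":
            return False
    return not _hydrophobic_stretch(window, phi_offsets, hydrophobic_set)


def _hydrophobic_stretch(
    window: str,
    phi_offsets: tuple[int, ...],
    hydrophobic_set: frozenset[str],
) -> bool:
    """True when a >4-residue hydrophobic run covers Phi2 and Phi3.

    The second and third conserved positions are counted from the C-terminal
    four-Phi core (so the extra N-terminal Phi0 of five-position classes is
    skipped).
    """
    core = phi_offsets[-4:]
    phi2, phi3 = core[1], core[2]
    run = 0
    for o, aa in enumerate(window):
        if aa in hydrophobic_set:
            run += 1
            if run > MAX_HYDROPHOBIC_RUN and o - run + 1 <= phi2 and o >= phi3:
                return True
        else:
            run = 0
    return False
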