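"""Flanking-region features of candidate NESs and their likelihood ratios.

Functional NESs sit in locally disordered, polar, often acidic sequence
context; hydrophobic decoys (membrane spans, buried cores) do not.  Two
cheap context features capture this:

* **HPR** — the hydrophobic-to-polar amino acid ratio of the 25 residues
  N-terminal to the candidate, on a 0-100 scale: ``100 * h / (h + p)`` with
  hydrophobic {A,V,L,I,M,F,W,C} and polar {S,T,N,Q,Y,H,K,R,D,E}; glycine and
  proline belong to neither class.
* **NC** — the net charge of the 25 residues C-terminal to the candidate,
  ``(#K + #R) - (#D + #E)``; histidine is not counted.

Each feature maps through a binned likelihood-ratio table (positive vs
negative NES flank frequency distributions) to a multiplier applied to the
candidate's score.  Candidates too close to a terminus for a 25-residue
flank get a neutral multiplier of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

FLANK_LENGTH = 25

HPR_HYDROPHOBIC = frozenset("AVLIMFWC")
HPR_POLAR = frozenset("STNQYHKRDE")
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")


@dataclass(frozen=True)
class LikelihoodTable:
    """Ordered half-open bins (lo, hi] over a feature value -> multiplier.

    ``lo=None`` / ``hi=None`` mark unbounded ends; the bins partition the
    feature range so exactly one matches any value.
    """

    bins: tuple[tuple[float | None, float | None, float], ...]

    def multiplier(self, value: float | None) -> float:
        if value is None:
            return 1.0
        for lo, hi, mult in self.bins:
            if (lo is None or value > lo) and (hi is None or value <= hi):
                return mult
        raise ValueError(f"value {value} matched no bin")


#: printed likelihood ratios for the N-flank hydrophobic-to-polar ratio
DEFAULT_HPR_TABLE = LikelihoodTable(
    bins=(
        (None, 30, 2.5),
        (30, 40, 2.0),
        (40, 50, 1.4),
        (50, 60, 1.0),
        (60, 80, 0.6),
        (80, None, 0.5),
    )
)

#: printed likelihood ratios for the C-flank net charge; the middle bin
#: (-4, 0] has no printed ratio and is neutral
DEFAULT_NC_TABLE = LikelihoodTable(
    bins=(
        (None, -4, 1.8),
        (-4, 0, 1.0),
        (0, None, 0.6),
    )
)


@dataclass(frozen=True)
class FlankFeatures:
    """HPR and NC of a candidate's flanks with their multipliers.

    A feature is ``None`` (undefined) when the flank is shorter than 25
    residues or, for HPR, when the flank holds no classified residues; an
    undefined feature contributes a neutral multiplier of 1.
    """

    hpr: float | None
    nc: int | None
    hpr_multiplier: float
    nc_multiplier: float

    @property
    def multiplier(self) -> float:
        return self.hpr_multiplier * self.nc_multiplier


NEUTRAL_FLANK = FlankFeatures(hpr=None, nc=None, hpr_multiplier=1.0, nc_multiplier=1.0)


def compute_hpr(n_flank: str) -> float | None:
    """Hydrophobic-to-polar ratio (percent) of a 25-residue N-flank."""
    if len(n_flank) != FLANK_LENGTH:
        raise ValueError(f"N-flank length {len(n_flank)} != {FLANK_LENGTH}")
    h = sum(1 for aa in n_flank if aa in HPR_HYDROPHOBIC)
    p = sum(1 for aa in n_flank if aa in HPR_POLAR)
    if h + p == 0:
        return None
    return 100.0 * h / (h + p)


def compute_nc(c_flank: str) -> int:
    """Net charge (#K + #R - #D - #E) of a 25-residue C-flank."""
    if len(c_flank) != FLANK_LENGTH:
        raise ValueError(f"C-flank length {len(c_flank)} != {FLANK_LENGTH}")
    basic = sum(1 for aa in c_flank if aa in BASIC)
    acidic = sum(1 for aa in c_flank if aa in ACIDIC)
    return basic - acidic


def hpr_multiplier(hpr: float | None, table: LikelihoodTable = DEFAULT_HPR_TABLE) -> float:
    return table.multiplier(hpr)


def nc_multiplier(nc: int | None, table: LikelihoodTable = DEFAULT_NC_TABLE) -> float:
    return table.multiplier(nc)


def flank_features(
    sequence: str,
    start: int,
    end: int,
    hpr_table: LikelihoodTable = DEFAULT_HPR_TABLE,
    nc_table: LikelihoodTable = DEFAULT_NC_TABLE,
) -> FlankFeatures:
    """Features of the flanks of the candidate at 1-based [start, end].

    Flanks shorter than 25 residues leave the corresponding feature
    undefined (multiplier 1).
    """
    n_flank = sequence[max(0, start - 1 - FLANK_LENGTH) : start - 1]
    c_flank = sequence[end : end + FLANK_LENGTH]
    hpr = compute_hpr(n_flank) if len(n_flank) == FLANK_LENGTH else None
    nc = compute_nc(c_flank) if len(c_flank) == FLANK_LENGTH else None
    return FlankFeatures(
        hpr=hpr,
        nc=nc,
        hpr_multiplier=hpr_table.multiplier(hpr),
        nc_multiplier=nc_table.multiplier(nc),
    )


def flank_adjust(score: float, features: FlankFeatures) -> float:
    """Multiply a positive score by the flank likelihood ratios.

    Non-positive scores pass through unchanged: scaling negative evidence by
    a ratio > 1 would strengthen it, inverting the ratio's meaning.
    """
    if score <= 0:
        return score
    return score * features.multiplier


def load_likelihood_tables(path: str | Path) -> tuple[LikelihoodTable, LikelihoodTable]:
    """Load retrained HPR/NC tables from a YAML file.

    Layout::

        hpr:
          - {hi: 30, multiplier: 2.5}
          - {lo: 30, hi: 40, multiplier: 2.0}
          ...
        nc:
          - {hi: -4, multiplier: 1.8}
          ...
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tables = []
    for key in ("hpr", "nc"):
        bins = tuple(
            (entry.get("lo"), entry.get("hi"), float(entry["multiplier"]))
            for entry in raw[key]
        )
        tables.append(LikelihoodTable(bins=bins))
    return tables[0], tables[1]
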