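"""Sequence and table I/O: FASTA records, prediction tables, annotations."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

from Bio import SeqIO

from .profiles import AMINO_ACIDS

if TYPE_CHECKING:  # pragma: no cover
    from .scanner import NesPrediction

VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

PREDICTION_COLUMNS = (
    "sequence_id",
    "class",
    "start",
    "end",
    "window_sequence",
    "raw_score",
    "penalty",
    "hpr",
    "nc",
    "multiplier",
    "adjusted_score",
)


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20-letter alphabet plus X (unknown)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: residues outside the amino-acid alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA; the record id is the first header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _fmt(value, decimals: int = 4) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{round(value, decimals):g}"
    return str(value)


def write_predictions(predictions: Iterable["NesPrediction"], path: str | Path) -> None:
    """Write the tab-separated prediction table (header line prefixed '#')."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PREDICTION_COLUMNS) + "\n")
        for pred in predictions:
            hpr = pred.flank.hpr if pred.flank is not None else None
            nc = pred.flank.nc if pred.flank is not None else None
            row = (
                pred.sequence_id,
                pred.nes_class.value if pred.nes_class is not None else "NA",
                pred.start,
                pred.end,
                pred.window,
                _fmt(pred.raw_score),
                _fmt(pred.penalty),
                _fmt(hpr),
                _fmt(nc),
                _fmt(pred.multiplier),
                _fmt(pred.adjusted_score),
            )
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_predictions(path: str | Path) -> list["NesPrediction"]:
    """Read a prediction table written by :func:`write_predictions`."""
    from .flanks import FlankFeatures, hpr_multiplier, nc_multiplier
    from .profiles import NesClass
    from .scanner import NesPrediction

    preds = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            hpr = None if f[7] == "NA" else float(f[7])
            nc = None if f[8] == "NA" else int(float(f[8]))
            flank = FlankFeatures(
                hpr=hpr,
                nc=nc,
                hpr_multiplier=hpr_multiplier(hpr),
                nc_multiplier=nc_multiplier(nc),
            )
            preds.append(
                NesPrediction(
                    sequence_id=f[0],
                    nes_class=None if f[1] == "NA" else NesClass(f[1]),
                    start=int(f[2]),
                    end=int(f[3]),
                    window=f[4],
                    raw_score=float("nan") if f[5] == "NA" else float(f[5]),
                    penalty=0.0 if f[6] == "NA" else float(f[6]),
                    spacer_hydrophobicity_rate=0.0,
                    flank=flank,
                    multiplier=1.0 if f[9] == "NA" else float(f[9]),
                    adjusted_score=float("nan") if f[10] == "NA" else float(f[10]),
                )
            )
    return preds
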