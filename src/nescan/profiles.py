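"""Activity-based NES profiles and the Ts scoring rule.

An activity profile is a matrix of nuclear-export activity scores, one per
(position, residue), measured by serially mutating a template NES peptide and
assaying the export activity of each variant.  The template row anchors the
matrix: the unmutated template has the profile's *standard score* St, and the
score of any candidate window is the standard score plus the sum of the
per-position deviations its residues cause,

    Ts = sum_{i=p..L} (S[i, w_i] - St) + St,

which is exact when residues contribute independently and additively to the
activity.  ``p > 1`` drops leading profile positions so that windows abutting
a protein's N-terminus (shorter than the profile) can still be scored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
#: conserved-position hydrophobics of the NES consensus
PHI = frozenset("LIVMF")
#: weak hydrophobics tolerated at a single conserved position
WEAK_PHI = frozenset("CWAT")

#: residue groups considered interchangeable when imputing blank profile cells
SIMILARITY_GROUPS = (
    frozenset("LIVM"),
    frozenset("FWY"),
    frozenset("DE"),
    frozenset("KR"),
    frozenset("ST"),
    frozenset("NQ"),
    frozenset("AG"),
    frozenset("C"),
    frozenset("H"),
    frozenset("P"),
)


class NesClass(enum.Enum):
    """NES spacing classes.

    Each class is a spacing pattern of conserved hydrophobic (Phi) positions;
    ``spacer_gaps`` gives the number of spacer residues between consecutive
    Phi positions.  CLASS_1A3 is the extended class 1a whose N-terminal Phi0
    merges the class 3 N-terminus onto class 1a, giving five conserved
    positions.
    """

    CLASS_1A = "1a"
    CLASS_1B = "1b"
    CLASS_1C = "1c"
    CLASS_1D = "1d"
    CLASS_2 = "2"
    CLASS_3 = "3"
    CLASS_1A3 = "1a3"

    @property
    def spacer_gaps(self) -> tuple[int, ...]:
        return _SPACER_GAPS[self]

    @property
    def phi_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the conserved positions within the motif."""
        offsets = [0]
        for gap in self.spacer_gaps:
            offsets.append(offsets[-1] + gap + 1)
        return tuple(offsets)

    @property
    def motif_span(self) -> int:
        return self.phi_offsets[-1] + 1


_SPACER_GAPS = {
    NesClass.CLASS_1A: (3, 2, 1),
    NesClass.CLASS_1B: (2, 2, 1),
    NesClass.CLASS_1C: (3, 3, 1),
    NesClass.CLASS_1D: (2, 3, 1),
    NesClass.CLASS_2: (1, 2, 1),
    NesClass.CLASS_3: (2, 3, 2),
    NesClass.CLASS_1A3: (2, 3, 2, 1),
}


class ProfileParseError(ValueError):
    """Raised when a profile file violates the dialect."""


@dataclass
class ActivityProfile:
    """Per-class activity score matrix.

    Parameters
    ----------
    nes_class
        Spacing class of the template NES.
    template
        Residue string of length L used to generate the profile.
    st
        Standard score: the measured activity of the unmutated template.
    matrix
        Array of shape (L, 20); ``matrix[i, AA_INDEX[j]]`` is the activity of
        the template with residue j substituted at position i+1.  NaN marks a
        blank (undetermined) cell.
    conserved_positions
        1-based Phi positions within the profile.
    filled_mask
        Boolean array marking cells imputed by :func:`fill_blanks`.
    """

    nes_class: NesClass
    template: str
    st: float
    matrix: np.ndarray
    conserved_positions: tuple[int, ...]
    filled_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        L = len(self.template)
        if not 1 <= L <= 15:
            raise ValueError(f"profile length {L} outside 1..15")
        if self.matrix.shape != (L, 20):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({L}, 20) for template "
                f"{self.template!r}"
            )
        bad = set(self.template) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"template contains non-canonical residues {bad}")
        for pos in self.conserved_positions:
            if not 1 <= pos <= L:
                raise ValueError(f"conserved position {pos} outside 1..{L}")
        if self.filled_mask is None:
            self.filled_mask = np.zeros_like(self.matrix, dtype=bool)

    @property
    def length(self) -> int:
        return len(self.template)

    @property
    def spacer_positions(self) -> tuple[int, ...]:
        conserved = set(self.conserved_positions)
        return tuple(i for i in range(1, self.length + 1) if i not in conserved)

    def score(self, position: int, residue: str) -> float:
        """Score of `residue` at 1-based `position`."""
        return float(self.matrix[position - 1, AA_INDEX[residue]])

    def has_blanks(self) -> bool:
        return bool(np.isnan(self.matrix).any())

    def check_template_identity(self, atol: float = 1e-4) -> bool:
        """True when every template cell equals the standard score."""
        cols = [AA_INDEX[aa] for aa in self.template]
        diag = self.matrix[np.arange(self.length), cols]
        return bool(np.all(np.abs(diag - self.st) <= atol))

    def copy(self) -> "ActivityProfile":
        return replace(
            self, matrix=self.matrix.copy(), filled_mask=self.filled_mask.copy()
        )


def read_profile(path: str | Path, *, strict_template: bool = False) -> ActivityProfile:
    """Read an activity profile from the tab-separated dialect.

    The file carries ``#class``, ``#template``, ``#standard_score`` and
    ``#phi`` headers followed by 20 rows (one per residue, first column the
    one-letter code) of per-position scores; blanks are written ``NA``.

    Profiles whose template cells disagree with the standard score are
    accepted with a warning unless ``strict_template`` is set (legacy matrices
    measured against modified templates can violate the identity; their cells
    are left as read).
    """
    import warnings

    path = Path(path)
    nes_class = template = st = phi = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#class"):
                token = line.split(None, 1)[1].strip()
                try:
                    nes_class = NesClass(token)
                except ValueError:
                    raise ProfileParseError(
                        f"{path}:{lineno}: unknown NES class {token!r}"
                    ) from None
            elif line.startswith("#template"):
                template = line.split(None, 1)[1].strip()
            elif line.startswith("#standard_score"):
                try:
                    st = float(line.split(None, 1)[1])
                except ValueError:
                    raise ProfileParseError(
                        f"{path}:{lineno}: non-numeric standard score"
                    ) from None
            elif line.startswith("#phi"):
                phi = tuple(int(x) for x in line.split(None, 1)[1].split(","))
            elif line.startswith("#"):
                raise ProfileParseError(f"{path}:{lineno}: unknown header {line!r}")
            else:
                fields = line.split("\t")
                residue = fields[0]
                if residue not in AA_INDEX:
                    raise ProfileParseError(
                        f"{path}:{lineno}: unknown residue row {residue!r}"
                    )
                try:
                    values = [
                        float("nan") if cell == "NA" else float(cell)
                        for cell in fields[1:]
                    ]
                except ValueError:
                    raise ProfileParseError(
                        f"{path}:{lineno}: non-numeric cell in row {residue}"
                    ) from None
                rows[residue] = values
    if nes_class is None or template is None or st is None or phi is None:
        raise ProfileParseError(f"{path}: missing required header line")
    if sorted(rows) != sorted(AMINO_ACIDS):
        missing = set(AMINO_ACIDS) - set(rows)
        raise ProfileParseError(f"{path}: missing residue rows {sorted(missing)}")
    L = len(template)
    for residue, values in rows.items():
        if len(values) != L:
            raise ProfileParseError(
                f"{path}: row {residue} has {len(values)} columns, template "
                f"length is {L}"
            )
    matrix = np.full((L, 20), np.nan)
    for residue, values in rows.items():
        matrix[:, AA_INDEX[residue]] = values
    profile = ActivityProfile(
        nes_class=nes_class,
        template=template,
        st=st,
        matrix=matrix,
        conserved_positions=phi,
    )
    if not profile.has_blanks() and not profile.check_template_identity():
        if strict_template:
            raise ProfileParseError(
                f"{path}: template cells disagree with standard score {st}"
            )
        warnings.warn(
            f"{path}: template cells disagree with standard score {st}; "
            "cells left as read",
            stacklevel=2,
        )
    return profile


def write_profile(profile: ActivityProfile, path: str | Path, *, decimals: int = 4) -> None:
    """Write `profile` in the tab-separated dialect (scores at 4 decimals)."""
    path = Path(path)
    lines = [
        f"#class {profile.nes_class.value}",
        f"#template {profile.template}",
        f"#standard_score {round(profile.st, decimals):g}",
        "#phi " + ",".join(str(p) for p in profile.conserved_positions),
    ]
    for aa in AMINO_ACIDS:
        cells = []
        for i in range(profile.length):
            v = profile.matrix[i, AA_INDEX[aa]]
            cells.append("NA" if np.isnan(v) else f"{round(float(v), decimals):g}")
        lines.append("\t".join([aa] + cells))
    path.write_text("\n".join(lines) + "\n")


def fill_blanks(
    profile: ActivityProfile,
    donors: list[ActivityProfile] | None = None,
    similarity: tuple[frozenset[str], ...] = SIMILARITY_GROUPS,
) -> ActivityProfile:
    """Impute blank (NaN) profile cells.

    Rules, in order of preference per cell:

    1. score of the most similar residue at the same position (first group
       partner with a determined score, in group order);
    2. the same (position, residue) cell of the first donor profile holding a
       determined value, positions aligned by Phi-offset within each class;
    3. the mean of the determined scores at the position.

    A profile with no blanks is returned unchanged (same object contract as a
    copy with an empty fill mask).
    """
    donors = donors or []
    out = profile.copy()
    nan_cells = np.argwhere(np.isnan(out.matrix))
    if nan_cells.size == 0:
        return out
    group_of = {}
    for group in similarity:
        for aa in group:
            group_of[aa] = group
    filled = out.matrix.copy()
    for i, k in nan_cells:
        residue = AMINO_ACIDS[k]
        value = np.nan
        # rule 1: same-position partner from the similarity group
        for partner in sorted(group_of.get(residue, ())):
            if partner == residue:
                continue
            v = out.matrix[i, AA_INDEX[partner]]
            if not np.isnan(v):
                value = v
                break
        # rule 2: donor profile cell at the aligned position
        if np.isnan(value):
            for donor in donors:
                j = _align_position(profile, donor, int(i))
                if j is None:
                    continue
                v = donor.matrix[j, k]
                if not np.isnan(v):
                    value = v
                    break
        # rule 3: position mean
        if np.isnan(value):
            row = out.matrix[i]
            determined = row[~np.isnan(row)]
            if determined.size == 0:
                raise ValueError(
                    f"position {i + 1}: no determined score to impute from"
                )
            value = float(determined.mean())
        filled[i, k] = value
        out.filled_mask[i, k] = True
    out.matrix = filled
    return out


def _align_position(profile: ActivityProfile, donor: ActivityProfile, i: int) -> int | None:
    """Map 0-based position `i` of `profile` onto `donor` by Phi anchoring.

    Positions are aligned so that the first conserved position of each profile
    coincides; this matches profiles whose motifs start at different offsets
    within their windows.
    """
    if not profile.conserved_positions or not donor.conserved_positions:
        return i if i < donor.length else None
    shift = (donor.conserved_positions[0] - 1) - (profile.conserved_positions[0] - 1)
    j = i + shift
    return j if 0 <= j < donor.length else None


def compute_ts(window: str, profile: ActivityProfile, p: int = 1) -> float:
    """Total activity score of `window` against `profile`.

    ``p`` is the 1-based start position of the profile: positions 1..p-1 are
    dropped (zero contribution), so the window must have length L - p + 1.
    Unknown residues (X) contribute a zero deviation from the standard score.
    """
    if not 1 <= p <= 4:
        raise ValueError(f"profile start p={p} outside 1..4")
    expected = profile.length - p + 1
    if len(window) != expected:
        raise ValueError(
            f"window length {len(window)} != profile length {profile.length} "
            f"- p + 1 = {expected}"
        )
    if profile.has_blanks():
        raise ValueError("profile has blank cells; fill_blanks first")
    total = profile.st
    for offset, residue in enumerate(window):
        if residue == "X":
            continue
        i = p + offset  # 1-based profile position
        total += profile.score(i, residue) - profile.st
    return float(total)
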