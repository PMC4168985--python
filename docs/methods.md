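# Methods

## Scoring model

A candidate NES window is scored against a per-class activity profile: a
matrix *S* of nuclear-export activity scores indexed by (position, residue),
anchored by a template peptide whose measured activity is the standard score
*S<sub>t</sub>*. Under the assumption that residues contribute independently
and additively to export activity, the predicted activity of a window *w* is

Ts = Σ<sub>i=p..L</sub> (S[i, w<sub>i</sub>] − S<sub>t</sub>) + S<sub>t</sub>.

This is exact additivity by construction: the score of any multiply
substituted window equals S<sub>t</sub> plus the sum of its
single-substitution deviations. Two conventions close gaps the data model
leaves open:

* **Template identity.** Profiles measured against modified templates with
  a different basal activity are normalised so that every template cell
  equals S<sub>t</sub>; `read_profile` warns (or errors under
  `strict_template`) when a file violates this, leaving cells as read.
* **Unknown residues.** `X` contributes a zero deviation — an unknown
  residue should fabricate evidence in neither direction.

Scanning slides a 14-column window with shift 1. Windows abutting the
N-terminus are scored with the first *p* − 1 profile positions dropped
(*p* = 2–4, window lengths 13–11); dropped positions contribute zero
deviation. Deeper truncation is not attempted — less than 11 residues no
longer covers the four-Φ core of any class.

## Penalty and flank adjustment

Hydrophobic-rich sequence (membrane spans, buried cores) mimics the NES
core but not its spacer composition. When the fraction of a window's spacer
positions (all positions not conserved-hydrophobic) occupied by Φ residues
{L,I,V,M,F} reaches 0.4, a penalty of −7 is added — the magnitude of the
measured activity collapse (8 → 1) when three spacer residues of a strong
NES were made hydrophobic. The Φ set for the rate is configurable; the
default is the same set that defines conserved positions.

Functional NESs also sit in locally polar, often acidic context. Two flank
features feed binned likelihood-ratio multipliers:

* HPR = 100·h/(h+p) over the 25-residue N-flank, h counting
  {A,V,L,I,M,F,W,C} and p counting {S,T,N,Q,Y,H,K,R,D,E}; glycine and
  proline belong to neither class, and h+p = 0 leaves HPR undefined. Bins:
  ≤30 → 2.5, (30,40] → 2, (40,50] → 1.4, (50,60] → 1, (60,80] → 0.6,
  >80 → 0.5.
* NC = (#K + #R) − (#D + #E) over the 25-residue C-flank (histidine not
  counted). Bins: ≤−4 → 1.8, (−4,0] → 1 (no ratio is defined for the
  middle bin; neutral is the only defensible default), >0 → 0.6.

Multipliers apply only to positive penalised scores: scaling negative
evidence by a ratio above 1 would strengthen it, inverting the ratio's
meaning. Candidates within 25 residues of a terminus get a neutral
multiplier — the ratio tables assume full-length flanks. Retrained tables
can be loaded from YAML (`flanks.load_likelihood_tables`).

Thresholding applies to the adjusted score (penalty, then multiplier), the
order in which the stages are described; overlapping same-class calls are
merged keeping the maximum-scoring window (ties: smaller start, then class
order 1a3 < 1b < 1c < 2), while cross-class overlaps are all reported —
class attribution is part of the output.

## Consensus dialects

The traditional consensus Φ–X<sub>2,3</sub>–Φ–X<sub>2,3</sub>–Φ–X–Φ and
the stricter per-class patterns (fixed Φ spacing; proline excluded from
marked spacer positions; at most one conserved position occupied by a weak
hydrophobic C/W/A/T; candidates rejected when a run of more than four
consecutive Φ residues covers the second and third conserved positions) are
implemented by explicit enumeration of starts and spacer-length choices.
All distinct (start, end) spans are reported, overlapping matches included.
The `strict` flag additionally bars weak hydrophobics from the two
C-terminal Φ positions. The hydrophobic-stretch rule uses the Φ set by
default (configurable); for five-Φ classes the "second and third" positions
are counted on the C-terminal four-Φ core.

## Profile training

Measured profiles describe isolated peptides; whole-protein scanning
over-calls. `optimize_profiles` runs greedy coordinate ascent on

objective = −(λ<sub>fn</sub>·FN + λ<sub>fp</sub>·FP),

with FN/FP counted by the evaluator at the scan threshold, flank adjustment
active. Defaults λ<sub>fn</sub> = 2, λ<sub>fp</sub> = 1: the intended
operating move is a large false-positive reduction bought with at most a
slight sensitivity loss, and the asymmetry keeps optimisation pointed that
way. Epochs visit every free cell in a seeded-shuffled order and try
±step (default 1) within bounds (default [−10, 15]).

A plain "accept only strict objective improvement" rule stalls immediately:
a false positive several score units above threshold cannot be removed by
any single-cell step, so no move ever improves the count. Acceptance is
therefore lexicographic — a move is kept when it strictly improves the
objective, or leaves it unchanged while strictly shrinking a continuous
violation term: the hinge excess of false-call windows above threshold plus
the hinge deficit of undetected true NESs below it, measured on an
unmerged, unthresholded scan (windows touching a true range are exempt from
the excess, since they merge into the true call). The logged objective
sequence remains non-decreasing; identical seeds and inputs give identical
profiles. Template-diagonal cells are always frozen so the
template-identity normalisation survives training; `freeze_conserved`
optionally freezes all conserved-position cells. Training stops at
`max_epochs` (default 20) or after an epoch with no accepted move.

## Evaluation conventions

A true NES counts as detected when a prediction overlaps its range by ≥ 8
residues (default; most of a motif core). Predictions contributing no
detection are false positives. With a negative dataset, each negative
protein is one specificity unit; the protein-level FP fraction is the share
of negative proteins with at least one call. ROC curves sweep the score
threshold; the FPR denominator is, by default, the number of
traditional-consensus matches in negative territory, counting as false
positives only calls whose window matches that consensus — the
normalisation under which consensus-based and profile-based methods are
comparable. A plain per-call normalisation is available
(`fpr_mode="window"`). AUC is the trapezoid over points sorted by FPR,
anchored at (0,0) and (1,1).

## Synthetic data

`make_toy_profile` builds matrices with the qualitative structure of
measured profiles: template cells at S<sub>t</sub>; non-Φ residues at
conserved positions at most S<sub>t</sub> − 3; spacer prolines at most
S<sub>t</sub> − 4 (proline is a strong repressor throughout the spacer);
all other cells uniform in [S<sub>t</sub> − 2, S<sub>t</sub> + 1]. Known
template sequences and standard scores anchor classes 1b
(PSSELAKLAGLDLN, S<sub>t</sub> = 4) and 1c (SELAEKLQAGLDLN,
S<sub>t</sub> = 8); the class 1a/3 (S<sub>t</sub> = 8), class 2
(S<sub>t</sub> = 3) and class 1d templates are designed here to satisfy
their class consensus. The bundled profile set under
`src/nescan/data/profiles/` is generated this way by
`scripts/build_profiles.py` with fixed per-class seeds and is synthetic —
it exercises the full pipeline but is not a measured profile set.

`generate_proteome` plants template-grade NESs (validated against their
improved class consensus before emission) into uniform-background proteins,
synthesising 25-residue flanks into requested HPR/NC bins by rejection
sampling (cap 10⁴ draws; defaults: HPR ≤ 30, NC ≤ −4, the favourable
bins). Decoy proteins carry an NES-shaped segment whose spacers were made
hydrophobic, rejection-sampled so its raw score lies in [2.5, 8.5] — called
without the penalty, suppressed by it — between neutral flanks, plus plain
hydrophobic stretches. One seeded generator drives everything, so equal
configurations give byte-identical FASTA and annotations.

What the generator does **not** emulate: real residue composition,
disorder/structure, correlated motif positions, or the size and difficulty
of curated NES collections. Passing tests on this data demonstrates the
machinery (recovery of planted signals, the direction of the penalty and
training effects), not real-proteome error rates; published benchmark
figures on curated datasets are out of scope here.

## Problem sizes and numerics

Default test/benchmark sizes: proteomes of 8–12 positive proteins
(120–200 aa, one planted NES each) and 4–6 decoys; trainer runs use a
single class 1c profile and ≤ 2 epochs; consensus matchers are checked
against an independent regex oracle on 10⁴ random 30-mers; the
chance-level AUC check averages 10³ resamples of a 20-unit toy set. Scores
are stored and written at 4 decimal places; scan scoring is vectorised per
profile (integer-encoded sequence against a (L, 21) deviation matrix with
an all-zero X column). Degenerate inputs: sequences shorter than the
shortest scannable window yield an empty result with a warning; a profile
position with no determined score cannot be imputed and errors; a zero
consensus denominator in ROC normalisation errors with guidance to use the
per-call mode.

## Known limitations

* The bundled profiles are synthetic; absolute scores on real proteins are
  meaningful only with measured matrices.
* Training is greedy and first-improvement; it finds local optima and its
  result depends (deterministically) on the seed.
* No structural features (disorder, surface accessibility) are used —
  deliberate, matching the scope of profile-plus-context scoring.
* Class 3 is scanned only through the merged class 1a/3 profile; standalone
  class 3 profiles are not bundled.
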