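# nescan

Prediction of leucine-rich, CRM1-dependent nuclear export signals (NESs) in
protein sequences using activity-based profiles.

Nuclear export of most proteins runs through the exportin CRM1, which
recognises a short leucine-rich peptide — the NES — via five hydrophobic
binding pockets. NESs follow loose spacing patterns of conserved hydrophobic
(Φ = L/I/V/M/F) positions (classes 1a/1b/1c/1d/2/3 and the extended class
1a/3 with an N-terminal Φ0), but consensus patterns alone drown in false
positives: hydrophobic-rich stretches from membrane anchors and buried cores
match them constantly. `nescan` instead scores candidates with **activity
profiles**: matrices of measured nuclear-export activity per (position,
residue), built by mutational assays of template NES peptides, and combines
them with sequence-context features that separate genuine export signals
from hydrophobic decoys.

## Model

For a window aligned to a profile of length *L* with per-cell scores
*S<sub>ij</sub>* (position *i*, residue *j*) and standard score *S<sub>t</sub>*
(the activity of the unmutated template), the predicted activity is additive:

```
Ts = Σ_{i=p..L} (S_ij − S_t) + S_t
```

with *p* = 1–4 dropping leading profile positions for windows abutting the
N-terminus (windows of 11–13 residues there, 14 elsewhere; shift 1). On top
of the raw score:

* **spacer-hydrophobicity penalty** — if ≥ 40 % of the window's non-Φ
  (spacer) positions are hydrophobic, −7 is added; calibrated to the
  observed collapse of a score-8 NES to score 1 when three spacer residues
  turn hydrophobic;
* **flank likelihood ratios** — the hydrophobic-to-polar ratio (HPR) of the
  25 residues N-terminal to the candidate and the net charge (NC) of the 25
  residues C-terminal map through binned likelihood ratios
  (2.5 for HPR ≤ 30 … 0.5 for HPR > 80; 1.8 for NC ≤ −4, 0.6 for NC > 0)
  that multiply positive scores — true NESs sit in polar, acidic context.

Windows scoring ≥ threshold (default 2) are reported, with overlapping
same-class calls merged to the best-scoring window. Profiles can be
**trained** against annotated positive/negative sequences (greedy
coordinate ascent on a weighted FN/FP count), and predictions benchmarked
with site-level sensitivity/specificity and ROC/AUC. Consensus matchers
(traditional Φ–X₂,₃–Φ–X₂,₃–Φ–X–Φ and stricter per-class patterns) are
included for comparison and for ROC normalisation.

The bundled profile set is *synthetic* (generated with realistic cell
structure around the known template sequences and standard scores — see
`docs/methods.md`); point `--profile-dir` / `NesScanner(profiles=...)` at
measured matrices for real predictions.

## Worked example

```python
from nescan import NesScanner, FixtureConfig, generate_proteome

scanner = NesScanner(threshold=2.0).fit([])          # bundled profiles
records, positives, negatives = generate_proteome(
    FixtureConfig(n_proteins=2, n_decoy_proteins=1, seed=7)
)
for record, predictions in zip(records, scanner.predict(records)):
    for p in predictions:
        print(f"{record.id}\t{p.nes_class.value}\t{p.start}-{p.end}\t{p.window}\t"
              f"raw={p.raw_score:.1f}\tpenalty={p.penalty:.0f}\t"
              f"mult={p.multiplier:.2f}\tscore={p.adjusted_score:.1f}")
```

prints

```
pos_0001  1c  30-43    SELAEKLQAGLDLN  raw=8.0  penalty=0  mult=4.50  score=36.0
pos_0002  1b  123-136  PSSELAKLAGLDLN  raw=4.0  penalty=0  mult=4.50  score=18.0
pos_0002  1c  160-173  EGVLNCHSSNVGEC  raw=1.1  penalty=0  mult=2.50  score=2.7
```

The two planted NESs are recovered at their exact coordinates with raw
score equal to their profile's standard score (8 for class 1c, 4 for class
1b); their favourable flanks (HPR ≤ 30 → ×2.5, NC ≤ −4 → ×1.8) lift the
adjusted score by ×4.5. The third line is a background window that crept
over the threshold only through its flank multiplier — the kind of marginal
call profile training removes. The decoy protein yields no calls: its
NES-like segment trips the −7 spacer-hydrophobicity penalty.

The same pipeline is available from the shell:

```
nescan simulate --out-fasta prot.fasta --out-annotations ann.tsv --seed 7
nescan predict prot.fasta -o preds.tsv
nescan evaluate preds.tsv prot.fasta ann.tsv -o metrics.tsv
```

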