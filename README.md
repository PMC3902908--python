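# g4context

Prediction of RNA G-quadruplex (G4) folding from genomic context.

Guanine-rich RNA can fold into G-quadruplexes — four-stranded structures
built from stacked G-tetrads and stabilized by K⁺.  Candidate sites (PG4s)
are conventionally found with the motif

```
G_x – N_{1–7} – G_x – N_{1–7} – G_x – N_{1–7} – G_x      (x ≥ 3)
```

but many motif hits never fold in a real transcript: cytosine tracks in the
flanking sequence pair with the G-tracks in stable Watson–Crick structures
and sequester the guanines.  `g4context` scores a PG4 *together with its
context* to separate folding from non-folding candidates.  It is aimed at
people curating PG4 predictions in UTRs and other transcript regions.

## The cG/cC score

For a sequence *s*, the consecutive-G score counts every substring of
consecutive Gs, weighting a substring of length *i* by 10·*i*:

```
cG(s) = Σ_i 10 · i · |Gs(i)|
```

where |Gs(i)| is the number of occurrences of exactly *i* consecutive Gs
("GGGCGGG" has |Gs(3)| = 2).  Equivalently, each maximal G-run of length *L*
contributes 10·L(L+1)(L+2)/6, so "GGG" scores 100 (three singles, two
doublets, one triplet) and "GG" scores 40.  cC is the same count over Cs,
and the predictor is the ratio

```
cG/cC over the PG4 plus 15 or 50 nt of flank on each side.
```

High ratios (abundant G-tracks, few competing C-tracks) predict folding.
Two calibrated decision thresholds are provided: **2.05** (sensitive) and
**3.05** (specific); folding is called when the ratio is strictly above the
threshold.  The package also ships the scanner (maximal G-run tracks,
minimum-total-loop tetrad assignment, 10-nt spacing retention), ROC/AUC
machinery with midpoint thresholds and strict-inequality
sensitivity/specificity, exact/asymptotic Mann–Whitney group comparison, the
in-line-probing fold-call rule (K⁺/Li⁺ ratio ≥ 2 at ≥ 2 loop-adjacent
nucleotides in ≥ 2 replicates), a seeded synthetic-data generator with
planted PG4s and C-tracks, and sklearn-compatible estimators
(`ConsecutiveRunScorer`, `ThresholdFoldClassifier`).

## Worked example

A candidate with a strong 4-track PG4 (tracks of 5,5,4,4 Gs) whose flanks
carry C-runs of lengths 5, 3, 2 and 1 plus one distal G-track:

```python
from g4context import SequenceRecord, scan_pg4, score_candidate, classify

seq = ("AUACCCCCAUAUCCCAUA"          # 5' flank: C5 and C3 tracks
       "GGGGGAGGGGGAUGGGGAGGGG"      # the PG4
       "AUAUCCAUAUAUAGGGAUCAU")      # 3' flank: C2, C1, distal G3
rec = SequenceRecord(id="demo", residues=seq)
(match,) = scan_pg4(rec)
print(match.start, match.end, match.loops)        # 18 40 (1, 2, 1)
result = score_candidate(rec, match, flank5=50, flank3=50)
print(result.cg, result.cc, round(result.ratio, 2))   # 1200 500 2.4
print(classify(result.ratio, 2.05))               # folding
print(classify(result.ratio, 3.05))               # non-folding
```

cG = 1200 (runs 5,5,4,4 in the motif plus the distal G3), cC = 500 (runs
5,3,2,1), ratio 2.40 — an intermediate-score candidate that the sensitive
threshold calls folding and the specific threshold rejects.

The same from the shell:

```bash
g4context scan input.fa                  # TSV of retained PG4 matches
g4context score input.fa --preset both   # cG, cC, cG/cC + calls at 2.05/3.05
g4context synth --seed 1 --n 20 --out-fasta s.fa --out-table s.tsv
g4context evaluate s.tsv --thresholds 2.05,3.05   # ROC, AUC, confusion
```

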