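# Methods

## Model and rationale

A potential G-quadruplex (PG4) is a motif
G_x–N_{1–7}–G_x–N_{1–7}–G_x–N_{1–7}–G_x with x ≥ 3.  Whether it actually
folds in a transcript depends on its neighbourhood: consecutive cytosines in
the flanks can pair with the G-tracks in Watson–Crick duplexes that
out-compete tetrad formation.  The package's predictor is therefore computed
on the PG4 *plus* its flanking context and balances the two tendencies:

- **cG score** — for every substring of exactly *i* consecutive Gs, add
  10·*i*.  A maximal run of length L contributes Σ_{i=1..L} 10·i·(L−i+1)
  = 10·L(L+1)(L+2)/6 (closed form used in the implementation; the brute-force
  substring sum is kept as a test oracle).  The score depends only on the
  multiset of maximal run lengths and grows superlinearly with run length,
  which encodes the disproportionate effect of long tracks.
- **cC score** — identical with C, measuring Watson–Crick competition.
- **cG/cC ratio** — the fold predictor; classification is *strictly*
  ratio > threshold.

Scores are exact integers (always multiples of 10); the ratio is kept at
full precision internally and reported to two decimals.

## Scanner conventions

- Tracks are **maximal** G-runs of length ≥ `min_track` (default 3).  An
  uninterrupted poly-G stretch is one track, so it can never satisfy the
  four-track pattern by itself; every loop must contain at least `loop_min`
  non-track nucleotides.
- IUPAC ambiguity codes are retained on input but are never G or C: they
  terminate runs and can only sit in loops.  This is deliberately
  conservative — tetrad guanines are never fabricated from ambiguous calls.
- Loops are end-to-start gaps between the four chosen tetrad tracks, bounded
  by `[loop_min, loop_max]` = [1, 7] by default.  When more than four tracks
  are usable, the reported extent is collapsed greedily to the
  leftmost-starting, then longest span, and the tetrad assignment is the
  in-order 4-subset minimizing total loop length (ties to the leftmost
  subset).  Gs of skipped surplus tracks count as loop nucleotides.  This
  makes total loop length a deterministic, reproducible quantity for
  multi-track regions that admit several G4 conformations.
- Retention: matches are filtered greedily left-to-right; a match is dropped
  when its start is closer than `min_gap` = 10 nt to the end of the last
  retained match.  The spacing rule itself is standard; greedy end-to-start
  retention is this package's declared convention (the alternative —
  keeping the "best" of a close pair — is underdetermined and
  order-sensitive).
- Only the given strand is scanned.  RNA is single-stranded and directional;
  there is no reverse-complement search.
- T and U are interchangeable on input; all computation is on U.

## Context windows

`score_candidate` scores the window `[match.start − flank5, match.end +
flank3)` **including** the PG4's own tracks — the predictor describes the
candidate, not the flanks alone.  Defaults are 50 nt per side ("long
context"); 15 nt is the named "short context" preset.  Windows are clamped
at sequence ends and the clamping is flagged, since a truncated flank makes
the ratio less comparable.  Candidate sequences supplied directly in a table
are scored verbatim, so published candidate sets can be reproduced without
knowing their transcript coordinates.

Degenerate windows are carried as sentinels rather than errors: cC = 0 gives
an infinite ratio that classifies as folding (no Watson–Crick competition
at all) but is excluded from ROC threshold generation; cG = cC = 0 gives an
undefined (NaN) ratio on which classification refuses to make a call.
Real transcript windows essentially always contain both bases.

## Evaluation machinery

- Candidate thresholds are midpoints between consecutive distinct scores,
  plus one value below the minimum and one above the maximum so the ROC
  spans (0,1)–(1,0) and the trapezoidal AUC is well defined.
- Sensitivity = fraction of folding candidates strictly above the threshold;
  specificity = fraction of non-folding candidates strictly below it.  Both
  inequalities are strict; midpoint thresholds make ties unreachable in
  practice, and a score exactly at a threshold counts in neither numerator.
- AUC is the trapezoid of sensitivity against (1 − specificity).  On
  tie-free data it equals the normalized pairwise-concordance statistic
  U/(n₁·n₂), which the tests verify exactly (and cross-check against
  scikit-learn's implementation, which is *not* used internally because its
  ≥-based operating points differ from the strict definitions above).
- Metric direction is always an explicit `lower_is_folding` flag (negation
  before applying the definitions): total loop length predicts folding when
  low; Mfe predicts folding when high (less negative = weaker competing
  structure); cG/cC when high.  Direction is never inferred from data.
- Group comparison is a two-sided Mann–Whitney U via scipy: exact null for
  combined n ≤ 20 without ties (the relevant regime — candidate sets here
  are 12–19 sequences, where the normal approximation is noisy), asymptotic
  with tie correction otherwise; the method used is reported.
- The in-line probing call operates on user-supplied per-nucleotide K⁺/Li⁺
  cleavage ratios: folding requires ≥ 2 loop-adjacent positions at ratio ≥ 2
  in each of ≥ 2 replicates.  All three constants are parameters.

## Synthetic data generator

The generator emulates the construct design used to probe context effects:
a planted canonical PG4 (4–6 tracks of ≥ 3 Gs, loops of 1–7 nt drawn from
{A,U}) inside background flanks, with C-runs of chosen length planted at
chosen distances (the wild-type-with-inhibitory-context situation) or
absent/replaced by A (the C/A-mutant situation).  G/A mutants substitute A
at every third position of each planted track — a single substitution for
tracks up to 5 Gs — leaving no G-run of length 3 anywhere, which guarantees
scanner rejection for arbitrary track lengths (a single mid-track
substitution would not for tracks of ≥ 6 Gs).

Background is sampled per position at a given GC fraction (default 0.4,
typical of UTR sequence) and post-processed to break accidental G- or
C-runs ≥ 3, so planted features are the only scanner-relevant ones and truth
annotations are exact.  Each record uses a private `numpy` generator seeded
from `(seed, record index)`: regeneration is byte-identical and independent
of generation order.  With > 4 tracks the generator verifies arithmetically
that some four-track chain spans the whole motif within the loop bounds and
rejects the spec otherwise, keeping the planted span scanner-recoverable by
construction.

The benchmark `example_dataset` (20 candidates by default) gives half the
candidates heavy planted C-tracks on both flanks (2 runs of 3–6 C per side,
5–40 nt from the PG4 — the distance range over which C-tracks are known to
act) and labels folding purely by construction (no planted C-run ≥ 3).
Loop lengths vary independently of the label, so loop length is
uninformative by design and the expected ROC ordering (cG/cC ≫ loop length)
is a genuine pipeline test, not a tautology.

What the generator does **not** model: folding thermodynamics or kinetics,
probing intensities (test profiles are constructed directly), G-richness
gradients, bulged or two-quartet G4s, and long-range base pairing beyond the
planted C-runs.  Passing tests on synthetic data therefore demonstrate the
correctness of scanning/scoring/evaluation machinery and the internal
consistency of the score's logic — not its biological accuracy, which rests
on the probing-calibrated thresholds.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `min_track` | 3 | minimum G-run length for a track (x ≥ 3) |
| `loop_min`, `loop_max` | 1, 7 | allowed loop lengths, nt |
| `min_gap` | 10 | retention spacing between matches, nt |
| `flank5`, `flank3` | 50 | context window, nt per side (preset short = 15) |
| threshold (sensitive) | 2.05 | fold call, maximal sensitivity operating point |
| threshold (specific) | 3.05 | fold call, high-specificity operating point |
| probing ratio / positions / replicates | 2, 2, 2 | in-line probing call rule |

## Design choices that were genuinely open

- The spacing retention rule does not dictate a procedure; greedy
  left-to-right end-to-start filtering was chosen for determinism.
- Overlap collapse (leftmost-starting, then longest) fixes one candidate
  per locus; alternative conformations of the same locus are deliberately
  not enumerated.
- The cC = 0 and 0/0 sentinel policies are package conventions (the score
  is simply undefined there otherwise).
- Exactly 50/15 nt of flank are used for the presets; published context
  sizes are approximate ("∼50 nt"), and the exact-width convention makes
  scores reproducible.
- CLI exit codes: 0 success, 1 usage error, 2 data error; click's default
  usage-exit of 2 is remapped accordingly.

## Problem sizes

Property suites run on 1000 random strings (scoring oracles), 60 random
G-rich 300-mers (scanner vs exhaustive 4-subset enumeration, the binomial
cost of which caps the practical string length), 20-candidate ROC datasets,
and 10-seed generator round-trips.  The whole suite completes in a few
seconds on one CPU.

## Known limitations

- The scanner targets canonical PG4s only: no bulged/discontinuous tracks,
  no two-quartet G4s, no loops > 7 nt by default (all reachable through
  parameters, none default).
- Mfe and QGRS G-score are accepted as precomputed input columns; the
  package neither folds RNA nor reimplements the G-score.
- Thresholds 2.05/3.05 were calibrated on RNA UTR candidates with ~50-nt
  contexts; DNA G4s, other window sizes, and coding regions likely need
  different operating points.
- No confidence intervals on AUC are computed.
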