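# Methods

`mimicryscan` implements a molecular-mimicry screen: given a microbial
target protein (the motivating case is microbial transglutaminase, mTG,
from *Streptomyces mobaraensis*, UniProt P81453, 331 aa) and a catalog of
linear human epitopes implicated in autoimmune disease, it finds epitopes
whose best local alignment to the target is similar enough to plausibly
support cross-reactive immunity, then narrows the candidates by predicted
HLA binding of the target-side peptide and by experimentally observed
antibody cross-reactivity. A companion module analyzes the ELISA
cross-reactivity panel itself.

## Local alignment

The aligner is a from-scratch Waterman–Eggert search: Smith–Waterman/Gotoh
dynamic programming with affine gaps, plus declumping — after the best
alignment is reported, its aligned residue pairs are forbidden and the
search repeats, so the *k*-th alignment never reuses a residue pair of the
first *k*−1.

Conventions (all exposed through `ScreenConfig`):

| parameter | default | meaning |
|---|---|---|
| `matrix_name` | BLOSUM62 | substitution matrix, bundled verbatim (half-bit integer scores) |
| `gap_open` | 14 | cost of the first residue of a gap run |
| `gap_extend` | 4 | cost of each further residue; a run of length *L* costs 14 + 4(*L*−1) |
| `n_alternatives` | 1 | declumped alignments returned per pair |

These are the documented protein defaults of the classic pairwise-local
alignment tools, and they reproduce the six published worked-example pairs
exactly (see the test suite). Column statistics follow the usual pair-report
conventions: **identity** counts equal-residue columns, **similarity**
counts columns whose substitution score is strictly positive (identities
included), **Ln** is the column count including gaps. Coordinates are
1-based inclusive. The ambiguity code X is accepted but scores 0 against
everything, so it neither builds nor breaks an alignment (the published
matrix's small negative X scores are deliberately overridden; the screen's
inputs are curated peptides where X is rare and uninformative).

Tie-breaking is deterministic and documented rather than meaningful: among
equal-scoring end cells the earliest target end position is preferred, the
traceback prefers substitutions over gaps and closing gaps over extending
them, and among tied tracebacks the alignment starting earliest in the
target with fewest gaps wins. Identical inputs always produce byte-identical
output.

The DP kernel is JIT-compiled with numba when available and falls back to
the identical pure-Python loop otherwise; both paths are exact integer
arithmetic in float64 (scores well below 2^53), so results are
platform-independent.

Correctness is checked two independent ways: an exhaustive geometric
enumeration of every local alignment with at most one gap run (tractable
for short sequences; at gap-open 14 a second gap run is never optimal on
≤12-residue 4-letter sequences, verified on 1000 seeded pairs), and a
second, established affine local aligner run at identical parameters.

## The screening chain

1. **Identity/length cutoff.** The best alignment per epitope passes iff
   `n_identity ≥ 7` and `Ln ≥ 12`. The cutoff's published wording is
   strict (`> 12`) while the published six-pair table contains two
   12-column rows; inclusive is therefore the default and
   `strict_length=True` preserves the literal reading. "Length" is
   interpreted as alignment columns (the table's Ln), not epitope length.
2. **Immunogenicity.** The degapped *target-side* peptide must have at
   least one precomputed HLA binding record with IC50 ≤ 50 nM (class I) or
   ≤ 500 nM (class II) — the conventional strong-binder bounds; both are
   config-exposed because the original analysis does not state its
   thresholds. Predictions are consumed from a table, never computed:
   MHC-binding predictors are a separate, well-served problem, and a table
   keeps the pipeline offline and reproducible. Peptides absent from the
   table are dropped and logged.
3. **Cross-reactivity.** The epitope's parent antigen must be in the
   reactive set (from the ELISA analysis or a user file). Matching is by
   accession when available, else case-insensitive name matching through a
   small extensible synonym map, because assay panels and epitope catalogs
   label the same antigen differently ("fibrinogen" vs "Fibrinogen alpha
   chain").

Each filter returns a subset of its input; per-stage counts are logged.

## ELISA reactivity

Reactive antigens are those whose mean OD (405 nm) exceeds
`background mean + cutoff_k · SD` with `cutoff_k = 1`, the published
arithmetic (0.16 + 0.12 = 0.28 polyclonal; 0.15 + 0.09 = 0.24 monoclonal).

Background membership is circular as usually stated — the cutoff defines
the background that defines the cutoff — and is resolved by iterative
outlier trimming: starting from all antigens, drop those above
`mean + trim_k · SD` of the current set and recompute until membership
stabilizes (membership only shrinks, so convergence is guaranteed). The
trimming multiplier is deliberately **2**, not the cutoff's 1: trimming a
roughly normal cluster at one SD removes the top ~16% every round and
collapses to a handful of points, whereas two-SD trimming removes only
clear off-cluster antigens. An explicit background list bypasses the
iteration for curated analyses. Limitation: when reactive ODs overlap the
background cluster, borderline antigens stay in the background and the
estimates are biased upward accordingly.

The per-antigen p-value is the one-sided upper normal tail
`P(N(bg mean, bg SD²) > OD)`. It is a clearly-labeled stand-in — the
original analysis reports p-values without naming a test or sample size —
chosen because it preserves the one property the narrative states:
p strictly decreases as OD rises above the cutoff. Reproducing the
published p-values is not claimed. Duplicate-well QC flags antigens whose
CV (100·|od₁−od₂|/mean) is ≥ 7%; single wells are "not assessable", not
failed. ODs are analyzed at full precision; two-decimal rounding is purely
a display concern.

## Synthetic studies

The generator (`mimicryscan.synthetic`) builds complete studies with known
ground truth; all randomness derives from one seed via independent named
streams, so every artifact is reproducible and the pipeline's recovery of
the design is a testable property.

* **Target**: 331 residues (mTG-like) drawn i.i.d. from natural amino-acid
  frequencies.
* **Planted epitopes** (default 5, length 15, 3 mutations): contiguous
  target windows with exactly 3 interior positions substituted by residues
  scoring in [−3, 0] against the original. Two deliberate restrictions
  make recovery *analytic* rather than statistical: mutations sit ≥ 3
  residues from the window ends, and substitutes are bounded below at −3,
  so every prefix/suffix of the segment scores positively and the optimal
  local alignment is provably the full ungapped window — identity exactly
  12/15, similarity exactly 12/15 (non-positive substitutes are never
  "similar"), no end-trimming at any seed.
* **Background epitopes** (default 200, lengths 8–12): i.i.d. residues,
  decoy disease tags. The length range is the typical short linear-epitope
  regime and is chosen so the identity/length stage is *structurally*
  closed to the null: a ≤12-mer must align essentially end-to-end with ≥7
  identities to pass, which measured at 0/4000 across seeded catalogs.
  This is benchmark design, not realism: with realistic longer epitopes
  (10–25 aa) random sequences pass the hard cutoff at ~0.5–1% — the same
  order as the original screen's 60 survivors out of ~67,000 epitopes —
  so passing the planted-recovery tests shows the machinery is correct,
  *not* that the cutoff suppresses chance hits in real catalogs.
* **ELISA panel** (default 77 antigens, 20 reactive): background ODs from
  Normal(0.16, 0.12²) truncated at 0, reactive ODs shifted by +0.30,
  duplicates jittered multiplicatively so CV < 6%. Antigens hosting
  planted epitopes are pinned near the middle of their designed class so
  the designed truth table is stable under the estimated cutoff.
* **Binding table**: IC50 log-uniform over [2, 50000] nM, with designated
  strong peptides forced under their class threshold and weak ones forced
  an order of magnitude above.

Planted epitope *i* is strong-binding iff *i* < 4 and cross-reactive iff
*i* < 3 (defaults), so the designed final hit set is the first 3 planted
epitopes and both downstream filters demonstrably remove something.

A note on classifier operating characteristics: with the cutoff at
background mean + 1 SD, the expected specificity against the generator's
own normal background is ≈ Φ(1) ≈ 0.84 *by construction*, independent of
the parameter values, and sensitivity at a +0.30 shift with SD 0.12 is
≈ 0.86–0.94 depending on the estimated cutoff. Near-perfect operating
points are therefore not a meaningful expectation under this OD model and
are not asserted; what is asserted is the published cutoff arithmetic, the
monotonicity of calls and p-values, and stability of the designed truth.

## What the synthetic results do not show

The original study's global counts (≈67,000 catalog epitopes → 60 aligned
survivors → 6 final pairs; 17/77 and 9/77 reactive antigens) depend on an
undeposited catalog snapshot, unpublished binding predictions and raw OD
data shown only graphically; they are not reproducible from first
principles and are not targeted. What is reproduced exactly: the six
published aligned pairs' identity/similarity statistics, both cutoff
computations, the quoted per-antigen classifications, and the per-disease
antigen counts (RA 4, T1DM 3, SS 2).

## Problem sizes

Default test and acceptance runs use 20 catalogs × (200 background + 5
planted) epitopes against a 331-residue target, 1000 short oracle pairs
plus 100 30-mer reference pairs, and one full pipeline run — a few seconds
end to end on one core, chosen so the whole suite iterates quickly while
every stage is exercised at meaningful scale.
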