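# Methods

## Problem and approach

A continuous-domain boundary predictor partitions a chain of length L into
n+1 segments. Two non-adjacent segments may in fact be the halves of one
discontinuous domain. `domex` tests every non-adjacent pair by
concatenation: if a single-domain library contains a template homologous to
the *joined* sequence — matching both halves symmetrically and with a
similar total length — the pair is called a discontinuous domain. The
method rests on three assumptions: (a) homologous domains are detectable by
sequence (profile) alignment; (b) homologous domains have similar lengths;
(c) when a template really spans both segments, its per-segment identity
and coverage are roughly symmetric across the junction.

Only two-segment assemblies are attempted; discontinuous domains with
three or more segments are rare enough that the added search cost is not
justified, and the machinery extends directly if ever needed.

## Scores and decision tree

For candidate Q (junction after residue n = |first segment|) and template
T with alignment E-value E:

- `h = max(0, min(E0, −log10 E) / E0)`, E0 = 10. The clamp at 0 covers
  E > 1, where the raw formula would go negative; hits that weak carry no
  evidence either way.
- coverage factor `l(c)`: 0 for c ≤ 1/3, else `1/(1 + (1/(3c−1))^5)`;
  c = aligned query residues / |Q|. This vanishes exactly in the regime
  where only one half of the candidate aligns (c ≈ 1/2 gives l ≈ 0.03),
  which is what kills most spurious pairings.
- `TS-score = s · h · l` with s = identical aligned columns / aligned
  columns (gap columns excluded — the denominator is not specified by
  convention elsewhere, so the package fixes it this way and applies it
  consistently).
- Symmetric Index: alignment columns are split by query position ≤ n;
  `s_k` = identities / aligned columns within part k, `c_k` = aligned
  query residues in part k / segment-k length; a part with no aligned
  columns contributes (0, 0). `SI = hypot(s_p − s_q, c_p − c_q)`. Under
  this definition identity and column counts are conserved exactly across
  the split, which the tests assert on random alignments.
- length variation `e = |L_T − L_Q| / L_Q`, accepted iff `e < 0.2`
  (strict, as the decision rule states it).
- SI cutoff from the constraint function `f(T_TS, b)` (pieces 0.3 /
  2·T_TS − b / 0.1 / 0 with breakpoints 0.15 + b/2, 0.05 + b/2, b/2).
  Breakpoint equalities are assigned to the lower piece; the two inner
  breakpoints are value-identical either way by continuity. The ramp is
  numerically clamped into [0.1, 0.3] to keep the stated range property
  exact under floating point.
- A hit is accepted iff `e < 0.2`, `TS-score > b/2` (the nonzero region of
  the constraint), `SI ≤ f(TS-score, b)` and — for sequence-source
  templates when b < 0.5 — `PPA < T_PPA` (default −1.90). The worked
  reading of the published example treats the SI comparison as ≤; a
  `strict_inequalities` flag flips SI to a strict <.

Among passing hits the decision ranks by ascending PPA score where one was
computed, treating hits without a PPA score as 0.0 (so any hit with a
genuinely good, negative PPA outranks them), then by descending TS-score,
ascending E-value and template id. The same key drives conflict
resolution: accepted candidates are taken greedily in rank order, each
segment claimable by at most one discontinuous domain. "Conflict" is thus
defined as segment overlap — the narrowest definition consistent with the
one-domain-per-segment output contract.

Defaults: `b = 0.3`, `e_max = 0.2`, `T_PPA = −1.90`, `E0 = 10`, minimum
segment length 40 residues, search E-value ceiling 10 (the value at which
h reaches 0, so weaker hits cannot score anyway). Reversed (C→N segment
order) assembly is off by default — it doubles search cost and pays off
only for rare segment-swapping domains — and is enabled with
`--allow-reversed`.

## Search backends

The search contract is pluggable:

* **builtin** (default): the bare candidate is aligned locally
  (Smith–Waterman, affine gaps −11/−1, BLOSUM62, via Biopython's
  `PairwiseAligner`) against every library record, with a
  Karlin–Altschul-style E-value `E = K·m·n·exp(−λS)` (λ = 0.267,
  K = 0.041, n = total library residues). It is deterministic, needs no
  external binaries, and is validated against an independent brute-force
  affine-gap recursion on all instances up to 30 residues.
* **psiblast**: a two-stage adapter around NCBI BLAST+ — stage one builds
  a PSSM by iterating the query against a configurable background set,
  stage two searches the domain library with that profile; tabular output
  with qseq/sseq alignment strings is parsed into the same hit structure.
  The number of stages and their E-value cutoffs are explicit
  configuration, since "profile search" admits many protocols.

## Profile–profile alignment score

The published filter's exact functional form is unpublished (it is
"PPA-I-like"); the package therefore defines its PPA precisely and treats
the cutoff as calibration-dependent configuration. Each position carries a
frequency vector f and a log-odds vector S over the 20 amino acids plus a
secondary-structure state in {H, E, C} with confidence. The column score is
the symmetrized cross product `(f_q·S_t + f_t·S_q)/2` plus
`w_ss · 1[ss_q = ss_t] · sqrt(conf_q · conf_t)` with `w_ss = 1`. A global
affine-gap Gotoh dynamic program (open 7, extend 0.5) finds the best
alignment; the reported score is `−(optimum / alignment length)`, so
better alignments are more negative and the score is length-invariant —
the only normalization under which a fixed cutoff like −1.90 is meaningful
across candidate lengths. Without a PSSM the profile degenerates to
one-hot frequencies and BLOSUM62 log-odds rows (the column score then
reduces to BLOSUM62 + ss bonus); without an ss file the state is all-coil
with confidence 1. PSI-BLAST ASCII PSSMs and PSIPRED `.ss2` files are
parsed when supplied. Consensus of multiple secondary-structure predictors
is reduced to a single pluggable ss input.

With these choices a near-self match scores around −5 to −6 per column and
unrelated same-length sequences score near or above 0, so the −1.90
default separates well; `calibrate_pct` re-fits the cutoff for any other
weight configuration.

## Evaluation and calibration

Labeled samples follow the segment-pair construction: every non-adjacent
pair (both segments ≥ 40 residues) of an annotated chain is a sample,
positive iff the two segments are exactly the two ranges of one annotated
discontinuous domain; adjacent pairs are never assembled; chains with
fewer than three segments carry no sample. Metrics are recall, precision
and MCC; undefined ratios (zero denominators) are reported as NaN with a
warning rather than silently coerced to 0.

The NDO score is implemented as residue-overlap under the best one-to-one
matching between predicted and reference domains (Hungarian assignment on
the overlap matrix), normalized by chain length. The original score is
cited without a formula, so this package's definition is documented here
and checked only by its properties (1.0 on identity, symmetry on full
partitions, hand-computable toy values).

Three calibration sweeps mirror the training protocol:

1. **EST** — exhaustive grid over T_TS ∈ [0.1, 1] and T_SI ∈ [0.05, 0.5],
   step 0.05 (19 × 10 cells), on cached per-sample scores.
2. **ECV** — the constraint-function decision run over b ∈ {0.1, …, 0.9}.
3. **PCT** — per b, the PPA cutoff swept from 0.0 to −5.0 in steps of
   −0.1 (51 values); the MCC-maximizing cutoff is reported, most
   permissive first among ties.

Whether such grids should be scored per sample or per chain is not fixed
by convention; per-sample counting is used throughout.

## Synthetic benchmark

The fixture generator emulates the benchmark construction at desk scale:
chains of 3–4 segments of 40–80 residues drawn from a fixed background
composition; for each positive chain a joint template equal to the
(optionally segment-swapped) concatenation of the chosen non-adjacent pair
under position-independent substitution noise (default rate 0.1, matching
the package's headline benchmark condition; an optional indel rate
stresses the coverage terms); continuous segments carry their own
single-segment templates with probability 0.5; decoys are random sequences
length-matched to the joint templates so the e < 0.2 filter is exercised.
Default sizes (30 chains, half discontinuous, 30 decoys) keep a full
pipeline run in seconds; tests use smaller seeds of the same family and
state their sizes locally.

What this emulates — homology detectable by alignment, symmetric halves,
length-matched confounders — and what it does not: real substitution
processes (no rate heterogeneity or conservation structure), real domain
length and composition distributions, boundary-prediction error, and
remote homology where profiles genuinely outperform single sequences.
Passing the synthetic benchmark therefore demonstrates the correctness of
the assembly-and-filter machinery, not field performance on real chains;
published-scale recall/precision depends on library coverage and is out of
scope here. A score-level variant (`planted_threshold_scores`) plants a
known (T_TS, T_SI) boundary directly in score space to test that the EST
grid search recovers it; this is the direct construction because the sweep
consumes cached scores by design.

## Numerical and degenerate-input choices

- Library deduplication identity = identical aligned residues / shorter
  sequence length, from a global BLOSUM62 (−11/−1) alignment; greedy
  longest-first clustering (ties by id) for determinism. Cutoff 1.0 thus
  removes exact duplicates and full-length identical subsequences.
- Candidates with empty hit lists, empty candidate sets, or chains with no
  boundaries degrade to continuous-domain output, never errors.
- E-values are floored at 1e−300 to stay positive; h is clamped at 0.
- Gapped alignment strings attribute gap runs between aligned blocks to
  the block boundary at which they occur; per-segment statistics use only
  gap-free columns, so no gap-attribution convention can affect scores.
- All user-facing coordinates are 1-based inclusive; a boundary at B means
  "break after residue B".
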