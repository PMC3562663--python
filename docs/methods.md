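# Methods

## Model

`topper` treats each external topology predictor as a witness whose
reliability is summarized by a single number, its overall recognition rate
Rc (trace of its residue confusion matrix over the grand total). An
abstract-level prediction — "this residue is class p" — becomes the
two-focal basic probability assignment m({p}) = Rc, m(Ω∖{p}) = 1 − Rc on
the frame Ω = {i, M, o}. Placing the complement mass on the doubleton
Ω∖{p} rather than on Ω is deliberate and changes the algebra: it says "if
the witness is wrong, the truth is one of the other two classes", which is
exactly what a confusion matrix licenses, and it makes wrong witnesses
actively vote against their own label (see *Fusion regimes* below).

Per residue, the N witnesses' BPAs are fused with Dempster's rule
(conjunctive combination, renormalized by 1 − K where K is the mass on
empty intersections). Residues are fused independently; no positional
smoothing or grammar model is applied at this stage. The fused mass is
converted to a probability by the pignistic transformation (each focal
element's mass split equally over its members) and decided by argmax.

Assumptions inherited from this design:

* **Independence.** Dempster's rule assumes the witnesses err
  independently given the truth. Real predictors that share training data
  or methodology (e.g. two variants of the same HMM) violate this and the
  fusion will over-count their shared evidence.
* **A single global Rc per predictor.** All three class-conditioned BPAs
  of a predictor use the same rate; per-class recognition/substitution
  rates are intentionally not modelled.
* **Abstract-level inputs.** Only hard labels are consumed, never
  posterior probabilities or ranked alternatives.

## Fusion regimes and tie handling

For N equal-rate witnesses unanimously voting class c, the fused singleton
mass is Rc^N / (Rc^N + (1−Rc)^N): the unanimous class wins if and only if
(Rc/(1−Rc))^N > 1/2. Hence unanimity (and plurality-majority dominance)
is guaranteed for Rc > 0.5 — the regime of every practical predictor —
but *not* below: a sub-coin-flip witness's unanimous vote is, correctly,
evidence against its own label, and at exactly Rc = 0.5 fusion is uniform.
The exhaustive property tests therefore sweep Rc grids strictly inside
(0.5, 1). Exact BetP ties (symmetric disagreement patterns) are broken in
the canonical class order i, M, o; the comparison uses a 1e-12 tolerance
so that floating-point drift cannot flip a mathematical tie.

Categorical BPAs (Rc ∈ {0, 1}, possible with degenerate confusion
matrices) can produce total conflict (K = 1), which raises an error naming
the predictors involved; K ≥ 1 − 1e-12 is treated as total. Optional
Laplace smoothing of confusion matrices (`smooth_matrix`, default
pseudocount 0, i.e. off) keeps Rc strictly inside (0, 1) when that is a
concern.

## Numerical choices

* Mass functions validate m(∅) = 0, masses ≥ 0 and Σm = 1 within 1e-9;
  zero-mass entries are dropped so the focal set equals the support.
* Each pairwise combination renormalizes by the realized non-empty product
  mass (equal to 1 − K in exact arithmetic), keeping every intermediate a
  valid BPA to machine precision; an independent full-power-set
  brute-force implementation agrees to 1e-12 in the tests.
* Propositions are `frozenset`s of class labels; the canonical order
  (i, M, o) fixes every matrix layout, serialization and tie-break.
* Report rounding is half-up (2 decimals for percentages, 4 for F), via
  `decimal`, matching the usual table conventions. One published
  benchmark cell is internally inconsistent at that precision: the
  ensemble's residue accuracy is stated as 80.00 % alongside a confusion
  matrix whose trace/total is 23918/29902 = 79.99 % at two decimals; the
  package reports what the counts imply.

## Topology decoding and scoring

Decoding keeps maximal runs of `M` with length ≥ `min_tm_length`
(default 5; the threshold is inclusive). Shorter runs are folded into the
adjacent loop, preserving residue count. The N-terminal side is taken
from the first non-M label — also when the sequence starts inside the
membrane; an all-M sequence has undefined orientation (`n_term_side =
None`), which never counts as a correct topology. Coordinates are 1-based
inclusive throughout.

Region scoring uses greedy in-order one-to-one matching with the
≥ 9-residue overlap rule (`min_overlap`, configurable): walking both
segment lists left to right, a pair that overlaps by at least the
threshold is matched and both pointers advance, otherwise the segment that
ends first is skipped. This prevents double counting and is
order-deterministic. Q is the geometric mean 100·√(M·C), the standard
overall prediction power for segment-overlap evaluation; note Q always
lies between M and C. Topology correctness requires equal segment counts,
every in-order pair overlapping ≥ 9 residues, and the same N-terminal
side — the strictest reading of "all TM regions and the orientation
correct".

## Cross-validation harness

`crossvalidate` shuffles the protein ids with a seeded PCG64 generator,
splits the shuffled order into contiguous near-equal folds (125 proteins /
10 folds → sizes 12-13), estimates each predictor's confusion matrix and
BPA profile on the training folds only, fuses the held-out fold, and pools
residue/region/topology metrics over all held-out predictions. Identical
seeds reproduce the entire run bit for bit.

## Synthetic benchmark generator

`SimSpec` defaults generate 125 proteins with 1-14 TM helices of 15-30
residues separated by loops of 1-60 residues, N-terminal side uniform —
the scale of a typical curated benchmark (a few hundred observed helices
across ~125 chains, several helices per protein). Five simulated
predictors corrupt the true labels independently with a row-stochastic
confusion law whose diagonal is ~0.78, the accuracy range of real
predictors; structural noise (whole-helix deletion, boundary jitter of up
to a chosen number of residues per end) can be layered before the residue
noise, in which case the per-residue resampling is conditioned on the
structurally corrupted label. Amino-acid content is uniform random:
sequence content never enters any computation, only labels do.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data:

* real predictors' errors are spatially coherent (whole helices missed or
  shifted), while the generator's residue noise is i.i.d.; i.i.d. errors
  at ~5 % residual rate frequently split a decoded helix in two, so
  region- and topology-level scores on synthetic data are much lower than
  on real benchmarks even at higher residue accuracy;
* real predictors are correlated with one another, so real fusion gains
  are smaller than the conditional-independence gains seen here;
* no signal peptides, re-entrant loops, or helix-length upper bounds.

## Problem sizes used in the checks

The bundled benchmark tables (six 3×3 confusion matrices over 29 902
residues; region counts over 515 observed helices) are recomputed exactly
and instantly. Monte-Carlo checks use 125 simulated proteins (~54 000
residues) for fusion-gain and cross-validation properties and ~10⁵
residues for corruption-law convergence, with 3-standard-error tolerances;
exhaustive fusion checks enumerate all 3^N label patterns for N ≤ 5 over
an Rc grid. The whole suite runs in a few seconds on one CPU.

## Known limitations

* Only the three-class frame {i, M, o} is supported publicly; alternative
  combination rules (Yager, PCR5), discounted/weighted evidence and
  interval-valued masses are out of scope.
* Native output formats of specific external predictors are not parsed;
  labels must be provided in the FASTA-like i/M/o format (an explicit
  dialect map handles simple alphabet differences such as H→M).
* The decoder enforces no topology grammar beyond the minimum helix
  length; loop-side alternation is used when reconstructing labels but
  not enforced when decoding noisy input.
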