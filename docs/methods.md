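# Methods

## Model and procedure

The package implements nonparametric cognitive diagnosis: each examinee's
observed response pattern (ORP, a binary vector over I items) is matched
against the ideal response patterns (IRPs) of candidate knowledge states
(binary vectors over K attributes), and the closest state is assigned.
Ideal responses come from a condensation rule applied to the Q-matrix:

- conjunctive (DINA-type): η<sup>(c)</sup> = 1 iff the state masters
  every attribute the item measures;
- disjunctive (DINO-type): η<sup>(d)</sup> = 1 iff it masters at least
  one.  The disjunctive rule is the standard DINO form; only the
  conjunctive rule has a canonical printed definition in the
  nonparametric-classification literature this follows, so the DINO form
  is adopted explicitly.
- weighted: the convex blend ωη<sup>(c)</sup> + (1−ω)η<sup>(d)</sup>
  per state–item cell.

NPC minimises Hamming distance to conjunctive IRPs.  GNPC iterates:
seed clusters with NPC, estimate each cell's ω as the within-cluster
least-squares value clamped to [0,1], rebuild the blended IRPs, reassign
by squared distance; stop when the membership partition repeats (this
covers both fixed points and cycles) or after `max_iter` (default 100,
flagged unconverged).  WGNPC scores reassignment with per-item weights
1/(p̄(1−p̄)) from the item passing rates.

Because the blended ideal is the conjunctive one wherever ω = 1, and
clamped ω is the constrained minimiser of a convex quadratic, the GNPC
objective (total within-cluster residual) is non-increasing across
iterations; this is a k-means-style alternating minimisation.  The same
is not guaranteed for WGNPC, whose reassignment metric differs from the
residual being minimised in the ω step; in practice it converges in a
handful of iterations.

### Conventions for degenerate cells

The weight formula is undefined when η<sup>(c)</sup> = η<sup>(d)</sup>
(single-attribute items; the blend is then independent of ω) and for
empty clusters.  Both get ω = 1, so unvisited states use their
conjunctive ideals.  The empty-cluster convention matters: with few
examinees and large K almost every candidate state is empty, and falling
back to conjunctive ideals makes the iteration well defined without
inventing data.  Passing rates of 0 or 1 are clamped symmetrically to
0.0001 / 0.9999; the lower clamp is the published convention and the
symmetric upper clamp is the only reading that keeps p̄(1−p̄) positive
at p̄ = 1.

### Tie-breaking

Distances can tie exactly (they are sums of low-denominator rationals).
The argmin prefers the state with the fewest mastered attributes, then
binary-counting order (attribute 1 as the low bit) — deterministic and
parsimony-favouring.  Float comparisons use a relative tolerance of
1e−9 so mathematically equal distances computed in different orders
still tie.

### Large attribute sets

Exhaustive enumeration is capped at K = 20.  Above the cap, attributes
are partitioned into connected components of the co-occurrence graph
(two attributes linked iff some item measures both; every item falls
wholly inside one component) and each component is classified
separately.  For NPC this decomposition is *exact*: the distance and the
tie-break order both factor over components.  For GNPC/WGNPC it is an
approximation: the weight formula clusters examinees by their full joint
state, a strictly finer partition than per-component substates, so
pooled per-component weights can differ from joint-space weights on
noisy data.  Empirically the assignments agree at ≈98% of attribute
calls on random noisy designs and exactly on noiseless ones; the test
suite checks exactly that, and exact joint-space behaviour is always
available below the cap.  A component that is itself wider than the cap
is searched by multi-start coordinate descent per examinee (starts:
all-zero, all-one, an attribute-wise pass-rate threshold state, the
current assignment, and seeded random states; single-bit flips accepted
only on strict improvement, so termination is guaranteed; the multi-start
winner is chosen with the global tie-break).  This search is heuristic;
on designs where exhaustive search is feasible it matches it in ≥95% of
attribute calls in the suite's spot checks.

## Reliability and validity metrics

- **Cronbach's α** from the standard variance-ratio formula with N−1
  sample variances; undefined (error) at zero total-score variance.
- **Retest consistency**: the stability metric is operationalised as
  seeded stratified random split-half re-classification agreement, the
  standard CDA practice when no parallel form exists.  Items are dealt
  alternately within q-vector pattern groups (so both halves keep every
  attribute's coverage whenever possible; degenerate splits are redrawn
  up to a cap), each half is classified independently, and agreement is
  scored per attribute call (attribute consistency) and per whole
  profile (pattern consistency), averaged over replicates (default 10).
  Pattern consistency can never exceed attribute consistency.  The
  report records the design, seed and replicate values.
- **Mastery level** is Σ<sub>k</sub> α<sub>k</sub>; its association with
  total scores uses the Pearson product-moment correlation (the common
  default when only "correlation coefficient" is specified).

## Synthetic data generator

The generator emulates a large single-best-answer MCQ bank diagnosed at
cohort scale: N examinees, I items, K attributes, 1–3 attributes per
item, and a heavily skewed attribute-coverage distribution given either
as explicit per-attribute item-count targets or a power-law exponent.
With targets, incidences are dealt like tokens — one per item first,
leftovers placed on random items with spare capacity — which pins column
sums to the targets up to occasional unplaceable tokens (tested within
±5%).  `complete=True` (default) reserves the first K items as an
identity block, making conjunctive IRPs pairwise distinct and the states
identifiable.  Responses follow a DINA slip/guess model,
P(correct) = 1−slip if the conjunctive ideal is 1 and guess otherwise
(a DINO variant exists for disjunctive testing); latent states are
independent Bernoulli(p<sub>k</sub>) or an explicit list.

The study-shaped preset (41 × 2,809 × 22 with the published subdomain
counts) uses slip = 0.1, guess = 0.2 (chance level on five-option
items) and mastery prevalence 0.85 per attribute — values chosen once
to reproduce the cohort's reported character (total scores around
77–90% and 17–20 of 22 attributes mastered).  What the generator does
*not* emulate: dependence between examinees (real model cohorts share
training data; rows here are independent), item-difficulty variation
within an ideal-response class, option-level distractor behaviour, and
any attribute hierarchy.  Passing recovery tests on this generator
therefore demonstrates correctness of the machinery under the assumed
response model, not robustness to violations of it.

## Problem sizes and numerical choices

The test suite runs oracle-equivalence checks at K ≤ 6, N ≤ 25 against
plain-Python brute-force implementations, recovery at K = 4, I = 30,
N = 500 over 20 seeds, and the acceptance script runs the full
41 × 2,809 × 22 shape with 5 consistency replicates — sizes chosen to
exercise every code path (exhaustive, component, coordinate-descent) at
desk scale.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); repeated runs are bit-identical.  The
closed-form ω is validated against a 1e−4-step grid search; distance
computations use the expanded quadratic form with a clamp at zero to
absorb roundoff.

## Known limitations

- GNPC/WGNPC component-mode results are approximations of joint-space
  classification (exact for NPC); see above.
- Coordinate descent offers no optimality guarantee for components wider
  than the enumeration cap.
- Retest consistency requires every attribute to be measured by at least
  two items; the coverage filter (default minimum 3) should be applied
  first.
- The scoring path handles single-correct-option MCQs only; partial
  credit and multi-correct items are out of scope.
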