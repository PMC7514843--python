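# Methods

## Model and procedure

The package mines decision rules for a binary accident-severity class
(1 = slight injury, 2 = fatal, meaning killed or seriously injured within 30
days) from 22 categorical predictors describing urban accidents of novice
drivers.  Intersection and non-intersection accidents are partitioned and
mined separately (the two intersection-only variables `I_T`, `PR` and the
non-intersection-only `TR_N_INT` exist in just one partition).

Mining proceeds in four stages:

1. **Variable ranking.**  For each split criterion, predictors are ranked by
   their criterion value on the full partition.  Variables with no observed
   variation are unrankable and excluded — they could only produce
   single-leaf trees, which yield no rules.
2. **Root-variation tree ensemble.**  One unpruned tree per ranked variable
   per criterion, with that variable forced as root (at most
   `#criteria × m` trees).  Below the root, each node splits on the
   criterion-maximising variable not yet used on its path, only while the
   score is strictly positive, depth < 4, and at least two children receive
   weight ≥ 2.  A forced root with strictly negative imprecise gain vetoes
   its whole tree (the criterion judges the variable to worsen the class
   information); the gain-ratio root is always split when it varies and the
   minimum-weight condition holds, because the ensemble requires the root
   even when it is uninformative.
3. **Rule extraction.**  One rule per leaf (root-to-leaf conditions →
   leaf majority class); single-leaf trees contribute nothing.  Pooled
   rules are deduplicated on (antecedent set, consequent).
4. **Selection.**  Support `S = P(A,B)` and probability `Pr = P(A,B)/P(A)`
   are computed on the original unit-weight records (fractional training
   weights are an induction device, not an evaluation convention; a missing
   value never matches a condition).  Rules with a fatal consequent,
   `Pr ≥ min_probability` and `S ≥ min_support` are kept, sorted by `Pr`
   descending, ties by `S` then antecedent order.

## Split criteria

With per-class counts `n_i` and total `N` at a node (both real-valued):

* **IGR** — `[H(C) − Σ_i p(x_i) H(C|X=x_i)] / H(X)`, entropies in bits;
  undefined when `H(X) = 0` (the caller skips the variable).
* **IIG** — imprecise-Dirichlet credal intervals
  `[n_i/(N+s), (n_i+s)/(N+s)]`; default `s = 1`, exposed as a parameter
  (the small-`s` limit collapses the credal set onto the empirical point,
  recovering the precise info-gain — an anchor used by the tests).
* **A-NPIM** — intervals `[max(0,(n_i−1)/N), min((n_i+1)/N,1)]`, no
  parameter.

Both imprecise gains replace entropy by the maximum entropy H\* over the
credal set and subtract the branch-weighted conditional H\* built from each
branch's own counts (each criterion consistently uses its own credal model
for marginal and branches).  They can be negative; the 10-record catalogue
fixture (class counts (8,2), two (4,1) branches) has IIG ≈ −0.0729 bits at
`s = 1` while its precise info-gain is exactly 0.

**Maximum entropy over an interval box ∩ simplex.**  The objective is
concave and the KKT conditions give the clamped-common-level form
`p_i = clamp(λ, l_i, u_i)`; λ is found by bisection on the monotone sum
constraint to 1e-12.  For two classes this reduces to the closed form
"point of the feasible `p_1` interval closest to 1/2", which the tree
builder uses vectorised; the equivalence is tested.  Correctness is
anchored to an independent brute-force oracle (grid-based pattern search
from a known feasible point) rather than to any specific published
algorithm, agreeing to ≤ 1e-4 bits over random interval systems.

## Missing values (C4.5 convention)

* Criterion values are computed on the observed weight of the candidate
  variable only, then scaled by the observed-weight fraction.
* At a split, a record missing the split variable descends **every** branch
  with its weight multiplied by the branch's share of observed weight;
  leaf class-count weights therefore sum exactly to the root weight
  (tested to 1e-6).
* At prediction time a missing split value fans out by the stored branch
  shares and the class with the larger aggregated class-count mass wins; a
  value unseen in training falls back to the node's majority class.

## Determinism and tie-breaking

Ranking ties and best-split ties break by schema column order (first
maximum); leaf-class ties break toward class 1, the global majority.
Identical data + configuration reproduce byte-identical rule tables.
Scores below 1e-12 are treated as zero to keep floating-point dust from
forcing splits.

## Synthetic generator

The generator emulates the *preprocessed* cohort, not the raw three-table
DGT files: ~30,000 records (default), per-variable categorical marginals
and missingness rates rounded from the published per-value instance counts
(e.g. road surface ~90% "dry and clean", visibility-restriction missing in
~75% of records; the published fringe-time count "75,112" exceeds the
dataset size and was read as 7,511 when rounding), a base fatal rate of 7%
(the cohort is stated to be below 10% fatal), an intersection share of 0.5,
and structural absence of partition-specific variables.  Severity is drawn
independently per record, so all predictor-class dependence comes from
**planted rules**: a chosen share of records is overwritten to match an
antecedent exactly (guaranteeing the target prevalence) and their severity
redrawn at the planted fatal probability.  Missingness is applied after
planting and never to the class or the partition indicator.  A truth log
records planted rows and realized rates.

What the generator does **not** emulate: real dependence among predictors,
exposure effects, multi-driver accidents, or the DGT recoding of raw codes.
Passing tests therefore demonstrate that the machinery recovers known
structure under the stated noise and imbalance — not that it reproduces the
published rule tables, which derive from non-redistributable microdata.

## Planted-rule recovery: design and a known limitation

Recovery is asserted as: some selected rule's antecedent is a subset of the
planted antecedent with `Pr` close to the planted fatal probability.  Two
design points matter:

* **Antecedent values form a marginal ladder** (~6.6%, 8%, 14%, 14.5%, all
  on missingness-free variables in the test configuration).  If all four
  values are rare, three conditions already isolate an almost purely
  planted node; the fourth planted variable is then near-constant there,
  greedy trees append an unrelated fourth condition instead, and no
  selected antecedent is a subset of the planted set.  The ladder keeps
  background records (hence contrast) present at every level, and the
  exact antecedent is then recovered in essentially every seed and both
  partitions.
* **The ±0.05 probability window is irreducibly stochastic.**  At 0.5%
  prevalence of n = 30,000 split over two partitions, a recovered rule has
  ~75 matches per partition, so `Pr̂` has binomial standard deviation
  ≈ 0.057; even with perfect structural recovery the per-seed probability
  that some partition lands within ±0.05 of 0.6 is ≈ 0.8, and a
  19-of-20-seeds requirement on that event fails with high probability by
  construction.  The corresponding acceptance test reports both numbers
  (structural recovery and within-window recovery) so the two effects are
  never conflated; typical observed values are 20/20 structural, 16/20
  within the window.

## Problem sizes used

Unit tests run on hand-built fixtures and generated datasets of 400–30,000
records; the oracle comparison uses 200 random credal sets (k ≤ 4); the
recovery study uses 20 seeds at n = 30,000 with all three criteria (about
45 non-vetoed trees per run).  The full suite and the acceptance script
each complete in about a minute on one CPU.

## Other design choices and limitations

* Real-valued class counts enter the credal interval formulas directly;
  both models are well-defined for fractional counts, which C4.5-style
  missing handling requires.
* "Four levels" is read as at most four split nodes on any root-to-leaf
  path, so extracted rules have 1–4 antecedent conditions.
* One ranking per partition per criterion; rankings are not shared across
  partitions.
* No pruning, no numeric attributes, no ensemble voting for prediction,
  no validation split (selection is deliberately in-sample: with <10%
  fatal records a held-out split would leave too few fatal cases to score
  rules), and no association mining beyond tree paths.
* The published rule statistics shipped with the package are a fixture for
  the selection thresholds and output format only; reproducing their
  numeric values would require the original microdata.
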