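# Methods

## Model

`rumselect` treats a normalized decision table ⟨U, A, D⟩ as a fuzzy
granular space. Each attribute b induces a similarity
r_b(x,y) = 1 − |x_b − y_b|, cut to zero when the distance exceeds 1 − α;
a subset B aggregates per-pair by the minimum; and the fuzzy neighborhood
granule of a sample is its similarity row with entries below the radius α
zeroed. The radius cut is applied both per attribute and on the
aggregate. After the per-attribute cut the aggregate cut is algebraically
redundant (the min of values that are each 0 or ≥ α is itself 0 or ≥ α),
but both are kept so the code matches the granule definition verbatim.
The cut is closed at the boundary: a pair at distance exactly 1 − α keeps
similarity α.

The *rough decision* RD assigns each sample a graded membership to each
class: the fraction of its similarity mass, under the **full** attribute
set at the working radius, that lies in that class. RD rows sum to 1 by
construction. The radius cut is treated as part of the similarity
relation itself, so RD is computed from the cut relation; RD is computed
once and held fixed while candidate subsets vary. The alternative
(computing RD from the un-cut relation) is indistinguishable on the
α = 0 desk example but behaves badly in practice: with RD diluted by the
full attribute set's min-aggregation, strongly similar within-class
neighbors exceed their RD values and stop counting as evidence, and the
significance measure then systematically prefers noise attributes.

The counting primitive is the soft-inclusion cardinality
|S ∩ T| = #{x : 0 < S(x) ≤ T(x)}. Two conventions are forced by the desk
examples: ties count, and S-zero positions never count. Note this makes
|S ∩ T| asymmetric and *not* a t-norm cardinality — it measures how much
of S sits below T, which is the intended reading (the granule should sit
below its class's rough-decision profile when B explains D).

Uncertainty is measured in bits:

- rough entropy E_c(B) = (1/n) Σ log₂ |[xᵢ]_B^α|,
- joint entropy over two subsets via the entrywise-minimum granule,
- conditional entropy E_c(RD|B) = (1/n) Σ log₂(cardᵢ / countᵢ) with
  countᵢ the soft-inclusion count of granule i against the RD column of
  xᵢ's own class.

The decomposition E_c(RD|B) = E_c(B) − E_c(RD,B) holds exactly when the
joint entropy with the decision reuses the same soft-inclusion counts,
and non-negativity follows from count ≤ card.

## Selection

Greedy forward search: starting from red = ∅ (whose granules are the
universal all-ones relation, entropy well-defined), each step adds the
candidate maximizing SIG(r, red, D) = E_c(RD|red) − E_c(RD|red ∪ {r}),
breaking ties toward the smaller column index, and stops once
E_c(RD|red) − E_c(RD|A) ≤ β. Two guards:

- if the rule already holds at red = ∅ the result is the empty subset
  with a warning (vacuous tolerance);
- if no candidate improves entropy by more than 10⁻¹² bits while the rule
  is unmet, the search stops and flags the trace as stalled rather than
  looping on noise.

Because only positive-significance attributes are ever added, the
per-step conditional entropies are strictly decreasing even though
subset monotonicity is not guaranteed in general (below). An optional
backward pass (`prune`) removes, in reverse selection order, any
attribute whose absence keeps the β criterion.

## Monotonicity is empirical, not structural

Growing B shrinks granules entrywise, but the soft-inclusion count can
shrink faster than the cardinality: when an entry that counted drops to
zero, the ratio card/count can rise. So E_c(RD|M) ≤ E_c(RD|N) for
N ⊆ M — the inequality behind "significance is non-negative" — can fail.
The property suite measures it on 200 random tables per run and reports
violations as a warning with their magnitude (typically ~1% of nested
pairs, worst excess a few hundredths of a bit) instead of asserting it.
On synthetic data at large α the violation can be substantial: a noise
attribute that isolates samples can push E_c(RD|B) below E_c(RD|A). This
is a real property of the measure, not an implementation artifact, and
the selector's guards are designed around it.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | neighborhood radius, unitless in [0,1) | 0.1 | larger ⇒ sparser granules; swept over [0, 0.5] |
| β | entropy tolerance, bits ≥ 0 | 0.25 | larger ⇒ smaller subsets; swept over [0, 0.5] |
| grid_step | sweep increment | 0.05 | 11 × 11 = 121 grid points |
| cv_folds | stratified CV folds | 10 | reduced (with warning) if the rarest class is smaller |
| knn_k | neighbors for KNN | 3 | Euclidean, majority vote |
| rng_seed | CV shuffle seed | 0 | the reduction itself is deterministic |

Classifier settings beyond "linear" and "k = 3" are plain defaults
(SVC C = 1.0), recorded in each `EvalResult`.

## Numerical choices

- Base-2 logarithms throughout (the desk example's 1.0118 bits fixes the
  base).
- Zero-count clamp: a sample whose granule–decision count is 0 (possible
  when its self-membership 1 exceeds its own RD value and nothing else
  qualifies) is clamped to 1 with a warning — the value it would have if
  only the sample itself counted. This case cannot occur in the desk
  examples and is rare elsewhere; it is the only guard between the
  definition and a divergent logarithm.
- Constant attribute columns min-max to all zeros (warned), since the
  scaling formula is undefined on them and they carry no information.
- Similarities are stored at full float precision; 4-decimal rounding is
  display-only.
- Min-max normalization is idempotent and rank-preserving; both are
  property-tested.

## Synthetic generator

`SyntheticSpec` plants known structure: class-conditional Gaussian
informative attributes (class means spaced `effect_size` apart, spread
`noise_sd`, clipped to [0,1] then per-column min-max rescaled), exact
duplicates of informative attributes, and uniform-[0,1] noise attributes.
Defaults: 60 samples, 2 balanced classes, 2 informative + 1 duplicate +
5 noise attributes, effect 0.6, spread 0.2, seed 7. The spread is chosen
so each informative attribute alone is imperfect (≈3 sd between class
means, a few percent Bayes error) while the pair is near-perfect — this
makes the planted pair the *unique* accuracy-optimal subset, which is
what a ground-truth-recovery fixture needs; with a much smaller spread
any single informative attribute ties at 100% and "the planted set" is
not identifiable by accuracy.

What it does not emulate: gene–gene correlation beyond the planted
duplicates, batch effects, heavy-tailed expression noise, class
imbalance. Recovery results on it show the selector works under its own
assumptions; they do not certify behavior on real microarrays.

Calibrated recovery under the defaults (computed by the test suite): for
seeds 0–19, at least one (α, β) grid point yields exactly the planted
pair in 20/20 replicates; the regression guard asserts the 90% floor
(18/20). The sweep's best-accuracy row (ties broken toward smaller
subsets) equals the planted pair in 13/20 replicates and at the default
seed; only the default-seed behavior is asserted. Uniform noise is
adversarial for this measure at large α — a noise attribute that
isolates every sample produces singleton granules that look perfectly
pure — which is why suitable parameters are found by the sweep rather
than fixed a priori.

## Problem sizes

Tests and the acceptance script run on the built-in desk fixtures
(n = 5, 10), random tables of 4–12 samples for oracle and theorem checks
(200 per run), and the 60-sample synthetic default (20 replicates for
the recovery guard); a full 121-point sweep with cached CV evaluation
takes about a second at that size. These sizes were chosen because every
claim they support is already decided at desk scale; the implementation
itself is vectorized (the per-attribute similarity stack is built once
per table and sliced per subset) and handles hundreds of samples and
thousands of attributes in the same way.

## Known limitations

- The conditional entropy is not monotone under subset growth (above),
  so the greedy search has no approximation guarantee; the β rule can be
  met by subsets a backward pass would shrink (hence `prune`).
- With many uniform-noise attributes and large α the measure can prefer
  sample-isolating attributes; inspect the sweep's accuracy surface
  rather than trusting a single (α, β).
- Reducts are order-dependent (greedy, smallest-index ties); no claim of
  minimality is made.
- No missing-value handling; tables must be fully numeric.
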