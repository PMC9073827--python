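# Methods

## Problem structure

A decision problem consists of M response alternatives, each with N possible
outcomes occurring with probabilities p_n (Σ p_n = 1 per alternative), K
criteria (benefit or cost type, weights w_j ≥ 0 summing to 1), and H experts.
All attribute values x_mnk and reference points are interval numbers
[lo, hi]: the bounds are the only information carried, no distributional
shape beyond the uniform density used in the payoff derivation is assumed.

## Consensus stage

Experts state interval reference points E_hk per criterion. Because criteria
live on different scales, the panel is min-max normalized per criterion over
*all* experts' bounds (benefit: (x − min)/(max − min); cost: reflected
(max − x)/(max − min) with the resulting bounds reordered so lo ≤ hi — the
reflection reverses them). A zero-range column (all experts identical)
normalizes to [0, 0] for everyone, so it contributes no distance and leaves
relative weights untouched.

Each expert's distance to the panel-mean interval on criterion k is the
root-mean-square distance of the two bounds,
d_hk = sqrt(((lo − mean_lo)² + (hi − mean_hi)²)/2) ∈ [0, 1] on normalized
data. Similarity d_h = Σ_k (1 − d_hk); weights w_h = d_h / Σ d_h. An expert
panel in perfect agreement yields equal weights 1/H. The degenerate case
Σ d_h = 0 (every expert at maximal distance on every criterion) cannot arise
from a panel mean but is rejected as an input error for safety.

The collective reference point is the weighted sum of the experts' **raw**
intervals, r_k = Σ_h w_h E_hk, so it lives on the original measurement scale
and can be compared with raw attribute values downstream. The normalized
panel exists solely to make distances comparable across criteria; because
min-max normalization is affine, aggregating normalized intervals and
de-normalizing would give the identical r_k for benefit criteria.

## Payoff stage

The relation of an attribute interval C to the reference R falls into six
cases (disjoint below/above, partial overlap low/high, reference nested in
C, C nested in R). The strict textbook inequalities leave boundary
equalities uncovered, so classification applies the fixed precedence
1, 2, 6, 5, 3, 4; this makes nested-equal intervals payoff-neutral and lets
point intervals reduce to the crisp sign comparison (C=[c,c], R=[r,r] gives
net c − r for a benefit criterion). Benefit-type payoffs:

| case | gain | loss |
|---|---|---|
| 1 (C below R) | 0 | 0.5(C^L + C^H) − R^L |
| 2 (C above R) | 0.5(C^L + C^H) − R^H | 0 |
| 3 (overlap, C low) | 0 | 0.5(C^L − R^L) |
| 4 (overlap, C high) | 0.5(C^H − R^H) | 0 |
| 5 (R nested in C) | 0.5(C^H − R^H) | 0.5(C^L − R^L) |
| 6 (C nested in R) | 0 | 0 |

For the disjoint cases 1–2 these are exactly the expectation of x − R^L
(resp. x − R^H) under a uniform density on C; the package ships a
numerical-integration oracle (`uniform_expected_payoff_oracle`) and the test
suite checks agreement to 1e-9 there. The overlap-case formulas are *not*
uniform-density expectations; they are implemented as the half-difference
forms above, as defined. Cost-type payoffs are the negate-and-swap mirror of
the benefit ones (gain_cost = −loss_benefit, loss_cost = −gain_benefit),
which keeps gains ≥ 0 and losses ≤ 0 in every case and encodes
"below the reference is good" for costs.

Case 5 produces a nonzero gain *and* loss. The two components are passed
through the value function separately and the valued results summed, since
prospect theory values gains and losses asymmetrically; the `net` field on a
payoff pair is reporting-only.

## CPT stage

Value function: v(z) = z^α (z ≥ 0), −λ(−z)^β (z < 0). Defaults α = β = 1,
λ = 2: linear value with losses weighing double. α, β ∈ (0, 1] give the
usual diminishing sensitivity; λ ≥ 1.

Per-criterion normalization: ṽ_mnk = v_mnk / v*_k with
v*_k = max_{m,n} |v_mnk|, taken **after** loss aversion (over the λ-scaled
losses). An all-zero criterion normalizes to zeros. With α = β this makes
prospect values invariant to rescaling any one criterion's values and
reference by a positive constant (a property test covers this).

Probability weighting: the neo-additive form w(p) = μp + (1 − μ)/2 on (0,1)
with w(0) = 0, w(1) = 1; default μ = 0.6. Small probabilities are
overweighted, large ones underweighted; w(p) + w(1 − p) = 1 identically.
μ = 1 gives w(p) = p, which is exactly how the "identity"
(objective-probability) option is implemented internally.

Decision weights follow the standard rank-dependent construction: per
criterion, outcomes are sorted by ṽ descending (stable, ties by input index;
ṽ = 0 grouped with the gains — their contribution is zero either way). The
n-th best gain receives π⁺ = w(p_1 + … + p_n) − w(p_1 + … + p_{n−1});
ranking losses from the worst upward, each receives
π⁻ = w(p_n + … + p_N) − w(p_{n+1} + … + p_N). One weighting function serves
both sides. The gain/loss partition is *per criterion*: an outcome may count
as a gain on one attribute and a loss on another. With two outcomes of
uniform sign across criteria this collapses to the familiar per-outcome
combined form (π⁺ = w(p_success), π⁻ = w(p_fail)), an equivalence the tests
assert.

PV_i = Σ_j w_j (Σ_gains π⁺ ṽ + Σ_losses π⁻ ṽ); alternatives are ranked by
descending PV with ties broken by input order. |PV| ≤ 1 whenever the
attribute weights sum to 1.

Numerical note: the cumulative probability grid is computed once per
prospect with its grand total pinned to exactly 1.0 before weighting, so the
telescoping identity Σπ⁺ + Σπ⁻ = 1 holds to machine precision regardless of
floating-point summation order; outcome probability sums and weight vectors
are validated to 1e-9.

## Scenario runners

`single_criterion_run(problem, k)` re-solves with attribute weight vector
e_k — equivalent to editing the weights by hand, and tested as such.
`expert_weight_scenarios(problem, scenarios)` injects explicit expert-weight
vectors into the collective-reference aggregation, bypassing the similarity
stage; every downstream stage re-runs unchanged, so cross-scenario
differences isolate the influence of whose reference point counts. The
baseline scenario (weights equal to the similarity-derived ones) reproduces
the ordinary solve bit for bit.

The identity-weighting and λ overrides exist because removing probability
distortion is only meaningful alongside the loss-aversion setting used for
the comparison; both switches are independent.

## Synthetic problem generator

`generate(GeneratorConfig(seed, ...))` draws well-formed problems: defaults
mirror the packaged example's scale (4 experts, 3 criteria, 3 alternatives,
2 outcomes). Criterion scales are uniform in [10, 100]; reference-point
centers sit in the middle 30–70% of each scale while outcome-value centers
span the full scale, both with half-widths up to 20% of the scale; outcome
probabilities come from a flat Dirichlet; two thirds of the criteria are
benefit-type by default so the cost branch is always exercised. One PRNG
stream (numpy `default_rng(seed)`) drives everything and the seed is
recorded in the document's `meta` block; identical config and seed always
reproduce the identical document.

What the generator does *not* emulate: correlated criteria, experts with
systematic bias rather than independent scatter, probabilities estimated
from data with sampling error, or interval widths reflecting elicitation
confidence. Passing property tests on generated problems therefore shows
the algebraic invariants hold on well-formed inputs, not that the model
describes real emergency-department behavior.

## Known limitations

- The payoff calculus assumes a uniform density inside intervals and only
  derives the disjoint cases from it; the overlap cases are conventions.
- Reference points are static; no dynamic updating during an unfolding
  emergency.
- Expert weighting rewards proximity to the mean opinion, which discounts
  a lone well-informed dissenter by construction.
- Probabilities and intervals are taken as given (elicitation is out of
  scope), and the neo-additive weighting is the only distortion offered.
- Cost-type reference normalization follows the reflected form above; the
  packaged example exercises only benefit criteria, so that branch is
  validated by property tests rather than published numbers.
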