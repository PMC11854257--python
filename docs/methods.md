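# Methods

This note records the scientific and numerical choices behind `ivfed`: the
interval calculus, the measure constructions, the classifier and federation
layers, what the synthetic generator emulates, and the decisions taken where
the design was genuinely open.

## Interval calculus

All quantities live in `L^I`, the closed subintervals of `[0, 1]`, read
epistemically (an interval bounds one unknown true degree). Four comparison
regimes are implemented:

| kind | definition | properties |
|---|---|---|
| `partial2` | `a_l ≤ b_l ∧ a_u ≤ b_u` | partial order, complete lattice |
| `admissible` | lexicographic on `(ψ, υ)` | total, refines `partial2` |
| `possible` | `a_l ≤ b_u` | strongly complete, not antisymmetric/transitive |
| `necessary` | `a_u ≤ b_l` | antisymmetric, transitive, Ferrers |

**Admissible order default.** Only the construction recipe (two scalarisations
that jointly separate points) is fixed by the theory; the concrete pair is a
free choice. We default to `ψ = midpoint`, `υ = upper endpoint` — the
conventional Xu–Yager-style instantiation — and keep both pluggable in
`OrderSpec`.

**Floating point.** All order predicates use an absolute endpoint tolerance
(default `1e-12`); `compare()` tests interval equality first, so lexicographic
discontinuities at ψ-ties are resolved deterministically. Under the possible
relation a mutually related pair maps to `equal` — the relation is not
antisymmetric, and ranking code needs a three-way outcome.

**Negations.** Only the standard negation `N([l, u]) = [1 − u, 1 − l]`
(equilibrium `[0.5, 0.5]`) is printed in the source material; the possible
and necessary variants are cited to prior work we do not have. All three
measure families therefore default to the standard negation, and
`NegationSpec` accepts any involutive replacement. If a custom negation has
several fixed points, the equilibrium should be the fixed point closest (in
Moore distance) to `[0.5, 0.5]`.

## Aggregations

`A_mean` is the componentwise arithmetic mean (n-ary directly). `A_pos` and
`A_nec` are printed as binary forms; the n-ary extension is a **left fold**,
which preserves the boundary conditions. `A_nec` is not associative, so the
fold order is pinned and documented. The scalar inner aggregation of `A_pos`
defaults to the arithmetic mean (matching `A_mean` used elsewhere); `min`,
`max` and `product` are available.

## Precedence, similarity, entropy

All three families share one three-branch precedence skeleton

```
Prec(a, b) = [1 − w(a), 1]   if a = b
           = [1, 1]          if a < b   (strictly, under the family's regime)
           = A_fam(N(a), b)  otherwise
```

with the family's order (≤₂ / ≤ₚₒₛ / ≤ₙₑ𝒸) and aggregation
(`A_mean` / `A_pos` / `A_nec`). Similarity pairs the two directions with the
lattice meet and averages over the universe; entropy is `S(A, A^N)`.
The printed construction exists only for the possible family; the standard
and necessary variants re-use the same skeleton with their own order and
aggregation, which provably satisfies the symmetry/idempotency/monotonicity
properties the entropy construction needs. Every branch is pluggable.

**Strictness is the asymmetric part.** `a < b` means `a ≤ b` and *not*
`b ≤ a`. For ≤₂ and ≤ₙₑ𝒸 this coincides with "≤ and not equal". For the
possible relation it is a deliberate choice with three consequences:

1. overlapping distinct intervals fall through to the graded else-branch
   instead of saturating both directions at `[1, 1]` — in particular a
   missing answer (`[0, 1]`) *reduces* similarity instead of counting as
   perfect agreement, which is what a screening instrument needs;
2. the possible entropy gets the closed elementwise form
   `E_pos([l, u]) = [min(l, 1 − u), 1]` (off the equal branch), i.e. the
   lower endpoint measures distance from crispness — a sensible fuzziness
   index;
3. the monotonicity axiom of the possible entropy holds on all continuously
   sampled chains. Under the alternative "≤ and not equal" reading the axiom
   fails outright at crisp boundaries (e.g. `A = [0, 0.8] ≤ₚₒₛ B = [0, 0]
   ≤ₚₒₛ e` would force `E(A) = [1, 1] ≰ₚₒₛ E(B) = [0, 0]`).

**Crisp vs degenerate.** The zero-entropy class is *classical* memberships
(`{[0,0], [1,1]}`), not all degenerate intervals: the degenerate equilibrium
`[0.5, 0.5]` must carry maximal entropy, so degeneracy alone cannot define
crispness. `Interval.is_degenerate` keeps the weaker sense for other uses.

**What the axiom suite establishes.** `axiom_suite` replays the entropy
axioms as seeded sampling: exact zero on random classical sets, the
equilibrium value `[1 − w(e), 1]`, order-monotonicity on random membership
chains toward the equilibrium, and negation stability (required for the
standard family; observed, and reported, for the other two under the standard
negation). Continuous sampling never hits the measure-zero crisp boundary
where the possible-family monotonicity axiom degenerates; a green suite
therefore certifies the axioms on the open region, not at the boundary.
Equality checks use `1e-9` slack for the arithmetic identities and exact
comparison for the classical-zero axiom (whose arithmetic is exact).

## Classifier

Pipeline per query: fuzzify → similarity to each training record over the 20
risk items → per class, rank candidates under the configured order, take the
top `k` (default 5), pick the minimal-entropy member as class representative →
decide from the representatives' similarity intervals `d0`, `d1` → apply the
verification override.

**Ranking is fully deterministic.** Top-`k` selection is repeated linear-scan
argmax under the comparator "strictly greater under the order, else smaller
interval width, else earlier training position", scanning in training order;
representative selection uses the mirrored comparator on entropies. With
partial regimes no scalar sort key exists, so the scan rule *is* the
definition; the brute-force oracle in the test suite re-implements it
independently and the pipeline matches it on hundreds of random toy datasets
for all four orders and both neighbor strategies.

**Neighbor strategies.** The narrative admits two readings of "k most
similar": per decision class (`per_class_k`, default) or one global top-`k`
then per-class selection (`global_k`). Both are implemented and tested.

**Decision cascade.** (i) a lone class wins; (ii) strict order between `d1`
and `d0` decides; (iii) the unique class at-or-above the neutral `[0.5, 0.5]`
while the other is below wins; (iv) narrower evidence wins; (v) abstain.
Abstentions survive verification as abstentions and are penalised in the
confusion counts (FN on positives, FP on negatives) — dropping them would
inflate every metric.

**Verification override.** A *known* (degenerate) answer `< 2` on either
reverse-keyed item flips a 0/abstention outcome to 1; missing verification
answers never trigger; a positive label is never changed.

## Synthetic cohort

The generator emulates the reference screening cohort profile: 750 records,
exactly 249 positive (class counts are pinned by construction, not Bernoulli
draws), ~5% missing cells uniformly at random. Each subject draws a latent
severity `s ~ Normal(1.2 + 1.5·class, 0.6)` on the 0–4 answer scale; risk
items are `clip(round(s + Normal(0, 0.7)))`, verification items use `4 − s`
(reverse-keyed). The base level, spreads and the 1.5 effect size were chosen
once so that a naive mean-score threshold reaches ≈0.85–0.9 accuracy —
the regime of the real instrument — and are not tuned thereafter.

Not emulated: item-specific difficulties/loadings, response styles,
informative missingness (missingness is MCAR here), test–retest dynamics, and
any psychometric structure of the real questionnaire. A green end-to-end test
certifies the algorithmic pipeline on this stated world, not clinical
validity.

## Splits and federation

* **Holdout 70/30** and **stratified 10-fold** are per-class deterministic
  samplers (class fractions preserved to ±1 record).
* **NON-IID 3 clients**: a class-balanced 15% test pool is removed first
  (112 = 56+56 records at defaults); the remainder is split into equal-size
  clients with class mixes 50/50, 80/20, 20/80. With the cohort's 2:1 class
  ratio an *exhaustive* partition with these mixes would force grotesquely
  unequal client sizes, so the splitter takes the largest feasible equal-size
  subsample (128 records per client at defaults) and returns the surplus
  majority-class records in an explicit `unused` pool; the disjointness
  contract covers `{test pool, clients, unused}`.
* **Federated vote**: plurality over non-abstaining client labels; exact ties
  go to the label backed by the overall minimal representative entropy
  (compared under the configured order, then interval midpoint, then client
  index); all-abstain federates to abstain.
* **Decision Rule**: a client adopts the federated predictions iff its local
  efficiency (default ACC; SENS/SPEC/PREC selectable) on the shared pool is
  strictly below the federation's. Post-rule efficiency is therefore exactly
  `max(local, federated)` — asserted by recomputation in the tests. The gate
  is evaluated on the shared balanced pool, the only common evaluation set
  available.
* The interaction of cross-validation with the fixed NON-IID design is
  resolved as `repetitions` independently reseeded splits (default 10) with
  mean ± sd reporting; scenario 1 additionally supports a stratified 10-fold
  plan.

## Known limitations

* The standard/necessary similarity constructions are a principled skeleton
  re-instantiation, not a transcription of unpublished formulas; results for
  those families should be read as "a measure of this class", with every
  branch configurable.
* The `decision_rule_best` row reports the best post-rule client; reference
  result tables of this design are ambiguous about what their Decision-Rule
  row aggregates, so per-client post-rule rows are always reported alongside.
* No imputation: missing answers stay `[0, 1]` by design.
* Headline numbers from the real 750-respondent cohort are not reproducible
  here (the data is external); the package reproduces the *qualitative*
  finding — federation lifts the skewed clients without harming the strong
  one — on the synthetic cohort.
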