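# ivfed

Interval-valued fuzzy calculus for depression-risk screening with federated,
privacy-preserving decision-making.

## The problem

Screening questionnaires produce imperfect data: respondents skip items,
answers are coarse Likert grades, and individual clinics hold small,
class-imbalanced (NON-IID) datasets they cannot pool for privacy reasons.
`ivfed` addresses both imperfections at once:

* **uncertainty** is carried explicitly as intervals — a fuzzified answer `a`
  on the 0–4 scale becomes the degenerate interval `[a/4, a/4]`, a missing
  answer the vacuous interval `[0, 1]` — and every downstream quantity
  (similarity, entropy, class evidence) stays interval-valued;
* **data fragmentation** is handled by a federated decision layer: clinics
  exchange only local *decisions*, which are combined by plurality voting with
  an entropy tie-break and gated by a Decision Rule so that no clinic's
  accuracy on a shared evaluation pool ever degrades.

The intended users are biostatisticians and ML researchers studying
reject-option classifiers on epistemic-uncertainty data, and anyone who wants
a clean, tested reference implementation of interval orders, order-consistent
aggregations and interval-valued entropies.

## The calculus

Intervals live in `L^I = {[l, u] : 0 ≤ l ≤ u ≤ 1}` and can be compared four
ways: the componentwise partial order `a ≤₂ b ⇔ a_l ≤ b_l ∧ a_u ≤ b_u`, an
admissible (total, lexicographic) refinement of it, the epistemic *possible*
relation `a ≤ₚₒₛ b ⇔ a_l ≤ b_u`, and the *necessary* relation
`a ≤ₙₑ𝒸 b ⇔ a_u ≤ b_l`.  Matching each regime there are aggregation functions
(`A_mean`, `A_pos`, `A_nec`), three-branch precedence indicators, symmetric
similarity measures `S(A, B)` over interval-valued fuzzy sets, and — the core
quantity — an **interval entropy**

```
E(A) = S(A, A^N),        N([l, u]) = [1 − u, 1 − l],
```

the similarity of a set to its own negation.  `E` is `[0, 0]` exactly on
classical sets, `[1, 1]` at the constant equilibrium map `x ↦ [0.5, 0.5]`,
and increases toward the equilibrium under the family's order.

The classifier (an interval kNN) ranks training records by interval
similarity, picks within the top `k` of each class the record with the
*lowest entropy* (least uncertain evidence), and decides from the two class
evidence intervals `d0`, `d1` by a cascade: strict order, position relative
to the neutral point `[0.5, 0.5]`, interval width — abstaining
(`NoDecision`) when nothing separates them.  Two reverse-keyed verification
items can override a non-depression outcome.  Abstentions are penalised in
all reported metrics.

## Worked example

```python
from ivfed import ClassifierConfig, generate_synthetic, run_scenario

cohort = generate_synthetic(seed=1)        # 750 records, 249 positive, ~5% missing
result = run_scenario("s3", cohort, ClassifierConfig(), repetitions=5, seed=1)
print(result["summary"]["ACC"])
```

which prints (means over 5 NON-IID repetitions, shared 112-record balanced
test pool):

```
                        mean       std
row
client1             0.807143  0.034349
client2             0.839286  0.033999
client3             0.780357  0.016220
federated           0.850000  0.031819
post_client1        0.850000  0.031819
post_client2        0.853571  0.031314
post_client3        0.850000  0.031819
decision_rule_best  0.853571  0.031314
```

Clients 1–3 are the local models (balanced, 80% class-0-skewed and 80%
class-1-skewed training sets); `federated` is the plurality vote; the
`post_client*` rows show each client after the accuracy-gated Decision Rule —
every client ends at `max(local, federated)` accuracy, so the skewed clients
improve and the strong client is never harmed.

The same is available from the shell:

```bash
ivfed scenario --which s3 --reps 5 --seed 1 --out-dir out/
ivfed generate --n 750 --seed 1 --out cohort.csv
ivfed predict --train cohort.csv --input queries.csv --out preds.csv
ivfed axioms --family possible --trials 1000 --seed 1
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the package's analytic targets (the entropy of a
classical 10-element IVFS in all three families and the upper entropy
endpoint of the constant equilibrium map) and the synthetic cohort profile
(record and positive-decision counts at default generator settings), writing
one JSON object with a value per target.

## Layout

- `src/ivfed/intervals.py` — `Interval`, the four comparison regimes, negations
- `src/ivfed/aggregation.py` — order-consistent aggregation families
- `src/ivfed/comparability.py` — Moore distance, precedence, similarity
- `src/ivfed/entropy.py` — interval entropies and the sampled axiom suite
- `src/ivfed/data.py` — questionnaire I/O, fuzzification, generator, splits
- `src/ivfed/knn.py` — the interval kNN pipeline
- `src/ivfed/federation.py` — voting, Decision Rule, scenario harness
- `docs/methods.md` — model assumptions, numerical choices, limitations
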