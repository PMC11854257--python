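"""Interval kNN: similarity, representative selection, the decision cascade,
verification override, and equivalence with the brute-force oracle."""

import numpy as np
import pytest

from ivfed import (
    ClassifierConfig,
    Interval,
    NO_DECISION,
    ONE,
    OrderSpec,
    PARTIAL2,
    QuestionnaireRecord,
    ZERO,
    classify_intervals,
    fuzzify,
    nearest_by_class,
    object_similarity,
    predict,
    predict_many,
    verify_decision,
)
from ivfed import _vector
from ivfed.knn import Prediction

from ._oracle import o_ent, o_predict, o_sim
from .conftest import assert_interval


def rec(answers, dec=0, id=0):
    return QuestionnaireRecord(id, tuple(answers), dec)


def full(value, dec=0, id=0):
    return rec([value] * 22, dec, id)


class TestObjectSimilarity:
    def test_identical_complete_records(self):
        y = full(3)
        assert object_similarity(y, y) == ONE

    def test_crisp_opposites(self):
        assert object_similarity(full(4), full(0)) == ZERO

    def test_one_missing_slot_drops_lower_endpoint(self):
        y = full(2)
        xa = [2] * 22
        xa[5] = None
        # the [0,1] slot contributes a [0.25, 1] pair value under the mean
        out = object_similarity(y, rec(xa))
        assert_interval(out, (19 + 0.25) / 20, 1.0)

    @pytest.mark.parametrize("family", ["standard", "possible", "necessary"])
    def test_matches_batch_path(self, family):
        rng = np.random.default_rng(12)
        config = ClassifierConfig(family=family)
        records = []
        for i in range(12):
            answers = [int(a) if a >= 0 else None
                       for a in rng.integers(-1, 5, size=22)]
            records.append(rec(answers, int(rng.integers(0, 2)), i))
        f = [fuzzify(r) for r in records]
        packed = _vector.pack(f, config.condition_attributes)
        sims = _vector.batch_similarity(packed[0], packed, family)
        ents = _vector.batch_entropy(packed, family)
        for i in range(len(records)):
            scalar = object_similarity(f[0], f[i], config)
            assert sims[i, 0] == pytest.approx(scalar.lo, abs=1e-12)
            assert sims[i, 1] == pytest.approx(scalar.hi, abs=1e-12)
            o = o_sim([tuple(m) for m in packed[0]], [tuple(m) for m in packed[i]], family)
            assert sims[i, 0] == pytest.approx(o[0], abs=1e-12)
            oe = o_ent([tuple(m) for m in packed[i]], family)
            assert ents[i, 0] == pytest.approx(oe[0], abs=1e-12)
            assert ents[i, 1] == pytest.approx(oe[1], abs=1e-12)

    def test_missing_degrades_lower_endpoint(self):
        """Masking an answer of x never raises similarity's lower endpoint."""
        rng = np.random.default_rng(21)
        config = ClassifierConfig()
        for _ in range(150):
            ya = [int(a) for a in rng.integers(0, 5, size=22)]
            xa = [int(a) for a in rng.integers(0, 5, size=22)]
            j = int(rng.integers(0, 20))
            masked = list(xa)
            masked[j] = None
            before = object_similarity(rec(ya), rec(xa), config)
            after = object_similarity(rec(ya), rec(masked), config)
            assert after.lo <= before.lo + 1e-12


class TestNearestByClass:
    def test_exact_duplicate_is_representative(self):
        y = full(4, id=99)
        train = [
            full(4, dec=0, id=0),        # duplicate of y, classical answers
            full(2, dec=0, id=1),
            full(1, dec=1, id=2),
        ]
        reps = nearest_by_class(y, train, ClassifierConfig(k=2))
        assert reps[0].record.id == 0
        assert reps[0].similarity == ONE

    def test_lower_entropy_wins_among_equally_similar(self):
        # two class-1 neighbors equally similar to y; the classical one
        # (entropy [0,0]) must be selected over the one with missing answers
        y = full(2, id=9)
        crisp = [0, 4] * 10 + [2, 2]
        vague = [0, 4] * 10 + [2, 2]
        vague[0] = None
        t1 = rec(crisp, dec=1, id=0)
        t2 = rec(vague, dec=1, id=1)
        config = ClassifierConfig(family="standard", order=PARTIAL2, k=5)
        for train in ([t1, t2], [t2, t1]):
            reps = nearest_by_class(y, train, config)
            assert reps[1].record.id == 0
            assert reps[1].entropy == ZERO

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            nearest_by_class(full(1), [], ClassifierConfig())


class TestClassifyIntervals:
    CFG = ClassifierConfig(order=PARTIAL2)

    def test_strict_dominance(self):
        assert classify_intervals(Interval(0.3, 0.4), Interval(0.8, 0.9), self.CFG).label == 1
        # d1 <2 d0 strictly
        assert classify_intervals(Interval(0.55, 0.6), Interval(0.4, 0.6), self.CFG).label == 0

    def test_equal_evidence_abstains(self):
        d = Interval(0.4, 0.6)
        assert classify_intervals(d, d, self.CFG).label == NO_DECISION

    def test_neutral_split(self):
        # incomparable under <=2 but on opposite sides of [0.5, 0.5]
        p = classify_intervals(Interval(0.1, 0.45), Interval(0.55, 0.8), self.CFG)
        assert p.label == 1

    def test_width_tie_break(self):
        # same midpoint side, incomparable, narrower d0 wins
        p = classify_intervals(Interval(0.58, 0.62), Interval(0.52, 0.70), self.CFG)
        assert p.label == 0

    def test_single_class(self):
        assert classify_intervals(None, Interval(0.2, 0.3), self.CFG).label == 1
        assert classify_intervals(Interval(0.2, 0.3), None, self.CFG).label == 0
        with pytest.raises(ValueError):
            classify_intervals(None, None, self.CFG)


class TestVerifyDecision:
    def test_low_verification_answer_fires(self):
        answers = [0] * 20 + [1, 3]
        p = verify_decision(rec(answers), Prediction(label=0))
        assert p.label == 1 and p.verification_fired

    def test_high_verification_answers_pass(self):
        answers = [0] * 20 + [3, 4]
        p = verify_decision(rec(answers), Prediction(label=0))
        assert p.label == 0 and not p.verification_fired

    def test_label_one_unchanged(self):
        answers = [0] * 20 + [0, 0]
        p = verify_decision(rec(answers), Prediction(label=1))
        assert p.label == 1 and not p.verification_fired

    def test_missing_verification_never_triggers(self):
        answers = [0] * 20 + [None, None]
        p = verify_decision(rec(answers), Prediction(label=0))
        assert p.label == 0 and not p.verification_fired

    def test_abstention_can_be_overridden(self):
        answers = [0] * 20 + [0, 4]
        p = verify_decision(rec(answers), Prediction(label=NO_DECISION))
        assert p.label == 1 and p.verification_fired


class TestPredict:
    def test_duplicate_positive_dominates(self):
        y = full(3, id=50)
        train = [full(3, dec=1, id=0), full(0, dec=0, id=1)]
        p = predict(y, train, ClassifierConfig(k=1))
        assert p.label == 1
        assert p.d1 == ONE

    def test_all_missing_query_abstains_on_symmetric_train(self):
        y = rec([None] * 22, id=5)
        train = [full(2, dec=0, id=0), full(2, dec=1, id=1)]
        p = predict(y, train, ClassifierConfig())
        assert p.label == NO_DECISION
        assert not p.verification_fired

    def test_determinism(self):
        rng = np.random.default_rng(4)
        train = [rec([int(a) for a in rng.integers(0, 5, 22)], int(rng.integers(0, 2)), i)
                 for i in range(10)]
        y = rec([int(a) for a in rng.integers(0, 5, 22)], id=99)
        cfg = ClassifierConfig()
        assert predict(y, train, cfg) == predict(y, train, cfg)

    def test_predict_many_matches_predict(self):
        rng = np.random.default_rng(8)
        train = [rec([int(a) for a in rng.integers(0, 5, 22)], int(rng.integers(0, 2)), i)
                 for i in range(15)]
        queries = [rec([int(a) for a in rng.integers(0, 5, 22)], 0, 100 + i)
                   for i in range(5)]
        cfg = ClassifierConfig(family="necessary", order=OrderSpec.possible())
        assert predict_many(queries, train, cfg) == [predict(q, train, cfg) for q in queries]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="k must"):
            ClassifierConfig(k=0)
        with pytest.raises(ValueError, match="verification"):
            ClassifierConfig(condition_attributes=(0, 1, 20))
        with pytest.raises(ValueError, match="strategy"):
            ClassifierConfig(neighbor_strategy="radius")


ORDERS = {
    "partial2": OrderSpec.partial2(),
    "admissible": OrderSpec.admissible(),
    "possible": OrderSpec.possible(),
    "necessary": OrderSpec.necessary(),
}


def _toy_dataset(rng):
    n_train = int(rng.integers(2, 9))
    train = []
    for i in range(n_train):
        answers = [int(a) if a >= 0 else None for a in rng.integers(-1, 5, size=22)]
        train.append((answers, int(rng.integers(0, 2))))
    query = [int(a) if a >= 0 else None for a in rng.integers(-1, 5, size=22)]
    return query, train


class TestOracleEquivalence:
    @pytest.mark.parametrize("order_name", list(ORDERS))
    @pytest.mark.parametrize("strategy", ["per_class_k", "global_k"])
    def test_predict_matches_brute_force(self, order_name, strategy):
        """Pipeline equals independent enumeration on random toy datasets."""
        seed = list(ORDERS).index(order_name) * 2 + (strategy == "global_k")
        rng = np.random.default_rng(seed)
        families = ("standard", "possible", "necessary")
        attrs = (0, 1, 2, 3)
        for case in range(50):
            family = families[case % 3]
            k = int(rng.integers(1, 5))
            query, train = _toy_dataset(rng)
            config = ClassifierConfig(k=k, family=family, order=ORDERS[order_name],
                                      condition_attributes=attrs,
                                      neighbor_strategy=strategy)
            y = rec(query, id=999)
            train_recs = [rec(a, d, i) for i, (a, d) in enumerate(train)]
            got = predict(y, train_recs, config)
            label, d0, d1, fired = o_predict(query, train, order_name, family,
                                             strategy, k, attrs)
            assert got.label == label, (case, family, k)
            assert got.verification_fired == fired
            assert (got.d0 is None) == (d0 is None)
            assert (got.d1 is None) == (d1 is None)
            if d0 is not None:
                assert got.d0.lo == pytest.approx(d0[0], abs=1e-12)
                assert got.d0.hi == pytest.approx(d0[1], abs=1e-12)
            if d1 is not None:
                assert got.d1.lo == pytest.approx(d1[0], abs=1e-12)
                assert got.d1.hi == pytest.approx(d1[1], abs=1e-12)
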