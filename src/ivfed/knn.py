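"""Interval kNN with entropy-based representative selection.

The classifier compares a query record with every training record through an
interval-valued similarity measure over the 20 risk items, ranks each decision
class's candidates under a configurable comparison regime, and within the top
``k`` picks the *least uncertain* candidate — the one with minimal object
entropy.  The two class representatives yield evidence intervals ``d0`` and
``d1``; a rule cascade against the neutral point ``[0.5, 0.5]`` produces a
label or an explicit abstention (``NoDecision``).  Finally the two
reverse-keyed verification items may override a non-depression outcome.

Ranking is deterministic: the top-``k`` are chosen by repeated linear-scan
selection of the maximum under the comparator "greater under the configured
order, else smaller similarity width, else earlier training position",
scanning in training order.  The same tie-break (with "less" for entropies)
picks the representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from . import _vector
from .comparability import SimilaritySpec, similarity
from .data import (
    FuzzifiedRecord,
    N_BASIC,
    QuestionnaireRecord,
    VERIFICATION_ATTRIBUTES,
    fuzzify,
)
from .entropy import EntropySpec, object_entropy
from .intervals import (
    ADMISSIBLE,
    Comparison,
    DEFAULT_ATOL,
    Interval,
    NEUTRAL,
    OrderSpec,
    compare,
)

__all__ = [
    "NO_DECISION",
    "ClassifierConfig",
    "Prediction",
    "Representative",
    "object_similarity",
    "nearest_by_class",
    "classify_intervals",
    "verify_decision",
    "predict",
    "predict_many",
]

#: Abstention label.
NO_DECISION = "ND"

NEIGHBOR_STRATEGIES = ("per_class_k", "global_k")


@dataclass(frozen=True)
class ClassifierConfig:
    """kNN configuration; measure families default to the possible class.

    ``condition_attributes`` are the items entering similarity and entropy
    (default: the 20 risk items); the verification items are reserved for the
    override stage and may not appear here.
    """

    k: int = 5
    family: str = "possible"
    order: OrderSpec = ADMISSIBLE
    similarity: SimilaritySpec = None  # type: ignore[assignment]
    entropy: EntropySpec = None  # type: ignore[assignment]
    condition_attributes: Tuple[int, ...] = tuple(range(N_BASIC))
    neighbor_strategy: str = "per_class_k"
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.neighbor_strategy not in NEIGHBOR_STRATEGIES:
            raise ValueError(f"unknown neighbor strategy {self.neighbor_strategy!r}")
        if not self.condition_attributes:
            raise ValueError("condition_attributes must be non-empty")
        overlap = set(self.condition_attributes) & set(VERIFICATION_ATTRIBUTES)
        if overlap:
            raise ValueError(
                f"condition attributes may not include verification attributes {sorted(overlap)}"
            )
        if self.similarity is None:
            object.__setattr__(self, "similarity", SimilaritySpec.for_family(self.family))
        if self.entropy is None:
            object.__setattr__(self, "entropy", EntropySpec.for_family(self.family))

    @classmethod
    def for_family(cls, family: str, **kwargs) -> "ClassifierConfig":
        return cls(family=family, **kwargs)


class Representative(NamedTuple):
    record: FuzzifiedRecord
    similarity: Interval
    entropy: Interval


@dataclass(frozen=True)
class Prediction:
    """A label in ``{0, 1, NO_DECISION}`` plus its interval evidence."""

    label: Union[int, str]
    d0: Optional[Interval] = None
    d1: Optional[Interval] = None
    entropy0: Optional[Interval] = None
    entropy1: Optional[Interval] = None
    verification_fired: bool = False
    id: Optional[Union[int, str]] = None

    def representative_entropy(self) -> Optional[Interval]:
        """Entropy evidence backing the predicted label (None for abstention)."""
        if self.label == 1:
            return self.entropy1
        if self.label == 0:
            return self.entropy0
        return None


def _as_fuzzified(record) -> FuzzifiedRecord:
    if isinstance(record, QuestionnaireRecord):
        return fuzzify(record)
    return record


def object_similarity(y, x, config: ClassifierConfig = ClassifierConfig()) -> Interval:
    """Similarity of two records' condition-attribute IVFSs."""
    fy = _as_fuzzified(y)
    fx = _as_fuzzified(x)
    attrs = config.condition_attributes
    return similarity([fy.memberships[i] for i in attrs],
                      [fx.memberships[i] for i in attrs], config.similarity)


def _ranks_above(sa: Interval, sb: Interval, pa: int, pb: int,
                 order: OrderSpec, atol: float) -> bool:
    """True if candidate a outranks candidate b (higher similarity)."""
    c = compare(sa, sb, order)
    if c is Comparison.GREATER:
        return True
    if c is Comparison.LESS:
        return False
    if sa.width < sb.width - atol:
        return True
    if sb.width < sa.width - atol:
        return False
    return pa < pb


def _entropy_below(ea: Interval, eb: Interval, pa: int, pb: int,
                   order: OrderSpec, atol: float) -> bool:
    """True if candidate a has lower uncertainty than candidate b."""
    c = compare(ea, eb, order)
    if c is Comparison.LESS:
        return True
    if c is Comparison.GREATER:
        return False
    if ea.width < eb.width - atol:
        return True
    if eb.width < ea.width - atol:
        return False
    return pa < pb


def _top_k(positions: List[int], sims: List[Interval], k: int,
           order: OrderSpec, atol: float) -> List[int]:
    remaining = list(positions)
    chosen: List[int] = []
    for _ in range(min(k, len(remaining))):
        best = remaining[0]
        for cand in remaining[1:]:
            if _ranks_above(sims[cand], sims[best], cand, best, order, atol):
                best = cand
        chosen.append(best)
        remaining.remove(best)
    return chosen


def _prepare_train(train: Sequence, config: ClassifierConfig):
    """Fuzzify the training set and precompute entropies (batch if possible)."""
    ftrain = [_as_fuzzified(r) for r in train]
    attrs = config.condition_attributes
    fast = _vector.supports(config.similarity, config.entropy)
    packed = _vector.pack(ftrain, attrs) if fast else None
    if fast:
        ent = _vector.batch_entropy(packed, config.family, config.atol)
        entropies = [Interval.clipped(ent[i, 0], ent[i, 1]) for i in range(len(ftrain))]
    else:
        entropies = [object_entropy(r, config.entropy, attrs) for r in ftrain]
    return ftrain, entropies, packed, fast


def _similarities_for(fy: FuzzifiedRecord, ftrain, packed, fast, config) -> List[Interval]:
    attrs = config.condition_attributes
    if fast:
        q = _vector.pack([fy], attrs)[0]
        s = _vector.batch_similarity(q, packed, config.family, config.atol)
        return [Interval.clipped(s[i, 0], s[i, 1]) for i in range(len(ftrain))]
    return [object_similarity(fy, x, config) for x in ftrain]


def _select_representatives(ftrain, sims, entropies, config) -> Dict[int, Representative]:
    order, atol, k = config.order, config.atol, config.k
    by_class: Dict[int, List[int]] = {}
    for pos, rec in enumerate(ftrain):
        by_class.setdefault(rec.decision, []).append(pos)

    reps: Dict[int, Representative] = {}
    if config.neighbor_strategy == "per_class_k":
        class_pools = {c: _top_k(positions, sims, k, order, atol)
                       for c, positions in by_class.items()}
    else:  # global_k: one shared top-k, then per class present among them
        top = _top_k(list(range(len(ftrain))), sims, k, order, atol)
        class_pools = {}
        for pos in top:
            class_pools.setdefault(ftrain[pos].decision, []).append(pos)

    for c, pool in class_pools.items():
        best = pool[0]
        for cand in pool[1:]:
            if _entropy_below(entropies[cand], entropies[best], cand, best, order, atol):
                best = cand
        reps[c] = Representative(record=ftrain[best], similarity=sims[best],
                                 entropy=entropies[best])
    return reps


def nearest_by_class(y, train: Sequence, config: ClassifierConfig = ClassifierConfig()
                     ) -> Dict[int, Representative]:
    """Per-class representative of the query's nearest neighbors.

    For each decision class, the class's candidates are ranked by similarity
    to ``y`` under ``config.order``; among the top ``k`` the member with
    minimal object entropy becomes the class representative and its similarity
    interval the class evidence (``per_class_k`` strategy).  ``global_k``
    takes one overall top-``k`` first.
    """
    if not train:
        raise ValueError("training set must be non-empty")
    fy = _as_fuzzified(y)
    ftrain, entropies, packed, fast = _prepare_train(train, config)
    sims = _similarities_for(fy, ftrain, packed, fast, config)
    return _select_representatives(ftrain, sims, entropies, config)


def classify_intervals(d0: Optional[Interval], d1: Optional[Interval],
                       config: ClassifierConfig = ClassifierConfig()) -> Prediction:
    """Turn per-class evidence intervals into a label or an abstention.

    Cascade: (i) a lone class wins; (ii) a strict order between ``d1`` and
    ``d0`` decides; (iii) the unique class at-or-above the neutral point
    ``[0.5, 0.5]`` while the other is below wins; (iv) the narrower evidence
    wins; (v) otherwise ``NoDecision``.
    """
    if d0 is None and d1 is None:
        raise ValueError("at least one evidence interval is required")
    if d0 is None:
        return Prediction(label=1, d1=d1)
    if d1 is None:
        return Prediction(label=0, d0=d0)
    order, atol = config.order, config.atol

    c = compare(d1, d0, order)
    if c is Comparison.GREATER:
        return Prediction(label=1, d0=d0, d1=d1)
    if c is Comparison.LESS:
        return Prediction(label=0, d0=d0, d1=d1)

    c1 = compare(d1, NEUTRAL, order)
    c0 = compare(d0, NEUTRAL, order)
    at_or_above = (Comparison.GREATER, Comparison.EQUAL)
    if c1 in at_or_above and c0 is Comparison.LESS:
        return Prediction(label=1, d0=d0, d1=d1)
    if c0 in at_or_above and c1 is Comparison.LESS:
        return Prediction(label=0, d0=d0, d1=d1)

    if d1.width < d0.width - atol:
        return Prediction(label=1, d0=d0, d1=d1)
    if d0.width < d1.width - atol:
        return Prediction(label=0, d0=d0, d1=d1)
    return Prediction(label=NO_DECISION, d0=d0, d1=d1)


def verify_decision(record, prediction: Prediction,
                    atol: float = DEFAULT_ATOL) -> Prediction:
    """Override a non-depression outcome using the verification items.

    A *known* (degenerate) verification answer below 2 on the raw 0-4 scale
    (membership below 0.5) signals a negative psychological situation: a label
    of 0 or an abstention is turned into 1.  Missing answers (``[0, 1]``)
    never trigger; label 1 always passes through unchanged.
    """
    if prediction.label == 1:
        return prediction
    fy = _as_fuzzified(record)
    for attr in VERIFICATION_ATTRIBUTES:
        m = fy.memberships[attr]
        if m.is_degenerate(atol) and m.hi < 0.5:
            return replace(prediction, label=1, verification_fired=True)
    return prediction


def predict(y, train: Sequence, config: ClassifierConfig = ClassifierConfig()) -> Prediction:
    """Full pipeline for a single query: fuzzify, select, classify, verify."""
    fy = _as_fuzzified(y)
    reps = nearest_by_class(fy, train, config)
    rep0 = reps.get(0)
    rep1 = reps.get(1)
    pred = classify_intervals(rep0.similarity if rep0 else None,
                              rep1.similarity if rep1 else None, config)
    pred = replace(pred,
                   entropy0=rep0.entropy if rep0 else None,
                   entropy1=rep1.entropy if rep1 else None,
                   id=fy.id)
    return verify_decision(fy, pred, config.atol)


def predict_many(queries: Sequence, train: Sequence,
                 config: ClassifierConfig = ClassifierConfig()) -> List[Prediction]:
    """Predict a batch of queries against one training set (shared precompute)."""
    if not train:
        raise ValueError("training set must be non-empty")
    ftrain, entropies, packed, fast = _prepare_train(train, config)
    out: List[Prediction] = []
    for y in queries:
        fy = _as_fuzzified(y)
        sims = _similarities_for(fy, ftrain, packed, fast, config)
        reps = _select_representatives(ftrain, sims, entropies, config)
        rep0 = reps.get(0)
        rep1 = reps.get(1)
        pred = classify_intervals(rep0.similarity if rep0 else None,
                                  rep1.similarity if rep1 else None, config)
        pred = replace(pred,
                       entropy0=rep0.entropy if rep0 else None,
                       entropy1=rep1.entropy if rep1 else None,
                       id=fy.id)
        out.append(verify_decision(fy, pred, config.atol))
    return out
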