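"""Distance, precedence indicators and similarity measures on ``L^I``.

An IVFS over a finite universe is represented either as a mapping
``element -> Interval`` or simply as a sequence of intervals (the universe is
then the index set).  Similarity of two IVFSs is built in three stages:

1. a *precedence indicator* ``Prec(a, b)`` — an interval-valued degree to
   which membership ``a`` precedes membership ``b``;
2. a symmetric *pairing* of the two directions, ``B(Prec(a,b), Prec(b,a))``
   (default: the lattice meet);
3. an *outer* aggregation over the universe (default: componentwise mean).

Each precedence family (standard / possible / necessary) shares the same
three-branch skeleton, instantiated with the family's comparison regime and
aggregation:

    Prec(a, b) = [1 - w(a), 1]        if a = b
               = 1_LI                 if a <  b  (strictly, under the regime)
               = A_fam(N(a), b)       otherwise

Strictness is the asymmetric part of the regime (``a <= b`` and not
``b <= a``).  For the possible relation this excludes overlapping pairs, so
overlap is graded by the else-branch rather than saturating — missing-data
intervals ``[0, 1]`` therefore reduce, not inflate, similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Sequence, Tuple, Union

from .aggregation import AggregationSpec, aggregate
from .intervals import (
    DEFAULT_ATOL,
    Interval,
    NegationSpec,
    ONE,
    OrderSpec,
    STANDARD_NEGATION,
    intervals_equal,
    leq,
    negate,
)

__all__ = [
    "moore_distance",
    "PrecedenceSpec",
    "precedence",
    "SimilaritySpec",
    "similarity",
    "aligned_memberships",
]

PRECEDENCE_FAMILIES = ("standard", "possible", "necessary")

#: Comparison regime used by each precedence family.
_FAMILY_ORDER = {
    "standard": OrderSpec.partial2(),
    "possible": OrderSpec.possible(),
    "necessary": OrderSpec.necessary(),
}

#: Else-branch aggregation used by each precedence family.
_FAMILY_AGG = {
    "standard": AggregationSpec.mean(),
    "possible": AggregationSpec.pos(),
    "necessary": AggregationSpec.nec(),
}

IVFSLike = Union[Mapping[object, Interval], Sequence[Interval]]


def moore_distance(a: Interval, b: Interval) -> float:
    """Moore (Chebyshev) distance ``max(|a.lo - b.lo|, |a.hi - b.hi|)``."""
    return max(abs(a.lo - b.lo), abs(a.hi - b.hi))


@dataclass(frozen=True)
class PrecedenceSpec:
    family: str = "possible"
    negation: NegationSpec = STANDARD_NEGATION
    aggregation: AggregationSpec = None  # type: ignore[assignment]
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        if self.family not in PRECEDENCE_FAMILIES:
            raise ValueError(
                f"unknown precedence family {self.family!r}; expected one of {PRECEDENCE_FAMILIES}"
            )
        if self.aggregation is None:
            object.__setattr__(self, "aggregation", _FAMILY_AGG[self.family])

    @classmethod
    def for_family(cls, family: str, negation: NegationSpec = None) -> "PrecedenceSpec":
        return cls(family=family, negation=negation or NegationSpec.for_family(
            family if family != "standard" else "standard"))

    @property
    def order(self) -> OrderSpec:
        return _FAMILY_ORDER[self.family]


def precedence(a: Interval, b: Interval, spec: PrecedenceSpec = PrecedenceSpec()) -> Interval:
    """Interval-valued degree to which ``a`` precedes ``b``."""
    if intervals_equal(a, b, spec.atol):
        return Interval.clipped(1.0 - a.width, 1.0)
    order = spec.order
    if leq(a, b, order) and not leq(b, a, order):
        return ONE
    return aggregate([negate(a, spec.negation), b], spec.aggregation)


@dataclass(frozen=True)
class SimilaritySpec:
    """Configuration of an IVFS similarity measure.

    ``outer`` aggregates per-element pair values over the universe and
    ``pairer`` combines the two precedence directions; the printed defaults
    are the componentwise mean and the lattice meet, which make the measure
    symmetric and idempotent-friendly.
    """

    family: str = "possible"
    precedence: PrecedenceSpec = None  # type: ignore[assignment]
    outer: AggregationSpec = field(default_factory=AggregationSpec.mean)
    pairer: AggregationSpec = field(default_factory=AggregationSpec.meet)

    def __post_init__(self) -> None:
        if self.family not in PRECEDENCE_FAMILIES:
            raise ValueError(
                f"unknown similarity family {self.family!r}; expected one of {PRECEDENCE_FAMILIES}"
            )
        if self.precedence is None:
            object.__setattr__(self, "precedence", PrecedenceSpec(family=self.family))

    @classmethod
    def for_family(cls, family: str) -> "SimilaritySpec":
        return cls(family=family)


def aligned_memberships(A: IVFSLike, B: IVFSLike) -> Tuple[List[Interval], List[Interval]]:
    """Align two IVFSs over the same universe; error on mismatch."""
    if isinstance(A, Mapping) and isinstance(B, Mapping):
        if set(A.keys()) != set(B.keys()):
            raise ValueError("IVFSs are defined over different universes")
        keys = list(A.keys())
        return [A[k] for k in keys], [B[k] for k in keys]
    a = list(A.values()) if isinstance(A, Mapping) else list(A)
    b = list(B.values()) if isinstance(B, Mapping) else list(B)
    if len(a) != len(b):
        raise ValueError(
            f"IVFSs are defined over different universes (sizes {len(a)} and {len(b)})"
        )
    return a, b


def similarity(A: IVFSLike, B: IVFSLike, spec: SimilaritySpec = SimilaritySpec()) -> Interval:
    """Interval-valued similarity of two IVFSs over a shared universe."""
    mem_a, mem_b = aligned_memberships(A, B)
    if not mem_a:
        raise ValueError("similarity requires a non-empty universe")
    pairs = [
        aggregate([precedence(ai, bi, spec.precedence), precedence(bi, ai, spec.precedence)],
                  spec.pairer)
        for ai, bi in zip(mem_a, mem_b)
    ]
    return aggregate(pairs, spec.outer)
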