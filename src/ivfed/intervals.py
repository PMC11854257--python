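"""Closed subintervals of the unit interval and the comparison regimes on them.

The value space is ``L^I = {[lo, hi] : 0 <= lo <= hi <= 1}``.  An interval is
read *epistemically*: it bounds a single unknown true membership degree.  Four
comparison regimes are supported:

``partial2``
    The componentwise lattice order: ``a <=2 b  iff  a.lo <= b.lo and
    a.hi <= b.hi``.  Partial — overlapping, non-nested pairs are incomparable.
``admissible``
    A linear refinement of ``partial2`` built lexicographically from two
    scalarisations ``psi`` and ``upsilon`` of ``(lo, hi)`` (default: midpoint,
    then upper endpoint).
``possible``
    ``a <=pos b  iff  a.lo <= b.hi`` — it is *possible* that the true value of
    ``a`` is below the true value of ``b``.  Strongly complete, not
    antisymmetric, not transitive.
``necessary``
    ``a <=nec b  iff  a.hi <= b.lo`` — *every* value of ``a`` is below every
    value of ``b``.  Antisymmetric, transitive, and Ferrers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Tuple

__all__ = [
    "DEFAULT_ATOL",
    "Interval",
    "Comparison",
    "OrderSpec",
    "NegationSpec",
    "PARTIAL2",
    "ADMISSIBLE",
    "POSSIBLE",
    "NECESSARY",
    "ZERO",
    "ONE",
    "NEUTRAL",
    "STANDARD_NEGATION",
    "standard_negation_map",
    "make_interval",
    "intervals_equal",
    "leq",
    "strictly_less",
    "compare",
    "negate",
    "join_meet",
]

#: Absolute tolerance used for floating-point equality of interval endpoints.
DEFAULT_ATOL = 1e-12

ORDER_KINDS = ("partial2", "admissible", "possible", "necessary")
NEGATION_FAMILIES = ("standard", "possible", "necessary")


@dataclass(frozen=True)
class Interval:
    """An element ``[lo, hi]`` of ``L^I``.

    Both endpoints must lie in ``[0, 1]`` with ``lo <= hi``.  Degenerate
    intervals (``lo == hi``) are valid and represent precisely known degrees.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        lo = float(self.lo)
        hi = float(self.hi)
        if math.isnan(lo) or not 0.0 <= lo <= 1.0:
            raise ValueError(f"lo={self.lo!r} outside [0, 1]")
        if math.isnan(hi) or not 0.0 <= hi <= 1.0:
            raise ValueError(f"hi={self.hi!r} outside [0, 1]")
        if lo > hi:
            raise ValueError(f"inverted endpoints: lo={lo!r} > hi={hi!r}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0

    def is_degenerate(self, atol: float = DEFAULT_ATOL) -> bool:
        return self.width <= atol

    def to_str(self) -> str:
        """Render as ``lo:hi`` with 17 significant digits (round-trip safe)."""
        return f"{self.lo:.17g}:{self.hi:.17g}"

    @classmethod
    def from_str(cls, text: str) -> "Interval":
        try:
            lo_s, hi_s = text.split(":")
        except ValueError as exc:
            raise ValueError(f"expected 'lo:hi', got {text!r}") from exc
        return cls(float(lo_s), float(hi_s))

    @classmethod
    def clipped(cls, lo: float, hi: float, eps: float = 1e-9) -> "Interval":
        """Construct after clamping small floating-point overshoot.

        Used on internally computed endpoints only; rejects genuine violations
        (overshoot beyond ``eps``).
        """
        lo = min(max(lo, 0.0), 1.0)
        hi = min(max(hi, 0.0), 1.0)
        if lo > hi:
            if lo - hi > eps:
                raise ValueError(f"inverted endpoints: lo={lo!r} > hi={hi!r}")
            lo = hi
        return cls(lo, hi)

    def __repr__(self) -> str:  # compact, notation-friendly
        return f"[{self.lo:g}, {self.hi:g}]"


ZERO = Interval(0.0, 0.0)
ONE = Interval(1.0, 1.0)
#: The neutral/equilibrium point of the standard negation.
NEUTRAL = Interval(0.5, 0.5)


def make_interval(lo: float, hi: float) -> Interval:
    """Validated constructor for :class:`Interval`."""
    return Interval(lo, hi)


def intervals_equal(a: Interval, b: Interval, atol: float = DEFAULT_ATOL) -> bool:
    return abs(a.lo - b.lo) <= atol and abs(a.hi - b.hi) <= atol


class Comparison(Enum):
    LESS = "less"
    EQUAL = "equal"
    GREATER = "greater"
    INCOMPARABLE = "incomparable"


def _midpoint(lo: float, hi: float) -> float:
    return (lo + hi) / 2.0


def _upper(lo: float, hi: float) -> float:
    return hi


@dataclass(frozen=True)
class OrderSpec:
    """One of the four comparison regimes.

    ``psi`` and ``upsilon`` are only consulted by the ``admissible`` kind; they
    must jointly separate points (equal ``psi`` *and* equal ``upsilon`` imply
    equal intervals), which holds for the default midpoint/upper pair.
    """

    kind: str = "partial2"
    psi: Callable[[float, float], float] = _midpoint
    upsilon: Callable[[float, float], float] = _upper
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        if self.kind not in ORDER_KINDS:
            raise ValueError(f"unknown order kind {self.kind!r}; expected one of {ORDER_KINDS}")

    @classmethod
    def partial2(cls) -> "OrderSpec":
        return cls(kind="partial2")

    @classmethod
    def admissible(cls, psi: Callable[[float, float], float] = _midpoint,
                   upsilon: Callable[[float, float], float] = _upper) -> "OrderSpec":
        return cls(kind="admissible", psi=psi, upsilon=upsilon)

    @classmethod
    def possible(cls) -> "OrderSpec":
        return cls(kind="possible")

    @classmethod
    def necessary(cls) -> "OrderSpec":
        return cls(kind="necessary")


PARTIAL2 = OrderSpec.partial2()
ADMISSIBLE = OrderSpec.admissible()
POSSIBLE = OrderSpec.possible()
NECESSARY = OrderSpec.necessary()


def leq(a: Interval, b: Interval, order: OrderSpec = PARTIAL2) -> bool:
    """``a <= b`` under the given comparison regime (with endpoint tolerance)."""
    tol = order.atol
    if order.kind == "partial2":
        return a.lo <= b.lo + tol and a.hi <= b.hi + tol
    if order.kind == "possible":
        return a.lo <= b.hi + tol
    if order.kind == "necessary":
        return a.hi <= b.lo + tol
    # admissible: lexicographic on (psi, upsilon)
    pa = order.psi(a.lo, a.hi)
    pb = order.psi(b.lo, b.hi)
    if pa < pb - tol:
        return True
    if pb < pa - tol:
        return False
    return order.upsilon(a.lo, a.hi) <= order.upsilon(b.lo, b.hi) + tol


def strictly_less(a: Interval, b: Interval, order: OrderSpec = PARTIAL2) -> bool:
    """The asymmetric part of the regime: ``a <= b`` and not ``b <= a``.

    For antisymmetric regimes this coincides with "``<=`` and not equal"; for
    the possible relation it excludes overlapping pairs (where both directions
    hold), which keeps precedence indicators informative on overlapping data.
    """
    return leq(a, b, order) and not leq(b, a, order)


def compare(a: Interval, b: Interval, order: OrderSpec = PARTIAL2) -> Comparison:
    """Three-way (or four-way, for partial regimes) comparison.

    Interval equality is decided first with absolute tolerance ``order.atol``.
    Under the possible relation a mutually-related pair (both directions hold)
    is mapped to ``EQUAL`` so that ranking code gets a deterministic outcome;
    ``admissible`` never returns ``INCOMPARABLE``.
    """
    if intervals_equal(a, b, order.atol):
        return Comparison.EQUAL
    ab = leq(a, b, order)
    ba = leq(b, a, order)
    if ab and ba:
        return Comparison.EQUAL
    if ab:
        return Comparison.LESS
    if ba:
        return Comparison.GREATER
    return Comparison.INCOMPARABLE


# ---------------------------------------------------------------------------
# Negations
# ---------------------------------------------------------------------------

def standard_negation_map(a: Interval) -> Interval:
    """The standard interval negation ``N([x, y]) = [1 - y, 1 - x]``."""
    return Interval(1.0 - a.hi, 1.0 - a.lo)


@dataclass(frozen=True)
class NegationSpec:
    """A strong (involutive, decreasing) interval negation.

    The printed possible/necessary negations are not available, so every family
    defaults to the standard negation, whose equilibrium is ``[0.5, 0.5]``.
    A user-supplied ``map`` must be involutive with the stated equilibrium.
    """

    family: str = "standard"
    map: Callable[[Interval], Interval] = standard_negation_map
    equilibrium: Interval = NEUTRAL

    def __post_init__(self) -> None:
        if self.family not in NEGATION_FAMILIES:
            raise ValueError(
                f"unknown negation family {self.family!r}; expected one of {NEGATION_FAMILIES}"
            )

    @classmethod
    def for_family(cls, family: str) -> "NegationSpec":
        return cls(family=family)

    @property
    def is_standard(self) -> bool:
        return self.map is standard_negation_map


STANDARD_NEGATION = NegationSpec()


def negate(a: Interval, neg: NegationSpec = STANDARD_NEGATION) -> Interval:
    return neg.map(a)


def join_meet(a: Interval, b: Interval) -> Tuple[Interval, Interval]:
    """Lattice join and meet: componentwise max / min of the endpoints."""
    join = Interval(max(a.lo, b.lo), max(a.hi, b.hi))
    meet = Interval(min(a.lo, b.lo), min(a.hi, b.hi))
    return join, meet
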