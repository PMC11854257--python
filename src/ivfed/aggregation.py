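"""Order-consistent interval aggregation functions.

Four families are provided, each increasing with respect to a matching
comparison regime and satisfying the boundary conditions
``A(0_LI, ..., 0_LI) = 0_LI`` and ``A(1_LI, ..., 1_LI) = 1_LI``:

* ``mean`` — componentwise arithmetic mean (monotone for ``partial2`` and the
  default admissible order);
* ``pos``  — ``[A(lo_1, lo_2), 1]`` unless both arguments are ``0_LI`` (then
  ``0_LI``), with ``A`` a scalar *inner* aggregation (default mean); monotone
  for the possible relation;
* ``nec``  — ``[(lo_1+lo_2)/2, max((lo_1+hi_2)/2, (hi_1+lo_2)/2)]``; monotone
  for the necessary relation;
* ``meet`` — the lattice meet (componentwise min), used as the pairing step of
  similarity measures.

The ``pos`` and ``nec`` forms are binary; n-ary application is a left fold,
which preserves the boundary conditions (``nec`` is not associative, so the
fold order is pinned left-to-right).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Union

import numpy as np

from .intervals import Interval, OrderSpec, ZERO, leq

__all__ = ["AggregationSpec", "aggregate", "check_monotonicity"]

AGGREGATION_FAMILIES = ("mean", "pos", "nec", "meet")

_INNER: Dict[str, Callable[[float, float], float]] = {
    "mean": lambda x, y: (x + y) / 2.0,
    "min": min,
    "max": max,
    "product": lambda x, y: x * y,
}


@dataclass(frozen=True)
class AggregationSpec:
    family: str = "mean"
    inner: Union[str, Callable[[float, float], float]] = "mean"

    def __post_init__(self) -> None:
        if self.family not in AGGREGATION_FAMILIES:
            raise ValueError(
                f"unknown aggregation family {self.family!r}; expected one of {AGGREGATION_FAMILIES}"
            )
        if isinstance(self.inner, str) and self.inner not in _INNER:
            raise ValueError(
                f"unknown inner aggregation {self.inner!r}; expected one of {tuple(_INNER)}"
            )

    def inner_fn(self) -> Callable[[float, float], float]:
        return _INNER[self.inner] if isinstance(self.inner, str) else self.inner

    @classmethod
    def mean(cls) -> "AggregationSpec":
        return cls(family="mean")

    @classmethod
    def pos(cls, inner: Union[str, Callable[[float, float], float]] = "mean") -> "AggregationSpec":
        return cls(family="pos", inner=inner)

    @classmethod
    def nec(cls) -> "AggregationSpec":
        return cls(family="nec")

    @classmethod
    def meet(cls) -> "AggregationSpec":
        return cls(family="meet")


def _pos_binary(a: Interval, b: Interval, inner: Callable[[float, float], float]) -> Interval:
    if a == ZERO and b == ZERO:
        return ZERO
    return Interval.clipped(inner(a.lo, b.lo), 1.0)


def _nec_binary(a: Interval, b: Interval) -> Interval:
    lo = (a.lo + b.lo) / 2.0
    hi = max((a.lo + b.hi) / 2.0, (a.hi + b.lo) / 2.0)
    return Interval.clipped(lo, hi)


def aggregate(values: Sequence[Interval], spec: AggregationSpec = AggregationSpec()) -> Interval:
    """Aggregate a non-empty sequence of intervals under ``spec``."""
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty sequence of intervals")
    if spec.family == "mean":
        lo = sum(v.lo for v in values) / len(values)
        hi = sum(v.hi for v in values) / len(values)
        return Interval.clipped(lo, hi)
    if spec.family == "meet":
        return Interval(min(v.lo for v in values), min(v.hi for v in values))
    if spec.family == "pos":
        inner = spec.inner_fn()
        acc = values[0]
        for v in values[1:]:
            acc = _pos_binary(acc, v, inner)
        return acc
    # nec
    acc = values[0]
    for v in values[1:]:
        acc = _nec_binary(acc, v)
    return acc


def _dominating(rng: np.random.Generator, a: Interval, kind: str) -> Interval:
    """Sample an interval ``b`` with ``a <= b`` under the given regime."""
    if kind in ("partial2", "admissible"):
        lo = rng.uniform(a.lo, 1.0)
        hi = rng.uniform(max(lo, a.hi), 1.0)
    elif kind == "possible":
        hi = rng.uniform(a.lo, 1.0)
        lo = rng.uniform(0.0, hi)
    elif kind == "necessary":
        lo = rng.uniform(a.hi, 1.0)
        hi = rng.uniform(lo, 1.0)
    else:  # pragma: no cover
        raise ValueError(kind)
    return Interval(lo, hi)


def check_monotonicity(spec: AggregationSpec, order: OrderSpec, trials: int = 1000,
                       seed: int = 0, arity: int = 3) -> dict:
    """Sampled monotonicity check of ``aggregate`` against a comparison regime.

    Draws ``trials`` pairs of componentwise order-related tuples and counts
    violations of ``zeta_i <= eta_i  =>  A(zeta) <= A(eta)``.  Matched
    family/order pairs (mean/partial2, pos/possible, nec/necessary) are
    expected to report zero violations.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(trials):
        zetas = []
        etas = []
        for _ in range(arity):
            lo = rng.uniform(0.0, 1.0)
            z = Interval(lo, rng.uniform(lo, 1.0))
            zetas.append(z)
            etas.append(_dominating(rng, z, order.kind))
        if not leq(aggregate(zetas, spec), aggregate(etas, spec), order):
            violations += 1
    return {
        "family": spec.family,
        "order": order.kind,
        "trials": trials,
        "violations": violations,
        "ok": violations == 0,
    }
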