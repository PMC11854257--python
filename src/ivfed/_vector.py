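"""Vectorised evaluation of the default similarity/entropy constructions.

The scalar path in :mod:`ivfed.comparability` / :mod:`ivfed.entropy` is the
reference implementation; this module replays the same three-branch precedence
skeleton on numpy arrays for the default configuration shape (standard
negation, mean outer aggregation, meet pairing, mean inner scalar).  The kNN
layer falls back to the scalar path for any other configuration.  Equivalence
of the two paths is asserted in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .intervals import DEFAULT_ATOL, standard_negation_map


def pack(records: Sequence, attributes: Sequence[int]) -> np.ndarray:
    """Stack fuzzified records into an ``(n, len(attributes), 2)`` array."""
    arr = np.empty((len(records), len(attributes), 2), dtype=float)
    for i, rec in enumerate(records):
        for j, a in enumerate(attributes):
            m = rec.memberships[a]
            arr[i, j, 0] = m.lo
            arr[i, j, 1] = m.hi
    return arr


def _prec(alo, ahi, blo, bhi, family: str, atol: float = DEFAULT_ATOL):
    """Elementwise precedence indicator; mirrors ``comparability.precedence``."""
    eq = (np.abs(alo - blo) <= atol) & (np.abs(ahi - bhi) <= atol)
    if family == "standard":
        ab = (alo <= blo + atol) & (ahi <= bhi + atol)
        ba = (blo <= alo + atol) & (bhi <= ahi + atol)
    elif family == "possible":
        ab = alo <= bhi + atol
        ba = blo <= ahi + atol
    else:  # necessary
        ab = ahi <= blo + atol
        ba = bhi <= alo + atol
    lt = ab & ~ba
    na_lo = 1.0 - ahi
    na_hi = 1.0 - alo
    if family == "standard":
        plo = (na_lo + blo) / 2.0
        phi = (na_hi + bhi) / 2.0
    elif family == "possible":
        zero = (na_lo == 0.0) & (na_hi == 0.0) & (blo == 0.0) & (bhi == 0.0)
        plo = np.where(zero, 0.0, (na_lo + blo) / 2.0)
        phi = np.where(zero, 0.0, 1.0)
    else:
        plo = (na_lo + blo) / 2.0
        phi = np.maximum((na_lo + bhi) / 2.0, (na_hi + blo) / 2.0)
    lo = np.where(eq, 1.0 - (ahi - alo), np.where(lt, 1.0, plo))
    hi = np.where(eq, 1.0, np.where(lt, 1.0, phi))
    return lo, hi


def _pairwise(alo, ahi, blo, bhi, family: str, atol: float):
    """meet(Prec(a,b), Prec(b,a)) then mean over the trailing attribute axis."""
    p1lo, p1hi = _prec(alo, ahi, blo, bhi, family, atol)
    p2lo, p2hi = _prec(blo, bhi, alo, ahi, family, atol)
    pair_lo = np.minimum(p1lo, p2lo)
    pair_hi = np.minimum(p1hi, p2hi)
    return np.clip(pair_lo.mean(axis=-1), 0.0, 1.0), np.clip(pair_hi.mean(axis=-1), 0.0, 1.0)


def batch_similarity(query: np.ndarray, train: np.ndarray, family: str,
                     atol: float = DEFAULT_ATOL) -> np.ndarray:
    """Similarity of one packed query ``(k, 2)`` against ``(n, k, 2)`` rows."""
    alo = query[None, :, 0]
    ahi = query[None, :, 1]
    blo = train[:, :, 0]
    bhi = train[:, :, 1]
    lo, hi = _pairwise(alo, ahi, blo, bhi, family, atol)
    return np.stack([lo, hi], axis=-1)


def batch_entropy(arr: np.ndarray, family: str, atol: float = DEFAULT_ATOL) -> np.ndarray:
    """Entropy ``S(A, A^N)`` of each packed record in ``(n, k, 2)``."""
    alo = arr[:, :, 0]
    ahi = arr[:, :, 1]
    lo, hi = _pairwise(alo, ahi, 1.0 - ahi, 1.0 - alo, family, atol)
    return np.stack([lo, hi], axis=-1)


def supports(similarity_spec, entropy_spec) -> bool:
    """True when both specs match the vectorisable default shape."""
    def sim_ok(spec):
        prec = spec.precedence
        inner_ok = prec.aggregation.inner == "mean" if prec.family == "possible" else True
        return (
            spec.outer.family == "mean"
            and spec.pairer.family == "meet"
            and prec.negation.map is standard_negation_map
            and prec.family == spec.family
            and prec.aggregation.family == {"standard": "mean", "possible": "pos",
                                            "necessary": "nec"}[prec.family]
            and inner_ok
        )

    return (
        sim_ok(similarity_spec)
        and sim_ok(entropy_spec.similarity)
        and entropy_spec.negation.map is standard_negation_map
    )
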