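"""Questionnaire I/O, fuzzification, synthetic data and experiment splits.

The screening instrument has 22 items answered on a five-point scale
(0 = "definitely not" ... 4 = "definitely yes").  Items 1-20 are risk items
("the more, the worse"); items 21-22 are reverse-keyed verification items
("the more, the better").  The binary decision marks depression risk.

Fuzzification is two-stage: answers are normalised to ``a/4`` and embedded as
degenerate intervals ``[a/4, a/4]``; a missing answer becomes the vacuous
interval ``[0, 1]`` — total ignorance about the true membership degree.

The synthetic generator emulates the profile of the real screening cohort
(750 respondents, 501 negative / 249 positive decisions, ~5% missing cells)
with a latent-severity response model; see ``docs/methods.md`` for what it
does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .intervals import Interval

__all__ = [
    "N_QUESTIONS",
    "N_BASIC",
    "VERIFICATION_ATTRIBUTES",
    "QuestionnaireRecord",
    "FuzzifiedRecord",
    "read_records",
    "write_records",
    "fuzzify",
    "generate_synthetic",
    "SplitPlan",
    "HoldoutSplit",
    "NonIIDSplit",
    "split",
]

N_QUESTIONS = 22
N_BASIC = 20
#: Zero-based indices of the two reverse-keyed verification items.
VERIFICATION_ATTRIBUTES = (20, 21)
SCALE_MAX = 4

MISSING_INTERVAL = Interval(0.0, 1.0)

# Latent-severity response model defaults (answer-scale units).  Chosen once as
# a plausible screening profile: negatives centred low on the 0-4 scale,
# positives shifted up by the effect size, with subject- and item-level noise.
_BASE_SEVERITY = 1.2
_SUBJECT_SD = 0.6
_ITEM_SD = 0.7
DEFAULT_N = 750
DEFAULT_POSITIVE_FRACTION = 249 / 750
DEFAULT_MISSING_RATE = 0.05
DEFAULT_EFFECT_SIZE = 1.5


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One respondent: 22 raw answers (``None`` = missing) and a decision."""

    id: Union[int, str]
    answers: Tuple[Optional[int], ...]
    decision: int

    def __post_init__(self) -> None:
        if len(self.answers) != N_QUESTIONS:
            raise ValueError(
                f"record {self.id!r}: expected {N_QUESTIONS} answers, got {len(self.answers)}"
            )
        for j, a in enumerate(self.answers):
            if a is not None and (not isinstance(a, (int, np.integer)) or not 0 <= a <= SCALE_MAX):
                raise ValueError(
                    f"record {self.id!r}, q{j + 1}: answer {a!r} out of range 0..{SCALE_MAX}"
                )
        if self.decision not in (0, 1):
            raise ValueError(f"record {self.id!r}: decision {self.decision!r} must be 0 or 1")


@dataclass(frozen=True)
class FuzzifiedRecord:
    """A record with answers embedded in ``L^I``."""

    id: Union[int, str]
    memberships: Tuple[Interval, ...]
    decision: int


def fuzzify(record: QuestionnaireRecord) -> FuzzifiedRecord:
    """Two-stage fuzzification: ``a -> [a/4, a/4]``, missing ``-> [0, 1]``."""
    memberships = tuple(
        MISSING_INTERVAL if a is None else Interval(a / SCALE_MAX, a / SCALE_MAX)
        for a in record.answers
    )
    return FuzzifiedRecord(id=record.id, memberships=memberships, decision=record.decision)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = [f"q{i}" for i in range(1, N_QUESTIONS + 1)] + ["dec"]


def read_records(path) -> List[QuestionnaireRecord]:
    """Read questionnaire records from a CSV with header ``q1..q22,dec``.

    Blank cells or ``NA`` denote missing answers; the decision column must be
    present and binary.  Row numbers (0-based, excluding the header) become
    record ids.
    """
    frame = pd.read_csv(path, dtype="string", keep_default_na=False)
    missing_cols = [c for c in _COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"missing columns in {path}: {missing_cols}")
    records = []
    for row_idx, row in enumerate(frame.itertuples(index=False)):
        answers: List[Optional[int]] = []
        for j, col in enumerate(_COLUMNS[:-1]):
            cell = str(getattr(row, col)).strip()
            if cell in ("", "NA"):
                answers.append(None)
                continue
            try:
                value = int(cell)
            except ValueError as exc:
                raise ValueError(f"row {row_idx}, column {col}: non-integer answer {cell!r}") from exc
            if not 0 <= value <= SCALE_MAX:
                raise ValueError(f"row {row_idx}, column {col}: answer {value} out of range 0..4")
            answers.append(value)
        dec_cell = str(getattr(row, "dec")).strip()
        if dec_cell in ("", "NA"):
            raise ValueError(f"row {row_idx}: missing decision")
        try:
            decision = int(dec_cell)
        except ValueError as exc:
            raise ValueError(f"row {row_idx}, column dec: non-integer decision {dec_cell!r}") from exc
        records.append(QuestionnaireRecord(id=row_idx, answers=tuple(answers), decision=decision))
    return records


def write_records(records: Sequence[QuestionnaireRecord], path) -> None:
    """Write records as CSV; missing answers become blank cells."""
    rows = []
    for rec in records:
        row = {f"q{j + 1}": ("" if a is None else a) for j, a in enumerate(rec.answers)}
        row["dec"] = rec.decision
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

def generate_synthetic(n: int = DEFAULT_N,
                       positive_fraction: float = DEFAULT_POSITIVE_FRACTION,
                       missing_rate: float = DEFAULT_MISSING_RATE,
                       effect_size: float = DEFAULT_EFFECT_SIZE,
                       seed: int = 0) -> List[QuestionnaireRecord]:
    """Generate a synthetic screening cohort with exact class counts.

    Each subject draws a latent severity ``s ~ Normal(mu_c, sd)`` where the
    positive class is shifted up by ``effect_size`` (answer-scale units).
    Risk items are noisy discretisations of ``s`` onto {0..4}; verification
    items are reverse-keyed (decreasing in ``s``).  Every cell is masked
    missing independently with probability ``missing_rate``.  The number of
    positives is ``round(n * positive_fraction)`` exactly, so the default
    configuration reproduces the reference cohort profile (750 records, 249
    positives) for every seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError(f"positive_fraction={positive_fraction} outside [0, 1]")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError(f"missing_rate={missing_rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * positive_fraction))
    decisions = np.zeros(n, dtype=int)
    decisions[:n_pos] = 1
    decisions = rng.permutation(decisions)

    severity = _BASE_SEVERITY + effect_size * decisions + rng.normal(0.0, _SUBJECT_SD, n)
    noise = rng.normal(0.0, _ITEM_SD, (n, N_QUESTIONS))
    raw = severity[:, None] + noise
    raw[:, N_BASIC:] = (SCALE_MAX - severity)[:, None] + noise[:, N_BASIC:]
    answers = np.clip(np.rint(raw), 0, SCALE_MAX).astype(int)
    missing_mask = rng.random((n, N_QUESTIONS)) < missing_rate

    records = []
    for i in range(n):
        row = tuple(
            None if missing_mask[i, j] else int(answers[i, j]) for j in range(N_QUESTIONS)
        )
        records.append(QuestionnaireRecord(id=i, answers=row, decision=int(decisions[i])))
    return records


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """A seeded split recipe for one of the three experimental scenarios.

    ``client_mixes`` gives each federation client's (class-0, class-1)
    fraction; defaults are the balanced / 80-20 / 20-80 NON-IID design.
    """

    scenario: str = "holdout_70_30"
    seed: int = 0
    test_fraction: Optional[float] = None  # default 0.3 holdout, 0.15 NON-IID
    n_folds: int = 10
    client_mixes: Tuple[Tuple[float, float], ...] = ((0.5, 0.5), (0.8, 0.2), (0.2, 0.8))

    def __post_init__(self) -> None:
        if self.scenario not in ("holdout_70_30", "noniid_3clients", "kfold_10"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass(frozen=True)
class HoldoutSplit:
    train: tuple
    test: tuple


@dataclass(frozen=True)
class NonIIDSplit:
    """Balanced shared test pool, equal-size NON-IID clients, unused surplus."""

    test_pool: tuple
    clients: Tuple[tuple, ...]
    unused: tuple


def _per_class_indices(records, rng):
    by_class = {0: [], 1: []}
    for i, rec in enumerate(records):
        by_class[rec.decision].append(i)
    for c in by_class:
        by_class[c] = list(rng.permutation(np.array(by_class[c], dtype=int)))
    return by_class


def split(records: Sequence[QuestionnaireRecord], plan: SplitPlan):
    """Apply a :class:`SplitPlan`; deterministic given ``plan.seed``."""
    rng = np.random.default_rng(plan.seed)
    records = list(records)
    by_class = _per_class_indices(records, rng)

    if plan.scenario == "holdout_70_30":
        frac = 0.3 if plan.test_fraction is None else plan.test_fraction
        test_idx: List[int] = []
        train_idx: List[int] = []
        for c, idx in by_class.items():
            n_test = int(round(frac * len(idx)))
            test_idx.extend(idx[:n_test])
            train_idx.extend(idx[n_test:])
        return HoldoutSplit(train=tuple(records[i] for i in sorted(train_idx)),
                            test=tuple(records[i] for i in sorted(test_idx)))

    if plan.scenario == "kfold_10":
        folds_idx: List[List[int]] = [[] for _ in range(plan.n_folds)]
        for c, idx in by_class.items():
            for pos, i in enumerate(idx):
                folds_idx[pos % plan.n_folds].append(i)
        folds = []
        for f in range(plan.n_folds):
            test = tuple(records[i] for i in sorted(folds_idx[f]))
            train = tuple(records[i] for f2 in range(plan.n_folds) if f2 != f
                          for i in sorted(folds_idx[f2]))
            folds.append(HoldoutSplit(train=train, test=test))
        return folds

    # noniid_3clients
    frac = 0.15 if plan.test_fraction is None else plan.test_fraction
    n = len(records)
    pool_size = int(round(frac * n))
    pool_size -= pool_size % 2  # class-balanced => even
    per_class_pool = pool_size // 2
    for c in (0, 1):
        if len(by_class[c]) < per_class_pool:
            raise ValueError(
                f"cannot build a balanced test pool: class {c} has {len(by_class[c])} "
                f"records, needs {per_class_pool}"
            )
    pool_idx = by_class[0][:per_class_pool] + by_class[1][:per_class_pool]
    rem = {c: by_class[c][per_class_pool:] for c in (0, 1)}

    # Equal client sizes with exact mixes over the largest feasible subsample.
    mixes = plan.client_mixes
    demand0 = sum(m[0] for m in mixes)
    demand1 = sum(m[1] for m in mixes)
    n_rem = len(rem[0]) + len(rem[1])
    size = min(n_rem // len(mixes),
               int(len(rem[0]) / demand0) if demand0 > 0 else n_rem,
               int(len(rem[1]) / demand1) if demand1 > 0 else n_rem)
    client_counts = []
    for m in mixes:
        c1 = int(round(m[1] * size))
        client_counts.append((size - c1, c1))
    need0 = sum(c[0] for c in client_counts)
    need1 = sum(c[1] for c in client_counts)
    # rounding may overdraw a class by a record or two; shrink evenly if so
    while need0 > len(rem[0]) or need1 > len(rem[1]):
        over = 0 if need0 > len(rem[0]) else 1
        worst = max(range(len(client_counts)), key=lambda i: client_counts[i][over])
        c0, c1 = client_counts[worst]
        client_counts[worst] = (c0 - 1, c1) if over == 0 else (c0, c1 - 1)
        need0 = sum(c[0] for c in client_counts)
        need1 = sum(c[1] for c in client_counts)
    if size < 1:
        raise ValueError(
            f"infeasible NON-IID split: {n_rem} records remain after the test pool "
            f"(class 0: {len(rem[0])}, class 1: {len(rem[1])}) but the client mixes "
            f"demand {demand0:.2f}/{demand1:.2f} records per unit of client size"
        )
    clients = []
    cursor = {0: 0, 1: 0}
    for c0, c1 in client_counts:
        idx = rem[0][cursor[0]:cursor[0] + c0] + rem[1][cursor[1]:cursor[1] + c1]
        cursor[0] += c0
        cursor[1] += c1
        clients.append(tuple(records[i] for i in sorted(idx)))
    unused_idx = rem[0][cursor[0]:] + rem[1][cursor[1]:]
    return NonIIDSplit(
        test_pool=tuple(records[i] for i in sorted(pool_idx)),
        clients=tuple(clients),
        unused=tuple(records[i] for i in sorted(unused_idx)),
    )
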