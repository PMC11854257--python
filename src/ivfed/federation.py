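"""Federated plurality decisions, the efficiency-gated Decision Rule, and the
scenario harness.

Clients are medical centres holding NON-IID local datasets that cannot be
pooled.  Each client fits the interval kNN locally and evaluates on a shared,
class-balanced test pool.  The federated decision for an object is the
plurality of the local labels (abstentions do not vote); an exact tie is
broken in favour of the label backed by the *least uncertain* representative
(minimal entropy interval).  The Decision Rule then lets each client adopt the
federated predictions only if its local efficiency (default: accuracy) is
below the federation's — so no client is made worse on the shared pool.

Abstentions are penalised in the confusion counts (``NoDecision`` counts as a
false negative on positives and a false positive on negatives); dropping them
would silently inflate every reported metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data import NonIIDSplit, SplitPlan, split
from .intervals import Comparison, Interval, OrderSpec, compare
from .knn import NO_DECISION, ClassifierConfig, Prediction, predict_many

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "federated_vote",
    "decision_rule",
    "FederationRun",
    "run_scenario",
]

EF_NAMES = ("ACC", "SENS", "SPEC", "PREC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _label_of(p) -> Union[int, str]:
    return p.label if isinstance(p, Prediction) else p


def confusion(predictions: Sequence, truth: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with abstentions penalised as misclassifications."""
    if len(predictions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} labels"
        )
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truth):
        label = _label_of(p)
        if label == NO_DECISION:
            label = 1 - t  # abstention counts against the truth
        if t == 1:
            tp += label == 1
            fn += label != 1
        else:
            tn += label == 0
            fp += label != 0
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> Dict[str, float]:
    """ACC / SENS / SPEC / PREC; zero-denominator metrics are NaN and flagged."""
    out: Dict[str, float] = {}
    undefined: List[str] = []

    def ratio(name: str, num: int, den: int) -> None:
        if den == 0:
            out[name] = math.nan
            undefined.append(name)
        else:
            out[name] = num / den

    ratio("ACC", c.tp + c.tn, c.total)
    ratio("SENS", c.tp, c.tp + c.fn)
    ratio("SPEC", c.tn, c.tn + c.fp)
    ratio("PREC", c.tp, c.tp + c.fp)
    out["undefined"] = tuple(undefined)  # type: ignore[assignment]
    return out


def _entropy_key(e: Optional[Interval], order: OrderSpec):
    return e


def federated_vote(per_client: Sequence[Prediction],
                   order: OrderSpec = OrderSpec.partial2()) -> Prediction:
    """Plurality vote over client labels with an entropy tie-break.

    Abstaining clients do not vote; if every client abstains the federated
    decision abstains too.  On an exact tie the label whose supporting clients
    contain the minimal representative entropy wins (compared under ``order``,
    residual ties by interval midpoint, then client index).
    """
    if not per_client:
        raise ValueError("federated_vote requires at least one client prediction")
    voters = [(i, p) for i, p in enumerate(per_client) if p.label in (0, 1)]
    if not voters:
        return Prediction(label=NO_DECISION, id=per_client[0].id)
    counts = {0: 0, 1: 0}
    for _, p in voters:
        counts[p.label] += 1

    if counts[1] != counts[0]:
        winner = 1 if counts[1] > counts[0] else 0
    else:
        # entropy tie-break: overall least-uncertain supporting client decides
        def better(a, b) -> bool:
            (ia, pa), (ib, pb) = a, b
            ea, eb = pa.representative_entropy(), pb.representative_entropy()
            if ea is None or eb is None:
                return eb is None and ea is not None
            c = compare(ea, eb, order)
            if c is Comparison.LESS:
                return True
            if c is Comparison.GREATER:
                return False
            if ea.midpoint < eb.midpoint:
                return True
            if eb.midpoint < ea.midpoint:
                return False
            return ia < ib

        leader = voters[0]
        for cand in voters[1:]:
            if better(cand, leader):
                leader = cand
        winner = leader[1].label

    # evidence is carried over from the least-uncertain client voting the winner
    supporting = [(i, p) for i, p in voters if p.label == winner]
    lead_i, lead = supporting[0]
    for i, p in supporting[1:]:
        ea, eb = p.representative_entropy(), lead.representative_entropy()
        if ea is not None and (eb is None or compare(ea, eb, order) is Comparison.LESS):
            lead_i, lead = i, p
    return Prediction(label=winner, d0=lead.d0, d1=lead.d1,
                      entropy0=lead.entropy0, entropy1=lead.entropy1, id=lead.id)


def decision_rule(ef_name: str,
                  local_efs: Sequence[float],
                  federated_ef: float,
                  local_preds: Sequence[Sequence[Prediction]],
                  federated_preds: Sequence[Prediction],
                  truth: Sequence[int]) -> dict:
    """Efficiency-gated adoption of the federated decisions.

    A client adopts the federated predictions as final only when its local
    efficiency is strictly below the federation's; otherwise it keeps its own.
    By construction each client's post-rule gating metric on the shared pool
    equals ``max(local, federated)``.
    """
    if ef_name not in EF_NAMES:
        raise ValueError(f"unknown efficiency measure {ef_name!r}; expected one of {EF_NAMES}")
    adopted = [ef < federated_ef for ef in local_efs]
    final = [list(federated_preds) if take else list(preds)
             for take, preds in zip(adopted, local_preds)]
    post_metrics = [metrics(confusion(preds, truth)) for preds in final]
    return {"ef": ef_name, "adopted": tuple(adopted), "final": final,
            "metrics": post_metrics}


@dataclass(frozen=True)
class FederationRun:
    """Everything one NON-IID repetition produced, for audit and recomputation."""

    truth: Tuple[int, ...]
    client_sizes: Tuple[int, ...]
    local_preds: Tuple[tuple, ...]
    local_metrics: Tuple[dict, ...]
    federated_preds: tuple = ()
    federated_metrics: Optional[dict] = None
    adopted: Tuple[bool, ...] = ()
    final_preds: Tuple[tuple, ...] = ()
    post_metrics: Tuple[dict, ...] = ()


def _derive_seed(seed: int, rep: int) -> int:
    return int(np.random.default_rng([seed, rep]).integers(0, 2**31 - 1))


def _metric_row(rep: int, row: str, m: dict, n_eval: int) -> dict:
    return {"rep": rep, "row": row, "ACC": m["ACC"], "SENS": m["SENS"],
            "SPEC": m["SPEC"], "PREC": m["PREC"], "n_eval": n_eval}


def run_scenario(scenario: str,
                 dataset: Sequence,
                 config: ClassifierConfig = ClassifierConfig(),
                 repetitions: int = 10,
                 seed: int = 0,
                 ef: str = "ACC",
                 keep_details: bool = False) -> dict:
    """Run one of the three experimental scenarios.

    ``s1`` — centralised 70/30 stratified holdout; ``s2`` — three NON-IID
    clients evaluated on a balanced shared pool; ``s3`` — ``s2`` plus the
    federated vote and the Decision Rule gated on ``ef`` (accuracy by
    default).  Each repetition uses an independently derived split seed;
    results are reported per repetition plus a mean/sd summary.
    """
    if scenario not in ("s1", "s2", "s3"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rows: List[dict] = []
    runs: List[FederationRun] = []

    for rep in range(repetitions):
        rep_seed = _derive_seed(seed, rep)
        if scenario == "s1":
            plan = SplitPlan(scenario="holdout_70_30", seed=rep_seed)
            ho = split(dataset, plan)
            preds = predict_many(ho.test, ho.train, config)
            truth = [r.decision for r in ho.test]
            m = metrics(confusion(preds, truth))
            rows.append(_metric_row(rep, "central", m, len(truth)))
            continue

        plan = SplitPlan(scenario="noniid_3clients", seed=rep_seed)
        sp: NonIIDSplit = split(dataset, plan)
        truth = [r.decision for r in sp.test_pool]
        local_preds = [predict_many(sp.test_pool, client, config) for client in sp.clients]
        local_metrics = [metrics(confusion(p, truth)) for p in local_preds]
        for i, m in enumerate(local_metrics):
            rows.append(_metric_row(rep, f"client{i + 1}", m, len(truth)))

        if scenario == "s2":
            if keep_details:
                runs.append(FederationRun(
                    truth=tuple(truth),
                    client_sizes=tuple(len(c) for c in sp.clients),
                    local_preds=tuple(tuple(p) for p in local_preds),
                    local_metrics=tuple(local_metrics),
                ))
            continue

        fed_preds = [federated_vote([p[j] for p in local_preds], config.order)
                     for j in range(len(truth))]
        fed_metrics = metrics(confusion(fed_preds, truth))
        rows.append(_metric_row(rep, "federated", fed_metrics, len(truth)))

        rule = decision_rule(ef, [m[ef] for m in local_metrics], fed_metrics[ef],
                             local_preds, fed_preds, truth)
        for i, m in enumerate(rule["metrics"]):
            rows.append(_metric_row(rep, f"post_client{i + 1}", m, len(truth)))
        best = max(range(len(rule["metrics"])), key=lambda i: rule["metrics"][i][ef])
        rows.append(_metric_row(rep, "decision_rule_best", rule["metrics"][best], len(truth)))

        if keep_details:
            runs.append(FederationRun(
                truth=tuple(truth),
                client_sizes=tuple(len(c) for c in sp.clients),
                local_preds=tuple(tuple(p) for p in local_preds),
                local_metrics=tuple(local_metrics),
                federated_preds=tuple(fed_preds),
                federated_metrics=fed_metrics,
                adopted=rule["adopted"],
                final_preds=tuple(tuple(p) for p in rule["final"]),
                post_metrics=tuple(rule["metrics"]),
            ))

    per_rep = pd.DataFrame(rows)
    summary = (per_rep.drop(columns=["rep", "n_eval"])
               .groupby("row", sort=False)
               .agg(["mean", "std"]))
    result = {"scenario": scenario, "ef": ef, "per_rep": per_rep, "summary": summary}
    if keep_details:
        result["runs"] = runs
    return result
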