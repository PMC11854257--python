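"""Independent brute-force oracle for the interval kNN pipeline.

Everything here is re-derived from the printed formulas on plain float tuples
``(lo, hi)`` — no code is shared with the package beyond the rule definitions
themselves (comparison regimes, three-branch precedence, meet/mean similarity,
entropy as self-negation similarity, linear-scan ranking, the classification
cascade and the verification override).
"""

T = 1e-12
NEUTRAL = (0.5, 0.5)
FAMILY_ORDER = {"standard": "partial2", "possible": "possible", "necessary": "necessary"}


def neg(a):
    return (1.0 - a[1], 1.0 - a[0])


def o_leq(a, b, kind):
    if kind == "partial2":
        return a[0] <= b[0] + T and a[1] <= b[1] + T
    if kind == "possible":
        return a[0] <= b[1] + T
    if kind == "necessary":
        return a[1] <= b[0] + T
    ma, mb = (a[0] + a[1]) / 2, (b[0] + b[1]) / 2
    if ma < mb - T:
        return True
    if mb < ma - T:
        return False
    return a[1] <= b[1] + T


def o_eq(a, b):
    return abs(a[0] - b[0]) <= T and abs(a[1] - b[1]) <= T


def o_cmp(a, b, kind):
    if o_eq(a, b):
        return "eq"
    ab, ba = o_leq(a, b, kind), o_leq(b, a, kind)
    if ab and ba:
        return "eq"
    if ab:
        return "lt"
    if ba:
        return "gt"
    return "inc"


def o_prec(a, b, family):
    kind = FAMILY_ORDER[family]
    if o_eq(a, b):
        return (1.0 - (a[1] - a[0]), 1.0)
    if o_leq(a, b, kind) and not o_leq(b, a, kind):
        return (1.0, 1.0)
    na = neg(a)
    if family == "standard":
        return ((na[0] + b[0]) / 2, (na[1] + b[1]) / 2)
    if family == "possible":
        if na == (0.0, 0.0) and b == (0.0, 0.0):
            return (0.0, 0.0)
        return ((na[0] + b[0]) / 2, 1.0)
    lo = (na[0] + b[0]) / 2
    return (lo, max((na[0] + b[1]) / 2, (na[1] + b[0]) / 2))


def o_sim(A, B, family):
    los, his = [], []
    for a, b in zip(A, B):
        p, q = o_prec(a, b, family), o_prec(b, a, family)
        los.append(min(p[0], q[0]))
        his.append(min(p[1], q[1]))
    return (sum(los) / len(los), sum(his) / len(his))


def o_ent(A, family):
    return o_sim(A, [neg(a) for a in A], family)


def width(a):
    return a[1] - a[0]


def rank_above(sa, sb, ia, ib, kind):
    c = o_cmp(sa, sb, kind)
    if c == "gt":
        return True
    if c == "lt":
        return False
    if width(sa) < width(sb) - T:
        return True
    if width(sb) < width(sa) - T:
        return False
    return ia < ib


def ent_below(ea, eb, ia, ib, kind):
    c = o_cmp(ea, eb, kind)
    if c == "lt":
        return True
    if c == "gt":
        return False
    if width(ea) < width(eb) - T:
        return True
    if width(eb) < width(ea) - T:
        return False
    return ia < ib


def fuzz(answers):
    return [(0.0, 1.0) if a is None else (a / 4, a / 4) for a in answers]


def _top_k(cands, sims, k, kind):
    remaining = list(cands)
    out = []
    for _ in range(min(k, len(remaining))):
        best = remaining[0]
        for c in remaining[1:]:
            if rank_above(sims[c], sims[best], c, best, kind):
                best = c
        out.append(best)
        remaining.remove(best)
    return out


def o_classify(d0, d1, kind):
    if d0 is None:
        return 1
    if d1 is None:
        return 0
    c = o_cmp(d1, d0, kind)
    if c == "gt":
        return 1
    if c == "lt":
        return 0
    c1, c0 = o_cmp(d1, NEUTRAL, kind), o_cmp(d0, NEUTRAL, kind)
    if c1 in ("gt", "eq") and c0 == "lt":
        return 1
    if c0 in ("gt", "eq") and c1 == "lt":
        return 0
    if width(d1) < width(d0) - T:
        return 1
    if width(d0) < width(d1) - T:
        return 0
    return "ND"


def o_predict(query_answers, train, kind, family, strategy, k, attrs):
    """train: list of (answers, decision). Returns (label, d0, d1, fired)."""
    y = fuzz(query_answers)
    ya = [y[i] for i in attrs]
    sims, ents, classes = [], [], []
    for answers, dec in train:
        x = fuzz(answers)
        xa = [x[i] for i in attrs]
        sims.append(o_sim(ya, xa, family))
        ents.append(o_ent(xa, family))
        classes.append(dec)

    pools = {}
    if strategy == "per_class_k":
        for c in sorted(set(classes)):
            members = [i for i in range(len(train)) if classes[i] == c]
            pools[c] = _top_k(members, sims, k, kind)
    else:
        for i in _top_k(list(range(len(train))), sims, k, kind):
            pools.setdefault(classes[i], []).append(i)

    reps = {}
    for c, pool in pools.items():
        best = pool[0]
        for cand in pool[1:]:
            if ent_below(ents[cand], ents[best], cand, best, kind):
                best = cand
        reps[c] = best

    d0 = sims[reps[0]] if 0 in reps else None
    d1 = sims[reps[1]] if 1 in reps else None
    label = o_classify(d0, d1, kind)

    fired = False
    if label in (0, "ND"):
        for attr in (20, 21):
            m = y[attr]
            if m[1] - m[0] <= T and m[1] < 0.5:
                label, fired = 1, True
                break
    return label, d0, d1, fired
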