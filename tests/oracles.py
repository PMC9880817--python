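"""Independent brute-force reference implementations used by the tests.

Deliberately naive (explicit loops, textbook formulas) so they cannot share
bugs with the vectorized implementations under test.
"""

import math


def pearson_oracle(x, y):
    n = len(x)
    if n < 2:
        return float("nan")
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def jaccard_oracle(x, y):
    inter = sum(1 for a, b in zip(x, y) if a > 0 and b > 0)
    union = sum(1 for a, b in zip(x, y) if a > 0 or b > 0)
    return inter / union if union else 0.0


def apex_oracle(x, y):
    def first_argmax(v):
        best = max(v)
        for i, a in enumerate(v):
            if a == best:
                return i
        raise AssertionError("unreachable")

    return int(first_argmax(x) == first_argmax(y))


def _bin_oracle(v, n_bins):
    # equal-width bins over [0, max]; exact integer arithmetic: value a is
    # past interior edge k*mx/n_bins iff k*mx <= a*n_bins
    mx = max(v)
    if mx <= 0:
        return [0] * len(v)
    out = []
    for a in v:
        b = sum(1 for k in range(1, n_bins) if k * mx <= a * n_bins)
        out.append(min(b, n_bins - 1))
    return out


def mi_oracle(x, y, n_bins):
    bx = _bin_oracle(x, n_bins)
    by = _bin_oracle(y, n_bins)
    n = len(x)
    joint = {}
    for i, j in zip(bx, by):
        joint[(i, j)] = joint.get((i, j), 0) + 1
    px = {}
    py = {}
    for (i, j), c in joint.items():
        px[i] = px.get(i, 0) + c
        py[j] = py.get(j, 0) + c
    mi = 0.0
    for (i, j), c in joint.items():
        p = c / n
        mi += p * math.log2(p / (px[i] / n * py[j] / n))
    return max(mi, 0.0)


def bayes_oracle(x, y, alpha):
    xs = [a + alpha for a in x]
    ys = [b + alpha for b in y]
    tx = sum(xs)
    ty = sum(ys)
    return pearson_oracle([a / tx for a in xs], [b / ty for b in ys])


def auc_oracle(y_true, y_score):
    """Probability a random positive outscores a random negative (ties 1/2)."""
    pos = [s for y, s in zip(y_true, y_score) if y == 1]
    neg = [s for y, s in zip(y_true, y_score) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def greedy_reachable_optimum(graph, seed_node, penalty, cohesiveness_fn):
    """Best cohesiveness among all sets reachable from the seed by any
    sequence of strictly improving single moves (breadth-first replay)."""
    start = frozenset({seed_node})
    seen = {start}
    frontier = [start]
    best = cohesiveness_fn(graph, start, penalty)
    while frontier:
        nxt = []
        for state in frontier:
            current = cohesiveness_fn(graph, state, penalty)
            moves = []
            boundary = {
                v for u in state for v in graph[u] if v not in state
            }
            moves.extend(state | {v} for v in boundary)
            if len(state) > 1:
                moves.extend(state - {u} for u in state)
            for move in moves:
                move = frozenset(move)
                if move in seen:
                    continue
                score = cohesiveness_fn(graph, move, penalty)
                if score > current:
                    seen.add(move)
                    nxt.append(move)
                    best = max(best, score)
        frontier = nxt
    return best
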