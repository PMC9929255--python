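"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives a statistic from its plain definition (loops,
enumeration, exhaustive search) without sharing code paths with the package
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bh_step_up(p):
    """Benjamini-Hochberg adjustment straight from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def auc_pair_count(scores, labels):
    """AUC as the fraction of concordant positive/negative pairs (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == labels.max()]
    neg = scores[labels != labels.max()]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def tom_triple_loop(a):
    """Topological overlap by the literal triple loop."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    k = a.sum(axis=0)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def mi_contingency(xb, yb):
    """Plug-in MI from a hand-built contingency table of binned data."""
    xb = np.asarray(xb)
    yb = np.asarray(yb)
    n = len(xb)
    total = 0.0
    for xv in np.unique(xb):
        for yv in np.unique(yb):
            nij = np.sum((xb == xv) & (yb == yv))
            if nij == 0:
                continue
            pij = nij / n
            pi = np.sum(xb == xv) / n
            pj = np.sum(yb == yv) / n
            total += pij * np.log(pij / (pi * pj))
    return total


def dpi_all_triangles(edges, epsilon):
    """DPI pruning by exhaustive triangle enumeration over all node triples."""
    w = {}
    nodes = set()
    for u, v, wt in edges:
        key = frozenset((u, v))
        w[key] = wt
        nodes |= {u, v}
    doomed = set()
    for i, j, k in combinations(sorted(nodes), 3):
        trio = [frozenset(p) for p in ((i, j), (i, k), (j, k))]
        if not all(t in w for t in trio):
            continue
        for t in trio:
            others = [w[o] for o in trio if o != t]
            if w[t] < (1 - epsilon) * min(others):
                doomed.add(t)
    return [(u, v, wt) for u, v, wt in edges if frozenset((u, v)) not in doomed]


def ks_from_definition(tags, ranked):
    """KS enrichment via an explicit loop over tag ranks."""
    tags = set(tags)
    n = len(ranked)
    positions = [i + 1 for i, g in enumerate(ranked) if g in tags]
    t = len(positions)
    a = max(((j + 1) / t) - (v / n) for j, v in enumerate(positions))
    b = max((v / n) - (j / t) for j, v in enumerate(positions))
    return a if a > b else -b


def hypergeom_enumerate(N, K, n, k):
    """Upper-tail hypergeometric p by enumerating every size-n draw."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total


def regulatory_score_loops(edges, lfc, assignment):
    """RS per (tf, module) by plain accumulation loops."""
    out = {}
    for reg, target, weight in edges:
        mod = assignment[target]
        key = (reg, mod)
        out[key] = out.get(key, 0.0) + weight * abs(lfc[target])
    return out


def mic_exhaustive(x, y, cap, max_axis):
    """MIC by exhaustive search over cut placements at clump boundaries.

    Shares only the equipartition/clump conventions with the implementation;
    the grid optimization itself is enumerated, not solved by DP.
    """
    from macnet.selection import _clump_counts, _equipartition

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    best = 0.0
    for u, v in ((x, y), (y, x)):
        for q in range(2, min(cap // 2, np.unique(v).size, max_axis) + 1):
            rows = _equipartition(v, q)
            q_eff = int(rows.max()) + 1
            if q_eff < 2:
                continue
            max_cols = min(cap // q_eff, max_axis)
            if max_cols < 2:
                continue
            counts = _clump_counts(u, rows, q_eff, 10**9)
            k = counts.shape[0]
            cum = np.vstack([np.zeros(q_eff, dtype=int), np.cumsum(counts, axis=0)])
            for c in range(2, max_cols + 1):
                if c > k:
                    break
                for cuts in combinations(range(1, k), c - 1):
                    bounds = [0, *cuts, k]
                    table = np.array(
                        [cum[bounds[i + 1]] - cum[bounds[i]] for i in range(c)]
                    )
                    mi = mi_from_table(table)
                    best = max(best, mi / np.log(min(q_eff, c)))
    return best


def mi_from_table(table):
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij == 0:
                continue
            total += (nij / n) * np.log(nij * n / (table[i].sum() * table[:, j].sum()))
    return total
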