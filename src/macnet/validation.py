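"""Cross-cohort validation statistics.

Hypergeometric overlap testing of gene lists (upper tail: is the overlap of
two differential-expression lists larger than chance given the shared
universe?) and single-sample gene-set enrichment (ssGSEA), the rank-weighted
running-sum score used to project a bulk signature onto individual samples
or cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OverlapTest", "hypergeometric_overlap", "deg_overlap", "ssgsea"]


@dataclass
class OverlapTest:
    """Upper-tail hypergeometric test of a k-gene overlap."""

    universe: int
    list1: int
    list2: int
    overlap: int
    p: float


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> OverlapTest:
    """P(X >= k) for an overlap of k between lists of sizes K and n in N."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(universe=N, list1=K, list2=n, overlap=k, p=min(1.0, p))


def deg_overlap(
    list_a,
    list_b,
    universe,
    de_a: pd.DataFrame | None = None,
    de_b: pd.DataFrame | None = None,
    lfc_threshold: float = 0.15,
) -> OverlapTest:
    """Hypergeometric overlap of two DEG lists within a shared universe.

    When DE tables are supplied, each list is first restricted to genes with
    ``|log2FC| > lfc_threshold``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(list_a)
    b = set(list_b)
    if de_a is not None:
        passing = set(de_a.index[de_a["log2FC"].abs() > lfc_threshold])
        a &= passing
    if de_b is not None:
        passing = set(de_b.index[de_b["log2FC"].abs() > lfc_threshold])
        b &= passing
    if not (a <= universe and b <= universe):
        raise ValueError("lists must be subsets of the universe")
    return hypergeometric_overlap(len(universe), len(a), len(b), len(a & b))


def _sample_es(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Integrated running-sum ES for one sample's gene ordering."""
    n = len(order)
    member = in_set[order]
    m = int(member.sum())
    if m == 0:
        raise ValueError("gene set has no members in the universe")
    if m == n:
        return 0.0
    # weight by rank from the top: position 0 (highest expression) has rank n
    ranks = np.arange(n, 0, -1, dtype=float)
    weights = np.where(member, ranks**alpha, 0.0)
    incr = weights / weights.sum()
    decr = np.where(member, 0.0, 1.0 / (n - m))
    running = np.cumsum(incr - decr)
    return float(running.sum())


def ssgsea(
    x: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    meta: pd.DataFrame | None = None,
    group_column: str = "group",
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (samples x sets).

    Per sample, genes are ranked by expression descending (ties by gene id);
    in-set positions add ``rank^alpha`` weight (normalized over the set),
    out-of-set positions subtract ``1/(N - set size)``, and the ES is the sum
    of the running values (integrated convention).  A set equal to the whole
    universe scores 0 by construction.  When ``meta`` is given the result
    carries per-group mean scores in ``.attrs['group_means']``.
    """
    if not sets:
        raise ValueError("no gene sets")
    genes = np.asarray(x.index.astype(str))
    universe = set(genes)
    memberships = {}
    for name, members in sets.items():
        hit = np.isin(genes, list(set(members)))
        if not hit.any():
            raise ValueError(f"gene set {name!r} has no members in the universe")
        memberships[name] = hit
    # precompute per-sample orderings: expression descending, ties by gene id
    gene_order = np.argsort(genes, kind="stable")
    out = pd.DataFrame(index=x.columns, columns=list(sets), dtype=float)
    vals = x.to_numpy()
    for j, sample in enumerate(x.columns):
        v = vals[:, j][gene_order]
        order = gene_order[np.argsort(-v, kind="stable")]
        for name, hit in memberships.items():
            out.loc[sample, name] = _sample_es(order, hit, alpha)
    if meta is not None:
        groups = meta.loc[out.index, group_column]
        out.attrs["group_means"] = out.groupby(groups).mean()
    return out
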