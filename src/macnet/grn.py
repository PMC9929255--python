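"""Mutual-information regulatory network inference with bootstrap consensus
and data-processing-inequality (DPI) pruning.

The estimator is a copula/rank transform followed by equal-frequency binning
into ``max(2, floor(n^(1/3)))`` bins per axis and the plug-in (maximum
likelihood) mutual information in nats.  Edge significance is set by an
exponential fit to the upper tail of a permutation null, extrapolated to the
requested p-value (direct counting at p = 1e-7 would need >1e7 permutations).
Candidate regulators come from a transcription-factor list; per bootstrap the
samples are resampled with replacement, significant TF-gene pairs are kept
and DPI-pruned, and the consensus network retains edges supported by at least
``min_support`` of the bootstraps, weighted by their mean MI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import scale_free_fit_index

__all__ = [
    "GRNConfig",
    "RegulatoryNetwork",
    "mutual_information",
    "fit_exponential_tail",
    "mi_threshold",
    "dpi_prune",
    "infer_grn",
]


@dataclass
class GRNConfig:
    """Inference parameters (defaults mirror common ARACNe practice)."""

    p_threshold: float = 1e-7
    dpi_tolerance: float = 0.1
    n_bootstraps: int = 100
    min_support: float = 0.5
    n_null_perms: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0,1)")
        if not (0 <= self.dpi_tolerance < 1):
            raise ValueError("dpi_tolerance must be in [0,1)")


@dataclass
class RegulatoryNetwork:
    """Directed TF->target edges with MI weight and bootstrap support."""

    edges: pd.DataFrame  # columns: regulator, target, weight, support
    tf_list: set
    scale_free_fit: float = float("nan")

    def __post_init__(self):
        if len(self.edges):
            if (self.edges["regulator"] == self.edges["target"]).any():
                raise ValueError("self-edges are not allowed")
            if (self.edges["weight"] < 0).any() or not np.isfinite(
                self.edges["weight"]
            ).all():
                raise ValueError("weights must be finite and nonnegative")
            extra = set(self.edges["regulator"]) - set(self.tf_list)
            if extra:
                raise ValueError(f"regulators outside tf_list: {sorted(extra)[:3]}")

    def __len__(self):
        return len(self.edges)


def n_bins_for(n: int) -> int:
    return max(2, int(np.floor(n ** (1.0 / 3.0))))


def rank_bin(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin indices from ordinal (stable argsort) ranks."""
    v = np.asarray(v)
    n = len(v)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _plugin_mi(xb: np.ndarray, yb: np.ndarray, bx: int, by: int) -> float:
    joint = np.bincount(xb * by + yb, minlength=bx * by).reshape(bx, by)
    return _mi_from_counts(joint)


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def _mi_rows(XB: np.ndarray, yb: np.ndarray, bx: int, by: int) -> np.ndarray:
    """Plug-in MI of each row of binned matrix ``XB`` against binned ``yb``."""
    g, n = XB.shape
    codes = XB * by + yb[None, :] + (np.arange(g)[:, None] * bx * by)
    counts = np.bincount(codes.ravel(), minlength=g * bx * by).reshape(g, bx, by)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return np.nansum(terms, axis=(1, 2))


def mutual_information(x, y, discrete_x: bool = False, discrete_y: bool = False) -> float:
    """Plug-in mutual information between two samples, in nats.

    Continuous variables are rank-transformed and split into
    ``max(2, floor(n^(1/3)))`` equal-frequency bins; discrete variables use
    their values as categories.  A constant variable has MI 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return 0.0
    if not (discrete_x and discrete_y) and n < 20:
        raise ValueError("continuous MI estimation needs n >= 20")
    nb = n_bins_for(n)
    if discrete_x:
        xb = np.unique(x, return_inverse=True)[1]
        bx = xb.max() + 1
    else:
        xb, bx = rank_bin(x, nb), nb
    if discrete_y:
        yb = np.unique(y, return_inverse=True)[1]
        by = yb.max() + 1
    else:
        yb, by = rank_bin(y, nb), nb
    return max(0.0, _plugin_mi(xb.astype(np.int64), yb.astype(np.int64), int(bx), int(by)))


def fit_exponential_tail(null_values: np.ndarray, p_threshold: float, tail: float = 0.05) -> float:
    """MI value whose extrapolated null tail probability equals ``p_threshold``.

    Fits ln(survival) linearly on the upper ``tail`` fraction of the null and
    inverts the fit at ``p_threshold``.
    """
    null_values = np.sort(np.asarray(null_values, dtype=float))
    m = len(null_values)
    if m < 100 or null_values[-1] <= 0:
        raise ValueError("degenerate null distribution")
    k = max(10, int(np.ceil(tail * m)))
    xs = null_values[-k:]
    # empirical survival just below each tail point (avoids ln 0 at the max)
    surv = (m - (m - k + np.arange(k))) / m
    ln_s = np.log(surv)
    slope, intercept = np.polyfit(xs, ln_s, 1)
    if slope >= 0:
        raise ValueError("null tail is not decaying; cannot extrapolate")
    return float((np.log(p_threshold) - intercept) / slope)


def _null_mis(binned: np.ndarray, nb: int, n_perms: int, rng: np.random.Generator) -> np.ndarray:
    g, n = binned.shape
    i_idx = rng.integers(0, g, size=n_perms)
    j_idx = rng.integers(0, g, size=n_perms)
    shuffled = rng.permuted(binned[j_idx], axis=1)
    out = np.empty(n_perms)
    chunk = 2000
    for s in range(0, n_perms, chunk):
        e = min(s + chunk, n_perms)
        blk = binned[i_idx[s:e]]
        codes = blk * nb + shuffled[s:e] + (np.arange(e - s)[:, None] * nb * nb)
        counts = np.bincount(codes.ravel(), minlength=(e - s) * nb * nb).reshape(e - s, nb, nb)
        p = counts / n
        px = p.sum(axis=2, keepdims=True)
        py = p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * np.log(p / (px * py))
        out[s:e] = np.nansum(terms, axis=(1, 2))
    return np.maximum(out, 0.0)


def mi_threshold(x: pd.DataFrame, config: GRNConfig, rng: np.random.Generator | None = None) -> float:
    """Permutation-null MI threshold at ``config.p_threshold``.

    Pools MI from random gene pairs with one member permuted, then
    extrapolates the exponential tail of the null.
    """
    if config.n_null_perms < 10_000:
        raise ValueError("n_null_perms must be >= 1e4")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vals = x.to_numpy()
    nb = n_bins_for(vals.shape[1])
    binned = np.vstack([rank_bin(row, nb) for row in vals])
    null = _null_mis(binned, nb, int(config.n_null_perms), rng)
    if null.max() <= 0:
        raise ValueError("degenerate null (all MI zero)")
    return fit_exponential_tail(null, config.p_threshold)


def dpi_prune(edges, epsilon: float):
    """Data-processing-inequality pruning of a weighted undirected edge set.

    ``edges`` is an iterable of ``(u, v, w)``.  For every triangle, the edge
    with ``w_ij < (1-epsilon) * min(w_ik, w_jk)`` is marked; all marked edges
    are removed simultaneously.
    """
    edge_w: dict[frozenset, float] = {}
    orig: dict[frozenset, tuple] = {}
    nbrs: dict[object, set] = {}
    for u, v, w in edges:
        key = frozenset((u, v))
        if key not in edge_w:
            orig[key] = (u, v)
        edge_w[key] = float(w)
        nbrs.setdefault(u, set()).add(v)
        nbrs.setdefault(v, set()).add(u)
    doomed = set()
    for key, (i, j) in orig.items():
        wij = edge_w[key]
        for k in nbrs[i] & nbrs[j]:
            wik = edge_w[frozenset((i, k))]
            wjk = edge_w[frozenset((j, k))]
            if wij < (1.0 - epsilon) * min(wik, wjk):
                doomed.add(key)
                break
    return [(u, v, edge_w[k]) for k, (u, v) in orig.items() if k not in doomed]


def infer_grn(x: pd.DataFrame, tf_list, config: GRNConfig | None = None) -> RegulatoryNetwork:
    """Bootstrap-consensus MI network restricted to candidate TFs.

    Per bootstrap: resample samples with replacement, estimate MI for every
    TF-gene pair, keep pairs above the permutation-null threshold (computed
    once on the original data), apply DPI.  Consensus edges need bootstrap
    support >= ``min_support``; their weight is the mean MI over supporting
    bootstraps.  TF-TF pairs are reported in both directions.
    """
    config = config or GRNConfig()
    tfs = [t for t in tf_list if t in x.index]
    if not tfs:
        raise ValueError("no candidate TF present in the expression matrix")
    rng = np.random.default_rng(config.seed)
    genes = list(x.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    tf_pos = np.array([gene_pos[t] for t in tfs])
    vals = x.to_numpy()
    n = vals.shape[1]
    nb = n_bins_for(n)
    threshold = mi_threshold(x, config, rng)

    counts: dict[tuple[str, str], int] = {}
    weight_sums: dict[tuple[str, str], float] = {}
    b_total = int(config.n_bootstraps)
    for _ in range(b_total):
        idx = rng.integers(0, n, size=n)
        boot = vals[:, idx]
        binned = np.vstack([rank_bin(row, nb) for row in boot])
        raw_edges = []
        seen = set()
        for t_i, tf in zip(tf_pos, tfs):
            mis = _mi_rows(binned, binned[t_i], nb, nb)
            hits = np.nonzero(mis >= threshold)[0]
            for h in hits:
                if h == t_i:
                    continue
                key = (tf, genes[h]) if tf <= genes[h] else (genes[h], tf)
                if key in seen:
                    continue
                seen.add(key)
                raw_edges.append((key[0], key[1], float(mis[h])))
        kept = dpi_prune(raw_edges, config.dpi_tolerance)
        for u, v, w in kept:
            counts[(u, v)] = counts.get((u, v), 0) + 1
            weight_sums[(u, v)] = weight_sums.get((u, v), 0.0) + w

    tf_set = set(tfs)
    rows = []
    for (u, v), c in counts.items():
        support = c / b_total
        if support < config.min_support:
            continue
        w = weight_sums[(u, v)] / c
        if u in tf_set:
            rows.append((u, v, w, support))
        if v in tf_set and v != u:
            rows.append((v, u, w, support))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight", "support"])
    edges = edges.sort_values(["regulator", "target"], kind="mergesort").reset_index(drop=True)
    if edges.empty:
        warnings.warn("empty consensus network")
        return RegulatoryNetwork(edges=edges, tf_list=set(tf_list), scale_free_fit=float("nan"))
    out_deg = edges.groupby("regulator")["target"].count().to_numpy(dtype=float)
    try:
        sf = scale_free_fit_index(out_deg)
    except ValueError:
        sf = float("nan")
    return RegulatoryNetwork(edges=edges, tf_list=set(tf_list), scale_free_fit=sf)
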