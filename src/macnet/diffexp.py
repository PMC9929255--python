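"""Per-gene differential statistics and group tests.

Differential expression between serum-exposure groups is computed gene-wise
with Welch's unequal-variance t-test on log2 expression; the log2 fold change
is the plain mean difference (contrast group minus reference, configurable).
p-values are corrected with the Benjamini-Hochberg step-up procedure and genes
are ranked by adjusted p (ties: raw p, then gene id) — the ranking consumed by
the top-100 DEG feature-selection route.

For functional readouts the module also provides a Mann-Whitney U test with
exact small-sample enumeration (tie-aware) and a tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_t",
    "mann_whitney",
    "bh_adjust",
    "differential_expression",
]


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's t statistic with Satterthwaite df and two-sided p.

    Returns ``(t, df, p)``.  If both samples are constant: equal means give
    (0, df, 1); different means are a degenerate-variance error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >=2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate variance: both samples constant with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (for sample ``a``) with two-sided p.

    Exact enumeration over all label assignments when n_a + n_b <= 12
    (midranks, so ties are handled); otherwise a normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    n = na + nb
    if n <= 12:
        pooled = np.concatenate([a, b])
        mu = na * nb / 2
        total = comb(n, na)
        extreme = 0
        dev = abs(u - mu)
        for idx in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= dev - 1e-12:
                extreme += 1
        return u, extreme / total
    pooled = np.concatenate([a, b])
    mu = na * nb / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = na * nb / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return u, float(min(1.0, 2 * stats.norm.sf(z)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    x: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("AMI", "control"),
    column: str = "group",
) -> pd.DataFrame:
    """Gene-wise Welch t contrast with BH correction and deterministic ranks.

    Parameters
    ----------
    x
        genes x samples log2 expression.
    meta
        sample metadata indexed by sample id with a ``column`` label.
    contrast
        ``(A, B)``: log2FC = mean(A) - mean(B) (contrast minus reference).

    Returns a DataFrame indexed by gene with columns ``log2FC, p, p_adj, rank``
    plus ``contrast`` metadata in ``df.attrs``.
    """
    group_a, group_b = contrast
    labels = meta.loc[x.columns, column]
    cols_a = x.columns[(labels == group_a).to_numpy()]
    cols_b = x.columns[(labels == group_b).to_numpy()]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"contrast groups need >=2 samples (got {len(cols_a)}, {len(cols_b)})")
    a = x[cols_a].to_numpy()
    b = x[cols_b].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        if (np.abs(lfc[degenerate]) > 0).any():
            bad = x.index[degenerate & (np.abs(lfc) > 0)][0]
            raise ValueError(f"degenerate variance for gene {bad!r}")
        p[degenerate] = 1.0
    out = pd.DataFrame({"log2FC": lfc, "p": p, "p_adj": bh_adjust(p)}, index=x.index)
    order = out.assign(_gene=out.index.astype(str)).sort_values(
        ["p_adj", "p", "_gene"], kind="mergesort"
    )
    out.loc[order.index, "rank"] = np.arange(1, len(out) + 1)
    out["rank"] = out["rank"].astype(int)
    out.attrs["contrast"] = f"{group_a}-minus-{group_b}"
    return out
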