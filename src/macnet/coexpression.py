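"""Weighted co-expression network analysis core.

Implements the standard WGCNA chain: soft-threshold selection against a
scale-free topology criterion, unsigned adjacency ``|cor|^beta``, the
topological overlap measure (TOM), average-linkage module detection on
``1 - TOM`` with a static branch cut, module eigengenes (first principal
component of the standardized member submatrix) and eigengene merging, and
Pearson module-trait correlation with Student asymptotic p-values corrected
by Benjamini-Hochberg within each trait.

Genes that fall in no co-expression cluster are collected in the
``UNASSIGNED`` pseudo-module (the analogue of the "not coexpressed" catch-all
module); it is excluded from eigengene computation and trait correlation
unless requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexp import bh_adjust

__all__ = [
    "UNASSIGNED",
    "SoftThresholdReport",
    "ModuleSet",
    "scale_free_fit_index",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "module_eigengene",
    "detect_modules",
    "module_trait_correlation",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class SoftThresholdReport:
    """Scale-free fit and mean connectivity per candidate power."""

    table: pd.DataFrame  # columns: power, fit_index, mean_connectivity
    chosen_power: int
    target_fit: float


@dataclass
class ModuleSet:
    """Gene->module assignment plus module eigengenes (modules x samples)."""

    assignment: pd.Series
    eigengenes: pd.DataFrame
    power: int

    @property
    def labels(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    def sizes(self, include_unassigned: bool = True) -> pd.Series:
        counts = self.assignment.value_counts()
        if not include_unassigned:
            counts = counts.drop(UNASSIGNED, errors="ignore")
        return counts

    def members(self, label: str) -> pd.Index:
        return self.assignment.index[self.assignment == label]


def scale_free_fit_index(degrees, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) on log10(mean degree) over equal-width bins.

    The scale-free fitting index of a degree (connectivity) distribution.
    """
    k = np.asarray(degrees, dtype=float)
    if (k < 0).any():
        raise ValueError("degrees must be nonnegative")
    pos = k[k > 0]
    if np.unique(pos).size < 2:
        raise ValueError("degenerate degree distribution: need >=2 distinct positive degrees")
    edges = np.linspace(pos.min(), pos.max(), n_bins + 1)
    idx = np.clip(np.digitize(pos, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        log_freq.append(np.log10(sel.mean()))
        log_k.append(np.log10(pos[sel].mean()))
    if len(log_k) < 2 or np.allclose(log_k, log_k[0]) or np.allclose(log_freq, log_freq[0]):
        raise ValueError("degenerate degree distribution: <2 occupied bins")
    r = stats.pearsonr(log_k, log_freq).statistic
    return float(r * r)


def _abs_cor(x: pd.DataFrame) -> np.ndarray:
    vals = x.to_numpy()
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = x.index[sd == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}")
    return np.abs(np.corrcoef(vals))


def adjacency(x: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned adjacency ``|cor(i,j)|^power`` with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    a = _abs_cor(x) ** power
    np.fill_diagonal(a, 0.0)
    return np.clip(a, 0.0, 1.0)


def pick_soft_threshold(
    x: pd.DataFrame,
    powers=range(1, 21),
    target_fit: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Choose the smallest power achieving the target scale-free fit.

    Falls back to the fit-maximizing power when no candidate reaches the
    target (e.g., pure noise input).
    """
    if x.shape[1] < 10:
        raise ValueError("need >=10 samples for soft-threshold selection")
    powers = list(powers)
    c = _abs_cor(x)
    np.fill_diagonal(c, 0.0)
    rows = []
    for beta in powers:
        a = c**beta
        k = a.sum(axis=0)
        try:
            fit = scale_free_fit_index(k, n_bins=n_bins)
        except ValueError:
            fit = np.nan
        rows.append({"power": beta, "fit_index": fit, "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["fit_index"] >= target_fit]
    if len(ok):
        chosen = int(ok["power"].iloc[0])
    else:
        chosen = int(table.loc[table["fit_index"].idxmax(), "power"])
    return SoftThresholdReport(table=table, chosen_power=chosen, target_fit=target_fit)


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any() or np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency entries must be in [0,1] with zero diagonal")
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(x: pd.DataFrame, members) -> pd.Series:
    """First principal component of the z-scored member submatrix.

    Unit-norm over samples; sign oriented so that its correlation with the
    module's mean expression profile is nonnegative.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    sub = x.loc[members].to_numpy()
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance member gene")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=x.columns)


def _merge_eigengenes(
    x: pd.DataFrame, modules: dict[str, list[str]], merge_cor: float
) -> dict[str, list[str]]:
    modules = {k: list(v) for k, v in modules.items()}
    while len(modules) > 1:
        labels = sorted(modules)
        eigs = np.vstack([module_eigengene(x, modules[lab]).to_numpy() for lab in labels])
        c = np.corrcoef(eigs)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= merge_cor:
            break
        keep, drop = sorted([labels[i], labels[j]])
        modules[keep] = modules[keep] + modules[drop]
        del modules[drop]
    return modules


def detect_modules(
    x: pd.DataFrame,
    power: int,
    min_size: int = 30,
    merge_cor: float = 0.75,
    cut_fraction: float = 0.99,
    include_unassigned_eigengene: bool = False,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    Branches are cut at ``cut_fraction`` x the maximum merge height; clusters
    below ``min_size`` go to UNASSIGNED; modules whose eigengenes correlate
    above ``merge_cor`` are merged iteratively (most correlated pair first).
    Labels M1..Mk are assigned by decreasing module size.
    """
    genes = x.index
    if len(genes) < min_size:
        warnings.warn("fewer genes than min_size: all genes UNASSIGNED")
        assignment = pd.Series(UNASSIGNED, index=genes)
        return ModuleSet(assignment=assignment, eigengenes=pd.DataFrame(columns=x.columns), power=power)
    a = adjacency(x, power)
    tom = topological_overlap(a)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    cut = cut_fraction * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")
    modules: dict[str, list[str]] = {}
    for cl in np.unique(raw):
        members = list(genes[raw == cl])
        if len(members) >= min_size:
            modules[f"tmp{cl}"] = members
    if modules:
        modules = _merge_eigengenes(x, modules, merge_cor)
        modules = {k: v for k, v in modules.items() if len(v) >= min_size}
    # relabel by decreasing size, ties by smallest first gene id
    ordered = sorted(modules.values(), key=lambda mem: (-len(mem), sorted(mem)[0]))
    assignment = pd.Series(UNASSIGNED, index=genes, dtype=object)
    final: dict[str, list[str]] = {}
    for i, mem in enumerate(ordered, start=1):
        final[f"M{i}"] = mem
        assignment.loc[mem] = f"M{i}"
    eig_labels = list(final)
    if include_unassigned_eigengene and (assignment == UNASSIGNED).any():
        final[UNASSIGNED] = list(genes[assignment == UNASSIGNED])
        eig_labels.append(UNASSIGNED)
    eigs = pd.DataFrame(
        [module_eigengene(x, final[lab]).to_numpy() for lab in eig_labels],
        index=eig_labels,
        columns=x.columns,
    )
    return ModuleSet(assignment=assignment, eigengenes=eigs, power=power)


def _pearson_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def module_trait_correlation(
    modules: ModuleSet,
    traits: pd.DataFrame,
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each clinical trait.

    p-values from the Student asymptotic formula t = r sqrt(n-2)/sqrt(1-r^2);
    BH adjustment is applied across modules separately within each trait.
    """
    eig = modules.eigengenes
    if not include_unassigned:
        eig = eig.drop(index=UNASSIGNED, errors="ignore")
    common = [s for s in eig.columns if s in traits.index]
    if len(common) < 4:
        raise ValueError("need >=4 shared samples between eigengenes and traits")
    eig = eig[common]
    tr = traits.loc[common]
    rows = []
    n = len(common)
    for trait in tr.columns:
        tvals = tr[trait].to_numpy()
        if tvals.std(ddof=1) == 0:
            raise ValueError(f"constant trait {trait!r}")
        ps = []
        for mod in eig.index:
            r = float(np.corrcoef(eig.loc[mod].to_numpy(), tvals)[0, 1])
            p = _pearson_p(r, n)
            ps.append(p)
            rows.append({"module": mod, "trait": trait, "r": r, "p": p})
        padj = bh_adjust(ps)
        for k, mod in enumerate(eig.index):
            rows[len(rows) - len(eig.index) + k]["p_adj"] = padj[k]
    return pd.DataFrame(rows)
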