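"""Feature selection (mRMR, MIC, top DEGs), ordination and classification.

The discriminative gene signature is the intersection of three top-k lists:
greedy minimum-redundancy-maximum-relevance selection (MID difference
criterion on plug-in mutual information), the maximal information
coefficient against the phenotype, and the adjusted-p ranking of the
differential-expression table.  Classification performance is measured by
ROC AUC and accuracy under repeated stratified k-fold cross-validation with
a native L2-regularized logistic model trained by gradient descent; external
classifiers plug in through a fit/score contract.  Feature contribution is
ranked by permutation importance (mean held-out AUC drop).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .grn import _mi_rows, n_bins_for, rank_bin

__all__ = [
    "FeatureSelectionResult",
    "CVReport",
    "LogisticGD",
    "mrmr_select",
    "mic",
    "mic_top",
    "deg_top",
    "intersect_signature",
    "auc",
    "stratified_cv_evaluate",
    "permutation_importance",
    "pca_scores",
    "plsda_scores",
]


# ---------------------------------------------------------------------------
# mutual-information feature selection


def _label_codes(labels) -> np.ndarray:
    codes = np.unique(np.asarray(labels), return_inverse=True)[1]
    if codes.max() < 1:
        raise ValueError("labels must contain two classes")
    return codes.astype(np.int64)


def mrmr_select(x: pd.DataFrame, labels, k: int = 100) -> list[str]:
    """Greedy mRMR (difference criterion) gene selection.

    The first gene maximizes MI(gene, label); each subsequent gene maximizes
    MI(gene, label) minus the mean MI with the already-selected genes.
    Ties break by lexicographic gene id.
    """
    if k > len(x):
        raise ValueError("k exceeds the number of genes")
    codes = _label_codes(labels)
    n = x.shape[1]
    nb = n_bins_for(n)
    vals = x.to_numpy()
    binned = np.vstack([rank_bin(row, nb) for row in vals])
    n_classes = int(codes.max()) + 1
    relevance = _mi_rows(binned, codes, nb, n_classes)
    genes = np.asarray(x.index)
    gene_rank = np.argsort(np.argsort(genes, kind="stable"), kind="stable")
    avail = np.ones(len(genes), dtype=bool)
    red_sum = np.zeros(len(genes))
    selected: list[int] = []
    for step in range(k):
        score = relevance if not selected else relevance - red_sum / len(selected)
        masked = np.where(avail, score, -np.inf)
        best = masked.max()
        ties = np.nonzero(masked >= best - 1e-15)[0]
        pick = ties[np.argmin(gene_rank[ties])]
        selected.append(pick)
        avail[pick] = False
        if step < k - 1:
            red_sum += _mi_rows(binned, binned[pick], nb, nb)
    return [str(g) for g in genes[selected]]


# ---------------------------------------------------------------------------
# maximal information coefficient


def _equipartition(v: np.ndarray, q: int) -> np.ndarray:
    """Equal-frequency row assignment keeping tied values together."""
    n = len(v)
    order = np.argsort(v, kind="stable")
    vs = v[order]
    assign = np.empty(n, dtype=np.int64)
    current = 0
    i = 0
    while i < n:
        j = i
        while j < n and vs[j] == vs[i]:
            j += 1
        assign[i:j] = current
        if j >= (current + 1) * n / q - 0.5 and current < q - 1:
            current += 1
        i = j
    rows = np.empty(n, dtype=np.int64)
    rows[order] = assign
    return rows


def _clump_counts(u: np.ndarray, rows: np.ndarray, q: int, max_clumps: int) -> np.ndarray:
    """Per-clump row-count vectors, tied u-values merged, capped at max_clumps."""
    order = np.argsort(u, kind="stable")
    us = u[order]
    rs = rows[order]
    n = len(u)
    clumps: list[np.ndarray] = []
    i = 0
    while i < n:
        j = i
        while j < n and us[j] == us[i]:
            j += 1
        clumps.append(np.bincount(rs[i:j], minlength=q))
        i = j
    if len(clumps) > max_clumps:
        target = n / max_clumps
        merged: list[np.ndarray] = []
        acc = np.zeros(q, dtype=np.int64)
        total = 0
        for c in clumps:
            acc = acc + c
            total += c.sum()
            if total >= (len(merged) + 1) * target - 0.5:
                merged.append(acc)
                acc = np.zeros(q, dtype=np.int64)
        if acc.sum():
            merged.append(acc)
        clumps = merged
    return np.asarray(clumps)


def _optimize_axis(
    clump_counts: np.ndarray, n: int, max_cols: int
) -> np.ndarray:
    """Max MI over partitions of the clumped axis into 2..max_cols columns.

    Exact interval dynamic program over clump boundaries: MI decomposes as
    H(rows) + sum over columns of [p_cr log p_cr - p_c log p_c] terms.
    """
    k, q = clump_counts.shape
    cum = np.vstack([np.zeros(q, dtype=np.int64), np.cumsum(clump_counts, axis=0)])
    row_p = cum[-1] / n
    h_rows = -np.sum(row_p[row_p > 0] * np.log(row_p[row_p > 0]))
    # G[s, t]: column term for a column made of clumps (s, t]
    G = np.full((k + 1, k + 1), -np.inf)
    for t in range(1, k + 1):
        counts = cum[t][None, :] - cum[:t]  # (t, q)
        nc = counts.sum(axis=1)
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            joint = np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        pc = nc / n
        marg = np.where(pc > 0, pc * np.log(pc), 0.0)
        G[:t, t] = joint - marg
    D = np.full((max_cols + 1, k + 1), -np.inf)
    D[0, 0] = 0.0
    best = np.zeros(max_cols + 1)
    for l in range(1, max_cols + 1):
        cand = D[l - 1][:, None] + G
        D[l] = np.max(cand, axis=0)
        best[l] = h_rows + D[l, k] if np.isfinite(D[l, k]) else 0.0
    return np.maximum(best, 0.0)


def mic(
    x,
    y,
    alpha: float = 0.6,
    max_cells_cap: int | None = None,
    max_axis: int | None = None,
    c_factor: int = 15,
) -> float:
    """Maximal information coefficient of two samples.

    Searches all grids with ``rows * cols <= cap`` (default
    ``max(4, floor(n^alpha))``): one axis equipartitioned, the other
    optimized exactly by dynamic programming over clump boundaries; the MI of
    each grid is normalized by ``log(min(rows, cols))`` and the maximum over
    grids and both axis orientations is returned.  Constant input gives 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 10:
        raise ValueError("MIC needs n >= 10")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return 0.0
    cap = max_cells_cap if max_cells_cap is not None else max(4, int(np.floor(n**alpha)))
    best = 0.0
    for u, v in ((x, y), (y, x)):
        q_hi = min(cap // 2, np.unique(v).size)
        if max_axis is not None:
            q_hi = min(q_hi, max_axis)
        for q in range(2, q_hi + 1):
            rows = _equipartition(v, q)
            q_eff = int(rows.max()) + 1
            if q_eff < 2:
                continue
            max_cols = cap // q_eff
            if max_axis is not None:
                max_cols = min(max_cols, max_axis)
            if max_cols < 2:
                continue
            counts = _clump_counts(u, rows, q_eff, max(max_clumps := c_factor * max_cols, 2))
            mis = _optimize_axis(counts, n, max_cols)
            for l in range(2, max_cols + 1):
                norm = np.log(min(q_eff, l))
                best = max(best, mis[l] / norm)
    return float(min(best, 1.0))


def mic_top(x: pd.DataFrame, labels, k: int = 100, alpha: float = 0.6) -> list[str]:
    """Genes ranked by MIC against the phenotype, top k (ties by gene id)."""
    y = np.unique(np.asarray(labels), return_inverse=True)[1].astype(float)
    scored = [(-mic(x.loc[g].to_numpy(), y, alpha=alpha), str(g)) for g in x.index]
    scored.sort()
    return [g for _, g in scored[:k]]


def deg_top(de: pd.DataFrame, k: int = 100) -> list[str]:
    """Top-k genes of a differential-expression table by its rank column."""
    return [str(g) for g in de.sort_values("rank").index[:k]]


@dataclass
class FeatureSelectionResult:
    mrmr_top: list[str]
    mic_top: list[str]
    deg_top: list[str]

    @property
    def intersection(self) -> set[str]:
        return set(self.mrmr_top) & set(self.mic_top) & set(self.deg_top)


def intersect_signature(fs: FeatureSelectionResult) -> pd.DataFrame:
    """Intersection of the three top lists with per-list ranks."""
    import warnings

    inter = sorted(fs.intersection)
    if not inter:
        warnings.warn("feature-selection lists have empty intersection")
    rows = [
        {
            "gene": g,
            "mrmr_rank": fs.mrmr_top.index(g) + 1,
            "mic_rank": fs.mic_top.index(g) + 1,
            "deg_rank": fs.deg_top.index(g) + 1,
        }
        for g in inter
    ]
    return pd.DataFrame(rows, columns=["gene", "mrmr_rank", "mic_rank", "deg_rank"])


# ---------------------------------------------------------------------------
# classification


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == labels.max()
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0 or len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class LogisticGD:
    """L2-regularized logistic classifier trained by plain gradient descent.

    Features are standardized internally; the intercept is unpenalized.  The
    step size is set from the Lipschitz constant of the penalized loss, so
    training is deterministic.
    """

    def __init__(self, l2: float = 1.0, max_iter: int = 2000, tol: float = 1e-8):
        self.l2 = l2
        self.max_iter = max_iter
        self.tol = tol

    def _standardize(self, X):
        return (X - self.mean_) / self.sd_

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        Z = self._standardize(X)
        n, p = Z.shape
        Zb = np.hstack([np.ones((n, 1)), Z])
        w = np.zeros(p + 1)
        lam = np.zeros(p + 1)
        lam[1:] = self.l2
        lipschitz = np.linalg.norm(Zb, 2) ** 2 / (4 * n) + self.l2
        step = 1.0 / lipschitz
        for _ in range(self.max_iter):
            pred = 1.0 / (1.0 + np.exp(-Zb @ w))
            grad = Zb.T @ (pred - y) / n + lam * w
            w -= step * grad
            if np.linalg.norm(grad) < self.tol:
                break
        self.coef_ = w
        return self

    def score_samples(self, X):
        Z = self._standardize(np.asarray(X, dtype=float))
        Zb = np.hstack([np.ones((len(Z), 1)), Z])
        return 1.0 / (1.0 + np.exp(-Zb @ self.coef_))


@dataclass
class CVReport:
    """Per-fold AUC/accuracy of repeated stratified cross-validation."""

    table: pd.DataFrame  # columns: repeat, fold, auc, accuracy
    n_folds: int
    n_repeats: int
    seed_list: list[int]

    def summary(self) -> dict[str, float]:
        return {
            "auc_mean": float(self.table["auc"].mean()),
            "auc_sd": float(self.table["auc"].std(ddof=1)),
            "accuracy_mean": float(self.table["accuracy"].mean()),
            "accuracy_sd": float(self.table["accuracy"].std(ddof=1)),
        }


def _as_binary(labels) -> np.ndarray:
    return np.unique(np.asarray(labels), return_inverse=True)[1]


def stratified_cv_evaluate(
    x,
    labels,
    classifier_factory=None,
    n_folds: int = 5,
    n_repeats: int = 10,
    base_seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV; repeat r is seeded ``base_seed + r``.

    ``classifier_factory()`` must return an object with ``fit(X, y)`` and
    ``score_samples(X)`` (probability-like scores); the default is the native
    logistic model.  Accuracy thresholds scores at 0.5.
    """
    X = np.asarray(x, dtype=float)
    y = _as_binary(labels)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds members")
    factory = classifier_factory or LogisticGD
    rows = []
    seeds = [base_seed + r for r in range(n_repeats)]
    for r, seed in enumerate(seeds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for f, (train, test) in enumerate(skf.split(X, y)):
            clf = factory()
            clf.fit(X[train], y[train])
            scores = clf.score_samples(X[test])
            rows.append(
                {
                    "repeat": r,
                    "fold": f,
                    "auc": auc(scores, y[test]),
                    "accuracy": float(((scores >= 0.5).astype(int) == y[test]).mean()),
                }
            )
    return CVReport(table=pd.DataFrame(rows), n_folds=n_folds, n_repeats=n_repeats, seed_list=seeds)


def permutation_importance(
    x,
    labels,
    classifier_factory=None,
    n_perms: int = 20,
    n_folds: int = 5,
    seed: int = 0,
    feature_names=None,
) -> pd.Series:
    """Mean held-out AUC drop when each feature's column is permuted.

    Raw (unnormalized) importances per feature, averaged over stratified
    folds and ``n_perms`` permutations.
    """
    X = np.asarray(x, dtype=float)
    y = _as_binary(labels)
    if feature_names is None:
        feature_names = (
            list(x.columns) if isinstance(x, pd.DataFrame) else [f"f{i}" for i in range(X.shape[1])]
        )
    factory = classifier_factory or LogisticGD
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    drops = np.zeros(X.shape[1])
    n_folds_done = 0
    for train, test in skf.split(X, y):
        clf = factory()
        clf.fit(X[train], y[train])
        base = auc(clf.score_samples(X[test]), y[test])
        for j in range(X.shape[1]):
            perm_aucs = []
            for _ in range(n_perms):
                Xp = X[test].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                perm_aucs.append(auc(clf.score_samples(Xp), y[test]))
            drops[j] += base - float(np.mean(perm_aucs))
        n_folds_done += 1
    return pd.Series(drops / n_folds_done, index=feature_names, name="importance")


# ---------------------------------------------------------------------------
# ordination


def pca_scores(x, n_components: int = 2, scale: bool = False) -> np.ndarray:
    """Principal-component sample scores from the SVD of centered data."""
    X = np.asarray(x, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 features")
    Z = X - X.mean(axis=0)
    if scale:
        sd = Z.std(axis=0, ddof=1)
        Z = Z / np.where(sd == 0, 1.0, sd)
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    return u[:, :n_components] * s[:n_components]


def plsda_scores(x, labels, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PLS-DA sample scores and X weights against a 0/1 response.

    NIPALS partial least squares on centered, unit-scaled features; returns
    ``(scores, weights)`` with scores per sample per component.
    """
    X = np.asarray(x, dtype=float)
    y = _as_binary(labels).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y)
    return pls.x_scores_, pls.x_weights_
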