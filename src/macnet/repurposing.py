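"""Connectivity-map style drug repurposing against an up/down signature.

A query signature (up- and down-regulated genes from differential expression
within selected co-expression modules) is scored against each perturbation
profile with the two-sided Kolmogorov-Smirnov enrichment statistic: profiles
are ranked by differential z-score, the up and down tag sets each get an
enrichment score, and the connectivity ``c = ES_up - ES_down`` (zeroed when
both enrichments share a sign) is rescaled within the database so the most
extreme scores are +/-1.  A score near -1 marks a profile that reverses the
signature — the repurposing candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import ModuleSet

__all__ = [
    "Signature",
    "build_signature",
    "ks_enrichment",
    "connectivity_scores",
    "candidate_filter",
    "META_COLUMNS",
]

META_COLUMNS = ["drug", "cell_type", "dose", "duration"]


@dataclass
class Signature:
    """Ordered up/down gene lists (by decreasing |log2FC|), disjoint."""

    up: list[str]
    down: list[str]

    def __post_init__(self):
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up/down overlap: {sorted(overlap)[:3]}")

    def to_gmt(self) -> dict[str, list[str]]:
        # an empty side is omitted (a member-less GMT line would be malformed)
        sets = {"SIG_UP": list(self.up), "SIG_DOWN": list(self.down)}
        return {k: v for k, v in sets.items() if v}

    @classmethod
    def from_gmt(cls, sets) -> "Signature":
        return cls(up=list(sets.get("SIG_UP", [])), down=list(sets.get("SIG_DOWN", [])))


def build_signature(
    de: pd.DataFrame, modules: ModuleSet, keep, alpha: float = 0.05
) -> Signature:
    """Signature from significant DE genes of the kept modules.

    Genes assigned to ``keep`` with ``p_adj < alpha`` are split by log2FC sign
    and ordered by decreasing |log2FC| (ties by gene id).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must name at least one module")
    in_kept = de.index[de.index.map(modules.assignment).isin(keep)]
    sub = de.loc[in_kept]
    sig = sub[(sub["p_adj"] < alpha) & (sub["log2FC"] != 0)].copy()
    if sig.empty:
        raise ValueError("no signature genes (all adjusted p above alpha)")
    sig["absfc"] = sig["log2FC"].abs()
    sig["_gene"] = sig.index.astype(str)
    sig = sig.sort_values(["absfc", "_gene"], ascending=[False, True], kind="mergesort")
    up = list(sig.index[sig["log2FC"] > 0])
    down = list(sig.index[sig["log2FC"] < 0])
    if not up and not down:
        raise ValueError("no signature genes")
    return Signature(up=up, down=down)


def ks_enrichment(tags, ranked_list) -> float:
    """Kolmogorov-Smirnov enrichment of a tag set in an ordered gene list.

    With t tags at ascending ranks V(1..t) in a list of length N:
    ``a = max_j(j/t - V(j)/N)``, ``b = max_j(V(j)/N - (j-1)/t)``; returns
    ``a`` if ``a > b`` else ``-b``.
    """
    tags = set(tags)
    if not tags:
        raise ValueError("empty tag set")
    positions = [i + 1 for i, g in enumerate(ranked_list) if g in tags]
    if len(positions) != len(tags):
        raise ValueError("tags must all be members of the ranked list")
    t = len(positions)
    n = len(ranked_list)
    j = np.arange(1, t + 1)
    v = np.asarray(positions, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def connectivity_scores(signature: Signature, db: pd.DataFrame) -> pd.DataFrame:
    """Score every perturbation profile against the signature.

    ``db`` has metadata columns ``drug, cell_type, dose, duration`` and one
    column per gene holding differential z-scores.  Per profile, genes are
    ranked by z descending (ties by gene id); connectivity
    ``c = ES_up - ES_down`` when the two enrichments disagree in sign (or one
    is zero), else 0; scores ``s`` rescale positive c by the maximum positive
    c and negative c by the magnitude of the most negative c.
    """
    if db.empty:
        raise ValueError("empty perturbation database")
    gene_cols = [c for c in db.columns if c not in META_COLUMNS]
    universe = set(gene_cols)
    up = [g for g in signature.up if g in universe]
    down = [g for g in signature.down if g in universe]
    if len(up) < len(signature.up) or len(down) < len(signature.down):
        warnings.warn("signature genes missing from perturbation universe were dropped")
    if not up or not down:
        raise ValueError("signature empty after restricting to the profile universe")
    genes = np.array(gene_cols)
    z = db[gene_cols].to_numpy(dtype=float)
    # rank by z descending, ties by gene id ascending
    gene_order = np.argsort(genes, kind="stable")
    rows = []
    for i in range(len(db)):
        zi = z[i][gene_order]
        order = gene_order[np.argsort(-zi, kind="stable")]
        ranking = genes[order]
        es_up = ks_enrichment(up, ranking)
        es_down = ks_enrichment(down, ranking)
        if es_up * es_down < 0 or es_up == 0 or es_down == 0:
            c = es_up - es_down
        else:
            c = 0.0
        rows.append({"ES_up": es_up, "ES_down": es_down, "c": c})
    out = pd.concat([db[META_COLUMNS].reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    c = out["c"].to_numpy()
    s = np.zeros(len(c))
    pos, neg = c[c > 0], c[c < 0]
    if len(pos):
        s[c > 0] = c[c > 0] / pos.max()
    if len(neg):
        s[c < 0] = c[c < 0] / abs(neg.min())
    out["s"] = s
    out["candidate"] = False
    return out


def candidate_filter(results: pd.DataFrame, cutoff: float = -0.60) -> pd.DataFrame:
    """Flag reversal candidates (s <= cutoff) and sort most-negative first."""
    out = results.copy()
    out["candidate"] = out["s"] <= cutoff
    return out.sort_values(["s", "drug"], kind="mergesort").reset_index(drop=True)
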