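"""Regulatory-score driver ranking on a module-restricted subnetwork.

The regulatory score (RS) of a transcription factor within a module is the
sum over its in-module targets of edge weight times the target's absolute
log2 fold change; the top 1% of TFs relative to each module's size (at least
one) are flagged as candidate drivers.
"""

from __future__ import annotations

import math
import warnings

import pandas as pd

from .coexpression import ModuleSet
from .grn import RegulatoryNetwork

__all__ = ["restrict_subnetwork", "regulatory_scores", "select_top_regulators"]


def restrict_subnetwork(network: RegulatoryNetwork, modules: ModuleSet, keep) -> RegulatoryNetwork:
    """Keep only edges whose *target* is assigned to one of the kept modules.

    The candidate-regulator list is unchanged.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must name at least one module")
    unknown = keep - set(modules.assignment.unique())
    if unknown:
        raise ValueError(f"unknown module labels: {sorted(unknown)}")
    target_mod = network.edges["target"].map(modules.assignment)
    kept = network.edges[target_mod.isin(keep)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("no edges target the kept modules")
    return RegulatoryNetwork(edges=kept, tf_list=set(network.tf_list), scale_free_fit=network.scale_free_fit)


def regulatory_scores(
    network: RegulatoryNetwork, de: pd.DataFrame, modules: ModuleSet
) -> pd.DataFrame:
    """Per-(TF, module) regulatory score RS = sum_t w(tf,t) * |log2FC(t)|.

    ``de`` is a differential-expression table indexed by gene with a
    ``log2FC`` column; every network target must have an entry.
    """
    edges = network.edges
    missing = set(edges["target"]) - set(de.index)
    if missing:
        raise ValueError(f"target missing from DE table: {sorted(missing)[0]!r}")
    work = edges.copy()
    work["module"] = work["target"].map(modules.assignment)
    work["abs_lfc"] = work["target"].map(de["log2FC"]).abs()
    work["contrib"] = work["weight"] * work["abs_lfc"]
    grouped = work.groupby(["regulator", "module"], sort=True).agg(
        RS=("contrib", "sum"),
        n_targets=("target", "count"),
        total_weight=("weight", "sum"),
    )
    out = grouped.reset_index().rename(columns={"regulator": "tf"})
    out["selected"] = False
    return out


def select_top_regulators(
    scores: pd.DataFrame, modules: ModuleSet, fraction: float = 0.01
) -> pd.DataFrame:
    """Flag the top-``fraction`` TFs per module (by RS) as selected drivers.

    Per module, ``n_sel = max(1, ceil(fraction * module_size))``; ties break
    by larger total edge weight, then lexicographic TF id.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    sizes = modules.sizes()
    out = scores.copy()
    out["selected"] = False
    for mod, grp in out.groupby("module"):
        if grp.empty:
            warnings.warn(f"module {mod} has no scored TFs")
            continue
        n_sel = max(1, math.ceil(fraction * int(sizes.get(mod, 0))))
        ranked = grp.sort_values(
            ["RS", "total_weight", "tf"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        out.loc[ranked.index[:n_sel], "selected"] = True
    return out
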