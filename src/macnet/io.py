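"""Readers/writers for the pipeline's file formats and functional-data z-scoring.

Conventions
-----------
Expression matrices are :class:`pandas.DataFrame` objects with genes as the
index and samples as the columns, on a log2 scale.  Sample metadata, clinical
traits and functional (high-content screening) profiles are DataFrames indexed
by sample id.  Gene sets are ``dict[str, list[str]]`` read from / written to
standard GMT.  Regulatory networks travel as TSV edge lists.
"""

from __future__ import annotations

import sys
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_sample_meta",
    "write_sample_meta",
    "read_traits",
    "write_traits",
    "read_functional",
    "write_functional",
    "read_gmt",
    "write_gmt",
    "read_tf_list",
    "read_edge_list",
    "write_edge_list",
    "zscore_by_readout",
    "load_config",
    "log_params",
]


class FormatError(ValueError):
    """Malformed input file (missing value, duplicate id, non-numeric cell)."""


def _check_matrix(df: pd.DataFrame, path) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate column id {dup!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise FormatError(f"{path}: missing or non-numeric value at row {row!r}, column {col!r}")


def read_expression(path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a TSV expression matrix; always returned genes x samples.

    ``orientation`` declares how the *file* is laid out; the result is
    transposed to genes x samples if necessary.  Ids are preserved verbatim.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    _check_matrix(df, path)
    if orientation == "samples_by_genes":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene"
    df.columns.name = "sample"
    return df.astype(float)


def write_expression(x: pd.DataFrame, path) -> None:
    x.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_sample_meta(path) -> pd.DataFrame:
    """Sample metadata TSV: columns sample, group, subgroup, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    for col in ("group", "subgroup", "sex"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample id")
    bad = df[(df["subgroup"] != "none") & (df["group"] != "AMI")]
    if len(bad):
        raise FormatError(f"{path}: subgroup set for non-AMI sample {bad.index[0]!r}")
    return df


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    _check_matrix(df, path)
    if not np.isfinite(df.to_numpy()).all():
        raise FormatError(f"{path}: non-finite trait value")
    return df.astype(float)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="sample", float_format="%.10g")


def read_functional(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    _check_matrix(df, path)
    return df.astype(float)


def write_functional(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name, description, tab-separated members.

    Members are de-duplicated preserving first occurrence; duplicate set
    names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_tf_list(path) -> list[str]:
    """One gene symbol per line; blank lines ignored; order preserved."""
    with open(path) as fh:
        return list(dict.fromkeys(ln.strip() for ln in fh if ln.strip()))


def write_edge_list(network, path) -> None:
    """Write a regulatory network as a TSV of regulator, target, weight, support."""
    edges = network.edges if hasattr(network, "edges") else network
    edges = edges[["regulator", "target", "weight", "support"]]
    edges.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_edge_list(path):
    from .grn import RegulatoryNetwork

    edges = pd.read_csv(
        path, sep="\t", dtype={"regulator": str, "target": str, "weight": float, "support": float}
    )
    for col in ("regulator", "target", "weight", "support"):
        if col not in edges.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return RegulatoryNetwork(edges=edges, tf_list=set(edges["regulator"]), scale_free_fit=float("nan"))


def zscore_by_readout(profiles: pd.DataFrame) -> pd.DataFrame:
    """z-transform each functional readout (column) separately, sample sd (n-1).

    Idempotent up to floating error; a zero-variance readout is an error.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = profiles.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero variance readout: {zero.index[0]!r}")
    return (profiles - profiles.mean(axis=0)) / sd


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg


def log_params(command: str, **params) -> None:
    """Log a command's parameters (including seeds) to stderr."""
    rendered = " ".join(f"{k}={v}" for k, v in params.items())
    print(f"[macnet] {command}: {rendered}", file=sys.stderr)
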