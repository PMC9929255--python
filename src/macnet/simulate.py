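"""Synthetic discovery-cohort generator with known ground truth.

A linear-Gaussian factor model stands in for the serum-stimulation cohort:
each planted co-expression module m has a latent per-sample factor
``f_m ~ N(0,1)`` shifted by ``group_shift_m`` in AMI samples and by
``subgroup_shift_m`` in the large-infarct subgroup.  Module genes load on
their factor (``x_i = lambda_i f_m + noise``), a planted transcription
factor per module tracks the factor directly, clinical traits are
correlation-calibrated linear functions of chosen factors, functional
readouts mix the group-shifted factors, and background genes are pure
noise.  The same truth object records module membership, regulators, trait
couplings and (once a perturbation database is drawn) the planted
signature-reversing drugs, so every pipeline stage has a recovery oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .repurposing import Signature

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_perturbation_db",
    "true_signature",
    "READOUTS",
]

READOUTS = [
    "phagocytosis",
    "lipid_uptake",
    "apoptosis",
    "hypertrophy",
    "morphology",
    "actin_stress",
    "granularity",
    "inflammasome",
    "cytokines",
]

BACKGROUND = "background"


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults define the emulated study design.

    Cohort sizes mirror the discovery cohort (47 AMI of which 23 small- and
    24 large-infarct, 20 controls).  Shifts are in units of factor SD.
    """

    n_genes: int = 2000
    n_ami: int = 47
    n_ctrl: int = 20
    n_small: int = 23
    n_large: int = 24
    n_modules: int = 5
    module_sizes: tuple = (200, 120, 70, 40, 30)
    loading_range: tuple = (0.3, 0.95)
    group_shift: tuple = (1.0, 1.0, 1.0, 0.0, 0.0)
    subgroup_shift: tuple = (0.0, 0.0, 0.0, 1.5, -1.5)
    trait_couplings: dict = field(
        default_factory=lambda: {
            3: ("infarct_size", 0.6),
            4: ("ejection_fraction", -0.6),
            2: ("end_diastolic_volume", 0.5),
        }
    )
    n_tfs: int = 5
    targets_per_tf: int | None = None
    tf_signal: float = 2.0
    n_drugs: int = 100
    n_reversers: int = 3
    reverser_gain: float = 3.0
    noise_sd: float = 0.3
    expr_location: float = 6.0
    expr_scale: float = 2.0
    sex_confounded: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_small + self.n_large != self.n_ami:
            raise ValueError("n_small + n_large must equal n_ami")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) + self.n_tfs > self.n_genes:
            raise ValueError("module sizes plus TFs exceed n_genes")
        if self.n_tfs > self.n_modules:
            raise ValueError("at most one planted TF per module")
        for m, (trait, r) in self.trait_couplings.items():
            if not (0 <= m < self.n_modules):
                raise ValueError(f"trait coupling to unknown module {m}")
            if abs(r) >= 1:
                raise ValueError(f"infeasible trait correlation target {r} for {trait!r}")
        if self.n_reversers > self.n_drugs:
            raise ValueError("n_reversers exceeds n_drugs")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "trait_couplings" in d:
            d["trait_couplings"] = {
                int(k): (v[0], float(v[1])) for k, v in dict(d["trait_couplings"]).items()
            }
        for key in ("module_sizes", "group_shift", "subgroup_shift", "loading_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted structure: the oracle for every recovery test."""

    module_of_gene: dict
    regulator_of_module: dict
    trait_module_links: dict
    reverser_drugs: set = field(default_factory=set)
    loadings: dict = field(default_factory=dict)

    def module_members(self, label: str) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == label]

    def to_json(self, path) -> None:
        payload = {
            "module_of_gene": self.module_of_gene,
            "regulator_of_module": self.regulator_of_module,
            "trait_module_links": self.trait_module_links,
            "reverser_drugs": sorted(self.reverser_drugs),
            "loadings": self.loadings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["reverser_drugs"] = set(payload.get("reverser_drugs", []))
        return cls(**payload)


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame
    meta: pd.DataFrame
    traits: pd.DataFrame
    functional: pd.DataFrame
    truth: SyntheticTruth
    factors: pd.DataFrame  # planted module factors (modules x samples)
    config: SyntheticConfig


def _sample_ids(cfg: SyntheticConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = (
        [f"AMI_S{i + 1:02d}" for i in range(cfg.n_small)]
        + [f"AMI_L{i + 1:02d}" for i in range(cfg.n_large)]
        + [f"CTRL{i + 1:02d}" for i in range(cfg.n_ctrl)]
    )
    is_ami = np.array([1] * cfg.n_ami + [0] * cfg.n_ctrl)
    is_large = np.array([0] * cfg.n_small + [1] * cfg.n_large + [0] * cfg.n_ctrl)
    return ids, is_ami, is_large


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw one synthetic discovery cohort from the factor model."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    ids, is_ami, is_large = _sample_ids(cfg)
    n = len(ids)

    factors = rng.normal(size=(cfg.n_modules, n))
    for m in range(cfg.n_modules):
        factors[m] += cfg.group_shift[m] * is_ami + cfg.subgroup_shift[m] * is_large

    genes: list[str] = []
    rows: list[np.ndarray] = []
    module_of_gene: dict[str, str] = {}
    regulator_of_module: dict[str, list[str]] = {}
    loadings: dict[str, float] = {}
    lo, hi = cfg.loading_range
    counter = 0
    for m in range(cfg.n_modules):
        label = f"P{m + 1}"
        size = cfg.module_sizes[m]
        n_targets = size if cfg.targets_per_tf is None else min(cfg.targets_per_tf, size)
        lam = rng.uniform(lo, hi, size=size)
        # TF targets load more strongly on the factor (the TF's signal)
        lam[:n_targets] = np.minimum(lam[:n_targets] * cfg.tf_signal, 0.98)
        for i in range(size):
            counter += 1
            g = f"G{counter:05d}"
            genes.append(g)
            rows.append(lam[i] * factors[m] + rng.normal(scale=cfg.noise_sd, size=n))
            module_of_gene[g] = label
            loadings[g] = float(lam[i])
        if m < cfg.n_tfs:
            tf = f"TF{m + 1}"
            genes.append(tf)
            rows.append(factors[m] + rng.normal(scale=cfg.noise_sd, size=n))
            module_of_gene[tf] = label
            loadings[tf] = 1.0
            regulator_of_module[label] = [tf]
    n_background = cfg.n_genes - len(genes)
    for _ in range(n_background):
        counter += 1
        g = f"G{counter:05d}"
        genes.append(g)
        rows.append(rng.normal(size=n))
        module_of_gene[g] = BACKGROUND
    expr = pd.DataFrame(np.vstack(rows), index=genes, columns=ids)
    expr = cfg.expr_location + cfg.expr_scale * expr
    expr.index.name = "gene"
    expr.columns.name = "sample"

    if cfg.sex_confounded:
        p_f = np.where(is_ami == 1, 0.7, 0.3)
        sex = np.where(rng.random(n) < p_f, "F", "M")
    else:
        sex = np.where(rng.random(n) < 0.5, "F", "M")
    meta = pd.DataFrame(
        {
            "group": np.where(is_ami == 1, "AMI", "control"),
            "subgroup": np.where(is_large == 1, "Large", np.where(is_ami == 1, "Small", "none")),
            "sex": sex,
        },
        index=pd.Index(ids, name="sample"),
    )

    # clinical traits: AMI samples only, correlation-calibrated to factors
    ami_ids = [s for s, a in zip(ids, is_ami) if a == 1]
    ami_mask = is_ami == 1
    trait_cols = {}
    trait_module_links = {}
    scale_map = {
        "infarct_size": (20.0, 12.0),
        "ejection_fraction": (50.0, 10.0),
        "end_diastolic_volume": (180.0, 40.0),
    }
    for m, (trait, r) in cfg.trait_couplings.items():
        f = factors[m][ami_mask]
        fstd = (f - f.mean()) / f.std(ddof=1)
        raw = r * fstd + np.sqrt(1.0 - r * r) * rng.normal(size=len(f))
        loc, sc = scale_map.get(trait, (0.0, 1.0))
        trait_cols[trait] = loc + sc * raw
        trait_module_links[trait] = f"P{m + 1}"
    traits = pd.DataFrame(trait_cols, index=pd.Index(ami_ids, name="sample"))

    # functional readouts mix the group-shifted factors
    shifted = [m for m in range(cfg.n_modules) if cfg.group_shift[m] != 0] or list(
        range(cfg.n_modules)
    )
    w = rng.uniform(0.5, 1.0, size=(len(READOUTS), len(shifted))) * rng.choice(
        [-1.0, 1.0], size=(len(READOUTS), len(shifted))
    )
    func_vals = w @ factors[shifted] + rng.normal(scale=cfg.noise_sd, size=(len(READOUTS), n))
    functional = pd.DataFrame(
        50.0 + 10.0 * func_vals.T, index=pd.Index(ids, name="sample"), columns=READOUTS
    )

    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        regulator_of_module=regulator_of_module,
        trait_module_links=trait_module_links,
        loadings=loadings,
    )
    factors_df = pd.DataFrame(
        factors, index=[f"P{m + 1}" for m in range(cfg.n_modules)], columns=ids
    )
    return SyntheticCohort(
        expression=expr,
        meta=meta,
        traits=traits,
        functional=functional,
        truth=truth,
        factors=factors_df,
        config=cfg,
    )


def true_signature(cohort: SyntheticCohort) -> Signature:
    """The planted large-vs-small signature: genes of subgroup-shifted modules.

    Direction follows the sign of the module's subgroup shift times the
    (positive) gene loading; genes are ordered by decreasing loading.
    """
    cfg = cohort.config
    up, down = [], []
    for m in range(cfg.n_modules):
        shift = cfg.subgroup_shift[m]
        if shift == 0:
            continue
        members = cohort.truth.module_members(f"P{m + 1}")
        members = sorted(members, key=lambda g: -cohort.truth.loadings[g])
        (up if shift > 0 else down).extend(members)
    if not up and not down:
        raise ValueError("no subgroup-shifted module: no planted signature")
    return Signature(up=up, down=down)


def generate_perturbation_db(
    config: SyntheticConfig,
    signature: Signature,
    universe,
    seed: int | None = None,
) -> tuple[pd.DataFrame, set]:
    """Perturbation-profile database with planted reversers among decoys.

    Each profile is a vector of per-gene differential z-scores over the
    cohort gene universe.  Reversers get ``-reverser_gain`` on signature-up
    genes and ``+reverser_gain`` on signature-down genes plus unit noise;
    decoys are pure noise.  Returns the database and the reverser drug ids.
    """
    if not (signature.up or signature.down):
        raise ValueError("signature is empty")
    universe = [str(g) for g in universe]
    missing = (set(signature.up) | set(signature.down)) - set(universe)
    if missing:
        raise ValueError(f"signature gene {sorted(missing)[0]!r} not in universe")
    rng = np.random.default_rng(config.seed + 1000 if seed is None else seed)
    drug_ids = [f"DRUG{i + 1:03d}" for i in range(config.n_drugs)]
    reversers = set(rng.choice(drug_ids, size=config.n_reversers, replace=False).tolist())
    z = rng.normal(size=(config.n_drugs, len(universe)))
    up_idx = [universe.index(g) for g in signature.up]
    down_idx = [universe.index(g) for g in signature.down]
    for i, drug in enumerate(drug_ids):
        if drug in reversers:
            z[i, up_idx] -= config.reverser_gain
            z[i, down_idx] += config.reverser_gain
    meta = pd.DataFrame(
        {
            "drug": drug_ids,
            "cell_type": "THP1",
            "dose": "10 uM",
            "duration": "24 h",
        }
    )
    db = pd.concat([meta, pd.DataFrame(z, columns=universe)], axis=1)
    return db, reversers
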