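"""Synthetic cohort generation with planted rank-correlation structure.

The generator emulates the statistical structure the network analysis
assumes, standing in for an unreleased clinical dataset: three groups
(15 never-smokers, 10 smokers, 35 COPD patients), ~50 variables spread over
four measurement levels, block-structured correlation that may differ by
group (a denser disease-group network), heavy-tailed marginals and
missing-at-random holes.

Data are drawn from a latent Gaussian copula: within each group, latent
variables are multivariate normal with pairwise correlation ``target_rho``
inside each active planted block and 0 elsewhere; each column is then pushed
through a strictly increasing marginal transform.  Because Spearman
correlation is rank-based, the planted structure is exact on the rank scale:
the population Spearman correlation of a latent pair at Pearson rho is
``(6/pi)*arcsin(rho/2)``.  Count-kind variables are floored to integers,
which introduces realistic ties (and a slight attenuation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import CohortTable, CohortValidationError, VariableMeta

__all__ = [
    "PlantedBlock",
    "CohortSpec",
    "GroundTruth",
    "latent_to_spearman",
    "generate_cohort",
    "default_study_spec",
    "spec_to_yaml",
    "spec_from_yaml",
    "write_ground_truth",
]


def latent_to_spearman(rho: float) -> float:
    """Population Spearman correlation implied by latent Gaussian Pearson rho."""
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))


@dataclass(frozen=True)
class PlantedBlock:
    """A set of variables sharing a pairwise latent correlation in some groups.

    Within every group listed in ``groups``, all pairs of ``variables`` get
    latent Pearson correlation ``target_rho``; elsewhere they are independent.
    """

    variables: tuple[str, ...]
    target_rho: float
    groups: frozenset[str]

    def __init__(self, variables: Sequence[str], target_rho: float,
                 groups: Sequence[str]):
        object.__setattr__(self, "variables", tuple(variables))
        object.__setattr__(self, "target_rho", float(target_rho))
        object.__setattr__(self, "groups", frozenset(groups))
        if len(self.variables) < 2:
            raise CohortValidationError("planted block needs >=2 variables")
        if len(set(self.variables)) != len(self.variables):
            raise CohortValidationError(
                f"duplicate variables in block: {self.variables}"
            )
        if not (0.0 < abs(self.target_rho) <= 0.95):
            raise CohortValidationError(
                f"target_rho must be nonzero with |rho| <= 0.95, got {self.target_rho}"
            )
        if not self.groups:
            raise CohortValidationError("block must be active in >=1 group")

    def pairs(self):
        for a, b in itertools.combinations(self.variables, 2):
            yield tuple(sorted((a, b)))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; identical spec+seed => identical data."""

    group_sizes: tuple[tuple[str, int], ...]
    variables: tuple[VariableMeta, ...]
    blocks: tuple[PlantedBlock, ...]
    noise_df: float = 8.0
    missing_rate: float = 0.05
    seed: int = 0

    def __init__(self, group_sizes, variables, blocks=(), noise_df=8.0,
                 missing_rate=0.05, seed=0):
        if isinstance(group_sizes, Mapping):
            group_sizes = tuple(group_sizes.items())
        object.__setattr__(self, "group_sizes",
                           tuple((str(g), int(n)) for g, n in group_sizes))
        object.__setattr__(self, "variables", tuple(variables))
        object.__setattr__(self, "blocks", tuple(blocks))
        object.__setattr__(self, "noise_df", float(noise_df))
        object.__setattr__(self, "missing_rate", float(missing_rate))
        object.__setattr__(self, "seed", int(seed))
        total = sum(n for _, n in self.group_sizes)
        if total < 10:
            raise CohortValidationError(f"total subjects must be >=10, got {total}")
        if any(n < 1 for _, n in self.group_sizes):
            raise CohortValidationError("every group must have >=1 subject")
        if not (0.0 <= self.missing_rate < 0.5):
            raise CohortValidationError(
                f"missing_rate must be in [0, 0.5), got {self.missing_rate}"
            )
        if self.noise_df <= 2:
            raise CohortValidationError("noise_df must exceed 2")
        names = [m.name for m in self.variables]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate variable names in spec")
        known = set(names)
        labels = {g for g, _ in self.group_sizes}
        for blk in self.blocks:
            missing = set(blk.variables) - known
            if missing:
                raise CohortValidationError(
                    f"block references unknown variables: {sorted(missing)}"
                )
            stray = blk.groups - labels
            if stray:
                raise CohortValidationError(
                    f"block active in unknown groups: {sorted(stray)}"
                )

    @property
    def group_size_map(self) -> dict[str, int]:
        return dict(self.group_sizes)

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.group_sizes)


@dataclass(frozen=True)
class GroundTruth:
    """Per-group set of variable pairs with nonzero latent correlation."""

    active_pairs: tuple[tuple[str, tuple[tuple[tuple[str, str], float], ...]], ...]

    @classmethod
    def from_spec(cls, spec: CohortSpec) -> "GroundTruth":
        per_group = []
        for group, _ in spec.group_sizes:
            pairs: dict[tuple[str, str], float] = {}
            for blk in spec.blocks:
                if group not in blk.groups:
                    continue
                for pair in blk.pairs():
                    if pair in pairs and pairs[pair] != blk.target_rho:
                        raise CohortValidationError(
                            f"conflicting target_rho for pair {pair} in group "
                            f"{group!r}: {pairs[pair]} vs {blk.target_rho}"
                        )
                    pairs[pair] = blk.target_rho
            per_group.append((group, tuple(sorted(pairs.items()))))
        return cls(active_pairs=tuple(per_group))

    def pairs(self, group: str) -> dict[tuple[str, str], float]:
        for g, items in self.active_pairs:
            if g == group:
                return dict(items)
        raise KeyError(group)

    def pair_set(self, group: str) -> set[tuple[str, str]]:
        return set(self.pairs(group))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "var_a": a, "var_b": b, "target_rho": rho}
            for g, items in self.active_pairs
            for (a, b), rho in items
        ]
        return pd.DataFrame(rows, columns=["group", "var_a", "var_b", "target_rho"])


def _latent_corr(spec: CohortSpec, group: str) -> np.ndarray:
    """Latent correlation matrix for one group; validates consistency and PSD."""
    names = [m.name for m in spec.variables]
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    assigned: dict[tuple[int, int], float] = {}
    for blk in spec.blocks:
        if group not in blk.groups:
            continue
        for a, b in blk.pairs():
            key = (idx[a], idx[b])
            if key in assigned and assigned[key] != blk.target_rho:
                raise CohortValidationError(
                    f"conflicting target_rho for pair ({a}, {b}) in group {group!r}"
                )
            assigned[key] = blk.target_rho
    for (i, j), rho in assigned.items():
        corr[i, j] = corr[j, i] = rho
    min_eig = float(np.linalg.eigvalsh(corr).min())
    if min_eig < -1e-8:
        raise CohortValidationError(
            f"latent correlation matrix for group {group!r} is not positive "
            f"semi-definite (min eigenvalue {min_eig:.3g}); overlapping blocks "
            f"are incompatible"
        )
    return corr


def _marginal_transform(z: np.ndarray, meta: VariableMeta, df: float) -> np.ndarray:
    """Strictly increasing map from latent normal scores to a clinical-looking scale."""
    u = stats.norm.cdf(z)
    # heavy-tailed continuous marginal via a t quantile; counts are floored
    y = stats.t.ppf(np.clip(u, 1e-12, 1 - 1e-12), df)
    if meta.kind == "count":
        return np.floor(60.0 * np.exp(0.5 * y))
    return y


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort from a :class:`CohortSpec`.

    Returns the cohort plus the ground truth of planted pairs per group.
    Deterministic: the same spec (including its seed) always yields a
    bitwise-identical table.
    """
    truth = GroundTruth.from_spec(spec)
    corrs = {g: _latent_corr(spec, g) for g, _ in spec.group_sizes}

    rng = np.random.default_rng(spec.seed)
    names = [m.name for m in spec.variables]
    rows, ids, labels = [], [], []
    offset = 0
    for group, n in spec.group_sizes:
        z = rng.multivariate_normal(
            np.zeros(len(names)), corrs[group], size=n, method="eigh"
        )
        rows.append(z)
        ids.extend(f"S{offset + i + 1:03d}" for i in range(n))
        labels.extend([group] * n)
        offset += n
    latent = np.vstack(rows)

    values = np.column_stack(
        [
            _marginal_transform(latent[:, j], meta, spec.noise_df)
            for j, meta in enumerate(spec.variables)
        ]
    )
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.copy()
        values[mask] = np.nan

    data = pd.DataFrame(values, index=pd.Index(ids, name="subject_id"),
                        columns=names)
    groups = pd.Series(labels, index=data.index, name="group")
    return CohortTable(data, groups, list(spec.variables)), truth


# ------------------------------------------------------------- default spec

def _var(name: str, level: str, kind: str = "continuous", units: str = "") -> VariableMeta:
    return VariableMeta(name=name, level=level, kind=kind, units=units)


def default_study_spec(seed: int) -> CohortSpec:
    """The default study-shaped cohort spec.

    60 subjects (15 never-smokers, 10 smokers, 35 COPD), 47 variables across
    the four levels.  Planted blocks emulate the modules the analysis is meant
    to resolve: a bone-marrow cellularity block, a circulating-blood count
    block and a small macrophage block active in every group, plus
    disease-specific blocks — a lung-function/repair block, eosinophil links
    to FEV1 and DLCO, a CD34 progenitor/immunity block and an inflammation
    block — so the COPD group's latent network is strictly denser than the
    never-smoker group's.
    """
    clinical = [
        _var("Age", "clinical", units="years"),
        _var("BMI", "clinical", units="kg/m2"),
        _var("PackYears", "clinical"),
        _var("mMRC", "clinical", kind="count"),
    ]
    lung = [
        _var("FEV1pp", "lung_function", units="% ref"),
        _var("FEV1FVC", "lung_function", units="%"),
        _var("FVCpp", "lung_function", units="% ref"),
        _var("RVpp", "lung_function", units="% ref"),
        _var("TLCpp", "lung_function", units="% ref"),
        _var("DLCOpp", "lung_function", units="% ref"),
    ]
    marrow = [
        _var("BM_WBC", "bone_marrow"),
        _var("BM_Lympho", "bone_marrow"),
        _var("BM_Segmented", "bone_marrow"),
        _var("BM_E_Polychrom", "bone_marrow"),
        _var("BM_E_Ortochrom", "bone_marrow"),
        _var("BM_E_Basophil", "bone_marrow"),
        _var("BM_CD3pct", "bone_marrow", units="%"),
        _var("BM_CD15pct", "bone_marrow", units="%"),
        _var("BM_CD19pct", "bone_marrow", units="%"),
        _var("BM_PlasmaCells", "bone_marrow"),
        _var("BM_Eos", "bone_marrow"),
        _var("BM_CD34pct", "bone_marrow", units="%"),
        _var("BM_CD34_cKit", "bone_marrow", units="%"),
        _var("BM_CD34_Ki67", "bone_marrow", units="%"),
        _var("BM_EPCpct", "bone_marrow", units="%"),
        _var("BM_Metamyelocytes", "bone_marrow"),
        _var("BM_MonoMacro", "bone_marrow"),
        _var("BM_IL6", "bone_marrow", units="pg/ml"),
        _var("BM_IL8", "bone_marrow", units="pg/ml"),
        _var("BM_HGF", "bone_marrow", units="pg/ml"),
    ]
    blood = [
        _var("Eos", "blood", kind="count", units="cells/uL"),
        _var("EosPct", "blood", units="%"),
        _var("Neutrophils", "blood", units="%"),
        _var("Lymphocytes", "blood", units="%"),
        _var("Monocytes", "blood", units="%"),
        _var("Basophils", "blood", units="%"),
        _var("WBC", "blood", kind="count", units="10^9/L"),
        _var("RBC", "blood"),
        _var("Hb", "blood", units="g/dL"),
        _var("Platelets", "blood", kind="count", units="10^9/L"),
        _var("CRP", "blood", units="mg/dl"),
        _var("IL6", "blood", units="pg/ml"),
        _var("IL8", "blood", units="pg/ml"),
        _var("HGF", "blood", units="pg/ml"),
        _var("VEGF", "blood", units="pg/ml"),
        _var("IGF1", "blood", units="ng/mL"),
        _var("TGFb", "blood", units="pg/ml"),
    ]
    variables = clinical + lung + marrow + blood
    all_groups = ("never_smoker", "smoker", "copd")

    blocks = (
        # physiologically expected modules, present in everyone
        PlantedBlock(
            ["BM_WBC", "BM_Lympho", "BM_Segmented", "BM_E_Polychrom",
             "BM_E_Ortochrom", "BM_E_Basophil", "BM_CD3pct", "BM_CD15pct",
             "BM_CD19pct", "BM_PlasmaCells", "BM_Eos"],
            0.55, all_groups,
        ),
        PlantedBlock(
            ["WBC", "RBC", "Hb", "Neutrophils", "Lymphocytes", "Monocytes",
             "Platelets"],
            0.55, all_groups,
        ),
        PlantedBlock(["BM_Metamyelocytes", "BM_MonoMacro"], 0.7, all_groups),
        # disease-specific structure: lung function + repair markers
        PlantedBlock(
            ["FEV1pp", "FEV1FVC", "FVCpp", "TLCpp", "DLCOpp", "BMI",
             "HGF", "VEGF", "IGF1", "TGFb", "BM_HGF", "BM_EPCpct"],
            0.5, ("copd",),
        ),
        PlantedBlock(["Eos", "FEV1pp"], -0.45, ("copd",)),
        PlantedBlock(["Eos", "DLCOpp"], -0.45, ("copd",)),
        # progenitor/immunity block
        PlantedBlock(
            ["BM_CD34pct", "BM_CD34_cKit", "BM_CD34_Ki67", "EosPct"],
            0.5, ("copd",),
        ),
        # smoking-driven systemic inflammation
        PlantedBlock(
            ["CRP", "IL6", "IL8", "BM_IL6", "BM_IL8"],
            0.5, ("smoker", "copd"),
        ),
    )
    return CohortSpec(
        group_sizes=(("never_smoker", 15), ("smoker", 10), ("copd", 35)),
        variables=variables,
        blocks=blocks,
        noise_df=8.0,
        missing_rate=0.05,
        seed=seed,
    )


# ---------------------------------------------------------- serialization

def spec_to_yaml(spec: CohortSpec, path) -> None:
    doc = {
        "group_sizes": {g: n for g, n in spec.group_sizes},
        "variables": [
            {"name": m.name, "level": m.level, "kind": m.kind, "units": m.units}
            for m in spec.variables
        ],
        "blocks": [
            {
                "variables": list(b.variables),
                "target_rho": b.target_rho,
                "groups": sorted(b.groups),
            }
            for b in spec.blocks
        ],
        "noise_df": spec.noise_df,
        "missing_rate": spec.missing_rate,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path) -> CohortSpec:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return CohortSpec(
            group_sizes=list(doc["group_sizes"].items()),
            variables=[
                VariableMeta(
                    name=v["name"], level=v["level"], kind=v["kind"],
                    units=v.get("units", "") or "",
                )
                for v in doc["variables"]
            ],
            blocks=[
                PlantedBlock(b["variables"], b["target_rho"], b["groups"])
                for b in doc.get("blocks", [])
            ],
            noise_df=doc.get("noise_df", 8.0),
            missing_rate=doc.get("missing_rate", 0.05),
            seed=doc["seed"],
        )
    except KeyError as exc:
        raise CohortValidationError(f"cohort spec missing field: {exc}") from None


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, index=False)
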