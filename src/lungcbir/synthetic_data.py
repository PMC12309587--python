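"""Synthetic paired lung-mask / finding-label / CT volumes.

Real inputs to the retrieval pipeline are produced upstream by a segmentation
and voxel-classification system; this module emulates that output so every
downstream stage is testable without patient data.  A generated case consists
of two ellipsoidal "lungs" on a voxel grid, a finding-label volume seeded as
normal lung and converted to findings by growing 6-connected blobs whose
centers follow a per-phenotype spatial prior over the 24 level-3 regions, and
a CT volume sampled per voxel from a per-finding Hounsfield-unit model.

A *phenotype* bundles the two binary clinical labels (ILD / non-ILD,
with-UIP / without-UIP) with a finding profile: target whole-lung fractions
and spatial priors.  Six canonical phenotypes loosely mirroring major
diffuse-lung-disease classes are shipped: a basal-peripheral fibrotic
pattern (honeycombing + reticulation), a ground-glass-dominant pattern, a
peripheral consolidation pattern, an upper-zone emphysema pattern, a nodular
bronchiolitic pattern, and a normal lung.  Profiles are configuration, not
clinical truth claims.

Blob growth stops exactly at each finding's voxel target (or earlier when no
normal lung remains), so achieved whole-lung fractions match targets almost
exactly; the *regional* distribution carries sampling noise.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import findings_schema as fs
from .case_database import CaseDatabase
from .feature_extraction import CaseFeatures, extract_case_features
from .region_partition import (
    ANTERO_POSTERIOR,
    LEVEL3_NAMES,
    MEDIO_LATERAL,
    VERTICAL,
    LungMask,
    RegionPartition,
    partition_lung,
    _save_nifti,
)

__all__ = [
    "GenerationError",
    "Phenotype",
    "CohortSpec",
    "SyntheticCase",
    "zone_prior",
    "generate_case",
    "generate_cohort",
    "build_database",
    "write_cohort",
    "PHENOTYPES",
    "DEFAULT_CT_MODEL",
]

logger = logging.getLogger(__name__)


class GenerationError(ValueError):
    """A phenotype profile cannot be realized on the requested grid."""


#: per-code CT attenuation model: code -> (mean HU, sd HU)
DEFAULT_CT_MODEL: dict[int, tuple[float, float]] = {
    1: (40.0, 50.0),     # consolidation
    2: (10.0, 30.0),     # pleural effusion
    3: (30.0, 40.0),     # pleural thickening
    4: (-600.0, 70.0),   # ground-glass opacity
    5: (-620.0, 70.0),   # centrilobular GGO
    6: (-350.0, 100.0),  # tree-in-bud
    7: (-150.0, 90.0),   # small nodules
    8: (-250.0, 90.0),   # centrilobular nodules
    9: (-550.0, 90.0),   # interlobular septal thickening
    10: (-940.0, 25.0),  # hyperlucency
    11: (-950.0, 25.0),  # centrilobular emphysema
    12: (-960.0, 20.0),  # panlobular emphysema
    13: (-900.0, 60.0),  # cyst
    14: (-300.0, 150.0), # cavity in infiltration
    15: (-250.0, 150.0), # cavity in mass
    16: (-700.0, 120.0), # bronchial wall thickening
    17: (-780.0, 140.0), # bronchiectasis
    18: (-820.0, 100.0), # air bronchogram
    19: (-750.0, 140.0), # traction bronchiectasis
    20: (-850.0, 40.0),  # normal lung
    21: (-880.0, 35.0),  # borderline normal / hyperlucency
    22: (-750.0, 50.0),  # faint GGO
    23: (-830.0, 50.0),  # borderline bronchiolar dilatation
    24: (-720.0, 120.0), # honeycombing
    25: (-650.0, 90.0),  # reticulation
    26: (-700.0, 80.0),  # fine reticulation
    fs.AIRWAY: (-950.0, 30.0),
    fs.VESSEL: (50.0, 40.0),
}

BACKGROUND_HU = -1000.0


def zone_prior(
    vertical: Mapping[str, float] | None = None,
    antero_posterior: Mapping[str, float] | None = None,
    medio_lateral: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Spatial prior over the 24 level-3 regions from per-zone multipliers.

    Weights multiply across the three anatomical axes (default 1 per zone)
    and are normalized to a probability vector in ``LEVEL3_NAMES`` order.
    """
    v = {z: 1.0 for z in VERTICAL} | dict(vertical or {})
    a = {z: 1.0 for z in ANTERO_POSTERIOR} | dict(antero_posterior or {})
    m = {z: 1.0 for z in MEDIO_LATERAL} | dict(medio_lateral or {})
    w = np.array([v[n.split("_")[1]] * a[n.split("_")[2]] * m[n.split("_")[3]] for n in LEVEL3_NAMES])
    if w.sum() <= 0:
        raise GenerationError("zone prior has zero total weight")
    return w / w.sum()


@dataclass(frozen=True)
class Phenotype:
    """Disease phenotype: labels + finding targets + spatial priors."""

    name: str
    ild: str  # "ILD" | "non-ILD"
    uip: str  # "with-UIP" | "without-UIP"
    #: finding code -> (target whole-lung fraction, prior over 24 regions)
    findings: Mapping[int, tuple[float, np.ndarray]] = field(default_factory=dict)
    ct_model: Mapping[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(f for f, _ in self.findings.values())
        if total > 1.0:
            raise GenerationError(f"phenotype {self.name!r}: target fractions sum to {total} > 1")
        for code, (frac, prior) in self.findings.items():
            if code not in fs.FINDINGS:
                raise fs.SchemaError(f"phenotype {self.name!r}: unknown finding code {code}")
            if not 0 <= frac <= 1:
                raise GenerationError(f"phenotype {self.name!r}: fraction {frac} out of range")
            p = np.asarray(prior)
            if p.shape != (24,) or not np.isclose(p.sum(), 1.0):
                raise GenerationError(f"phenotype {self.name!r}: prior must be a 24-way probability vector")

    @property
    def labels(self) -> dict[str, str]:
        return {"ILD": self.ild, "UIP": self.uip}


_BASAL_PERIPHERAL = zone_prior({"upper": 1, "middle": 2, "lower": 4}, {"dorsal": 2}, {"outer": 4})
_BASAL = zone_prior({"upper": 1, "middle": 2, "lower": 3}, {"dorsal": 1.5}, {"outer": 2})
_PERIPHERAL = zone_prior({"middle": 2, "lower": 2}, medio_lateral={"outer": 3})
_UPPER = zone_prior({"upper": 4, "middle": 2, "lower": 1})
_MID = zone_prior({"middle": 2})

#: six canonical phenotypes
PHENOTYPES: dict[str, Phenotype] = {
    p.name: p
    for p in (
        Phenotype(
            "uip_like", "ILD", "with-UIP",
            {24: (0.12, _BASAL_PERIPHERAL), 25: (0.10, _BASAL_PERIPHERAL),
             19: (0.03, _BASAL), 4: (0.03, _BASAL)},
        ),
        Phenotype(
            "nsip_like", "ILD", "without-UIP",
            {4: (0.20, _BASAL), 26: (0.06, _BASAL), 22: (0.04, _BASAL)},
        ),
        Phenotype(
            "op_like", "ILD", "without-UIP",
            {1: (0.12, _PERIPHERAL), 4: (0.08, _PERIPHERAL), 18: (0.02, _PERIPHERAL)},
        ),
        Phenotype(
            "emphysema_like", "non-ILD", "without-UIP",
            {11: (0.18, _UPPER), 10: (0.07, _UPPER)},
        ),
        Phenotype(
            "nodular_like", "non-ILD", "without-UIP",
            {7: (0.06, _MID), 6: (0.05, _MID), 17: (0.04, _MID), 8: (0.03, _MID)},
        ),
        Phenotype("normal", "non-ILD", "without-UIP", {}),
    )
}


@dataclass
class SyntheticCase:
    """One generated case: volumes + labels (+ the partition already built)."""

    case_id: str
    lung_mask: LungMask
    label_volume: np.ndarray
    ct_volume: np.ndarray
    labels: dict[str, str]
    phenotype: str
    partition: RegionPartition

    def features(self) -> CaseFeatures:
        return extract_case_features(
            self.case_id,
            self.label_volume,
            self.ct_volume,
            self.partition,
            labels=self.labels,
            diagnosis=self.phenotype,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort recipe: (phenotype, n) pairs, grid geometry, master seed."""

    groups: Sequence[tuple[Phenotype | str, int]]
    grid: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0


def _ellipsoid_lungs(grid: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Two jittered ellipsoids: 1 = right (low axis-2 indices), 2 = left."""
    n0, n1, n2 = grid
    zz, yy, xx = np.meshgrid(np.arange(n0), np.arange(n1), np.arange(n2), indexing="ij")
    mask = np.zeros(grid, dtype=np.uint8)
    for label, cx_frac in ((1, 0.30), (2, 0.70)):
        jitter = 1.0 + rng.uniform(-0.06, 0.06, size=3)
        c = (0.5 * n0, 0.5 * n1, cx_frac * n2)
        a = (0.40 * n0 * jitter[0], 0.28 * n1 * jitter[1], 0.15 * n2 * jitter[2])
        inside = (
            ((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2 + ((xx - c[2]) / a[2]) ** 2
        ) <= 1.0
        mask[inside] = label
    return mask


def _grow_finding(
    labels: np.ndarray,
    level3: np.ndarray,
    code: int,
    target: int,
    prior: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Convert up to ``target`` normal-lung voxels to ``code`` by region-seeded
    6-connected blob growth.  Returns the number of voxels converted."""
    shape = labels.shape
    placed = 0
    stall = 0
    while placed < target and stall < 50:
        # sample a seed region by prior, restricted to regions with capacity
        normal = labels == fs.NORMAL_LUNG
        capacity = np.bincount(level3[normal], minlength=25)[1:]
        weights = prior * (capacity > 0)
        if weights.sum() == 0:
            logger.warning("finding %d saturated at %d/%d voxels", code, placed, target)
            break
        region = rng.choice(24, p=weights / weights.sum()) + 1
        candidates = np.argwhere(normal & (level3 == region))
        seed_voxel = tuple(candidates[rng.integers(len(candidates))])

        blob_target = min(target - placed, max(1, int(rng.lognormal(np.log(200.0), 0.8))))
        queue = deque([seed_voxel])
        grown = 0
        while queue and grown < blob_target:
            v = queue.popleft()
            if labels[v] != fs.NORMAL_LUNG:
                continue
            labels[v] = code
            grown += 1
            i, j, k = v
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                w = (i + d[0], j + d[1], k + d[2])
                if all(0 <= w[a] < shape[a] for a in range(3)) and labels[w] == fs.NORMAL_LUNG:
                    queue.append(w)
        placed += grown
        stall = stall + 1 if grown == 0 else 0
    return placed


def generate_case(
    phenotype: Phenotype | str,
    grid: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    case_id: str | None = None,
    vessel_fraction: float = 0.02,
    airway_fraction: float = 0.005,
) -> SyntheticCase:
    """Generate one paired lung-mask / finding-label / CT case."""
    if isinstance(phenotype, str):
        phenotype = PHENOTYPES[phenotype]
    rng = np.random.default_rng(seed)

    mask = _ellipsoid_lungs(grid, rng)
    lung = LungMask(mask, spacing)
    partition = partition_lung(lung)

    inside = np.argwhere(mask > 0)
    n_lung = len(inside)
    labels = np.where(mask > 0, fs.NORMAL_LUNG, fs.BACKGROUND).astype(np.uint8)

    # airway/vessel sprinkle: inside the lung, excluded from findings
    n_aux = int(round((vessel_fraction + airway_fraction) * n_lung))
    aux_idx = inside[rng.choice(n_lung, size=n_aux, replace=False)]
    n_air = int(round(airway_fraction * n_lung))
    for row in aux_idx[:n_air]:
        labels[tuple(row)] = fs.AIRWAY
    for row in aux_idx[n_air:]:
        labels[tuple(row)] = fs.VESSEL

    targets = {code: int(round(frac * n_lung)) for code, (frac, _) in phenotype.findings.items()}
    if sum(targets.values()) > int((labels == fs.NORMAL_LUNG).sum()):
        raise GenerationError(
            f"phenotype {phenotype.name!r}: targets exceed available lung capacity"
        )
    for code in sorted(targets):
        _grow_finding(labels, partition.level3, code, targets[code], phenotype.findings[code][1], rng)

    ct_model = dict(DEFAULT_CT_MODEL) | dict(phenotype.ct_model)
    ct = np.full(grid, BACKGROUND_HU, dtype=np.float32)
    for code in np.unique(labels):
        if code == fs.BACKGROUND:
            continue
        mean, sd = ct_model[int(code)]
        where = labels == code
        ct[where] = rng.normal(mean, sd, size=int(where.sum())).astype(np.float32)

    return SyntheticCase(
        case_id=case_id or f"{phenotype.name}_{seed}",
        lung_mask=lung,
        label_volume=labels,
        ct_volume=ct,
        labels=phenotype.labels,
        phenotype=phenotype.name,
        partition=partition,
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticCase]:
    """Generate a cohort; per-case seeds derive from the master seed."""
    rng = np.random.default_rng(spec.seed)
    cases: list[SyntheticCase] = []
    for phenotype, n in spec.groups:
        if isinstance(phenotype, str):
            phenotype = PHENOTYPES[phenotype]
        if n < 1:
            raise GenerationError(f"phenotype {phenotype.name!r}: n_cases must be >= 1")
        for i in range(n):
            child_seed = int(rng.integers(2**31))
            try:
                cases.append(
                    generate_case(
                        phenotype, spec.grid, spec.spacing, seed=child_seed,
                        case_id=f"{phenotype.name}_{i:03d}",
                    )
                )
            except GenerationError as err:
                raise GenerationError(f"case {phenotype.name}_{i:03d}: {err}") from err
    return cases


def build_database(cases: Sequence[SyntheticCase]) -> CaseDatabase:
    """Extract features for every case and register them in a database."""
    db = CaseDatabase()
    db.register_all(case.features() for case in cases)
    db.compute_stats()
    return db


def write_cohort(cases: Sequence[SyntheticCase], directory: str | Path) -> None:
    """Write NIfTI volumes + labels.csv in the layout the pipeline consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        case.lung_mask.to_nifti(directory / f"{case.case_id}_lung.nii.gz")
        _save_nifti(case.label_volume, case.lung_mask.spacing, directory / f"{case.case_id}_findings.nii.gz")
        _save_nifti(case.ct_volume, case.lung_mask.spacing, directory / f"{case.case_id}_ct.nii.gz")
        rows.append(
            {"case_id": case.case_id, "phenotype": case.phenotype,
             "ILD": case.labels["ILD"], "UIP": case.labels["UIP"]}
        )
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)
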