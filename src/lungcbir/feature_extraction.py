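"""Per-region quantification of a finding-label volume.

For each of the 24 level-3 regions a *fine* vector of 30 features is
computed: the volume fraction of each of the 26 findings, the region volume
(mL), the mean and population variance of the CT values (HU, HU^2), and the
lesion fraction.  For each of the 9 coarser regions (whole lung, two lungs,
six sextants) a *coarse* vector of 12 features is computed: the 11 grouped
finding fractions plus the region volume.

Denominator convention: every fraction is taken over *all* lung-mask voxels
of the region, so airway and vessel voxels (which are inside the lung but are
not findings) dilute the finding percentages — the fine fractions sum to at
most 1.  CT statistics likewise run over all region voxels.  Empty regions
yield all-zero features with a logged warning rather than an error, so
degenerate masks stay usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import findings_schema as fs
from .region_partition import (
    ALL_REGION_NAMES,
    COARSE_NAMES,
    LEVEL3_NAMES,
    REGION_MEMBERS,
    RegionPartition,
)

__all__ = [
    "GridMismatchError",
    "FineFeatureVector",
    "CoarseFeatureVector",
    "CaseFeatures",
    "extract_fine_features",
    "extract_coarse_features",
    "extract_case_features",
    "lesion_proportion",
    "N_FINE_FEATURES",
    "N_COARSE_FEATURES",
    "FINE_VOLUME",
    "FINE_CT_MEAN",
    "FINE_CT_VAR",
    "FINE_LESION",
]

logger = logging.getLogger(__name__)


class GridMismatchError(ValueError):
    """Volumes do not share the partition's voxel grid."""


N_FINE_FEATURES = 30
N_COARSE_FEATURES = 12

# 0-based indices of the non-fraction fine features
FINE_VOLUME = 26
FINE_CT_MEAN = 27
FINE_CT_VAR = 28
FINE_LESION = 29

_MAX_CODE = max(fs.VALID_VOLUME_CODES)
_LESION = np.array(sorted(fs.LESION_CODES))
_GROUP_OF = np.zeros(fs.N_FINDINGS + 1, dtype=np.intp)  # finding code -> group
for _f in fs.FINDINGS.values():
    _GROUP_OF[_f.code] = _f.group

FineFeatureVector = np.ndarray  # shape (30,)
CoarseFeatureVector = np.ndarray  # shape (12,)


@dataclass
class CaseFeatures:
    """All per-region feature vectors for one case.

    ``coarse`` has shape (9, 12) over ``COARSE_NAMES``; ``fine`` has shape
    (24, 30) over ``LEVEL3_NAMES``; ``lesion`` holds the lesion fraction of
    all 33 regions in ``ALL_REGION_NAMES`` order.  ``labels`` optionally
    carries the binary clinical axes, e.g. ``{"ILD": "ILD",
    "UIP": "without-UIP"}``.
    """

    case_id: str
    coarse: np.ndarray
    fine: np.ndarray
    lesion: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        self.coarse = np.asarray(self.coarse, dtype=np.float64)
        self.fine = np.asarray(self.fine, dtype=np.float64)
        self.lesion = np.asarray(self.lesion, dtype=np.float64)
        if self.coarse.shape != (len(COARSE_NAMES), N_COARSE_FEATURES):
            raise ValueError(f"coarse features must be (9, 12), got {self.coarse.shape}")
        if self.fine.shape != (len(LEVEL3_NAMES), N_FINE_FEATURES):
            raise ValueError(f"fine features must be (24, 30), got {self.fine.shape}")
        if self.lesion.shape != (len(ALL_REGION_NAMES),):
            raise ValueError(f"lesion proportions must be (33,), got {self.lesion.shape}")


def _check_grids(label_volume: np.ndarray, ct_volume: np.ndarray, partition: RegionPartition) -> None:
    if label_volume.shape != partition.level3.shape or ct_volume.shape != partition.level3.shape:
        raise GridMismatchError(
            f"grids differ: labels {label_volume.shape}, CT {ct_volume.shape}, "
            f"partition {partition.level3.shape}"
        )
    codes = np.unique(label_volume)
    bad = set(int(c) for c in codes) - set(fs.VALID_VOLUME_CODES)
    if bad:
        raise fs.SchemaError(f"label volume contains unknown codes {sorted(bad)}")


def _region_tables(
    label_volume: np.ndarray, ct_volume: np.ndarray, partition: RegionPartition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per level-3 region: (24, ncodes) label counts and CT sum / sum-of-squares."""
    inside = partition.level3 > 0
    region = partition.level3[inside].astype(np.intp) - 1
    labels = label_volume[inside].astype(np.intp)
    ct = np.asarray(ct_volume, dtype=np.float64)[inside]

    joint = region * (_MAX_CODE + 1) + labels
    counts = np.bincount(joint, minlength=24 * (_MAX_CODE + 1)).reshape(24, _MAX_CODE + 1)
    ct_sum = np.bincount(region, weights=ct, minlength=24)
    ct_sumsq = np.bincount(region, weights=ct * ct, minlength=24)
    return counts, ct_sum, ct_sumsq


def _fractions(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Finding fractions (n_regions, 26) and totals from a count table."""
    totals = counts.sum(axis=1).astype(np.float64)
    safe = np.maximum(totals, 1.0)
    frac = counts[:, 1 : fs.N_FINDINGS + 1] / safe[:, None]
    if (totals == 0).any():
        logger.warning("empty region(s) encountered; features default to 0")
    return frac, totals


def extract_fine_features(
    label_volume: np.ndarray,
    ct_volume: np.ndarray,
    partition: RegionPartition,
    spacing: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """The (24, 30) fine feature matrix over the level-3 regions."""
    _check_grids(label_volume, ct_volume, partition)
    spacing = spacing or partition.spacing
    voxel_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0

    counts, ct_sum, ct_sumsq = _region_tables(label_volume, ct_volume, partition)
    frac, totals = _fractions(counts)
    safe = np.maximum(totals, 1.0)

    fine = np.zeros((24, N_FINE_FEATURES))
    fine[:, : fs.N_FINDINGS] = frac
    fine[:, FINE_VOLUME] = totals * voxel_ml
    mean = ct_sum / safe
    fine[:, FINE_CT_MEAN] = np.where(totals > 0, mean, 0.0)
    var = ct_sumsq / safe - mean**2
    fine[:, FINE_CT_VAR] = np.where(totals > 0, np.maximum(var, 0.0), 0.0)
    fine[:, FINE_LESION] = frac[:, _LESION - 1].sum(axis=1)
    return fine


def extract_coarse_features(
    label_volume: np.ndarray,
    ct_volume: np.ndarray,
    partition: RegionPartition,
    spacing: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """The (9, 12) coarse feature matrix over whole lung, lungs and sextants."""
    _check_grids(label_volume, ct_volume, partition)
    spacing = spacing or partition.spacing
    voxel_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0

    counts, _, _ = _region_tables(label_volume, ct_volume, partition)
    coarse = np.zeros((len(COARSE_NAMES), N_COARSE_FEATURES))
    for i, name in enumerate(COARSE_NAMES):
        member = np.array(REGION_MEMBERS[name]) - 1
        region_counts = counts[member].sum(axis=0)
        total = region_counts.sum()
        if total == 0:
            logger.warning("empty region %s; coarse features default to 0", name)
            continue
        finding_frac = region_counts[1 : fs.N_FINDINGS + 1] / total
        coarse[i, : fs.N_COARSE_GROUPS] = np.bincount(
            _GROUP_OF[1:], weights=finding_frac, minlength=fs.N_COARSE_GROUPS + 1
        )[1:]
        coarse[i, N_COARSE_FEATURES - 1] = total * voxel_ml
    return coarse


def lesion_proportion(label_volume: np.ndarray, region_mask: np.ndarray) -> float:
    """Fraction of a region's voxels bearing any lesion finding."""
    n = int(np.count_nonzero(region_mask))
    if n == 0:
        logger.warning("lesion_proportion of empty region; returning 0")
        return 0.0
    return float(np.isin(label_volume[region_mask], _LESION).sum()) / n


def extract_case_features(
    case_id: str,
    label_volume: np.ndarray,
    ct_volume: np.ndarray,
    partition: RegionPartition,
    spacing: tuple[float, float, float] | None = None,
    labels: Mapping[str, str] | None = None,
    diagnosis: str | None = None,
) -> CaseFeatures:
    """All feature vectors and lesion proportions for one case."""
    fine = extract_fine_features(label_volume, ct_volume, partition, spacing)
    coarse = extract_coarse_features(label_volume, ct_volume, partition, spacing)

    counts, _, _ = _region_tables(label_volume, ct_volume, partition)
    lesion_counts = counts[:, _LESION].sum(axis=1).astype(np.float64)
    totals = counts.sum(axis=1).astype(np.float64)
    lesion = np.zeros(len(ALL_REGION_NAMES))
    for i, name in enumerate(ALL_REGION_NAMES):
        member = np.array(REGION_MEMBERS[name]) - 1
        t = totals[member].sum()
        lesion[i] = lesion_counts[member].sum() / t if t > 0 else 0.0

    return CaseFeatures(
        case_id=case_id,
        coarse=coarse,
        fine=fine,
        lesion=lesion,
        labels=dict(labels or {}),
        diagnosis=diagnosis,
    )
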