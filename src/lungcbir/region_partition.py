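"""Hierarchical partition of a left/right lung mask into 33 regions.

The lung field is divided across four levels:

* level 0 — whole lung (1 region),
* level 1 — right / left lung (2 regions),
* level 2 — upper / middle / lower thirds per lung (6 regions),
* level 3 — upper/middle/lower x ventral/dorsal x inner/outer per lung
  (24 regions).

Splits are *nested* volume-ratio cuts: cranio-caudal 1:1:1 within each lung,
antero-posterior 1:1 within each third, and medio-lateral 1:2 (inner:outer,
inner = mediastinal side) within each sextant, so each level exactly refines
the previous one.  Every cut is a whole-slice cut perpendicular to one grid
axis; the cut indices are chosen to minimise the maximum absolute deviation
between achieved and target cumulative volume fractions, with ties broken
toward the smaller index, so the partition is deterministic and robust to
resolution.

Axis convention (declared, not inferred): axis 0 is cranio-caudal with the
slice index increasing caudally, axis 1 is antero-posterior increasing
dorsally, axis 2 is medio-lateral in either direction — the mediastinal side
of each lung is located from the mask itself (the side facing the whole-lung
centroid), so mirrored volumes partition mirror-symmetrically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "PartitionError",
    "LungMask",
    "RegionPartition",
    "split_axis_by_volume",
    "partition_lung",
    "LEVEL3_NAMES",
    "COARSE_NAMES",
    "ALL_REGION_NAMES",
    "RIGHT_LUNG",
    "LEFT_LUNG",
]


class PartitionError(ValueError):
    """A lung mask cannot be partitioned as requested."""


RIGHT_LUNG = 1
LEFT_LUNG = 2

SIDES = ("right", "left")
VERTICAL = ("upper", "middle", "lower")
ANTERO_POSTERIOR = ("ventral", "dorsal")
MEDIO_LATERAL = ("inner", "outer")

#: canonical order of the 24 level-3 regions; the level-3 label map uses
#: code = index + 1
LEVEL3_NAMES: tuple[str, ...] = tuple(
    f"{side}_{vert}_{ap}_{ml}"
    for side in SIDES
    for vert in VERTICAL
    for ap in ANTERO_POSTERIOR
    for ml in MEDIO_LATERAL
)

#: canonical order of the 9 coarse regions (level 0 + level 1 + level 2)
COARSE_NAMES: tuple[str, ...] = (
    "whole",
    "right",
    "left",
    "right_upper",
    "right_middle",
    "right_lower",
    "left_upper",
    "left_middle",
    "left_lower",
)

ALL_REGION_NAMES: tuple[str, ...] = COARSE_NAMES + LEVEL3_NAMES


def _level3_codes_for(name: str) -> tuple[int, ...]:
    """Level-3 codes contained in a named region at any level."""
    if name == "whole":
        prefix = ""
    elif name in SIDES:
        prefix = name + "_"
    else:
        prefix = name + "_"
    return tuple(i + 1 for i, n in enumerate(LEVEL3_NAMES) if n.startswith(prefix))


#: region name -> member level-3 codes, for all 33 regions
REGION_MEMBERS: dict[str, tuple[int, ...]] = {
    **{name: _level3_codes_for(name) for name in COARSE_NAMES},
    **{name: (i + 1,) for i, name in enumerate(LEVEL3_NAMES)},
}

LEVEL_REGIONS: dict[int, tuple[str, ...]] = {
    0: ("whole",),
    1: SIDES,
    2: COARSE_NAMES[3:],
    3: LEVEL3_NAMES,
}


@dataclass
class LungMask:
    """Lung segmentation on a voxel grid.

    ``data`` holds 0 = background, 1 = right lung, 2 = left lung.
    ``spacing`` is the physical voxel size in mm along (axis0, axis1, axis2).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PartitionError("lung mask must be a 3-D volume")
        if any(s <= 0 for s in self.spacing):
            raise PartitionError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LungMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj).astype(np.uint8), spacing)

    def to_nifti(self, path: str | Path) -> None:
        _save_nifti(self.data.astype(np.uint8), self.spacing, path)


def _save_nifti(data: np.ndarray, spacing: Sequence[float], path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def split_axis_by_volume(
    mask: np.ndarray, axis: int, ratios: Sequence[float]
) -> list[np.ndarray]:
    """Split a voxel set into contiguous whole-slice slabs along one axis.

    The cut indices minimise the maximum absolute deviation between achieved
    and target cumulative volume fractions, searched exhaustively over all
    cut positions within the occupied slice range; ties break toward smaller
    cut indices.  Returns boolean masks that partition ``mask``.
    """
    mask = np.asarray(mask, dtype=bool)
    ratios = [float(r) for r in ratios]
    if len(ratios) < 2:
        raise PartitionError("need at least 2 ratios")
    if any(r <= 0 for r in ratios):
        raise PartitionError("ratios must be positive")

    other_axes = tuple(a for a in range(mask.ndim) if a != axis)
    counts = mask.sum(axis=other_axes)
    occupied = np.flatnonzero(counts)
    if occupied.size == 0:
        raise PartitionError("empty mask")
    lo, hi = int(occupied[0]), int(occupied[-1])
    n_slices = hi - lo + 1
    if n_slices < len(ratios):
        raise PartitionError(
            f"mask spans {n_slices} slices along axis {axis}; cannot cut into {len(ratios)} slabs"
        )

    local = counts[lo : hi + 1].astype(np.float64)
    cum = np.cumsum(local) / local.sum()
    targets = np.cumsum(ratios)[:-1] / sum(ratios)

    # Exhaustive search over interior cut positions; a cut at position c puts
    # local slices [0, c) in the slab before the cut.
    best: tuple[int, ...] | None = None
    best_dev = np.inf
    for cuts in itertools.combinations(range(1, n_slices), len(ratios) - 1):
        dev = max(abs(cum[c - 1] - t) for c, t in zip(cuts, targets))
        if dev < best_dev - 1e-15:
            best_dev = dev
            best = cuts
    assert best is not None

    bounds = (lo,) + tuple(lo + c for c in best) + (hi + 1,)
    slabs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        slab = np.zeros_like(mask)
        index = [slice(None)] * mask.ndim
        # extend the first/last slab to the grid edge so slabs cover the mask
        index[axis] = slice(a if a != lo else 0, b if b != hi + 1 else mask.shape[axis])
        slab[tuple(index)] = mask[tuple(index)]
        slabs.append(slab)
    return slabs


@dataclass
class RegionPartition:
    """The 33-region hierarchy encoded as a level-3 label map.

    ``level3`` assigns each lung voxel a code 1..24 (0 outside the lung);
    every coarser region is a union of level-3 codes (``REGION_MEMBERS``),
    which makes the nesting and conservation invariants structural.
    """

    level3: np.ndarray
    spacing: tuple[float, float, float]

    names = ALL_REGION_NAMES
    level_regions = LEVEL_REGIONS
    members = REGION_MEMBERS

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of a named region (any of the 33)."""
        codes = REGION_MEMBERS[name]
        if len(codes) == 24:
            return self.level3 > 0
        return np.isin(self.level3, codes)

    def iter_level(self, level: int) -> Iterator[tuple[str, np.ndarray]]:
        for name in LEVEL_REGIONS[level]:
            yield name, self.mask(name)

    def volume_ml(self, name: str) -> float:
        sx, sy, sz = self.spacing
        return float(self.mask(name).sum()) * sx * sy * sz / 1000.0

    def to_nifti(self, path: str | Path) -> None:
        """Write the level-3 label map plus a JSON lookup for coarser levels."""
        _save_nifti(self.level3.astype(np.uint8), self.spacing, path)
        lookup = {
            "level3_codes": {name: i + 1 for i, name in enumerate(LEVEL3_NAMES)},
            "region_members": {k: list(v) for k, v in REGION_MEMBERS.items()},
        }
        p = Path(str(path))
        stem = p.name[: -len(".nii.gz")] if p.name.endswith(".nii.gz") else p.stem
        (p.parent / f"{stem}_regions.json").write_text(json.dumps(lookup, indent=1))


def _medial_high(side_mask: np.ndarray, whole_centroid: float) -> bool:
    """True if the mediastinal (inner) side of this lung lies at high axis-2
    indices, i.e. the lung sits on the low-index side of the whole-lung
    centroid."""
    idx = np.flatnonzero(side_mask.sum(axis=(0, 1)))
    counts = side_mask.sum(axis=(0, 1))[idx]
    side_centroid = float((idx * counts).sum() / counts.sum())
    return side_centroid <= whole_centroid


def partition_lung(mask: LungMask) -> RegionPartition:
    """Build the full 33-region hierarchy from a left/right lung mask."""
    data = mask.data
    level3 = np.zeros(data.shape, dtype=np.uint8)

    both = data > 0
    if not both.any():
        raise PartitionError("empty lung mask")
    cols = both.sum(axis=(0, 1))
    whole_centroid = float((np.arange(data.shape[2]) * cols).sum() / cols.sum())

    code = {name: i + 1 for i, name in enumerate(LEVEL3_NAMES)}
    for side, label in (("right", RIGHT_LUNG), ("left", LEFT_LUNG)):
        side_mask = data == label
        if not side_mask.any():
            raise PartitionError(f"{side} lung absent from mask")
        inner_high = _medial_high(side_mask, whole_centroid)

        thirds = split_axis_by_volume(side_mask, axis=0, ratios=(1, 1, 1))
        for vert, third in zip(VERTICAL, thirds):
            halves = split_axis_by_volume(third, axis=1, ratios=(1, 1))
            for ap, half in zip(ANTERO_POSTERIOR, halves):
                # medio-lateral 1:2 inner:outer; slab order follows the axis,
                # so the ratio order depends on which end is mediastinal
                if inner_high:
                    outer, inner = split_axis_by_volume(half, axis=2, ratios=(2, 1))
                else:
                    inner, outer = split_axis_by_volume(half, axis=2, ratios=(1, 2))
                level3[inner] = code[f"{side}_{vert}_{ap}_inner"]
                level3[outer] = code[f"{side}_{vert}_{ap}_outer"]

    assert ((level3 > 0) == both).all()
    return RegionPartition(level3=level3, spacing=mask.spacing)
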