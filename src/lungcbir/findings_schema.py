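"""Finding-label schema: the 26 parenchymal finding categories, their coarse
11-group regrouping, and the lesion definition.

A finding-label volume assigns every voxel one small integer code:

* ``0`` — background (outside the lung mask),
* ``1..26`` — one of the 26 parenchymal finding categories,
* ``27`` / ``28`` — airway / vessel.  These lie inside the lung mask but are
  *not* findings: they contribute to region volumes (denominators) and never
  to finding percentages (numerators).

Two derived structures drive feature extraction and similarity weighting:

* the **coarse groups** — an 11-way partition of the 26 findings used for the
  wide regions (whole lung, per-lung, sextants), where related findings such
  as the bronchiectasis family are pooled;
* the **lesion set** — the 24 findings other than normal lung and the
  borderline-normal category; the regional lesion fraction feeds the area
  weight of the similarity measure.

The schema is shipped as a versioned JSON file (``data/findings_schema.json``)
so that label volumes written by other tools can declare the same dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

__all__ = [
    "FindingLabel",
    "SchemaError",
    "BACKGROUND",
    "AIRWAY",
    "VESSEL",
    "NORMAL_LUNG",
    "BORDERLINE_NORMAL",
    "FINDINGS",
    "FINDING_CODES",
    "COARSE_GROUPS",
    "N_FINDINGS",
    "N_COARSE_GROUPS",
    "LESION_CODES",
    "VALID_VOLUME_CODES",
    "coarse_group_of",
    "is_lesion",
    "finding_name",
    "schema_dict",
]


class SchemaError(KeyError):
    """Raised for label codes outside the schema."""


# Reserved auxiliary codes (never findings).
BACKGROUND = 0
AIRWAY = 27
VESSEL = 28

NORMAL_LUNG = 20
BORDERLINE_NORMAL = 21


@dataclass(frozen=True)
class FindingLabel:
    """One of the 26 parenchymal finding categories."""

    code: int
    name: str
    group: int
    lesion: bool


def _load_schema() -> dict:
    with resources.files("lungcbir.data").joinpath("findings_schema.json").open() as fh:
        return json.load(fh)


_SCHEMA = _load_schema()

FINDINGS: Mapping[int, FindingLabel] = {
    entry["code"]: FindingLabel(entry["code"], entry["name"], entry["group"], entry["lesion"])
    for entry in _SCHEMA["findings"]
}

FINDING_CODES: tuple[int, ...] = tuple(sorted(FINDINGS))
N_FINDINGS = len(FINDING_CODES)
N_COARSE_GROUPS = len(_SCHEMA["coarse_groups"])

#: group index -> frozenset of member finding codes (partition of the findings)
COARSE_GROUPS: Mapping[int, frozenset[int]] = {
    g: frozenset(f.code for f in FINDINGS.values() if f.group == g)
    for g in range(1, N_COARSE_GROUPS + 1)
}

#: the 24 findings that count as lesion
LESION_CODES: frozenset[int] = frozenset(f.code for f in FINDINGS.values() if f.lesion)

#: every code a finding-label volume may legally contain
VALID_VOLUME_CODES: frozenset[int] = frozenset(FINDING_CODES) | {BACKGROUND, AIRWAY, VESSEL}


def _check(code: int) -> FindingLabel:
    try:
        return FINDINGS[int(code)]
    except (KeyError, ValueError, TypeError):
        raise SchemaError(f"unknown finding code: {code!r}") from None


def coarse_group_of(code: int) -> int:
    """Coarse group index (1..11) of a finding code."""
    return _check(code).group


def is_lesion(code: int) -> bool:
    """Whether a finding counts as lesion (all but normal lung and
    borderline between normal and hyperlucency)."""
    return _check(code).lesion


def finding_name(code: int) -> str:
    return _check(code).name


def schema_dict() -> dict:
    """The shipped machine-readable schema (a fresh copy)."""
    return json.loads(json.dumps(_SCHEMA))


# Internal sanity: the schema file must describe a valid dialect.
assert FINDING_CODES == tuple(range(1, 27)), "finding codes must be contiguous 1..26"
assert sum(len(m) for m in COARSE_GROUPS.values()) == N_FINDINGS
assert len(LESION_CODES) == 24
assert NORMAL_LUNG not in LESION_CODES and BORDERLINE_NORMAL not in LESION_CODES
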