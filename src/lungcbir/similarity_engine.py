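"""Weighted multi-level similarity between two quantified cases.

The dissimilarity between a query q and a database candidate c is a weighted
sum of four per-level terms, one per tier of the 33-region hierarchy::

    S_k = sum_m  wr(m) * sqrt( sum_n  wf(m, n) * (zc(m, n) - zq(m, n))^2 )

where m runs over the regions of level k, n over that level's features
(12 coarse features for levels 0-2, 30 fine features for level 3), and z are
database-normalized feature values.  At level 3 the 26 per-finding fractions
form a wf-weighted block and the remaining four features (volume, CT mean,
CT variance, lesion fraction) an unweighted block, each under its own square
root; both share the region's area weight.

Two logistic weights shape the comparison (arguments are *raw* proportions
on [0, 1], never z-scores):

* **area weight** ``wr(p) = 1 / (1 + exp(-5.0 * (p - 0.5)))`` of the QUERY's
  regional lesion proportion — regions where the query actually has disease
  dominate the comparison;
* **feature weight** ``wf(p) = 1.5 / (1 + exp(300.0 * p)) + 0.25`` of the
  CANDIDATE's raw finding (or group) proportion — a steep decay that boosts
  findings that are rare in the candidate.  The volume feature of the coarse
  levels is not a finding and carries wf = 1.

The level weights ws_k = 1/(M_k * sqrt(N_k)) (level 3:
1/(M_3 * (sqrt(26) + sqrt(4)))) make a uniform unit z-difference contribute
equally through every level, which is the stated intent of the level
weighting; they are configurable.

Because wr depends on the query and wf on the candidate, S_total is
intentionally asymmetric.  Lower S_total means more similar; retrieval sorts
ascending with lexicographic case-id tie-breaking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .case_database import CaseDatabase, NormalizationStats, NormalizedCase
from .feature_extraction import N_COARSE_FEATURES

__all__ = [
    "SimilarityConfig",
    "SimilarityBreakdown",
    "RetrievalResult",
    "area_weight",
    "feature_weight",
    "level_similarity",
    "level3_similarity",
    "total_similarity",
    "retrieve",
    "DEFAULT_CONFIG",
]

#: coarse-region row indices of each coarse level (rows of the (9, 12) block)
LEVEL_ROWS = {0: (0,), 1: (1, 2), 2: (3, 4, 5, 6, 7, 8)}

#: lesion-proportion indices: rows 0..8 of CaseFeatures.lesion are the coarse
#: regions, rows 9..32 the 24 level-3 regions
LEVEL3_LESION_OFFSET = 9

N_FINDINGS_FINE = 26


def _default_ws() -> tuple[float, float, float, float]:
    return (
        1.0 / (1 * math.sqrt(12)),
        1.0 / (2 * math.sqrt(12)),
        1.0 / (6 * math.sqrt(12)),
        1.0 / (24 * (math.sqrt(26) + math.sqrt(4))),
    )


@dataclass(frozen=True)
class SimilarityConfig:
    """Constants of the similarity measure (defaults are the printed values)."""

    wr_gain: float = 5.0
    wr_center: float = 0.5
    wf_scale: float = 1.5
    wf_gain: float = 300.0
    wf_floor: float = 0.25
    ws: tuple[float, float, float, float] = field(default_factory=_default_ws)

    def with_ws(self, ws: Sequence[float]) -> "SimilarityConfig":
        return replace(self, ws=tuple(float(w) for w in ws))


DEFAULT_CONFIG = SimilarityConfig()


@dataclass(frozen=True)
class SimilarityBreakdown:
    """The four level dissimilarities and their weighted total."""

    s0: float
    s1: float
    s2: float
    s3: float
    ws: tuple[float, float, float, float]
    s_total: float

    @property
    def levels(self) -> tuple[float, float, float, float]:
        return (self.s0, self.s1, self.s2, self.s3)


@dataclass(frozen=True)
class RetrievalResult:
    """Ranked candidates, ascending in s_total (most similar first)."""

    query_id: str
    ranking: tuple[tuple[str, SimilarityBreakdown], ...]
    k_requested: int

    @property
    def truncated(self) -> bool:
        """True when fewer candidates existed than were requested."""
        return len(self.ranking) < self.k_requested

    def ids(self) -> list[str]:
        return [cid for cid, _ in self.ranking]


def _check_unit(p: np.ndarray | float, what: str) -> np.ndarray:
    arr = np.asarray(p, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{what} must lie in [0, 1], got {p!r}")
    return arr


def area_weight(lesion_proportion, config: SimilarityConfig = DEFAULT_CONFIG):
    """Logistic area weight of a regional lesion proportion (query side)."""
    p = _check_unit(lesion_proportion, "lesion proportion")
    out = 1.0 / (1.0 + np.exp(-config.wr_gain * (p - config.wr_center)))
    return float(out) if np.isscalar(lesion_proportion) else out


def feature_weight(finding_proportion, config: SimilarityConfig = DEFAULT_CONFIG):
    """Decaying feature weight of a raw finding proportion (candidate side)."""
    p = _check_unit(finding_proportion, "finding proportion")
    out = config.wf_scale / (1.0 + np.exp(config.wf_gain * p)) + config.wf_floor
    return float(out) if np.isscalar(finding_proportion) else out


def level_similarity(
    query: NormalizedCase,
    candidate: NormalizedCase,
    level: int,
    config: SimilarityConfig = DEFAULT_CONFIG,
) -> float:
    """Coarse-level dissimilarity S0, S1 or S2."""
    rows = np.array(LEVEL_ROWS[level])
    dz = candidate.coarse_z[rows] - query.coarse_z[rows]  # (M, 12)
    wf = feature_weight(candidate.raw.coarse[rows, : N_COARSE_FEATURES - 1], config)
    wf = np.concatenate([wf, np.ones((len(rows), 1))], axis=1)  # volume: wf = 1
    wr = area_weight(query.raw.lesion[rows], config)
    return float(np.sum(wr * np.sqrt(np.sum(wf * dz**2, axis=1))))


def level3_similarity(
    query: NormalizedCase,
    candidate: NormalizedCase,
    config: SimilarityConfig = DEFAULT_CONFIG,
) -> float:
    """Fine-level dissimilarity S3 over the 24 level-3 regions."""
    dz = candidate.fine_z - query.fine_z  # (24, 30)
    wf = feature_weight(candidate.raw.fine[:, :N_FINDINGS_FINE], config)
    wr = area_weight(query.raw.lesion[LEVEL3_LESION_OFFSET:], config)
    findings_term = np.sqrt(np.sum(wf * dz[:, :N_FINDINGS_FINE] ** 2, axis=1))
    other_term = np.sqrt(np.sum(dz[:, N_FINDINGS_FINE:] ** 2, axis=1))
    return float(np.sum(wr * findings_term) + np.sum(wr * other_term))


def total_similarity(
    query: NormalizedCase,
    candidate: NormalizedCase,
    config: SimilarityConfig = DEFAULT_CONFIG,
) -> SimilarityBreakdown:
    """All four level dissimilarities and their ws-weighted total."""
    s = (
        level_similarity(query, candidate, 0, config),
        level_similarity(query, candidate, 1, config),
        level_similarity(query, candidate, 2, config),
        level3_similarity(query, candidate, config),
    )
    total = float(np.dot(config.ws, s))
    return SimilarityBreakdown(*s, ws=config.ws, s_total=total)


def retrieve(
    query_id: str,
    db: CaseDatabase,
    k: int = 5,
    config: SimilarityConfig = DEFAULT_CONFIG,
    stats: NormalizationStats | None = None,
) -> RetrievalResult:
    """Rank the k most similar registered cases for a registered query.

    The query is excluded from the candidate set.  Normalization uses
    ``stats`` if given (e.g. leave-one-out statistics), else the database's
    stored statistics, which must have been computed.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if query_id not in db:
        raise KeyError(f"unknown query id: {query_id!r}")
    stats = stats if stats is not None else db.stats
    if stats is None:
        raise ValueError("normalization statistics not computed; call compute_stats()")

    qn = db.normalize(db.cases[query_id], stats)
    scored: list[tuple[float, str, SimilarityBreakdown]] = []
    for cid, case in db.cases.items():
        if cid == query_id:
            continue
        breakdown = total_similarity(qn, db.normalize(case, stats), config)
        scored.append((breakdown.s_total, cid, breakdown))
    scored.sort(key=lambda t: (t[0], t[1]))
    top = tuple((cid, br) for _, cid, br in scored[:k])
    return RetrievalResult(query_id=query_id, ranking=top, k_requested=k)
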