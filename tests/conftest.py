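"""Shared fixtures and the independent scalar-loop similarity oracle.

The oracle recomputes normalization and all four level dissimilarities with
plain Python loops straight from the formula definitions, sharing no code
with the vectorized engine.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from lungcbir.case_database import NormalizationStats
from lungcbir.feature_extraction import CaseFeatures
from lungcbir.region_partition import LungMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def cuboid_lungs():
    """Two solid 30 x 20 x 30 cuboid 'lungs' (right at low axis-2 indices)."""
    mask = np.zeros((30, 20, 70), dtype=np.uint8)
    mask[:, :, 2:32] = 1   # right lung
    mask[:, :, 38:68] = 2  # left lung
    return LungMask(mask, spacing=(1.0, 1.0, 1.0))


def make_case(rng: np.random.Generator, case_id: str, labels: dict | None = None) -> CaseFeatures:
    """Random but internally consistent CaseFeatures (all proportions in [0, 1])."""
    coarse = np.zeros((9, 12))
    raw = rng.random((9, 11))
    coarse[:, :11] = raw / raw.sum(axis=1, keepdims=True) * rng.uniform(0.2, 0.95, size=(9, 1))
    coarse[:, 11] = rng.uniform(100, 5000, size=9)

    fine = np.zeros((24, 30))
    raw = rng.random((24, 26))
    fine[:, :26] = raw / raw.sum(axis=1, keepdims=True) * rng.uniform(0.2, 0.95, size=(24, 1))
    fine[:, 26] = rng.uniform(10, 400, size=24)
    fine[:, 27] = rng.uniform(-950, 0, size=24)
    fine[:, 28] = rng.uniform(0, 1e4, size=24)
    fine[:, 29] = fine[:, :26].sum(axis=1) - fine[:, 19] - fine[:, 20]

    lesion = rng.uniform(0, 1, size=33)
    return CaseFeatures(case_id, coarse, fine, lesion, labels=dict(labels or {}))


# ---------------------------------------------------------------------------
# independent oracle: pure-Python, loop-by-loop transliteration of the formulas
# ---------------------------------------------------------------------------

WR = lambda p: 1.0 / (1.0 + math.exp(-5.0 * (p - 0.5)))
WF = lambda p: 1.5 / (1.0 + math.exp(min(300.0 * p, 700.0))) + 0.25

COARSE_LEVEL_ROWS = {0: [0], 1: [1, 2], 2: [3, 4, 5, 6, 7, 8]}


def oracle_z(x: float, mean: float, std: float) -> float:
    return 0.0 if std == 0 else (x - mean) / std


def oracle_level_similarity(
    query: CaseFeatures, cand: CaseFeatures, stats: NormalizationStats, level: int
) -> float:
    s = 0.0
    for m in COARSE_LEVEL_ROWS[level]:
        inner = 0.0
        for n in range(12):
            zq = oracle_z(query.coarse[m, n], stats.coarse_mean[m, n], stats.coarse_std[m, n])
            zc = oracle_z(cand.coarse[m, n], stats.coarse_mean[m, n], stats.coarse_std[m, n])
            wf = WF(cand.coarse[m, n]) if n < 11 else 1.0
            inner += wf * (zc - zq) ** 2
        s += WR(query.lesion[m]) * math.sqrt(inner)
    return s


def oracle_level3_similarity(
    query: CaseFeatures, cand: CaseFeatures, stats: NormalizationStats
) -> float:
    first = 0.0
    second = 0.0
    for m in range(24):
        wr = WR(query.lesion[9 + m])
        inner_a = 0.0
        for n in range(26):
            zq = oracle_z(query.fine[m, n], stats.fine_mean[m, n], stats.fine_std[m, n])
            zc = oracle_z(cand.fine[m, n], stats.fine_mean[m, n], stats.fine_std[m, n])
            inner_a += WF(cand.fine[m, n]) * (zc - zq) ** 2
        inner_b = 0.0
        for n in range(26, 30):
            zq = oracle_z(query.fine[m, n], stats.fine_mean[m, n], stats.fine_std[m, n])
            zc = oracle_z(cand.fine[m, n], stats.fine_mean[m, n], stats.fine_std[m, n])
            inner_b += (zc - zq) ** 2
        first += wr * math.sqrt(inner_a)
        second += wr * math.sqrt(inner_b)
    return first + second


def oracle_total_similarity(
    query: CaseFeatures, cand: CaseFeatures, stats: NormalizationStats
) -> tuple[float, float, float, float, float]:
    s0 = oracle_level_similarity(query, cand, stats, 0)
    s1 = oracle_level_similarity(query, cand, stats, 1)
    s2 = oracle_level_similarity(query, cand, stats, 2)
    s3 = oracle_level3_similarity(query, cand, stats)
    ws = [
        1.0 / (1 * math.sqrt(12)),
        1.0 / (2 * math.sqrt(12)),
        1.0 / (6 * math.sqrt(12)),
        1.0 / (24 * (math.sqrt(26) + math.sqrt(4))),
    ]
    total = ws[0] * s0 + ws[1] * s1 + ws[2] * s2 + ws[3] * s3
    return s0, s1, s2, s3, total


def oracle_stats(cases: list[CaseFeatures]) -> NormalizationStats:
    """Two-pass population mean/std with plain Python accumulation."""
    n = len(cases)

    def two_pass(block):
        arrs = [getattr(c, block) for c in cases]
        shape = arrs[0].shape
        mean = np.zeros(shape)
        for a in arrs:
            mean += a
        mean /= n
        var = np.zeros(shape)
        for a in arrs:
            var += (a - mean) ** 2
        return mean, np.sqrt(var / n)

    cm, cs = two_pass("coarse")
    fm, fsd = two_pass("fine")
    return NormalizationStats(cm, cs, fm, fsd, n)
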