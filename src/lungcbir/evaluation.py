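"""Label-concordance evaluation of retrieval results.

For each query the top-k (default 5) retrieved cases are compared to the
query on one binary label axis (ILD / non-ILD, or with-UIP / without-UIP);
the *concordance* is the fraction of retrieved cases sharing the query's
label.  A leave-one-out run treats each selected case in turn as the query,
recomputing the normalization statistics over the remaining cases so the
query never influences its own search.

The summary reports, per label: the number of queries, the histogram of
match counts (k/k ... 0/k), mean +/- deviation of concordance, and a
normal-approximation 95% confidence interval; plus the pooled accuracy over
both labels and an equal-variance two-sample t-test between them (Welch's
variant available behind a flag).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .case_database import CaseDatabase
from .similarity_engine import DEFAULT_CONFIG, SimilarityConfig, retrieve

__all__ = [
    "ConcordanceRecord",
    "GroupSummary",
    "ConcordanceSummary",
    "label_concordance",
    "summarize",
    "run_leave_one_out",
    "summary_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceRecord:
    """Top-k label agreement for one query."""

    query_id: str
    query_label: str
    matches_in_topk: int
    k: int

    @property
    def concordance(self) -> float:
        return self.matches_in_topk / self.k


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n_queries: int
    histogram: tuple[int, ...]  # counts of k/k, (k-1)/k, ..., 0/k
    mean: float
    deviation: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class ConcordanceSummary:
    groups: tuple[GroupSummary, GroupSummary]
    pooled_accuracy: float
    pooled_deviation: float
    t_statistic: float | None
    p_value: float | None
    k: int


def label_concordance(
    query_id: str, query_label: str, retrieved_labels: Sequence[str | None], k: int | None = None
) -> ConcordanceRecord:
    """Concordance record for one query against its retrieved labels."""
    k = k if k is not None else len(retrieved_labels)
    if len(retrieved_labels) != k:
        raise ValueError(f"expected {k} retrieved labels, got {len(retrieved_labels)}")
    if any(lab is None or lab == "" for lab in retrieved_labels):
        raise ValueError(f"query {query_id!r}: a retrieved case is missing its label")
    matches = sum(1 for lab in retrieved_labels if lab == query_label)
    return ConcordanceRecord(query_id, query_label, matches, k)


def _group_summary(label: str, records: Sequence[ConcordanceRecord], k: int) -> GroupSummary:
    values = np.array([r.concordance for r in records])
    hist = tuple(int(sum(1 for r in records if r.matches_in_topk == m)) for m in range(k, -1, -1))
    mean = float(values.mean()) if len(values) else math.nan
    sd = float(values.std()) if len(values) else math.nan
    half = 1.96 * sd / math.sqrt(len(values)) if len(values) else math.nan
    return GroupSummary(label, len(records), hist, mean, sd, (mean - half, mean + half))


def summarize(
    records: Sequence[ConcordanceRecord],
    group_a_label: str,
    group_b_label: str,
    welch: bool = False,
) -> ConcordanceSummary:
    """Per-label summaries, pooled accuracy and the between-label t-test."""
    if not records:
        raise ValueError("no concordance records to summarize")
    k = records[0].k
    a = [r for r in records if r.query_label == group_a_label]
    b = [r for r in records if r.query_label == group_b_label]
    pooled = np.array([r.concordance for r in a + b])

    t_stat: float | None = None
    p_val: float | None = None
    if len(a) >= 2 and len(b) >= 2:
        with warnings.catch_warnings():
            # near-constant groups are routine here; degenerate outcomes are
            # handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sstats.ttest_ind(
                [r.concordance for r in a], [r.concordance for r in b], equal_var=not welch
            )
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        if math.isnan(t_stat):  # identical constant groups: no separation
            t_stat, p_val = 0.0, 1.0
    else:
        logger.warning("degenerate group sizes (%d vs %d); t-test skipped", len(a), len(b))

    return ConcordanceSummary(
        groups=(_group_summary(group_a_label, a, k), _group_summary(group_b_label, b, k)),
        pooled_accuracy=float(pooled.mean()),
        pooled_deviation=float(pooled.std()),
        t_statistic=t_stat,
        p_value=p_val,
        k=k,
    )


def run_leave_one_out(
    db: CaseDatabase,
    query_ids: Sequence[str] | None = None,
    label_axis: str = "ILD",
    k: int = 5,
    config: SimilarityConfig = DEFAULT_CONFIG,
) -> list[ConcordanceRecord]:
    """Leave-one-out retrieval with per-query re-normalization.

    Each query is searched against the database minus itself, with the
    normalization statistics recomputed over those remaining cases.
    Concordance is only defined over labeled cases, so cases without a label
    on the chosen axis take no part in the run (skipped with a warning).
    """
    unlabeled = [cid for cid, c in db.cases.items() if not c.labels.get(label_axis)]
    search_db = db
    if unlabeled:
        logger.warning(
            "%d case(s) lack a %s label and are excluded from the run: %s",
            len(unlabeled), label_axis, unlabeled[:5],
        )
        search_db = CaseDatabase()
        search_db.register_all(c for cid, c in db.cases.items() if cid not in unlabeled)

    ids = list(query_ids) if query_ids is not None else list(search_db.cases)
    records: list[ConcordanceRecord] = []
    for qid in ids:
        if qid in unlabeled:
            logger.warning("query %r has no %s label; skipped", qid, label_axis)
            continue
        query = search_db.cases[qid]
        loo_stats = search_db.compute_stats(exclude=[qid])
        result = retrieve(qid, search_db, k=k, config=config, stats=loo_stats)
        retrieved = [search_db.cases[cid].labels.get(label_axis) for cid in result.ids()]
        records.append(
            label_concordance(qid, query.labels[label_axis], retrieved, k=len(retrieved))
        )
    return records


def summary_table(summary: ConcordanceSummary) -> pd.DataFrame:
    """The summary as a table: one row per label plus a pooled total."""
    k = summary.k
    cols = [f"{m}/{k}" for m in range(k, -1, -1)]
    rows = []
    for g in summary.groups:
        rows.append(
            {"label": g.label, "n_queries": g.n_queries, **dict(zip(cols, g.histogram)),
             "mean": g.mean, "deviation": g.deviation,
             "ci95_low": g.ci95[0], "ci95_high": g.ci95[1]}
        )
    total_hist = [sum(g.histogram[i] for g in summary.groups) for i in range(k + 1)]
    n_total = sum(g.n_queries for g in summary.groups)
    half = 1.96 * summary.pooled_deviation / math.sqrt(n_total) if n_total else math.nan
    rows.append(
        {"label": "Total", "n_queries": n_total, **dict(zip(cols, total_hist)),
         "mean": summary.pooled_accuracy, "deviation": summary.pooled_deviation,
         "ci95_low": summary.pooled_accuracy - half, "ci95_high": summary.pooled_accuracy + half}
    )
    return pd.DataFrame(rows)
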