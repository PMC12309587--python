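"""Fast internal consistency checks, exposed as ``lungcbir selftest``.

These verify the closed-form properties of the similarity measure, the
partition hierarchy on a synthetic mask, and retrieval sanity on a tiny
generated cohort.  They complement (and are narrower than) the test suite.
"""

from __future__ import annotations

import math

import numpy as np

from .case_database import CaseDatabase
from .region_partition import LungMask, partition_lung
from .similarity_engine import area_weight, feature_weight, retrieve, total_similarity
from .synthetic_data import CohortSpec, build_database, generate_cohort


def run() -> list[str]:
    """Run all checks; return a list of failure descriptions (empty = pass)."""
    failures: list[str] = []

    def check(ok: bool, what: str) -> None:
        if not ok:
            failures.append(what)

    # logistic weight anchors
    check(abs(area_weight(0.5) - 0.5) < 1e-12, "area_weight(0.5) != 0.5")
    check(abs(area_weight(0.0) - 1.0 / (1.0 + math.exp(2.5))) < 1e-12, "area_weight(0) anchor")
    check(abs(feature_weight(0.0) - 1.0) < 1e-12, "feature_weight(0) != 1")
    check(abs(feature_weight(1.0) - 0.25) < 1e-9, "feature_weight(1) floor")

    # partition hierarchy on a cuboid pair of lungs
    mask = np.zeros((30, 20, 32), dtype=np.uint8)
    mask[:, :, 2:14] = 1
    mask[:, :, 18:30] = 2
    part = partition_lung(LungMask(mask))
    check(len(part.names) == 33, "region count != 33")
    check(int((part.level3 > 0).sum()) == int((mask > 0).sum()), "level-3 map does not cover the mask")
    for level in (0, 1, 2, 3):
        total = sum(int(m.sum()) for _, m in part.iter_level(level))
        check(total == int((mask > 0).sum()), f"level {level} does not conserve volume")

    # retrieval sanity on a tiny cohort: self-duplicate ranks first at 0
    cases = generate_cohort(CohortSpec([("uip_like", 2), ("normal", 2)], grid=(32, 32, 32), seed=7))
    db = build_database(cases)
    dup = cases[0].features()
    dup.case_id = "duplicate_of_first"
    db.register_case(dup)
    db.compute_stats()
    result = retrieve("duplicate_of_first", db, k=1)
    check(result.ranking[0][0] == cases[0].case_id, "duplicate query does not rank its twin first")
    check(result.ranking[0][1].s_total < 1e-12, "duplicate pair has nonzero distance")

    qn = db.normalize(db.cases[cases[0].case_id], db.stats)
    check(total_similarity(qn, qn).s_total == 0.0, "self-similarity != 0")

    return failures
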