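"""The weighted multi-level dissimilarity: formula anchors, closed forms,
oracle equivalence, and ranking behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungcbir.case_database import CaseDatabase, NormalizationStats
from lungcbir.feature_extraction import CaseFeatures
from lungcbir.similarity_engine import (
    DEFAULT_CONFIG,
    area_weight,
    feature_weight,
    level3_similarity,
    level_similarity,
    retrieve,
    total_similarity,
)

from conftest import make_case, oracle_total_similarity


def unit_stats() -> NormalizationStats:
    """mean 0 / deviation 1 everywhere: z-scores equal raw values."""
    return NormalizationStats(
        np.zeros((9, 12)), np.ones((9, 12)), np.zeros((24, 30)), np.ones((24, 30)), 1
    )


def zero_case(case_id="z", lesion=0.5) -> CaseFeatures:
    return CaseFeatures(case_id, np.zeros((9, 12)), np.zeros((24, 30)), np.full(33, lesion))


class TestWeights:
    def test_area_weight_anchors(self):
        assert area_weight(0.5) == pytest.approx(0.5, abs=1e-15)
        assert area_weight(0.0) == pytest.approx(1 / (1 + math.exp(2.5)), abs=1e-12)
        assert area_weight(1.0) == pytest.approx(1 / (1 + math.exp(-2.5)), abs=1e-12)
        assert area_weight(0.0) + area_weight(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_feature_weight_anchors(self):
        assert feature_weight(0.0) == pytest.approx(1.0, abs=1e-15)
        assert feature_weight(1.0) == pytest.approx(0.25, abs=1e-15)  # asymptotic floor
        assert feature_weight(0.01) == pytest.approx(1.5 / (1 + math.exp(3.0)) + 0.25, abs=1e-12)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, p, q):
        if p < q:
            assert area_weight(p) <= area_weight(q)
            assert feature_weight(p) >= feature_weight(q)  # saturates at the floor

    def test_strict_monotonicity_on_grid(self):
        grid = np.linspace(0, 1, 21)
        wr = area_weight(grid)
        assert np.all(np.diff(wr) > 0)
        wf = feature_weight(np.linspace(0, 0.04, 21))  # before the floor saturates
        assert np.all(np.diff(wf) < 0)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            area_weight(bad)
        with pytest.raises(ValueError):
            feature_weight(bad)


class TestLevelSimilarities:
    def test_self_similarity_is_zero(self, rng):
        case = make_case(rng, "q")
        stats = oracle_like_stats(rng)
        qn = CaseDatabase.normalize(case, stats)
        for level in (0, 1, 2):
            assert level_similarity(qn, qn, level) == 0.0
        assert level3_similarity(qn, qn) == 0.0
        assert total_similarity(qn, qn).s_total == 0.0

    def test_single_coarse_difference_closed_form(self):
        # one nonzero z-difference d in coarse slot (m, n) reduces the level
        # similarity to wr(lesion_m) * sqrt(wf(raw_mn)) * |d|
        stats = unit_stats()
        q = zero_case("q", lesion=0.3)
        c = zero_case("c")
        m, n, d = 4, 2, 0.8  # a level-2 region, a finding group
        c.coarse[m, n] = d
        qn = CaseDatabase.normalize(q, stats)
        cn = CaseDatabase.normalize(c, stats)
        expected = area_weight(0.3) * math.sqrt(feature_weight(d)) * d
        assert level_similarity(qn, cn, 2) == pytest.approx(expected, abs=1e-12)
        assert level_similarity(qn, cn, 0) == 0.0

    def test_single_volume_difference_has_unit_feature_weight(self):
        stats = unit_stats()
        q, c = zero_case("q", lesion=0.5), zero_case("c")
        c.coarse[0, 11] = 2.5  # the volume feature
        qn, cn = CaseDatabase.normalize(q, stats), CaseDatabase.normalize(c, stats)
        assert level_similarity(qn, cn, 0) == pytest.approx(0.5 * 2.5, abs=1e-12)

    def test_single_ct_mean_difference_closed_form(self):
        # fine features 27-30 form the unweighted block: wr * |dz| only
        stats = unit_stats()
        q, c = zero_case("q", lesion=0.4), zero_case("c")
        c.fine[7, 27] = 1.7  # CT mean of one region
        qn, cn = CaseDatabase.normalize(q, stats), CaseDatabase.normalize(c, stats)
        lesion_7 = q.lesion[9 + 7]
        assert level3_similarity(qn, cn) == pytest.approx(
            area_weight(lesion_7) * 1.7, abs=1e-12
        )

    def test_total_is_weighted_sum(self, rng):
        q, c = make_case(rng, "q"), make_case(rng, "c")
        stats = oracle_like_stats(rng)
        qn, cn = CaseDatabase.normalize(q, stats), CaseDatabase.normalize(c, stats)
        br = total_similarity(qn, cn)
        assert br.s_total == pytest.approx(sum(w * s for w, s in zip(br.ws, br.levels)), rel=1e-15)
        assert all(s >= 0 for s in br.levels)

    def test_query_monotonic_in_feature_gap(self):
        # widening one |fc - fq| from the query side (weights fixed) never
        # decreases any level similarity
        stats = unit_stats()
        c = zero_case("c")
        cn = CaseDatabase.normalize(c, stats)
        prev = -1.0
        for gap in (0.1, 0.5, 1.0, 2.0):
            q = zero_case("q")
            q.fine[3, 10] = gap
            s3 = level3_similarity(CaseDatabase.normalize(q, stats), cn)
            assert s3 > prev
            prev = s3

    def test_uniform_offset_contributes_equally_per_level(self):
        # a constant z-offset in every slot makes each ws_k * S_k identical:
        # the normalization rationale of the level weights
        stats = unit_stats()
        q = zero_case("q", lesion=0.5)
        q.coarse += 0.7
        q.fine += 0.7
        c = zero_case("c")  # raw proportions 0 -> wf = 1 everywhere
        qn, cn = CaseDatabase.normalize(q, stats), CaseDatabase.normalize(c, stats)
        br = total_similarity(qn, cn)
        contributions = [w * s for w, s in zip(br.ws, br.levels)]
        assert np.allclose(contributions, contributions[0], rtol=1e-12)

    def test_asymmetry_on_constructed_pair(self):
        # wr follows the query, wf the candidate: swapping roles changes the value
        stats = unit_stats()
        a = zero_case("a", lesion=0.9)
        b = zero_case("b", lesion=0.1)
        a.coarse[0, 3] = 0.6
        b.coarse[0, 5] = 0.2
        an, bn = CaseDatabase.normalize(a, stats), CaseDatabase.normalize(b, stats)
        s_ab = total_similarity(an, bn).s_total
        s_ba = total_similarity(bn, an).s_total
        assert s_ab != pytest.approx(s_ba, rel=1e-6)


def oracle_like_stats(rng):
    cases = [make_case(rng, f"s{i}") for i in range(8)]
    db = CaseDatabase()
    db.register_all(cases)
    return db.compute_stats()


class TestOracleEquivalence:
    def test_vectorized_matches_scalar_loop_oracle(self, rng):
        cases = [make_case(rng, f"c{i:02d}") for i in range(12)]
        db = CaseDatabase()
        db.register_all(cases)
        stats = db.compute_stats()
        n_pairs = 0
        for q in cases:
            qn = db.normalize(q, stats)
            for c in cases:
                if c.case_id == q.case_id:
                    continue
                br = total_similarity(qn, db.normalize(c, stats))
                o0, o1, o2, o3, ototal = oracle_total_similarity(q, c, stats)
                assert br.s0 == pytest.approx(o0, rel=1e-9)
                assert br.s1 == pytest.approx(o1, rel=1e-9)
                assert br.s2 == pytest.approx(o2, rel=1e-9)
                assert br.s3 == pytest.approx(o3, rel=1e-9)
                assert br.s_total == pytest.approx(ototal, rel=1e-9)
                n_pairs += 1
        assert n_pairs >= 100


class TestRetrieve:
    @pytest.fixture
    def db(self, rng):
        db = CaseDatabase()
        db.register_all(make_case(rng, f"c{i:02d}") for i in range(30))
        db.register_case(make_case(rng, "query"))
        db.compute_stats()
        return db

    def test_duplicate_of_query_ranks_first_at_zero(self, db):
        dup = CaseFeatures(
            "dup", db.cases["query"].coarse, db.cases["query"].fine, db.cases["query"].lesion
        )
        db.register_case(dup)
        db.compute_stats()
        result = retrieve("query", db, k=5)
        assert result.ids()[0] == "dup"
        assert result.ranking[0][1].s_total == pytest.approx(0.0, abs=1e-12)

    def test_ranking_matches_brute_force_oracle(self, db):
        result = retrieve("query", db, k=30)
        stats = db.stats
        q = db.cases["query"]
        scored = sorted(
            (oracle_total_similarity(q, c, stats)[4], cid)
            for cid, c in db.cases.items()
            if cid != "query"
        )
        assert result.ids() == [cid for _, cid in scored]

    def test_ranking_is_ascending(self, db):
        result = retrieve("query", db, k=30)
        totals = [br.s_total for _, br in result.ranking]
        assert totals == sorted(totals)

    def test_tie_break_lexicographic(self, db):
        twin_a = CaseFeatures("aa_twin", db.cases["c00"].coarse, db.cases["c00"].fine, db.cases["c00"].lesion)
        twin_b = CaseFeatures("zz_twin", db.cases["c00"].coarse, db.cases["c00"].fine, db.cases["c00"].lesion)
        db.register_case(twin_b)
        db.register_case(twin_a)
        db.compute_stats()
        ids = retrieve("query", db, k=33).ids()
        assert ids.index("aa_twin") + 1 == ids.index("c00")
        assert ids.index("c00") + 1 == ids.index("zz_twin")

    def test_insertion_order_does_not_change_ranking(self, rng):
        cases = [make_case(rng, f"c{i:02d}") for i in range(15)] + [make_case(rng, "query")]
        db1, db2 = CaseDatabase(), CaseDatabase()
        db1.register_all(cases)
        db2.register_all(reversed(cases))
        db1.compute_stats()
        db2.compute_stats()
        assert retrieve("query", db1, k=15).ids() == retrieve("query", db2, k=15).ids()

    def test_k_larger_than_candidates_is_flagged(self, db):
        result = retrieve("query", db, k=100)
        assert len(result.ranking) == 30
        assert result.truncated

    def test_errors(self, db):
        with pytest.raises(KeyError):
            retrieve("missing", db, k=5)
        with pytest.raises(ValueError):
            retrieve("query", db, k=0)
        db.register_case(make_case(np.random.default_rng(1), "new"))  # stats now stale
        with pytest.raises(ValueError):
            retrieve("query", db, k=5)
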