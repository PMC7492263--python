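"""Composition, enrichment and distribution statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from nucloc.enrichment import (
    bh_adjust,
    fold_enrichment,
    go_enrichment,
    hypergeom_p,
    keyword_screen,
    proteome_overlap,
    score_distribution_test,
    tf_composition,
)
from nucloc.records import Category, ConsensusResult, ProteinRecord


def _cons(pid, votes):
    tools = ("wolfpsort", "yloc", "cello", "nucpred")[:votes]
    return ConsensusResult(pid, votes, Category.from_votes(votes), frozenset(tools))


class TestHypergeometric:
    def test_fold_simple(self):
        assert fold_enrichment(2, 10, 10, 100) == pytest.approx(2.0)

    def test_fold_undefined_reference(self):
        assert fold_enrichment(0, 10, 0, 100) is None

    def test_saturated_draw_is_certain(self):
        assert hypergeom_p(5, 5, 5, 5) == pytest.approx(1.0)

    def test_all_successes_small_universe(self):
        # drawing all 3 successes in 3 draws from 10: 1 / C(10,3)
        assert hypergeom_p(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_matches_enumeration_small_universes(self):
        """Exhaustive subset enumeration for every (k,n,K,N) with N <= 8."""
        for N in range(0, 9):
            for n in range(0, N + 1):
                for K in range(0, N + 1):
                    for k in range(0, min(n, K) + 1):
                        expected = oracles.hypergeom_upper_tail_enum(k, n, K, N)
                        assert hypergeom_p(k, n, K, N) == pytest.approx(
                            expected, abs=1e-12
                        ), (k, n, K, N)

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            hypergeom_p(5, 3, 4, 10)

    def test_category_and_complement_folds_bracket_one(self):
        k, n, K, N = 30, 100, 100, 1000
        f_cat = fold_enrichment(k, n, K, N)
        f_comp = fold_enrichment(K - k, N - n, K, N)
        assert (f_cat - 1) * (f_comp - 1) < 0


class TestBH:
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_q_monotone_in_p_rank(self, ps):
        qs = bh_adjust(ps)
        order = np.argsort(ps)
        sorted_q = [qs[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(sorted_q, sorted_q[1:]))
        assert all(0 <= q <= 1 for q in qs)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_rejection_set_is_p_downward_closed(self, ps):
        """Rejecting at any level never rejects a larger p while keeping a smaller one."""
        qs = bh_adjust(ps)
        for alpha in (0.01, 0.05, 0.1):
            rejected = [p for p, q in zip(ps, qs) if q <= alpha]
            kept = [p for p, q in zip(ps, qs) if q > alpha]
            if rejected and kept:
                assert max(rejected) <= min(kept)

    def test_empty(self):
        assert bh_adjust([]) == []


class TestWelch:
    def test_identical_groups(self):
        assert score_distribution_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_hand_computed_example(self):
        t, p = score_distribution_test([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_degenerate_group_is_missing(self):
        assert score_distribution_test([1.0], [1, 2, 3]) is None
        assert score_distribution_test([2, 2], [3, 3]) is None


class TestTFComposition:
    def test_printed_precision_rows(self):
        consensus = {}
        for i in range(9549):
            consensus[f"n{i}"] = _cons(f"n{i}", 0)
        for i in range(2617):
            consensus[f"c3_{i}"] = _cons(f"c3_{i}", 3)
        tf_map = {f"n{i}": "bZIP" for i in range(108)}
        tf_map.update({f"c3_{i}": "WRKY" for i in range(766)})
        rows, _ = tf_composition(consensus, tf_map)
        by_cat = {r.category: r for r in rows}
        assert by_cat["non_nuclear"].tf_percent == 1.13
        assert by_cat["cat3"].tf_percent == 29.27

    def test_no_tf_table(self):
        consensus = {"p1": _cons("p1", 2)}
        rows, dist = tf_composition(consensus, {})
        assert all(r.n_tf == 0 for r in rows)
        assert all(v is None for v in dist.values())

    def test_percents_recompute_from_counts(self):
        consensus = {f"p{i}": _cons(f"p{i}", 1 + i % 4) for i in range(40)}
        tf_map = {f"p{i}": "MYB" for i in range(0, 40, 3)}
        rows, _ = tf_composition(consensus, tf_map)
        for r in rows:
            if r.n_proteins:
                assert r.tf_percent == round(100 * r.n_tf / r.n_proteins, 2)


class TestKeywordScreen:
    @staticmethod
    def _records(n_hits, n_total):
        return [
            ProteinRecord(
                locus_id=f"p{i}", sequence="MKV",
                annotation_text="40S ribosomal protein" if i < n_hits else "protein kinase",
            )
            for i in range(n_total)
        ]

    def test_fraction_and_case_folding(self):
        recs = self._records(3, 10)
        hits, pct = keyword_screen(recs, "ribosome")
        assert hits == set() and pct == 0.0  # literal match, no stemming
        hits, pct = keyword_screen(recs, "ribosomal")
        hits2, pct2 = keyword_screen(recs, "RIBOSOMAL")
        assert hits == hits2 == {f"p{i}" for i in range(3)}
        assert pct == pct2 == 30.0

    def test_empty_keyword_errors(self):
        with pytest.raises(ValueError):
            keyword_screen(self._records(1, 2), "")


class TestProteomeOverlap:
    def test_union_and_universe_intersection(self):
        consensus = {"a": _cons("a", 2), "b": _cons("b", 0)}
        ov = proteome_overlap(consensus, [["a", "b"], ["b", "c"]], ["a", "b"])
        assert ov.n_union == 3 and ov.n_seed_expressed == 2
        assert ov.by_category["cat2"] == 1 and ov.by_category["non_nuclear"] == 1
        assert ov.percent_predicted_nuclear == 50.0

    def test_all_non_nuclear(self):
        consensus = {"a": _cons("a", 0)}
        ov = proteome_overlap(consensus, [["a"]], ["a"])
        assert ov.percent_predicted_nuclear == 0.0

    def test_printed_precision_at_scale(self):
        """511 of 972 proteome loci in category >= 1 -> 52.57%."""
        consensus = {f"p{i}": _cons(f"p{i}", 1 if i < 511 else 0) for i in range(972)}
        ov = proteome_overlap(consensus, [[f"p{i}" for i in range(972)]],
                              [f"p{i}" for i in range(972)])
        assert ov.percent_predicted_nuclear == 52.57


def test_go_enrichment_detects_planted_term():
    """A term present in 80% of cat4 vs 20% of the universe is enriched with small p."""
    consensus, go_map = {}, {}
    for i in range(200):
        pid = f"bg{i}"
        consensus[pid] = _cons(pid, 0)
        if i < 40:
            go_map[pid] = {"GO:0005634"}
    for i in range(50):
        pid = f"c4_{i}"
        consensus[pid] = _cons(pid, 4)
        if i < 40:
            go_map[pid] = {"GO:0005634"}
    res = go_enrichment(consensus, go_map, sorted(consensus), categories=(Category.CAT4,))
    (row,) = res
    assert row.fold == pytest.approx((40 / 50) / (80 / 250))
    assert row.p_value < 1e-6
    assert row.q_value >= row.p_value
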