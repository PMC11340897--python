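"""Implied rankings, match criteria, Kendall distance, concordance."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import vocabrank as vr
from vocabrank.errors import ValidationError
from vocabrank.ranking import intended_order

from conftest import order_from_ranks, table_from_wide

ELIFE_IMP = vr.Vocabulary(
    "elife", "importance", ("landmark", "fundamental", "important", "valuable", "useful")
)
# published medians on the significance/importance dimension
MEDIAN_RATINGS = {
    "landmark": 94, "fundamental": 83, "important": 72, "valuable": 70, "useful": 60
}


def strict_order(seq, vid="v"):
    return order_from_ranks({p: float(i + 1) for i, p in enumerate(seq)}, vid)


def inversion_count(perm):
    """Independent oracle: inversions of a permutation by nested scan."""
    return sum(
        1 for i in range(len(perm)) for j in range(i + 1, len(perm)) if perm[i] > perm[j]
    )


def brute_force_kd(ranks_a, ranks_b):
    """Pairwise discordance enumeration, written independently of the package."""
    total = 0.0
    for p, q in combinations(sorted(ranks_a), 2):
        sa = np.sign(ranks_a[p] - ranks_a[q])
        sb = np.sign(ranks_b[p] - ranks_b[q])
        if sa == sb:
            continue
        total += 0.5 if (sa == 0 or sb == 0) else 1.0
    return total


class TestImpliedRanking:
    def test_published_medians_give_intended_order(self):
        order = vr.implied_ranking(MEDIAN_RATINGS, ELIFE_IMP)
        assert not order.has_ties
        assert vr.matches_intended(order, ELIFE_IMP)
        assert order.ranks["landmark"] == 1 and order.ranks["useful"] == 5

    def test_all_equal_ratings_fully_tied(self):
        order = vr.implied_ranking({p: 50 for p in ELIFE_IMP.phrases}, ELIFE_IMP)
        assert order.has_ties
        assert all(r == 3.0 for r in order.ranks.values())

    def test_increasing_ratings_reverse_the_order(self):
        ratings = {p: 10 * r for p, r in ELIFE_IMP.intended_rank.items()}
        order = vr.implied_ranking(ratings, ELIFE_IMP)
        assert vr.kendall_distance(order, intended_order(ELIFE_IMP)) == 10.0

    def test_missing_phrase_named(self):
        with pytest.raises(ValidationError, match="landmark"):
            vr.implied_ranking({"useful": 10}, ELIFE_IMP)

    def test_midranks_sum_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ratings = dict(zip(ELIFE_IMP.phrases, rng.integers(0, 101, 5)))
            order = vr.implied_ranking(ratings, ELIFE_IMP)
            assert sum(order.ranks.values()) == pytest.approx(15.0)


class TestMatchesIntended:
    def test_swapped_adjacent_pair_does_not_match(self):
        support = vr.Vocabulary(
            "elife", "strength_of_support",
            ("exceptional", "compelling", "convincing", "solid", "incomplete", "inadequate"),
        )
        ranks = {p: float(r) for p, r in support.intended_rank.items()}
        ranks["convincing"], ranks["solid"] = ranks["solid"], ranks["convincing"]
        order = order_from_ranks(ranks, "elife")
        assert not vr.matches_intended(order, support)
        assert vr.kendall_distance(order, intended_order(support)) == 1.0

    def test_tied_order_never_matches(self):
        ratings = dict(MEDIAN_RATINGS, valuable=72)  # ties with 'important'
        order = vr.implied_ranking(ratings, ELIFE_IMP)
        assert order.has_ties and not vr.matches_intended(order, ELIFE_IMP)

    def test_match_iff_zero_distance_and_strict(self):
        rng = np.random.default_rng(1)
        target = intended_order(ELIFE_IMP)
        for _ in range(50):
            ratings = dict(zip(ELIFE_IMP.phrases, rng.integers(40, 70, 5)))
            order = vr.implied_ranking(ratings, ELIFE_IMP)
            matches = vr.matches_intended(order, ELIFE_IMP)
            assert matches == (
                vr.kendall_distance(order, target) == 0 and not order.has_ties
            )


class TestKendallDistance:
    def test_identical_orders_distance_zero(self):
        o = strict_order("abcde")
        assert vr.kendall_distance(o, o) == 0.0

    def test_full_reversal_attains_maximum(self):
        a, b = strict_order("abcde"), strict_order("edcba")
        assert vr.kendall_distance(a, b) == 10.0
        assert vr.normalized_kendall_distance(a, b) == 1.0

    def test_adjacent_transposition_is_one_swap(self):
        a, b = strict_order("abcde"), strict_order("bacde")
        assert vr.kendall_distance(a, b) == 1.0

    def test_adjacent_swap_normalised_n6(self):
        a, b = strict_order("abcdef"), strict_order("abcdfe")
        assert vr.normalized_kendall_distance(a, b) == pytest.approx(1 / 15)

    def test_tie_in_one_order_counts_half(self):
        a = order_from_ranks({"x": 1.5, "y": 1.5, "z": 3.0})
        b = strict_order("xyz")
        assert vr.kendall_distance(a, b) == 0.5

    def test_mismatched_phrase_sets_rejected(self):
        with pytest.raises(ValidationError):
            vr.kendall_distance(strict_order("abc"), strict_order("abd"))

    def test_equals_inversion_count_all_120_permutations(self):
        """Exhaustive n=5 check against an independent inversion counter."""
        identity = strict_order("abcde")
        for perm in permutations("abcde"):
            order = strict_order(perm)
            # rank of each letter in `perm`, read off in identity order
            positions = [perm.index(ch) + 1 for ch in "abcde"]
            assert vr.kendall_distance(order, identity) == inversion_count(positions)

    @given(
        st.integers(2, 6).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 4), min_size=n, max_size=n),
                st.lists(st.integers(0, 4), min_size=n, max_size=n),
                st.lists(st.integers(0, 4), min_size=n, max_size=n),
            )
        )
    )
    def test_metric_properties_on_weak_orders(self, triple):
        """Identity, symmetry and the triangle inequality over random weak
        orders of up to six items (ratings drawn from a small range to force
        frequent ties)."""
        phrases = [f"p{i}" for i in range(len(triple[0]))]
        voc = vr.Vocabulary("v", "d", tuple(phrases))
        a, b, c = (
            vr.implied_ranking(dict(zip(phrases, vals)), voc) for vals in triple
        )
        dab = vr.kendall_distance(a, b)
        assert dab == vr.kendall_distance(b, a)
        assert dab == pytest.approx(brute_force_kd(a.ranks, b.ranks))
        if a.ranks == b.ranks:
            assert dab == 0.0
        assert dab <= vr.kendall_distance(a, c) + vr.kendall_distance(c, b) + 1e-9


class TestFrequenciesAndDistances:
    def test_two_sharing_one_apart(self):
        voc = vr.Vocabulary("v", "d", ("a", "b", "c"))
        wide = pd.DataFrame(
            {"a": [90, 80, 10], "b": [50, 50, 50], "c": [10, 20, 90]},
            index=["p1", "p2", "p3"],
        )
        freq = vr.ranking_frequencies(table_from_wide(wide, voc), voc)
        assert freq.n_distinct == 2
        assert [c for _, c in freq.entries] == [2, 1]

    def test_all_identical(self):
        voc = vr.Vocabulary("v", "d", ("a", "b"))
        wide = pd.DataFrame({"a": [90, 90], "b": [10, 10]}, index=["p1", "p2"])
        freq = vr.ranking_frequencies(table_from_wide(wide, voc), voc)
        assert freq.n_distinct == 1 and freq.n_total == 2

    def test_counts_match_brute_force_grouping(self, clean_table, vocabs):
        voc = vocabs[0]
        freq = vr.ranking_frequencies(clean_table, voc)
        block = clean_table.block(voc).dropna()
        groups = {}
        for _, row in block.iterrows():
            key = tuple(sorted(row.items(), key=lambda kv: (-kv[1], kv[0])))
            # collapse the key to the tie structure: sorted phrases per rating
            sig = []
            for rating in sorted(set(row), reverse=True):
                sig.append(tuple(sorted(p for p, v in row.items() if v == rating)))
            groups[tuple(sig)] = groups.get(tuple(sig), 0) + 1
        assert sorted(c for _, c in freq.entries) == sorted(groups.values())
        assert freq.n_total == len(block)

    def test_incomplete_participant_reported(self):
        voc = vr.Vocabulary("v", "d", ("a", "b"))
        wide = pd.DataFrame({"a": [90, 80], "b": [10, np.nan]}, index=["p1", "p2"])
        freq = vr.ranking_frequencies(table_from_wide(wide, voc), voc)
        assert freq.excluded == ("p2",) and freq.n_total == 1

    def test_distance_distribution_perfect_and_reversed(self):
        voc = vr.Vocabulary("v", "d", ("a", "b", "c"))
        wide = pd.DataFrame(
            {"a": [90, 90, 10], "b": [50, 50, 50], "c": [10, 10, 90]},
            index=["p1", "p2", "p3"],
        )
        dist = vr.distance_distribution(table_from_wide(wide, voc), voc)
        kd = dist.distances.set_index("participant_id")["kd_normalized"]
        assert kd["p1"] == kd["p2"] == 0.0
        assert kd["p3"] == 1.0
        hist = dist.histogram()
        assert hist["count"].sum() == 3

    def test_distances_match_pairwise_enumeration(self, clean_table, vocabs):
        voc = vocabs[1]  # six-phrase block
        dist = vr.distance_distribution(clean_table, voc).distances
        block = clean_table.block(voc).dropna()
        intended = {p: float(r) for p, r in voc.intended_rank.items()}
        from scipy.stats import rankdata

        for _, row in dist.iterrows():
            ratings = block.loc[row.participant_id]
            ranks = dict(zip(block.columns, rankdata(-ratings.to_numpy())))
            assert row.kd == pytest.approx(brute_force_kd(ranks, intended))
            assert row.kd_normalized == pytest.approx(row.kd / 15.0)


class TestConcordance:
    def test_perfect_cohort_is_diagonal(self):
        voc = vr.Vocabulary("v", "d", ("a", "b", "c"))
        wide = pd.DataFrame({"a": [90, 91], "b": [50, 51], "c": [10, 11]}, index=["p1", "p2"])
        cm = vr.concordance_matrix(table_from_wide(wide, voc), voc)
        assert np.allclose(cm.cell, 100 * np.eye(3))

    def test_single_adjacent_swap(self):
        voc = vr.Vocabulary("v", "d", ("a", "b", "c"))
        wide = pd.DataFrame({"a": [90], "b": [20], "c": [50]}, index=["p1"])
        cm = vr.concordance_matrix(table_from_wide(wide, voc), voc)
        assert cm.cell[0, 0] == 100.0  # 'a' kept rank 1
        assert cm.cell[1, 2] == 100.0  # 'b' fell to rank 3
        assert cm.cell[2, 1] == 100.0  # 'c' rose to rank 2

    def test_ties_distribute_fractionally(self):
        voc = vr.Vocabulary("v", "d", ("a", "b", "c"))
        wide = pd.DataFrame({"a": [90], "b": [50], "c": [50]}, index=["p1"])
        cm = vr.concordance_matrix(table_from_wide(wide, voc), voc)
        assert cm.cell[1, 1] == cm.cell[1, 2] == 50.0
        assert cm.cell[2, 1] == cm.cell[2, 2] == 50.0

    def test_doubly_stochastic_on_simulated_cohort(self, clean_table, vocabs):
        for voc in vocabs:
            cm = vr.concordance_matrix(clean_table, voc)
            assert np.allclose(cm.cell.sum(axis=1), 100.0)
            assert np.allclose(cm.cell.sum(axis=0), 100.0)

    def test_matches_brute_force_tabulation(self, clean_table, vocabs):
        """Strict-order participants only: direct per-phrase position tally."""
        voc = vocabs[2]
        block = clean_table.block(voc).dropna()
        strict = block[block.apply(lambda r: r.nunique() == voc.n, axis=1)]
        cm = vr.concordance_matrix(table_from_wide(strict, voc), voc)
        n = len(strict)
        counts = np.zeros((voc.n, voc.n))
        for _, row in strict.iterrows():
            by_rating = sorted(row.items(), key=lambda kv: -kv[1])
            for pos, (phrase, _) in enumerate(by_rating, start=1):
                counts[voc.intended_rank[phrase] - 1, pos - 1] += 1
        assert np.allclose(cm.cell, 100 * counts / n)


class TestMatchedProportion:
    def test_all_matched_clamps_at_one(self):
        voc = vr.Vocabulary("v", "d", ("a", "b"))
        wide = pd.DataFrame({"a": [90, 80], "b": [10, 20]}, index=["p1", "p2"])
        est = vr.matched_proportion(table_from_wide(wide, voc), voc)
        assert est.point == 1.0 and est.upper == 1.0

    def test_counts_consistent_with_match_rate(self, clean_table, vocabs):
        voc = vocabs[3]
        est = vr.matched_proportion(clean_table, voc)
        block = clean_table.block(voc).dropna()
        matched = sum(
            vr.matches_intended(
                vr.implied_ranking(row.to_dict(), voc), voc
            )
            for _, row in block.iterrows()
        )
        assert est.point == pytest.approx(matched / len(block))
        assert est.lower <= est.point <= est.upper
        assert est.method == "sison-glaz"
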