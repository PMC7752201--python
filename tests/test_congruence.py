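"""Dominant-grouping percentages, partition agreement, theme matching."""

import random
from collections import Counter

import pytest
from sklearn.metrics import adjusted_rand_score

from pilesort.congruence import (
    ThemeCoverageError,
    adjusted_rand_index,
    dominant_grouping,
    match_theme_sets,
    theme_congruence_table,
)
from pilesort.sortdata import PilesortError, ThemeSet


class TestDominantGrouping:
    def test_unanimous_theme_scores_exactly_100(self):
        res = dominant_grouping([23, 49, 54], {23: "Blue", 49: "Blue", 54: "Blue"})
        assert res.dominant == "Blue" and res.percentage == 100.0
        assert res.render_percentage("one_decimal") == "100%"

    def test_tie_has_no_dominant_grouping(self):
        asg = {q: "green" for q in range(1, 5)}
        asg.update({q: "pink" for q in range(5, 9)})
        asg.update({q: "blue" for q in range(9, 12)})
        res = dominant_grouping(list(range(1, 12)), asg)
        assert res.dominant is None and res.percentage is None
        assert res.render_percentage("integer") == "N/A"
        assert res.breakdown() == "4 green; 4 pink; 3 blue"

    def test_nine_of_eleven_renders_82_percent_at_integer_rounding(self):
        asg = {q: "blue" for q in range(1, 10)}
        asg.update({10: "green", 11: "pink"})
        res = dominant_grouping(list(range(1, 12)), asg)
        assert res.percentage == pytest.approx(900 / 11)
        assert res.render_percentage("integer") == "82%"

    def test_six_of_seven_renders_85_7_percent_at_one_decimal(self):
        asg = {q: "pink" for q in range(1, 7)}
        asg[7] = "red"
        res = dominant_grouping(list(range(1, 8)), asg)
        assert res.percentage == pytest.approx(600 / 7)
        assert res.render_percentage("one_decimal") == "85.7%"

    def test_five_of_seven_renders_71_percent_at_integer_rounding(self):
        asg = {q: "blue" for q in range(1, 6)}
        asg.update({6: "green", 7: "green"})
        # 2 green ties nothing: blue still unique leader with 5
        res = dominant_grouping(list(range(1, 8)), asg)
        assert res.render_percentage("integer") == "71%"

    def test_missing_quote_is_a_coverage_error_naming_it(self):
        with pytest.raises(ThemeCoverageError, match="ID07"):
            dominant_grouping([1, 7], {1: "a"})

    def test_invariant_under_reordering_and_relabelling(self):
        rng = random.Random(0)
        quotes = list(range(1, 10))
        asg = {q: rng.choice("abc") for q in quotes}
        base = dominant_grouping(quotes, asg).percentage
        rng.shuffle(quotes)
        relabelled = {q: v.upper() for q, v in asg.items()}
        assert dominant_grouping(quotes, relabelled).percentage == base


class TestCongruenceTable:
    def test_rows_preserve_theme_order_and_match_a_direct_recount(self):
        rng = random.Random(3)
        asg = {q: rng.randint(1, 3) for q in range(1, 30)}
        themes = ThemeSet(
            [(f"T{k}", rng.sample(range(1, 30), rng.randint(3, 8))) for k in range(6)]
        )
        table = theme_congruence_table(themes, asg, rounding="full")
        assert list(table["theme"]) == themes.labels
        for (_, ids), (_, row) in zip(themes, table.iterrows()):
            counts = Counter(str(asg[q]) for q in ids)
            top = max(counts.values())
            if sum(1 for c in counts.values() if c == top) > 1:
                assert row["percentage"] == "N/A"
            else:
                assert float(row["percentage"].rstrip("%")) == pytest.approx(
                    100 * top / len(ids)
                )

    def test_tie_row_carries_the_breakdown_string(self):
        themes = ThemeSet([("T", [1, 2])])
        table = theme_congruence_table(themes, {1: "a", 2: "b"})
        assert "1 a; 1 b" in table.loc[0, "dominant_grouping"]
        assert table.loc[0, "percentage"] == "N/A"


def pair_counting_ari(a, b) -> float:
    """First-principles all-pairs agreement, chance corrected."""
    items = sorted(a)
    same_a = same_b = same_both = 0
    n_pairs = 0
    for i, x in enumerate(items):
        for y in items[i + 1:]:
            n_pairs += 1
            sa, sb = a[x] == a[y], b[x] == b[y]
            same_a += sa
            same_b += sb
            same_both += sa and sb
    expected = same_a * same_b / n_pairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (same_both - expected) / (max_index - expected)


class TestAdjustedRandIndex:
    def test_identical_and_relabelled_assignments_score_one(self):
        a = {q: q % 3 for q in range(12)}
        b = {q: f"c{v}" for q, v in a.items()}
        assert adjusted_rand_index(a, a) == 1.0
        assert adjusted_rand_index(a, b) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_from_first_principles(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 12)
        a = {q: rng.randint(1, 3) for q in range(n)}
        b = {q: rng.randint(1, 4) for q in range(n)}
        assert adjusted_rand_index(a, b) == pytest.approx(
            pair_counting_ari(a, b), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_the_scikit_learn_reference(self, seed):
        rng = random.Random(100 + seed)
        items = list(range(10))
        a = {q: rng.randint(1, 3) for q in items}
        b = {q: rng.randint(1, 3) for q in items}
        ref = adjusted_rand_score([a[q] for q in items], [b[q] for q in items])
        assert adjusted_rand_index(a, b) == pytest.approx(ref, abs=1e-12)

    def test_symmetry(self):
        rng = random.Random(5)
        a = {q: rng.randint(1, 3) for q in range(9)}
        b = {q: rng.randint(1, 3) for q in range(9)}
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(b, a)
        )

    def test_single_community_against_nontrivial_partition_scores_zero(self):
        a = {q: 1 for q in range(8)}
        b = {q: q % 2 for q in range(8)}
        assert adjusted_rand_index(a, b) == pytest.approx(0.0)

    def test_mismatched_item_sets_raise_with_the_difference(self):
        with pytest.raises(PilesortError, match="3"):
            adjusted_rand_index({1: 1, 2: 1}, {1: 1, 3: 1})


class TestMatchThemeSets:
    def test_identical_sets_match_identically_with_jaccard_one(self):
        ts = ThemeSet([("A", [1, 2, 3]), ("B", [4, 5])])
        report = match_theme_sets(ts, ts)
        assert [(m.index_a, m.index_b) for m in report.matches] == [(0, 0), (1, 1)]
        assert all(m.jaccard == 1.0 for m in report.matches)

    def test_disjoint_sets_produce_no_matches(self):
        a = ThemeSet([("A", [1, 2])])
        b = ThemeSet([("B", [3, 4])])
        report = match_theme_sets(a, b)
        assert report.jaccard[0, 0] == 0.0 and report.matches == []

    def test_published_social_theme_pair_overlaps_at_six_ninths(self):
        """Co-analyst 'social element' vs academic 'social environment'."""
        a = ThemeSet([("Social element/group dynamic", [14, 4, 2, 40, 49, 12, 80, 89])])
        b = ThemeSet([("A social environment", [2, 4, 12, 14, 80, 89, 10])])
        report = match_theme_sets(a, b)
        assert report.matches[0].shared == [2, 4, 12, 14, 80, 89]
        assert report.matches[0].jaccard == pytest.approx(6 / 9)

    def test_matrix_entries_lie_in_unit_interval_and_each_theme_used_once(self):
        rng = random.Random(2)
        a = ThemeSet([(f"A{k}", rng.sample(range(1, 30), 6)) for k in range(4)])
        b = ThemeSet([(f"B{k}", rng.sample(range(1, 30), 6)) for k in range(5)])
        report = match_theme_sets(a, b)
        assert ((report.jaccard >= 0) & (report.jaccard <= 1)).all()
        assert len({m.index_a for m in report.matches}) == len(report.matches)
        assert len({m.index_b for m in report.matches}) == len(report.matches)

    def test_greedy_matching_takes_largest_jaccard_first(self):
        a = ThemeSet([("A1", [1, 2, 3, 4]), ("A2", [1, 2])])
        b = ThemeSet([("B1", [1, 2])])
        report = match_theme_sets(a, b)
        # A2 vs B1 is a perfect match and wins over the larger A1 overlap
        assert report.matches[0].label_a == "A2"
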