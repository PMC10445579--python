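"""Kendall's W, Fleiss' kappa, Landis-Koch bands, and listwise deletion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from morphosex import (
    RatingsMatrix,
    Trait,
    complete_cases,
    fleiss_kappa,
    kendalls_w,
    landis_koch_label,
    midrank,
    sex_label_matrix,
)
from morphosex.errors import DegenerateInputError, UndefinedStatisticError


def matrix_of(rows, **kwargs):
    rows = [tuple(r) for r in rows]
    m, n = len(rows), len(rows[0])
    return RatingsMatrix(
        tuple(rows),
        kwargs.get("raters", tuple(f"r{j}" for j in range(m))),
        kwargs.get("items", tuple(range(n))),
    )


def brute_force_w(rows):
    """Textbook tie-corrected W, coded independently with explicit loops."""
    m, n = len(rows), len(rows[0])
    all_ranks = []
    for row in rows:
        ranks = []
        for value in row:
            below = sum(1 for other in row if other < value)
            tied = sum(1 for other in row if other == value)
            ranks.append(below + (tied + 1) / 2.0)
        all_ranks.append(ranks)
    s = 0.0
    for i in range(n):
        r_i = sum(all_ranks[j][i] for j in range(m))
        s += (r_i - m * (n + 1) / 2.0) ** 2
    tie_sum = 0.0
    for ranks in all_ranks:
        for value in set(ranks):
            t = ranks.count(value)
            tie_sum += t**3 - t
    return 12.0 * s / (m * m * (n**3 - n) - m * tie_sum)


class TestMidrank:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3], [1, 2, 3]),
            ([5, 5, 1], [2.5, 2.5, 1]),
            ([3, 3, 3, 3], [2.5, 2.5, 2.5, 2.5]),
            ([2, 1, 2, 5], [2.5, 1, 2.5, 4]),
        ],
    )
    def test_examples(self, values, expected):
        assert midrank(values).tolist() == expected

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=30))
    def test_ranks_sum_to_triangular_number(self, values):
        n = len(values)
        assert midrank(values).sum() == pytest.approx(n * (n + 1) / 2)


class TestKendallsW:
    def test_identical_rankings_no_ties_give_one(self):
        result = kendalls_w(matrix_of([[1, 2, 3, 4]] * 3))
        assert result.value == pytest.approx(1.0)
        assert result.label == "almost perfect"

    def test_study_values(self, observer_table, video_table):
        w = kendalls_w(complete_cases(observer_table, Trait.GLABELLA))
        assert round(w.value, 2) == 0.81
        w = kendalls_w(complete_cases(video_table, Trait.MASTOID_PROCESS))
        assert round(w.value, 2) == 0.79

    @given(
        st.lists(
            st.lists(st.integers(1, 5), min_size=5, max_size=5),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_independent_brute_force(self, rows):
        if all(len(set(row)) == 1 for row in rows):
            return  # undefined case, checked separately
        result = kendalls_w(matrix_of(rows))
        assert result.value == pytest.approx(brute_force_w(rows), abs=1e-12)

    @given(
        st.lists(
            st.lists(st.integers(1, 5), min_size=6, max_size=6),
            min_size=4,
            max_size=4,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_permutations(self, rows, rand):
        try:
            base = kendalls_w(matrix_of(rows)).value
        except UndefinedStatisticError:
            return
        item_order = list(range(6))
        rand.shuffle(item_order)
        rater_order = list(range(4))
        rand.shuffle(rater_order)
        shuffled = [[rows[j][i] for i in item_order] for j in rater_order]
        assert kendalls_w(matrix_of(shuffled)).value == pytest.approx(base, abs=1e-12)

    @given(
        st.lists(
            st.lists(st.integers(1, 5), min_size=6, max_size=6),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_monotone_transform_of_one_rater(self, rows):
        # W depends on each rater's values only through their ranks
        try:
            base = kendalls_w(matrix_of(rows)).value
        except UndefinedStatisticError:
            return
        transformed = [list(rows[0]), list(rows[1]), [v**3 + 2 * v for v in rows[2]]]
        assert kendalls_w(matrix_of(transformed)).value == pytest.approx(base, abs=1e-12)

    @given(
        st.lists(st.integers(0, 10**6), min_size=4, max_size=12, unique=True),
        st.lists(st.integers(0, 10**6), min_size=12, max_size=12, unique=True),
    )
    @settings(max_examples=60, derandomize=True)
    def test_two_raters_no_ties_spearman_closed_form(self, a, b):
        a, b = a[: len(a)], b[: len(a)]
        rho = spearmanr(a, b).statistic
        w = kendalls_w(matrix_of([a, b])).value
        assert w == pytest.approx((rho + 1) / 2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            matrix_of([[1, 2, 3]])  # one rater
        with pytest.raises(DegenerateInputError):
            matrix_of([[1], [2]])  # one item
        with pytest.raises(UndefinedStatisticError):
            kendalls_w(matrix_of([[2, 2, 2], [5, 5, 5]]))  # all-constant raters


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        result = fleiss_kappa(matrix_of([["a", "b", "a", "b"]] * 3))
        assert result.value == pytest.approx(1.0)
        assert result.label == "almost perfect"

    def test_hand_worked_example(self):
        # 3 raters x 4 items, per-item category counts (3,0),(2,1),(1,2),(0,3):
        # P_i = (1, 1/3, 1/3, 1), P_bar = 2/3, p = (1/2, 1/2), P_e = 1/2
        # kappa = (2/3 - 1/2) / (1 - 1/2) = 1/3
        rows = [
            ["x", "x", "y", "y"],
            ["x", "x", "x", "y"],
            ["x", "y", "y", "y"],
        ]
        result = fleiss_kappa(matrix_of(rows))
        assert result.value == pytest.approx(1 / 3)
        assert result.components["P_bar"] == pytest.approx(2 / 3)
        assert result.components["P_e"] == pytest.approx(1 / 2)

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fleiss_kappa(matrix_of([["a", "a"], ["a", "a"]]))

    def test_independent_uniform_ratings_near_zero(self):
        rng = np.random.default_rng(20230623)
        rows = rng.integers(0, 2, size=(4, 4000))
        result = fleiss_kappa(matrix_of([[f"c{v}" for v in row] for row in rows]))
        assert abs(result.value) < 0.05

    @given(
        st.lists(
            st.lists(st.sampled_from("abc"), min_size=8, max_size=8),
            min_size=3,
            max_size=5,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_statsmodels_oracle(self, rows):
        matrix = matrix_of(rows)
        if len({v for row in rows for v in row}) < 2:
            return
        table, _ = aggregate_raters(np.array(rows, dtype=object).T)
        assert fleiss_kappa(matrix).value == pytest.approx(
            sm_fleiss_kappa(table), abs=1e-12
        )

    @given(
        st.lists(
            st.lists(st.sampled_from("abc"), min_size=6, max_size=6),
            min_size=3,
            max_size=4,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_category_relabeling(self, rows):
        relabel = {"a": "zebra", "b": "yak", "c": "xerus"}
        try:
            base = fleiss_kappa(matrix_of(rows)).value
        except UndefinedStatisticError:
            return
        renamed = [[relabel[v] for v in row] for row in rows]
        assert fleiss_kappa(matrix_of(renamed)).value == pytest.approx(base, abs=1e-12)


class TestLandisKoch:
    @pytest.mark.parametrize(
        "value, band",
        [
            (-0.1, "poor"),
            (0.0, "slight"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.50, "moderate"),
            (0.60, "moderate"),
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_band_boundaries(self, value, band):
        assert landis_koch_label(value) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            landis_koch_label(1.01)

    @given(st.floats(-2, 1))
    def test_bands_partition_the_line(self, value):
        # every admissible value lands in exactly one named band
        assert landis_koch_label(value) in {
            "poor", "slight", "fair", "moderate", "substantial", "almost perfect",
        }


class TestCompleteCases:
    def test_observer_table_mastoid_drops_cranium_4(self, observer_table):
        matrix = complete_cases(observer_table, Trait.MASTOID_PROCESS)
        assert matrix.n == 19
        assert matrix.dropped == (4,)

    def test_observer_table_glabella_keeps_all(self, observer_table):
        assert complete_cases(observer_table, Trait.GLABELLA).n == 20

    @pytest.mark.parametrize("trait", list(Trait))
    def test_video_table_complete(self, video_table, trait):
        matrix = complete_cases(video_table, trait)
        assert matrix.n == 20 and matrix.dropped == ()

    def test_sex_label_matrix_drops_missing_estimates(self, observer_estimates):
        matrix = sex_label_matrix(observer_estimates)
        assert matrix.n == 19 and matrix.dropped == (4,)
        assert matrix.m == 4
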