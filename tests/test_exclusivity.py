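"""The conditional-probability statistic and its permutation null."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mutexsig.consensus import MutationMatrix
from mutexsig.exclusivity import (
    UndefinedPairError,
    NullSummary,
    conditional_probability,
    curveball_null_values,
    evaluate_all_pairs,
    pair_seed,
    pairs_table,
    rgcp_null,
    sigma_and_p,
)
from mutexsig.synthetic_data import SimulationConfig, simulate_cohort
from conftest import make_matrix


def incidence_from_sets(n, sets):
    return make_matrix({g: [1 if i in cases else 0 for i in range(n)] for g, cases in sets.items()})


class TestConditionalProbability:
    def test_perfect_exclusivity(self):
        m = incidence_from_sets(4, {"A": {0, 1}, "B": {2, 3}})
        assert conditional_probability(m, "A", "B") == 1.0

    def test_a_everywhere(self):
        m = incidence_from_sets(10, {"A": set(range(10)), "B": {0, 1}})
        assert conditional_probability(m, "A", "B") == 0.0

    def test_hand_enumeration(self):
        # P(notA and B) = 3/10, P(B) = 4/10 -> 0.75
        m = incidence_from_sets(10, {"A": {0, 1, 2}, "B": {2, 3, 4, 5}})
        assert conditional_probability(m, "A", "B") == pytest.approx(0.75)

    def test_ordering_matters(self):
        m = incidence_from_sets(10, {"A": {0, 1, 2}, "B": {2, 3, 4, 5}})
        assert conditional_probability(m, "A", "B") != conditional_probability(m, "B", "A")

    def test_no_b_carriers_is_undefined(self):
        m = make_matrix({"A": [1, 0], "B": [0, 0]})
        with pytest.raises(UndefinedPairError):
            conditional_probability(m, "A", "B")


class TestRgcpNull:
    def test_null_mean_matches_closed_form(self):
        # E[CP] = (n - a_A)/n regardless of B under per-gene re-assignment
        m = incidence_from_sets(50, {"A": set(range(15)), "B": set(range(10, 30))})
        null = rgcp_null(m, "A", "B", n_permutations=2000, seed=1)
        expected = (50 - 15) / 50
        assert abs(null.mean - expected) < 3 * null.sd / np.sqrt(2000)

    def test_gene_in_every_case_is_degenerate(self):
        m = make_matrix({"A": [1, 1, 1, 1], "B": [1, 0, 1, 0]})
        null = rgcp_null(m, "A", "B", n_permutations=100, seed=0)
        assert null.degenerate
        assert null.sd == 0.0
        assert np.all(null.values == 0.0)

    def test_deterministic_under_seed(self):
        m = incidence_from_sets(30, {"A": set(range(8)), "B": set(range(5, 17))})
        a = rgcp_null(m, "A", "B", n_permutations=500, seed=42)
        b = rgcp_null(m, "A", "B", n_permutations=500, seed=42)
        assert np.array_equal(a.values, b.values)
        assert (a.mean, a.sd, a.max_value, a.shapiro_p) == (b.mean, b.sd, b.max_value, b.shapiro_p)

    def test_agrees_with_exhaustive_enumeration(self):
        # n <= 8, 2 genes: enumerate all C(n,a)*C(n,b) subset placements
        n, a, b = 8, 3, 4
        cases = range(n)
        vals = []
        for set_a in combinations(cases, a):
            sa = set(set_a)
            for set_b in combinations(cases, b):
                vals.append(len(set(set_b) - sa) / b)
        vals = np.array(vals)
        exact_mean, exact_sd = vals.mean(), vals.std(ddof=0)

        m = incidence_from_sets(n, {"A": {0, 1, 2}, "B": {0, 3, 4, 5}})
        nperm = 20_000
        null = rgcp_null(m, "A", "B", n_permutations=nperm, seed=3)
        assert abs(null.mean - exact_mean) < 4 * exact_sd / np.sqrt(nperm)
        assert null.sd == pytest.approx(exact_sd, rel=0.05)


class TestSigmaAndP:
    def test_observed_at_null_mean(self):
        null = NullSummary(("A", "B"), mean=0.6, sd=0.1, max_value=0.9, shapiro_p=0.5, n_permutations=2000)
        r = sigma_and_p(0.6, null)
        assert r.sigma == 0.0
        assert r.p_value == 1.0

    def test_three_sigma_maps_to_p_0_003(self):
        null = NullSummary(("A", "B"), mean=0.5, sd=0.1, max_value=0.95, shapiro_p=0.5, n_permutations=2000)
        r = sigma_and_p(0.8, null)
        assert r.sigma == pytest.approx(3.0)
        assert round(r.p_value, 3) == 0.003

    def test_two_sigma_maps_to_p_0_05(self):
        null = NullSummary(("A", "B"), mean=0.5, sd=0.1, max_value=0.95, shapiro_p=0.5, n_permutations=2000)
        r = sigma_and_p(0.7, null)
        assert r.sigma == pytest.approx(2.0)
        assert round(r.p_value, 2) == 0.05

    def test_exclusivity_direction_is_positive_sigma(self):
        null = NullSummary(("A", "B"), mean=0.5, sd=0.1, max_value=0.95, shapiro_p=0.5, n_permutations=2000)
        assert sigma_and_p(0.8, null).sigma > 0  # more exclusive than expected
        assert sigma_and_p(0.2, null).sigma < 0  # co-occurring direction

    def test_degenerate_null_yields_excluded_marker(self):
        null = NullSummary(("A", "B"), mean=0.0, sd=0.0, max_value=0.0, shapiro_p=float("nan"), n_permutations=100)
        r = sigma_and_p(0.5, null)
        assert r.excluded
        assert np.isnan(r.sigma)

    def test_outside_null_flag(self):
        values = np.linspace(0.3, 0.7, 2000)
        null = NullSummary(
            ("A", "B"), mean=0.5, sd=float(values.std(ddof=1)), max_value=0.7,
            shapiro_p=0.5, n_permutations=2000, values=values,
        )
        assert sigma_and_p(0.75, null).outside_null
        assert not sigma_and_p(0.65, null).outside_null


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(8)
    inc = (rng.random((60, 4)) < 0.3).astype(np.int8)
    return MutationMatrix(
        pd.DataFrame(inc, index=[f"c{i}" for i in range(60)], columns=["D", "B", "A", "C"])
    )


class TestEvaluateAllPairs:
    def test_three_genes_give_six_ordered_results(self):
        m = incidence_from_sets(20, {"A": {0, 1, 2}, "B": {3, 4}, "C": {5, 6, 7, 8}})
        results = evaluate_all_pairs(m, n_permutations=200, seed=0)
        assert len(results) == 6
        assert len({r.pair for r in results}) == 6

    def test_deterministic_sigma_table(self, random_matrix):
        t1 = pairs_table(evaluate_all_pairs(random_matrix, n_permutations=300, seed=5))
        t2 = pairs_table(evaluate_all_pairs(random_matrix, n_permutations=300, seed=5))
        pd.testing.assert_frame_equal(t1, t2)

    def test_column_order_invariance(self, random_matrix):
        shuffled = MutationMatrix(random_matrix.incidence[["A", "C", "D", "B"]].copy())
        t1 = pairs_table(evaluate_all_pairs(random_matrix, n_permutations=300, seed=5))
        t2 = pairs_table(evaluate_all_pairs(shuffled, n_permutations=300, seed=5))
        key = ["geneA", "geneB"]
        pd.testing.assert_frame_equal(
            t1.sort_values(key).reset_index(drop=True), t2.sort_values(key).reset_index(drop=True)
        )

    def test_planted_exclusive_pair_reaches_two_sigma_both_ways(self):
        cfg = SimulationConfig(
            n_cases=400, gene_specs=[("A", 0.3), ("B", 0.3)], exclusive_pairs=[("A", "B", 1.0)], seed=2
        )
        truth, _, _ = simulate_cohort(cfg)
        m = MutationMatrix(truth.incidence)
        results = evaluate_all_pairs(m, n_permutations=1000, seed=0)
        assert all(r.sigma >= 2 for r in results)

    def test_pair_seed_is_order_invariant(self):
        assert pair_seed(7, "KDM6A", "KMT2D") == pair_seed(7, "KMT2D", "KDM6A")
        assert pair_seed(7, "KDM6A", "KMT2D") != pair_seed(8, "KDM6A", "KMT2D")


def test_curveball_null_preserves_both_margins():
    rng = np.random.default_rng(0)
    inc = (rng.random((25, 4)) < 0.4).astype(np.int8)
    m = MutationMatrix(pd.DataFrame(inc, index=[f"c{i}" for i in range(25)], columns=list("ABCD")))
    # the trade operation itself preserves per-gene and per-case totals
    from mutexsig.exclusivity import _curveball_trade

    sets = [set(np.flatnonzero(m.column(g))) for g in m.genes]
    before_gene = [len(s) for s in sets]
    before_case = np.zeros(25, dtype=int)
    for s in sets:
        for c in s:
            before_case[c] += 1
    _curveball_trade(sets, np.random.default_rng(1), 200)
    after_case = np.zeros(25, dtype=int)
    for s in sets:
        for c in s:
            after_case[c] += 1
    assert [len(s) for s in sets] == before_gene
    assert np.array_equal(before_case, after_case)


def test_curveball_null_mean_is_sane():
    rng = np.random.default_rng(3)
    inc = (rng.random((40, 3)) < 0.35).astype(np.int8)
    m = MutationMatrix(pd.DataFrame(inc, index=[f"c{i}" for i in range(40)], columns=list("ABC")))
    values = curveball_null_values(m, n_permutations=200, seed=9)
    for (a, b), vals in values.items():
        assert vals.shape == (200,)
        assert ((0 <= vals) & (vals <= 1)).all()
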