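import functools
import itertools
import math

import numpy as np
import pytest

import cytopanel as cp
from cytopanel.search import (EXHAUSTIVE_BUDGET, SearchError, _nth_permutation,
                              _energy, sa_energy)
from conftest import make_matrix, random_matrix


class TestCountPanels:
    @pytest.mark.parametrize("F,D,n,expected", [
        (8, 19, 5, 78_140_160),
        (8, 16, 4, 3_057_600),
        (1, 1, 1, 1),
        (3, 3, 2, 18),
    ])
    def test_known_counts(self, F, D, n, expected):
        assert cp.count_panels(F, D, n) == expected

    def test_closed_form(self):
        assert cp.count_panels(12, 7, 3) == math.comb(12, 3) * math.perm(7, 3)

    @pytest.mark.parametrize("F,D,n", [(2, 5, 3), (5, 2, 3), (4, 4, 0)])
    def test_infeasible_sizes_rejected(self, F, D, n):
        with pytest.raises(SearchError):
            cp.count_panels(F, D, n)

    def test_count_matches_literal_enumeration_small(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            F, D = rng.integers(1, 7, size=2)
            n = int(rng.integers(1, min(F, D) + 1))
            fl = [f"f{i}" for i in range(F)]
            dt = [f"d{j}" for j in range(D)]
            stream = list(cp.enumerate_panels(fl, dt, n))
            assert len(stream) == cp.count_panels(F, D, n)
            assert len(set(stream)) == len(stream)  # each panel exactly once


class TestEnumerate:
    def test_square_case_yields_factorial(self):
        panels = list(cp.enumerate_panels(["a", "b", "c"], ["x", "y", "z"], 3))
        assert len(panels) == math.factorial(3)

    def test_deterministic_order(self):
        twice = [list(cp.enumerate_panels(["a", "b", "c"], ["x", "y"], 1))
                 for _ in range(2)]
        assert twice[0] == twice[1]


class TestValidityCensus:
    def brute_force_count(self, matrix, n):
        return sum(cp.is_valid(p, matrix) for p in cp.enumerate_panels(
            matrix.fluorophores, matrix.detectors, n))

    def test_census_equals_brute_force_on_random_sparse_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(6):
            matrix = random_matrix(rng, int(rng.integers(2, 7)),
                                   int(rng.integers(2, 7)))
            n = int(rng.integers(1, min(*matrix.values.shape) + 1))
            assert cp.count_valid_panels(matrix, n) == \
                self.brute_force_count(matrix, n)

    def test_dense_matrix_census_is_whole_space(self):
        matrix = make_matrix({f"f{i}": {f"d{j}": 0.5 for j in range(4)}
                              for i in range(4)})
        assert cp.count_valid_panels(matrix, 2) == cp.count_panels(4, 4, 2)


def brute_force_ranking(matrix, n, eta):
    """Independent oracle: literal enumeration + comparator sort (stable)."""
    scored = [(p, cp.score_panel(p, matrix, eta))
              for p in cp.enumerate_panels(matrix.fluorophores,
                                           matrix.detectors, n)
              if cp.is_valid(p, matrix)]
    return sorted(scored, key=functools.cmp_to_key(
        lambda a, b: -cp.compare_panels(a[1], b[1])))


class TestExhaustiveSearch:
    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            matrix = random_matrix(rng, int(rng.integers(3, 7)),
                                   int(rng.integers(3, 7)), zero_fraction=0.4)
            n = int(rng.integers(1, min(3, min(*matrix.values.shape)) + 1))
            expected = brute_force_ranking(matrix, n, 0.10)
            got = cp.exhaustive_search(None, None, n, 0.10, matrix=matrix)
            assert [p for p, _ in got] == [p for p, _ in expected]
            for (_, sa), (_, sb) in zip(got, expected):
                assert cp.compare_panels(sa, sb) == 0

    def test_output_is_totally_ordered(self):
        rng = np.random.default_rng(8)
        matrix = random_matrix(rng, 5, 6, zero_fraction=0.3)
        ranked = cp.exhaustive_search(None, None, 2, matrix=matrix)
        for (_, a), (_, b) in zip(ranked, ranked[1:]):
            assert cp.compare_panels(a, b) >= 0

    def test_top_k_truncates_only(self):
        rng = np.random.default_rng(9)
        matrix = random_matrix(rng, 5, 5, zero_fraction=0.2)
        full = cp.exhaustive_search(None, None, 2, matrix=matrix)
        head = cp.exhaustive_search(None, None, 2, matrix=matrix, top_k=5)
        assert head == full[:5]

    def test_no_valid_panels_gives_empty_list(self):
        matrix = make_matrix({"f1": {"d1": 0.0, "d2": 0.0},
                              "f2": {"d1": 0.0, "d2": 0.0}})
        assert cp.exhaustive_search(None, None, 2, matrix=matrix) == []

    def test_single_valid_panel_found(self):
        matrix = make_matrix({"f1": {"d1": 0.9, "d2": 0.0},
                              "f2": {"d1": 0.0, "d2": 0.8}})
        ranked = cp.exhaustive_search(None, None, 2, matrix=matrix)
        assert len(ranked) == 1
        assert ranked[0][0] == cp.Panel(("f1", "f2"), ("d1", "d2"))

    def test_budget_guard(self):
        lib = [f"f{i}" for i in range(40)]
        det = [f"d{j}" for j in range(40)]
        frame = {f: {d: 0.5 for d in det} for f in lib}
        matrix = make_matrix(frame)
        assert cp.count_panels(40, 40, 6) > EXHAUSTIVE_BUDGET
        with pytest.raises(SearchError, match="budget"):
            cp.exhaustive_search(None, None, 6, matrix=matrix)

    def test_nth_permutation_matches_itertools(self):
        perms = list(itertools.permutations(range(5), 3))
        for i, p in enumerate(perms):
            assert _nth_permutation(5, 3, i) == p


class TestPanelRanks:
    def test_rank_counts_strictly_better_valid_panels(self):
        rng = np.random.default_rng(21)
        matrix = random_matrix(rng, 5, 5, zero_fraction=0.3)
        ranking = brute_force_ranking(matrix, 2, 0.10)
        # oracle rank of each distinct score: ties share the lowest rank
        for idx in (0, len(ranking) // 2, len(ranking) - 1):
            score = ranking[idx][1]
            expected = 1 + sum(cp.compare_panels(s, score) > 0
                               for _, s in ranking)
            assert cp.panel_ranks(matrix, 2, 0.10, [score]) == [expected]


class TestProposeNeighbor:
    def test_neighbor_differs_in_at_most_one_assignment(self, toy_matrix):
        rng = np.random.default_rng(0)
        library, detectors = ["f1", "f2", "f3"], ["d1", "d2", "d3", "d4"]
        panel = cp.Panel(("f1", "f2"), ("d1", "d2"))
        for _ in range(50):
            neighbor = cp.propose_neighbor(panel, library, detectors, rng)
            changed = set(panel.assignments) - set(neighbor.assignments)
            assert 1 <= len(changed) <= 2

    def test_both_move_types_occur(self):
        rng = np.random.default_rng(1)
        library, detectors = ["f1", "f2", "f3"], ["d1", "d2", "d3"]
        panel = cp.Panel(("f1", "f2"), ("d1", "d2"))
        fluor_moves = detector_moves = 0
        for _ in range(200):
            neighbor = cp.propose_neighbor(panel, library, detectors, rng)
            if set(neighbor.fluorophores) != set(panel.fluorophores):
                fluor_moves += 1
            else:
                detector_moves += 1
        assert fluor_moves > 30 and detector_moves > 30

    def test_saturated_space_only_permutes_detectors(self):
        rng = np.random.default_rng(2)
        panel = cp.Panel(("f1", "f2"), ("d1", "d2"))
        for _ in range(20):
            neighbor = cp.propose_neighbor(panel, ["f1", "f2"], ["d1", "d2"], rng)
            assert set(neighbor.fluorophores) == {"f1", "f2"}
            assert set(neighbor.detectors) == {"d1", "d2"}


class TestSAEnergy:
    def test_perfect_panel_has_zero_energy(self):
        matrix = make_matrix({"f1": {"d1": 1.0, "d2": 0.0},
                              "f2": {"d1": 0.0, "d2": 1.0}})
        panel = cp.Panel(("f1", "f2"), ("d1", "d2"))
        assert sa_energy(panel, matrix) == 0.0

    def test_fully_invalid_panel_pays_quadratic_penalty(self):
        matrix = make_matrix({"f1": {"d1": 0.0, "d2": 0.0},
                              "f2": {"d1": 0.0, "d2": 0.0}})
        panel = cp.Panel(("f1", "f2"), ("d1", "d2"))
        assert sa_energy(panel, matrix) >= 4  # n * n with n = 2

    def test_energy_order_consistent_with_tier1(self):
        rng = np.random.default_rng(4)
        n = 5
        for _ in range(500):
            wa, wb = rng.integers(0, n + 1, size=2)
            ga, gb = rng.random(2)
            ba, bb = rng.random(2) * 2
            ea = _energy(int(wa), ga, ba, 0, n)
            eb = _energy(int(wb), gb, bb, 0, n)
            if wa > wb:
                assert ea < eb
            elif wa < wb:
                assert ea > eb


FAST = cp.SAParams(initial_temperature=0.5, cooling_rate=0.99,
                   min_temperature=1e-3, restarts=4, seed=0)


class TestSimulatedAnnealing:
    def test_default_schedule_iteration_count(self):
        assert cp.SAParams().n_steps == 9206

    def test_same_seed_reproduces_panel(self, flex_matrix):
        a = cp.simulated_annealing(None, None, 4, matrix=flex_matrix,
                                   params=FAST, seed=123)
        b = cp.simulated_annealing(None, None, 4, matrix=flex_matrix,
                                   params=FAST, seed=123)
        assert a == b

    def test_returned_panel_is_valid(self, flex_matrix):
        panel, score = cp.simulated_annealing(None, None, 4,
                                              matrix=flex_matrix,
                                              params=FAST, seed=5)
        assert cp.is_valid(panel, flex_matrix)
        assert score.geomean_signal > 0

    def test_no_valid_panel_raises_signal(self):
        matrix = make_matrix({"f1": {"d1": 0.0, "d2": 0.0},
                              "f2": {"d1": 0.0, "d2": 0.0}})
        with pytest.raises(cp.NoValidPanelError):
            cp.simulated_annealing(None, None, 2, matrix=matrix, params=FAST)

    def test_finds_optimum_of_tiny_instance(self):
        matrix = make_matrix({"f1": {"d1": 0.9, "d2": 0.1},
                              "f2": {"d1": 0.1, "d2": 0.8},
                              "f3": {"d1": 0.4, "d2": 0.3}})
        best = cp.exhaustive_search(None, None, 2, matrix=matrix)[0]
        panel, score = cp.simulated_annealing(None, None, 2, matrix=matrix,
                                              params=FAST, seed=9)
        assert cp.compare_panels(score, best[1]) == 0


class TestMultistart:
    def test_single_restart_equals_plain_run(self, flex_matrix):
        params = cp.SAParams(initial_temperature=0.5, cooling_rate=0.99,
                             min_temperature=1e-3, restarts=1, seed=77)
        single = cp.simulated_annealing(None, None, 4, matrix=flex_matrix,
                                        params=params, seed=77)
        multi = cp.multistart_sa(None, None, 4, matrix=flex_matrix,
                                 params=params)
        assert single == multi

    def test_best_of_restarts_never_worse_than_any_run(self, flex_matrix):
        best = cp.multistart_sa(None, None, 4, matrix=flex_matrix, params=FAST)
        for i in range(FAST.restarts):
            _, score = cp.simulated_annealing(None, None, 4,
                                              matrix=flex_matrix,
                                              params=FAST, seed=FAST.seed + i)
            assert cp.compare_panels(best[1], score) >= 0

    def test_doubling_restarts_is_monotone_under_comparator(self, flex_matrix):
        short = cp.SAParams(initial_temperature=0.5, cooling_rate=0.99,
                            min_temperature=1e-3, restarts=2, seed=31)
        long = cp.SAParams(initial_temperature=0.5, cooling_rate=0.99,
                           min_temperature=1e-3, restarts=4, seed=31)
        a = cp.multistart_sa(None, None, 4, matrix=flex_matrix, params=short)
        b = cp.multistart_sa(None, None, 4, matrix=flex_matrix, params=long)
        assert cp.compare_panels(b[1], a[1]) >= 0
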