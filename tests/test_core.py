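"""Unit and property tests for the prefix-overlap significance engine."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prefixvenn.core import (
    InputError,
    RankedList,
    SizeGuardError,
    adjust_pvalues,
    backtrack_path,
    build_universe,
    find_optimum,
    hypergeometric_prefix_pvalue,
    multiway_heuristic,
    prefix_overlap_grid,
    significance_grid,
    triple_prefix_pvalue,
    triple_significance_grid,
)
from prefixvenn.fixtures import ScenarioSpec, make_scenario, random_ranked_pair

from helpers import (
    bh_stepup,
    brute_overlap_grid,
    closed_form_tail,
    enum_hypergeom_tail,
    monte_carlo_triple_tail,
)


def rl(name, items):
    return RankedList(name=name, items=tuple(items))


# ---------------------------------------------------------------------------
# ranked lists and universe
# ---------------------------------------------------------------------------


class TestRankedList:
    def test_duplicate_item_rejected_with_names(self):
        with pytest.raises(InputError, match=r"'x'.*'L'|'L'.*'x'"):
            rl("L", ["a", "x", "b", "x"])

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            rl("L", [])

    def test_scores_must_be_ascending_and_aligned(self):
        with pytest.raises(InputError):
            RankedList("L", ("a", "b"), scores=(0.2, 0.1))
        with pytest.raises(InputError):
            RankedList("L", ("a", "b"), scores=(0.1,))


class TestUniverse:
    def test_identical_lists_union(self):
        items = [f"g{i}" for i in range(500)]
        uni = build_universe([rl("A", items), rl("B", items)])
        assert uni.size == 500

    def test_small_union(self):
        uni = build_universe([rl("A", "abc"), rl("B", "cd")])
        assert uni.size == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_sublists_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(50)]
        a = list(rng.choice(pool, size=rng.integers(5, 40), replace=False))
        b = list(rng.choice(pool, size=rng.integers(5, 40), replace=False))
        uni = build_universe([rl("A", a), rl("B", b)])
        assert uni.size == len(set(a) | set(b))


# ---------------------------------------------------------------------------
# overlap grids
# ---------------------------------------------------------------------------


class TestPrefixOverlapGrid:
    def test_identical_lists(self):
        n = 12
        a = rl("A", [f"g{i}" for i in range(n)])
        b = rl("B", a.items)
        grid = prefix_overlap_grid(a, b)
        i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
        assert np.array_equal(grid, np.minimum(i, j))

    def test_reversed_lists(self):
        n = 15
        a = rl("A", [f"g{i}" for i in range(n)])
        b = rl("B", a.items[::-1])
        grid = prefix_overlap_grid(a, b)
        i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
        assert np.array_equal(grid, np.maximum(0, i + j - n))

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_random_lists_match_per_cell_intersection(self, seed):
        a, b = random_ranked_pair(50, 0.6, 0.4, seed=seed)
        assert np.array_equal(
            prefix_overlap_grid(a, b), brute_overlap_grid(a.items, b.items)
        )


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------


class TestHypergeometricTail:
    def test_minimal_overlap_is_one(self):
        assert hypergeometric_prefix_pvalue(3, 3, 0, 6) == 1.0

    def test_full_overlap_small_case(self):
        # 1 / C(6,3): exactly one of the 20 possible draws hits all three
        assert hypergeometric_prefix_pvalue(3, 3, 3, 6) == pytest.approx(
            1 / 20, rel=1e-12
        )

    def test_extreme_magnitude_matches_log_gamma_closed_form(self):
        got = hypergeometric_prefix_pvalue(100, 100, 100, 500)
        want = math.exp(
            -(math.lgamma(501) - math.lgamma(101) - math.lgamma(401))
        )
        assert got == pytest.approx(want, rel=1e-10)
        assert 1e-110 < got < 1e-105

    @pytest.mark.parametrize(
        "n_universe,i,j", [(6, 3, 3), (9, 4, 5), (12, 5, 6), (12, 7, 7)]
    )
    def test_matches_exhaustive_enumeration(self, n_universe, i, j):
        for k in range(max(0, i + j - n_universe), min(i, j) + 1):
            want = enum_hypergeom_tail(i, j, k, n_universe)
            got = hypergeometric_prefix_pvalue(i, j, k, n_universe)
            assert got == pytest.approx(want, rel=1e-11, abs=1e-14)

    def test_exactly_one_at_support_floor(self):
        # k at the minimum possible overlap must give exactly 1.0, not 1-eps
        assert hypergeometric_prefix_pvalue(30, 40, 20, 50) == 1.0
        assert hypergeometric_prefix_pvalue(5, 7, 0, 50) == 1.0

    def test_support_violations_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_prefix_pvalue(3, 3, 4, 6)
        with pytest.raises(ValueError):
            hypergeometric_prefix_pvalue(4, 4, 0, 6)  # k below floor 2
        with pytest.raises(ValueError):
            hypergeometric_prefix_pvalue(7, 3, 1, 6)  # i > N


# ---------------------------------------------------------------------------
# adjustment
# ---------------------------------------------------------------------------


class TestAdjustment:
    def test_all_ones_stay_one(self):
        for method in ("none", "bonferroni", "bh"):
            out = adjust_pvalues(np.ones(9), method)
            assert np.all(out == 1.0)

    def test_bh_hand_case(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_dominance_and_agreement_with_stepup_oracle(self, pvals):
        raw = np.asarray(pvals)
        bh = adjust_pvalues(raw, "bh")
        bonf = adjust_pvalues(raw, "bonferroni")
        none = adjust_pvalues(raw, "none")
        assert np.all(none == raw)
        assert np.all(raw <= bh + 1e-15)
        assert np.all(bh <= bonf + 1e-12)
        assert np.all(bonf <= 1.0)
        assert bh == pytest.approx(bh_stepup(raw), rel=1e-12, abs=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm")


# ---------------------------------------------------------------------------
# significance grid
# ---------------------------------------------------------------------------


class TestSignificanceGrid:
    def test_cell_count(self):
        a, _ = random_ranked_pair(7, 1.0, 1.0, seed=0)
        b = rl("B", [f"x{i}" for i in range(5)])
        grid = significance_grid(a, b)
        assert grid.dims == (7, 5)
        assert grid.n_cells == 35

    @pytest.mark.parametrize("seed", [5, 6])
    def test_raw_p_matches_closed_form_oracle_per_cell(self, seed):
        a, b = random_ranked_pair(25, 0.7, 0.5, seed=seed)
        grid = significance_grid(a, b)
        n_uni = grid.universe.size
        for i in range(1, len(a) + 1):
            for j in range(1, len(b) + 1):
                k = int(grid.overlap[i - 1, j - 1])
                want = 1.0 if k == max(0, i + j - n_uni) else closed_form_tail(
                    i, j, k, n_uni
                )
                assert grid.raw_p[i - 1, j - 1] == pytest.approx(
                    want, rel=1e-9, abs=1e-300
                )

    def test_transposition_symmetry(self):
        a, b = random_ranked_pair(30, 0.6, 0.3, seed=21)
        g_ab = significance_grid(a, b)
        g_ba = significance_grid(b, a)
        assert np.array_equal(g_ab.overlap, g_ba.overlap.T)
        # tail sums accumulate in a different order for (i,j) vs (j,i):
        # symmetric to rounding, not bit-for-bit
        assert np.allclose(g_ab.raw_p, g_ba.raw_p.T, rtol=1e-10, atol=0)
        assert np.allclose(g_ab.adj_p, g_ba.adj_p.T, rtol=1e-10, atol=0)
        assert find_optimum(g_ab).indices == find_optimum(g_ba).indices[::-1]

    def test_reversal_scenario_every_cell_is_one(self):
        a, b = make_scenario(ScenarioSpec("reversed", 60))
        grid = significance_grid(a, b)
        assert np.all(grid.raw_p == 1.0)
        assert np.all(grid.adj_p == 1.0)

    def test_size_guard(self):
        big = rl("A", [f"g{i}" for i in range(3001)])
        other = rl("B", [f"g{i}" for i in range(10)])
        with pytest.raises(SizeGuardError):
            significance_grid(big, other)

    def test_duplicate_names_rejected(self):
        a = rl("A", "abc")
        b = rl("A", "abd")
        with pytest.raises(InputError):
            significance_grid(a, b)


# ---------------------------------------------------------------------------
# optimum
# ---------------------------------------------------------------------------


class TestFindOptimum:
    @pytest.mark.parametrize("n", [4, 10, 50])
    def test_identical_even_lists_select_half(self, n):
        a, b = make_scenario(ScenarioSpec("identical", n))
        opt = find_optimum(significance_grid(a, b))
        assert opt.indices == (n // 2, n // 2)
        assert len(opt.overlap_items) == n // 2
        assert not opt.not_significant

    def test_disjoint_lists_not_significant(self):
        a = rl("A", [f"a{i}" for i in range(8)])
        b = rl("B", [f"b{i}" for i in range(8)])
        opt = find_optimum(significance_grid(a, b))
        assert opt.not_significant
        assert opt.adj_p == 1.0
        assert opt.raw_p == 1.0
        assert opt.overlap_items == ()

    def test_overlap_items_are_exact_prefix_intersection(self):
        a, b = random_ranked_pair(40, 0.8, 0.7, seed=3)
        grid = significance_grid(a, b)
        opt = find_optimum(grid)
        i, j = opt.indices
        assert set(opt.overlap_items) == set(a.items[:i]) & set(b.items[:j])

    def test_adjusted_minimum_is_global(self):
        a, b = random_ranked_pair(35, 0.7, 0.6, seed=9)
        grid = significance_grid(a, b)
        opt = find_optimum(grid)
        assert opt.adj_p == grid.adj_p.min()


# ---------------------------------------------------------------------------
# backtracking
# ---------------------------------------------------------------------------


def assert_valid_staircase(path, grid, opt):
    dims = grid.dims
    ndim = len(dims)
    assert len(path.steps) == sum(dims)
    prev = tuple(0 for _ in dims)
    seen_per_list = {lst.name: set() for lst in grid.lists}
    visited_optimum = False
    for step in path.steps:
        deltas = [b - a for a, b in zip(prev, step.cell)]
        assert sorted(deltas) == [0] * (ndim - 1) + [1]
        ax = deltas.index(1)
        assert grid.lists[ax].name == step.source_list
        assert grid.lists[ax].items[step.cell[ax] - 1] == step.item
        assert step.item not in seen_per_list[step.source_list]
        seen_per_list[step.source_list].add(step.item)
        if 0 in step.cell:
            assert step.adj_p is None
        else:
            assert step.adj_p == grid.adj_p[tuple(x - 1 for x in step.cell)]
        if step.cell == opt.indices:
            visited_optimum = True
        prev = step.cell
    assert visited_optimum
    assert prev == dims
    for lst in grid.lists:
        assert seen_per_list[lst.name] == set(lst.items)


class TestBacktrack:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_path_is_monotone_staircase_through_optimum(self, seed):
        a, b = random_ranked_pair(20, 0.6, 0.5, seed=seed)
        grid = significance_grid(a, b)
        opt = find_optimum(grid)
        assert_valid_staircase(backtrack_path(grid, opt), grid, opt)

    def test_optimum_at_origin_gives_two_entry_steps(self):
        a = rl("A", ["s", "a2", "a3"])
        b = rl("B", ["s", "b2", "b3"])
        grid = significance_grid(a, b)
        opt = find_optimum(grid)
        assert opt.indices == (1, 1)
        path = backtrack_path(grid, opt)
        assert [s.cell for s in path.steps[:2]] == [(1, 0), (1, 1)]
        assert path.optimum_step == 1

    def test_identical_small_list_diagonal_pvalues_match_enumeration(self):
        a, b = make_scenario(ScenarioSpec("identical", 4))
        grid = significance_grid(a, b)
        opt = find_optimum(grid)
        path = backtrack_path(grid, opt)
        assert_valid_staircase(path, grid, opt)
        for i in range(1, 5):
            want = enum_hypergeom_tail(i, i, i, 4)
            assert grid.raw_p[i - 1, i - 1] == pytest.approx(want, rel=1e-12)

    def test_three_list_staircase(self):
        a, b = random_ranked_pair(10, 0.8, 0.6, seed=5)
        c = rl("C", tuple(np.random.default_rng(6).permutation(a.items)))
        grid = triple_significance_grid(a, b, c)
        opt = find_optimum(grid)
        assert_valid_staircase(backtrack_path(grid, opt), grid, opt)


# ---------------------------------------------------------------------------
# three lists
# ---------------------------------------------------------------------------


class TestTriple:
    def test_zero_overlap_is_certain(self):
        assert triple_prefix_pvalue(5, 6, 7, 0, 20) == 1.0

    def test_forced_full_overlap_is_certain(self):
        assert triple_prefix_pvalue(9, 9, 9, 9, 9) == 1.0

    def test_matches_seeded_monte_carlo_within_3_se(self):
        exact = triple_prefix_pvalue(8, 8, 8, 4, 20)
        freq, se = monte_carlo_triple_tail(20, 8, 8, 8, 4, n_draws=200_000, seed=2024)
        assert abs(exact - freq) < 3 * se

    def test_identical_lists_cube_counts(self):
        items = tuple(f"g{i}" for i in range(20))
        grid = triple_significance_grid(
            rl("A", items), rl("B", items), rl("C", items)
        )
        i, j, m = np.meshgrid(*(np.arange(1, 21),) * 3, indexing="ij")
        assert np.array_equal(grid.overlap, np.minimum(np.minimum(i, j), m))

    def test_cube_counts_match_brute_force(self):
        rng = np.random.default_rng(17)
        pool = [f"g{i}" for i in range(18)]
        a = rl("A", rng.permutation(pool)[:10])
        b = rl("B", rng.permutation(pool)[:10])
        c = rl("C", rng.permutation(pool)[:10])
        grid = triple_significance_grid(a, b, c)
        for i in range(1, 11):
            for j in range(1, 11):
                for m in range(1, 11):
                    want = len(
                        set(a.items[:i]) & set(b.items[:j]) & set(c.items[:m])
                    )
                    assert grid.overlap[i - 1, j - 1, m - 1] == want

    def test_pairwise_disjoint_lists_all_one(self):
        a = rl("A", [f"a{i}" for i in range(6)])
        b = rl("B", [f"b{i}" for i in range(6)])
        c = rl("C", [f"c{i}" for i in range(6)])
        grid = triple_significance_grid(a, b, c)
        assert np.all(grid.raw_p == 1.0)

    def test_size_guard(self):
        big = rl("A", [f"g{i}" for i in range(401)])
        b = rl("B", [f"g{i}" for i in range(5)])
        c = rl("C", [f"h{i}" for i in range(5)])
        with pytest.raises(SizeGuardError):
            triple_significance_grid(big, b, c)


# ---------------------------------------------------------------------------
# more than three lists
# ---------------------------------------------------------------------------


class TestMultiway:
    def test_identical_lists_reduce_to_nonempty_core(self):
        items = tuple(f"g{i}" for i in range(10))
        lists = [rl(f"L{i}", items) for i in range(4)]
        res = multiway_heuristic(lists)
        assert res.final is not None and len(res.final) > 0
        assert res.iterations[0].optimum.indices == (5, 5)

    def test_first_iteration_equals_pairwise_optimum(self):
        lists = []
        for s in range(4):
            a, b = random_ranked_pair(50, 0.7, 0.6, seed=100 + s)
            lists.append(rl(f"L{s}", b.items))
        res = multiway_heuristic(lists)
        direct = find_optimum(significance_grid(lists[0], lists[1]))
        assert res.iterations[0].optimum == direct

    def test_three_lists_reported_separately_from_cube(self):
        a, b = random_ranked_pair(12, 0.9, 0.5, seed=8)
        c = rl("C", tuple(np.random.default_rng(9).permutation(a.items)))
        heur = multiway_heuristic([a, b, c])
        cube_opt = find_optimum(triple_significance_grid(a, b, c))
        # both routes exist and answer different questions; neither replaces
        # the other
        assert len(heur.iterations) == 2
        assert len(cube_opt.indices) == 3

    def test_empty_overlap_stops(self):
        a = rl("A", [f"a{i}" for i in range(5)])
        b = rl("B", [f"b{i}" for i in range(5)])
        c = rl("C", [f"c{i}" for i in range(5)])
        res = multiway_heuristic([a, b, c])
        assert res.final is None
        assert res.iterations[-1].merged is None

    def test_needs_two_lists(self):
        with pytest.raises(InputError):
            multiway_heuristic([rl("A", "ab")])
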