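"""Exhaustive prefix-overlap significance testing for ranked lists.

Two (or three) lists ranked by significance are compared by treating every
prefix pair ``(i, j)`` — the top *i* items of the first list against the top
*j* items of the second — as a candidate Venn diagram.  Each cell of the
resulting matrix (cube, for three lists) is scored with an upper-tail
hypergeometric p-value for the observed prefix overlap against the universe
of all items seen in any full input list, the whole matrix is adjusted for
multiple testing, and the cell with the smallest adjusted p-value defines
the most significant overlap.  A dynamic-programming style traceback then
recovers the order in which single items are added to reach (and pass) that
optimum.

All binomial coefficients are evaluated through log-gamma and tail sums are
accumulated with log-sum-exp, so p-values remain exact to double precision
down to magnitudes around 1e-300.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "InputError",
    "SizeGuardError",
    "RankedList",
    "Universe",
    "SignificanceGrid",
    "OptimumResult",
    "BacktrackStep",
    "BacktrackPath",
    "MultiwayIteration",
    "MultiwayResult",
    "build_universe",
    "prefix_overlap_grid",
    "triple_prefix_overlap_cube",
    "log_hypergeom_sf",
    "hypergeometric_prefix_pvalue",
    "triple_prefix_pvalue",
    "adjust_pvalues",
    "significance_grid",
    "triple_significance_grid",
    "find_optimum",
    "backtrack_path",
    "multiway_heuristic",
    "PAIR_SIZE_GUARD",
    "TRIPLE_SIZE_GUARD",
]

#: Above these per-list lengths a run must be forced explicitly: the pair
#: grid grows quadratically and the triple cube cubically with list length.
PAIR_SIZE_GUARD = 3000
TRIPLE_SIZE_GUARD = 400

ADJUST_METHODS = ("none", "bonferroni", "bh")


class InputError(ValueError):
    """Invalid user input (malformed list, bad score column, duplicate item)."""


class SizeGuardError(InputError):
    """Input exceeds the practical size limit and no override was given."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedList:
    """An ordered list of unique item identifiers, most significant first.

    Parameters
    ----------
    name : str
        Label used in reports and error messages.
    items : tuple of str
        Item identifiers in rank order.  Must be unique and non-empty.
    scores : tuple of float, optional
        Per-item scores, ascending (smaller = more significant).  Purely
        informative once the order is fixed.
    """

    name: str
    items: tuple[str, ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if len(items) < 1:
            raise InputError(f"list {self.name!r} is empty")
        seen: set[str] = set()
        for it in items:
            if it in seen:
                raise InputError(
                    f"duplicate item {it!r} in list {self.name!r}: "
                    "items must be unique within a list"
                )
            seen.add(it)
        if self.scores is not None:
            scores = tuple(float(s) for s in self.scores)
            object.__setattr__(self, "scores", scores)
            if len(scores) != len(items):
                raise InputError(
                    f"list {self.name!r}: {len(scores)} scores for "
                    f"{len(items)} items"
                )
            if any(b < a for a, b in zip(scores, scores[1:])):
                raise InputError(
                    f"list {self.name!r}: scores must be non-decreasing "
                    "(most significant first)"
                )

    def __len__(self) -> int:
        return len(self.items)

    def prefix(self, n: int) -> tuple[str, ...]:
        """The top-``n`` items as an ordered tuple."""
        if not 1 <= n <= len(self):
            raise ValueError(f"prefix length {n} outside 1..{len(self)}")
        return self.items[:n]


@dataclass(frozen=True)
class Universe:
    """The hypergeometric background: all distinct items of the full inputs."""

    items: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class SignificanceGrid:
    """Per-prefix-combination overlap counts and p-values.

    ``overlap[i-1, j-1]`` is the overlap of the top ``i`` items of the first
    list with the top ``j`` of the second (one more trailing axis for three
    lists); ``raw_p`` and ``adj_p`` are aligned with it.  Prefix indices are
    1-based: there is no empty-prefix row or column.
    """

    lists: tuple[RankedList, ...]
    universe: Universe
    overlap: np.ndarray
    raw_p: np.ndarray
    adj_p: np.ndarray
    method: str

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(self.overlap.shape)

    @property
    def ndim(self) -> int:
        return self.overlap.ndim

    @property
    def n_cells(self) -> int:
        return int(self.overlap.size)


@dataclass(frozen=True)
class OptimumResult:
    """The most significant prefix combination of a grid."""

    indices: tuple[int, ...]
    overlap_items: tuple[str, ...]
    raw_p: float
    adj_p: float
    not_significant: bool


@dataclass(frozen=True)
class BacktrackStep:
    """A single item addition along the traceback staircase.

    ``cell`` is the grid position after the addition; indices still at zero
    mean that list has not contributed yet, and ``adj_p`` is None for such
    cells (the grid has no empty-prefix cells).
    """

    source_list: str
    item: str
    cell: tuple[int, ...]
    adj_p: float | None


@dataclass(frozen=True)
class BacktrackPath:
    """The full item-addition order from empty lists through the optimum."""

    steps: tuple[BacktrackStep, ...]
    optimum_cell: tuple[int, ...]

    @property
    def optimum_step(self) -> int:
        """0-based index of the step that lands on the optimum cell."""
        for idx, step in enumerate(self.steps):
            if step.cell == self.optimum_cell:
                return idx
        raise RuntimeError("path does not visit its optimum cell")

    def pvalue_course(self) -> list[float | None]:
        """Adjusted p-value at each visited cell — the animation's p track."""
        return [s.adj_p for s in self.steps]


@dataclass(frozen=True)
class MultiwayIteration:
    pair: tuple[str, str]
    optimum: OptimumResult
    merged: RankedList | None  # None when the optimum overlap is empty


@dataclass(frozen=True)
class MultiwayResult:
    """Greedy pairwise reduction of more than three ranked lists."""

    iterations: tuple[MultiwayIteration, ...]
    final: RankedList | None


# ---------------------------------------------------------------------------
# universe and overlap counting
# ---------------------------------------------------------------------------


def build_universe(lists: Iterable[RankedList]) -> Universe:
    """Union of all items across the *full* input lists.

    The universe is fixed once from the complete lists and reused for every
    prefix combination, so each cell is tested against the same background.
    """
    all_items: set[str] = set()
    n = 0
    for lst in lists:
        all_items.update(lst.items)
        n += 1
    if n == 0:
        raise InputError("at least one list is required")
    return Universe(frozenset(all_items))


def prefix_overlap_grid(a: RankedList, b: RankedList) -> np.ndarray:
    """Overlap count ``k[i-1, j-1] = |top-i of a ∩ top-j of b|`` for all cells.

    Computed in O(|a|·|b|) by mapping each item of ``a`` to its rank in
    ``b`` and accumulating, rather than intersecting sets per cell.
    """
    nb = len(b)
    pos_b = {item: r for r, item in enumerate(b.items)}
    # sentinel nb: item absent from b, never inside any prefix of b
    rank_in_b = np.array([pos_b.get(item, nb) for item in a.items])
    inside = rank_in_b[:, None] < np.arange(1, nb + 1)[None, :]
    return np.cumsum(inside, axis=0, dtype=np.int64)


def triple_prefix_overlap_cube(
    a: RankedList, b: RankedList, c: RankedList
) -> np.ndarray:
    """Triple overlap count per cell ``(i, j, m)`` of the prefix cube."""
    common = set(a.items) & set(b.items) & set(c.items)
    cube = np.zeros((len(a), len(b), len(c)), dtype=np.int32)
    if common:
        pos_a = {item: r for r, item in enumerate(a.items)}
        pos_b = {item: r for r, item in enumerate(b.items)}
        pos_c = {item: r for r, item in enumerate(c.items)}
        for item in common:
            cube[pos_a[item], pos_b[item], pos_c[item]] += 1
        cube = np.cumsum(np.cumsum(np.cumsum(cube, axis=0), axis=1), axis=2)
    return cube


# ---------------------------------------------------------------------------
# hypergeometric tails in log space
# ---------------------------------------------------------------------------


def _check_support(i: int, j: int, k: int, n_universe: int) -> None:
    if not (0 <= k <= min(i, j) <= n_universe and max(i, j) <= n_universe):
        raise ValueError(
            f"invalid hypergeometric arguments: i={i}, j={j}, k={k}, N={n_universe}"
        )
    if k < max(0, i + j - n_universe):
        raise ValueError(
            f"overlap k={k} below the minimum possible "
            f"{max(0, i + j - n_universe)} for i={i}, j={j}, N={n_universe}"
        )


def log_hypergeom_sf(k: int, n_universe: int, n_marked, n_draws: int):
    """log P(X >= k) for X ~ Hypergeometric(N, K, n), exact in log space.

    ``n_marked`` may be an integer or an integer array (vectorised over the
    number of marked items); the result follows its shape.  Values of ``k``
    beyond ``min(n_marked, n_draws)`` give ``-inf``; ``k`` at or below the
    lower support bound gives exactly 0.0 (p = 1).
    """
    marked = np.atleast_1d(np.asarray(n_marked, dtype=np.int64))
    n, big_n = int(n_draws), int(n_universe)
    k = int(k)
    lg = gammaln(np.arange(big_n + 2, dtype=np.float64) + 1.0)  # lg[a] = log(a!)

    def log_c(a, b):
        return lg[a] - lg[b] - lg[a - b]

    upper = np.minimum(marked, n)
    out = np.full(marked.shape, -np.inf)
    certain = k <= np.maximum(0, marked + n - big_n)
    out[certain] = 0.0
    todo = ~certain & (k <= upper)
    if np.any(todo):
        max_l = int(upper[todo].max())
        ell = np.arange(k, max_l + 1, dtype=np.int64)
        mk = marked[todo][:, None]
        ll = ell[None, :]
        valid = (ll <= np.minimum(mk, n)) & (n - ll <= big_n - mk)
        ll_s = np.where(valid, ll, 0)
        mk_s = np.where(valid, mk, big_n)
        terms = np.where(
            valid,
            log_c(mk_s, ll_s) + log_c(big_n - mk_s, n - ll_s),
            -np.inf,
        )
        out[todo] = np.minimum(
            logsumexp(terms, axis=1) - log_c(big_n, n), 0.0
        )
    return out if np.ndim(n_marked) else float(out[0])


def hypergeometric_prefix_pvalue(i: int, j: int, k: int, n_universe: int) -> float:
    """Upper-tail p-value P(X >= k) for the overlap of an i- and a j-prefix.

    X is the overlap of a uniformly random i-subset and j-subset of an
    ``n_universe``-item background.  Exactly 1.0 when ``k`` equals the
    smallest possible overlap ``max(0, i + j - N)``.
    """
    _check_support(i, j, k, n_universe)
    if k == max(0, i + j - n_universe):
        return 1.0
    return float(np.exp(log_hypergeom_sf(k, n_universe, i, j)))


def _tail_pvalue_grid(overlap: np.ndarray, n_universe: int) -> np.ndarray:
    """Upper-tail p-value for every cell of a 2-d overlap grid.

    Works one first-list prefix length ``i`` at a time: all terms
    C(i, l)·C(N-i, j-l)/C(N, j) with ``l`` at or above the observed overlap
    are summed by log-sum-exp across the whole row of ``j`` values at once.
    Cells whose overlap equals the lower support bound are set to exactly 1.
    """
    na, nb = overlap.shape
    big_n = n_universe
    lg = gammaln(np.arange(big_n + 2, dtype=np.float64) + 1.0)  # lg[a] = log(a!)

    def log_c(a, b):
        return lg[a] - lg[b] - lg[a - b]

    j = np.arange(1, nb + 1, dtype=np.int64)
    log_c_nj = log_c(np.full(nb, big_n), j)
    out = np.empty((na, nb), dtype=np.float64)
    for i in range(1, na + 1):
        k_row = overlap[i - 1]
        at_floor = k_row == np.maximum(0, i + j - big_n)
        ell = np.arange(0, min(i, nb) + 1, dtype=np.int64)
        ll = ell[None, :]
        jj = j[:, None]
        valid = (
            (ll >= k_row[:, None])
            & (ll <= np.minimum(i, jj))
            & (jj - ll <= big_n - i)
            & (jj - ll >= 0)
        )
        jl = np.where(valid, jj - ll, 0)
        terms = np.where(
            valid, log_c(np.full_like(ll, i), ll) + log_c(big_n - i, jl), -np.inf
        )
        row = np.exp(logsumexp(terms, axis=1) - log_c_nj)
        np.minimum(row, 1.0, out=row)
        row[at_floor] = 1.0
        out[i - 1] = row
    return out


def triple_prefix_pvalue(
    i: int, j: int, m: int, k: int, n_universe: int
) -> float:
    """P(|X ∩ Y ∩ Z| >= k) for independent random subsets of sizes i, j, m.

    X, Y, Z are uniformly random subsets of fixed sizes drawn from an
    ``n_universe``-item background.  Computed exactly by conditioning on the
    pairwise overlap T = |X ∩ Y| (hypergeometric with i marked, j drawn) and
    integrating the tail P(|T' ∩ Z| >= k) over T, all in log space.
    """
    big_n = int(n_universe)
    if not (0 <= k <= min(i, j, m) <= big_n and max(i, j, m) <= big_n):
        raise ValueError(
            f"invalid arguments: i={i}, j={j}, m={m}, k={k}, N={big_n}"
        )
    if k == 0:
        return 1.0
    t_lo = max(0, i + j - big_n)
    t_hi = min(i, j)
    t = np.arange(t_lo, t_hi + 1, dtype=np.int64)
    lg = gammaln(np.arange(big_n + 2, dtype=np.float64) + 1.0)  # lg[a] = log(a!)

    def log_c(a, b):
        return lg[a] - lg[b] - lg[a - b]

    log_pmf_t = (
        log_c(np.full_like(t, i), t)
        + log_c(big_n - i, j - t)
        - log_c(big_n, j)
    )
    log_sf_t = log_hypergeom_sf(k, big_n, t, m)
    total = logsumexp(log_pmf_t + log_sf_t)
    return float(min(np.exp(total), 1.0))


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------


def adjust_pvalues(raw, method: str = "bh") -> np.ndarray:
    """Adjust a flat collection of p-values over the whole grid.

    ``bonferroni`` multiplies by the number of cells (capped at 1); ``bh``
    is the Benjamini–Hochberg step-up with cumulative-minimum
    monotonisation; ``none`` is the identity.  The adjustment pool is always
    every cell of the grid or cube.
    """
    p = np.asarray(raw, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    if method == "none" or p.size == 0:
        return p.copy()
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p.ravel(), method=sm_method)[1].reshape(p.shape)


# ---------------------------------------------------------------------------
# grid assembly
# ---------------------------------------------------------------------------


def _check_unique_across(lists: Sequence[RankedList]) -> None:
    names = [lst.name for lst in lists]
    if len(set(names)) != len(names):
        raise InputError(f"list names must be distinct, got {names}")


def significance_grid(
    a: RankedList,
    b: RankedList,
    method: str = "bh",
    force_large: bool = False,
) -> SignificanceGrid:
    """Score every prefix pair of two ranked lists.

    Builds the universe from the full lists, counts per-cell overlaps,
    evaluates the upper-tail hypergeometric p-value for each of the
    ``|a|·|b|`` cells and adjusts them jointly.
    """
    _check_unique_across([a, b])
    if max(len(a), len(b)) > PAIR_SIZE_GUARD and not force_large:
        raise SizeGuardError(
            f"lists of length {len(a)} and {len(b)} exceed the two-list "
            f"guard of {PAIR_SIZE_GUARD} items (quadratic cost); pass "
            "force_large=True (CLI: --force-large) to run anyway"
        )
    universe = build_universe([a, b])
    overlap = prefix_overlap_grid(a, b)
    raw = _tail_pvalue_grid(overlap, universe.size)
    adj = adjust_pvalues(raw, method)
    return SignificanceGrid((a, b), universe, overlap, raw, adj, method)


def triple_significance_grid(
    a: RankedList,
    b: RankedList,
    c: RankedList,
    method: str = "bh",
    force_large: bool = False,
) -> SignificanceGrid:
    """Score every prefix triple of three ranked lists (the cube)."""
    _check_unique_across([a, b, c])
    if max(len(a), len(b), len(c)) > TRIPLE_SIZE_GUARD and not force_large:
        raise SizeGuardError(
            f"lists of length {len(a)}, {len(b)} and {len(c)} exceed the "
            f"three-list guard of {TRIPLE_SIZE_GUARD} items (cubic cost); "
            "pass force_large=True (CLI: --force-large) to run anyway"
        )
    universe = build_universe([a, b, c])
    cube = triple_prefix_overlap_cube(a, b, c)
    raw = np.empty(cube.shape, dtype=np.float64)
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            for m in range(1, len(c) + 1):
                k = int(cube[i - 1, j - 1, m - 1])
                key = (i, j, m, k)
                p = cache.get(key)
                if p is None:
                    p = triple_prefix_pvalue(i, j, m, k, universe.size)
                    cache[key] = p
                raw[i - 1, j - 1, m - 1] = p
    adj = adjust_pvalues(raw, method)
    return SignificanceGrid((a, b, c), universe, cube, raw, adj, method)


# ---------------------------------------------------------------------------
# optimum and traceback
# ---------------------------------------------------------------------------


def _overlap_items(grid: SignificanceGrid, indices: tuple[int, ...]) -> tuple[str, ...]:
    prefixes = [set(lst.items[:n]) for lst, n in zip(grid.lists, indices)]
    common = set.intersection(*prefixes)
    # report in first-list rank order for determinism
    return tuple(it for it in grid.lists[0].items if it in common)


def find_optimum(grid: SignificanceGrid) -> OptimumResult:
    """The cell with the smallest adjusted p-value.

    Step-up adjustment frequently leaves a plateau of cells sharing the
    minimum adjusted value, so ties are broken by the smallest raw p-value
    (which pinpoints the strongest overlap inside the plateau), then by the
    smallest prefix-length sum, then lexicographically.
    """
    adj = grid.adj_p
    min_adj = adj.min()
    cand = np.argwhere(adj == min_adj)
    raws = grid.raw_p[tuple(cand.T)]
    sums = cand.sum(axis=1)
    keys = np.lexsort(tuple(cand[:, ax] for ax in range(cand.shape[1] - 1, -1, -1))
                      + (sums, raws))
    best = cand[keys[0]]
    indices = tuple(int(x) + 1 for x in best)
    raw_p = float(grid.raw_p[tuple(best)])
    return OptimumResult(
        indices=indices,
        overlap_items=_overlap_items(grid, indices),
        raw_p=raw_p,
        adj_p=float(min_adj),
        not_significant=bool(raw_p == 1.0),
    )


def _greedy_walk(
    adj: np.ndarray, start: tuple[int, ...], direction: int
) -> list[tuple[int, ...]]:
    """Greedy staircase from ``start`` (1-based) toward the origin (-1) or the
    full-lists cell (+1), always moving along the axis with the smaller
    adjusted p; ties take the lowest axis."""
    dims = adj.shape
    cell = list(start)
    path = []
    while True:
        moves = []
        for ax in range(len(dims)):
            nxt = list(cell)
            nxt[ax] += direction
            if 1 <= nxt[ax] <= dims[ax]:
                moves.append((float(adj[tuple(x - 1 for x in nxt)]), ax, nxt))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1]))
        _, _, cell = moves[0]
        path.append(tuple(cell))
    return path


def backtrack_path(grid: SignificanceGrid, optimum: OptimumResult) -> BacktrackPath:
    """Recover the single-item addition order through the grid.

    From the optimum cell the walk steps backward to the all-ones origin,
    at each cell choosing whichever admissible predecessor has the smaller
    adjusted p-value, then forward from the optimum to the full-lists cell
    by the same greedy rule.  The reversed backward walk plus the forward
    walk is the addition order; the first item of every list is prepended
    (in list order) to start from empty diagrams.  Exactly one item is
    added per step, ``sum(dims)`` steps in total.
    """
    adj = grid.adj_p
    back = _greedy_walk(adj, optimum.indices, -1)
    fwd = _greedy_walk(adj, optimum.indices, +1)
    # backward walk ends at the all-ones origin; reversed, it leads up to
    # the optimum, which the forward walk then extends to the full lists
    cells = list(reversed(back)) + [optimum.indices] + fwd

    steps: list[BacktrackStep] = []
    # entry steps: first item of each list, in list order, up to the origin
    partial = [0] * len(grid.dims)
    for ax, lst in enumerate(grid.lists):
        partial[ax] = 1
        cell = tuple(partial)
        p = float(adj[tuple(x - 1 for x in cell)]) if 0 not in cell else None
        steps.append(BacktrackStep(lst.name, lst.items[0], cell, p))
    prev = cells[0]
    for cell in cells[1:]:
        deltas = [b - a for a, b in zip(prev, cell)]
        ax = deltas.index(1)
        lst = grid.lists[ax]
        steps.append(
            BacktrackStep(
                lst.name,
                lst.items[cell[ax] - 1],
                cell,
                float(adj[tuple(x - 1 for x in cell)]),
            )
        )
        prev = cell
    return BacktrackPath(tuple(steps), optimum.indices)


# ---------------------------------------------------------------------------
# more than three lists: greedy pairwise reduction
# ---------------------------------------------------------------------------


def multiway_heuristic(
    lists: Sequence[RankedList],
    method: str = "bh",
    force_large: bool = False,
) -> MultiwayResult:
    """Greedy reduction for more than three ranked lists.

    Repeatedly replaces the first two lists with the items of their most
    significant overlap — ordered by the step at which each item is first
    added along the pair's traceback — and re-runs, until a single list
    remains.  An iteration whose optimum has an empty overlap stops the
    reduction and is reported as such.
    """
    if len(lists) < 2:
        raise InputError("multiway reduction needs at least two lists")
    work = list(lists)
    iterations: list[MultiwayIteration] = []
    merge_no = 0
    while len(work) > 1:
        a, b = work[0], work[1]
        grid = significance_grid(a, b, method=method, force_large=force_large)
        opt = find_optimum(grid)
        if not opt.overlap_items:
            # nothing to merge: stop and report the empty result
            iterations.append(MultiwayIteration((a.name, b.name), opt, None))
            return MultiwayResult(tuple(iterations), None)
        path = backtrack_path(grid, opt)
        overlap = set(opt.overlap_items)
        ordered = []
        seen: set[str] = set()
        for step in path.steps:
            if step.item in overlap and step.item not in seen:
                ordered.append(step.item)
                seen.add(step.item)
        merge_no += 1
        merged = RankedList(name=f"merge_{merge_no}", items=tuple(ordered))
        iterations.append(MultiwayIteration((a.name, b.name), opt, merged))
        work = [merged] + work[2:]
    return MultiwayResult(tuple(iterations), work[0])
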