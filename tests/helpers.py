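"""Independent oracles used across the test suite.

These deliberately recompute quantities by brute force (exhaustive
enumeration, naive per-cell set intersections, numerical quadrature) and
never share code with the implementation they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def enum_hypergeom_tail(i: int, j: int, k: int, n_universe: int) -> float:
    """P(|draw ∩ marked| >= k) by enumerating all C(N, j) draws."""
    universe = range(n_universe)
    marked = set(range(i))  # which i items are marked is irrelevant by symmetry
    hits = 0
    total = 0
    for draw in combinations(universe, j):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def brute_overlap_grid(a_items, b_items) -> np.ndarray:
    """Naive per-cell |prefix ∩ prefix| recomputation."""
    na, nb = len(a_items), len(b_items)
    out = np.zeros((na, nb), dtype=int)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            out[i - 1, j - 1] = len(set(a_items[:i]) & set(b_items[:j]))
    return out


def closed_form_tail(i: int, j: int, k: int, n_universe: int) -> float:
    """Upper tail from log-factorials via math.lgamma (no scipy, no shared code)."""

    def log_c(a, b):
        if b < 0 or b > a:
            return -math.inf
        return (
            math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)
        )

    terms = []
    for ell in range(k, min(i, j) + 1):
        if j - ell > n_universe - i:
            continue
        terms.append(log_c(i, ell) + log_c(n_universe - i, j - ell))
    if not terms:
        return 0.0
    top = max(terms)
    s = sum(math.exp(t - top) for t in terms)
    return min(math.exp(top + math.log(s) - log_c(n_universe, j)), 1.0)


def bh_stepup(pvals) -> np.ndarray:
    """Hand-rolled Benjamini–Hochberg step-up adjusted values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = min(running, 1.0)
    return adj


def lens_area_quadrature(r1: float, r2: float, d: float) -> float:
    """Circle-circle intersection area by numerical integration over x."""
    from scipy.integrate import quad

    lo = max(-r1, d - r2)
    hi = min(r1, d + r2)
    if lo >= hi:
        return 0.0

    def height(x):
        h1 = math.sqrt(max(r1 * r1 - x * x, 0.0))
        h2 = math.sqrt(max(r2 * r2 - (x - d) * (x - d), 0.0))
        return 2.0 * min(h1, h2)

    val, _ = quad(height, lo, hi, limit=400, epsabs=1e-12, epsrel=1e-12)
    return val


def monte_carlo_triple_tail(
    n_universe: int, i: int, j: int, m: int, k: int, n_draws: int, seed: int
) -> tuple[float, float]:
    """(frequency, standard error) of |X∩Y∩Z| >= k over random subsets."""
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 20000
    done = 0
    while done < n_draws:
        nb = min(batch, n_draws - done)
        keys = rng.random((3, nb, n_universe))
        xs = np.argsort(keys[0], axis=1)[:, :i]
        ys = np.argsort(keys[1], axis=1)[:, :j]
        zs = np.argsort(keys[2], axis=1)[:, :m]
        mem = np.zeros((nb, n_universe), dtype=np.int8)
        np.put_along_axis(mem, xs, 1, axis=1)
        memy = np.zeros((nb, n_universe), dtype=np.int8)
        np.put_along_axis(memy, ys, 1, axis=1)
        memz = np.zeros((nb, n_universe), dtype=np.int8)
        np.put_along_axis(memz, zs, 1, axis=1)
        triple = (mem & memy & memz).sum(axis=1)
        hits += int((triple >= k).sum())
        done += nb
    freq = hits / n_draws
    se = math.sqrt(max(freq * (1 - freq), 1e-12) / n_draws)
    return freq, se
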