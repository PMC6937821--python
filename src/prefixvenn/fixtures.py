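"""Synthetic ranked lists: four extreme scenarios and random ranked pairs.

The extreme scenarios probe characteristic behaviours of prefix-overlap
testing without any external data:

``identical``
    The second list equals the first — the optimum sits at the half-length
    prefixes by the symmetry of the hypergeometric distribution.
``shuffled``
    A seeded uniform permutation — overlaps behave like chance draws.
``reversed``
    The full reversal — every prefix pair attains the minimum possible
    overlap, so no cell drops below p = 1.
``partial_flip``
    The first ``f``·n items reversed among themselves and the remaining
    items reversed among themselves (blocks kept in place) — the block
    boundary is recoverable as the optimum.

Item identifiers are zero-padded (``item_0001`` …) so lexicographic and
rank order coincide, which makes failures easy to read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InputError, RankedList

__all__ = ["ScenarioSpec", "make_scenario", "random_ranked_pair", "SCENARIO_KINDS"]

SCENARIO_KINDS = ("identical", "shuffled", "reversed", "partial_flip")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one extreme scenario."""

    kind: str
    n: int
    flip_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise InputError(
                f"unknown scenario kind {self.kind!r}; "
                f"expected one of {SCENARIO_KINDS}"
            )
        if self.n < 2:
            raise InputError("scenario length n must be at least 2")
        if self.kind == "partial_flip" and not 0.0 < self.flip_fraction < 1.0:
            raise InputError("flip_fraction must lie strictly between 0 and 1")


def _base_items(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"item_{i:0{width}d}" for i in range(1, n + 1))


def make_scenario(spec: ScenarioSpec) -> tuple[RankedList, RankedList]:
    """Build the (A, B) pair of one extreme scenario.

    A is always ``item_0001 .. item_n`` in order; B depends on the kind.
    Pure in its spec: the same spec always yields bit-identical lists.
    """
    items = _base_items(spec.n)
    if spec.kind == "identical":
        b_items = items
    elif spec.kind == "reversed":
        b_items = items[::-1]
    elif spec.kind == "shuffled":
        rng = np.random.default_rng(spec.seed)
        b_items = tuple(np.array(items)[rng.permutation(spec.n)])
    else:  # partial_flip
        cut = round(spec.flip_fraction * spec.n)
        b_items = items[:cut][::-1] + items[cut:][::-1]
    return (
        RankedList(name="A", items=items),
        RankedList(name="B", items=b_items),
    )


def random_ranked_pair(
    n: int,
    shared_fraction: float,
    concordance: float,
    seed: int,
) -> tuple[RankedList, RankedList]:
    """Seeded random pair of ranked lists with controlled similarity.

    The lists share ``round(shared_fraction * n)`` items; each shared
    item's position in B is a noisy monotone transform of its position in
    A, with ``concordance`` in [0, 1] interpolating between pure noise (0)
    and identical ranking (1).  Non-shared items of B get fresh
    identifiers at random positions.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise InputError("shared_fraction must lie in [0, 1]")
    if not 0.0 <= concordance <= 1.0:
        raise InputError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a_items = _base_items(n)
    n_shared = round(shared_fraction * n)
    shared_idx = np.sort(rng.choice(n, size=n_shared, replace=False))
    width = max(4, len(str(2 * n)))
    fresh = [f"only_b_{i:0{width}d}" for i in range(1, n - n_shared + 1)]

    # sort key: rank in A pulled toward uniform noise as concordance drops
    keys = np.empty(n, dtype=np.float64)
    labels: list[str] = []
    for slot, a_pos in enumerate(shared_idx):
        labels.append(a_items[a_pos])
        keys[slot] = concordance * a_pos + (1.0 - concordance) * n * rng.random()
    for slot, item in enumerate(fresh, start=n_shared):
        labels.append(item)
        keys[slot] = n * rng.random()
    order = np.argsort(keys, kind="stable")
    b_items = tuple(labels[i] for i in order)
    return (
        RankedList(name="A", items=a_items),
        RankedList(name="B", items=b_items),
    )
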