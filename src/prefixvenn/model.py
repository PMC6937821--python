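"""Model/Results interface over the prefix-overlap machinery.

:class:`PrefixOverlap` bundles two or three ranked lists the way a
statistical model bundles its data; :meth:`PrefixOverlap.fit` performs the
exhaustive scan and returns a :class:`PrefixOverlapResults` carrying the
grid, the most significant overlap, the traceback and every derived
artifact (summary table, Venn layout, SVG, JSON document).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .core import (
    BacktrackPath,
    InputError,
    OptimumResult,
    RankedList,
    SignificanceGrid,
    backtrack_path,
    find_optimum,
    significance_grid,
    triple_significance_grid,
)
from .geometry import CircleLayout, RegionAreas, render_svg, three_circle_layout, two_circle_layout
from .io import (
    read_ranked_list,
    result_document,
    write_animation_trace,
    write_heatmap_tsv,
    write_result_json,
)

__all__ = ["PrefixOverlap", "PrefixOverlapResults"]


class PrefixOverlap:
    """Most-significant-overlap model for two or three ranked lists.

    Parameters
    ----------
    list_a, list_b : RankedList
        The ranked inputs, most significant item first.
    list_c : RankedList, optional
        Third list; switches the scan from a matrix to a cube.

    Examples
    --------
    >>> from prefixvenn import PrefixOverlap
    >>> from prefixvenn.fixtures import ScenarioSpec, make_scenario
    >>> a, b = make_scenario(ScenarioSpec("identical", 100))
    >>> res = PrefixOverlap(a, b).fit()
    >>> res.optimum.indices
    (50, 50)
    """

    def __init__(
        self,
        list_a: RankedList,
        list_b: RankedList,
        list_c: RankedList | None = None,
    ) -> None:
        self.lists: tuple[RankedList, ...] = tuple(
            lst for lst in (list_a, list_b, list_c) if lst is not None
        )
        if len(self.lists) < 2:
            raise InputError("two ranked lists are required")

    @classmethod
    def from_files(
        cls,
        path_a: str | Path,
        path_b: str | Path,
        path_c: str | Path | None = None,
        format: str = "plain",
        descending: bool = False,
    ) -> "PrefixOverlap":
        """Build the model from list files (see :func:`~prefixvenn.io.read_ranked_list`)."""
        lists = [
            read_ranked_list(p, format=format, descending=descending)
            for p in (path_a, path_b, path_c)
            if p is not None
        ]
        return cls(*lists)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        list_col: str = "list",
        item_col: str = "item",
        score_col: str | None = None,
    ) -> "PrefixOverlap":
        """Build the model from a long-format DataFrame.

        Rows are grouped by ``list_col``; within each group items are taken
        in frame order, or stably sorted ascending by ``score_col`` when
        given.
        """
        lists: list[RankedList] = []
        for name, group in frame.groupby(list_col, sort=True):
            if score_col is not None:
                group = group.sort_values(score_col, kind="stable")
                scores = tuple(float(s) for s in group[score_col])
            else:
                scores = None
            lists.append(
                RankedList(
                    name=str(name),
                    items=tuple(str(i) for i in group[item_col]),
                    scores=scores,
                )
            )
        if not 2 <= len(lists) <= 3:
            raise InputError(
                f"expected 2 or 3 lists in column {list_col!r}, got {len(lists)}"
            )
        return cls(*lists)

    def fit(
        self, method: str = "bh", force_large: bool = False
    ) -> "PrefixOverlapResults":
        """Scan every prefix combination and locate the optimum.

        ``method`` selects the multiple-testing adjustment over all cells:
        ``"bh"`` (Benjamini–Hochberg, the default), ``"bonferroni"`` or
        ``"none"``.
        """
        if len(self.lists) == 2:
            grid = significance_grid(
                *self.lists, method=method, force_large=force_large
            )
        else:
            grid = triple_significance_grid(
                *self.lists, method=method, force_large=force_large
            )
        return PrefixOverlapResults(self, grid)


class PrefixOverlapResults:
    """Fitted results: the significance grid plus everything derived from it."""

    def __init__(self, model: PrefixOverlap, grid: SignificanceGrid) -> None:
        self.model = model
        self.grid = grid
        self._optimum: OptimumResult | None = None
        self._path: BacktrackPath | None = None

    @property
    def optimum(self) -> OptimumResult:
        if self._optimum is None:
            self._optimum = find_optimum(self.grid)
        return self._optimum

    @property
    def path(self) -> BacktrackPath:
        if self._path is None:
            self._path = backtrack_path(self.grid, self.optimum)
        return self._path

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary of inputs, optimum and significance."""
        opt = self.optimum
        lines = [
            "Most significant prefix overlap",
            "=" * 47,
            f"{'Adjustment:':<22}{self.grid.method}",
            f"{'Universe size N:':<22}{self.grid.universe.size}",
            f"{'Cells evaluated:':<22}{self.grid.n_cells}",
        ]
        for lst, idx in zip(self.grid.lists, opt.indices):
            lines.append(
                f"{'List ' + lst.name + ':':<22}{len(lst)} items, "
                f"top {idx} selected"
            )
        lines += [
            f"{'Overlap size:':<22}{len(opt.overlap_items)}",
            f"{'Raw p-value:':<22}{opt.raw_p:.6g}",
            f"{'Adjusted p-value:':<22}{opt.adj_p:.6g}",
            f"{'Not significant:':<22}{opt.not_significant}",
            "=" * 47,
        ]
        return "\n".join(lines)

    # -- geometry ----------------------------------------------------------

    def region_counts(self) -> dict[str, int]:
        """Item counts of the disjoint Venn regions at the optimum."""
        names = [lst.name for lst in self.grid.lists]
        prefixes = [
            set(lst.items[:n])
            for lst, n in zip(self.grid.lists, self.optimum.indices)
        ]
        out: dict[str, int] = {}
        n = len(prefixes)
        for mask in range(1, 2 ** n):
            inside = [i for i in range(n) if mask >> i & 1]
            outside = [i for i in range(n) if not mask >> i & 1]
            region = set.intersection(*(prefixes[i] for i in inside))
            for i in outside:
                region -= prefixes[i]
            out["+".join(names[i] for i in inside)] = len(region)
        return out

    def venn_layout(self) -> CircleLayout:
        """Area-proportional circle layout of the optimum's Venn diagram."""
        counts = self.region_counts()
        names = tuple(lst.name for lst in self.grid.lists)
        if len(names) == 2:
            a, b = names
            return two_circle_layout(
                counts[a] + counts[f"{a}+{b}"],
                counts[b] + counts[f"{a}+{b}"],
                counts[f"{a}+{b}"],
                names=(a, b),
            )
        a, b, c = names
        areas = RegionAreas(
            only_a=counts[a],
            only_b=counts[b],
            ab=counts[f"{a}+{b}"],
            only_c=counts[c],
            ac=counts[f"{a}+{c}"],
            bc=counts[f"{b}+{c}"],
            abc=counts[f"{a}+{b}+{c}"],
        )
        return three_circle_layout(areas, names=(a, b, c))

    def render_svg(self) -> str:
        """SVG document of the optimum's area-proportional Venn diagram."""
        return render_svg(self.venn_layout(), self.region_counts())

    # -- artifacts ---------------------------------------------------------

    def result_document(self, include_path: bool = True) -> dict:
        return result_document(
            self.grid,
            self.optimum,
            self.path if include_path else None,
            __version__,
        )

    def save_json(self, path: str | Path) -> None:
        write_result_json(self.result_document(), path)

    def save_heatmap(self, path: str | Path) -> None:
        write_heatmap_tsv(self.grid, path)

    def save_trace(self, path: str | Path) -> None:
        write_animation_trace(self.path, path)

    def save_svg(self, path: str | Path) -> None:
        Path(path).write_text(self.render_svg(), encoding="utf-8")
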