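"""Reading ranked lists and writing result artifacts.

Input formats: ``plain`` (one identifier per line, most significant first)
and ``scored`` (two tab-separated columns, identifier and numeric score,
stably sorted ascending by score — the p-value convention).  Blank lines
and ``#`` comments are ignored.

Output artifacts: a self-contained JSON result document, a −log10 p-value
heatmap as TSV, an animation trace as JSON, and (via :mod:`.geometry`) an
SVG diagram.  Every artifact is reproducible bit-for-bit from the same
inputs and package version.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    BacktrackPath,
    InputError,
    OptimumResult,
    RankedList,
    SignificanceGrid,
)

__all__ = [
    "read_ranked_list",
    "result_document",
    "write_result_json",
    "write_heatmap_tsv",
    "write_animation_trace",
    "RuntimeModel",
    "estimate_runtime",
    "calibrate_runtime",
    "DEFAULT_PAIR_RUNTIME",
    "DEFAULT_TRIPLE_RUNTIME",
]

#: cap for −log10(p) when p underflows double precision
NEGLOG_CAP = 320.0


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------


def read_ranked_list(
    path: str | Path,
    format: str = "plain",
    descending: bool = False,
    name: str | None = None,
) -> RankedList:
    """Read a ranked list from a text file.

    ``plain`` files are taken in file order.  ``scored`` files are stably
    sorted by the score column, ascending by default (smaller score = more
    significant); ``descending=True`` flips that for fold-change-style
    scores, in which case scores are not attached to the returned list
    (its score convention is ascending).
    """
    path = Path(path)
    if format not in ("plain", "scored"):
        raise InputError(f"unknown list format {format!r}")
    if name is None:
        name = path.stem
    rows: list[tuple[int, str, float | None]] = []
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if format == "plain":
            rows.append((lineno, stripped, None))
        else:
            fields = stripped.split("\t")
            if len(fields) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected identifier<TAB>score, "
                    f"got {len(fields)} field(s)"
                )
            ident, score_text = fields[0].strip(), fields[1].strip()
            try:
                score = float(score_text)
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: non-numeric score {score_text!r} "
                    f"for item {ident!r}"
                ) from None
            rows.append((lineno, ident, score))
    if not rows:
        raise InputError(f"{path}: no items found (empty list)")
    first_line: dict[str, int] = {}
    for lineno, ident, _ in rows:
        if ident in first_line:
            raise InputError(
                f"{path}: duplicate item {ident!r} on lines "
                f"{first_line[ident]} and {lineno}"
            )
        first_line[ident] = lineno
    if format == "plain":
        return RankedList(name=name, items=tuple(r[1] for r in rows))
    rows_sorted = sorted(rows, key=lambda r: r[2], reverse=descending)
    items = tuple(r[1] for r in rows_sorted)
    scores = None if descending else tuple(r[2] for r in rows_sorted)
    return RankedList(name=name, items=items, scores=scores)


# ---------------------------------------------------------------------------
# result document
# ---------------------------------------------------------------------------


def result_document(
    grid: SignificanceGrid,
    optimum: OptimumResult,
    path: BacktrackPath | None,
    version: str,
) -> dict:
    """Assemble the self-contained JSON-serialisable result document."""
    doc = {
        "schema": "prefixvenn-result/1",
        "version": version,
        "method": grid.method,
        "universe_size": grid.universe.size,
        "inputs": [
            {"name": lst.name, "length": len(lst)} for lst in grid.lists
        ],
        "grid": {
            "dims": list(grid.dims),
            "n_cells": grid.n_cells,
            "min_raw_p": float(grid.raw_p.min()),
            "max_raw_p": float(grid.raw_p.max()),
            "min_adj_p": float(grid.adj_p.min()),
        },
        "optimum": {
            "indices": list(optimum.indices),
            "overlap_size": len(optimum.overlap_items),
            "overlap_items": list(optimum.overlap_items),
            "raw_p": optimum.raw_p,
            "adj_p": optimum.adj_p,
            "not_significant": optimum.not_significant,
        },
    }
    if path is not None:
        doc["path"] = {
            "optimum_step": path.optimum_step,
            "steps": [
                {
                    "step": idx,
                    "source_list": s.source_list,
                    "item": s.item,
                    "cell": list(s.cell),
                    "adj_p": s.adj_p,
                }
                for idx, s in enumerate(path.steps)
            ],
        }
    return doc


def write_result_json(doc: dict, path: str | Path) -> None:
    """Write a result document as UTF-8 JSON with sorted keys.

    Floats use Python's shortest round-trip representation, so p-values at
    1e-150 magnitudes survive a parse cycle exactly.
    """
    out = json.dumps(doc, sort_keys=True, ensure_ascii=False, indent=1)
    Path(path).write_text(out + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# heatmap and animation trace
# ---------------------------------------------------------------------------


def _neglog10(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        v = -np.log10(p)
    return np.minimum(v, NEGLOG_CAP)


def write_heatmap_tsv(grid: SignificanceGrid, path: str | Path) -> None:
    """Write the −log10 adjusted-p heatmap of a 2-d grid as TSV.

    Row and column headers are prefix lengths.  A twin file with the
    ``.raw.tsv`` suffix carries −log10 raw p.  Values are capped at 320
    where p underflowed to zero.  Cubes are refused — export per-slice
    instead.
    """
    if grid.ndim != 2:
        raise InputError(
            "heatmap export supports two-list grids only; "
            "export cube slices individually"
        )
    path = Path(path)
    na, nb = grid.dims
    idx = pd.Index(range(1, na + 1), name="prefix_a")
    cols = pd.Index(range(1, nb + 1), name="prefix_b")
    pd.DataFrame(_neglog10(grid.adj_p), index=idx, columns=cols).to_csv(
        path, sep="\t", lineterminator="\n"
    )
    raw_path = path.with_suffix(".raw.tsv") if path.suffix == ".tsv" else Path(
        str(path) + ".raw.tsv"
    )
    pd.DataFrame(_neglog10(grid.raw_p), index=idx, columns=cols).to_csv(
        raw_path, sep="\t", lineterminator="\n"
    )


def write_animation_trace(path: BacktrackPath, out: str | Path) -> None:
    """Write the item-addition order as a JSON step array.

    One entry per added item, from empty diagrams to the complete lists;
    the ``adj_p`` column is the p-value course and the optimum step is
    flagged.
    """
    opt_step = path.optimum_step
    steps = [
        {
            "step": idx,
            "source_list": s.source_list,
            "item": s.item,
            "cell": list(s.cell),
            "adj_p": s.adj_p,
            "is_optimum": idx == opt_step,
        }
        for idx, s in enumerate(path.steps)
    ]
    text = json.dumps(steps, sort_keys=True, ensure_ascii=False, indent=1)
    Path(out).write_text(text + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# runtime estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RuntimeModel:
    """Polynomial run-time model in the per-list length.

    Degree 2 for two lists (quadratic cell count), degree 3 for three.
    Coefficients are ordered from the constant term upward.  Purely
    advisory: predictions feed the size-guard message, never control flow.
    """

    degree: int
    coefficients: tuple[float, ...]

    def predict(self, n: int) -> float:
        t = float(np.polynomial.polynomial.polyval(n, self.coefficients))
        return max(t, 0.0)


#: Advisory defaults fitted on equal-length random lists on one CPU core
#: (dominant even-power term only, so predictions stay monotone);
#: recalibrate with :func:`calibrate_runtime` for the machine at hand.
DEFAULT_PAIR_RUNTIME = RuntimeModel(2, (0.0, 0.0, 1.25e-5))
DEFAULT_TRIPLE_RUNTIME = RuntimeModel(3, (0.0, 0.0, 0.0, 1.6e-4))


def estimate_runtime(n: int, model: RuntimeModel) -> float:
    """Predicted seconds to score all prefix combinations of length-``n`` lists."""
    return model.predict(n)


def calibrate_runtime(
    sizes: Sequence[int],
    runner: Callable[[int], None],
    degree: int = 2,
) -> RuntimeModel:
    """Fit a RuntimeModel from live timings.

    ``runner(n)`` must perform a representative run for per-list length
    ``n``; each size is timed once with a monotonic clock.
    """
    sizes = list(sizes)
    if len(sizes) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} sizes to fit degree {degree}"
        )
    times = []
    for n in sizes:
        t0 = time.perf_counter()
        runner(n)
        times.append(time.perf_counter() - t0)
    coeffs = np.polynomial.polynomial.polyfit(
        np.asarray(sizes, float), np.asarray(times, float), degree
    )
    return RuntimeModel(degree, tuple(float(c) for c in coeffs))
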