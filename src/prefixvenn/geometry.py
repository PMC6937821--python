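"""Area-proportional circle layouts for two- and three-set Venn diagrams.

One item corresponds to one unit of area, so a set of size *s* is drawn as a
circle of radius sqrt(s/pi).  For two sets the centre distance that makes
the circle-circle lens area equal the overlap count is solved exactly by
root bisection; two circles can always realise two-set region areas
exactly.  For three sets exact circle layouts are generally impossible, so
the three pairwise distances are solved exactly and the triangle of centres
realising them is placed, falling back to a least-squares placement when
the distances violate the triangle inequality; the worst relative region
error is reported as a first-class ``residual``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.optimize import brentq, least_squares
from shapely.geometry import Point

__all__ = [
    "RegionAreas",
    "CircleLayout",
    "lens_area",
    "two_circle_layout",
    "three_circle_layout",
    "region_polygons",
    "render_svg",
]

# polygonal resolution used when a region area has no closed form
_QUAD_SEGS = 512


@dataclass(frozen=True)
class RegionAreas:
    """Target areas (item counts) of the disjoint regions of a Venn diagram."""

    only_a: float
    only_b: float
    ab: float
    only_c: float | None = None
    ac: float | None = None
    bc: float | None = None
    abc: float | None = None

    @property
    def n_sets(self) -> int:
        return 3 if self.only_c is not None else 2

    def set_sizes(self) -> tuple[float, ...]:
        if self.n_sets == 2:
            return (self.only_a + self.ab, self.only_b + self.ab)
        return (
            self.only_a + self.ab + self.ac + self.abc,
            self.only_b + self.ab + self.bc + self.abc,
            self.only_c + self.ac + self.bc + self.abc,
        )

    def as_dict(self) -> dict[str, float]:
        d = {"only_a": self.only_a, "only_b": self.only_b, "ab": self.ab}
        if self.n_sets == 3:
            d.update(only_c=self.only_c, ac=self.ac, bc=self.bc, abc=self.abc)
        return d

    def __post_init__(self) -> None:
        three = [self.only_c, self.ac, self.bc, self.abc]
        if any(v is not None for v in three) and any(v is None for v in three):
            raise ValueError("three-set areas need only_c, ac, bc and abc")
        vals = [self.only_a, self.only_b, self.ab] + (
            three if self.n_sets == 3 else []
        )
        if any(v < 0 for v in vals):
            raise ValueError("region areas must be non-negative")


@dataclass(frozen=True)
class CircleLayout:
    """Circle centres and radii realising (approximately) requested areas."""

    set_names: tuple[str, ...]
    centers: tuple[tuple[float, float], ...]
    radii: tuple[float, ...]
    residual: float


def lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two circles with radii ``r1, r2`` at distance ``d``.

    Continuous and non-increasing in ``d``: the full small circle for
    nested placements, zero once the circles separate.
    """
    if r1 < 0 or r2 < 0 or d < 0:
        raise ValueError("radii and distance must be non-negative")
    if r1 == 0 or r2 == 0 or d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    x2 = (d * d + r2 * r2 - r1 * r1) / (2.0 * d)
    part1 = r1 * r1 * math.acos(max(-1.0, min(1.0, x1 / r1)))
    part2 = r2 * r2 * math.acos(max(-1.0, min(1.0, x2 / r2)))
    sq = (
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return part1 + part2 - 0.5 * math.sqrt(max(sq, 0.0))


def _distance_for_overlap(size_a: float, size_b: float, overlap: float) -> float:
    """Centre distance making the lens area equal ``overlap`` area units."""
    r1 = math.sqrt(size_a / math.pi)
    r2 = math.sqrt(size_b / math.pi)
    if overlap <= 0:
        return r1 + r2  # externally tangent by convention
    if overlap >= min(size_a, size_b):
        return abs(r1 - r2)  # nested (concentric when equal sizes)
    lo, hi = abs(r1 - r2), r1 + r2
    return brentq(
        lambda d: lens_area(r1, r2, d) - overlap, lo, hi,
        xtol=1e-14, rtol=8.9e-16, maxiter=200,
    )


def two_circle_layout(
    size_a: float, size_b: float, overlap: float,
    names: tuple[str, str] = ("A", "B"),
) -> CircleLayout:
    """Exact area-proportional layout of two sets.

    Disjoint sets are drawn externally tangent and full containment is
    drawn internally tangent (concentric when the sizes are equal), both
    exactly; otherwise the centre distance is solved by bisection so the
    lens area matches ``overlap`` to near machine precision.
    """
    if size_a < 1 or size_b < 1:
        raise ValueError("set sizes must be at least 1")
    if not 0 <= overlap <= min(size_a, size_b):
        raise ValueError(
            f"overlap {overlap} impossible for sizes {size_a}, {size_b}"
        )
    r1 = math.sqrt(size_a / math.pi)
    r2 = math.sqrt(size_b / math.pi)
    d = _distance_for_overlap(size_a, size_b, overlap)
    achieved = lens_area(r1, r2, d)
    if overlap == 0 or overlap == min(size_a, size_b):
        resid = abs(achieved - overlap)  # exact placements
    else:
        resid = abs(achieved - overlap) / overlap
    return CircleLayout(
        set_names=tuple(names),
        centers=((0.0, 0.0), (d, 0.0)),
        radii=(r1, r2),
        residual=resid,
    )


def _circle(center: tuple[float, float], r: float):
    if r <= 0:
        return Point(center).buffer(0)
    return Point(center).buffer(r, quad_segs=_QUAD_SEGS)


def region_polygons(layout: CircleLayout) -> dict[str, object]:
    """Disjoint-region polygons of a layout keyed like ``"A"``, ``"A+B"``.

    Regions are built from high-resolution polygonal circles; empty regions
    are included with empty geometry.
    """
    names = layout.set_names
    discs = [
        _circle(c, r) for c, r in zip(layout.centers, layout.radii)
    ]
    regions: dict[str, object] = {}
    n = len(discs)
    for mask in range(1, 2 ** n):
        inside = [i for i in range(n) if mask >> i & 1]
        outside = [i for i in range(n) if not mask >> i & 1]
        geom = discs[inside[0]]
        for i in inside[1:]:
            geom = geom.intersection(discs[i])
        for i in outside:
            geom = geom.difference(discs[i])
        regions["+".join(names[i] for i in inside)] = geom
    return regions


def _exact_region_areas_or_none(
    layout: CircleLayout,
) -> dict[str, float] | None:
    """Closed-form region areas when every circle pair is nested, coincident
    or disjoint (no partial lens); None otherwise."""
    names = layout.set_names
    n = len(names)
    areas_full = [math.pi * r * r for r in layout.radii]
    # pairwise relations
    rel: dict[tuple[int, int], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            (x1, y1), (x2, y2) = layout.centers[i], layout.centers[j]
            d = math.hypot(x1 - x2, y1 - y2)
            r1, r2 = layout.radii[i], layout.radii[j]
            if d >= r1 + r2 - 1e-12:
                rel[i, j] = "disjoint"
            elif d <= abs(r1 - r2) + 1e-12:
                rel[i, j] = "nested"
            else:
                return None
    out: dict[str, float] = {}
    for mask in range(1, 2 ** n):
        inside = [i for i in range(n) if mask >> i & 1]
        outside = [i for i in range(n) if not mask >> i & 1]
        # intersection of nested/disjoint discs is either empty or the
        # smallest inside disc
        area = min(areas_full[i] for i in inside)
        small = min(inside, key=lambda i: areas_full[i])
        for i in inside:
            if i != small and rel[tuple(sorted((i, small)))] == "disjoint":
                area = 0.0
        # subtract any outside disc nested within all inside discs
        for o in outside:
            if area > 0 and all(
                rel[tuple(sorted((o, i)))] == "nested"
                and areas_full[o] <= areas_full[i]
                for i in inside
            ):
                area = max(0.0, area - areas_full[o])
        out["+".join(names[i] for i in inside)] = area
    return out


def three_circle_layout(
    areas: RegionAreas, names: tuple[str, str, str] = ("A", "B", "C")
) -> CircleLayout:
    """Approximate area-proportional layout of three sets.

    Each pairwise centre distance is solved exactly for the pairwise
    overlap area; the triangle realising the three distances is placed with
    the first centre at the origin.  When the distances violate the
    triangle inequality the third centre is placed by least squares.  The
    ``residual`` is the worst relative error across the seven regions
    (absolute error scaled by total area for empty regions) — three-circle
    layouts are approximate by construction and the residual says how far
    this one is off.
    """
    if areas.n_sets != 2 and areas.n_sets != 3:
        raise ValueError("RegionAreas must describe two or three sets")
    if areas.n_sets == 2:
        raise ValueError("use two_circle_layout for two sets")
    sa, sb, sc = areas.set_sizes()
    ov_ab = areas.ab + areas.abc
    ov_ac = areas.ac + areas.abc
    ov_bc = areas.bc + areas.abc
    radii = tuple(math.sqrt(max(s, 0.0) / math.pi) for s in (sa, sb, sc))

    def pair_distance(s1, s2, ov, r1, r2):
        if s1 <= 0 or s2 <= 0:
            return r1 + r2
        return _distance_for_overlap(max(s1, 1e-12), max(s2, 1e-12), ov)

    d12 = pair_distance(sa, sb, ov_ab, radii[0], radii[1])
    d13 = pair_distance(sa, sc, ov_ac, radii[0], radii[2])
    d23 = pair_distance(sb, sc, ov_bc, radii[1], radii[2])

    c1 = (0.0, 0.0)
    c2 = (d12, 0.0)
    if d12 > 0:
        x = (d12 * d12 + d13 * d13 - d23 * d23) / (2.0 * d12)
    else:
        x = d13
    y_sq = d13 * d13 - x * x
    if y_sq >= 0:
        c3 = (x, math.sqrt(y_sq))
    else:
        # triangle inequality violated: least-squares placement of centre 3
        def resid(p):
            return [
                math.hypot(p[0] - c1[0], p[1] - c1[1]) - d13,
                math.hypot(p[0] - c2[0], p[1] - c2[1]) - d23,
            ]

        sol = least_squares(resid, x0=[x, 0.0])
        c3 = (float(sol.x[0]), abs(float(sol.x[1])))

    layout = CircleLayout(
        set_names=tuple(names), centers=(c1, c2, c3), radii=radii,
        residual=0.0,
    )
    targets = {
        names[0]: areas.only_a,
        names[1]: areas.only_b,
        names[2]: areas.only_c,
        f"{names[0]}+{names[1]}": areas.ab,
        f"{names[0]}+{names[2]}": areas.ac,
        f"{names[1]}+{names[2]}": areas.bc,
        f"{names[0]}+{names[1]}+{names[2]}": areas.abc,
    }
    total = sum(targets.values())
    exact = _exact_region_areas_or_none(layout)
    if exact is not None:
        achieved = exact
    else:
        achieved = {
            key: geom.area for key, geom in region_polygons(layout).items()
        }
    worst = 0.0
    for key, tgt in targets.items():
        ach = achieved.get(key, 0.0)
        if tgt > 0:
            err = abs(ach - tgt) / tgt
        elif total > 0:
            err = abs(ach) / total
        else:
            err = abs(ach)
        worst = max(worst, err)
    return CircleLayout(
        set_names=tuple(names), centers=(c1, c2, c3), radii=radii,
        residual=worst,
    )


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

_FILLS = ("#1f77b4", "#ff7f0e", "#2ca02c")


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def render_svg(
    layout: CircleLayout,
    region_counts: Mapping[str, int] | None = None,
    width: float = 480.0,
) -> str:
    """Standalone SVG 1.1 document for a circle layout.

    Region labels (``region_counts`` keyed like :func:`region_polygons`)
    are placed at a representative interior point of each non-empty
    region.  Rendering is deterministic: identical inputs produce
    byte-identical documents.
    """
    rmax = max(layout.radii) if layout.radii else 1.0
    xs = [c[0] for c in layout.centers]
    ys = [c[1] for c in layout.centers]
    pad = 0.25 * rmax if rmax > 0 else 1.0
    x0 = min(x - r for x, r in zip(xs, layout.radii)) - pad
    x1 = max(x + r for x, r in zip(xs, layout.radii)) + pad
    y0 = min(y - r for y, r in zip(ys, layout.radii)) - pad
    y1 = max(y + r for y, r in zip(ys, layout.radii)) + pad
    span_x, span_y = x1 - x0, y1 - y0
    height = width * span_y / span_x if span_x > 0 else width
    font = 0.12 * rmax if rmax > 0 else 1.0

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="{_fmt(x0)} {_fmt(y0)} {_fmt(span_x)} {_fmt(span_y)}">',
    ]
    for idx, (name, (cx, cy), r) in enumerate(
        zip(layout.set_names, layout.centers, layout.radii)
    ):
        fill = _FILLS[idx % len(_FILLS)]
        lines.append(
            f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
            f'fill="{fill}" fill-opacity="0.35" stroke="{fill}" '
            f'stroke-width="{_fmt(0.01 * rmax)}"/>'
        )
        lines.append(
            f'<text x="{_fmt(cx)}" y="{_fmt(cy - r - 0.05 * rmax)}" '
            f'font-size="{_fmt(font)}" text-anchor="middle" '
            f'font-family="sans-serif">{name}</text>'
        )
    if region_counts:
        regions = region_polygons(layout)
        for key in sorted(region_counts):
            geom = regions.get(key)
            if geom is None or geom.is_empty or geom.area <= 0:
                continue
            pt = geom.representative_point()
            lines.append(
                f'<text x="{_fmt(pt.x)}" y="{_fmt(pt.y)}" '
                f'font-size="{_fmt(font)}" text-anchor="middle" '
                f'font-family="sans-serif">{region_counts[key]}</text>'
            )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"
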