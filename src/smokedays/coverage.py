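"""Daily plume flattening and point-under-smoke queries.

HMS builds a day's smoke layer from several satellite passes, so one
location may sit under many plumes of the same density.  Flattening
resolves this to one observation per location per day: a location is
covered at a density iff *any* plume of that density from any pass
contains it.  No geometric union is computed — the coverage keeps the
polygon set and ORs per-point containment, which is observationally
identical to a dissolved layer and avoids union robustness failures on
sloppy plume rings.

Containment is evaluated on the lon/lat plane with the even-odd
(ray-crossing) fill rule over all rings; points exactly on a boundary
edge or vertex count as inside, which biases toward exposure — the
conservative direction for public health.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from ._shp import Ring, Rings
from .density import Density
from .hms import PlumeRecord


class SmokeIndicators(NamedTuple):
    """Independent 0/1 indicators for light/medium/heavy smoke overhead."""

    light: int
    medium: int
    heavy: int

    def indicator(self, density: Density) -> int:
        return self[density.numeric_level - 1]


NO_SMOKE = SmokeIndicators(0, 0, 0)


def max_density(ind: SmokeIndicators) -> int:
    """Numeric maximum smoke level: none=0, light=1, medium=2, heavy=3."""
    if ind.heavy:
        return 3
    if ind.medium:
        return 2
    if ind.light:
        return 1
    return 0


@dataclass(frozen=True)
class _Bbox:
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax


def _bbox(rings: Rings) -> _Bbox:
    xs = [x for r in rings for x, _ in r]
    ys = [y for r in rings for _, y in r]
    return _Bbox(min(xs), min(ys), max(xs), max(ys))


@dataclass(frozen=True)
class DailyCoverage:
    """One day's plumes partitioned by density.

    Every density key is always present; a density with no plumes maps to an
    empty tuple (no absent-vs-empty ambiguity).  Polygons are stored in a
    deterministic order but order never affects any query.
    """

    date: datetime.date
    per_density: dict[Density, tuple[Rings, ...]]
    _bboxes: dict[Density, tuple[_Bbox, ...]] = field(
        default_factory=dict, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        for d in Density:
            self.per_density.setdefault(d, ())
        if not self._bboxes:
            for d, polys in self.per_density.items():
                self._bboxes[d] = tuple(_bbox(p) for p in polys)

    def polygons(self, density: Density) -> tuple[Rings, ...]:
        return self.per_density[density]

    @property
    def n_plumes(self) -> int:
        return sum(len(v) for v in self.per_density.values())


def flatten_day(
    plumes: Iterable[PlumeRecord], date: datetime.date
) -> DailyCoverage:
    """Partition one day's plumes by density into a :class:`DailyCoverage`.

    Raises ``ValueError`` on a plume whose date differs from ``date``.
    """
    per: dict[Density, list[Rings]] = {d: [] for d in Density}
    for p in plumes:
        if p.date != date:
            raise ValueError(f"plume dated {p.date} in flatten for {date}")
        per[p.density].append(p.geometry)
    return DailyCoverage(
        date=date, per_density={d: tuple(v) for d, v in per.items()}
    )


def _on_segment(px: float, py: float, ax: float, ay: float,
                bx: float, by: float) -> bool:
    """Exact test: point lies on the closed segment a-b."""
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if cross != 0.0:
        return False
    return min(ax, bx) <= px <= max(ax, bx) and min(ay, by) <= py <= max(ay, by)


def _ring_edges(ring: Ring):
    n = len(ring)
    closed = ring[0] == ring[-1]
    last = n - 1 if closed else n
    for i in range(last):
        a = ring[i]
        b = ring[(i + 1) % n] if not closed else ring[i + 1]
        yield a, b


def point_in_polygon(pt: tuple[float, float], poly: Rings) -> bool:
    """Even-odd containment of a lon/lat point in a (multi-ring) polygon.

    Crossing parity is accumulated over *all* rings, so nested rings and
    self-intersecting outlines follow the even-odd fill rule without any
    geometry repair.  Boundary points (on an edge or vertex) are inside.
    """
    px, py = pt
    inside = False
    for ring in poly:
        for (ax, ay), (bx, by) in _ring_edges(ring):
            if ax == bx and ay == by:
                continue  # zero-length edge (explicit closure duplicates)
            if _on_segment(px, py, ax, ay, bx, by):
                return True
            # half-open rule on y avoids double-counting vertex crossings
            if (ay > py) != (by > py):
                x_at = ax + (py - ay) * (bx - ax) / (by - ay)
                if px < x_at:
                    inside = not inside
    return inside


def point_indicators(
    pt: tuple[float, float],
    cov: DailyCoverage,
    *,
    use_bbox_prefilter: bool = True,
) -> SmokeIndicators:
    """0/1 smoke indicators for a point under a day's coverage.

    Each density is evaluated independently: the indicator is 1 iff at least
    one polygon of that density contains the point.  The bounding-box
    prefilter is an optimization only — observationally identical to the
    naive scan (a point outside a polygon's bbox cannot be inside it).
    """
    px, py = pt
    flags = []
    for d in Density:
        polys = cov.per_density[d]
        boxes = cov._bboxes[d]
        hit = 0
        for poly, box in zip(polys, boxes):
            if use_bbox_prefilter and not box.contains(px, py):
                continue
            if point_in_polygon(pt, poly):
                hit = 1
                break
        flags.append(hit)
    return SmokeIndicators(*flags)
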