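"""Seeded synthetic scenarios: HMS-style plume files, population points and
ground-truth exposure tables.

The generator stands in for the NOAA archive and the Census file so the whole
pipeline can be exercised offline with a known answer.  Everything is driven
by a single seed: the same seed and spec produce byte-identical files and the
identical ground truth.

The ground-truth table is computed by an independent route — a brute-force
double loop using shapely containment — sharing no geometry code with the
coverage/exposure modules, so pipeline-vs-truth comparisons are a real
two-implementation check.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely

from ._shp import Rings
from .cenpop import BlockGroupPoint, write_cenpop
from .density import Density
from .exposure import ExposureRecord, write_exposure_csv
from .hms import PlumeRecord, write_hms_day

#: lon/lat box loosely covering the western US, where most HMS smoke sits
DEFAULT_EXTENT = (-125.0, 32.0, -102.0, 49.0)  # xmin, ymin, xmax, ymax

#: raw label variants per category, as they appear across archive years
#: (mixed case strings, the "Dense" synonym, and GASP numeric codes)
RAW_LABELS = {
    Density.LIGHT: ("light", "Light", "5.000"),
    Density.MEDIUM: ("medium", "Medium", "16.000"),
    Density.HEAVY: ("heavy", "Heavy", "Dense", "27.000"),
}


@dataclass(frozen=True)
class PlumeDaySpec:
    """Per-day plume counts and geometry ranges for the generator."""

    counts: Mapping[Density, int]
    radius_range: tuple[float, float] = (1.0, 6.0)  # degrees
    vertex_range: tuple[int, int] = (5, 12)
    concave: bool = False  # star-shaped polygons exercising the even-odd rule


def generate_population(
    n: int,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    seed: int = 0,
    *,
    n_states: int = 2,
    counties_per_state: int = 4,
    path: str | Path | None = None,
) -> list[BlockGroupPoint]:
    """Generate ``n`` block-group points uniform in ``extent``.

    Populations are lognormal (median ≈ 1200 persons, σ=1 on the log scale,
    the right-skewed shape of real block-group populations) rounded to
    integers.  County assignment is skewed (earlier counties get more
    points) so county partitions mix dense and sparse — weighted-density
    tests then see nontrivial population shares.  Synthetic FIPS codes are
    valid-width and unique.  If ``path`` is given, a CenPop-dialect CSV is
    also written that parses back to the identical collection.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    lons = rng.uniform(xmin, xmax, n)
    lats = rng.uniform(ymin, ymax, n)
    pops = np.maximum(0, np.round(rng.lognormal(np.log(1200.0), 1.0, n))).astype(int)

    n_counties = n_states * counties_per_state
    weights = 1.0 / np.arange(1, n_counties + 1)  # Zipf-ish skew
    weights /= weights.sum()
    county_idx = rng.choice(n_counties, size=n, p=weights)

    points: list[BlockGroupPoint] = []
    per_county_counter: dict[int, int] = {}
    for i in range(n):
        c = int(county_idx[i])
        seq = per_county_counter.get(c, 0)
        per_county_counter[c] = seq + 1
        points.append(
            BlockGroupPoint(
                statefp=f"{c // counties_per_state + 1:02d}",
                countyfp=f"{(c % counties_per_state) * 2 + 1:03d}",
                tractce=f"{seq // 9 + 1:06d}",
                blkgrpce=str(seq % 9 + 1),
                population=int(pops[i]),
                latitude=float(np.round(lats[i], 6)),
                longitude=float(np.round(lons[i], 6)),
            )
        )
    if path is not None:
        write_cenpop(points, path)
    return points


def _convex_ring(center: tuple[float, float], radius: float,
                 k: int, rng: np.random.Generator) -> Rings:
    angles = np.sort(rng.uniform(0, 2 * np.pi, k))
    cx, cy = center
    ring = tuple(
        (float(np.round(cx + radius * np.cos(a), 6)),
         float(np.round(cy + radius * np.sin(a), 6)))
        for a in angles
    )
    return (ring + (ring[0],),)


def _star_ring(center: tuple[float, float], radius: float,
               k: int, rng: np.random.Generator) -> Rings:
    # alternating inner/outer radii -> simple star-shaped (concave) polygon
    k = max(k, 6) // 2 * 2
    angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
    cx, cy = center
    ring = []
    for i, a in enumerate(angles):
        r = radius if i % 2 == 0 else radius * rng.uniform(0.3, 0.6)
        ring.append(
            (float(np.round(cx + r * np.cos(a), 6)),
             float(np.round(cy + r * np.sin(a), 6)))
        )
    ring.append(ring[0])
    return (tuple(ring),)


def generate_plume_day(
    date: datetime.date,
    spec: PlumeDaySpec,
    seed: int,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    *,
    out_path: str | Path | None = None,
) -> list[PlumeRecord]:
    """Generate one day's plumes; optionally write the HMS-dialect shapefile.

    Polygons are simple convex k-gons (or star polygons with ``concave``)
    with random center and radius inside a margin of ``extent``; raw density
    labels are drawn from the documented label variants including "Dense".
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    rmin, rmax = spec.radius_range
    plumes: list[PlumeRecord] = []
    for density in Density:  # fixed iteration order keeps output deterministic
        for _ in range(spec.counts.get(density, 0)):
            radius = float(rng.uniform(rmin, rmax))
            cx = float(rng.uniform(xmin + rmax, xmax - rmax))
            cy = float(rng.uniform(ymin + rmax, ymax - rmax))
            k = int(rng.integers(spec.vertex_range[0], spec.vertex_range[1] + 1))
            ring_fn = _star_ring if spec.concave else _convex_ring
            geometry = ring_fn((cx, cy), radius, k, rng)
            labels = RAW_LABELS[density]
            raw = labels[int(rng.integers(len(labels)))]
            plumes.append(
                PlumeRecord(date=date, density=density, geometry=geometry,
                            raw_label=raw)
            )
    if out_path is not None:
        write_hms_day(out_path, plumes)
    return plumes


def ground_truth_exposures(
    points: Sequence[BlockGroupPoint],
    plumes: Iterable[PlumeRecord],
) -> list[ExposureRecord]:
    """Brute-force oracle exposure table for one day (or several days).

    For every point and every plume, boundary-inclusive containment is
    evaluated with shapely (``covers``); indicators are the per-density OR,
    and only smoke-present rows are kept.  Independent of the coverage and
    exposure modules by construction.
    """
    by_day: dict[datetime.date, list[PlumeRecord]] = {}
    for p in plumes:
        by_day.setdefault(p.date, []).append(p)

    out: list[ExposureRecord] = []
    for day in sorted(by_day):
        day_plumes = by_day[day]
        polys = [
            (shapely.Polygon(p.geometry[0], holes=list(p.geometry[1:])), p.density)
            for p in day_plumes
        ]
        for bg in points:
            pt = shapely.Point(bg.longitude, bg.latitude)
            flags = {d: 0 for d in Density}
            for poly, density in polys:
                if flags[density]:
                    continue
                if shapely.covers(poly, pt):
                    flags[density] = 1
            if not any(flags.values()):
                continue
            out.append(
                ExposureRecord(
                    date=day.strftime("%Y%m%d"),
                    statefp=bg.statefp,
                    countyfp=bg.countyfp,
                    tractce=bg.tractce,
                    blkgrpce=bg.blkgrpce,
                    population=bg.population,
                    light=flags[Density.LIGHT],
                    medium=flags[Density.MEDIUM],
                    heavy=flags[Density.HEAVY],
                )
            )
    out.sort(key=lambda r: (r.date, r.geoid))
    return out


@dataclass
class SyntheticScenario:
    """A fully materialized scenario: inputs plus the known-truth table."""

    seed: int
    points: list[BlockGroupPoint]
    plumes_by_day: dict[datetime.date, list[PlumeRecord]]
    ground_truth: list[ExposureRecord]
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT
    manifest: dict = field(default_factory=dict)

    @property
    def days(self) -> list[datetime.date]:
        return sorted(self.plumes_by_day)


def generate_scenario(
    seed: int,
    *,
    n_points: int = 100,
    n_days: int = 5,
    start: datetime.date = datetime.date(2017, 10, 1),
    plumes_per_day: Mapping[Density, int] | None = None,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    concave: bool = False,
    out_dir: str | Path | None = None,
) -> SyntheticScenario:
    """Build a seeded scenario; optionally write it as a self-contained dir.

    The directory layout is ``cenpop.csv``, ``plumes/<yyyymmdd>.shp`` (+
    ``.shx``/``.dbf``), ``ground_truth.csv`` and ``manifest.json``.  Derived
    per-day seeds stay below 2**31.
    """
    counts = dict(plumes_per_day) if plumes_per_day else {
        Density.LIGHT: 3, Density.MEDIUM: 2, Density.HEAVY: 2
    }
    spec = PlumeDaySpec(counts=counts, concave=concave)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "plumes").mkdir(parents=True, exist_ok=True)

    points = generate_population(
        n_points, extent, seed,
        path=(out_dir / "cenpop.csv") if out_dir else None,
    )
    plumes_by_day: dict[datetime.date, list[PlumeRecord]] = {}
    all_plumes: list[PlumeRecord] = []
    for i in range(n_days):
        day = start + datetime.timedelta(days=i)
        day_seed = (seed * 10007 + i * 101 + 1) % (2**31)
        plumes = generate_plume_day(
            day, spec, day_seed, extent,
            out_path=(out_dir / "plumes" / f"{day:%Y%m%d}.shp") if out_dir else None,
        )
        plumes_by_day[day] = plumes
        all_plumes.extend(plumes)

    truth = ground_truth_exposures(points, all_plumes)
    manifest = {
        "seed": seed,
        "n_points": n_points,
        "n_days": n_days,
        "start": start.isoformat(),
        "extent": list(extent),
        "plumes_per_day": {d.name.lower(): c for d, c in counts.items()},
        "concave": concave,
    }
    if out_dir is not None:
        write_exposure_csv(truth, out_dir / "ground_truth.csv")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )
    return SyntheticScenario(
        seed=seed, points=points, plumes_by_day=plumes_by_day,
        ground_truth=truth, extent=extent, manifest=manifest,
    )
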