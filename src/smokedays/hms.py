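"""Reading daily NOAA HMS Smoke plume files into normalized plume records.

An HMS day is one shapefile set (possibly zipped, possibly several per-pass
files) of analyst-drawn smoke polygons, each carrying a density attribute.
This module parses those into :class:`PlumeRecord` objects with the density
label normalized to the three canonical categories, and can fetch and cache
daily archives from the NOAA OSPO layout.
"""

from __future__ import annotations

import datetime
import logging
import shutil
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from . import _shp
from .density import Density, UnknownDensityError, normalize_density

log = logging.getLogger(__name__)

#: dBASE attribute names probed, in order, for the density label.  The
#: column name drifts across archive years, so this is configuration, not
#: a constant of the format.
DEFAULT_DENSITY_ATTRS: tuple[str, ...] = ("Density", "density")

DEFAULT_BASE_URL = "https://satepsanone.nesdis.noaa.gov/pub/volcano/FIRE/HMS_ARCHIVE"


class DayAbsentError(FileNotFoundError):
    """The archive has no file set for the requested day.

    Distinct from a present-but-empty day, which yields zero records.
    """


class RetryableFetchError(ConnectionError):
    """A transient network/HTTP failure while fetching an archive day."""


@dataclass(frozen=True)
class PlumeRecord:
    """One dated, density-labelled smoke plume polygon.

    ``geometry`` is a tuple of rings in geographic lon/lat degrees; rings may
    be nested or self-intersecting — containment downstream uses the even-odd
    fill rule, so no repair is attempted here.  ``raw_label`` preserves the
    verbatim source attribute for provenance.
    """

    date: datetime.date
    density: Density
    geometry: _shp.Rings
    raw_label: str

    def __post_init__(self) -> None:
        if not self.geometry:
            raise ValueError("plume geometry must have at least one ring")
        for ring in self.geometry:
            if len(_distinct_vertices(ring)) < 3:
                raise ValueError("plume ring needs >=3 distinct vertices")
            for lon, lat in ring:
                if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                    raise ValueError(f"coordinate out of range: ({lon}, {lat})")


def _distinct_vertices(ring: _shp.Ring) -> set[tuple[float, float]]:
    return set(ring)


def read_hms_day(
    source: str | Path | Sequence[str | Path],
    date: datetime.date,
    *,
    density_attrs: Sequence[str] = DEFAULT_DENSITY_ATTRS,
    skip_unknown_density: bool = False,
) -> list[PlumeRecord]:
    """Parse one day's HMS Smoke file set into plume records.

    ``source`` may be a ``.shp``/``.zip`` path, a directory, or a sequence of
    such paths (the archive sometimes serves several per-pass files for one
    day; all are read and concatenated).  Features with degenerate geometry
    (no ring with 3 distinct vertices) are dropped with a logged count.

    Raises
    ------
    DayAbsentError
        If ``source`` does not exist.
    UnknownDensityError
        On an unrecognized density label, unless ``skip_unknown_density`` is
        set, in which case the feature is dropped with a log message.
    KeyError
        If none of ``density_attrs`` is a field of the file.
    """
    if isinstance(source, (str, Path)):
        sources: list[Path] = [Path(source)]
    else:
        sources = [Path(s) for s in source]
    for p in sources:
        if not p.exists():
            raise DayAbsentError(str(p))

    records: list[PlumeRecord] = []
    n_degenerate = 0
    n_unknown = 0
    for path in sources:
        shapes, fields = _shp.read_shapefile(path)
        attr = _pick_density_attr(fields, density_attrs, path)
        for shape in shapes:
            geometry = _clean_geometry(shape.rings)
            if geometry is None:
                n_degenerate += 1
                continue
            raw = shape.attrs.get(attr)
            try:
                density = normalize_density(raw, source=str(path))
            except UnknownDensityError:
                if skip_unknown_density:
                    n_unknown += 1
                    continue
                raise
            records.append(
                PlumeRecord(date=date, density=density, geometry=geometry,
                            raw_label=str(raw))
            )
    if n_degenerate:
        log.warning("%s: dropped %d degenerate plume feature(s)", date, n_degenerate)
    if n_unknown:
        log.warning("%s: dropped %d plume(s) with unknown density", date, n_unknown)
    return records


def _pick_density_attr(
    fields: list[_shp.FieldDef], candidates: Sequence[str], path: Path
) -> str:
    names = {f.name for f in fields}
    for cand in candidates:
        if cand in names:
            return cand
    raise KeyError(
        f"{path}: no density attribute among {list(candidates)}; "
        f"file has fields {sorted(names)}"
    )


def _clean_geometry(rings: _shp.Rings) -> _shp.Rings | None:
    """Drop degenerate rings; return None if nothing usable remains."""
    kept = tuple(r for r in rings if len(_distinct_vertices(r)) >= 3)
    return kept or None


def write_hms_day(
    path: str | Path,
    plumes: Iterable[PlumeRecord],
    *,
    density_attr: str = "Density",
) -> Path:
    """Write plume records as an HMS-dialect shapefile (fixtures, round-trips)."""
    fields = [
        _shp.FieldDef(density_attr, "C", 10),
        _shp.FieldDef("Start", "C", 12),
    ]
    records = [
        _shp.ShapeRecord(
            rings=p.geometry,
            attrs={density_attr: p.raw_label, "Start": p.date.strftime("%Y%j")},
        )
        for p in plumes
    ]
    return _shp.write_shapefile(path, records, fields)


def hms_archive_url(date: datetime.date, base_url: str = DEFAULT_BASE_URL) -> str:
    """URL of a day's zipped smoke shapefile set in the NOAA archive layout."""
    return (
        f"{base_url.rstrip('/')}/{date.year}/GIS/SMOKE/"
        f"hms_smoke{date:%Y%m%d}.zip"
    )


def fetch_hms(
    date: datetime.date,
    cache_dir: str | Path,
    base_url: str = DEFAULT_BASE_URL,
    *,
    opener: Callable[[str], object] | None = None,
) -> Path:
    """Return a local path to the day's archive, downloading on cache miss.

    Idempotent: a cached file is returned with no network traffic.  A 404
    raises :class:`DayAbsentError`; other HTTP or connection failures raise
    :class:`RetryableFetchError`.  ``opener`` (a ``urlopen``-compatible
    callable) exists for testing.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"hms_smoke{date:%Y%m%d}.zip"
    if target.exists():
        return target

    url = hms_archive_url(date, base_url)
    open_url = opener or urllib.request.urlopen
    tmp = target.with_suffix(".part")
    try:
        with open_url(url) as resp, open(tmp, "wb") as out:  # type: ignore[union-attr]
            shutil.copyfileobj(resp, out)
    except urllib.error.HTTPError as exc:
        tmp.unlink(missing_ok=True)
        if exc.code == 404:
            raise DayAbsentError(url) from exc
        raise RetryableFetchError(f"HTTP {exc.code} for {url}") from exc
    except (urllib.error.URLError, ConnectionError, TimeoutError) as exc:
        tmp.unlink(missing_ok=True)
        raise RetryableFetchError(f"fetch failed for {url}: {exc}") from exc
    tmp.replace(target)
    return target
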