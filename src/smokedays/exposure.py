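"""Building and serializing the daily block-group exposure table.

One output row is one (block group, day) with 0/1 indicators for light,
medium and heavy smoke overhead, plus the block group's 2010 population.
Only smoke-present rows are kept (the published dataset omits unexposed
locations to keep file sizes workable); a dense mode that emits every
point is available behind a flag.

The CSV schema is fixed: header
``date,STATEFP,COUNTYFP,TRACTCE,BLKGRPCE,POPULATION,light,medium,heavy``,
the date as ``yyyymmdd`` text, and FIPS components as plain integers
(leading zeros dropped on write, restored by width on read).  One file per
day, named ``<yyyymmdd>.csv``.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Iterable, Sequence

from .cenpop import FIPS_WIDTHS, BlockGroupPoint
from .coverage import DailyCoverage, flatten_day, max_density, point_indicators
from .hms import DayAbsentError, read_hms_day

log = logging.getLogger(__name__)

CSV_HEADER = "date,STATEFP,COUNTYFP,TRACTCE,BLKGRPCE,POPULATION,light,medium,heavy"


class ExposureSchemaError(ValueError):
    """An exposure CSV whose header or rows violate the fixed schema."""


@dataclass(frozen=True)
class ExposureRecord:
    """One smoke-present (block group, day) row of the exposure table."""

    date: str  # yyyymmdd
    statefp: str
    countyfp: str
    tractce: str
    blkgrpce: str
    population: int
    light: int
    medium: int
    heavy: int
    dense_mode: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.date) != 8 or not self.date.isdigit():
            raise ValueError(f"date must be yyyymmdd text, got {self.date!r}")
        for v in (self.light, self.medium, self.heavy):
            if v not in (0, 1):
                raise ValueError("indicators must be 0 or 1")
        if not self.dense_mode and not (self.light or self.medium or self.heavy):
            raise ValueError("exposure rows must have at least one indicator set")
        if self.population < 0:
            raise ValueError("population must be nonnegative")

    @property
    def geoid(self) -> str:
        return self.statefp + self.countyfp + self.tractce + self.blkgrpce

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.date, self.statefp, self.countyfp, self.tractce, self.blkgrpce)


def assign_exposures(
    cov: DailyCoverage,
    points: Sequence[BlockGroupPoint],
    *,
    dense: bool = False,
) -> list[ExposureRecord]:
    """Intersect a day's coverage with population points.

    Returns one record per point under any plume (all three indicators in a
    single row, never one row per density), sorted by GEOID for output
    determinism.  With ``dense=True`` every point is returned, including
    all-zero rows — the "all day-location combinations" form.
    """
    date_text = cov.date.strftime("%Y%m%d")
    out: list[ExposureRecord] = []
    for bg in points:
        ind = point_indicators((bg.longitude, bg.latitude), cov)
        if not dense and max_density(ind) == 0:
            continue
        out.append(
            ExposureRecord(
                date=date_text,
                statefp=bg.statefp,
                countyfp=bg.countyfp,
                tractce=bg.tractce,
                blkgrpce=bg.blkgrpce,
                population=bg.population,
                light=ind.light,
                medium=ind.medium,
                heavy=ind.heavy,
                dense_mode=dense,
            )
        )
    out.sort(key=lambda r: r.geoid)
    return out


def write_exposure_csv(
    records: Iterable[ExposureRecord], sink: str | Path | IO[str]
) -> int:
    """Write records in the fixed 9-column schema; returns bytes written.

    FIPS components serialize as plain integers for fidelity with the
    published schema; an empty collection produces a header-only file.
    """
    lines = [CSV_HEADER]
    for r in records:
        lines.append(
            f"{r.date},{int(r.statefp)},{int(r.countyfp)},{int(r.tractce)},"
            f"{int(r.blkgrpce)},{r.population},{r.light},{r.medium},{r.heavy}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text, newline="")
    return len(text.encode())


def read_exposure_csv(
    source: str | Path | IO[str], *, dense: bool = False
) -> list[ExposureRecord]:
    """Read an exposure CSV, re-padding FIPS components by width."""
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text()
    lines = text.splitlines()
    if not lines or lines[0] != CSV_HEADER:
        got = lines[0] if lines else "<empty file>"
        raise ExposureSchemaError(f"unknown header: {got!r}")
    records: list[ExposureRecord] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 9:
            raise ExposureSchemaError(f"line {i}: expected 9 columns, got {len(parts)}")
        date, st, co, tr, bg, pop, light, medium, heavy = parts
        if any(v not in ("0", "1") for v in (light, medium, heavy)):
            raise ExposureSchemaError(f"line {i}: indicator outside {{0,1}}")
        records.append(
            ExposureRecord(
                date=date,
                statefp=st.zfill(FIPS_WIDTHS["STATEFP"]),
                countyfp=co.zfill(FIPS_WIDTHS["COUNTYFP"]),
                tractce=tr.zfill(FIPS_WIDTHS["TRACTCE"]),
                blkgrpce=bg.zfill(FIPS_WIDTHS["BLKGRPCE"]),
                population=int(pop),
                light=int(light),
                medium=int(medium),
                heavy=int(heavy),
                dense_mode=dense,
            )
        )
    return records


@dataclass
class RunSummary:
    """Outcome of a multi-day processing run."""

    days_processed: int = 0
    days_absent: int = 0
    records_written: int = 0
    failures: dict[str, str] = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)


def run_range(
    start: datetime.date,
    end: datetime.date,
    points: Sequence[BlockGroupPoint],
    source_for_day: Callable[[datetime.date], str | Path],
    out_dir: str | Path,
    *,
    dense: bool = False,
    skip_unknown_density: bool = False,
) -> RunSummary:
    """Process every day in [start, end], writing one CSV per day.

    ``source_for_day`` maps a date to that day's plume file (raise
    :class:`~smokedays.hms.DayAbsentError` for a missing day).  Absent days
    produce no file and are counted; any other per-day failure is recorded
    in the summary without aborting the range.  Re-running the same range
    writes byte-identical files.
    """
    if end < start:
        raise ValueError("end date before start date")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()
    day = start
    while day <= end:
        try:
            source = source_for_day(day)
            plumes = read_hms_day(
                source, day, skip_unknown_density=skip_unknown_density
            )
        except DayAbsentError:
            log.info("%s: archive day absent", day)
            summary.days_absent += 1
            day += datetime.timedelta(days=1)
            continue
        except Exception as exc:  # noqa: BLE001 — enumerate, don't abort
            log.error("%s: failed: %s", day, exc)
            summary.failures[day.isoformat()] = str(exc)
            day += datetime.timedelta(days=1)
            continue
        cov = flatten_day(plumes, day)
        records = assign_exposures(cov, points, dense=dense)
        path = out_dir / f"{day:%Y%m%d}.csv"
        write_exposure_csv(records, path)
        summary.days_processed += 1
        summary.records_written += len(records)
        summary.files.append(path)
        log.info("%s: %d plume(s), %d record(s)", day, cov.n_plumes, len(records))
        day += datetime.timedelta(days=1)
    return summary


def directory_source(
    plume_dir: str | Path, pattern: str = "{date:%Y%m%d}.shp"
) -> Callable[[datetime.date], Path]:
    """Day->path mapper over a local directory of per-day plume files."""
    plume_dir = Path(plume_dir)

    def source_for_day(date: datetime.date) -> Path:
        path = plume_dir / pattern.format(date=date)
        for cand in (path, path.with_suffix(".shp"), path.with_suffix(".zip")):
            if cand.exists():
                return cand
        raise DayAbsentError(str(path))

    return source_for_day
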