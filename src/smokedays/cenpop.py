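"""US Census block-group Centers of Population reader.

The Census Bureau publishes one national CSV (``CenPop2010_Mean_BG.txt``)
giving, for each of the 220,334 2010 block groups, its population and the
lon/lat of its center of population — the "balance point" of where people
actually live, which represents a census unit far better than a geographic
centroid in sparsely populated areas.  FIPS components are kept as
zero-padded text internally (``"01"`` is not ``1``); width is the only thing
that makes them unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

REQUIRED_COLUMNS = (
    "STATEFP",
    "COUNTYFP",
    "TRACTCE",
    "BLKGRPCE",
    "POPULATION",
    "LATITUDE",
    "LONGITUDE",
)

#: zero-pad widths of the FIPS components of a block-group GEOID
FIPS_WIDTHS = {"STATEFP": 2, "COUNTYFP": 3, "TRACTCE": 6, "BLKGRPCE": 1}


class CenpopSchemaError(ValueError):
    """The source table is missing a required column."""


@dataclass(frozen=True)
class BlockGroupPoint:
    """A block group's center of population with its 2010 population count."""

    statefp: str
    countyfp: str
    tractce: str
    blkgrpce: str
    population: int
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        for name, width in (
            ("statefp", 2), ("countyfp", 3), ("tractce", 6), ("blkgrpce", 1)
        ):
            value = getattr(self, name)
            if len(value) != width or not value.isdigit():
                raise ValueError(f"{name}={value!r} is not {width} digits")
        if self.population < 0:
            raise ValueError("population must be nonnegative")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude out of range: {self.longitude}")

    @property
    def fips_key(self) -> tuple[str, str, str, str]:
        return (self.statefp, self.countyfp, self.tractce, self.blkgrpce)


def geoid(bg: BlockGroupPoint) -> str:
    """The 12-character block-group GEOID (state+county+tract+block group)."""
    return bg.statefp + bg.countyfp + bg.tractce + bg.blkgrpce


def read_cenpop(source: str | Path | IO[str]) -> list[BlockGroupPoint]:
    """Parse a CenPop2010 block-group CSV into population points.

    Leading zeros of FIPS components are restored by zero-padding to the
    component widths, so the file may carry them either as text or as bare
    integers.  Coordinates tolerate explicit ``+`` signs as printed in the
    Census file.

    Raises
    ------
    CenpopSchemaError
        If a required column is absent.
    ValueError
        On a non-numeric population/coordinate (with the offending row
        number) or on duplicate FIPS keys.
    """
    df = pd.read_csv(source, dtype=str, skipinitialspace=True,
                     encoding="latin-1")
    df.columns = [c.strip().upper() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CenpopSchemaError(f"missing required column {col!r}")

    points: list[BlockGroupPoint] = []
    seen: set[tuple[str, str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(df.columns, row))
        try:
            pop = int(str(rec["POPULATION"]).strip())
            lat = float(str(rec["LATITUDE"]).strip().lstrip("+"))
            lon = float(str(rec["LONGITUDE"]).strip().lstrip("+"))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {i}: unparseable numeric field: {exc}") from None
        bg = BlockGroupPoint(
            statefp=str(rec["STATEFP"]).strip().zfill(2),
            countyfp=str(rec["COUNTYFP"]).strip().zfill(3),
            tractce=str(rec["TRACTCE"]).strip().zfill(6),
            blkgrpce=str(rec["BLKGRPCE"]).strip().zfill(1),
            population=pop,
            latitude=lat,
            longitude=lon,
        )
        if bg.fips_key in seen:
            raise ValueError(f"line {i}: duplicate block group {geoid(bg)}")
        seen.add(bg.fips_key)
        points.append(bg)
    return points


def write_cenpop(points: Iterable[BlockGroupPoint], path: str | Path) -> Path:
    """Write points in the CenPop2010 dialect (signed coordinates, header row)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(REQUIRED_COLUMNS) + "\n")
        for p in points:
            fh.write(
                f"{p.statefp},{p.countyfp},{p.tractce},{p.blkgrpce},"
                f"{p.population},{p.latitude:+.6f},{p.longitude:+.6f}\n"
            )
    return path
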