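import datetime

import pytest

import smokedays as sd


UNIT_SQUARE = (((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0), (0.0, 0.0)),)


def run_pipeline(scenario: sd.SyntheticScenario) -> list[sd.ExposureRecord]:
    """Run the production route (flatten -> assign) over a scenario in memory."""
    out: list[sd.ExposureRecord] = []
    for day in scenario.days:
        cov = sd.flatten_day(scenario.plumes_by_day[day], day)
        out.extend(sd.assign_exposures(cov, scenario.points))
    out.sort(key=lambda r: (r.date, r.geoid))
    return out


def square_plume(
    density: sd.Density,
    lo: float,
    hi: float,
    date: datetime.date = datetime.date(2017, 10, 11),
    raw: str | None = None,
) -> sd.PlumeRecord:
    ring = ((lo, lo), (hi, lo), (hi, hi), (lo, hi), (lo, lo))
    return sd.PlumeRecord(
        date=date, density=density, geometry=(ring,),
        raw_label=raw or density.name.lower(),
    )


def make_point(
    lon: float, lat: float, pop: int = 100, *,
    statefp: str = "06", countyfp: str = "097",
    tractce: str = "153704", blkgrpce: str = "2",
) -> sd.BlockGroupPoint:
    return sd.BlockGroupPoint(
        statefp=statefp, countyfp=countyfp, tractce=tractce,
        blkgrpce=blkgrpce, population=pop, latitude=lat, longitude=lon,
    )


@pytest.fixture
def sample_day() -> datetime.date:
    return datetime.date(2017, 10, 11)
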