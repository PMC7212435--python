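import numpy as np
import pandas as pd
import pytest

import smokedays as sd
from smokedays import Density

from conftest import make_point


def _record(date, st, co, tr, bg, pop, light, medium, heavy):
    return sd.ExposureRecord(date, st, co, tr, bg, pop, light, medium, heavy)


def _random_table(seed, n=30):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        flags = rng.integers(0, 2, 3)
        if not flags.any():
            flags[rng.integers(3)] = 1
        rows.append(_record(
            f"201710{rng.integers(1, 10):02d}",
            f"{rng.integers(1, 3):02d}",
            f"{rng.integers(1, 4) * 2 - 1:03d}",
            f"{i + 1:06d}", "1",
            int(rng.integers(0, 5000)),
            int(flags[0]), int(flags[1]), int(flags[2]),
        ))
    return rows


def _naive_person_days(rows, density, key_fn):
    col = {Density.LIGHT: "light", Density.MEDIUM: "medium",
           Density.HEAVY: "heavy"}[density]
    out: dict[tuple, int] = {}
    for r in rows:
        out.setdefault(key_fn(r), 0)
        out[key_fn(r)] += getattr(r, col) * r.population
    return out


def test_single_row_national_person_days():
    rows = [_record("20171011", "06", "097", "000100", "1", 1000, 0, 0, 1)]
    out = sd.person_days(rows, [], Density.HEAVY)
    assert out["person_days"].tolist() == [1000]


def test_empty_table_is_zero():
    assert sd.person_days([], [], Density.LIGHT)["person_days"].tolist() == [0]


def test_unknown_grouping_field_errors():
    with pytest.raises(ValueError, match="unknown grouping"):
        sd.person_days([], ["zipcode"], Density.LIGHT)


@pytest.mark.parametrize("density", list(Density))
def test_person_days_match_naive_oracle_per_county(density):
    rows = _random_table(5)
    out = sd.person_days(rows, ["statefp", "countyfp"], density)
    got = {(r.statefp, r.countyfp): r.person_days for r in out.itertuples()}
    expected = _naive_person_days(rows, density, lambda r: (r.statefp, r.countyfp))
    assert {k: v for k, v in expected.items() if v} == {
        k: v for k, v in got.items() if v
    }


def test_counties_sum_to_state_total():
    rows = _random_table(8, n=60)
    for density in Density:
        by_county = sd.person_days(rows, ["statefp", "countyfp"], density)
        by_state = sd.person_days(rows, ["statefp"], density)
        merged = by_county.groupby("statefp")["person_days"].sum()
        assert merged.to_dict() == by_state.set_index("statefp")["person_days"].to_dict()


def test_series_sums_to_national_person_days():
    rows = _random_table(12, n=50)
    for density in Density:
        series = sd.exposed_population_series(rows, density)
        national = sd.person_days(rows, [], density)["person_days"].iloc[0]
        assert series["population_exposed"].sum() == national


def test_series_simple_day():
    rows = [
        _record("20171011", "06", "097", "000100", "1", 100, 1, 0, 0),
        _record("20171011", "06", "097", "000100", "2", 250, 1, 0, 0),
        _record("20171011", "06", "097", "000100", "3", 999, 0, 1, 0),
    ]
    out = sd.exposed_population_series(rows, Density.LIGHT)
    assert out.loc[out["date"] == "20171011", "population_exposed"].item() == 350


def test_exclusive_series_partitions_exposed_population():
    rows = _random_table(23, n=80)
    df = sd.records_to_frame(rows)
    total_exposed = df.groupby("date")["population"].sum()
    parts = sum(
        sd.exposed_population_series_exclusive(rows, d)
        .set_index("date")["population_exposed"]
        .reindex(total_exposed.index, fill_value=0)
        for d in Density
    )
    assert parts.to_dict() == total_exposed.to_dict()
    # a light+heavy row counts only under heavy in the exclusive variant
    row = [_record("20171011", "06", "097", "000100", "1", 70, 1, 0, 1)]
    heavy = sd.exposed_population_series_exclusive(row, Density.HEAVY)
    light = sd.exposed_population_series_exclusive(row, Density.LIGHT)
    assert heavy["population_exposed"].sum() == 70
    assert light["population_exposed"].sum() == 0


def test_county_day_counted_once_however_many_block_groups():
    rows = [
        _record("20171011", "06", "097", f"{i:06d}", "1", 10, 0, 0, 1)
        for i in range(1, 6)
    ]
    out = sd.county_density_days(rows, Density.HEAVY)
    assert out["days"].tolist() == [1]


def test_county_never_exposed_absent_from_table():
    rows = [_record("20171011", "06", "097", "000100", "1", 10, 1, 0, 0)]
    out = sd.county_density_days(rows, Density.HEAVY)
    assert out.empty


def test_county_days_match_distinct_date_oracle():
    rows = _random_table(31, n=100)
    for density in Density:
        out = sd.county_density_days(rows, density)
        got = {(r.statefp, r.countyfp): r.days for r in out.itertuples()}
        col = density.name.lower()
        expected: dict[tuple, set] = {}
        for r in rows:
            if getattr(r, col):
                expected.setdefault((r.statefp, r.countyfp), set()).add(r.date)
        assert got == {k: len(v) for k, v in expected.items()}
        n_dates = len({r.date for r in rows})
        assert all(v <= n_dates for v in got.values())


def _two_bg_county():
    pop_table = [
        make_point(-122.0, 38.0, 100, statefp="06", countyfp="097",
                   tractce="000100", blkgrpce="1"),
        make_point(-122.1, 38.1, 300, statefp="06", countyfp="097",
                   tractce="000100", blkgrpce="2"),
    ]
    rows = [_record("20171011", "06", "097", "000100", "1", 100, 0, 0, 1)]
    return rows, pop_table


def test_weighted_density_two_block_group_value():
    """100 people under heavy (level 3), 300 under none -> 300/400 = 0.75."""
    rows, pop_table = _two_bg_county()
    out = sd.population_weighted_density(rows, pop_table)
    assert out["weighted_density"].tolist() == [pytest.approx(0.75)]


def test_weighted_density_bounds_attained():
    rows, pop_table = _two_bg_county()
    all_heavy = rows + [
        _record("20171011", "06", "097", "000100", "2", 300, 0, 0, 1)
    ]
    out = sd.population_weighted_density(all_heavy, pop_table)
    assert out["weighted_density"].tolist() == [pytest.approx(3.0)]
    none = sd.population_weighted_density([], pop_table, dates=["20171011"])
    assert none["weighted_density"].tolist() == [0.0]


def test_weighted_density_stays_in_bounds_on_random_tables():
    scenario = sd.generate_scenario(3, n_points=150, n_days=5)
    out = sd.population_weighted_density(scenario.ground_truth, scenario.points)
    vals = out["weighted_density"].dropna()
    assert ((vals >= 0) & (vals <= 3)).all()


def test_weighted_density_monotone_in_block_group_level():
    rows, pop_table = _two_bg_county()
    low = sd.population_weighted_density(
        [_record("20171011", "06", "097", "000100", "1", 100, 1, 0, 0)], pop_table
    )["weighted_density"].iloc[0]
    high = sd.population_weighted_density(rows, pop_table)["weighted_density"].iloc[0]
    assert high > low


def test_weighted_density_zero_population_county_is_missing():
    pop_table = [
        make_point(-122.0, 38.0, 0, statefp="06", countyfp="097",
                   tractce="000100", blkgrpce="1"),
    ]
    out = sd.population_weighted_density([], pop_table, dates=["20171011"])
    assert np.isnan(out["weighted_density"].iloc[0])


def test_weighted_density_rejects_unknown_block_group():
    rows, pop_table = _two_bg_county()
    rows = rows + [_record("20171011", "48", "001", "000100", "1", 10, 1, 0, 0)]
    with pytest.raises(ValueError, match="absent from the population table"):
        sd.population_weighted_density(rows, pop_table)


def test_plot_helper_writes_file(tmp_path):
    scenario = sd.generate_scenario(4, n_points=50, n_days=3)
    out = sd.metrics.plot_exposed_population(
        scenario.ground_truth, tmp_path / "series.png"
    )
    assert out.exists() and out.stat().st_size > 0
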