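"""Aggregation metrics over exposure tables.

Four summaries of the daily block-group smoke table:

* **person-days** — Σ over rows of indicator × population, the burden
  metric: one person under smoke for one day is one person-day.
* **exposed-population series** — person-days grouped by date, the
  national (or regional) time-series of people under each category.
* **county density days** — per county, the number of distinct dates on
  which *any* of its block groups sat under the given density (the
  county inherits its worst block group's exposure).
* **population-weighted density** — per county and day, each block
  group's maximum smoke level (none=0, light=1, medium=2, heavy=3)
  weighted by its share of county population; a continuous index in
  [0, 3].  Because exposure files keep only smoke-present rows, this one
  needs the full population table so unexposed block groups can enter as
  level 0.

All functions accept either a list of :class:`~smokedays.exposure.ExposureRecord`
or a tidy DataFrame from :func:`records_to_frame`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cenpop import BlockGroupPoint
from .density import Density
from .exposure import ExposureRecord, read_exposure_csv

KEY_FIELDS = ("date", "statefp", "countyfp", "tractce", "blkgrpce")
_IND_COL = {Density.LIGHT: "light", Density.MEDIUM: "medium", Density.HEAVY: "heavy"}


def records_to_frame(records: Iterable[ExposureRecord]) -> pd.DataFrame:
    """Exposure records as a tidy DataFrame (FIPS as zero-padded text)."""
    rows = [
        (r.date, r.statefp, r.countyfp, r.tractce, r.blkgrpce,
         r.population, r.light, r.medium, r.heavy)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["date", "statefp", "countyfp", "tractce", "blkgrpce",
                 "population", "light", "medium", "heavy"],
    )


def load_exposure_dir(path: str | Path) -> pd.DataFrame:
    """Concatenate all per-day ``<yyyymmdd>.csv`` files in a directory."""
    frames = [
        records_to_frame(read_exposure_csv(f))
        for f in sorted(Path(path).glob("*.csv"))
    ]
    if not frames:
        return records_to_frame([])
    return pd.concat(frames, ignore_index=True)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def _check_group_by(group_by: Sequence[str]) -> list[str]:
    bad = [g for g in group_by if g not in KEY_FIELDS]
    if bad:
        raise ValueError(f"unknown grouping field(s): {bad}; valid: {KEY_FIELDS}")
    return list(group_by)


def person_days(
    records, group_by: Sequence[str], density: Density
) -> pd.DataFrame:
    """Person-days of exposure: per group, Σ indicator(density) × population.

    ``group_by=[]`` gives the single national total.  Result column is
    ``person_days``; an empty table yields a total of 0.
    """
    df = _as_frame(records)
    keys = _check_group_by(group_by)
    contrib = df[_IND_COL[density]] * df["population"]
    if not keys:
        return pd.DataFrame({"person_days": [int(contrib.sum())]})
    out = (
        contrib.groupby([df[k] for k in keys])
        .sum()
        .astype(int)
        .rename("person_days")
        .reset_index()
    )
    out.columns = keys + ["person_days"]
    return out.sort_values(keys, ignore_index=True)


def exposed_population_series(records, density: Density) -> pd.DataFrame:
    """Per-date total population under the given density (indicator sum).

    Identical to :func:`person_days` grouped by date; summing the series
    over all dates recovers the national person-days total.
    """
    out = person_days(records, ["date"], density)
    return out.rename(columns={"person_days": "population_exposed"})


def exposed_population_series_exclusive(records, density: Density) -> pd.DataFrame:
    """Per-date population whose *maximum* density equals the given level.

    The exclusive variant: a person under both light and heavy counts only
    in the heavy series, so the per-date series over the three levels
    partitions the exposed population.
    """
    df = _as_frame(records)
    level = np.select(
        [df["heavy"] == 1, df["medium"] == 1, df["light"] == 1], [3, 2, 1], 0
    )
    mask = level == density.numeric_level
    contrib = df["population"].where(mask, 0)
    out = (
        contrib.groupby(df["date"]).sum().astype(int)
        .rename("population_exposed").reset_index()
    )
    return out.sort_values("date", ignore_index=True)


def county_density_days(records, density: Density) -> pd.DataFrame:
    """Per county, the number of distinct dates with any exposed block group.

    The county-scale "days of smoke" count behind heavy-smoke-days maps: a
    county experiences a density day if at least one of its block groups
    carries that indicator, regardless of how many do.
    """
    df = _as_frame(records)
    hit = df[df[_IND_COL[density]] == 1]
    if hit.empty:
        return pd.DataFrame(columns=["statefp", "countyfp", "days"])
    out = (
        hit.groupby(["statefp", "countyfp"])["date"]
        .nunique()
        .rename("days")
        .reset_index()
    )
    return out.sort_values(["statefp", "countyfp"], ignore_index=True)


def population_weighted_density(
    records,
    population_table: Sequence[BlockGroupPoint],
    *,
    dates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """County-day smoke index in [0, 3] weighted by population shares.

    For each county and day: Σ_bg max_level(bg) × pop(bg) / Σ_bg pop(bg),
    where the sum runs over *all* the county's block groups — unexposed
    ones contribute level 0 — so ``population_table`` must cover every
    block group referenced by the exposure rows.  Days with no exposure
    anywhere in a county score 0; a county with zero total population is
    reported as missing (NaN).

    Raises ``ValueError`` if an exposure row's block group is absent from
    the population table (inconsistent inputs).
    """
    df = _as_frame(records)
    pop = pd.DataFrame(
        [(p.statefp, p.countyfp, p.tractce, p.blkgrpce, p.population)
         for p in population_table],
        columns=["statefp", "countyfp", "tractce", "blkgrpce", "population"],
    )
    county_pop = pop.groupby(["statefp", "countyfp"])["population"].sum()

    known = set(map(tuple, pop[["statefp", "countyfp", "tractce", "blkgrpce"]].values))
    if not df.empty:
        refs = set(map(tuple, df[["statefp", "countyfp", "tractce", "blkgrpce"]].values))
        missing = refs - known
        if missing:
            geoids = sorted("".join(k) for k in missing)
            raise ValueError(
                f"{len(missing)} exposed block group(s) absent from the "
                f"population table, e.g. {geoids[:3]}"
            )

    if dates is None:
        dates = sorted(df["date"].unique()) if not df.empty else []

    if df.empty:
        weighted = pd.DataFrame(columns=["statefp", "countyfp", "date", "wsum"])
    else:
        level = np.select(
            [df["heavy"] == 1, df["medium"] == 1, df["light"] == 1], [3, 2, 1], 0
        )
        # populations come from the authoritative table, not the exposure rows
        keyed = df[["statefp", "countyfp", "tractce", "blkgrpce", "date"]].copy()
        keyed["level"] = level
        merged = keyed.merge(
            pop, on=["statefp", "countyfp", "tractce", "blkgrpce"], how="left"
        )
        merged["wsum"] = merged["level"] * merged["population"]
        weighted = (
            merged.groupby(["statefp", "countyfp", "date"])["wsum"]
            .sum()
            .reset_index()
        )

    counties = county_pop.reset_index()[["statefp", "countyfp"]]
    grid = counties.merge(pd.DataFrame({"date": list(dates)}), how="cross")
    out = grid.merge(weighted, on=["statefp", "countyfp", "date"], how="left")
    out["wsum"] = pd.to_numeric(out["wsum"], errors="coerce").fillna(0.0)
    totals = out.set_index(["statefp", "countyfp"]).index.map(county_pop)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["weighted_density"] = np.where(
            np.asarray(totals) > 0, out["wsum"] / np.asarray(totals), np.nan
        )
    out = out.drop(columns="wsum")
    return out.sort_values(["statefp", "countyfp", "date"], ignore_index=True)


def plot_exposed_population(
    records, out_path: str | Path, *, exclusive: bool = False
):
    """Save a stacked per-category exposed-population time series plot.

    Presentation helper only; the numbers come from the series functions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series_fn = (
        exposed_population_series_exclusive if exclusive else exposed_population_series
    )
    df = _as_frame(records)
    dates = sorted(df["date"].unique()) if not df.empty else []
    fig, ax = plt.subplots(figsize=(9, 4))
    colors = {Density.LIGHT: "#ffd54f", Density.MEDIUM: "#fb8c00",
              Density.HEAVY: "#b71c1c"}
    for d in Density:
        s = series_fn(records, d).set_index("date")["population_exposed"]
        s = s.reindex(dates, fill_value=0)
        ax.plot(range(len(dates)), s.values, label=d.name.lower(),
                color=colors[d])
    ax.set_xticks(range(len(dates)))
    ax.set_xticklabels(dates, rotation=90, fontsize=6)
    ax.set_ylabel("population under smoke")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
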