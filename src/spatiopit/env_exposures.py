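"""Airborne-pollutant exposure attachment: grid lookup and time aggregation.

Pollutant estimates arrive as a long-format table (cell_id, lat, lon,
timestamp, pollutant, value) at hourly, daily or annual native resolution.
Whatever the native resolution, each patient-year is summarised per
pollutant as

* ``avg_daily`` — the mean over the year of daily means, and
* ``max_daily`` — the maximum over the year of daily means.

Hourly series are first collapsed to daily means/maxima, requiring at least
75% of the 24 hours to be present (the standard completeness rule in
air-quality practice); daily input bypasses that step; annual input is
passed through unchanged (avg and max both equal the annual value).

Patients are assigned to the grid cell whose center is nearest by
great-circle distance; a point farther than the coverage radius from every
center is out of coverage and yields missing exposures rather than a
far-fetched value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .fhir_ingest import GeoPoint

EARTH_RADIUS_M = 6_371_008.8

#: Fraction of the 24 hours that must be present for a daily mean.
DAILY_COMPLETENESS = 0.75


class CoverageError(ValueError):
    """Point beyond the coverage radius of every grid cell."""


@dataclass
class ExposureGrid:
    """Pollutant-estimate grid: cell centers plus a long-format series table.

    ``table`` columns: cell_id, lat, lon, timestamp (ISO 8601), pollutant,
    value.  ``native_resolution`` is one of hourly/daily/annual.
    """

    table: pd.DataFrame
    native_resolution: str

    def __post_init__(self) -> None:
        if self.native_resolution not in ("hourly", "daily", "annual"):
            raise ValueError(f"bad resolution {self.native_resolution!r}")
        centers = self.table.drop_duplicates("cell_id")[["cell_id", "lat", "lon"]]
        if centers.duplicated(["lat", "lon"]).any():
            raise ValueError("cell centers must be unique")
        self.centers = centers.sort_values("cell_id").reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str, native_resolution: str) -> "ExposureGrid":
        df = pd.read_csv(path, dtype={"cell_id": str})
        return cls(df, native_resolution)

    def spacing(self) -> float:
        """Median nearest-neighbor great-circle distance between centers (m)."""
        lat = np.radians(self.centers["lat"].to_numpy())
        lon = np.radians(self.centers["lon"].to_numpy())
        if len(lat) < 2:
            return math.inf
        d = _haversine_matrix(lat, lon)
        np.fill_diagonal(d, np.inf)
        return float(np.median(d.min(axis=1)))


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def haversine_m(p: GeoPoint, q: GeoPoint) -> float:
    """Great-circle distance in meters between two WGS84 points."""
    lat1, lon1, lat2, lon2 = map(math.radians, (p.lat, p.lon, q.lat, q.lon))
    a = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def aggregate_daily(hourly_values: "pd.Series | list[float]") -> dict:
    """Daily mean and max from up to 24 hourly values.

    Returns ``{"mean": nan, "max": nan}`` when fewer than 75% of the 24
    hours are present — an incomplete day would bias the daily statistics.
    """
    s = pd.Series(hourly_values, dtype=float).dropna()
    if len(s) < DAILY_COMPLETENESS * 24:
        return {"mean": math.nan, "max": math.nan}
    return {"mean": float(s.mean()), "max": float(s.max())}


def aggregate_annual(daily_means: "pd.Series | list[float]") -> dict:
    """Annual summary of a year of daily means (missing days ignored)."""
    s = pd.Series(daily_means, dtype=float).dropna()
    if s.empty:
        return {"avg_daily": math.nan, "max_daily": math.nan}
    return {"avg_daily": float(s.mean()), "max_daily": float(s.max())}


def lookup_cell(
    grid: ExposureGrid, p: GeoPoint, coverage_radius_m: float | None = None
) -> str:
    """Nearest cell (by great-circle distance) covering point *p*.

    Ties broken by lexicographically smallest cell_id.  The default coverage
    radius is 1.5x the grid spacing; a nearest center beyond it raises
    :class:`CoverageError`.
    """
    if grid.centers.empty:
        raise ValueError("grid has no cells")
    if coverage_radius_m is None:
        coverage_radius_m = 1.5 * grid.spacing()
    lat = np.radians(grid.centers["lat"].to_numpy())
    lon = np.radians(grid.centers["lon"].to_numpy())
    plat, plon = math.radians(p.lat), math.radians(p.lon)
    a = (
        np.sin((lat - plat) / 2) ** 2
        + np.cos(plat) * np.cos(lat) * np.sin((lon - plon) / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    dmin = d.min()
    if dmin > coverage_radius_m:
        raise CoverageError(
            f"nearest cell is {dmin:.0f} m away, beyond coverage "
            f"radius {coverage_radius_m:.0f} m"
        )
    ids = grid.centers.loc[np.isclose(d, dmin), "cell_id"]
    return str(ids.min())


def summarize_cell_year(grid: ExposureGrid, year: int) -> pd.DataFrame:
    """Per-cell, per-pollutant annual statistics for one year.

    Columns: cell_id, pollutant, avg_daily, max_daily.  The aggregation
    path depends on the grid's native resolution; daily and annual inputs
    bypass the finer stages so that already-aggregated statistics pass
    through unchanged.
    """
    df = grid.table
    ts = df["timestamp"].astype(str)
    df = df[ts.str[:4] == f"{year:04d}"].copy()
    if df.empty:
        return pd.DataFrame(columns=["cell_id", "pollutant", "avg_daily", "max_daily"])

    if grid.native_resolution == "annual":
        out = df.rename(columns={"value": "avg_daily"})[
            ["cell_id", "pollutant", "avg_daily"]
        ].copy()
        out["max_daily"] = out["avg_daily"]
        return out.reset_index(drop=True)

    if grid.native_resolution == "hourly":
        df["date"] = df["timestamp"].astype(str).str[:10]
        daily = (
            df.groupby(["cell_id", "pollutant", "date"])["value"]
            .agg(n_present="count", mean="mean")
            .reset_index()
        )
        daily.loc[daily["n_present"] < DAILY_COMPLETENESS * 24, "mean"] = np.nan
        df = daily.rename(columns={"mean": "value"})
    # daily resolution: each row is already a daily mean
    out = (
        df.groupby(["cell_id", "pollutant"])["value"]
        .agg(avg_daily="mean", max_daily="max")
        .reset_index()
    )
    return out


def attach_exposures(
    features: pd.DataFrame,
    geocodes: Mapping[str, GeoPoint | None],
    grid: ExposureGrid,
    coverage_radius_m: float | None = None,
) -> pd.DataFrame:
    """One exposure row per (patient, year) of the clinical feature table.

    Output columns: patient_id, year, then ``<pollutant>_avg_daily`` and
    ``<pollutant>_max_daily`` per pollutant.  Patients with no geocode or
    out of grid coverage keep their row with missing exposure values — the
    decision to drop incomplete rows belongs to the analyst, not the join.
    """
    if coverage_radius_m is None:
        coverage_radius_m = 1.5 * grid.spacing()
    keys = features[["patient_id", "year"]].drop_duplicates()
    pollutants = sorted(grid.table["pollutant"].unique())

    cell_year: dict[int, pd.DataFrame] = {}
    rows = []
    for patient_id, year in keys.itertuples(index=False):
        year = int(year)
        row: dict = {"patient_id": patient_id, "year": year}
        point = geocodes.get(patient_id)
        cell = None
        if point is not None:
            try:
                cell = lookup_cell(grid, point, coverage_radius_m)
            except CoverageError:
                cell = None
        if cell is not None:
            if year not in cell_year:
                cell_year[year] = summarize_cell_year(grid, year)
            summary = cell_year[year]
            sub = summary[summary["cell_id"] == cell]
            for _, r in sub.iterrows():
                row[f"{r['pollutant']}_avg_daily"] = r["avg_daily"]
                row[f"{r['pollutant']}_max_daily"] = r["max_daily"]
        for pol in pollutants:
            row.setdefault(f"{pol}_avg_daily", math.nan)
            row.setdefault(f"{pol}_max_daily", math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
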