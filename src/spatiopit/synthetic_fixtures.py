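"""Deterministic synthetic inputs for every source family the pipeline joins.

Real inputs to this pipeline — clinical warehouse FHIR extracts, national
pollutant-model grids, census road and polygon files — are either protected
health information or bulk downloads.  These generators emulate all four
families at small scale so the full pipeline and its statistics run
self-contained:

* a cohort of FHIR R4 JSON resources (Patient with geocoded address,
  Encounters with respiratory diagnosis codes, MedicationRequests),
* a pollutant grid (long CSV) at hourly, daily or annual resolution,
* a road lattice (GeoJSON LineStrings) in census-style and highway-style
  attribute flavors, a census-polygon partition of the bounding box
  (GeoJSON) and an ACS-style attribute table (CSV) with an urban/rural
  field.

The key design point is the *planted effect*: patients residing inside a
designated high-exposure sub-region both see elevated PM2.5 in the grid and
draw their exacerbation status (two or more annual ED/inpatient respiratory
visits) with an elevated probability.  Prednisone orders correlate with
exacerbation status.  The pipeline should therefore recover an
exposure-outcome association whose strength the caller controls — setting
the high probability equal to the baseline yields a true null for type-I
calibration.

All randomness flows from one seed; each generator draws from its own
fixed substream so adding a generator never perturbs the others.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fhir_ingest import GEOLOCATION_URL, US_CORE_ETHNICITY, US_CORE_RACE

# Fixed substream offsets (seed + offset -> per-generator stream).
_COHORT_STREAM = 11
_GRID_STREAM = 23
_GEO_STREAM = 37


class FixtureSpecError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic data set.

    The defaults describe a modest single-year cohort over a small
    coastal-plain bounding box: 500 patients, a 4x4 pollutant grid, a 10%
    baseline annual exacerbation probability rising to 30% in the
    high-exposure quadrant, and prednisone ordered for 17% of exacerbating
    vs 10% of non-exacerbating patients (the rough usage split seen in
    published prednisone-by-exacerbation tables).
    """

    seed: int = 0
    n_patients: int = 500
    bbox: tuple[float, float, float, float] = (35.0, 36.0, -79.5, -78.5)
    grid_shape: tuple[int, int] = (4, 4)
    years: tuple[int, ...] = (2010,)
    high_exposure_region: tuple[float, float, float, float] | None = None
    baseline_exacerbation_prob: float = 0.1
    high_exposure_exacerbation_prob: float = 0.3
    prednisone_prob_exac: float = 0.17
    prednisone_prob_no_exac: float = 0.10
    pm25_low_mean: float = 7.0
    pm25_high_mean: float = 12.0
    pm25_sd: float = 2.0
    resolution: str = "daily"  # native grid resolution: hourly|daily|annual

    def __post_init__(self) -> None:
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise FixtureSpecError("bbox must be well-ordered")
        if self.n_patients <= 0:
            raise FixtureSpecError("n_patients must be positive")
        for p in (
            self.baseline_exacerbation_prob,
            self.high_exposure_exacerbation_prob,
            self.prednisone_prob_exac,
            self.prednisone_prob_no_exac,
        ):
            if not 0.0 <= p <= 1.0:
                raise FixtureSpecError(f"probability {p} outside [0, 1]")
        if self.high_exposure_exacerbation_prob < self.baseline_exacerbation_prob:
            raise FixtureSpecError("high-exposure probability must be >= baseline")
        if self.high_exposure_region is None:
            # default: the north-east quadrant of the bbox
            self.high_exposure_region = (
                (lat_min + lat_max) / 2,
                lat_max,
                (lon_min + lon_max) / 2,
                lon_max,
            )

    def in_high_region(self, lat: float, lon: float) -> bool:
        a, b, c, d = self.high_exposure_region
        return a <= lat <= b and c <= lon <= d

    @classmethod
    def from_yaml(cls, path: str) -> "FixtureSpec":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("bbox", "grid_shape", "years", "high_exposure_region"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# FHIR cohort

_RACES = [("2054-5", 0.35), ("2106-3", 0.55), ("2028-9", 0.10)]
_RESP_CODES = ["J45.901", "J45.21", "J20.9", "J18.9"]
_OTHER_CODES = ["E11.9", "I10", "M54.5"]


def _patient_resource(spec: FixtureSpec, pid: str, rng: np.random.Generator) -> dict:
    lat_min, lat_max, lon_min, lon_max = spec.bbox
    lat = float(rng.uniform(lat_min, lat_max))
    lon = float(rng.uniform(lon_min, lon_max))
    race = _RACES[rng.choice(len(_RACES), p=[w for _, w in _RACES])][0]
    birth_year = int(rng.integers(1915, 2008))
    return {
        "resourceType": "Patient",
        "id": pid,
        "gender": "female" if rng.random() < 0.5 else "male",
        "birthDate": f"{birth_year:04d}-{int(rng.integers(1, 13)):02d}-01",
        "extension": [
            {
                "url": US_CORE_RACE,
                "extension": [{"url": "ombCategory", "valueCoding": {"code": race}}],
            },
            {
                "url": US_CORE_ETHNICITY,
                "extension": [
                    {"url": "ombCategory", "valueCoding": {"code": "2186-5"}}
                ],
            },
        ],
        "address": [
            {
                "use": "home",
                "period": {"start": "2000-01-01"},
                "extension": [
                    {
                        "url": GEOLOCATION_URL,
                        "extension": [
                            {"url": "latitude", "valueDecimal": round(lat, 6)},
                            {"url": "longitude", "valueDecimal": round(lon, 6)},
                        ],
                    }
                ],
            }
        ],
    }


def _encounter(pid: str, eid: str, klass: str, date: str, codes: list[str]) -> dict:
    return {
        "resourceType": "Encounter",
        "id": eid,
        "subject": {"reference": f"Patient/{pid}"},
        "class": {"code": klass},
        "period": {"start": f"{date}T10:00:00"},
        "reasonCode": [{"coding": [{"code": c}]} for c in codes],
    }


def _random_date(rng: np.random.Generator, year: int) -> str:
    day = int(rng.integers(0, 365))
    return str(pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=day))[:10]


def generate_cohort(spec: FixtureSpec, out_dir: str) -> dict:
    """Write a synthetic FHIR cohort as NDJSON; return planting metadata.

    One ``cohort.ndjson`` file holds all resources, shuffled so grouping
    logic cannot rely on input order.  Returns per-patient truth (region,
    exacerbation status per year) for test oracles.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed + _COHORT_STREAM)
    resources: list[dict] = []
    truth: dict[str, dict] = {}

    for i in range(spec.n_patients):
        pid = f"p{i:05d}"
        patient = _patient_resource(spec, pid, rng)
        geo = patient["address"][0]["extension"][0]["extension"]
        lat, lon = geo[0]["valueDecimal"], geo[1]["valueDecimal"]
        high = spec.in_high_region(lat, lon)
        resources.append(patient)
        truth[pid] = {"high_exposure": high, "exacerbation": {}}

        for year in spec.years:
            p_exac = (
                spec.high_exposure_exacerbation_prob
                if high
                else spec.baseline_exacerbation_prob
            )
            exac = bool(rng.random() < p_exac)
            truth[pid]["exacerbation"][year] = exac
            n_resp = int(rng.integers(2, 5)) if exac else int(rng.integers(0, 2))
            for j in range(n_resp):
                klass = "EMER" if rng.random() < 0.7 else "IMP"
                code = _RESP_CODES[int(rng.integers(len(_RESP_CODES)))]
                resources.append(
                    _encounter(
                        pid,
                        f"{pid}-e{year}-{j}",
                        klass,
                        _random_date(rng, year),
                        [code],
                    )
                )
            # background ambulatory / non-respiratory noise
            for j in range(int(rng.integers(0, 3))):
                code = _OTHER_CODES[int(rng.integers(len(_OTHER_CODES)))]
                resources.append(
                    _encounter(
                        pid,
                        f"{pid}-a{year}-{j}",
                        "AMB",
                        _random_date(rng, year),
                        [code],
                    )
                )
            p_med = spec.prednisone_prob_exac if exac else spec.prednisone_prob_no_exac
            if rng.random() < p_med:
                resources.append(
                    {
                        "resourceType": "MedicationRequest",
                        "id": f"{pid}-m{year}",
                        "subject": {"reference": f"Patient/{pid}"},
                        "medicationCodeableConcept": {
                            "coding": [{"code": "prednisone"}],
                            "text": "prednisone",
                        },
                        "authoredOn": _random_date(rng, year),
                    }
                )

    order = rng.permutation(len(resources))
    path = os.path.join(out_dir, "cohort.ndjson")
    with open(path, "w", encoding="utf-8") as fh:
        for k in order:
            fh.write(json.dumps(resources[int(k)], sort_keys=True) + "\n")
    return truth


# ---------------------------------------------------------------------------
# Pollutant grid


def _grid_centers(spec: FixtureSpec) -> pd.DataFrame:
    lat_min, lat_max, lon_min, lon_max = spec.bbox
    nrow, ncol = spec.grid_shape
    lats = lat_min + (np.arange(nrow) + 0.5) * (lat_max - lat_min) / nrow
    lons = lon_min + (np.arange(ncol) + 0.5) * (lon_max - lon_min) / ncol
    rows = []
    for i, lat in enumerate(lats):
        for j, lon in enumerate(lons):
            rows.append(
                {
                    "cell_id": f"c{i:02d}{j:02d}",
                    "lat": round(float(lat), 6),
                    "lon": round(float(lon), 6),
                }
            )
    return pd.DataFrame(rows)


def generate_env_grid(spec: FixtureSpec, out_path: str) -> pd.DataFrame:
    """Write the pollutant grid CSV; return the frame.

    PM2.5 values are Gaussian around the low mean, shifted to the high mean
    for cells whose center falls in the high-exposure region.  The native
    resolution (hourly / daily / annual) exercises each aggregation path.
    """
    rng = np.random.default_rng(spec.seed + _GRID_STREAM)
    centers = _grid_centers(spec)
    rows = []
    for _, cell in centers.iterrows():
        mean = (
            spec.pm25_high_mean
            if spec.in_high_region(cell["lat"], cell["lon"])
            else spec.pm25_low_mean
        )
        for year in spec.years:
            days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            if spec.resolution == "annual":
                value = float(rng.normal(mean, spec.pm25_sd / math.sqrt(365)))
                rows.append(
                    {
                        "cell_id": cell["cell_id"],
                        "lat": cell["lat"],
                        "lon": cell["lon"],
                        "timestamp": f"{year}-01-01",
                        "pollutant": "pm25",
                        "value": round(max(value, 0.0), 4),
                    }
                )
                continue
            daily = rng.normal(mean, spec.pm25_sd, size=len(days))
            if spec.resolution == "daily":
                for d, v in zip(days, daily):
                    rows.append(
                        {
                            "cell_id": cell["cell_id"],
                            "lat": cell["lat"],
                            "lon": cell["lon"],
                            "timestamp": str(d)[:10],
                            "pollutant": "pm25",
                            "value": round(max(float(v), 0.0), 4),
                        }
                    )
            else:  # hourly
                for d, v in zip(days, daily):
                    hourly = rng.normal(v, spec.pm25_sd / 2, size=24)
                    for h, hv in enumerate(hourly):
                        rows.append(
                            {
                                "cell_id": cell["cell_id"],
                                "lat": cell["lat"],
                                "lon": cell["lon"],
                                "timestamp": f"{str(d)[:10]}T{h:02d}:00:00",
                                "pollutant": "pm25",
                                "value": round(max(float(hv), 0.0), 4),
                            }
                        )
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False)
    return df


# ---------------------------------------------------------------------------
# Roads, census polygons, ACS table


def generate_geo_layers(spec: FixtureSpec, out_dir: str) -> dict[str, str]:
    """Write road GeoJSONs (two attribute flavors), census GeoJSON, ACS CSV.

    Roads form a lattice along the census-grid lines: one LineString per
    interior row/column boundary plus the bbox frame, each with a stable id.
    The census layer partitions the bbox into ``grid_shape`` rectangles.
    Returns the paths written, keyed by layer name.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed + _GEO_STREAM)
    lat_min, lat_max, lon_min, lon_max = spec.bbox
    nrow, ncol = spec.grid_shape
    lat_edges = np.linspace(lat_min, lat_max, nrow + 1)
    lon_edges = np.linspace(lon_min, lon_max, ncol + 1)

    road_features = []
    rid = 0
    for lat in lat_edges:
        road_features.append(
            {
                "type": "Feature",
                "properties": {"segment_id": f"r{rid:03d}", "road_class": "secondary"},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [round(lon_min, 6), round(float(lat), 6)],
                        [round(lon_max, 6), round(float(lat), 6)],
                    ],
                },
            }
        )
        rid += 1
    for lon in lon_edges:
        road_features.append(
            {
                "type": "Feature",
                "properties": {"segment_id": f"r{rid:03d}", "road_class": "primary"},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [round(float(lon), 6), round(lat_min, 6)],
                        [round(float(lon), 6), round(lat_max, 6)],
                    ],
                },
            }
        )
        rid += 1

    paths = {}
    paths["roads_tiger"] = os.path.join(out_dir, "roads_tiger.geojson")
    with open(paths["roads_tiger"], "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": road_features}, fh)

    # highway flavor: identical geometry, traffic-count attributes
    hpms_features = []
    for feat in road_features:
        f2 = json.loads(json.dumps(feat))
        f2["properties"] = {
            "segment_id": feat["properties"]["segment_id"],
            "aadt": int(rng.integers(500, 40000)),
        }
        hpms_features.append(f2)
    paths["roads_hpms"] = os.path.join(out_dir, "roads_hpms.geojson")
    with open(paths["roads_hpms"], "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": hpms_features}, fh)

    census_features = []
    acs_rows = []
    for i in range(nrow):
        for j in range(ncol):
            uid = f"37000{i:02d}{j:02d}"
            lo_la, hi_la = float(lat_edges[i]), float(lat_edges[i + 1])
            lo_lo, hi_lo = float(lon_edges[j]), float(lon_edges[j + 1])
            ring = [
                [lo_lo, lo_la],
                [hi_lo, lo_la],
                [hi_lo, hi_la],
                [lo_lo, hi_la],
                [lo_lo, lo_la],
            ]
            census_features.append(
                {
                    "type": "Feature",
                    "properties": {"unit_id": uid},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
            center_lat = (lo_la + hi_la) / 2
            center_lon = (lo_lo + hi_lo) / 2
            acs_rows.append(
                {
                    "unit_id": uid,
                    "est_household_income": int(rng.integers(25, 120)) * 1000,
                    "residential_density": round(float(rng.uniform(0.1, 8.0)), 2),
                    "ur": "urban"
                    if spec.in_high_region(center_lat, center_lon)
                    else "rural",
                }
            )

    paths["census"] = os.path.join(out_dir, "census.geojson")
    with open(paths["census"], "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": census_features}, fh)

    paths["acs"] = os.path.join(out_dir, "acs.csv")
    pd.DataFrame(acs_rows).to_csv(paths["acs"], index=False)
    return paths


def generate_all(spec: FixtureSpec, out_dir: str) -> dict:
    """Generate every input family under *out_dir*; return a manifest."""
    os.makedirs(out_dir, exist_ok=True)
    truth = generate_cohort(spec, os.path.join(out_dir, "fhir"))
    grid_path = os.path.join(out_dir, "pm25_grid.csv")
    generate_env_grid(spec, grid_path)
    geo_paths = generate_geo_layers(spec, out_dir)
    return {
        "fhir_dir": os.path.join(out_dir, "fhir"),
        "grid": grid_path,
        "resolution": spec.resolution,
        **geo_paths,
        "truth": truth,
    }
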