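"""Nearest-road distance and census-polygon / ACS attribute joins.

Road exposure: for each residence geocode, find the road segment (polyline,
WGS84) minimizing point-to-polyline distance and carry its attributes
(road class, traffic counts).  Distances are computed in meters in a local
equirectangular projection centered on the query point — at the sub-10-km
scales relevant to nearest-road exposure the error versus full geodesics is
negligible, and the planar formulation is directly checkable against a
brute-force oracle.  Two road sources (census TIGER-like geometry, highway
HPMS-like traffic data) run through the same core and differ only in the
attributes carried.

Socio-environmental exposure: assign the residence to the census polygon
containing it (even-odd rule) and join the polygon's attribute row from an
ACS-style table keyed by unit id.  The v2 table adds a ``ur`` urban/rural
field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import LineString, Point, shape

from .env_exposures import EARTH_RADIUS_M
from .fhir_ingest import GeoPoint


class GeometryConfigError(ValueError):
    pass


class InputIntegrityError(ValueError):
    pass


@dataclass
class RoadSegment:
    """A road polyline in WGS84 with source-specific attributes."""

    segment_id: str
    vertices: Sequence[tuple[float, float]]  # (lat, lon)
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise GeometryConfigError(
                f"segment {self.segment_id}: needs >= 2 vertices"
            )
        for lat, lon in self.vertices:
            if not (math.isfinite(lat) and math.isfinite(lon)):
                raise GeometryConfigError(
                    f"segment {self.segment_id}: non-finite coordinate"
                )


@dataclass
class NearestRoadResult:
    patient_id: str | None
    segment_id: str
    distance_m: float
    attributes: dict[str, Any] = field(default_factory=dict)


@dataclass
class CensusUnit:
    """A census polygon (possibly with holes) identified by its unit code."""

    unit_id: str
    polygon: Any  # shapely Polygon/MultiPolygon


def _project_local(
    p: GeoPoint, latlon: Iterable[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Equirectangular projection centered at p: degrees -> meters."""
    coslat = math.cos(math.radians(p.lat))
    out = []
    for lat, lon in latlon:
        x = math.radians(lon - p.lon) * coslat * EARTH_RADIUS_M
        y = math.radians(lat - p.lat) * EARTH_RADIUS_M
        out.append((x, y))
    return out


def nearest_road(
    p: GeoPoint, segments: Sequence[RoadSegment], patient_id: str | None = None
) -> NearestRoadResult:
    """Segment minimizing point-to-polyline distance from *p*, in meters.

    The minimum over edges uses the perpendicular foot where it falls within
    the edge and the nearest vertex otherwise (shapely's point-to-linestring
    distance on the locally projected coordinates).  Exact ties go to the
    smallest segment_id.
    """
    if not segments:
        raise GeometryConfigError("nearest_road requires a non-empty segment list")
    origin = Point(0.0, 0.0)
    best: tuple[float, str, RoadSegment] | None = None
    for seg in segments:
        line = LineString(_project_local(p, seg.vertices))
        d = origin.distance(line)
        key = (d, seg.segment_id)
        if best is None or key < (best[0], best[1]):
            best = (d, seg.segment_id, seg)
    d, sid, seg = best
    return NearestRoadResult(
        patient_id=patient_id,
        segment_id=sid,
        distance_m=d,
        attributes=dict(seg.attributes),
    )


def assign_census_unit(p: GeoPoint, units: Sequence[CensusUnit]) -> str | None:
    """Unit whose polygon contains *p*; None when no polygon does.

    Boundary points are assigned to the containing unit earliest in
    unit_id order, making the assignment deterministic on shared edges of a
    polygon partition.
    """
    if not units:
        raise GeometryConfigError("assign_census_unit requires >= 1 unit")
    pt = Point(p.lon, p.lat)  # GeoJSON axis order: x=lon, y=lat
    for unit in sorted(units, key=lambda u: u.unit_id):
        if unit.polygon.covers(pt):
            return unit.unit_id
    return None


def attach_acs(
    unit_id: str | None, acs: pd.DataFrame, version: int = 1
) -> dict[str, Any]:
    """Attribute row for *unit_id* from an ACS table keyed by unit_id.

    Returns an all-missing map for an unmatched (or None) unit.  A version-2
    table must carry the ``ur`` urban/rural field; duplicate unit ids are an
    input-integrity error because the join would silently multiply rows.
    """
    if acs["unit_id"].duplicated().any():
        dupes = acs.loc[acs["unit_id"].duplicated(), "unit_id"].tolist()
        raise InputIntegrityError(f"duplicate unit_id in ACS table: {dupes}")
    if version == 2 and "ur" not in acs.columns:
        raise InputIntegrityError("ACS v2 table must include the 'ur' field")
    attr_cols = [c for c in acs.columns if c != "unit_id"]
    if unit_id is not None:
        match = acs[acs["unit_id"] == unit_id]
        if len(match):
            return {c: match.iloc[0][c] for c in attr_cols}
    return {c: None for c in attr_cols}


# ---------------------------------------------------------------------------
# GeoJSON I/O (reference geometry format; plain text, no binary deps)


def read_roads_geojson(path: str, id_property: str = "segment_id") -> list[RoadSegment]:
    """Road segments from a GeoJSON FeatureCollection of LineStrings."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    segments = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            continue
        props = dict(feat.get("properties") or {})
        sid = str(props.pop(id_property, i))
        vertices = [(lat, lon) for lon, lat in geom["coordinates"]]
        segments.append(RoadSegment(segment_id=sid, vertices=vertices, attributes=props))
    return segments


def read_census_geojson(path: str, id_property: str = "unit_id") -> list[CensusUnit]:
    """Census units from a GeoJSON FeatureCollection of (Multi)Polygons."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    units = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") not in ("Polygon", "MultiPolygon"):
            continue
        props = feat.get("properties") or {}
        units.append(
            CensusUnit(unit_id=str(props.get(id_property, i)), polygon=shape(geom))
        )
    return units


def nearest_road_table(
    geocodes: Mapping[str, GeoPoint | None],
    segments: Sequence[RoadSegment],
    prefix: str = "road",
) -> pd.DataFrame:
    """Per-patient nearest-road rows; missing geocodes yield missing values."""
    rows = []
    for pid in sorted(geocodes):
        p = geocodes[pid]
        row: dict[str, Any] = {"patient_id": pid}
        if p is not None:
            res = nearest_road(p, segments, patient_id=pid)
            row[f"{prefix}_segment_id"] = res.segment_id
            row[f"{prefix}_distance_m"] = res.distance_m
            for k, v in res.attributes.items():
                row[f"{prefix}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def acs_table(
    geocodes: Mapping[str, GeoPoint | None],
    units: Sequence[CensusUnit],
    acs: pd.DataFrame,
    version: int = 1,
) -> pd.DataFrame:
    """Per-patient ACS attributes via point-in-polygon unit assignment."""
    rows = []
    for pid in sorted(geocodes):
        p = geocodes[pid]
        unit = assign_census_unit(p, units) if p is not None else None
        row = {"patient_id": pid, "census_unit": unit}
        row.update(attach_acs(unit, acs, version=version))
        rows.append(row)
    return pd.DataFrame(rows)
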