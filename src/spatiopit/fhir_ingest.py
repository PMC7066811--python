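"""Consolidate FHIR resources into per-patient bundles and extract geocodes.

Clinical input arrives as a stream of FHIR R4 JSON resources (Patient,
Encounter, Condition, MedicationRequest), either one resource per file or
newline-delimited JSON.  Consolidation groups every non-Patient resource
under the Patient it references, producing one :class:`PatientBundle` per
patient; resources referencing no known patient are counted as orphans and
excluded.  The patient's primary home residence is read from the standard
FHIR address geolocation extension as WGS84 latitude/longitude.

Geocodes are Protected Health Information: they exist only in this
identified, intermediate stage of the pipeline and are stripped before any
table leaves it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Iterator, Mapping

GEOLOCATION_URL = "http://hl7.org/fhir/StructureDefinition/geolocation"
US_CORE_RACE = "http://hl7.org/fhir/us/core/StructureDefinition/us-core-race"
US_CORE_ETHNICITY = (
    "http://hl7.org/fhir/us/core/StructureDefinition/us-core-ethnicity"
)

#: Encounter class codes (ActCode) mapped onto the four classes the feature
#: extractor distinguishes.
ENCOUNTER_CLASS_MAP = {
    "EMER": "emergency",
    "IMP": "inpatient",
    "ACUTE": "inpatient",
    "NONAC": "inpatient",
    "AMB": "ambulatory",
}


class MalformedResourceError(ValueError):
    """A JSON object that is not a usable FHIR resource."""

    def __init__(self, message: str, context: str = ""):
        self.context = context
        super().__init__(f"{message}" + (f" [{context}]" if context else ""))


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate, decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"coordinate out of range: ({self.lat}, {self.lon})")
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError("coordinate must be finite")


@dataclass
class Address:
    """A patient address with optional geolocation and validity period."""

    point: GeoPoint | None = None
    period_start: str | None = None  # ISO date
    period_end: str | None = None
    use: str | None = None


@dataclass
class Encounter:
    encounter_id: str
    klass: str  # emergency | inpatient | ambulatory | other
    start: str  # ISO datetime
    diagnosis_codes: list[str] = field(default_factory=list)


@dataclass
class Medication:
    code: str  # drug name or code, lower-cased for matching
    authored: str  # ISO date


@dataclass
class Condition:
    code: str
    onset: str | None = None


@dataclass
class PatientBundle:
    """All clinical material for one patient, consolidated.

    Encounters are kept sorted ascending by start time so that downstream
    per-year windowing is a contiguous scan.
    """

    patient_id: str
    birth_date: str | None = None
    sex: str | None = None
    race: str | None = None
    ethnicity: str | None = None
    addresses: list[Address] = field(default_factory=list)
    encounters: list[Encounter] = field(default_factory=list)
    conditions: list[Condition] = field(default_factory=list)
    medications: list[Medication] = field(default_factory=list)

    def sort(self) -> None:
        self.encounters.sort(key=lambda e: (e.start, e.encounter_id))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PatientBundle":
        d = json.loads(text)
        d["addresses"] = [
            Address(
                point=GeoPoint(**a["point"]) if a.get("point") else None,
                period_start=a.get("period_start"),
                period_end=a.get("period_end"),
                use=a.get("use"),
            )
            for a in d.get("addresses", [])
        ]
        d["encounters"] = [Encounter(**e) for e in d.get("encounters", [])]
        d["conditions"] = [Condition(**c) for c in d.get("conditions", [])]
        d["medications"] = [Medication(**m) for m in d.get("medications", [])]
        return cls(**d)


def _reference_id(ref: Any) -> str | None:
    """Extract a Patient id from a FHIR reference like 'Patient/p1'."""
    if isinstance(ref, Mapping):
        ref = ref.get("reference")
    if not isinstance(ref, str):
        return None
    if "/" in ref:
        rtype, rid = ref.rsplit("/", 1)
        return rid if rtype.endswith("Patient") else None
    return ref or None


def _codings(codeable: Any) -> list[str]:
    """All coding codes (and text fallback) from a CodeableConcept."""
    out: list[str] = []
    if isinstance(codeable, Mapping):
        for coding in codeable.get("coding") or []:
            code = coding.get("code")
            if code:
                out.append(str(code))
        if not out and codeable.get("text"):
            out.append(str(codeable["text"]))
    return out


def _extension_coordinates(address: Mapping[str, Any]) -> GeoPoint | None:
    for ext in address.get("extension") or []:
        if ext.get("url") != GEOLOCATION_URL:
            continue
        lat = lon = None
        for sub in ext.get("extension") or []:
            if sub.get("url") == "latitude":
                lat = sub.get("valueDecimal")
            elif sub.get("url") == "longitude":
                lon = sub.get("valueDecimal")
        if lat is not None and lon is not None:
            return GeoPoint(float(lat), float(lon))
    return None


def _race_ethnicity(patient: Mapping[str, Any]) -> tuple[str | None, str | None]:
    race = ethnicity = None
    for ext in patient.get("extension") or []:
        url = ext.get("url")
        if url not in (US_CORE_RACE, US_CORE_ETHNICITY):
            continue
        code = None
        for sub in ext.get("extension") or []:
            if sub.get("url") in ("ombCategory", "detailed"):
                vc = sub.get("valueCoding") or {}
                code = vc.get("code") or code
            elif sub.get("url") == "text" and code is None:
                code = sub.get("valueString")
        if url == US_CORE_RACE:
            race = code
        else:
            ethnicity = code
    return race, ethnicity


def _parse_patient(res: Mapping[str, Any]) -> PatientBundle:
    pid = str(res.get("id"))
    race, ethnicity = _race_ethnicity(res)
    bundle = PatientBundle(
        patient_id=pid,
        birth_date=res.get("birthDate"),
        sex=res.get("gender"),
        race=race,
        ethnicity=ethnicity,
    )
    for addr in res.get("address") or []:
        period = addr.get("period") or {}
        bundle.addresses.append(
            Address(
                point=_extension_coordinates(addr),
                period_start=period.get("start"),
                period_end=period.get("end"),
                use=addr.get("use"),
            )
        )
    return bundle


def _parse_encounter(res: Mapping[str, Any]) -> Encounter:
    klass_raw = res.get("class") or {}
    code = klass_raw.get("code") if isinstance(klass_raw, Mapping) else klass_raw
    klass = ENCOUNTER_CLASS_MAP.get(str(code), "other")
    period = res.get("period") or {}
    codes: list[str] = []
    for rc in res.get("reasonCode") or []:
        codes.extend(_codings(rc))
    return Encounter(
        encounter_id=str(res.get("id")),
        klass=klass,
        start=str(period.get("start") or ""),
        diagnosis_codes=codes,
    )


def iter_resources(paths: Iterable[str]) -> Iterator[tuple[dict, str]]:
    """Yield (resource, context) from JSON and NDJSON files.

    A ``.ndjson`` file yields one resource per line; any other JSON file may
    hold a single resource or a FHIR Bundle (entries unwrapped).
    """
    for path in paths:
        if path.endswith(".ndjson"):
            with open(path, encoding="utf-8") as fh:
                for i, line in enumerate(fh, start=1):
                    line = line.strip()
                    if line:
                        yield json.loads(line), f"{path}:{i}"
        else:
            with open(path, encoding="utf-8") as fh:
                doc = json.load(fh)
            if isinstance(doc, Mapping) and doc.get("resourceType") == "Bundle":
                for i, entry in enumerate(doc.get("entry") or []):
                    yield entry.get("resource") or {}, f"{path}#entry{i}"
            else:
                yield doc, path


def consolidate(
    resources: Iterable[tuple[Mapping[str, Any], str] | Mapping[str, Any]],
) -> tuple[dict[str, PatientBundle], int]:
    """Group a resource stream into one bundle per patient.

    Returns ``(bundles, orphan_count)`` where *orphan_count* is the number of
    non-Patient resources whose subject references no Patient in the stream.
    The result is independent of stream order: resources may arrive before
    their Patient.

    Raises
    ------
    MalformedResourceError
        For an entry with no ``resourceType``, carrying the file/offset
        context when the stream provides one.
    """
    bundles: dict[str, PatientBundle] = {}
    pending: list[tuple[str, str, Mapping[str, Any]]] = []  # (type, pid, res)

    for item in resources:
        res, context = item if isinstance(item, tuple) else (item, "")
        if not isinstance(res, Mapping) or not res.get("resourceType"):
            raise MalformedResourceError("resource missing resourceType", context)
        rtype = res["resourceType"]
        if rtype == "Patient":
            bundles[str(res.get("id"))] = _parse_patient(res)
            continue
        pid = _reference_id(res.get("subject") or res.get("patient"))
        if pid is None:
            pending.append((rtype, "", res))
        else:
            pending.append((rtype, pid, res))

    orphans = 0
    for rtype, pid, res in pending:
        bundle = bundles.get(pid)
        if bundle is None:
            orphans += 1
            continue
        if rtype == "Encounter":
            bundle.encounters.append(_parse_encounter(res))
        elif rtype == "Condition":
            codes = _codings(res.get("code"))
            bundle.conditions.append(
                Condition(
                    code=codes[0] if codes else "",
                    onset=res.get("onsetDateTime"),
                )
            )
        elif rtype in ("MedicationRequest", "MedicationStatement"):
            codes = _codings(res.get("medicationCodeableConcept"))
            authored = res.get("authoredOn") or res.get("effectiveDateTime") or ""
            bundle.medications.append(
                Medication(code=(codes[0] if codes else "").lower(), authored=authored)
            )
        else:
            orphans += 0  # unknown referencing types are silently ignored
    for b in bundles.values():
        b.sort()
    return bundles, orphans


def consolidate_csv(path: str) -> dict[str, PatientBundle]:
    """Flat-CSV fallback for geocode fixtures: columns patient_id, lat, lon."""
    import csv

    bundles: dict[str, PatientBundle] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"]
            bundles[pid] = PatientBundle(
                patient_id=pid,
                addresses=[
                    Address(point=GeoPoint(float(row["lat"]), float(row["lon"])))
                ],
            )
    return bundles


def extract_geocode(bundle: PatientBundle, study_year: int) -> GeoPoint | None:
    """Residence coordinate for the address valid during *study_year*.

    An address qualifies when its validity period covers any part of the
    study year (open-ended periods qualify).  Among qualifying geocoded
    addresses the one with the latest period start wins; an address with no
    period at all is the fallback when no dated address qualifies.  Returns
    None when the patient has no geocoded address — the patient is flagged,
    not dropped, so the row survives to the final table with missing
    exposures.
    """
    year_start = f"{study_year:04d}-01-01"
    year_end = f"{study_year:04d}-12-31"

    qualifying: list[tuple[str, GeoPoint]] = []
    undated: list[GeoPoint] = []
    for addr in bundle.addresses:
        if addr.point is None:
            continue
        start, end = addr.period_start, addr.period_end
        if start is None and end is None:
            undated.append(addr.point)
            continue
        if (start is None or start[:10] <= year_end) and (
            end is None or end[:10] >= year_start
        ):
            qualifying.append((start or "", addr.point))
    if qualifying:
        qualifying.sort(key=lambda t: t[0])
        return qualifying[-1][1]
    if undated:
        return undated[0]
    return None


# ---------------------------------------------------------------------------
# Step-chainable I/O: bundles directory format


def write_bundles(bundles: Mapping[str, PatientBundle], out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for pid in sorted(bundles):
        path = os.path.join(out_dir, f"{pid}.json")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(bundles[pid].to_json())


def read_bundles(in_dir: str) -> dict[str, PatientBundle]:
    bundles = {}
    for name in sorted(os.listdir(in_dir)):
        if not name.endswith(".json"):
            continue
        with open(os.path.join(in_dir, name), encoding="utf-8") as fh:
            b = PatientBundle.from_json(fh.read())
        bundles[b.patient_id] = b
    return bundles


def geocode_table(
    bundles: Mapping[str, PatientBundle], study_year: int
) -> dict[str, GeoPoint | None]:
    """Per-patient geocode for one study year (None where missing)."""
    return {pid: extract_geocode(b, study_year) for pid, b in bundles.items()}
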