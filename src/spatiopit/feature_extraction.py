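"""Per-patient-per-year clinical feature vectors from consolidated bundles.

The central clinical outcome is the count of emergency-department or
inpatient encounters in a calendar year that carry a respiratory diagnosis
code; two or more such visits in a year is the operational definition of an
asthma exacerbation.  Medication and condition flags are 0/1 indicators of
any qualifying record authored (medications) or coded (conditions) in the
study year.  Code sets and demographic code maps are configuration: sites
differ in coding practice, so the shipped defaults are small and
illustrative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .fhir_ingest import PatientBundle


class FeatureConfigError(ValueError):
    pass


#: Illustrative ICD-10 respiratory codes (asthma and acute lower-respiratory
#: J-codes).  Matching is by exact code or dotted-prefix, so "J45" covers
#: "J45.901".
DEFAULT_RESPIRATORY_CODES = frozenset(
    {"J45", "J44", "J20", "J21", "J18", "J06", "J96"}
)
DEFAULT_ASTHMA_CODES = frozenset({"J45"})
DEFAULT_MEDICATIONS = ("prednisone",)

#: Source demographic codes → display labels used in the feature tables.
DEFAULT_RACE_MAP = {
    "2054-5": "AfricanAmerican",
    "2106-3": "Caucasian",
    "2028-9": "Asian",
    "1002-5": "AmericanIndian",
    "2076-8": "PacificIslander",
}
DEFAULT_SEX_MAP = {"female": "Female", "male": "Male"}
DEFAULT_ETHNICITY_MAP = {
    "2135-2": "HispanicOrLatino",
    "2186-5": "NotHispanicOrLatino",
}


@dataclass
class FeatureConfig:
    """Code sets and code maps driving feature extraction."""

    respiratory_codes: frozenset[str] = DEFAULT_RESPIRATORY_CODES
    condition_flags: dict[str, frozenset[str]] = field(
        default_factory=lambda: {"AsthmaDx": DEFAULT_ASTHMA_CODES}
    )
    medication_flags: tuple[str, ...] = DEFAULT_MEDICATIONS
    race_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_RACE_MAP))
    sex_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SEX_MAP))
    ethnicity_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_MAP)
    )


def _code_matches(code: str, code_set: Iterable[str]) -> bool:
    """Exact or dotted-prefix match: 'J45' matches 'J45' and 'J45.901'."""
    for c in code_set:
        if code == c or code.startswith(c + "."):
            return True
    return False


def _in_year(date_str: str, year: int) -> bool:
    """Half-open calendar-year window [year-01-01, year+1-01-01)."""
    return bool(date_str) and date_str[:4] == f"{year:04d}"


def count_respiratory_visits(
    bundle: PatientBundle, code_set: frozenset[str] | set[str], year: int
) -> int:
    """Count ED/inpatient encounters in *year* carrying a respiratory code.

    Each qualifying encounter counts once regardless of how many of its
    diagnosis codes match; ambulatory and other encounter classes never
    count.  An empty code set is a configuration error, not an empty count.
    """
    if not code_set:
        raise FeatureConfigError("respiratory code set must be non-empty")
    n = 0
    for enc in bundle.encounters:
        if enc.klass not in ("emergency", "inpatient"):
            continue
        if not _in_year(enc.start, year):
            continue
        if any(_code_matches(c, code_set) for c in enc.diagnosis_codes):
            n += 1
    return n


def _age_at_year_start(birth_date: str | None, year: int) -> int | None:
    if not birth_date:
        return None
    by, bm, bd = int(birth_date[:4]), int(birth_date[5:7]), int(birth_date[8:10])
    age = year - by
    if (bm, bd) > (1, 1):
        age -= 1
    return age


def to_vector(
    bundle: PatientBundle, year: int, config: FeatureConfig | None = None
) -> dict:
    """One clinical feature row for (patient, year).

    Age is computed at January 1 of the study year.  A birth date after the
    year start yields a negative age; the row is flagged invalid_age rather
    than dropped, so the anomaly is visible downstream.
    """
    config = config or FeatureConfig()
    age = _age_at_year_start(bundle.birth_date, year)
    row: dict = {
        "patient_id": bundle.patient_id,
        "year": year,
        "age_in_years": age,
        "sex": config.sex_map.get(bundle.sex or "", bundle.sex),
        "race": config.race_map.get(bundle.race or "", bundle.race),
        "ethnicity": config.ethnicity_map.get(bundle.ethnicity or "", bundle.ethnicity),
        "invalid_age": int(age is not None and age < 0),
        "total_ed_inpatient_visits": count_respiratory_visits(
            bundle, config.respiratory_codes, year
        ),
    }
    for flag, codes in config.condition_flags.items():
        row[flag] = int(
            any(
                _code_matches(c.code, codes)
                and (c.onset is None or _in_year(c.onset, year) or c.onset[:4] <= str(year))
                for c in bundle.conditions
            )
        )
    for med in config.medication_flags:
        row[med.capitalize()] = int(
            any(
                med.lower() in m.code and _in_year(m.authored, year)
                for m in bundle.medications
            )
        )
    return row


def extract_features(
    bundles: Mapping[str, PatientBundle],
    years: Iterable[int],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Clinical feature table: one row per (patient, year), no duplicates."""
    config = config or FeatureConfig()
    rows = [
        to_vector(bundles[pid], year, config)
        for year in years
        for pid in sorted(bundles)
    ]
    df = pd.DataFrame(rows)
    if not df.empty and df.duplicated(["patient_id", "year"]).any():
        raise FeatureConfigError("duplicate (patient_id, year) rows")
    return df


def write_features(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_features(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})
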