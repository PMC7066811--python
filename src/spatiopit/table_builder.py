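"""Build the de-identified, binned integrated feature table.

The final product of the pipeline: one row per patient per study year,
merging clinical features with exposure, road and socio-environmental
attributes, continuous variables binned into quantile ranges, and the table
de-identified in the Safe-Harbor style of HIPAA §164.514(b) — identifiers
and geocodes removed, dates truncated to year, ages above 89 collapsed into
a "90+" top category.  Rows are sorted on all columns before writing, so
outputs are byte-reproducible and row order cannot leak source ordering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("spatiopit")


class IntegrityError(ValueError):
    pass


class SchemaError(ValueError):
    pass


class PolicyGapError(ValueError):
    """A column matching an identifier deny-pattern escaped the policy."""


@dataclass
class BinSpec:
    """How one variable is binned: quantiles, fixed edges, or a recode map."""

    variable: str
    method: str = "quantile"  # quantile | fixed_edges | categorical_recode
    n_bins: int = 5
    edges: list[float] | None = None
    recode: dict | None = None

    def __post_init__(self) -> None:
        if self.method == "quantile" and self.n_bins < 2:
            raise ValueError("quantile binning needs n_bins >= 2")
        if self.method == "fixed_edges":
            if not self.edges or list(self.edges) != sorted(set(self.edges)):
                raise ValueError("fixed edges must be strictly increasing")


def merge_sources(
    clinical: pd.DataFrame,
    exposures: pd.DataFrame | None = None,
    roads: pd.DataFrame | None = None,
    acs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Left-join exposure, road and ACS tables onto the clinical table.

    Sources keyed by (patient_id, year) join on both; sources keyed by
    patient_id alone (roads, ACS — geometry does not vary within a study
    year) join on patient_id.  Row count is conserved: duplicate keys in any
    source are an integrity error naming the source, and patients missing
    from a source keep their row with missing values.
    """
    out = clinical.copy()
    if out.duplicated(["patient_id", "year"]).any():
        raise IntegrityError("duplicate (patient_id, year) keys in source 'clinical'")
    for name, src in (("exposures", exposures), ("roads", roads), ("acs", acs)):
        if src is None:
            continue
        keys = ["patient_id", "year"] if "year" in src.columns else ["patient_id"]
        if src.duplicated(keys).any():
            raise IntegrityError(f"duplicate {keys} keys in source {name!r}")
        out = out.merge(src, on=keys, how="left", validate="many_to_one")
    return out


def _range_labels(edges: np.ndarray) -> list[str]:
    """"(a, b]" labels from bin edges, shortest decimals keeping them unique."""
    for places in range(3, 13):
        rounded = [repr(float(round(float(e), places))) for e in edges]
        if len(set(rounded)) == len(edges):
            return [
                f"({lo}, {hi}]" for lo, hi in zip(rounded, rounded[1:])
            ]
    return [f"({float(lo)}, {float(hi)}]" for lo, hi in zip(edges, edges[1:])]


def bin_quantiles(
    values: pd.Series | Sequence[float], n_bins: int = 5
) -> tuple[pd.Series, list[float]]:
    """Quantile-bin a numeric vector into range-labelled categories.

    Edges sit at the empirical quantiles k/n_bins (linear interpolation);
    intervals are right-closed "(a, b]" with the minimum included in the
    first bin, the qcut convention.  Duplicate edges (heavy ties) are
    collapsed with a warning, yielding fewer bins.  An all-missing vector is
    returned unchanged with a warning.

    Returns (labels, edges); labels is a string series aligned with the
    input (missing stays missing).
    """
    s = pd.Series(values, dtype=float)
    if s.notna().sum() == 0:
        logger.warning("bin_quantiles: all values missing; no-op")
        return s.astype(object), []
    try:
        cats, edges = pd.qcut(s, n_bins, retbins=True, duplicates="raise")
    except ValueError:
        logger.warning(
            "bin_quantiles: duplicate quantile edges for n_bins=%d; collapsing",
            n_bins,
        )
        cats, edges = pd.qcut(s, n_bins, retbins=True, duplicates="drop")
    if len(edges) < 2:  # constant vector: one bin spanning the single value
        v = float(s.dropna().iloc[0])
        eps = max(abs(v) * 1e-3, 1e-3)
        edges = np.array([v - eps, v])
        names = _range_labels(edges)
        labels = pd.Series(
            np.where(s.notna(), names[0], None), index=s.index, dtype=object
        )
        return labels, [float(e) for e in edges]
    names = _range_labels(np.asarray(edges))
    codes = cats.cat.codes
    labels = pd.Series(
        [names[c] if c >= 0 else np.nan for c in codes], index=s.index, dtype=object
    )
    return labels, [float(e) for e in edges]


def apply_binning(
    table: pd.DataFrame, specs: Iterable[BinSpec]
) -> tuple[pd.DataFrame, dict]:
    """Bin/recode the listed variables in place; return (table, manifest).

    The manifest records method and realized edges (or recode map) per
    variable so the range labels can be interpreted downstream.
    """
    out = table.copy()
    manifest: dict[str, dict] = {}
    for spec in specs:
        if spec.variable not in out.columns:
            raise SchemaError(f"bin spec names unknown variable {spec.variable!r}")
        col = out[spec.variable]
        if spec.method == "quantile":
            labels, edges = bin_quantiles(col, spec.n_bins)
            out[spec.variable] = labels
            manifest[spec.variable] = {"method": "quantile", "edges": edges}
        elif spec.method == "fixed_edges":
            cats = pd.cut(col.astype(float), bins=spec.edges, include_lowest=True)
            names = _range_labels(np.asarray(spec.edges, dtype=float))
            out[spec.variable] = pd.Series(
                [names[c] if c >= 0 else np.nan for c in cats.cat.codes],
                index=col.index,
                dtype=object,
            )
            manifest[spec.variable] = {
                "method": "fixed_edges",
                "edges": [float(e) for e in spec.edges],
            }
        elif spec.method == "categorical_recode":
            out[spec.variable] = col.map(spec.recode or {}).where(col.notna())
            manifest[spec.variable] = {
                "method": "categorical_recode",
                "recode": dict(spec.recode or {}),
            }
        else:
            raise ValueError(f"unknown binning method {spec.method!r}")
    return out, manifest


#: Column-name patterns that must be covered by the de-identification policy.
DENY_PATTERNS = (
    r"(^|_)(patient_?id|mrn|ssn)($|_)",
    r"(^|_)(lat|latitude|lon|lng|longitude|geocode)($|_)",
    r"(^|_)(address|street|zip)($|_)",
    r"(^|_)(birth_?date|dob)($|_)",
)


@dataclass
class DeidPolicy:
    """Columns to drop, date columns to truncate, and the age column.

    ``keep`` is the declared output feature list; everything else is
    dropped, so a column added upstream cannot leak by default.
    """

    identifier_columns: tuple[str, ...] = ("patient_id",)
    geocode_columns: tuple[str, ...] = ()
    date_columns: tuple[str, ...] = ()
    age_column: str | None = "age_in_years"
    keep: tuple[str, ...] | None = None
    age_top: int = 89  # ages above this recode to "90+"
    removed: tuple[str, ...] = field(init=False, default=())

    def covered(self) -> set[str]:
        cols = set(self.identifier_columns) | set(self.geocode_columns) | set(
            self.date_columns
        )
        if self.age_column:
            cols.add(self.age_column)
        return cols


def _truncate_to_year(value) -> object:
    if pd.isna(value):
        return value
    return str(value)[:4]


def deidentify(table: pd.DataFrame, policy: DeidPolicy) -> pd.DataFrame:
    """Safe-Harbor-style de-identification of an identified wide table.

    Identifier and geocode columns are removed; date columns truncated to
    year; ages above ``age_top`` recoded to the "90+" top category (other
    ages kept as strings of the integer age); finally the schema is reduced
    to the declared keep-list when one is given.  Idempotent: applying the
    policy to its own output changes nothing.

    Raises
    ------
    PolicyGapError
        When a column name matches an identifier deny-pattern (id-like,
        coordinate-like, address-like, birth-date-like) but the policy does
        not cover or keep it — the conservative failure mode.
    """
    drop = [
        c
        for c in (*policy.identifier_columns, *policy.geocode_columns)
        if c in table.columns
    ]
    out = table.drop(columns=drop)

    declared = policy.covered() | set(policy.keep or ())
    for col in out.columns:
        if col in declared:
            continue
        for pat in DENY_PATTERNS:
            if re.search(pat, col, flags=re.IGNORECASE):
                raise PolicyGapError(
                    f"column {col!r} matches deny-pattern {pat!r} but is not "
                    "covered by the de-identification policy"
                )

    for col in policy.date_columns:
        if col in out.columns:
            out[col] = out[col].map(_truncate_to_year)

    age_col = policy.age_column
    if age_col and age_col in out.columns and out[age_col].dtype != object:
        ages = out[age_col]
        out[age_col] = np.where(
            ages.isna(),
            None,
            np.where(ages > policy.age_top, "90+", ages.astype("Int64").astype(str)),
        )
        out.loc[ages.isna(), age_col] = np.nan

    if policy.keep is not None:
        missing = [c for c in policy.keep if c not in out.columns]
        if missing:
            raise SchemaError(f"keep-list names absent columns: {missing}")
        out = out[list(policy.keep)]
    return out


def write_feature_table(
    rows: pd.DataFrame | Sequence[Mapping], path: str
) -> None:
    """Write the integrated feature table as deterministic RFC 4180 CSV.

    UTF-8, header row, missing values as empty fields, rows sorted by all
    columns — identical inputs yield byte-identical files.  A sequence of
    row mappings must share one schema.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        schemas = {tuple(r.keys()) for r in rows}
        if len(schemas) > 1:
            raise SchemaError(f"heterogeneous row schemas: {sorted(schemas)}")
        df = pd.DataFrame(list(rows))
    if len(df):
        df = df.sort_values(list(df.columns), kind="mergesort", na_position="last")
    df.to_csv(path, index=False, na_rep="", encoding="utf-8")


def write_bin_manifest(manifest: Mapping[str, dict], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(manifest), fh, sort_keys=True)
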