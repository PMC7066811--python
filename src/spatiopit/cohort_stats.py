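"""Cohort interrogation of an integrated feature table.

Mirrors the open-API style of querying de-identified feature tables: select
a cohort by conjunctive filters, cross-tabulate a binary-ized feature
against a dichotomized outcome (canonically: fewer than two vs. two or more
annual ED/inpatient respiratory visits), and report the Pearson chi-square
(no continuity correction), its nominal p-value, and the per-column
"N (p%)" presentation.

The chi-square here is authored directly from the textbook formula
``sum (O-E)^2 / E`` with expectations from the row/column marginals; only
the tail probability comes from scipy's chi-square distribution.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist


class QueryError(ValueError):
    pass


class DegenerateTableError(ValueError):
    """A 2x2 dimension with a single observed level, or a zero marginal."""


@dataclass
class ContingencyTable:
    """A 2x2 cross-tabulation with its labels and cohort size."""

    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    counts: np.ndarray  # shape (2, 2), non-negative ints
    cohort_n: int
    n_excluded_missing: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.cohort_n != int(self.counts.sum()):
            raise ValueError("cohort_n must equal the sum of counts")


_OPS = {
    "=": lambda col, v: col == v,
    "==": lambda col, v: col == v,
    "<": lambda col, v: col.astype(float) < float(v),
    ">=": lambda col, v: col.astype(float) >= float(v),
    "≥": lambda col, v: col.astype(float) >= float(v),
}


def select_cohort(
    table: pd.DataFrame, filters: Sequence[tuple[str, str, Any]]
) -> pd.DataFrame:
    """Rows satisfying every (variable, operator, value) filter.

    Operators: ``=`` (equality, works on binned labels and categories),
    ``<`` and ``>=`` (numeric).  An empty filter list selects the whole
    table; an unknown variable or operator is a query error.
    """
    mask = pd.Series(True, index=table.index)
    for variable, op, value in filters:
        if variable not in table.columns:
            raise QueryError(f"unknown variable {variable!r}")
        if op not in _OPS:
            raise QueryError(f"unknown operator {op!r}")
        mask &= _OPS[op](table[variable], value)
    return table[mask]


def _interval_left_edge(label: str) -> float | None:
    m = re.match(r"^[\(\[]\s*(-?[\d.eE+]+)\s*,", str(label))
    return float(m.group(1)) if m else None


def level_order(levels: Sequence[str]) -> list[str]:
    """Deterministic ordering of categorical levels.

    Quantile-range labels like "(7.2, 9.1]" sort by their numeric left
    edge; anything else sorts lexicographically.
    """
    levels = list(levels)
    edges = [_interval_left_edge(l) for l in levels]
    if all(e is not None for e in edges):
        return [l for _, l in sorted(zip(edges, levels))]
    return sorted(levels, key=str)


def dichotomize(
    series: pd.Series, threshold: Any, labels: tuple[str, str] | None = None
) -> tuple[pd.Series, tuple[str, str]]:
    """Split a variable at a threshold into a two-level string series.

    Numeric variables split as ``< threshold`` vs ``>= threshold``.
    Categorical variables (e.g. quantile-bin labels) split by level order:
    levels at or above the threshold level form the upper class.  Missing
    stays missing.
    """
    if pd.api.types.is_numeric_dtype(series):
        thr = float(threshold)
        labels = labels or (f"<{threshold}", f">={threshold}")
        out = pd.Series(np.where(series >= thr, labels[1], labels[0]), index=series.index)
    else:
        levels = level_order(series.dropna().unique())
        if str(threshold) not in levels:
            raise QueryError(
                f"threshold level {threshold!r} not among observed levels {levels}"
            )
        hi = set(levels[levels.index(str(threshold)):])
        labels = labels or (f"<{threshold}", f">={threshold}")
        out = pd.Series(
            np.where(series.astype(str).isin(hi), labels[1], labels[0]),
            index=series.index,
        )
    out[series.isna()] = np.nan
    return out, labels


def contingency_2x2(
    cohort: pd.DataFrame,
    feature: tuple[str, Any],
    outcome: tuple[str, Any],
) -> ContingencyTable:
    """Cross-tabulate a dichotomized feature against a dichotomized outcome.

    ``feature`` and ``outcome`` are (variable, cutpoint-or-level) pairs: a
    numeric cutpoint splits at ``< c`` / ``>= c``; for a binary categorical
    feature the level itself is the "Yes" class (No/Yes rows, as in a
    medication-use table).  Rows missing either variable are excluded and
    counted in ``n_excluded_missing``.
    """
    fvar, fcut = feature
    ovar, ocut = outcome
    for v in (fvar, ovar):
        if v not in cohort.columns:
            raise QueryError(f"unknown variable {v!r}")

    fcol, ocol = cohort[fvar], cohort[ovar]
    keep = fcol.notna() & ocol.notna()
    n_excluded = int((~keep).sum())
    fcol, ocol = fcol[keep], ocol[keep]

    if pd.api.types.is_numeric_dtype(fcol) and not _is_binary_level(fcol, fcut):
        frow, row_labels = dichotomize(fcol, fcut)
    else:
        # level semantics: the named level is the positive ("Yes") class
        if pd.api.types.is_numeric_dtype(fcol):
            match = fcol == float(fcut)
        else:
            match = fcol.astype(str) == str(fcut)
        frow = pd.Series(np.where(match, "Yes", "No"), index=fcol.index)
        row_labels = ("No", "Yes")
    ocol_d, col_labels = dichotomize(ocol, ocut)

    counts = np.zeros((2, 2), dtype=np.int64)
    for i, rl in enumerate(row_labels):
        for j, cl in enumerate(col_labels):
            counts[i, j] = int(((frow == rl) & (ocol_d == cl)).sum())
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError(
            f"single observed level in a dimension: counts={counts.tolist()}"
        )
    return ContingencyTable(
        row_labels=row_labels,
        col_labels=col_labels,
        counts=counts,
        cohort_n=int(counts.sum()),
        n_excluded_missing=n_excluded,
    )


def _is_binary_level(col: pd.Series, cut: Any) -> bool:
    """0/1 flag columns queried with level 1 are No/Yes features."""
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1} and cut in (0, 1)


def pearson_chi2_stat(counts: np.ndarray) -> float:
    """Unrounded Pearson chi-square, no continuity correction.

    ``sum (O-E)^2 / E`` with expectations from the row/column marginals.
    """
    counts = np.asarray(counts, dtype=float)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("zero marginal: chi-square undefined")
    expected = np.outer(row, col) / counts.sum()
    return float(((counts - expected) ** 2 / expected).sum())


def chi_square(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = 1.

    Returns ``(statistic rounded half-up to 4 decimals, nominal p-value)``,
    the precision published tables print.  A zero marginal leaves the
    statistic undefined.
    """
    stat = pearson_chi2_stat(t.counts)
    p = float(chi2_dist.sf(stat, df=1))
    return _round_half_up(stat, 4), p


def _round_half_up(x: float, places: int) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def column_percent(t: ContingencyTable) -> list[list[str]]:
    """Cells formatted as "N (p%)", percentages within column.

    p = 100 * cell / column sum, rounded half-up to 2 decimals, so each
    column's two percentages sum to 100.00 up to rounding.  Counts of five
    or more digits take a thousands separator (10,071 but 4536), the
    convention of published 2x2 tables.
    """
    colsum = t.counts.sum(axis=0)
    if (colsum == 0).all():
        raise DegenerateTableError("all column sums zero: percentages undefined")
    out = []
    for i in range(2):
        row = []
        for j in range(2):
            n = int(t.counts[i, j])
            n_str = f"{n:,}" if n >= 10_000 else str(n)
            if colsum[j] == 0:  # percentage undefined in an empty column
                row.append(f"{n_str} (NA)")
                continue
            pct = _round_half_up(100.0 * n / colsum[j], 2)
            row.append(f"{n_str} ({pct:.2f}%)")
        out.append(row)
    return out


def run_query(table: pd.DataFrame, query: dict) -> dict:
    """Execute a JSON-style query against a feature table.

    Schema::

        {"cohort": [[variable, op, value], ...],
         "feature": [variable, cutpoint_or_level],
         "outcome": [variable, threshold]}

    Returns the contingency table, chi-square statistic, p-value and
    formatted cells as a JSON-serializable dict.
    """
    cohort = select_cohort(table, [tuple(f) for f in query.get("cohort", [])])
    t = contingency_2x2(
        cohort, tuple(query["feature"]), tuple(query["outcome"])
    )
    stat, p = chi_square(t)
    return {
        "cohort_n": t.cohort_n,
        "n_excluded_missing": t.n_excluded_missing,
        "row_labels": list(t.row_labels),
        "col_labels": list(t.col_labels),
        "counts": t.counts.tolist(),
        "chi_square": stat,
        "p_value": p,
        "formatted": column_percent(t),
    }


def run_query_file(table_path: str, query_path: str, out_path: str | None = None) -> dict:
    table = pd.read_csv(table_path)
    with open(query_path, encoding="utf-8") as fh:
        query = json.load(fh)
    result = run_query(table, query)
    if out_path:
        with open(out_path, "w", encoding="utf-8") as fh:
            json.dump(result, fh, indent=2)
    return result
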