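# Methods

This note records the models, conventions and deliberate design choices
behind `spatiopit`, in the order the pipeline runs.

## Pipeline execution model

A pipeline is a list of named step instances with a `dependsOn` relation;
validation requires unique names, known plugin functions, defined
dependencies and acyclicity. Execution order is Kahn's algorithm with ties
broken by declaration order, so runs are reproducible. Steps communicate
only through the file paths named in their arguments; given that contract,
any topological-order execution (serial or parallel) yields identical
outputs, and the implementation runs serially.

Failure policy: a step whose plugin raises is reported *failed* with the
error message; its transitive dependants are reported *skipped
(upstream_failure)*; siblings not downstream continue. A step with
`skip: true` is reported *skipped (configured_skip)* and its dependants
still run, on the assumption that its outputs exist from an earlier run —
this is what makes partial re-execution work: re-running with previously
succeeded steps skipped leaves all outputs byte-identical. The report's
three lists always partition the configured step names.

Year templating: `expand_years` instantiates a step template once per study
year by substituting a `{{year}}` token in the name and (recursively) the
arguments, replacing the role a general configuration language would play.

## Clinical ingestion and features

FHIR R4 JSON is the reference dialect (Patient, Encounter, Condition,
MedicationRequest/Statement, consumed from NDJSON or per-resource files).
Consolidation is order-independent and conserves resources: every
non-Patient resource either attaches to its referenced patient or is
counted as an orphan. Encounter classes map ActCode codes onto
{emergency, inpatient, ambulatory, other}; diagnosis codes are read from
`reasonCode`.

Residence geocodes come from the standard FHIR address geolocation
extension. When several addresses qualify, the one whose validity period
covers the study year wins, latest period start breaking ties; an undated
geocoded address is the fallback. A patient with no geocode is flagged,
not dropped — the row survives to the final table with missing exposures,
so attrition is visible rather than silent.

Features are per patient per calendar year (half-open interval at year
boundaries). The central outcome variable counts emergency or inpatient
encounters carrying a respiratory diagnosis code, one per encounter no
matter how many codes match; two or more such visits in a year is the
operational asthma-exacerbation definition used by the cohort statistics.
Code sets are configuration: defaults ship a small illustrative set of
ICD-10 J-codes (dotted-prefix matching, so `J45` covers `J45.901`) and the
medication string "prednisone", because real deployments substitute
site-specific code sets. Age is computed at January 1 of the study year; a
birth date after year start flags the row `invalid_age` instead of
discarding it.

## Exposure attachment

Pollutant input is a long-format table (cell, coordinates, ISO timestamp,
pollutant, value) at hourly, daily or annual native resolution. The
per-patient-year summary is the mean and maximum of daily means. Hourly
days require at least 75 % of the 24 hours (the standard completeness rule
in air-quality practice; configurable); incomplete days are treated as
missing. Daily input skips the within-day stage; annual input passes
through with avg = max = the annual value, so already-aggregated statistics
are never re-aggregated.

Cell assignment is nearest center by haversine distance on WGS84, ties to
the lexicographically smallest cell id, with a coverage radius defaulting
to 1.5× the grid spacing (median nearest-neighbor center distance); beyond
it the patient is out of coverage and gets missing exposures. Nearest-
neighbor assignment, not interpolation, keeps the estimate checkable
against an exhaustive-scan oracle and is defensible at the grid spacings
involved; bilinear or geostatistical interpolation is out of scope.

## Road and census joins

Nearest-road distance is computed in a local equirectangular projection
centered on the query point (x = R·cos φ₀·Δλ, y = R·Δφ): at the sub-10-km
distances relevant to roadway-exposure studies the divergence from full
geodesics is far below the geocoding error, and the planar formulation is
directly testable against a dense-sampling oracle. Point-to-polyline
distance follows the standard rule (perpendicular foot within the edge,
else nearest vertex, via shapely); ties go to the smallest segment id. Two
road sources — census-style geometry with a road class, highway-style with
traffic counts — run through the same core and differ only in carried
attributes.

Census assignment is even-odd point-in-polygon; a boundary point belongs to
the containing unit earliest in unit-id order, making shared edges of a
polygon partition deterministic. The attribute join is a unique-key lookup;
duplicate unit ids are an input-integrity error, and the version-2 table
must carry the `ur` (urban/rural) field. Unit granularity (block vs block
group) is treated as opaque: any polygon partition with a keyed attribute
table works. Geometry I/O is GeoJSON; a binary-shapefile reader is not
included, keeping fixtures plain text.

## Integrated table: merge, binning, de-identification

Sources left-join onto the clinical table — on (patient, year) where the
source is yearly, on patient alone for geometry-derived sources — so the
row count is conserved and duplicate keys in any source are an error naming
the source.

Continuous variables are quantile-binned with `qcut` semantics: edges at
linear-interpolation empirical quantiles, right-closed intervals with the
minimum included in the first bin, labels rendered as `(a, b]` with the
fewest decimals (≥ 3) that keep edges distinct. Heavy ties collapse
duplicate edges with a logged warning; a constant vector yields a single
bin. Default 5 bins for continuous exposures. A per-year manifest
(`bins_<year>.yaml`) records method and realized edges so range labels stay
interpretable downstream.

De-identification is the Safe-Harbor subset relevant to this schema:
identifier and geocode columns removed, date columns truncated to year,
ages above 89 recoded to a "90+" top category, and — when a keep-list is
given — the output schema reduced to exactly the declared features. A
deny-pattern scan (id-like, coordinate-like, address-like, birth-date-like
column names) raises on any column the policy does not cover, so a column
added upstream fails loudly rather than leaking. De-identification is
idempotent. Rows are sorted on all columns before writing, making outputs
byte-reproducible and removing row-order re-identification. Small-cell
suppression (complementary to Safe Harbor) is *not* applied; consumers
exposing tables publicly should consider it. Expert-determination
de-identification is out of scope.

## Cohort statistics

2×2 association tables dichotomize the outcome at a threshold (numeric
`< c` / `≥ c`; ordered bin labels split by their numeric left edge) and the
feature either the same way or — for binary flags and categorical levels —
as level = "Yes" vs rest. Rows missing either variable are excluded and
counted. The chi-square is Pearson's Σ(O−E)²/E with marginal expectations,
df = 1, **no Yates continuity correction** — the uncorrected statistic is
what reproduces published panels from their printed counts exactly, and the
correction is anyway inappropriate at these cell sizes. Statistics are
rounded half-up to 4 decimals and percentages to 2, matching the
presentation convention of published tables; p-values come from the
chi-square survival function. Only 2×2 tables are supported; r×c tables
and any multivariable modelling are out of scope.

## Synthetic study conditions

The generators emulate the four real source families at small scale. The
default spec places 500 patients uniformly over a 1°×1° bounding box with a
4×4 pollutant grid and one study year; the north-east quadrant is the
high-exposure region (PM2.5 mean 12 vs 7 μg/m³, daily noise σ = 2 — values
in the range of typical annual US averages). Patients inside the region
exacerbate (≥ 2 annual ED/inpatient respiratory visits) with probability
0.3, others 0.1; prednisone is ordered for 17 % of exacerbating and 10 %
of non-exacerbating patients, the rough usage split of published
prednisone-by-exacerbation panels. Roads form a lattice along the census
grid lines, census polygons tile the box exactly, and the ACS-style table
marks high-region units urban. One global seed feeds fixed per-generator
substreams, so outputs are byte-identical under a repeated seed and adding
a generator never perturbs the others.

The end-to-end study (tests and acceptance script) uses 2000 patients per
seed, effect 0.1 → 0.4, 20 seeds with the effect planted and 20 without —
sizes chosen so the whole study runs in minutes while the planted effect is
overwhelming (median X² ≈ 150) and the null calibration is informative.
Over 20 null seeds the expected number of nominal rejections is 1, so the
calibration check accepts up to 3.

What the generators do *not* emulate: realistic ICD coding practice,
pollutant spatial autocorrelation beyond a two-level step, patient
mobility, address changes within a study year, missing-data mechanisms
other than geography. Passing tests therefore demonstrate the mechanics of
integration, binning, de-identification and inference — not that any
specific epidemiological estimate transfers to real data.

## Numerical conventions

- Great-circle distances use the IUGG mean Earth radius 6 371 008.8 m.
- Quantile edges use linear interpolation (`numpy`/`pandas` default),
  recorded to full precision in the bin manifest even when labels round.
- Chi-square oracle agreement is checked against exact rational arithmetic
  (`fractions.Fraction`) at 1e-9 on the unrounded statistic.
- All CSV output is UTF-8 with a header row and empty fields for missing.
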