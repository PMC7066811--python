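"""Built-in plugins: the step vocabulary a pipeline config can invoke.

Each plugin is a callable ``fn(arguments, global_settings)`` reading and
writing only the paths named in its arguments, so steps chain through the
filesystem exactly as the config declares.  Argument keys:

``FHIR``
    input (dir of .json/.ndjson FHIR resources), output (bundle dir).
``ToVector``
    input (bundle dir), output (CSV), year.
``EnvData``
    grid (long CSV), resolution, input (bundle dir), output (CSV), year,
    optional coverage_radius_m.
``NearestRoad`` / ``NearestRoad2``
    roads (GeoJSON), input (bundle dir), output (CSV), year, optional
    prefix (defaults road/hwy — same geometry core, different attributes).
``ACS`` / ``ACS2``
    census (GeoJSON), acs (CSV), input (bundle dir), output (CSV), year;
    the v2 plugin requires and carries the ``ur`` urban/rural field.
``CSVTable``
    clinical, exposures, roads (list of CSVs), acs, output_dir, year,
    optional bin_variables / n_bins / keep.
``NOOP``
    nothing; a placeholder step.
"""

from __future__ import annotations

import glob
import os
from typing import Any

import pandas as pd

from . import env_exposures, fhir_ingest, spatial_join, table_builder
from .feature_extraction import FeatureConfig, extract_features

Args = dict[str, Any]


def _bundles(args: Args) -> dict[str, fhir_ingest.PatientBundle]:
    return fhir_ingest.read_bundles(args["input"])


def _geocodes(args: Args) -> dict[str, fhir_ingest.GeoPoint | None]:
    return fhir_ingest.geocode_table(_bundles(args), int(args["year"]))


def plugin_noop(args: Args, global_settings: Args) -> None:
    return None


def plugin_fhir(args: Args, global_settings: Args) -> None:
    paths = sorted(
        p
        for p in glob.glob(os.path.join(args["input"], "*"))
        if p.endswith((".json", ".ndjson"))
    )
    bundles, orphans = fhir_ingest.consolidate(fhir_ingest.iter_resources(paths))
    fhir_ingest.write_bundles(bundles, args["output"])
    if orphans:
        import logging

        logging.getLogger("spatiopit").warning(
            "FHIR consolidation: %d orphan resources excluded", orphans
        )


def plugin_to_vector(args: Args, global_settings: Args) -> None:
    df = extract_features(_bundles(args), [int(args["year"])], FeatureConfig())
    df.to_csv(args["output"], index=False)


def plugin_env_data(args: Args, global_settings: Args) -> None:
    grid = env_exposures.ExposureGrid.from_csv(
        args["grid"], args.get("resolution", "daily")
    )
    year = int(args["year"])
    bundles = _bundles(args)
    features = pd.DataFrame(
        {"patient_id": sorted(bundles), "year": year}
    )
    out = env_exposures.attach_exposures(
        features,
        fhir_ingest.geocode_table(bundles, year),
        grid,
        coverage_radius_m=args.get("coverage_radius_m"),
    )
    out.to_csv(args["output"], index=False)


def _plugin_nearest_road(args: Args, default_prefix: str) -> None:
    segments = spatial_join.read_roads_geojson(args["roads"])
    table = spatial_join.nearest_road_table(
        _geocodes(args), segments, prefix=args.get("prefix", default_prefix)
    )
    table.to_csv(args["output"], index=False)


def plugin_nearest_road(args: Args, global_settings: Args) -> None:
    _plugin_nearest_road(args, "road")


def plugin_nearest_road2(args: Args, global_settings: Args) -> None:
    _plugin_nearest_road(args, "hwy")


def _plugin_acs(args: Args, version: int) -> None:
    units = spatial_join.read_census_geojson(args["census"])
    acs = pd.read_csv(args["acs"], dtype={"unit_id": str})
    table = spatial_join.acs_table(_geocodes(args), units, acs, version=version)
    table.to_csv(args["output"], index=False)


def plugin_acs(args: Args, global_settings: Args) -> None:
    _plugin_acs(args, 1)


def plugin_acs2(args: Args, global_settings: Args) -> None:
    _plugin_acs(args, 2)


#: Continuous variables binned by default when present in the merged table.
DEFAULT_BIN_VARIABLES = (
    "pm25_avg_daily",
    "pm25_max_daily",
    "road_distance_m",
    "hwy_distance_m",
    "hwy_aadt",
    "est_household_income",
    "residential_density",
)


def plugin_csv_table(args: Args, global_settings: Args) -> None:
    year = int(args["year"])
    clinical = pd.read_csv(args["clinical"], dtype={"patient_id": str})
    exposures = (
        pd.read_csv(args["exposures"], dtype={"patient_id": str})
        if args.get("exposures")
        else None
    )
    roads = None
    for path in args.get("roads") or []:
        df = pd.read_csv(path, dtype={"patient_id": str})
        roads = df if roads is None else roads.merge(df, on="patient_id", how="outer")
    acs = (
        pd.read_csv(args["acs"], dtype={"patient_id": str, "census_unit": str})
        if args.get("acs")
        else None
    )

    merged = table_builder.merge_sources(clinical, exposures, roads, acs)

    bin_vars = args.get("bin_variables")
    if bin_vars is None:
        bin_vars = [v for v in DEFAULT_BIN_VARIABLES if v in merged.columns]
    specs = [
        table_builder.BinSpec(v, n_bins=int(args.get("n_bins", 5))) for v in bin_vars
    ]
    binned, manifest = table_builder.apply_binning(merged, specs)

    policy = table_builder.DeidPolicy(
        identifier_columns=("patient_id",),
        geocode_columns=("census_unit", "road_segment_id", "hwy_segment_id"),
        keep=tuple(args["keep"]) if args.get("keep") else None,
    )
    deid = table_builder.deidentify(binned, policy)

    out_dir = args["output_dir"]
    os.makedirs(out_dir, exist_ok=True)
    table_builder.write_feature_table(
        deid, os.path.join(out_dir, f"icees_features_{year}.csv")
    )
    table_builder.write_bin_manifest(
        manifest, os.path.join(out_dir, f"bins_{year}.yaml")
    )


DEFAULT_REGISTRY = {
    "NOOP": plugin_noop,
    "FHIR": plugin_fhir,
    "ToVector": plugin_to_vector,
    "EnvData": plugin_env_data,
    "NearestRoad": plugin_nearest_road,
    "NearestRoad2": plugin_nearest_road2,
    "ACS": plugin_acs,
    "ACS2": plugin_acs2,
    "CSVTable": plugin_csv_table,
}


def standard_config(
    fixture_manifest: dict, year: int, work_dir: str, out_dir: str
) -> "PipelineConfig":
    """The canonical single-year pipeline over one set of generated inputs.

    FHIR consolidation feeds feature extraction, exposure attachment, two
    nearest-road passes and the v2 census/ACS join; the table step merges
    everything into the de-identified feature table.  Returned as a
    validated :class:`~spatiopit.pipeline_core.PipelineConfig`, the same
    object a YAML document with these steps would load to.
    """
    from .pipeline_core import PipelineConfig, StepInstance

    bundles = os.path.join(work_dir, "bundles")
    clinical = os.path.join(work_dir, f"clinical_{year}.csv")
    exposures = os.path.join(work_dir, f"exposures_{year}.csv")
    tiger = os.path.join(work_dir, f"roads_tiger_{year}.csv")
    hpms = os.path.join(work_dir, f"roads_hpms_{year}.csv")
    acs = os.path.join(work_dir, f"acs_{year}.csv")
    steps = [
        StepInstance(
            "consolidate",
            "FHIR",
            {"input": fixture_manifest["fhir_dir"], "output": bundles},
        ),
        StepInstance(
            "features",
            "ToVector",
            {"input": bundles, "output": clinical, "year": year},
            depends_on=["consolidate"],
        ),
        StepInstance(
            "exposures",
            "EnvData",
            {
                "grid": fixture_manifest["grid"],
                "resolution": fixture_manifest.get("resolution", "daily"),
                "input": bundles,
                "output": exposures,
                "year": year,
            },
            depends_on=["consolidate"],
        ),
        StepInstance(
            "nearest_road",
            "NearestRoad",
            {
                "roads": fixture_manifest["roads_tiger"],
                "input": bundles,
                "output": tiger,
                "year": year,
            },
            depends_on=["consolidate"],
        ),
        StepInstance(
            "nearest_highway",
            "NearestRoad2",
            {
                "roads": fixture_manifest["roads_hpms"],
                "input": bundles,
                "output": hpms,
                "year": year,
            },
            depends_on=["consolidate"],
        ),
        StepInstance(
            "acs_join",
            "ACS2",
            {
                "census": fixture_manifest["census"],
                "acs": fixture_manifest["acs"],
                "input": bundles,
                "output": acs,
                "year": year,
            },
            depends_on=["consolidate"],
        ),
        StepInstance(
            "feature_table",
            "CSVTable",
            {
                "clinical": clinical,
                "exposures": exposures,
                "roads": [tiger, hpms],
                "acs": acs,
                "output_dir": out_dir,
                "year": year,
            },
            depends_on=["features", "exposures", "nearest_road", "nearest_highway", "acs_join"],
        ),
    ]
    config = PipelineConfig(steps=steps)
    config.validate()
    return config
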