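"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import pytest

from spatiopit import FixtureSpec, generate_all
from spatiopit.pipeline_core import run_pipeline
from spatiopit.plugins import DEFAULT_REGISTRY, standard_config


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(seed=7, n_patients=120)


@pytest.fixture(scope="session")
def fixture_set(small_spec, tmp_path_factory):
    """Generated inputs for all four source families plus planting truth."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = generate_all(small_spec, str(out))
    return manifest


@pytest.fixture(scope="session")
def pipeline_run(fixture_set, tmp_path_factory):
    """One complete pipeline execution over the small fixture set."""
    work = tmp_path_factory.mktemp("work")
    out = tmp_path_factory.mktemp("tables")
    config = standard_config(fixture_set, 2010, str(work), str(out))
    report = run_pipeline(config, DEFAULT_REGISTRY)
    assert not report.failed, f"pipeline failures: {report.failed}"
    return {
        "report": report,
        "config": config,
        "work": str(work),
        "table": str(out / "icees_features_2010.csv"),
        "bins": str(out / "bins_2010.yaml"),
        "manifest": fixture_set,
    }
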