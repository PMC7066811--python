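"""Declarative ETL pipeline: YAML configuration, DAG resolution, dispatch.

A pipeline is a list of named step instances.  Each step names a plugin
(``function``), a plugin-specific argument map, the steps it depends on, and
an optional ``skip`` flag that allows partial re-execution: a step whose
outputs already exist on disk can be switched off without editing the rest of
the workflow.  Execution is sequential in dependency order; the contract that
every step reads only the paths named in its arguments and writes only its
declared outputs means any topological order (serial or parallel) yields
identical results.

Running a pipeline produces an :class:`ExecutionReport` partitioning the
configured steps into succeeded, skipped (with a reason) and failed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

import yaml

logger = logging.getLogger("spatiopit")

#: Token substituted by :func:`expand_years` in step names and arguments.
YEAR_PLACEHOLDER = "{{year}}"

#: Plugin identifiers accepted in a step's ``step.function`` field.  The
#: registry passed to :func:`run_pipeline` must cover every function a config
#: uses; this set is the validation vocabulary.
KNOWN_FUNCTIONS = {
    "FHIR",
    "ToVector",
    "EnvData",
    "CSVTable",
    "ACS",
    "ACS2",
    "NearestRoad",
    "NearestRoad2",
    "NOOP",
}


class ConfigError(ValueError):
    """Raised for a malformed or inconsistent pipeline configuration."""


class CycleError(ConfigError):
    """Raised when the dependsOn relation contains a cycle."""

    def __init__(self, members: list[str]):
        self.members = members
        super().__init__(f"dependency cycle among steps: {members}")


@dataclass
class StepInstance:
    """One configured invocation of a plugin.

    Parameters mirror the YAML step schema: ``name``, ``dependsOn``, ``skip``
    and ``step: {function, arguments}``.
    """

    name: str
    function: str
    arguments: dict[str, Any] = field(default_factory=dict)
    depends_on: list[str] = field(default_factory=list)
    skip: bool = False

    def validate(self) -> None:
        if not self.name:
            raise ConfigError("step name must be non-empty")
        if self.function not in KNOWN_FUNCTIONS:
            raise ConfigError(
                f"step {self.name!r}: unknown function {self.function!r}; "
                f"known: {sorted(KNOWN_FUNCTIONS)}"
            )


@dataclass
class PipelineConfig:
    steps: list[StepInstance] = field(default_factory=list)
    global_settings: dict[str, Any] = field(default_factory=dict)

    def step_names(self) -> list[str]:
        return [s.name for s in self.steps]

    def validate(self) -> None:
        names = self.step_names()
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate step names: {sorted(dupes)}")
        for s in self.steps:
            s.validate()
            for dep in s.depends_on:
                if dep not in names:
                    raise ConfigError(
                        f"step {s.name!r} dependsOn undefined step {dep!r}"
                    )
        resolve_execution_order(self, _validated=True)  # raises CycleError


@dataclass
class ExecutionReport:
    """Outcome of one pipeline run.

    ``succeeded``, ``skipped`` and ``failed`` partition the configured step
    names: every step appears in exactly one list.  Skip reasons are
    ``configured_skip`` (the step's skip flag was set) or ``upstream_failure``
    (a transitive dependency failed).
    """

    succeeded: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    failed: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "succeeded": list(self.succeeded),
            "skipped": [{"name": n, "reason": r} for n, r in self.skipped],
            "failed": [{"name": n, "error": e} for n, e in self.failed],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def all_names(self) -> set[str]:
        return (
            set(self.succeeded)
            | {n for n, _ in self.skipped}
            | {n for n, _ in self.failed}
        )


def _parse_step(raw: Mapping[str, Any]) -> StepInstance:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"step entry must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"name", "dependsOn", "skip", "step"}
    if unknown:
        raise ConfigError(f"unknown step keys: {sorted(unknown)}")
    try:
        name = raw["name"]
        step = raw["step"]
        function = step["function"]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"step missing required field: {exc}") from exc
    arguments = step.get("arguments") or {}
    if not isinstance(arguments, dict):
        raise ConfigError(f"step {name!r}: arguments must be a mapping")
    skip = raw.get("skip", False)
    if isinstance(skip, str):  # Table-2 convention: skip is "true"/"false"
        skip = skip.strip().lower() == "true"
    return StepInstance(
        name=str(name),
        function=str(function),
        arguments=dict(arguments),
        depends_on=[str(d) for d in (raw.get("dependsOn") or [])],
        skip=bool(skip),
    )


def load_config(yaml_text: str) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration.

    The document holds a ``steps:`` list (each entry with keys ``name``,
    ``dependsOn``, ``skip``, ``step: {function, arguments}``) and an optional
    ``global:`` mapping.  ``skip`` defaults to false when absent.

    Raises
    ------
    ConfigError
        On malformed YAML, unknown plugin names, undefined dependencies or
        dependency cycles.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigError("top-level YAML document must be a mapping")
    raw_steps = doc.get("steps", [])
    if raw_steps is None:
        raw_steps = []
    if not isinstance(raw_steps, list):
        raise ConfigError("'steps' must be a list")
    config = PipelineConfig(
        steps=[_parse_step(r) for r in raw_steps],
        global_settings=dict(doc.get("global") or {}),
    )
    config.validate()
    return config


def load_config_file(path: str) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        return load_config(fh.read())


def resolve_execution_order(
    config: PipelineConfig, _validated: bool = False
) -> list[str]:
    """Topological order of step names respecting every dependsOn edge.

    Ties are broken by declaration order, so the result is deterministic:
    Kahn's algorithm with a ready-queue kept sorted by position in the config.

    Raises
    ------
    CycleError
        Listing the members of (a strongly connected portion of) the cycle.
    """
    if not _validated:
        names = config.step_names()
        for s in config.steps:
            for d in s.depends_on:
                if d not in names:
                    raise ConfigError(
                        f"step {s.name!r} dependsOn undefined step {d!r}"
                    )
    position = {s.name: i for i, s in enumerate(config.steps)}
    indeg = {s.name: len(set(s.depends_on)) for s in config.steps}
    dependants: dict[str, list[str]] = {s.name: [] for s in config.steps}
    for s in config.steps:
        for d in set(s.depends_on):
            dependants[d].append(s.name)

    ready = sorted((n for n, k in indeg.items() if k == 0), key=position.__getitem__)
    order: list[str] = []
    while ready:
        n = ready.pop(0)
        order.append(n)
        changed = False
        for m in dependants[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                ready.append(m)
                changed = True
        if changed:
            ready.sort(key=position.__getitem__)
    if len(order) != len(config.steps):
        raise CycleError(sorted(set(indeg) - set(order), key=position.__getitem__))
    return order


PluginFn = Callable[[dict[str, Any], dict[str, Any]], None]


def run_pipeline(
    config: PipelineConfig,
    registry: Mapping[str, PluginFn],
    only: str | None = None,
) -> ExecutionReport:
    """Execute a validated pipeline against a plugin registry.

    Steps run sequentially in the order of :func:`resolve_execution_order`.
    A step with ``skip=true`` is not executed (its outputs are presumed to
    exist from an earlier run) and is reported ``skipped(configured_skip)``;
    its dependants still run.  A plugin that raises marks its step failed
    with the error message, and every step downstream of the failure is
    reported ``skipped(upstream_failure)``; siblings not downstream continue.

    Parameters
    ----------
    registry
        Maps plugin function names to callables ``fn(arguments, global_settings)``.
    only
        If given, execute just this step (its skip flag ignored); all other
        steps are reported skipped(configured_skip).
    """
    config.validate()
    order = resolve_execution_order(config, _validated=True)
    by_name = {s.name: s for s in config.steps}
    for s in config.steps:
        if s.function not in registry:
            raise ConfigError(
                f"step {s.name!r}: no plugin registered for {s.function!r}"
            )

    report = ExecutionReport()
    failed_or_downstream: set[str] = set()
    for name in order:
        step = by_name[name]
        if any(d in failed_or_downstream for d in step.depends_on):
            failed_or_downstream.add(name)
            report.skipped.append((name, "upstream_failure"))
            continue
        if only is not None and name != only:
            report.skipped.append((name, "configured_skip"))
            continue
        if step.skip and only is None:
            report.skipped.append((name, "configured_skip"))
            continue
        logger.info("running step %s (%s)", name, step.function)
        try:
            registry[step.function](step.arguments, config.global_settings)
        except Exception as exc:  # noqa: BLE001 - report, don't crash the run
            logger.error("step %s failed: %s", name, exc)
            report.failed.append((name, str(exc)))
            failed_or_downstream.add(name)
        else:
            report.succeeded.append(name)
    return report


def _substitute(value: Any, year: str) -> Any:
    if isinstance(value, str):
        return value.replace(YEAR_PLACEHOLDER, year)
    if isinstance(value, Mapping):
        return {k: _substitute(v, year) for k, v in value.items()}
    if isinstance(value, list):
        return [_substitute(v, year) for v in value]
    return value


def expand_years(
    template: StepInstance, years: Iterable[str | int]
) -> list[StepInstance]:
    """Instantiate a year-templated step once per study year.

    The template carries the ``{{year}}`` placeholder in its name and
    (recursively) in its arguments; each output step has the placeholder
    replaced by one year, so the names stay unique.  An empty year list
    yields an empty list.
    """
    out = []
    for y in years:
        y = str(y)
        out.append(
            StepInstance(
                name=_substitute(template.name, y),
                function=template.function,
                arguments=_substitute(template.arguments, y),
                depends_on=[_substitute(d, y) for d in template.depends_on],
                skip=template.skip,
            )
        )
    return out
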