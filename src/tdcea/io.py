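"""Configuration files, report writers, and run manifests.

The model is configured from a single JSON document::

    {
      "cohort":     {"deployment_size": {"value": ..., "low": ..., "high": ..., "dist": "triangular"}, ...},
      "parameters": {"p_no_mh": {...}, ...}
    }

The shipped default configuration (``tdcea/data/default_config.json``)
reproduces the base-case estimates exactly; regional adaptations (e.g.
different antibiotic-resistance environments) are expressed as user-edited
copies of it.  Probabilities are stored as fractions in [0, 1].

CSV reports round for display; every CSV has a full-precision JSON sidecar,
and every written report references a :class:`RunManifest` recording the
command, configuration hash, seed and package version so it can be
regenerated.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .parameters import (
    COHORT_NAMES,
    PARAMETER_NAMES,
    ModelParameter,
    ParameterSet,
    default_parameter_set,
    validate,
)
from .scenarios import ComparisonResult, ScenarioSpec
from .tree import EvaluationResult
from .util import round_half_up

__all__ = [
    "ConfigError",
    "ConfigParseError",
    "ConfigSchemaError",
    "ConfigValidationError",
    "RunManifest",
    "default_config_path",
    "load_config",
    "loads_config",
    "parameter_set_to_dict",
    "read_scenario_report",
    "save_config",
    "write_scenario_table",
]

_FIELD_KEYS = {"value", "low", "high", "dist"}


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigParseError(ConfigError):
    """The file is not well-formed JSON."""


class ConfigSchemaError(ConfigError):
    """The JSON document does not match the expected structure."""


class ConfigValidationError(ConfigError):
    """The parsed parameter set violates model invariants."""


def default_config_path() -> Path:
    """Path of the shipped base-case configuration."""
    return Path(str(resources.files("tdcea").joinpath("data/default_config.json")))


def _param_to_dict(p: ModelParameter) -> dict:
    return {"value": p.value, "low": p.low, "high": p.high, "dist": p.dist}


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    return {
        "cohort": {name: _param_to_dict(ps.cohort_params[name]) for name in COHORT_NAMES},
        "parameters": {name: _param_to_dict(ps.params[name]) for name in PARAMETER_NAMES},
    }


def save_config(ps: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(parameter_set_to_dict(ps), indent=1) + "\n")


def _parse_param(name: str, raw: dict, template: ModelParameter) -> ModelParameter:
    if not isinstance(raw, dict):
        raise ConfigSchemaError(f"parameter {name!r}: expected an object, got {type(raw).__name__}")
    unknown = set(raw) - _FIELD_KEYS
    if unknown:
        raise ConfigSchemaError(f"parameter {name!r}: unknown key(s) {sorted(unknown)}")
    missing = _FIELD_KEYS - set(raw)
    if missing:
        raise ConfigSchemaError(f"parameter {name!r}: missing key(s) {sorted(missing)}")
    try:
        return ModelParameter(
            name=name,
            role=template.role,
            value=float(raw["value"]),
            low=float(raw["low"]),
            high=float(raw["high"]),
            dist=str(raw["dist"]),
            group=template.group,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigSchemaError(f"parameter {name!r}: {exc}") from exc


def loads_config(text: str) -> ParameterSet:
    """Parse a configuration document from a JSON string."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigSchemaError("top level must be a JSON object")
    unknown = set(doc) - {"cohort", "parameters"}
    if unknown:
        raise ConfigSchemaError(f"unknown top-level key(s) {sorted(unknown)}")
    for section in ("cohort", "parameters"):
        if section not in doc:
            raise ConfigSchemaError(f"missing section {section!r}")

    template = default_parameter_set()
    expected = {"cohort": set(COHORT_NAMES), "parameters": set(PARAMETER_NAMES)}
    for section, names in expected.items():
        got = set(doc[section])
        if got - names:
            raise ConfigSchemaError(f"{section}: unknown parameter(s) {sorted(got - names)}")
        if names - got:
            raise ConfigSchemaError(f"{section}: missing parameter(s) {sorted(names - got)}")

    params = {
        name: _parse_param(name, doc["parameters"][name], template.params[name])
        for name in PARAMETER_NAMES
    }
    cohort = {
        name: _parse_param(name, doc["cohort"][name], template.cohort_params[name])
        for name in COHORT_NAMES
    }
    ps = ParameterSet(params=params, cohort_params=cohort)
    report = validate(ps)
    if not report.ok:
        raise ConfigValidationError(f"configuration violates model invariants:\n{report}")
    return ps


def load_config(path: str | Path) -> ParameterSet:
    """Load and validate a configuration file."""
    return loads_config(Path(path).read_text())


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one command invocation, written next to its reports."""

    command: str
    config_path: str | None
    config_sha256: str | None
    seed: int | None
    timestamp: str
    version: str

    @classmethod
    def create(cls, command: str, config_path: str | Path | None, seed: int | None) -> "RunManifest":
        from . import __version__

        digest = None
        if config_path is not None:
            digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        return cls(
            command=command,
            config_path=str(config_path) if config_path is not None else None,
            config_sha256=digest,
            seed=seed,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
            version=__version__,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


_METRIC_ROWS = (
    "annual_episodes",
    "total_cost",
    "cost_difference",
    "ddl_per_year",
    "ddl_averted",
    "cost_ratio",
    "cer",
)


def _column(ev: EvaluationResult, cmp: ComparisonResult | None) -> dict:
    col = {
        "annual_episodes": ev.episodes,
        "total_cost": ev.total_cost,
        "ddl_per_year": ev.total_ddl,
        "cost_ratio": ev.cost_ratio,
        "cost_difference": math.nan,
        "ddl_averted": math.nan,
        "cer": math.nan,
    }
    if cmp is not None:
        col["cost_difference"] = cmp.cost_difference
        col["ddl_averted"] = cmp.ddl_averted
        col["cer"] = cmp.cer
    return col


def write_scenario_table(
    results: list[tuple[ScenarioSpec, EvaluationResult, ComparisonResult | None]],
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the management-scenario outcome table.

    One column per scenario (base case first, by convention), one row per
    metric.  CSV cells are rounded to integer dollars/days for display
    (currency as integer dollars); the JSON sidecar carries full precision.
    Returns the *unrounded* table.
    """
    if not results:
        raise ValueError("no results to write")
    table = pd.DataFrame(
        {spec.key: _column(ev, cmp) for spec, ev, cmp in results},
        index=list(_METRIC_ROWS),
    )
    display = table.map(lambda x: "" if (isinstance(x, float) and math.isnan(x)) else round_half_up(x))
    display.to_csv(csv_path, index_label="metric")
    if json_path is not None:
        payload = {
            key: {m: (None if (isinstance(x, float) and math.isnan(x)) else x) for m, x in table[key].items()}
            for key in table.columns
        }
        Path(json_path).write_text(json.dumps(payload, indent=1) + "\n")
    return table


def read_scenario_report(json_path: str | Path) -> dict:
    """Read back a full-precision scenario JSON report (None → NaN)."""
    doc = json.loads(Path(json_path).read_text())
    return {
        key: {m: (math.nan if x is None else x) for m, x in col.items()}
        for key, col in doc.items()
    }
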