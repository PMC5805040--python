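"""Model parameters for the deployment travelers'-diarrhea cost-of-illness model.

The model is driven by a fixed vocabulary of named quantities: branch
probabilities of the eight-leaf care-pathway decision tree, per-episode
treatment costs (USD), per-episode duty days lost (DDL), and three cohort
scalars (deployment size, deployment duration in months, monthly incidence
of travelers' diarrhea).  Each parameter carries a point estimate, a low/high
range, and the probability distribution used by the probabilistic
sensitivity analysis (triangular or range-as-95%-CI normal).

Probabilities that share a branch point form *sibling groups* that must sum
to one:

* ``disposition`` — the four top-level medical dispositions of an episode
  (no provider treatment, outpatient provider treatment, hospitalization,
  medical evacuation);
* ``outpatient`` — suboptimal care / optimal care / bed rest, conditional on
  outpatient treatment;
* ``self_management`` — run its course / self-treatment success /
  self-treatment failure, conditional on no provider treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "DistributionSpec",
    "ModelParameter",
    "CohortSpec",
    "ParameterSet",
    "ValidationReport",
    "GroupCheck",
    "PARAMETER_NAMES",
    "COHORT_NAMES",
    "PROBABILITY_GROUPS",
    "default_parameter_set",
    "build_distribution",
    "validate",
]

#: tolerance for sibling-group sums in :func:`validate`
GROUP_SUM_TOL = 1e-6

#: the range (low, high) is read as a central 95% interval, so sd = range / 3.92
NORMAL_RANGE_Z = 2 * 1.96

PROBABILITY_GROUPS: dict[str, tuple[str, ...]] = {
    "disposition": ("p_no_mh", "p_mh_treatment", "p_hospitalization", "p_medevac"),
    "outpatient": ("p_suboptimal", "p_optimal", "p_bedrest"),
    "self_management": ("p_run_course", "p_self_success", "p_self_failure"),
}

COHORT_NAMES: tuple[str, ...] = ("deployment_size", "duration_months", "monthly_incidence")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one model parameter.

    ``triangular`` uses (a, m, b) = (low, mode, high); ``normal`` uses mean
    ``m`` and standard deviation ``sd`` truncated to ``support``; ``point``
    is the degenerate distribution at ``m``.
    """

    kind: str  # "triangular" | "normal" | "point"
    a: float
    m: float
    b: float
    sd: float | None = None
    support: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.kind not in ("triangular", "normal", "point"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "triangular" and not (self.a <= self.m <= self.b):
            raise ValueError(f"triangular requires a <= m <= b, got ({self.a}, {self.m}, {self.b})")
        if self.kind == "normal" and (self.sd is None or self.sd < 0):
            raise ValueError("normal distribution requires sd >= 0")
        if self.kind == "point" and not (self.a == self.m == self.b):
            raise ValueError("point distribution requires a = m = b")

    def mean(self) -> float:
        """Theoretical mean (ignoring truncation for the normal case)."""
        if self.kind == "triangular":
            return (self.a + self.m + self.b) / 3.0
        return self.m

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution; scalar when ``size`` is None.

        Normal draws falling outside ``support`` are redrawn (at most 100
        rounds) so costs, durations and probabilities stay in their
        physically meaningful ranges.
        """
        if self.kind == "point":
            return self.m if size is None else np.full(size, self.m)
        if self.kind == "triangular":
            if self.a == self.b:  # degenerate triangle
                return self.a if size is None else np.full(size, self.a)
            return rng.triangular(self.a, self.m, self.b, size=size)
        # truncated normal via rejection
        n = 1 if size is None else size
        out = rng.normal(self.m, self.sd, size=n)
        lo, hi = self.support
        for _ in range(100):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                break
            out[bad] = rng.normal(self.m, self.sd, size=int(bad.sum()))
        else:
            raise RuntimeError(
                f"could not draw a normal({self.m}, {self.sd}) value inside {self.support} "
                "after 100 rounds"
            )
        return float(out[0]) if size is None else out


@dataclass(frozen=True)
class ModelParameter:
    """One named model quantity with its point estimate, range and distribution."""

    name: str
    role: str  # "probability" | "cost_usd" | "ddl_days" | "cohort"
    value: float
    low: float
    high: float
    dist: str = "triangular"  # "triangular" | "normal" | "point"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("probability", "cost_usd", "ddl_days", "cohort"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.dist not in ("triangular", "normal", "point"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")

    @property
    def is_point(self) -> bool:
        return self.low == self.high

    def with_value(self, value: float) -> "ModelParameter":
        """Copy with a new point estimate (bounds untouched)."""
        return replace(self, value=value)

    def as_point(self, value: float | None = None) -> "ModelParameter":
        """Collapse to a point mass at ``value`` (default: current estimate)."""
        v = self.value if value is None else value
        return replace(self, value=v, low=v, high=v, dist="point")


def build_distribution(p: ModelParameter) -> DistributionSpec:
    """Sampling distribution for a parameter.

    * ``low == high`` (or ``dist == "point"``) → point mass at the estimate.
    * triangular → (a, m, b) = (low, value, high).
    * normal → mean = value, sd = (high − low) / 3.92, i.e. the printed range
      is read as a central 95% interval; draws are truncated to [0, ∞) for
      costs and durations and to [0, 1] for probabilities (including the
      monthly incidence, which is a per-person-month probability).
    """
    fraction = p.role == "probability" or (p.role == "cohort" and p.high <= 1.0)
    support = (0.0, 1.0) if fraction else (0.0, math.inf)
    if p.is_point or p.dist == "point":
        return DistributionSpec("point", p.value, p.value, p.value, support=support)
    if p.dist == "triangular":
        return DistributionSpec("triangular", p.low, p.value, p.high, support=support)
    if p.dist == "normal":
        sd = (p.high - p.low) / NORMAL_RANGE_Z
        return DistributionSpec("normal", p.low, p.value, p.high, sd=sd, support=support)
    raise ValueError(f"unknown distribution kind {p.dist!r}")


@dataclass(frozen=True)
class CohortSpec:
    """The deployed cohort: size, mean deployment length and TD incidence."""

    deployment_size: float
    duration_months: float
    monthly_incidence: float

    def __post_init__(self) -> None:
        for name in ("deployment_size", "duration_months", "monthly_incidence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.monthly_incidence > 1:
            raise ValueError("monthly_incidence is a probability and cannot exceed 1")


@dataclass(frozen=True)
class ParameterSet:
    """A complete parameterization of the model: 24 tree parameters + 3 cohort scalars."""

    params: Mapping[str, ModelParameter]
    cohort_params: Mapping[str, ModelParameter]

    def __post_init__(self) -> None:
        missing = set(PARAMETER_NAMES) - set(self.params)
        extra = set(self.params) - set(PARAMETER_NAMES)
        if missing or extra:
            raise ValueError(f"parameter names mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        if set(self.cohort_params) != set(COHORT_NAMES):
            raise ValueError(f"cohort parameter names must be {COHORT_NAMES}")

    def __getitem__(self, name: str) -> ModelParameter:
        if name in self.params:
            return self.params[name]
        return self.cohort_params[name]

    def __iter__(self) -> Iterator[ModelParameter]:
        yield from self.cohort_params.values()
        yield from self.params.values()

    def value(self, name: str) -> float:
        return self[name].value

    def values(self) -> dict[str, float]:
        """Point estimates of every parameter (tree and cohort), keyed by name."""
        return {p.name: p.value for p in self}

    @property
    def cohort(self) -> CohortSpec:
        return CohortSpec(
            deployment_size=self.cohort_params["deployment_size"].value,
            duration_months=self.cohort_params["duration_months"].value,
            monthly_incidence=self.cohort_params["monthly_incidence"].value,
        )

    def replace_params(self, **updates: ModelParameter) -> "ParameterSet":
        """Copy with some parameters replaced (tree or cohort, matched by name)."""
        params = dict(self.params)
        cohort = dict(self.cohort_params)
        for name, p in updates.items():
            if p.name != name:
                raise ValueError(f"keyword {name!r} does not match parameter name {p.name!r}")
            if name in params:
                params[name] = p
            elif name in cohort:
                cohort[name] = p
            else:
                raise KeyError(name)
        return ParameterSet(params=params, cohort_params=cohort)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Copy with one point estimate changed, bounds untouched."""
        return self.replace_params(**{name: self[name].with_value(value)})

    def with_point(self, name: str, value: float) -> "ParameterSet":
        """Copy with one parameter fixed as a point mass at ``value``."""
        return self.replace_params(**{name: self[name].as_point(value)})

    def as_point_masses(self) -> "ParameterSet":
        """Copy with every distribution collapsed to its point estimate."""
        return ParameterSet(
            params={k: p.as_point() for k, p in self.params.items()},
            cohort_params={k: p.as_point() for k, p in self.cohort_params.items()},
        )


@dataclass(frozen=True)
class GroupCheck:
    group: str
    members: tuple[str, ...]
    total: float
    ok: bool


@dataclass(frozen=True)
class ValidationReport:
    group_checks: tuple[GroupCheck, ...]
    bound_violations: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return all(g.ok for g in self.group_checks) and not self.bound_violations

    def __str__(self) -> str:
        lines = []
        for g in self.group_checks:
            status = "ok" if g.ok else "FAIL"
            lines.append(f"group {g.group}: sum={g.total:.9f} [{status}]")
        lines.extend(f"bound violation: {v}" for v in self.bound_violations)
        return "\n".join(lines)


def validate(ps: ParameterSet, tol: float = GROUP_SUM_TOL) -> ValidationReport:
    """Check sibling-group sums and per-parameter bound invariants.

    Returns a report object rather than raising, so callers can surface every
    problem at once (e.g. when rejecting a user-edited configuration).
    """
    checks = []
    for group, members in PROBABILITY_GROUPS.items():
        total = sum(ps.value(m) for m in members)
        checks.append(GroupCheck(group, members, total, abs(total - 1.0) <= tol))

    violations = []
    for p in ps:
        if not (p.low <= p.value <= p.high):
            violations.append(f"{p.name}: value {p.value} outside [{p.low}, {p.high}]")
        if p.role == "probability" and not (0.0 <= p.low and p.high <= 1.0):
            violations.append(f"{p.name}: probability bounds [{p.low}, {p.high}] outside [0, 1]")
        if p.role in ("cost_usd", "ddl_days") and p.low < 0:
            violations.append(f"{p.name}: negative lower bound {p.low}")
        if p.role == "cohort" and p.low <= 0:
            violations.append(f"{p.name}: cohort bound must be strictly positive")
    return ValidationReport(tuple(checks), tuple(violations))


# (name, role, value, low, high, dist, group) — base-case estimates with low/high
# ranges and PSA distributions for every model quantity.
_BASE_TABLE: tuple[tuple[str, str, float, float, float, str, str | None], ...] = (
    ("p_no_mh",            "probability", 0.6907, 0.68,   0.87,   "triangular", "disposition"),
    ("p_run_course",       "probability", 0.60,   0.30,   0.90,   "triangular", "self_management"),
    ("p_self_success",     "probability", 0.32,   0.16,   0.48,   "triangular", "self_management"),
    ("p_self_failure",     "probability", 0.08,   0.04,   0.12,   "triangular", "self_management"),
    ("p_medevac",          "probability", 0.0003, 0.0002, 0.0004, "triangular", "disposition"),
    ("p_mh_treatment",     "probability", 0.30,   0.13,   0.42,   "triangular", "disposition"),
    ("p_suboptimal",       "probability", 0.278,  0.16,   0.51,   "triangular", "outpatient"),
    ("p_optimal",          "probability", 0.351,  0.27,   0.57,   "triangular", "outpatient"),
    ("p_bedrest",          "probability", 0.371,  0.13,   0.47,   "triangular", "outpatient"),
    ("p_hospitalization",  "probability", 0.009,  0.003,  0.024,  "triangular", "disposition"),
    ("cost_medevac",       "cost_usd",    16938,  13550,  20326,  "triangular", None),
    ("cost_hospital",      "cost_usd",    2907,   2325,   3488,   "triangular", None),
    ("cost_bedrest",       "cost_usd",    104,    84,     125,    "triangular", None),
    ("cost_suboptimal",    "cost_usd",    70,     56,     84,     "triangular", None),
    ("cost_optimal",       "cost_usd",    82,     65,     98,     "triangular", None),
    ("cost_self_failure",  "cost_usd",    27,     22,     32,     "triangular", None),
    ("ddl_suboptimal",     "ddl_days",    0.7,    0.4,    1.0,    "normal",     None),
    ("ddl_optimal",        "ddl_days",    0.37,   0.23,   0.52,   "normal",     None),
    ("ddl_bedrest",        "ddl_days",    1.6,    1.0,    2.0,    "triangular", None),
    ("ddl_hospital",       "ddl_days",    1.7,    1.0,    3.0,    "triangular", None),
    ("ddl_medevac",        "ddl_days",    7,      3,      10,     "triangular", None),
    ("ddl_run_course",     "ddl_days",    0.37,   0.23,   0.52,   "normal",     None),
    ("ddl_self_success",   "ddl_days",    0.18,   0.11,   0.25,   "normal",     None),
    ("ddl_self_failure",   "ddl_days",    0.48,   0.29,   0.67,   "normal",     None),
)

_COHORT_TABLE: tuple[tuple[str, float, float, float, str], ...] = (
    ("deployment_size",   50000, 35000, 80000, "triangular"),
    ("duration_months",   3.5,   1.0,   12.0,  "triangular"),
    ("monthly_incidence", 0.289, 0.162, 0.416, "normal"),
)

PARAMETER_NAMES: tuple[str, ...] = tuple(row[0] for row in _BASE_TABLE)


def default_parameter_set() -> ParameterSet:
    """The base-case parameterization: a 50,000-person, 3.5-month deployment
    with 28.9% monthly TD incidence and current care-seeking/treatment patterns."""
    params = {
        name: ModelParameter(name, role, value, low, high, dist, group)
        for name, role, value, low, high, dist, group in _BASE_TABLE
    }
    cohort = {
        name: ModelParameter(name, "cohort", value, low, high, dist)
        for name, value, low, high, dist in _COHORT_TABLE
    }
    return ParameterSet(params=params, cohort_params=cohort)
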