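"""Management-strategy scenarios and base-case comparison.

Three hypothetical strategies are modeled against the base case, each at
three implementation levels:

* **HCSB** (health-care-seeking behavior): more service members seek provider
  care, and earlier (pretreatment duration drops from 1.5 days to ~8 hours).
  The probability of outpatient MH treatment rises from 30% to 40/55/70% with
  a complement reduction of the no-treatment arm; optimal-care DDL drops to
  0.31 and bed-rest DDL to 1.41.
* **OPB** (optimized provider behavior): providers shift toward single-dose
  antibiotic + loperamide.  The optimal:suboptimal prescribing ratio rises
  from the base 55.8% to 65/75/85%; optimal care costs $30 (blended
  medic/treatment-facility cost), optimal DDL 0.33, bed-rest DDL 0.88
  (12-hour instead of 24-hour bed rest).
* **combination**: both, applied level-for-level (40%/65%, 55%/75%, 70%/85%),
  with optimal DDL 0.11 (8-hour pretreatment + 15-hour time to last unformed
  stool) and bed-rest DDL 0.69.

The scenario DDL overrides are *reconciled* values: where published accounts
of this model disagree internally, the values used here are the ones that
exactly reproduce the published annual-DDL outcomes at every level (see
docs/methods.md).  In particular, the combination bed-rest DDL of 0.69 is
the OPB value 0.88 minus the 0.19-day pretreatment reduction of HCSB
(1.60 − 1.41).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet
from .tree import EvaluationResult, evaluate
from .util import round_half_up

__all__ = [
    "ScenarioSpec",
    "ComparisonResult",
    "ScenarioError",
    "BASE_SCENARIO",
    "HCSB_LEVELS",
    "OPB_LEVELS",
    "standard_scenarios",
    "opb_split",
    "apply_scenario",
    "apply_overrides",
    "compare",
    "run_scenario",
]

HCSB_LEVELS: tuple[float, ...] = (0.40, 0.55, 0.70)
OPB_LEVELS: tuple[float, ...] = (0.65, 0.75, 0.85)

#: DDL (and cost) overrides per strategy, applied as fixed point values
_OVERRIDES: dict[str, dict[str, float]] = {
    "hcsb": {"ddl_optimal": 0.31, "ddl_bedrest": 1.41},
    "opb": {"cost_optimal": 30.0, "ddl_optimal": 0.33, "ddl_bedrest": 0.88},
    "combination": {"cost_optimal": 30.0, "ddl_optimal": 0.11, "ddl_bedrest": 0.69},
}


class ScenarioError(ValueError):
    """A scenario transformation produced an invalid probability."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One strategy at one implementation level."""

    strategy: str  # "base" | "hcsb" | "opb" | "combination"
    hcsb_level: float | None = None  # target P(MH treatment | illness)
    opb_level: float | None = None  # target optimal:(optimal+suboptimal) ratio

    def __post_init__(self) -> None:
        if self.strategy not in ("base", "hcsb", "opb", "combination"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        needs_hcsb = self.strategy in ("hcsb", "combination")
        needs_opb = self.strategy in ("opb", "combination")
        if needs_hcsb != (self.hcsb_level is not None):
            raise ValueError(f"{self.strategy}: hcsb_level {'required' if needs_hcsb else 'not allowed'}")
        if needs_opb != (self.opb_level is not None):
            raise ValueError(f"{self.strategy}: opb_level {'required' if needs_opb else 'not allowed'}")
        for lvl in (self.hcsb_level, self.opb_level):
            if lvl is not None and not (0.0 < lvl < 1.0):
                raise ValueError(f"implementation level {lvl} outside (0, 1)")

    @property
    def key(self) -> str:
        """Stable identifier used as a report column name, e.g. ``hcsb_55``."""
        if self.strategy == "base":
            return "base"
        parts = [self.strategy]
        if self.hcsb_level is not None:
            parts.append(f"{self.hcsb_level * 100:.0f}")
        if self.opb_level is not None:
            parts.append(f"{self.opb_level * 100:.0f}")
        return "_".join(parts)

    @property
    def label(self) -> str:
        if self.strategy == "base":
            return "Base case"
        levels = [f"{l * 100:.0f}%" for l in (self.hcsb_level, self.opb_level) if l is not None]
        return f"{self.strategy.upper() if self.strategy != 'combination' else 'Combination'} {'/'.join(levels)}"


BASE_SCENARIO = ScenarioSpec("base")


def standard_scenarios(
    hcsb_levels: tuple[float, ...] = HCSB_LEVELS,
    opb_levels: tuple[float, ...] = OPB_LEVELS,
) -> tuple[ScenarioSpec, ...]:
    """The nine standard scenarios: three per strategy, combination paired level-for-level."""
    out = [ScenarioSpec("hcsb", hcsb_level=h) for h in hcsb_levels]
    out += [ScenarioSpec("opb", opb_level=o) for o in opb_levels]
    out += [
        ScenarioSpec("combination", hcsb_level=h, opb_level=o)
        for h, o in zip(hcsb_levels, opb_levels)
    ]
    return tuple(out)


def opb_split(level: float, pool: float = 0.629):
    """Split the therapeutic outpatient pool into (suboptimal, optimal) shares.

    ``pool`` is the outpatient probability not allocated to bed rest
    (1 − 0.371 = 0.629 in the base case).  The optimal share is
    ``level × pool`` rounded half-up to 3 decimals — the published one-decimal
    percentage convention, without which the published annual-DDL outcomes
    are not reproducible — and suboptimal takes the remainder.
    """
    p_optimal = round_half_up(np.asarray(level, dtype=float) * pool, 3)
    p_suboptimal = pool - p_optimal
    if isinstance(level, float) and not isinstance(pool, np.ndarray):
        return float(p_suboptimal), float(p_optimal)
    return p_suboptimal, p_optimal


def apply_overrides(values: dict, s: ScenarioSpec) -> dict:
    """Scenario transformation on a name→value mapping (scalars or arrays).

    This is the single code path used both for deterministic evaluation and
    for the Monte Carlo engine (where overrides are applied *after* sampling,
    as fixed point values).
    """
    if s.strategy == "base":
        return dict(values)
    v = dict(values)
    if s.hcsb_level is not None:
        transfer = s.hcsb_level - v["p_mh_treatment"]
        new_no_mh = v["p_no_mh"] - transfer
        if np.any(np.asarray(new_no_mh) < 0) or np.any(np.asarray(new_no_mh) > 1):
            raise ScenarioError(
                f"HCSB level {s.hcsb_level} pushes P(no MH treatment) outside [0, 1]"
            )
        v["p_mh_treatment"] = s.hcsb_level if np.isscalar(v["p_mh_treatment"]) else np.full_like(
            np.asarray(v["p_mh_treatment"], dtype=float), s.hcsb_level
        )
        v["p_no_mh"] = new_no_mh
    if s.opb_level is not None:
        pool = v["p_suboptimal"] + v["p_optimal"]
        p_sub, p_opt = opb_split(s.opb_level, pool)
        v["p_suboptimal"], v["p_optimal"] = p_sub, p_opt
    for name, value in _OVERRIDES[s.strategy].items():
        v[name] = value if np.isscalar(v[name]) else np.full_like(np.asarray(v[name], dtype=float), value)
    return v


def apply_scenario(ps: ParameterSet, s: ScenarioSpec) -> ParameterSet:
    """Return a new parameter set with the scenario's overrides applied.

    Overridden parameters become point masses: scenario targets are policy
    levers, not uncertain quantities, so the probabilistic sensitivity
    analysis does not sample them.  Everything else (cohort, hospitalization
    and medevac parameters, non-targeted costs/DDL) is untouched.
    """
    if s.strategy == "base":
        return ps
    before = ps.values()
    after = apply_overrides(before, s)
    out = ps
    for name, value in after.items():
        if value != before[name]:
            out = out.with_point(name, float(value))
    # p_mh_treatment may already equal the target level; still pin it for hcsb
    if s.hcsb_level is not None:
        out = out.with_point("p_mh_treatment", s.hcsb_level)
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """A scenario evaluated against the base case.

    ``ddl_averted`` is base − scenario (negative values are duty days
    *gained*, i.e. the scenario performs worse).  The cost-effectiveness
    ratio is cost_difference / |ddl_averted|: positive cost with DDL gained
    reports as positive $/DDL-gained, cost savings with DDL averted as a
    negative $/DDL-averted.  NaN when the scenario changes nothing.
    """

    scenario: ScenarioSpec
    cost_difference: float
    ddl_averted: float

    @property
    def cer(self) -> float:
        if self.ddl_averted == 0:
            return math.nan
        return self.cost_difference / abs(self.ddl_averted)


def compare(base: EvaluationResult, scen: EvaluationResult, scenario: ScenarioSpec = BASE_SCENARIO) -> ComparisonResult:
    """Compare a scenario evaluation to the base case (same cohort)."""
    return ComparisonResult(
        scenario=scenario,
        cost_difference=scen.total_cost - base.total_cost,
        ddl_averted=base.total_ddl - scen.total_ddl,
    )


def run_scenario(ps: ParameterSet, s: ScenarioSpec) -> tuple[EvaluationResult, ComparisonResult]:
    """Evaluate one scenario against the base case built from ``ps``."""
    base_eval = evaluate(ps)
    scen_eval = evaluate(apply_scenario(ps, s))
    return scen_eval, compare(base_eval, scen_eval, s)
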