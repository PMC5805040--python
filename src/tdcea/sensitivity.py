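"""One-way (tornado) and probabilistic (Monte Carlo) sensitivity analysis.

The tornado sweep moves one parameter at a time to its low and then its high
estimate and records the base-case cost ratio (USD per duty day lost) at each
end.  Sibling probabilities are deliberately *not* renormalized during the
sweep — the branch mass may transiently differ from 1 — matching the behavior
of conventional spreadsheet one-way sensitivity tools on this class of model.

The probabilistic sensitivity analysis (PSA) draws every parameter from its
distribution, rescales each sibling probability group proportionally so it
sums to one, evaluates the base case and the scenario *on the same draw*
(common random numbers), and summarizes DDL-averted and the
cost-effectiveness ratio over the iterations by median and interquartile
range.  Scenario overrides are applied after sampling as fixed point values:
they are policy targets, not uncertain inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    PROBABILITY_GROUPS,
    ModelParameter,
    ParameterSet,
    build_distribution,
    validate,
)
from .scenarios import BASE_SCENARIO, ScenarioSpec, apply_overrides
from .tree import evaluate, expectation_from_values

__all__ = [
    "TornadoEntry",
    "PSASummary",
    "tornado",
    "sample_parameter_set",
    "sample_values",
    "run_psa",
]


@dataclass(frozen=True)
class TornadoEntry:
    """One-way swing of the base-case cost ratio for a single parameter."""

    parameter: str
    low_output: float
    high_output: float

    @property
    def swing(self) -> float:
        return abs(self.high_output - self.low_output)


def _cost_ratio(ps: ParameterSet) -> float:
    return evaluate(ps, check=False).cost_ratio


def tornado(ps: ParameterSet, top_k: int = 10) -> list[TornadoEntry]:
    """Rank parameters by their one-way swing of the base cost ratio.

    Every tree and cohort parameter is swept.  (Cohort scalars rescale cost
    and DDL identically, so their swing on the ratio is zero; they simply
    rank last.)  Ties are broken alphabetically for deterministic output.
    """
    report = validate(ps)
    if not report.ok:
        raise ValueError(f"invalid parameter set:\n{report}")
    entries = []
    for p in ps:
        low = _cost_ratio(ps.with_value(p.name, p.low))
        high = _cost_ratio(ps.with_value(p.name, p.high))
        entries.append(TornadoEntry(p.name, low, high))
    entries.sort(key=lambda e: (-e.swing, e.parameter))
    return entries[:top_k]


def sample_values(
    ps: ParameterSet,
    rng: np.random.Generator,
    size: int | None = None,
    sample_cohort: bool = True,
) -> dict:
    """Draw parameter values (scalars, or arrays of length ``size``).

    Each parameter is drawn independently from its distribution; each sibling
    probability group is then rescaled proportionally so percentages sum to
    100%.  Cohort scalars are drawn from their own distributions when
    ``sample_cohort`` is true, else held at their point estimates.
    """
    v: dict = {}
    for p in ps.cohort_params.values():
        if sample_cohort:
            v[p.name] = build_distribution(p).sample(rng, size=size)
        else:
            v[p.name] = p.value if size is None else np.full(size, p.value)
    for p in ps.params.values():
        v[p.name] = build_distribution(p).sample(rng, size=size)
    for members in PROBABILITY_GROUPS.values():
        total = sum(v[m] for m in members)
        for m in members:
            v[m] = v[m] / total
    return v


def sample_parameter_set(
    ps: ParameterSet,
    rng: np.random.Generator,
    sample_cohort: bool = True,
) -> ParameterSet:
    """One random realization of the parameter space, as a point-mass set.

    The returned set always passes :func:`~tdcea.parameters.validate`: every
    parameter is pinned at its draw and the probability groups sum to one by
    construction.
    """
    v = sample_values(ps, rng, size=None, sample_cohort=sample_cohort)
    params = {name: ps.params[name].as_point(float(v[name])) for name in ps.params}
    cohort = {name: ps.cohort_params[name].as_point(float(v[name])) for name in ps.cohort_params}
    return ParameterSet(params=params, cohort_params=cohort)


@dataclass(frozen=True)
class PSASummary:
    """Median/IQR summary of a scenario's PSA output metrics."""

    scenario: ScenarioSpec
    n_iterations: int
    seed: int | None
    ddl_averted_median: float
    ddl_averted_iqr: tuple[float, float]
    cer_median: float
    cer_iqr: tuple[float, float]
    n_cer_excluded: int  # iterations with ddl_averted == 0, excluded from CER
    sample_cohort: bool = False
    draws: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.key,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "sample_cohort": self.sample_cohort,
            "ddl_averted": {
                "median": self.ddl_averted_median,
                "q1": self.ddl_averted_iqr[0],
                "q3": self.ddl_averted_iqr[1],
            },
            "cer": {
                "median": self.cer_median,
                "q1": self.cer_iqr[0],
                "q3": self.cer_iqr[1],
                "n_excluded": self.n_cer_excluded,
            },
        }


def run_psa(
    base_ps: ParameterSet,
    s: ScenarioSpec = BASE_SCENARIO,
    n: int = 3000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_cohort: bool = False,
    keep_draws: bool = False,
) -> PSASummary:
    """Monte Carlo PSA of one scenario against the base case.

    Per iteration the base case and the scenario are evaluated on the same
    sampled parameter set; DDL-averted and the CER are recorded.  Quartiles
    use numpy's linear interpolation between order statistics, so summaries
    are bit-reproducible given a seed.  Iterations with exactly zero
    DDL-averted contribute to the DDL summaries but are excluded from the
    CER summaries (their count is reported).

    The cohort multiplier (size × months × incidence) is held at its point
    estimate by default; pass ``sample_cohort=True`` to draw it as well.
    """
    report = validate(base_ps)
    if not report.ok:
        raise ValueError(f"invalid parameter set:\n{report}")
    if rng is None:
        rng = np.random.default_rng(seed)
    v = sample_values(base_ps, rng, size=n, sample_cohort=sample_cohort)
    episodes = v["deployment_size"] * v["duration_months"] * v["monthly_incidence"]

    base_cost, base_ddl = expectation_from_values(v)
    sv = apply_overrides(v, s)
    scen_cost, scen_ddl = expectation_from_values(sv)

    ddl_averted = (base_ddl - scen_ddl) * episodes
    cost_difference = (scen_cost - base_cost) * episodes
    nonzero = ddl_averted != 0
    cer = np.full(n, np.nan)
    cer[nonzero] = cost_difference[nonzero] / np.abs(ddl_averted[nonzero])

    q1a, meda, q3a = np.quantile(ddl_averted, [0.25, 0.5, 0.75])
    if nonzero.any():
        q1c, medc, q3c = np.quantile(cer[nonzero], [0.25, 0.5, 0.75])
    else:
        q1c = medc = q3c = np.nan

    draws = None
    if keep_draws:
        draws = pd.DataFrame(
            {
                "iteration": np.arange(n),
                "episodes": episodes if np.ndim(episodes) else np.full(n, episodes),
                "ddl_averted": ddl_averted,
                "cost_difference": cost_difference,
                "cer": cer,
            }
        )
    return PSASummary(
        scenario=s,
        n_iterations=n,
        seed=seed,
        ddl_averted_median=float(meda),
        ddl_averted_iqr=(float(q1a), float(q3a)),
        cer_median=float(medc),
        cer_iqr=(float(q1c), float(q3c)),
        n_cer_excluded=int(n - nonzero.sum()),
        sample_cohort=sample_cohort,
        draws=draws,
    )
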