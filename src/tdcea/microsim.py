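"""Per-episode microsimulator: synthetic cohorts and a brute-force oracle.

Every deterministic expectation in the model has a sampling counterpart:
draw each episode's terminal pathway from the categorical distribution of
leaf probabilities and accrue that leaf's cost and duty days lost.  By the
law of large numbers the simulated per-episode means converge to the tree
expectations, which makes the simulator an independent check on the
deterministic engine (and a generator of realistic episode-level data).

Episodes are independent draws — the model has no transmission dynamics or
time structure — and costs/DDL are deterministic given the pathway, since
the model carries no within-pathway variance.

`random_parameter_set` generates arbitrary *valid* parameterizations
(uniform probability simplexes, log-uniform costs, uniform DDL) for
property-based testing of the engine across the whole parameter space,
not just the base case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, PROBABILITY_GROUPS, default_parameter_set, validate
from .tree import DecisionTree, EvaluationResult, LEAF_LABELS, build_tree

__all__ = [
    "EpisodeRecord",
    "SimulatedCohort",
    "simulate_cohort",
    "summarize",
    "random_parameter_set",
]


@dataclass(frozen=True)
class EpisodeRecord:
    episode_id: int
    pathway: str
    cost: float
    ddl: float


@dataclass(frozen=True)
class SimulatedCohort:
    """Episode-level records plus the provenance needed to regenerate them."""

    records: pd.DataFrame = field(compare=False)  # episode_id, pathway, cost, ddl
    seed: int | None
    source_parameters: ParameterSet

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> EpisodeRecord:
        row = self.records.iloc[i]
        return EpisodeRecord(int(row.episode_id), str(row.pathway), float(row.cost), float(row.ddl))


def simulate_cohort(
    ps: ParameterSet,
    n_episodes: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Simulate ``n_episodes`` independent TD episodes through the tree."""
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    report = validate(ps)
    if not report.ok:
        raise ValueError(f"invalid parameter set:\n{report}")
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = build_tree(ps)
    probs = np.array([leaf.path_probability for leaf in tree.leaves])
    probs = probs / probs.sum()  # remove float residue from the unit-mass invariant
    costs = np.array([leaf.unit_cost for leaf in tree.leaves])
    ddls = np.array([leaf.unit_ddl for leaf in tree.leaves])

    idx = rng.choice(len(tree.leaves), size=n_episodes, p=probs)
    records = pd.DataFrame(
        {
            "episode_id": np.arange(n_episodes),
            "pathway": pd.Categorical.from_codes(idx, categories=list(LEAF_LABELS)),
            "cost": costs[idx],
            "ddl": ddls[idx],
        }
    )
    return SimulatedCohort(records=records, seed=seed, source_parameters=ps)


def summarize(c: SimulatedCohort) -> EvaluationResult:
    """Cohort totals of a simulated cohort, in the same shape as the
    deterministic engine's output."""
    if len(c) == 0:
        raise ValueError("cannot summarize an empty cohort")
    total_cost = float(c.records["cost"].sum())
    total_ddl = float(c.records["ddl"].sum())
    return EvaluationResult(episodes=float(len(c)), total_cost=total_cost, total_ddl=total_ddl)


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A random valid parameterization for property-based testing.

    Sibling probability groups are drawn from the uniform simplex
    (flat Dirichlet), costs log-uniform on [1, 20000] USD, DDL uniform on
    [0, 10] days, and cohort scalars uniform within their base-case ranges.
    All parameters are point masses, so the set trivially validates.
    """
    template = default_parameter_set()
    values: dict[str, float] = {}
    for members in PROBABILITY_GROUPS.values():
        simplex = rng.dirichlet(np.ones(len(members)))
        for name, v in zip(members, simplex):
            values[name] = float(v)
    for p in template.params.values():
        if p.role == "cost_usd":
            values[p.name] = float(np.exp(rng.uniform(np.log(1.0), np.log(20000.0))))
        elif p.role == "ddl_days":
            values[p.name] = float(rng.uniform(0.0, 10.0))
    cohort_values = {
        name: float(rng.uniform(p.low, p.high))
        for name, p in template.cohort_params.items()
    }
    params = {name: template.params[name].as_point(values[name]) for name in template.params}
    cohort = {name: template.cohort_params[name].as_point(cohort_values[name]) for name in template.cohort_params}
    return ParameterSet(params=params, cohort_params=cohort)
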