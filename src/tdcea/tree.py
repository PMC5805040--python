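"""Eight-leaf decision tree: deterministic expected burden and cost.

Every travelers'-diarrhea episode follows exactly one of eight terminal care
pathways.  Four top-level dispositions — outpatient treatment by a military
healthcare (MH) provider, no MH treatment, hospitalization, medical
evacuation — with the outpatient branch splitting into suboptimal care /
optimal care / bed rest and the no-treatment branch into run-its-course /
self-treatment success / self-treatment failure.  Each leaf carries a unit
cost (USD, cost to the military health system) and a unit effectiveness loss
(duty days lost, DDL).

The cohort burden is a plain expectation: annual episodes × Σ pᵢ·costᵢ and
× Σ pᵢ·DDLᵢ.  The self-treatment-failure leaf is terminal (own cost $27 and
DDL 0.48); it does not cascade into a second outpatient encounter.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import CohortSpec, ParameterSet, validate

__all__ = [
    "LEAF_LABELS",
    "TerminalOutcome",
    "DecisionTree",
    "EvaluationResult",
    "build_tree",
    "annual_episodes",
    "expected_per_episode",
    "evaluate",
    "expectation_from_values",
]

#: (label, top-level branch probability, conditional probability | None,
#:  cost parameter | None (None → $0), DDL parameter)
_LEAF_SPEC: tuple[tuple[str, str, str | None, str | None, str], ...] = (
    ("outpatient_suboptimal", "p_mh_treatment", "p_suboptimal", "cost_suboptimal", "ddl_suboptimal"),
    ("outpatient_optimal", "p_mh_treatment", "p_optimal", "cost_optimal", "ddl_optimal"),
    ("outpatient_bedrest", "p_mh_treatment", "p_bedrest", "cost_bedrest", "ddl_bedrest"),
    ("no_tx_run_course", "p_no_mh", "p_run_course", None, "ddl_run_course"),
    ("no_tx_self_success", "p_no_mh", "p_self_success", None, "ddl_self_success"),
    ("no_tx_self_failure", "p_no_mh", "p_self_failure", "cost_self_failure", "ddl_self_failure"),
    ("hospitalization", "p_hospitalization", None, "cost_hospital", "ddl_hospital"),
    ("medevac", "p_medevac", None, "cost_medevac", "ddl_medevac"),
)

LEAF_LABELS: tuple[str, ...] = tuple(row[0] for row in _LEAF_SPEC)


@dataclass(frozen=True)
class TerminalOutcome:
    """One terminal care pathway: unconditional probability, unit cost, unit DDL."""

    label: str
    path_probability: float
    unit_cost: float
    unit_ddl: float


@dataclass(frozen=True)
class DecisionTree:
    leaves: tuple[TerminalOutcome, ...]

    def probability_mass(self) -> float:
        return sum(leaf.path_probability for leaf in self.leaves)

    def __getitem__(self, label: str) -> TerminalOutcome:
        for leaf in self.leaves:
            if leaf.label == label:
                return leaf
        raise KeyError(label)


@dataclass(frozen=True)
class EvaluationResult:
    """Cohort-level outcome of one parameterization.

    ``episodes`` is kept unrounded; reports round at the final step only.
    """

    episodes: float
    total_cost: float
    total_ddl: float

    @property
    def cost_ratio(self) -> float:
        """Management cost per duty day lost (USD/DDL)."""
        if self.total_ddl == 0:
            raise ZeroDivisionError("cost ratio undefined: total DDL is zero")
        return self.total_cost / self.total_ddl


def build_tree(ps: ParameterSet, check: bool = True) -> DecisionTree:
    """Assemble the eight terminal outcomes from a parameter set.

    ``check=False`` skips validation and the unit-mass invariant; the one-way
    sensitivity sweep relies on this because it perturbs a single sibling
    probability without renormalizing the others.
    """
    if check:
        report = validate(ps)
        if not report.ok:
            raise ValueError(f"invalid parameter set:\n{report}")
    v = ps.values()
    leaves = []
    for label, branch, cond, cost_name, ddl_name in _LEAF_SPEC:
        prob = v[branch] if cond is None else v[branch] * v[cond]
        cost = 0.0 if cost_name is None else v[cost_name]
        leaves.append(TerminalOutcome(label, prob, cost, v[ddl_name]))
    tree = DecisionTree(tuple(leaves))
    if check and abs(tree.probability_mass() - 1.0) > 1e-9:
        raise ValueError(f"leaf probabilities sum to {tree.probability_mass()}, not 1")
    return tree


def annual_episodes(c: CohortSpec) -> float:
    """Expected TD episodes per deployment-year: size × months × monthly incidence.

    The unrounded value is retained; reports round half-up at the last step.
    """
    return c.deployment_size * c.duration_months * c.monthly_incidence


def expected_per_episode(t: DecisionTree) -> tuple[float, float]:
    """(expected cost USD, expected DDL) for a single episode."""
    cost = sum(leaf.path_probability * leaf.unit_cost for leaf in t.leaves)
    ddl = sum(leaf.path_probability * leaf.unit_ddl for leaf in t.leaves)
    return cost, ddl


def expectation_from_values(v) -> tuple:
    """Per-episode (cost, ddl) directly from a name→value mapping.

    Values may be scalars or equal-length numpy arrays (the Monte Carlo
    engine evaluates thousands of parameter draws in one vectorized pass).
    """
    cost = 0.0
    ddl = 0.0
    for _, branch, cond, cost_name, ddl_name in _LEAF_SPEC:
        prob = v[branch] if cond is None else v[branch] * v[cond]
        if cost_name is not None:
            cost = cost + prob * v[cost_name]
        ddl = ddl + prob * v[ddl_name]
    return cost, ddl


def evaluate(ps: ParameterSet, check: bool = True) -> EvaluationResult:
    """Cohort-year totals for one parameter set."""
    tree = build_tree(ps, check=check)
    episodes = annual_episodes(ps.cohort)
    cost, ddl = expected_per_episode(tree)
    return EvaluationResult(episodes=episodes, total_cost=cost * episodes, total_ddl=ddl * episodes)
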