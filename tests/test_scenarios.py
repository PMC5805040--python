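"""Management-strategy transformations and base-case comparison.

The published outcome table for this model prints annual DDL for the base
case and nine scenario-levels; those integers (and the derived DDL-averted
row) are the gold standard the scenario engine must hit exactly.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdcea.scenarios import (
    ScenarioSpec,
    apply_scenario,
    compare,
    opb_split,
    run_scenario,
    standard_scenarios,
)
from tdcea.tree import evaluate
from tdcea.util import round_half_up

# scenario key -> (DDL/yr, DDL-averted, total cost USD, CER $/DDL)
PUBLISHED = {
    "hcsb_40": (27_101, -1_183, 3_403_120, 363),
    "hcsb_55": (30_958, -5_041, 4_046_333, 213),
    "hcsb_70": (34_816, -8_898, 4_689_547, 193),
    "opb_65": (21_326, 4_592, 2_660_662, -68),
    "opb_75": (20_973, 4_945, 2_622_427, -71),
    "opb_85": (20_619, 5_299, 2_584_192, -74),
    "combination_40_65": (19_584, 6_333, 2_988_061, 2),
    "combination_55_75": (19_590, 6_328, 3_405_534, 68),
    "combination_70_85": (19_031, 6_887, 3_784_775, 118),
}


def _by_key(key):
    return {s.key: s for s in standard_scenarios()}[key]


@pytest.mark.parametrize(
    "level, expected",
    [(0.65, (0.220, 0.409)), (0.75, (0.157, 0.472)), (0.558, (0.278, 0.351)), (0.85, (0.094, 0.535))],
)
def test_opb_split_matches_printed_percentages(level, expected):
    sub, opt = opb_split(level)
    assert (round(sub, 3), round(opt, 3)) == expected


@given(st.floats(0.01, 0.99))
@settings(derandomize=True, max_examples=100)
def test_opb_split_conserves_the_pool(level):
    sub, opt = opb_split(level)
    assert sub + opt == pytest.approx(0.629, abs=1e-12)
    assert 0.0 <= opt <= 0.629


def test_hcsb_overrides(base_ps):
    ps = apply_scenario(base_ps, _by_key("hcsb_70"))
    assert ps.value("p_mh_treatment") == 0.70
    assert ps.value("p_no_mh") == pytest.approx(0.2907)
    assert ps.value("ddl_optimal") == 0.31
    assert ps.value("ddl_bedrest") == 1.41
    assert ps.value("cost_optimal") == 82  # HCSB does not touch treatment cost


def test_opb_overrides(base_ps):
    ps = apply_scenario(base_ps, _by_key("opb_85"))
    assert ps.value("p_suboptimal") == pytest.approx(0.094)
    assert ps.value("p_optimal") == pytest.approx(0.535)
    assert ps.value("cost_optimal") == 30
    assert ps.value("ddl_optimal") == 0.33
    assert ps.value("ddl_bedrest") == 0.88
    assert ps.value("p_mh_treatment") == 0.30  # care-seeking unchanged


def test_combination_overrides(base_ps):
    ps = apply_scenario(base_ps, _by_key("combination_70_85"))
    assert ps.value("ddl_optimal") == 0.11
    assert ps.value("ddl_bedrest") == 0.69
    assert ps.value("p_mh_treatment") == 0.70
    assert ps.value("p_optimal") == pytest.approx(0.535)


def test_scenarios_leave_unrelated_parameters_alone(base_ps):
    for spec in standard_scenarios():
        ps = apply_scenario(base_ps, spec)
        for name in ("p_hospitalization", "p_medevac", "cost_hospital", "cost_medevac",
                     "ddl_hospital", "ddl_medevac", "deployment_size", "monthly_incidence"):
            assert ps.value(name) == base_ps.value(name), (spec.key, name)
        assert ps.cohort == base_ps.cohort


def test_base_case_ddl_per_year(base_ps):
    assert round_half_up(evaluate(base_ps).total_ddl) == 25_918


@pytest.mark.parametrize("key", sorted(PUBLISHED))
def test_scenario_ddl_per_year_exact(base_ps, key):
    scen_eval, _ = run_scenario(base_ps, _by_key(key))
    assert round_half_up(scen_eval.total_ddl) == PUBLISHED[key][0]


@pytest.mark.parametrize("key", sorted(PUBLISHED))
def test_ddl_averted_exact(base_ps, key):
    _, cmp = run_scenario(base_ps, _by_key(key))
    assert round_half_up(cmp.ddl_averted) == PUBLISHED[key][1]


@pytest.mark.parametrize("key", sorted(PUBLISHED))
def test_scenario_costs_within_two_permille(base_ps, key):
    scen_eval, _ = run_scenario(base_ps, _by_key(key))
    assert scen_eval.total_cost == pytest.approx(PUBLISHED[key][2], rel=2e-3)


@pytest.mark.parametrize("key", sorted(PUBLISHED))
def test_cer_within_two_dollars(base_ps, key):
    _, cmp = run_scenario(base_ps, _by_key(key))
    assert abs(cmp.cer - PUBLISHED[key][3]) <= 2.0


def test_cer_sign_convention(base_ps):
    _, hcsb = run_scenario(base_ps, _by_key("hcsb_70"))
    _, opb = run_scenario(base_ps, _by_key("opb_85"))
    _, combo = run_scenario(base_ps, _by_key("combination_70_85"))
    assert hcsb.ddl_averted < 0 and hcsb.cer > 0  # $/DDL-gained
    assert opb.ddl_averted > 0 and opb.cer < 0  # cost saving per DDL-averted
    assert combo.ddl_averted > 0 and combo.cer > 0


def test_ddl_monotone_in_implementation_level(base_ps):
    hcsb = [run_scenario(base_ps, ScenarioSpec("hcsb", hcsb_level=l))[0].total_ddl
            for l in (0.40, 0.55, 0.70)]
    opb = [run_scenario(base_ps, ScenarioSpec("opb", opb_level=l))[0].total_ddl
           for l in (0.65, 0.75, 0.85)]
    assert hcsb == sorted(hcsb)  # more care-seeking -> more DDL (strictly)
    assert hcsb[0] < hcsb[1] < hcsb[2]
    assert opb[0] > opb[1] > opb[2]  # more optimal prescribing -> fewer DDL


def test_identity_comparison_has_undefined_cer(base_ps):
    r = evaluate(base_ps)
    cmp = compare(r, r)
    assert cmp.cost_difference == 0.0
    assert cmp.ddl_averted == 0.0
    assert math.isnan(cmp.cer)


def test_hcsb_level_that_exhausts_the_complement_errors(base_ps):
    squeezed = (
        base_ps.with_point("p_no_mh", 0.05)
        .with_point("p_mh_treatment", 0.6497)
        .with_point("p_hospitalization", 0.30)
    )
    with pytest.raises(ValueError):
        apply_scenario(squeezed, ScenarioSpec("hcsb", hcsb_level=0.72))


def test_scenario_spec_validation():
    with pytest.raises(ValueError):
        ScenarioSpec("hcsb")  # level required
    with pytest.raises(ValueError):
        ScenarioSpec("base", hcsb_level=0.4)
    with pytest.raises(ValueError):
        ScenarioSpec("opb", opb_level=1.5)
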