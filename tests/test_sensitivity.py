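"""One-way (tornado) and Monte Carlo probabilistic sensitivity analysis."""

import math

import numpy as np
import pytest

from tdcea.scenarios import BASE_SCENARIO, ScenarioSpec
from tdcea.sensitivity import run_psa, sample_parameter_set, tornado
from tdcea.parameters import build_distribution, validate
from tdcea.tree import evaluate
from tdcea.util import round_half_up


def test_hospitalization_probability_dominates_the_tornado(base_ps):
    entries = tornado(base_ps, top_k=27)
    top = entries[0]
    assert top.parameter == "p_hospitalization"
    # one-way sweep without sibling renormalization reproduces the published endpoints
    assert round_half_up(top.low_output) == 82
    assert round_half_up(top.high_output) == 190
    names = [e.parameter for e in entries]
    assert {"p_run_course", "ddl_bedrest", "cost_hospital"} <= set(names[:5])


def test_tornado_base_output_value(base_ps):
    # the unrounded base cost ratio is ~114.7 USD/DDL (prints as $115)
    ratio = evaluate(base_ps).cost_ratio
    assert ratio == pytest.approx(114.7, abs=0.1)
    assert round_half_up(ratio) == 115


def test_tornado_sorted_and_truncated(base_ps):
    entries = tornado(base_ps, top_k=10)
    assert len(entries) == 10
    swings = [e.swing for e in entries]
    assert swings == sorted(swings, reverse=True)


def test_tornado_point_masses_have_zero_swing(base_ps):
    entries = tornado(base_ps.as_point_masses(), top_k=27)
    assert all(e.swing == 0.0 for e in entries)


def test_cohort_scalars_do_not_move_the_ratio(base_ps):
    entries = {e.parameter: e for e in tornado(base_ps, top_k=27)}
    for name in ("deployment_size", "duration_months", "monthly_incidence"):
        assert entries[name].swing == pytest.approx(0.0, abs=1e-9)


def test_sampled_sets_are_valid(base_ps, rng):
    for _ in range(50):
        s = sample_parameter_set(base_ps, rng)
        assert validate(s).ok


def test_sampling_point_masses_is_identity(base_ps, rng):
    frozen = base_ps.as_point_masses()
    s = sample_parameter_set(frozen, rng)
    for name, v in frozen.values().items():
        # group renormalization may touch the last float bit of the probabilities
        assert s.value(name) == pytest.approx(v, rel=1e-12), name


def test_sampled_cost_hospital_mean(base_ps, rng):
    # costs are not renormalized, so set-level draws follow the raw triangular
    draws = np.array([sample_parameter_set(base_ps, rng).value("cost_hospital")
                      for _ in range(2000)])
    mean = (2325 + 2907 + 3488) / 3
    var = (2325**2 + 2907**2 + 3488**2 - 2325 * 2907 - 2325 * 3488 - 2907 * 3488) / 18
    assert abs(draws.mean() - mean) < 3 * math.sqrt(var / len(draws))


def test_psa_is_deterministic_under_seed(base_ps):
    s = ScenarioSpec("opb", opb_level=0.85)
    a = run_psa(base_ps, s, n=500, seed=42)
    b = run_psa(base_ps, s, n=500, seed=42)
    c = run_psa(base_ps, s, n=500, seed=43)
    assert a == b
    assert a.ddl_averted_median != c.ddl_averted_median
    assert a.seed == 42


def test_psa_point_mass_degenerates_to_deterministic(base_ps):
    from tdcea.scenarios import run_scenario

    s = ScenarioSpec("opb", opb_level=0.85)
    frozen = base_ps.as_point_masses()
    r = run_psa(frozen, s, n=200, seed=0)
    _, cmp = run_scenario(frozen, s)
    assert r.ddl_averted_median == pytest.approx(cmp.ddl_averted, rel=1e-12)
    assert r.ddl_averted_iqr[0] == pytest.approx(r.ddl_averted_iqr[1])
    assert r.cer_median == pytest.approx(cmp.cer, rel=1e-12)


def test_psa_excludes_zero_averted_from_cer(base_ps):
    r = run_psa(base_ps.as_point_masses(), BASE_SCENARIO, n=100, seed=0)
    assert r.n_cer_excluded == 100
    assert math.isnan(r.cer_median)
    assert r.ddl_averted_median == 0.0


def test_psa_median_inside_published_iqr(base_ps):
    r = run_psa(base_ps, ScenarioSpec("opb", opb_level=0.85), n=1000, seed=7)
    assert 3_151 <= r.ddl_averted_median <= 9_463
    assert r.ddl_averted_iqr[0] <= r.ddl_averted_median <= r.ddl_averted_iqr[1]


def test_psa_median_stable_in_n(base_ps):
    # growing n tenfold moves the median by less than the inter-seed spread at n=3000
    s = ScenarioSpec("combination", hcsb_level=0.70, opb_level=0.85)
    medians = [run_psa(base_ps, s, n=3000, seed=k).ddl_averted_median for k in range(5)]
    spread = max(medians) - min(medians)
    big = run_psa(base_ps, s, n=30_000, seed=99).ddl_averted_median
    assert abs(big - float(np.mean(medians))) < max(spread, 1.0)


def test_psa_draws_audit_table(base_ps):
    r = run_psa(base_ps, ScenarioSpec("hcsb", hcsb_level=0.40), n=50, seed=1, keep_draws=True)
    assert len(r.draws) == 50
    nz = r.draws[r.draws.ddl_averted != 0]
    assert np.allclose(nz.cer, nz.cost_difference / nz.ddl_averted.abs())


def test_cohort_sampling_mode_widens_episode_spread(base_ps):
    fixed = run_psa(base_ps, ScenarioSpec("opb", opb_level=0.85), n=400, seed=3, keep_draws=True)
    sampled = run_psa(
        base_ps, ScenarioSpec("opb", opb_level=0.85), n=400, seed=3,
        sample_cohort=True, keep_draws=True,
    )
    assert fixed.draws.episodes.nunique() == 1
    assert sampled.draws.episodes.nunique() > 1
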