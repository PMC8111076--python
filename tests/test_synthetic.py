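from dataclasses import replace

import numpy as np
import pytest

from nsclc_cea.km import km_estimate, reconstruct_ipd
from nsclc_cea.survival import FitError, ParametricSurvival, fit_mle, rmst
from nsclc_cea.synthetic import (
    ArmSpec,
    CostInputs,
    GeneratorSpec,
    calibrate_drug_price,
    evaluate_population,
    make_cost_config,
    sample_survival,
    simulate_trial,
)


def _spec(seed=1, **kw):
    base = dict(
        arms=(
            ArmSpec(
                "atezo-like", 286, "exponential", {"rate": 0.12},
                post_progression_params={"rate": 0.05},
            ),
        ),
        admin_censor=24.0,
        seed=seed,
    )
    base.update(kw)
    return GeneratorSpec(**base)


def test_same_seed_gives_identical_fixtures():
    a = simulate_trial(_spec(seed=9))
    b = simulate_trial(_spec(seed=9))
    da = a.get("atezo-like", "pfs").digitization
    db = b.get("atezo-like", "pfs").digitization
    assert np.array_equal(da.coords, db.coords)
    assert np.array_equal(da.risk_table, db.risk_table)
    c = simulate_trial(_spec(seed=10))
    dc = c.get("atezo-like", "pfs").digitization
    assert not np.array_equal(da.coords, dc.coords)


def test_os_dominates_pfs_in_fixtures():
    trial = simulate_trial(_spec(seed=4))
    dig_pfs = trial.get("atezo-like", "pfs").digitization
    dig_os = trial.get("atezo-like", "os").digitization
    t = dig_pfs.coords[:, 0]
    s_pfs = dig_pfs.coords[:, 1]
    s_os = np.interp(t, dig_os.coords[:, 0], dig_os.coords[:, 1])
    assert np.all(s_os >= s_pfs - 1e-12)


def test_zero_censor_time_propagates_no_events_error():
    trial = simulate_trial(_spec(admin_censor=0.0))
    ipd = trial.get("atezo-like", "pfs").ipd
    assert ipd.events.sum() == 0
    with pytest.raises(FitError):
        fit_mle(ipd.times, ipd.events, "exponential")


def test_end_to_end_rate_recovery():
    """simulate → digitize → reconstruct → refit recovers the truth ±15%."""
    trial = simulate_trial(_spec(seed=2))
    dig = trial.get("atezo-like", "pfs").digitization
    ipd = reconstruct_ipd(dig)
    rate = fit_mle(ipd.times, ipd.events, "exponential").params["rate"]
    assert rate == pytest.approx(0.12, rel=0.15)


def test_pipeline_life_years_match_generating_distribution():
    """Full chain at n=1000, fine digitization: model life-years within
    0.05 years of the generating OS distribution's restricted mean."""
    from nsclc_cea.markov import ModelSettings, trace_from_curves
    from nsclc_cea.survival import fit_all, select_best

    spec = _spec(
        seed=6,
        arms=(
            ArmSpec("big", 1000, "exponential", {"rate": 0.12},
                    post_progression_params={"rate": 0.05}),
        ),
        admin_censor=60.0,
        grid_step=0.25,
    )
    trial = simulate_trial(spec)
    fits = {}
    for endpoint in ("pfs", "os"):
        ipd = reconstruct_ipd(trial.get("big", endpoint).digitization)
        fits[endpoint] = select_best(fit_all(ipd.times, ipd.events)).best
    st = ModelSettings()
    tr = trace_from_curves(fits["pfs"], fits["os"], st)
    # true OS is exponential(0.12) + exponential(0.05): RMST by quadrature
    from scipy.integrate import quad

    def s_os_true(t):
        r1, r2 = 0.12, 0.05
        return (r1 * np.exp(-r2 * t) - r2 * np.exp(-r1 * t)) / (r1 - r2)

    truth = quad(s_os_true, 0, st.horizon, limit=200)[0] / 12.0
    assert tr.life_years() == pytest.approx(truth, abs=0.05)


@pytest.mark.parametrize("family,params", [
    ("gompertz", {"shape": -0.02, "rate": 0.043}),
    ("log_logistic", {"shape": 1.5, "scale": 12.0}),
    ("log_normal", {"meanlog": 2.0, "sdlog": 1.0}),
])
def test_sampler_matches_survival_function(family, params, rng):
    """Empirical survival of sampled times tracks the analytic S(t)."""
    draws = sample_survival(family, params, 20_000, rng)
    ps = ParametricSurvival(family, params)
    for t in (3.0, 12.0, 36.0):
        emp = float(np.mean(draws > t))
        assert emp == pytest.approx(float(ps.survival(t)), abs=0.01)


# -- cost config -------------------------------------------------------------


def test_make_cost_config_structure():
    inputs, specs = make_cost_config("high")
    assert inputs.synthetic is True
    assert inputs.u_pfs == 0.804 and inputs.u_pd == 0.321
    assert inputs.discount_rate == 0.05
    assert inputs.wtp == 30828.0
    names = {s.name for s in specs}
    assert "atezolizumab_cost_per_cycle" in names and "u_pd" in names


def test_sae_rule_applied_in_build():
    inputs = CostInputs()
    cfg_t, cfg_c, _ = inputs.build()
    # "fatigue" differs by only 1 percentage point: filtered out
    assert len(cfg_t.sae_incidences) == 3
    assert cfg_t.sae_costs == cfg_c.sae_costs


def test_calibration_hits_target_delta_cost(calibrated_inputs):
    _, _, ic = evaluate_population("high", calibrated_inputs)
    assert ic.delta_cost == pytest.approx(112744.35, abs=1.0)


def test_pap_strictly_reduces_treatment_cost(calibrated_inputs):
    res_t, _, _ = evaluate_population("high", calibrated_inputs, with_pap=False)
    res_tp, _, _ = evaluate_population("high", calibrated_inputs, with_pap=True)
    assert res_tp.total_cost < res_t.total_cost


def test_config_yaml_roundtrip(tmp_path, calibrated_inputs):
    path = tmp_path / "config.yaml"
    calibrated_inputs.to_yaml(path)
    assert "synthetic: true" in path.read_text()
    back = CostInputs.from_yaml(path)
    assert back == calibrated_inputs


def test_unreachable_calibration_target_raises():
    with pytest.raises(ValueError):
        calibrate_drug_price(CostInputs(), "high", -1e9)
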