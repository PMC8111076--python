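import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nsclc_cea.survival import (
    FAMILIES,
    FitError,
    ParametricSurvival,
    aic,
    fit_all,
    fit_mle,
    rmst,
    select_best,
)

# -- closed-form values ------------------------------------------------------


def test_log_logistic_median_is_scale():
    # published chemotherapy OS curve (high PD-L1): S(scale) = 1/2
    ps = ParametricSurvival("log_logistic", {"shape": 1.407, "scale": 11.610})
    assert ps.survival(11.610) == pytest.approx(0.5, abs=1e-12)


def test_log_normal_median_is_exp_meanlog():
    ps = ParametricSurvival("log_normal", {"meanlog": 3.180, "sdlog": 2.002})
    assert ps.survival(math.exp(3.180)) == pytest.approx(0.5, abs=1e-12)


def test_gompertz_negative_shape_plateaus():
    # with shape a < 0 the survival converges to exp(rate/shape) > 0
    ps = ParametricSurvival("gompertz", {"shape": -0.020, "rate": 0.043})
    plateau = math.exp(0.043 / -0.020)
    assert plateau == pytest.approx(0.11648, abs=1e-4)
    assert ps.survival(1e4) == pytest.approx(plateau, rel=1e-9)


def test_invalid_params_rejected_at_construction():
    with pytest.raises(ValueError):
        ParametricSurvival("log_normal", {"meanlog": 1.0, "sdlog": -0.5})
    with pytest.raises(ValueError):
        ParametricSurvival("weibull", {"shape": 0.0, "scale": 5.0})
    with pytest.raises(ValueError):
        ParametricSurvival("exponential", {"rate": 1.0, "extra": 2.0})


# -- shape properties --------------------------------------------------------

_param_strategies = {
    "exponential": st.tuples(st.floats(0.01, 2.0)),
    "weibull": st.tuples(st.floats(0.3, 4.0), st.floats(0.5, 50.0)),
    "gamma": st.tuples(st.floats(0.3, 5.0), st.floats(0.01, 2.0)),
    "log_logistic": st.tuples(st.floats(0.3, 4.0), st.floats(0.5, 50.0)),
    "log_normal": st.tuples(st.floats(-2.0, 4.0), st.floats(0.2, 3.0)),
    "gompertz": st.tuples(st.floats(-0.2, 0.2), st.floats(0.005, 1.0)),
}


@pytest.mark.parametrize("family", FAMILIES)
@settings(deadline=None, max_examples=30, derandomize=True)
@given(data=st.data())
def test_survival_is_proper(family, data):
    """S(0)=1, S nonincreasing, values in [0,1] for any valid parameters."""
    params = dict(zip(
        {"exponential": ("rate",), "weibull": ("shape", "scale"),
         "gamma": ("shape", "rate"), "log_logistic": ("shape", "scale"),
         "log_normal": ("meanlog", "sdlog"), "gompertz": ("shape", "rate")}[family],
        data.draw(_param_strategies[family]),
    ))
    ps = ParametricSurvival(family, params)
    t = np.linspace(0.0, 240.0, 200)
    s = ps.survival(t)
    assert s[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(s >= -1e-12) and np.all(s <= 1.0 + 1e-12)
    assert np.all(np.diff(s) <= 1e-12)


# -- maximum likelihood ------------------------------------------------------


def test_exponential_mle_is_events_over_exposure():
    # single event at t=5 -> rate 1/5; matches the closed form exactly
    ps = fit_mle([5.0], [1], "exponential")
    assert ps.params["rate"] == pytest.approx(0.2, abs=1e-14)
    times = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
    events = np.array([1, 1, 0, 1, 0])
    ps = fit_mle(times, events, "exponential")
    assert ps.params["rate"] == pytest.approx(3 / 20, abs=1e-14)


def test_weibull_parameter_recovery(rng):
    t = 10.0 * rng.weibull(1.5, 500)
    ps = fit_mle(t, np.ones(500), "weibull")
    assert ps.params["shape"] == pytest.approx(1.5, abs=0.15)
    assert ps.params["scale"] == pytest.approx(10.0, abs=1.0)
    assert ps.loglik is not None and ps.vcov is not None


def test_fit_matches_lifelines_oracle(rng):
    """Dual route: our MLE against lifelines' fitters on censored data."""
    from lifelines import LogNormalFitter, WeibullFitter

    t_true = rng.lognormal(2.0, 0.8, 400)
    obs = np.minimum(t_true, 20.0)
    ev = t_true <= 20.0
    ours = fit_mle(obs, ev, "log_normal")
    lnf = LogNormalFitter().fit(obs, ev)
    assert ours.params["meanlog"] == pytest.approx(lnf.mu_, rel=1e-3)
    assert ours.params["sdlog"] == pytest.approx(lnf.sigma_, rel=1e-3)

    ours_w = fit_mle(obs, ev, "weibull")
    wf = WeibullFitter().fit(obs, ev)
    assert ours_w.params["scale"] == pytest.approx(wf.lambda_, rel=1e-3)
    assert ours_w.params["shape"] == pytest.approx(wf.rho_, rel=1e-3)


def test_fit_is_deterministic_and_order_invariant(rng):
    t = rng.exponential(8.0, 150)
    ev = np.ones(150)
    a = fit_mle(t, ev, "gamma")
    b = fit_mle(t, ev, "gamma")
    perm = rng.permutation(150)
    c = fit_mle(t[perm], ev[perm], "gamma")
    assert a.params == b.params
    assert a.params["shape"] == pytest.approx(c.params["shape"], rel=1e-9)


def test_no_events_raises():
    with pytest.raises(FitError):
        fit_mle([1.0, 2.0], [0, 0], "weibull")


# -- AIC and family selection ------------------------------------------------


def test_aic_formula():
    assert aic(-100.0, 2) == pytest.approx(204.0)


def test_aic_tie_broken_by_fewer_parameters():
    # same loglik: exponential (k=1) must beat weibull (k=2)
    e = ParametricSurvival("exponential", {"rate": 0.1}, loglik=-50.0)
    w = ParametricSurvival("weibull", {"shape": 1.0, "scale": 10.0}, loglik=-51.0)
    sel = select_best({"weibull": w, "exponential": e})
    assert sel.best_family == "exponential"
    # exact AIC tie: -50 with k=1 (AIC 102) vs -49 with k=2 (AIC 102)
    w2 = ParametricSurvival("weibull", {"shape": 1.0, "scale": 10.0}, loglik=-49.0)
    sel = select_best({"weibull": w2, "exponential": e})
    assert sel.best_family == "exponential"


def test_select_best_recovers_lognormal_at_large_n(rng):
    t = rng.lognormal(2.0, 0.9, 1000)
    sel = select_best(fit_all(t, np.ones(1000)))
    assert sel.best_family == "log_normal"
    assert sel.aics["log_normal"] < sel.aics["exponential"]


def test_select_best_all_failed():
    with pytest.raises(FitError):
        select_best({"weibull": FitError("no events")})


# -- restricted mean survival time -------------------------------------------


def test_rmst_exponential_mean():
    ps = ParametricSurvival("exponential", {"rate": 0.1})
    assert rmst(ps, 1000.0) == pytest.approx(10.0, rel=1e-6)


def test_rmst_monotone_in_horizon():
    ps = ParametricSurvival("log_logistic", {"shape": 1.407, "scale": 11.610})
    values = [rmst(ps, h) for h in (6.0, 12.0, 60.0, 120.0, 240.0)]
    assert all(b > a for a, b in zip(values, values[1:]))
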