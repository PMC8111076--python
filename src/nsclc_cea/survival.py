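"""Parametric survival families, right-censored maximum likelihood, AIC selection.

Six families are supported — exponential, gamma, Weibull, log-logistic,
log-normal and Gompertz — in the parameterizations conventional for health
economic extrapolation (time unit: months):

===========   ==================  =========================================
family        parameters          survival function
===========   ==================  =========================================
exponential   rate λ>0            S(t) = exp(−λt)
weibull       shape k>0, scale    S(t) = exp(−(t/λ)^k)
              λ>0
gamma         shape a>0, rate     S(t) = 1 − P(a, bt)   (regularized lower
              b>0                 incomplete gamma)
log_logistic  shape k>0, scale    S(t) = 1 / (1 + (t/λ)^k)
              λ>0
log_normal    meanlog μ, sdlog    S(t) = 1 − Φ((ln t − μ)/σ)
              σ>0
gompertz      shape a, rate b>0   hazard b·e^{at};  S(t) = exp((b/a)(1−e^{at}))
===========   ==================  =========================================

A negative Gompertz shape gives a survival plateau exp(b/a) > 0 — the form
needed to represent long-term survivors under immunotherapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from scipy.integrate import quad

FAMILIES = ("exponential", "gamma", "weibull", "log_logistic", "log_normal", "gompertz")

# (parameter names, which parameters must be strictly positive)
_PARAM_NAMES = {
    "exponential": ("rate",),
    "gamma": ("shape", "rate"),
    "weibull": ("shape", "scale"),
    "log_logistic": ("shape", "scale"),
    "log_normal": ("meanlog", "sdlog"),
    "gompertz": ("shape", "rate"),
}
_POSITIVE = {
    "exponential": (True,),
    "gamma": (True, True),
    "weibull": (True, True),
    "log_logistic": (True, True),
    "log_normal": (False, True),
    "gompertz": (False, True),
}


@dataclass(frozen=True)
class ParametricSurvival:
    """A fitted (or specified) parametric survival curve.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : dict
        Named parameters in the module's parameterization, time in months.
    loglik : float, optional
        Maximized log-likelihood (populated by :func:`fit_mle`).
    vcov : ndarray, optional
        Covariance of the estimates on the *internal* fit scale (log for
        positive parameters, identity otherwise); used for probabilistic
        sensitivity resampling.
    """

    family: str
    params: dict
    loglik: float | None = None
    vcov: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        names = _PARAM_NAMES[self.family]
        if tuple(self.params) != names:
            missing = set(names) - set(self.params)
            extra = set(self.params) - set(names)
            if missing or extra:
                raise ValueError(
                    f"{self.family} expects parameters {names}; "
                    f"missing {sorted(missing)}, unexpected {sorted(extra)}"
                )
            object.__setattr__(self, "params", {k: self.params[k] for k in names})
        for name, pos in zip(names, _POSITIVE[self.family]):
            v = self.params[name]
            if not np.isfinite(v):
                raise ValueError(f"{self.family}.{name} must be finite, got {v}")
            if pos and v <= 0:
                raise ValueError(f"{self.family}.{name} must be > 0, got {v}")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def _pvec(self) -> tuple:
        return tuple(self.params.values())

    def survival(self, t):
        """S(t) for t ≥ 0 (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        return _survival(self.family, self._pvec(), t)

    def logpdf(self, t):
        t = np.asarray(t, dtype=float)
        return _logpdf(self.family, self._pvec(), t)

    def __call__(self, t):
        return self.survival(t)


def survival(ps: ParametricSurvival, t):
    """Functional alias for ``ps.survival(t)``."""
    return ps.survival(t)


def _survival(family, p, t):
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = p
        return np.exp(-rate * t)
    if family == "weibull":
        shape, scale = p
        return np.exp(-((t / scale) ** shape))
    if family == "gamma":
        shape, rate = p
        return special.gammaincc(shape, rate * t)
    if family == "log_logistic":
        shape, scale = p
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 + (t / scale) ** shape)
    if family == "log_normal":
        meanlog, sdlog = p
        with np.errstate(divide="ignore"):
            logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
        return special.ndtr(-(logt - meanlog) / sdlog)
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:  # a→0 limit is exponential(rate=b)
            return np.exp(-b * t)
        # guard overflow for a>0 at large t
        z = np.clip(a * t, None, 700.0)
        return np.exp((b / a) * (1.0 - np.exp(z)))
    raise ValueError(family)


def _logpdf(family, p, t):
    """log f(t) = log h(t) + log S(t); −inf where the density is 0."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "exponential":
            (rate,) = p
            return math.log(rate) - rate * t
        if family == "weibull":
            shape, scale = p
            logt = np.log(t)
            return (
                math.log(shape)
                - shape * math.log(scale)
                + (shape - 1.0) * logt
                - (t / scale) ** shape
            )
        if family == "gamma":
            shape, rate = p
            return stats.gamma.logpdf(t, shape, scale=1.0 / rate)
        if family == "log_logistic":
            shape, scale = p
            logt = np.log(t)
            z = shape * (logt - math.log(scale))
            # f = (k/λ)(t/λ)^{k−1} / (1+(t/λ)^k)^2
            return (
                math.log(shape)
                - math.log(scale)
                + (shape - 1.0) * (logt - math.log(scale))
                - 2.0 * np.logaddexp(0.0, z)
            )
        if family == "log_normal":
            meanlog, sdlog = p
            return stats.lognorm.logpdf(t, sdlog, scale=math.exp(meanlog))
        if family == "gompertz":
            a, b = p
            if abs(a) < 1e-12:
                return math.log(b) - b * t
            z = np.clip(a * t, None, 700.0)
            return math.log(b) + z + (b / a) * (1.0 - np.exp(z))
    raise ValueError(family)


# ---------------------------------------------------------------------------
# maximum likelihood under right censoring
# ---------------------------------------------------------------------------

def _to_internal(family, p):
    """Map natural parameters to the unconstrained fit scale (log-positive)."""
    return np.array(
        [math.log(v) if pos else v for v, pos in zip(p, _POSITIVE[family])]
    )


def _from_internal(family, x):
    return tuple(
        math.exp(v) if pos else v for v, pos in zip(x, _POSITIVE[family])
    )


def _negloglik(family, x, times, events):
    p = _from_internal(family, x)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ll_ev = _logpdf(family, p, times[events])
        S = _survival(family, p, times[~events])
        ll_cens = np.log(np.maximum(S, 1e-300))
    total = np.sum(ll_ev) + np.sum(ll_cens)
    if not np.isfinite(total):
        return 1e12
    return -total


def _start_grid(family, times, events):
    """Deterministic multi-start grid from data summaries."""
    ev = times[events]
    tbar = float(np.mean(times)) if times.size else 1.0
    n_ev = max(int(events.sum()), 1)
    rate0 = n_ev / max(float(np.sum(times)), 1e-12)
    med = float(np.median(ev)) if ev.size else tbar
    med = max(med, 1e-6)
    if family == "exponential":
        return [(rate0,), (rate0 * 2,), (rate0 / 2,)]
    if family in ("weibull", "log_logistic"):
        return [(1.0, med), (1.5, med), (0.7, med), (2.5, med * 1.5)]
    if family == "gamma":
        return [(1.0, rate0), (2.0, 2 * rate0), (0.5, 0.5 * rate0)]
    if family == "log_normal":
        lev = np.log(np.maximum(ev, 1e-12)) if ev.size else np.array([0.0])
        mu0, sd0 = float(np.mean(lev)), max(float(np.std(lev)), 0.25)
        return [(mu0, sd0), (mu0, 2 * sd0), (mu0 + 0.5, sd0)]
    if family == "gompertz":
        return [(0.01, rate0), (-0.01, rate0), (0.05, rate0 / 2), (-0.05, 2 * rate0)]
    raise ValueError(family)


def _numeric_hessian(f, x, eps=1e-4):
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


class FitError(RuntimeError):
    """Raised when a parametric fit cannot be computed."""


def fit_mle(times, events, family: str) -> ParametricSurvival:
    """Fit one family to right-censored data by maximum likelihood.

    Parameters
    ----------
    times, events : array-like
        Observation times (months) and event indicators (1 = event,
        0 = right-censored). Also accepts a ``ReconstructedIPD``-like object
        with ``.times`` / ``.events`` as the first argument.
    family : str
        One of :data:`FAMILIES`.

    Returns
    -------
    ParametricSurvival with ``loglik`` and ``vcov`` populated.

    The optimizer runs L-BFGS-B from a small deterministic start grid on the
    log-positive scale, so repeated fits of the same data are bit-identical.

    Raises
    ------
    FitError
        If the data contain no events or no start converges.
    """
    if events is None and hasattr(times, "times"):
        ipd = times
        times, events = ipd.times, ipd.events
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise FitError("empty data")
    if times.shape != events.shape:
        raise ValueError("times and events must be the same length")
    if np.any(times < 0):
        raise ValueError("negative times")
    if not events.any():
        raise FitError("no events in data; cannot fit a survival model")

    # closed form for the exponential: rate = events / total follow-up
    if family == "exponential":
        rate = float(events.sum()) / float(np.sum(times))
        ps = ParametricSurvival(family, {"rate": rate})
        ll = -_negloglik(family, _to_internal(family, (rate,)), times, events)
        vcov = np.array([[1.0 / events.sum()]])  # var(log rate) = 1/d
        return ParametricSurvival(family, {"rate": rate}, loglik=float(ll), vcov=vcov)

    # sort for deterministic summation regardless of subject order
    order = np.lexsort((events.view(np.uint8), times))
    times, events = times[order], events[order]

    best = None
    for p0 in _start_grid(family, times, events):
        x0 = _to_internal(family, p0)
        try:
            res = optimize.minimize(
                lambda x: _negloglik(family, x, times, events),
                x0,
                method="L-BFGS-B",
                options={"maxiter": 500},
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or best.fun >= 1e11:
        raise FitError(f"{family}: no start point converged")

    names = _PARAM_NAMES[family]
    params = dict(zip(names, _from_internal(family, best.x)))
    H = _numeric_hessian(lambda x: _negloglik(family, x, times, events), best.x)
    try:
        vcov = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            vcov = None
    except np.linalg.LinAlgError:
        vcov = None
    return ParametricSurvival(family, params, loglik=-float(best.fun), vcov=vcov)


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, 2k − 2·logL."""
    return 2.0 * n_params - 2.0 * loglik


@dataclass
class FitSelection:
    """All successful fits with their AIC, plus the selected family."""

    fits: dict  # family -> ParametricSurvival
    aics: dict  # family -> float
    failures: dict  # family -> error message
    best_family: str

    @property
    def best(self) -> ParametricSurvival:
        return self.fits[self.best_family]


def fit_all(times, events=None, families=FAMILIES) -> dict:
    """Fit every family, returning ``{family: ParametricSurvival | FitError}``."""
    if events is None and hasattr(times, "times"):
        times, events = times.times, times.events
    out = {}
    for fam in families:
        try:
            out[fam] = fit_mle(times, events, fam)
        except FitError as err:
            out[fam] = err
    return out


def select_best(fits: dict) -> FitSelection:
    """Select the minimum-AIC family among successful fits.

    Ties are broken by fewer parameters, then by the canonical family order
    of :data:`FAMILIES`.
    """
    ok = {f: ps for f, ps in fits.items() if isinstance(ps, ParametricSurvival)}
    failures = {f: str(e) for f, e in fits.items() if not isinstance(e, ParametricSurvival)}
    if not ok:
        raise FitError("all parametric fits failed")
    aics = {f: aic(ps.loglik, ps.n_params) for f, ps in ok.items()}
    order = {f: i for i, f in enumerate(FAMILIES)}
    best_family = min(ok, key=lambda f: (aics[f], ok[f].n_params, order[f]))
    return FitSelection(fits=ok, aics=aics, failures=failures, best_family=best_family)


def rmst(ps: ParametricSurvival, horizon: float) -> float:
    """Restricted mean survival time ∫₀ᴴ S(t) dt by adaptive quadrature (months)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    val, _ = quad(lambda t: float(ps.survival(t)), 0.0, horizon,
                  epsrel=1e-8, epsabs=1e-10, limit=200)
    return val
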