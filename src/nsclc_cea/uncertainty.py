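"""Sensitivity analysis: tornado (one-way), probabilistic (Monte Carlo), CEAC.

The *model* throughout is a closure ``model(overrides) -> ICERResult`` where
``overrides`` maps parameter names to values; everything not named stays at
its base value. :func:`one_way` varies one parameter at a time to its low and
high value; :func:`psa` jointly samples all parameters from their assigned
distributions (gamma for costs, beta for incidences/proportions/utilities,
log-normal for ratio-like quantities, normal on the fit scale for survival
parameters); :func:`ceac` converts the sampled increments to the probability
of cost-effectiveness by the incremental net-monetary-benefit rule; and
:func:`price_scan` repeats the PSA under scaled treatment-drug prices using
common random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DISTRIBUTIONS = ("gamma", "beta", "lognormal", "normal", "degenerate")


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range, and PSA distribution.

    ``low``/``high`` default to ±25% of the base value. When they are a
    reported 95% CI the standard error is (high − low)/3.92; otherwise it
    defaults to base/4. Distribution hyperparameters are derived by method
    of moments from (base, SE).
    """

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    dist: str = "gamma"
    se: float | None = None
    is_ci: bool = False  # low/high are a 95% CI rather than a ±25% range

    def __post_init__(self):
        if self.dist not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.low is None:
            object.__setattr__(self, "low", self.base - 0.25 * abs(self.base))
        if self.high is None:
            object.__setattr__(self, "high", self.base + 0.25 * abs(self.base))
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low ≤ base ≤ high")
        if self.dist == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"{self.name}: beta range must stay within [0,1]")

    @property
    def std_error(self) -> float:
        if self.se is not None:
            return self.se
        if self.is_ci:
            return (self.high - self.low) / (2 * 1.959963984540054)
        return abs(self.base) / 4.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values by method-of-moments on (base, SE)."""
        m, s = self.base, self.std_error
        if self.dist == "degenerate" or s == 0.0 or m == 0.0 and self.dist != "normal":
            return np.full(size, m)
        if self.dist == "gamma":
            shape = (m / s) ** 2
            scale = s * s / m
            return rng.gamma(shape, scale, size)
        if self.dist == "beta":
            if not 0.0 < m < 1.0:
                return np.full(size, m)
            nu = m * (1.0 - m) / (s * s) - 1.0
            if nu <= 0:  # variance too large for a beta; fall back to clipping
                return np.clip(rng.normal(m, s, size), 0.0, 1.0)
            return rng.beta(m * nu, (1.0 - m) * nu, size)
        if self.dist == "lognormal":
            sigma2 = math.log1p((s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size)
        if self.dist == "normal":
            return rng.normal(m, s, size)
        raise AssertionError


@dataclass
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(params, model) -> list:
    """Tornado analysis: ICER at each parameter's low and high, others at base.

    Returns entries sorted by spread, largest first.
    """
    entries = []
    for p in params:
        lo = model({p.name: p.low}).icer
        hi = model({p.name: p.high}).icer
        entries.append(TornadoEntry(p.name, lo, hi))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def psa(params, model, n_iter: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Probabilistic sensitivity analysis by joint Monte-Carlo sampling.

    Every iteration samples all parameters independently from their
    distributions, reruns both arms through ``model``, and records the
    incremental cost and QALYs. Reproducible for a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be ≥ 1")
    rng = np.random.default_rng(seed)
    draws = {p.name: p.sample(rng, n_iter) for p in params}
    dc = np.empty(n_iter)
    dq = np.empty(n_iter)
    for i in range(n_iter):
        res = model({name: vals[i] for name, vals in draws.items()})
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
    return pd.DataFrame({"delta_cost": dc, "delta_qaly": dq})


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probability[idx])


def ceac(samples: pd.DataFrame, wtp_grid=None) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA samples.

    At each willingness-to-pay λ the probability is the fraction of samples
    with positive incremental net monetary benefit λ·ΔQALY − Δcost.
    """
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 1000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dc = samples["delta_cost"].to_numpy()
    dq = samples["delta_qaly"].to_numpy()
    nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    return CEACCurve(wtp=wtp_grid, probability=(nmb > 0).mean(axis=1))


def ce_probability(samples: pd.DataFrame, wtp: float) -> float:
    """Fraction of PSA samples cost-effective at a single threshold."""
    dc = samples["delta_cost"].to_numpy()
    dq = samples["delta_qaly"].to_numpy()
    return float(np.mean(wtp * dq - dc > 0))


def price_scan(
    params,
    model,
    price_param: str,
    reductions,
    wtp: float,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Probability of cost-effectiveness under treatment-drug price cuts.

    For each reduction ρ the ParamSpec named ``price_param`` is rescaled by
    (1 − ρ) — base, range and spread alike — and the PSA is rerun. All scan
    points share the same seed (common random numbers), so the
    zero-reduction row equals the baseline PSA and the probability is
    monotone under a pure price effect.
    """
    if price_param not in {p.name for p in params}:
        raise ValueError(f"{price_param!r} is not among the PSA parameters")
    rows = []
    for red in reductions:
        if not 0.0 <= red <= 1.0:
            raise ValueError("price reductions must lie in [0, 1]")
        mult = 1.0 - red
        scaled = [
            replace(
                p,
                base=p.base * mult,
                low=p.low * mult,
                high=p.high * mult,
                se=None if p.se is None else p.se * mult,
            )
            if p.name == price_param
            else p
            for p in params
        ]
        samples = psa(scaled, model, n_iter=n_iter, seed=seed)
        rows.append((red, ce_probability(samples, wtp)))
    return pd.DataFrame(rows, columns=["price_reduction", "ce_probability"])
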