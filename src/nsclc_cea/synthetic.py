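"""Ground-truth generators: synthetic trials and cost/utility configurations.

Two generators make the whole pipeline testable without external data:

* :func:`simulate_trial` draws event times from known survival families,
  applies censoring, and emits digitized-KM fixtures (step-curve coordinates
  plus numbers-at-risk) alongside the true individual-patient data, so
  reconstruction and fitting can be validated against known truth. Overall
  survival is generated additively (OS = PFS + post-progression residual),
  which guarantees the OS curve dominates the PFS curve.

* :func:`make_cost_config` emits a complete cost/utility/SAE configuration
  in the shape the economic model needs. The published utilities
  (0.804 progression-free / 0.321 progressed), discounting (5%/year),
  willingness-to-pay threshold, SAE rule (≥3 percentage points) and the
  2-paid/3-free assistance-program schedule are fixed; monetary magnitudes
  are synthetic placeholders (flagged ``synthetic: true`` on serialization)
  because the source supplementary cost tables are not public.
  :func:`calibrate_drug_price` solves the treatment-drug price so the
  base-case incremental cost hits a chosen target exactly — the entry point
  for regression tests against published incremental costs.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .survival import ParametricSurvival
from .km import KMDigitization, ReconstructedIPD, km_estimate
from .markov import ModelSettings, trace_from_curves
from .economics import (
    SAE,
    PAPSchedule,
    StrategyConfig,
    UtilitySet,
    accumulate,
    icer,
    sae_filter,
)
from .uncertainty import ParamSpec
from . import impower110


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def sample_survival(family: str, params: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw event times from one of the six supported families (months).

    A negative-shape Gompertz has a surviving fraction exp(rate/shape); those
    subjects get time = +inf and are expected to be censored downstream.
    """
    from scipy import stats

    if family == "exponential":
        return rng.exponential(1.0 / params["rate"], size)
    if family == "weibull":
        return params["scale"] * rng.weibull(params["shape"], size)
    if family == "gamma":
        return rng.gamma(params["shape"], 1.0 / params["rate"], size)
    if family == "log_normal":
        return rng.lognormal(params["meanlog"], params["sdlog"], size)
    if family == "log_logistic":
        u = rng.uniform(size=size)
        return params["scale"] * (u / (1.0 - u)) ** (1.0 / params["shape"])
    if family == "gompertz":
        a, b = params["shape"], params["rate"]
        u = rng.uniform(size=size)
        if abs(a) < 1e-12:
            return -np.log(u) / b
        arg = 1.0 - (a / b) * np.log(u)
        out = np.full(size, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / a
        return out
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class ArmSpec:
    """True generating distributions for one arm."""

    label: str
    n: int
    pfs_family: str
    pfs_params: dict
    post_progression_family: str = "exponential"
    post_progression_params: dict = field(default_factory=lambda: {"rate": 0.08})

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("arm size must be positive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-design knobs for a synthetic two-endpoint trial.

    ``admin_censor`` is the administrative follow-up cut-off (months);
    ``dropout_rate_monthly`` an exponential loss-to-follow-up hazard;
    ``risk_interval`` the spacing of the numbers-at-risk table; and
    ``grid_step`` the spacing of the digitization grid. The seed is
    mandatory: fixtures are fully reproducible.
    """

    arms: tuple
    admin_censor: float = 24.0
    dropout_rate_monthly: float = 0.0
    risk_interval: float = 3.0
    grid_step: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.admin_censor < 0:
            raise ValueError("admin_censor must be nonnegative")
        if self.risk_interval <= 0 or self.grid_step <= 0:
            raise ValueError("risk_interval and grid_step must be positive")


@dataclass
class EndpointData:
    """Observed IPD plus its digitized-KM fixture for one arm × endpoint."""

    ipd: ReconstructedIPD  # truth-level observed data (same container)
    digitization: KMDigitization
    true_curve: ParametricSurvival | None = None


@dataclass
class TrialData:
    """All synthetic per-arm endpoint data keyed by (arm label, endpoint)."""

    endpoints: dict
    spec: GeneratorSpec

    def get(self, arm: str, endpoint: str) -> EndpointData:
        return self.endpoints[(arm, endpoint)]


def _digitize(ipd: ReconstructedIPD, spec: GeneratorSpec, label: str) -> KMDigitization:
    sf = km_estimate(ipd)
    t_max = float(np.max(ipd.times))
    # grid offset by half a step so clicks fall between risk-table times,
    # as they do when digitizing real curves at the visible steps
    grid = np.concatenate(
        [[0.0], np.arange(spec.grid_step / 2, t_max + spec.grid_step, spec.grid_step)]
    )
    coords = np.column_stack([grid, sf(grid)])
    risk_times = np.arange(0.0, t_max + 1e-9, spec.risk_interval)
    if len(risk_times) < 2:
        risk_times = np.array([0.0, max(t_max, spec.risk_interval)])
    n_risk = [int(np.sum(ipd.times >= rt)) for rt in risk_times]
    return KMDigitization(
        arm_label=label,
        coords=coords,
        risk_table=np.column_stack([risk_times, n_risk]),
        total_events=int(ipd.events.sum()),
    )


def simulate_trial(spec: GeneratorSpec) -> TrialData:
    """Simulate PFS and OS data for every arm and digitize their KM curves.

    OS times are PFS times plus a positive post-progression residual, so the
    generated OS curve stochastically dominates PFS. Subjects are censored at
    the administrative cut-off and (optionally) by exponential dropout.
    """
    rng = np.random.default_rng(spec.seed)
    endpoints = {}
    for arm in spec.arms:
        t_pfs = sample_survival(arm.pfs_family, arm.pfs_params, arm.n, rng)
        t_pp = sample_survival(
            arm.post_progression_family, arm.post_progression_params, arm.n, rng
        )
        t_os = t_pfs + t_pp
        censor = np.full(arm.n, float(spec.admin_censor))
        if spec.dropout_rate_monthly > 0:
            censor = np.minimum(
                censor, rng.exponential(1.0 / spec.dropout_rate_monthly, arm.n)
            )
        for endpoint, t_true in (("pfs", t_pfs), ("os", t_os)):
            obs = np.minimum(t_true, censor)
            ev = (t_true <= censor).astype(int)
            ipd = ReconstructedIPD(times=obs, events=ev, arm_label=arm.label)
            if spec.admin_censor == 0:
                dig = None  # degenerate: nothing to digitize
            else:
                dig = _digitize(ipd, spec, arm.label)
            true_curve = None
            if endpoint == "pfs":
                true_curve = ParametricSurvival(arm.pfs_family, dict(arm.pfs_params))
            endpoints[(arm.label, endpoint)] = EndpointData(ipd, dig, true_curve)
    return TrialData(endpoints=endpoints, spec=spec)


# ---------------------------------------------------------------------------
# cost / utility configuration
# ---------------------------------------------------------------------------

_DEFAULT_SAES = (
    # name, incidence treatment arm, incidence comparator arm, cost USD, disutility
    ("anemia", 0.02, 0.14, 1300.0, 0.0),
    ("neutropenia", 0.01, 0.12, 900.0, 0.0),
    ("thrombocytopenia", 0.01, 0.06, 1100.0, 0.0),
    ("fatigue", 0.03, 0.04, 500.0, 0.0),  # <3 pp difference: filtered out
)


@dataclass(frozen=True)
class CostInputs:
    """Scalar economic inputs for a treatment-vs-chemotherapy comparison.

    All monetary values are synthetic stand-ins (USD) for the unavailable
    supplementary cost tables; structural constants (utilities, discount
    rate, SAE threshold, PAP schedule) are the published ones. ``build``
    turns the scalars into per-arm :class:`StrategyConfig` objects.
    """

    atezolizumab_cost_per_cycle: float = 4750.0
    chemotherapy_cost_per_cycle: float = 1200.0
    supportive_care_cost_per_cycle: float = 250.0
    followup_cost_per_cycle: float = 120.0
    end_of_life_cost: float = 1800.0
    second_line_cost_per_cycle: float = 800.0
    second_line_fraction: float = 0.40
    u_pfs: float = impower110.UTILITY_PFS
    u_pd: float = impower110.UTILITY_PD
    discount_rate: float = impower110.DISCOUNT_RATE_ANNUAL
    wtp: float = impower110.WTP_USD_PER_QALY
    sae_threshold: float = 0.03
    saes: tuple = _DEFAULT_SAES
    synthetic: bool = True

    def sae_objects(self):
        return [
            SAE(name, it, ic, cost, dis) for name, it, ic, cost, dis in self.saes
        ]

    def build(self, with_pap: bool = False):
        """(treatment config, comparator config, utilities)."""
        kept = sae_filter(self.sae_objects(), self.sae_threshold)
        common = dict(
            supportive_care_cost_per_cycle=self.supportive_care_cost_per_cycle,
            followup_cost_per_cycle=self.followup_cost_per_cycle,
            end_of_life_cost=self.end_of_life_cost,
            second_line_fraction=self.second_line_fraction,
            second_line_cost_per_cycle=self.second_line_cost_per_cycle,
            sae_costs=tuple(s.cost for s in kept),
            sae_disutilities=tuple(s.disutility for s in kept),
        )
        treatment = StrategyConfig(
            arm_label="atezolizumab",
            drug_cost_per_cycle=self.atezolizumab_cost_per_cycle,
            pap=PAPSchedule() if with_pap else None,
            sae_incidences=tuple(s.incidence_treatment for s in kept),
            **common,
        )
        comparator = StrategyConfig(
            arm_label="chemotherapy",
            drug_cost_per_cycle=self.chemotherapy_cost_per_cycle,
            sae_incidences=tuple(s.incidence_comparator for s in kept),
            **common,
        )
        return treatment, comparator, UtilitySet(self.u_pfs, self.u_pd)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["saes"] = [list(s) for s in d["saes"]]
        d["currency"] = "USD"
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CostInputs":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("currency", None)
        d["saes"] = tuple(tuple(s) for s in d["saes"])
        return cls(**d)


def make_cost_config(population: str = "high", with_pap: bool = False):
    """A complete synthetic cost configuration plus its sensitivity ParamSpecs.

    Returns ``(CostInputs, [ParamSpec, ...])``. Ranges are ±25% of base;
    gamma distributions for costs, beta for incidences and utilities.
    """
    if population not in impower110.POPULATIONS:
        raise KeyError(f"unknown population {population!r}")
    inputs = CostInputs()
    return inputs, param_specs(inputs)


def param_specs(inputs: CostInputs) -> list:
    """ParamSpecs (±25% ranges, PSA distributions) for every uncertain input."""
    specs = [
        ParamSpec("atezolizumab_cost_per_cycle", inputs.atezolizumab_cost_per_cycle, dist="gamma"),
        ParamSpec("chemotherapy_cost_per_cycle", inputs.chemotherapy_cost_per_cycle, dist="gamma"),
        ParamSpec("supportive_care_cost_per_cycle", inputs.supportive_care_cost_per_cycle, dist="gamma"),
        ParamSpec("followup_cost_per_cycle", inputs.followup_cost_per_cycle, dist="gamma"),
        ParamSpec("end_of_life_cost", inputs.end_of_life_cost, dist="gamma"),
        ParamSpec("second_line_cost_per_cycle", inputs.second_line_cost_per_cycle, dist="gamma"),
        ParamSpec("second_line_fraction", inputs.second_line_fraction, dist="beta"),
        _beta_spec("u_pfs", inputs.u_pfs),
        _beta_spec("u_pd", inputs.u_pd),
    ]
    for name, it, ic, cost, _dis in inputs.saes:
        specs.append(ParamSpec(f"sae.{name}.cost", cost, dist="gamma"))
        specs.append(_beta_spec(f"sae.{name}.incidence_treatment", it))
        specs.append(_beta_spec(f"sae.{name}.incidence_comparator", ic))
    return specs


def _beta_spec(name: str, base: float) -> ParamSpec:
    """±25% range truncated to the unit interval (utilities, incidences)."""
    return ParamSpec(
        name, base, low=max(0.0, 0.75 * base), high=min(1.0, 1.25 * base), dist="beta"
    )


def apply_overrides(inputs: CostInputs, overrides: dict) -> CostInputs:
    """New CostInputs with named parameters replaced (dotted names hit SAEs)."""
    plain = {}
    saes = [list(s) for s in inputs.saes]
    sae_field = {"incidence_treatment": 1, "incidence_comparator": 2, "cost": 3, "disutility": 4}
    names = [s[0] for s in saes]
    for key, val in overrides.items():
        if key.startswith("sae."):
            _, name, attr = key.split(".")
            saes[names.index(name)][sae_field[attr]] = val
        else:
            plain[key] = val
    return replace(inputs, saes=tuple(tuple(s) for s in saes), **plain)


def make_model(
    population: str,
    inputs: CostInputs,
    with_pap: bool = False,
    settings: ModelSettings = ModelSettings(),
):
    """Closure ``model(overrides) -> ICERResult`` over the published curves.

    Traces depend only on the survival curves, so they are computed once and
    reused across sensitivity-analysis evaluations.
    """
    tr_t = trace_from_curves(*impower110.curves(population, "atezolizumab"), settings)
    tr_c = trace_from_curves(*impower110.curves(population, "chemotherapy"), settings)

    def model(overrides: dict | None = None):
        ci = apply_overrides(inputs, overrides) if overrides else inputs
        cfg_t, cfg_c, util = ci.build(with_pap=with_pap)
        res_t = accumulate(tr_t, cfg_t, util, ci.discount_rate)
        res_c = accumulate(tr_c, cfg_c, util, ci.discount_rate)
        return icer(res_t, res_c)

    return model


def evaluate_population(
    population: str,
    inputs: CostInputs,
    with_pap: bool = False,
    settings: ModelSettings = ModelSettings(),
):
    """(treatment EconomicResult, comparator EconomicResult, ICERResult)."""
    tr_t = trace_from_curves(*impower110.curves(population, "atezolizumab"), settings)
    tr_c = trace_from_curves(*impower110.curves(population, "chemotherapy"), settings)
    cfg_t, cfg_c, util = inputs.build(with_pap=with_pap)
    res_t = accumulate(tr_t, cfg_t, util, inputs.discount_rate)
    res_c = accumulate(tr_c, cfg_c, util, inputs.discount_rate)
    return res_t, res_c, icer(res_t, res_c)


def calibrate_drug_price(
    inputs: CostInputs,
    population: str,
    target_delta_cost: float,
    with_pap: bool = False,
    settings: ModelSettings = ModelSettings(),
) -> CostInputs:
    """Solve the treatment-drug price so Δcost equals ``target_delta_cost``.

    The incremental cost is affine in the per-cycle price, so the solution is
    exact (to floating point). Raises if the target is unreachable with a
    nonnegative price.
    """
    def delta_at(price):
        ci = replace(inputs, atezolizumab_cost_per_cycle=price)
        return evaluate_population(population, ci, with_pap, settings)[2].delta_cost

    d0 = delta_at(0.0)
    d1 = delta_at(1.0)
    slope = d1 - d0
    if slope <= 0:
        raise RuntimeError("treatment arm accrues no drug cost; cannot calibrate")
    price = (target_delta_cost - d0) / slope
    if price < 0:
        raise ValueError("target incremental cost unreachable with nonnegative price")
    return replace(inputs, atezolizumab_cost_per_cycle=price)
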