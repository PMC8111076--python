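"""Costs, utilities, discounting, and incremental cost-effectiveness.

Only direct medical costs enter the model: drug acquisition, supportive
care and routine follow-up, management of serious adverse events (SAEs,
grade ≥3) whose between-arm incidence differs by at least 3 percentage
points, second-line therapy after progression, and end-of-life care. Costs
and QALYs are discounted at 5%/year; life-years are reported undiscounted.

Accrual conventions (cycle k spans (t_{k−1}, t_k], discount factor
v(k) = (1+r)^(−t_k/12)):

* QALYs: trapezoidal occupancy-weighted utility × cycle length × v(k);
* per-cycle costs (drug, supportive care while progression-free, follow-up
  while alive, second-line while progressed): start-of-cycle occupancy × v(k);
* end-of-life cost: incident deaths in cycle k × v(k);
* SAE costs and disutilities: once, in the first cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import MarkovTrace


@dataclass(frozen=True)
class PAPSchedule:
    """Patient-assistance program: pay ``paid_cycles``, then ``free_cycles`` free.

    The default (2 paid, 3 free, repeating) halves-and-more the drug bill:
    cycles 1,2 paid; 3–5 free; 6,7 paid; and so on.
    """

    paid_cycles: int = 2
    free_cycles: int = 3
    repeating: bool = True

    def __post_init__(self):
        if self.paid_cycles + self.free_cycles <= 0:
            raise ValueError("paid + free cycles must be positive")
        if self.paid_cycles < 0 or self.free_cycles < 0:
            raise ValueError("cycle counts must be nonnegative")

    def is_paid(self, k: int) -> bool:
        """Whether drug is charged in (1-indexed) cycle k."""
        if k < 1:
            raise ValueError("cycle index starts at 1")
        period = self.paid_cycles + self.free_cycles
        pos = (k - 1) % period if self.repeating else min(k - 1, period - 1)
        if not self.repeating and k - 1 >= period:
            return False
        return pos < self.paid_cycles


@dataclass(frozen=True)
class SAE:
    """One serious adverse event: per-arm incidences, unit cost, QALY decrement."""

    name: str
    incidence_treatment: float
    incidence_comparator: float
    cost: float
    disutility: float = 0.0

    def __post_init__(self):
        for inc in (self.incidence_treatment, self.incidence_comparator):
            if not 0.0 <= inc <= 1.0:
                raise ValueError(f"SAE incidence out of [0,1]: {inc}")
        if self.cost < 0 or self.disutility < 0:
            raise ValueError("SAE cost and disutility must be nonnegative")


def sae_filter(sae_candidates, threshold: float = 0.03):
    """Keep SAEs whose between-arm incidence difference is ≥ threshold."""
    return [
        s
        for s in sae_candidates
        if abs(s.incidence_treatment - s.incidence_comparator) >= threshold
    ]


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities (death fixed at 0)."""

    u_pfs: float = 0.804
    u_pd: float = 0.321

    def __post_init__(self):
        for u in (self.u_pfs, self.u_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")


@dataclass(frozen=True)
class StrategyConfig:
    """Economic inputs for one treatment arm.

    ``sae_incidences``/``sae_costs``/``sae_disutilities`` are the *this-arm*
    values of the SAEs retained by :func:`sae_filter`. Costs are per cycle in
    a single currency (the analyses use USD).
    """

    arm_label: str
    drug_cost_per_cycle: float
    treatment_while_in: tuple = ("pfs",)
    max_treatment_cycles: int | None = None
    pap: PAPSchedule | None = None
    sae_incidences: tuple = ()
    sae_costs: tuple = ()
    sae_disutilities: tuple = ()
    supportive_care_cost_per_cycle: float = 0.0
    followup_cost_per_cycle: float = 0.0
    end_of_life_cost: float = 0.0
    second_line_fraction: float = 0.0
    second_line_cost_per_cycle: float = 0.0

    def __post_init__(self):
        for c in (
            self.drug_cost_per_cycle,
            self.supportive_care_cost_per_cycle,
            self.followup_cost_per_cycle,
            self.end_of_life_cost,
            self.second_line_cost_per_cycle,
        ):
            if c < 0:
                raise ValueError("costs must be nonnegative")
        if not 0.0 <= self.second_line_fraction <= 1.0:
            raise ValueError("second_line_fraction must be in [0,1]")
        if not (
            len(self.sae_incidences) == len(self.sae_costs) == len(self.sae_disutilities)
        ):
            raise ValueError("SAE fields must be parallel")


def drug_cost_at_cycle(cfg: StrategyConfig, k: int) -> float:
    """Drug acquisition cost charged in (1-indexed) cycle k, per treated patient."""
    if k < 1:
        raise ValueError("cycle index starts at 1")
    if cfg.max_treatment_cycles is not None and k > cfg.max_treatment_cycles:
        return 0.0
    if cfg.pap is not None and not cfg.pap.is_paid(k):
        return 0.0
    return cfg.drug_cost_per_cycle


def chemo_dose_mg(dose_per_m2: float, bsa_m2: float = 1.72) -> float:
    """Body-surface-area dosing helper (linear per-mg pricing, no vial rounding)."""
    if dose_per_m2 < 0 or bsa_m2 <= 0:
        raise ValueError("invalid dose or BSA")
    return dose_per_m2 * bsa_m2


@dataclass
class EconomicResult:
    """Discounted cost and QALYs, undiscounted life-years, for one arm."""

    arm_label: str
    total_cost: float
    total_ly: float
    total_qaly: float
    breakdown: pd.DataFrame | None = field(default=None, repr=False)


def accumulate(
    trace: MarkovTrace,
    cfg: StrategyConfig,
    utilities: UtilitySet = UtilitySet(),
    discount_rate: float = 0.05,
) -> EconomicResult:
    """Attach costs and utilities to a cohort trace.

    Returns discounted total cost and QALYs and undiscounted life-years.
    With ``discount_rate`` 0 the totals are the plain sums; doubling every
    cost input exactly doubles ``total_cost`` (the accrual is linear).
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be nonnegative")
    mu = trace.settings.cycle_length
    K = trace.settings.n_cycles
    t = trace.t
    v = (1.0 + discount_rate) ** (-t[1:] / 12.0)  # v[k-1] discounts cycle k

    occ_pfs0, occ_pd0 = trace.n_pfs[:-1], trace.n_pd[:-1]  # start-of-cycle
    state_occ0 = {"pfs": occ_pfs0, "pd": occ_pd0}
    treated0 = sum(state_occ0[s] for s in cfg.treatment_while_in)

    drug_unit = np.array([drug_cost_at_cycle(cfg, k) for k in range(1, K + 1)])
    drug = drug_unit * treated0 * v
    supportive = cfg.supportive_care_cost_per_cycle * occ_pfs0 * v
    alive0 = occ_pfs0 + occ_pd0
    followup = cfg.followup_cost_per_cycle * alive0 * v
    second_line = (
        cfg.second_line_cost_per_cycle * cfg.second_line_fraction * occ_pd0 * v
    )
    eol = cfg.end_of_life_cost * trace.incident_deaths[1:] * v
    sae_cost = float(np.dot(cfg.sae_incidences, cfg.sae_costs)) if cfg.sae_incidences else 0.0
    sae = np.zeros(K)
    if K > 0:
        sae[0] = sae_cost * v[0]

    q = trace.n_pfs * utilities.u_pfs + trace.n_pd * utilities.u_pd
    qaly_cycle = (q[:-1] + q[1:]) / 2.0 * mu / 12.0 * v
    sae_disutil = (
        float(np.dot(cfg.sae_incidences, cfg.sae_disutilities))
        if cfg.sae_incidences
        else 0.0
    )
    if K > 0:
        qaly_cycle = qaly_cycle.copy()
        qaly_cycle[0] -= sae_disutil * v[0]

    breakdown = pd.DataFrame(
        {
            "cycle": np.arange(1, K + 1),
            "t_months": t[1:],
            "drug": drug,
            "supportive_care": supportive,
            "followup": followup,
            "second_line": second_line,
            "end_of_life": eol,
            "sae": sae,
            "qaly": qaly_cycle,
        }
    )
    total_cost = float(drug.sum() + supportive.sum() + followup.sum()
                       + second_line.sum() + eol.sum() + sae.sum())
    return EconomicResult(
        arm_label=cfg.arm_label,
        total_cost=total_cost,
        total_ly=trace.life_years(),
        total_qaly=float(qaly_cycle.sum()),
        breakdown=breakdown,
    )


@dataclass
class ICERResult:
    """Incremental cost-effectiveness of treatment vs comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominant: bool = False  # cheaper and more effective
    dominated: bool = False  # dearer and less effective

    def nmb(self, wtp: float) -> float:
        """Incremental net monetary benefit at willingness-to-pay ``wtp``."""
        return wtp * self.delta_qaly - self.delta_cost


def icer(res_treatment: EconomicResult, res_comparator: EconomicResult) -> ICERResult:
    """Δcost/ΔQALY of treatment over comparator, with dominance flags."""
    dc = res_treatment.total_cost - res_comparator.total_cost
    dq = res_treatment.total_qaly - res_comparator.total_qaly
    if dq == 0.0:
        return ICERResult(dc, dq, None)
    return ICERResult(
        delta_cost=dc,
        delta_qaly=dq,
        icer=dc / dq,
        dominant=(dq > 0 and dc < 0),
        dominated=(dq < 0 and dc > 0),
    )


def with_pap(cfg: StrategyConfig, pap: PAPSchedule | None = None) -> StrategyConfig:
    """Copy of a strategy with the patient-assistance program attached."""
    return replace(cfg, pap=pap if pap is not None else PAPSchedule())
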