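"""Three-state cohort model: progression-free (PFS), progressed (PD), death.

The cohort starts fully progression-free and is redistributed each 3-week
cycle by time-dependent transition probabilities derived from the fitted
PFS and OS curves:

* staying progression-free is the conditional survival
  ``S_PFS(t) / S_PFS(t−μ)`` over one cycle of length μ;
* death from PFS follows background (natural) mortality;
* progression takes the remainder of the leaving mass;
* overall survival retention ``S_OS(t) / S_OS(t−μ)`` pins total survivors,
  and the PD→PD probability is solved from the balance
  ``[(n_PFS+n_PD)·P_S→S − n_PFS·P_PFS→PFS − n_PFS·P_PFS→PD] / n_PD``
  so that PFS occupancy tracks S_PFS and total alive tracks S_OS exactly
  (which also makes life-years invariant to the background-mortality
  setting).

Time convention: a month is taken as four weeks, so the 3-week cycle is
μ = 0.75 months and the 10-year horizon is 174 cycles. This is the
discretization under which the model reproduces the published base-case
life-years from the published survival parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: months per cycle (3 weeks, four-week month)
CYCLE_LENGTH_MONTHS = 0.75
#: cycles in the 10-year horizon (10 × 365.25 / 21 days)
N_CYCLES_10Y = 174


@dataclass(frozen=True)
class ModelSettings:
    """Discretization and background mortality for the cohort model.

    ``background_mortality_annual`` is the annual probability of death from
    causes other than the disease while progression-free; it is converted to
    a per-cycle probability. Outcomes are insensitive to it by construction
    (see module docstring) — it only relabels the route to death.
    """

    cycle_length: float = CYCLE_LENGTH_MONTHS
    n_cycles: int = N_CYCLES_10Y
    background_mortality_annual: float = 0.01
    half_cycle_correction: bool = True

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be ≥ 1")
        if not 0 <= self.background_mortality_annual < 1:
            raise ValueError("background mortality must be in [0, 1)")

    @property
    def horizon(self) -> float:
        """Model horizon in months."""
        return self.cycle_length * self.n_cycles

    @property
    def times(self) -> np.ndarray:
        """Cycle boundary times t_k = k·μ, k = 0..n_cycles."""
        return np.arange(self.n_cycles + 1) * self.cycle_length

    @property
    def background_mortality_per_cycle(self) -> float:
        return 1.0 - (1.0 - self.background_mortality_annual) ** (self.cycle_length / 12.0)


def transition_schedule(pfs, os_, settings: ModelSettings = ModelSettings()) -> pd.DataFrame:
    """Per-cycle transition probabilities from fitted PFS and OS curves.

    Returns a DataFrame indexed by cycle k = 1..n_cycles with columns
    ``p_pfs_pfs, p_pfs_pd, p_pfs_death, p_pd_pd, p_pd_death`` and the cycle
    boundary time ``t``. The PD-row probabilities use the previous cycle's
    occupancies, which under this scheme equal ``S_PFS`` and
    ``S_OS − S_PFS`` at the cycle boundaries.
    """
    t = settings.times
    s_pfs = np.asarray(pfs.survival(t), dtype=float)
    s_os = np.asarray(os_.survival(t), dtype=float)
    if abs(s_pfs[0] - 1.0) > 1e-9 or abs(s_os[0] - 1.0) > 1e-9:
        raise ValueError("survival curves must satisfy S(0) = 1")
    if np.any(s_pfs > s_os + 1e-9):
        warnings.warn(
            "PFS curve exceeds OS curve on part of the horizon; "
            "PD occupancy clamped at 0 there"
        )

    m = settings.background_mortality_per_cycle
    K = settings.n_cycles
    rows = np.empty((K, 6))
    n_pfs, n_pd = 1.0, 0.0
    for k in range(1, K + 1):
        stay = min(s_pfs[k] / s_pfs[k - 1], 1.0) if s_pfs[k - 1] > 0 else 0.0
        p_s_s = min(s_os[k] / s_os[k - 1], 1.0) if s_os[k - 1] > 0 else 0.0
        # targets implied by the curves: PFS tracks S_PFS, alive tracks S_OS
        target_pd = max((n_pfs + n_pd) * p_s_s - n_pfs * stay, 0.0)

        p_pfs_pd = max(1.0 - stay - m, 0.0)  # nominal: death at background rate
        if n_pd > 1e-15:
            p_pd_pd = (
                (n_pfs + n_pd) * p_s_s - n_pfs * stay - n_pfs * p_pfs_pd
            ) / n_pd
        else:
            p_pd_pd = 1.0  # no mass to move
        p_pd_pd = min(max(p_pd_pd, 0.0), 1.0)
        # when clamping (or an empty PD state) breaks the balance, re-split the
        # PFS leaving mass between progression and death to restore it
        implied_pd = n_pfs * p_pfs_pd + n_pd * p_pd_pd
        if abs(implied_pd - target_pd) > 1e-15 and n_pfs > 1e-15:
            p_pfs_pd = min(max((target_pd - n_pd * p_pd_pd) / n_pfs, 0.0),
                           max(1.0 - stay, 0.0))
        p_pfs_death = max(1.0 - stay - p_pfs_pd, 0.0)
        rows[k - 1] = (t[k], stay, p_pfs_pd, p_pfs_death, p_pd_pd, 1.0 - p_pd_pd)
        n_pfs, n_pd = n_pfs * stay, n_pfs * p_pfs_pd + n_pd * p_pd_pd
    return pd.DataFrame(
        rows,
        index=pd.RangeIndex(1, K + 1, name="cycle"),
        columns=["t", "p_pfs_pfs", "p_pfs_pd", "p_pfs_death", "p_pd_pd", "p_pd_death"],
    )


@dataclass
class MarkovTrace:
    """Per-cycle state occupancy of the cohort (fractions of the cohort).

    Arrays are indexed by cycle boundary k = 0..n_cycles; ``incident_deaths``
    holds the deaths occurring during cycle k (0 at k=0).
    """

    t: np.ndarray
    n_pfs: np.ndarray
    n_pd: np.ndarray
    n_death: np.ndarray
    incident_deaths: np.ndarray
    settings: ModelSettings = field(default_factory=ModelSettings)

    def life_years(self) -> float:
        """Undiscounted life-years: trapezoidal area under alive-occupancy."""
        alive = self.n_pfs + self.n_pd
        mu = self.settings.cycle_length
        return float(np.sum((alive[:-1] + alive[1:]) / 2.0) * mu / 12.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.t)),
                "t_months": self.t,
                "n_pfs": self.n_pfs,
                "n_pd": self.n_pd,
                "n_death": self.n_death,
                "incident_deaths": self.incident_deaths,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_trace(schedule: pd.DataFrame, settings: ModelSettings = ModelSettings()) -> MarkovTrace:
    """Run the cohort recursion over a transition schedule.

    The cohort starts 100% progression-free. Death is absorbing. Raises if
    any occupancy goes negative beyond numerical tolerance (a sign that the
    fitted curves cross badly).
    """
    K = len(schedule)
    n_pfs = np.empty(K + 1)
    n_pd = np.empty(K + 1)
    n_death = np.empty(K + 1)
    inc = np.zeros(K + 1)
    n_pfs[0], n_pd[0], n_death[0] = 1.0, 0.0, 0.0
    cols = schedule[["p_pfs_pfs", "p_pfs_pd", "p_pfs_death", "p_pd_pd", "p_pd_death"]].to_numpy()
    for k in range(1, K + 1):
        stay, p_pd_in, p_die_pfs, p_pd_pd, p_pd_death = cols[k - 1]
        new_pfs = n_pfs[k - 1] * stay
        new_pd = n_pfs[k - 1] * p_pd_in + n_pd[k - 1] * p_pd_pd
        deaths = n_pfs[k - 1] * p_die_pfs + n_pd[k - 1] * p_pd_death
        if new_pfs < -1e-9 or new_pd < -1e-9:
            raise RuntimeError(f"negative occupancy at cycle {k}")
        new_pfs, new_pd = max(new_pfs, 0.0), max(new_pd, 0.0)
        n_pfs[k] = new_pfs
        n_pd[k] = new_pd
        n_death[k] = n_death[k - 1] + deaths
        inc[k] = deaths
    times = np.arange(K + 1) * settings.cycle_length
    return MarkovTrace(times, n_pfs, n_pd, n_death, inc, settings)


def trace_from_curves(pfs, os_, settings: ModelSettings = ModelSettings()) -> MarkovTrace:
    """Convenience: schedule + trace in one call."""
    return run_trace(transition_schedule(pfs, os_, settings), settings)
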