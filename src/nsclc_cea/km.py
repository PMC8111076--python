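"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published KM curves plus their numbers-at-risk tables can be inverted to a
set of event/censoring times whose product-limit estimate reproduces the
curve — the Guyot algorithm widely used for survival extrapolation in health
technology assessment. Within each risk-table interval the number censored
is solved iteratively so the implied number at risk matches the published
table, with censoring times spread uniformly across the interval (the
standard variant when per-arm event totals are not published).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


@dataclass
class KMDigitization:
    """Digitized step-curve coordinates and numbers-at-risk for one arm.

    ``coords`` rows are (time months, survival fraction); ``risk_table`` rows
    are (time months, number at risk). The first risk-table entry defines the
    arm size.
    """

    arm_label: str
    coords: np.ndarray
    risk_table: np.ndarray
    total_events: int | None = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.risk_table = np.atleast_2d(np.asarray(self.risk_table, dtype=float))
        t, s = self.coords[:, 0], self.coords[:, 1]
        if np.any(np.diff(t) < 0):
            raise ValueError("coordinate times must be nondecreasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival fractions must be nonincreasing")
        if s[0] > 1.0 + 1e-12 or np.any(s < -1e-12) or np.any(s > 1.0 + 1e-12):
            raise ValueError("survival fractions must lie in [0, 1]")
        rt, rn = self.risk_table[:, 0], self.risk_table[:, 1]
        if len(rt) < 2:
            raise ValueError("need at least two risk-table entries")
        if np.any(np.diff(rn) > 0):
            raise ValueError("numbers at risk must be nonincreasing")
        if rn[0] <= 0:
            raise ValueError("arm size (n at risk at t=0) must be positive")
        if t[0] > rt[0] or t[-1] < rt[-2]:
            raise ValueError("coordinates must span the risk-table interval")

    @property
    def n_subjects(self) -> int:
        return int(round(self.risk_table[0, 1]))


@dataclass
class ReconstructedIPD:
    """Event/censoring times recovered from a digitized curve."""

    times: np.ndarray
    events: np.ndarray
    arm_label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must be parallel")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")

    def __len__(self):
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events})


def _interval_pass(t_clicks, s_clicks, n_start, n_events, n_cens, t_lo, t_hi, km_in):
    """Lay out one risk interval with fixed event and censoring counts.

    Censor times sit at the midpoints of ``n_cens`` equal subintervals
    (uniform-censoring assumption); events are placed at the digitized click
    times, tracking the digitized survival values, with the totals forced to
    ``n_events``. Returns (event times, censor times, n remaining, KM value
    leaving the interval).
    """
    if n_cens > 0:
        cens_times = t_lo + (np.arange(1, n_cens + 1) - 0.5) * (t_hi - t_lo) / n_cens
    else:
        cens_times = np.empty(0)
    ev_times, used_cens = [], []
    n, km, ci, left = n_start, km_in, 0, n_events
    for j, (tk, sk) in enumerate(zip(t_clicks, s_clicks)):
        while ci < len(cens_times) and cens_times[ci] < tk and n > 0:
            used_cens.append(cens_times[ci]); n -= 1; ci += 1
        if n <= 0:
            break
        if j == len(t_clicks) - 1:
            d = left  # force the interval total onto the last click
        elif km > 0:
            d = int(round(n * (1.0 - sk / km)))
        else:
            d = 0
        d = min(max(d, 0), n, left)
        if d > 0:
            km *= 1.0 - d / n
            ev_times.extend([tk] * d)
            n -= d
            left -= d
    while ci < len(cens_times) and n > 0:
        used_cens.append(cens_times[ci]); n -= 1; ci += 1
    return np.array(ev_times), np.array(used_cens), n, km


def reconstruct_ipd(dig: KMDigitization) -> ReconstructedIPD:
    """Invert a digitized KM curve + risk table to pseudo-IPD.

    Within each risk-table interval the total number leaving is fixed by the
    published counts; its split into events and censorings is found by
    binary search so that the reconstructed product-limit value at the end
    of the interval matches the digitized curve (censoring times uniform
    within the interval — the standard variant when per-arm event totals are
    not published). Beyond the last risk-table time, events follow the
    remaining digitized steps (capped by ``total_events`` when given) and
    survivors are censored at the last digitized time.
    """
    coords = dig.coords
    rt, rn = dig.risk_table[:, 0], dig.risk_table[:, 1].astype(int)

    all_times, all_events = [], []
    km = 1.0
    n = int(rn[0])
    for i in range(len(rt) - 1):
        t_lo, t_hi = rt[i], rt[i + 1]
        target_next = int(rn[i + 1])
        mask = (coords[:, 0] > t_lo) & (coords[:, 0] <= t_hi)
        t_clicks, s_clicks = coords[mask, 0], coords[mask, 1]
        leaving = n - target_next

        if len(t_clicks) == 0 or km <= 0 or s_clicks[-1] >= km - 1e-12:
            # no digitized drop: everyone leaving is censored
            best = _interval_pass(t_clicks, s_clicks, n, 0, leaving, t_lo, t_hi, km)
        else:
            s_end = s_clicks[-1]
            lo_c, hi_c = 0, leaving
            best, best_err = None, np.inf
            while lo_c <= hi_c:
                c = (lo_c + hi_c) // 2
                cand = _interval_pass(
                    t_clicks, s_clicks, n, leaving - c, c, t_lo, t_hi, km
                )
                err = abs(cand[3] - s_end)
                if err < best_err:
                    best, best_err = cand, err
                if cand[3] < s_end:  # too many events -> censor more
                    lo_c = c + 1
                else:
                    hi_c = c - 1
        ev, ce, n_end, km_end = best
        if n_end != target_next:
            warnings.warn(
                f"could not match number at risk at t={t_hi} "
                f"({n_end} vs {target_next}); digitization may be inconsistent"
            )
        all_times.extend(ev); all_events.extend([1] * len(ev))
        all_times.extend(ce); all_events.extend([0] * len(ce))
        n, km = n_end, km_end

    # final segment: beyond the last risk-table time
    t_last = rt[-1]
    mask = coords[:, 0] > t_last
    t_clicks, s_clicks = coords[mask, 0], coords[mask, 1]
    events_so_far = sum(all_events)
    for tk, sk in zip(t_clicks, s_clicks):
        if n <= 0 or km <= 0:
            break
        d = int(round(n * (1.0 - sk / km)))
        if dig.total_events is not None:
            d = min(d, dig.total_events - events_so_far)
        d = min(max(d, 0), n)
        if d > 0:
            km *= 1.0 - d / n
            all_times.extend([tk] * d)
            all_events.extend([1] * d)
            events_so_far += d
            n -= d
    if n > 0:  # administratively censor survivors at the curve end
        t_end = max(coords[-1, 0], t_last)
        all_times.extend([t_end] * n)
        all_events.extend([0] * n)

    order = np.lexsort((all_events, all_times))
    return ReconstructedIPD(
        times=np.asarray(all_times)[order],
        events=np.asarray(all_events)[order],
        arm_label=dig.arm_label,
    )


@dataclass
class KMStepFunction:
    """Product-limit estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)


def km_estimate(ipd: ReconstructedIPD) -> KMStepFunction:
    """Kaplan-Meier product-limit estimator of an IPD set (via lifelines)."""
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    return KMStepFunction(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def n_at_risk(ipd: ReconstructedIPD, t: float) -> int:
    """Number of subjects still under observation just before/at time t."""
    return int(np.sum(ipd.times >= t))


# --- CSV plumbing ----------------------------------------------------------

def read_digitization(coords_path, risk_path, arm_label="", total_events=None) -> KMDigitization:
    """Load a digitization from two CSVs: (time,survival) and (time,n_risk)."""
    cdf = pd.read_csv(coords_path)
    rdf = pd.read_csv(risk_path)
    return KMDigitization(
        arm_label=arm_label,
        coords=cdf[["time", "survival"]].to_numpy(),
        risk_table=rdf[["time", "n_risk"]].to_numpy(),
        total_events=total_events,
    )


def write_ipd(ipd: ReconstructedIPD, path) -> None:
    ipd.to_frame().to_csv(path, index=False)


def read_ipd(path, arm_label="") -> ReconstructedIPD:
    df = pd.read_csv(path)
    return ReconstructedIPD(df["time"].to_numpy(), df["event"].to_numpy(), arm_label)
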