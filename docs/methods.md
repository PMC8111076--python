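# Methods

## Decision problem and model structure

The package evaluates first-line atezolizumab against platinum-based
chemotherapy for EGFR/ALK wild-type metastatic non-small-cell lung cancer
from a payer perspective, separately for three PD-L1 expression populations
of the IMpower110 trial (high; high or intermediate; any). The disease
course is projected with a three-state Markov cohort model — progression-free
(PFS), progressed disease (PD), and death — over a 10-year horizon with a
3-week cycle, the treatment administration interval. The whole cohort starts
in PFS; death is absorbing.

Outcomes are total cost, life-years (LYs) and quality-adjusted life-years
(QALYs) per arm, and the incremental cost-effectiveness ratio
ICER = ΔC/ΔQALY between arms. Costs and QALYs are discounted at 5% per year;
LYs are reported undiscounted (this combination reproduces the published
base-case tables). Cost-effectiveness is judged against a willingness-to-pay
(WTP) threshold of US $30,828/QALY (three times China's 2019 per-capita GDP).

## Survival inputs

Two entry points provide the survival curves that drive the model:

1. **Published parameters.** `impower110.py` carries the best-fitting
   parametric models per population × arm × endpoint (log-normal,
   log-logistic, and one Gompertz OS curve with negative shape, i.e. a
   long-term survivor plateau exp(rate/shape) ≈ 0.116). Time is in months.
2. **Reconstruction + refitting.** Digitized KM coordinates plus a
   numbers-at-risk table are inverted to pseudo individual-patient data with
   the Guyot algorithm, then six families (exponential, gamma, Weibull,
   log-logistic, log-normal, Gompertz) are fitted by right-censored maximum
   likelihood and ranked by AIC = 2k − 2·logL (ties: fewer parameters, then
   a fixed family order).

### KM inversion details

Within each risk-table interval the number of subjects leaving is fixed by
the published counts; its split into events and censorings is found by
binary search so the reconstructed product-limit value at the interval's end
matches the digitized curve. Censoring times are spread uniformly within the
interval — the standard variant when per-arm event totals are not published
(an optional `total_events` caps events beyond the last risk time). Survivors
past the last digitized time are administratively censored there. The
reconstruction therefore matches the risk table exactly and the digitized
curve to within click-rounding; on synthetic fixtures with n ≥ 100 the KM
round-trip error stays below 0.02 absolute.

### Maximum likelihood

The log-likelihood is Σ_events log f(t) + Σ_censored log S(t). Positive
parameters are optimized on the log scale with L-BFGS-B from a small
deterministic start grid, so fits are bit-reproducible and invariant to
subject order; the exponential uses its closed form (events / total
follow-up). The covariance of the estimates on the fit scale comes from the
numerically differentiated Hessian and feeds normal-on-fit-scale resampling
in the probabilistic sensitivity analysis when fitted (rather than
published) curves are used.

## Transition probabilities

For cycle length μ and cycle boundary t: staying progression-free is the
conditional survival S_PFS(t)/S_PFS(t−μ); death from PFS occurs at the
background (all-cause) mortality rate; progression takes the remainder.
Overall-survival retention S_OS(t)/S_OS(t−μ) pins the total number alive,
and the PD→PD probability is solved from the balance

    P_PD→PD = [(n_PFS + n_PD)·P_S→S − n_PFS·P_PFS→PFS − n_PFS·P_PFS→PD] / n_PD

using the previous cycle's occupancies. When the PD state is empty or the
balance would leave [0, 1] (notably in the first cycles, when PD holds too
few patients to absorb the OS-implied deaths), the probability is clamped
and the PFS leaving mass is re-split between progression and death so that
PFS occupancy still tracks S_PFS and total alive still tracks S_OS exactly.
Consequences: life-years are provably invariant to the background-mortality
setting (default 1%/year, configurable), and if the fitted curves cross
(S_PFS > S_OS) the PD state is clamped at zero with a warning while
conservation still holds.

## Time discretization

The model treats a month as four weeks: the 3-week cycle is μ = 0.75 months
and the 10-year horizon is 174 cycles (10 × 365.25/21 ≈ 173.9). This is the
discretization under which the published per-arm life-years and QALYs are
reproduced from the published survival parameters (all twelve table cells
and all printed increments within ±0.05); with a 30.44-day month the same
computation falls 0.07–0.20 LY short, so the four-week-month convention is
adopted as the model default. Both the cycle length and cycle count are
plain `ModelSettings` fields. Halving the cycle length changes 10-year
life-years by well under 0.02 years.

Accrual is trapezoidal (half-cycle-corrected): LY = Σ (alive_{k−1} +
alive_k)/2 · μ/12, and likewise for utility-weighted QALYs, with the
discount factor (1 + r)^(−t_k/12) applied per cycle at its end boundary.
Life-years computed this way agree with adaptive-quadrature restricted mean
survival time of the OS curve to < 0.01 years for every published curve.

## Costs and utilities

Utilities: 0.804 (PFS), 0.321 (PD), 0 (death). Direct medical costs only:
per-cycle drug acquisition (charged while progression-free, optionally
capped at a maximum number of cycles), supportive care while
progression-free, routine follow-up while alive, second-line therapy for a
treated fraction of the PD state, end-of-life cost per incident death, and
serious adverse events (grade ≥3). Only SAEs whose between-arm incidence
differs by ≥3 percentage points are costed; their costs and QALY decrements
are charged once in the first cycle. The patient-assistance program (PAP)
charges the drug in a repeating 2-paid/3-free cycle pattern. A helper
converts per-m² chemotherapy doses with the reference body surface area of
1.72 m² under linear per-mg pricing (no vial rounding — vial-wastage rules
for the original setting are not public). Carboplatin AUC-based doses are
entered directly in config for the same reason.

The source's supplementary cost tables are not public, so all monetary
magnitudes live in a synthetic configuration (`CostInputs`, serialized with
a `synthetic: true` flag) with magnitudes chosen to be realistic for the
2019 Chinese setting (e.g. ≈$4,750 per 1200 mg atezolizumab cycle at
¥6.899/$). `calibrate_drug_price` solves the treatment-drug price — the
incremental cost is affine in it — so that the base-case Δcost equals a
chosen target, which is how the analyses anchor to the published incremental
costs ($112,744.35 / $81,831.03 / $70,346.51). ICER checks against the
published values are therefore *arithmetic-consistency* checks, not
independent reproductions of the cost side.

## Sensitivity analysis

One-way (tornado) analysis moves each parameter to its low/high value
(reported 95% CI where available, otherwise ±25% of base, truncated to
[0, 1] for probabilities and utilities) with everything else at base, and
ranks parameters by ICER spread. The probabilistic analysis runs 1,000
Monte-Carlo iterations sampling all parameters jointly and independently —
gamma for costs, beta for incidences/proportions/utilities, log-normal for
ratio-like quantities — with hyperparameters from method of moments on
(mean, SE), SE defaulting to mean/4 when no CI is given. The acceptability
curve reports, per WTP λ, the fraction of iterations with positive
incremental net monetary benefit λ·ΔQALY − Δcost. The price scan rescales
the treatment-drug price parameter (base, range and spread) by 1 − ρ and
reruns the PSA with common random numbers, so the probability is monotone in
ρ and the ρ = 0 row equals the baseline PSA.

The model has no hazard-ratio term, so no log-normal HR channel exists in
the PSA; survival-curve uncertainty is propagated (when fitted curves are
used) by resampling the fitted parameters from a normal on the fit scale
with the MLE covariance.

## Synthetic trial generator

`simulate_trial` draws PFS times from a chosen family and adds an
independent exponential post-progression residual for OS — guaranteeing the
OS curve dominates PFS by construction — applies administrative censoring
and optional exponential dropout, and digitizes the resulting KM curves on a
regular grid offset by half a step from the risk-table times (as real
digitization clicks fall between table rows). Default study conditions
mirror a first-line metastatic NSCLC trial arm: n ≈ 260–290 per arm,
24–31 months of follow-up, 3-month risk-table spacing, 0.5-month
digitization grid. What the generator does *not* emulate: correlated
PFS/OS sampling beyond the additive construction, non-proportional dropout,
digitization noise (coordinates are exact step-curve values), and reading
error in the risk table — so passing recovery tests show the pipeline's
correctness, not robustness to sloppy digitization.

## Numerical choices and degenerate inputs

* Transition probabilities are clamped to [0, 1]; occupancies below −1e−9
  abort the trace (a symptom of badly crossing curves).
* An empty PD state defines P_PD→PD = 1 (no mass to move).
* A family that fails to converge is excluded from AIC selection with a
  recorded failure; all-failed selection raises.
* Data with zero events refuse to fit (`FitError`), which is how a
  degenerate all-censored trial propagates.
* Gompertz with |shape| < 1e−12 falls back to its exponential limit.
* ICER with ΔQALY = 0 is flagged undefined rather than infinite; sign
  disagreements set dominance flags.

## Problem sizes

The test suite and analysis scripts run the full 174-cycle model everywhere
(it is millisecond-scale). Stochastic stages use n = 200–1,000 subjects per
simulated arm, 50 replicates per family for the selection-accuracy study,
and 1,000 PSA iterations — the same order as the source analysis.

## Known limitations

* The three-state structure cannot represent treatment beyond progression
  or re-challenge; second-line therapy is a cost stream, not a state.
* Partitioned-survival-style pinning to S_PFS/S_OS means background
  mortality never shortens projected survival; it only relabels routes to
  death. A setting where other-cause mortality should dominate the tail
  would need cause-specific hazards instead.
* Monetary conclusions inherit the synthetic cost configuration; only
  survival-side outputs (LY, QALY) and increment arithmetic are anchored to
  published values.
* AIC selection is the only goodness-of-fit criterion implemented; the
  visual-inspection step of the original workflow is out of scope.
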