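"""Published survival-model parameters for the IMpower110 populations.

Best-fitting parametric survival models (time in months) for progression-free
and overall survival, per arm, in the three PD-L1 expression populations of
the IMpower110 trial, as selected by AIC in the source cost-effectiveness
analysis. These are model *inputs*: the alternative entry point that bypasses
curve reconstruction and refitting.

Health-state utilities, discounting and the willingness-to-pay threshold of
the Chinese setting are included alongside.
"""

from __future__ import annotations

from .survival import ParametricSurvival

POPULATIONS = ("high", "high_or_intermediate", "any")
ARMS = ("atezolizumab", "chemotherapy")

#: (population, arm, endpoint) -> (family, params)
SURVIVAL_PARAMS = {
    ("high", "atezolizumab", "pfs"): ("log_normal", {"meanlog": 2.098, "sdlog": 1.494}),
    ("high", "atezolizumab", "os"): ("log_normal", {"meanlog": 3.180, "sdlog": 2.002}),
    ("high", "chemotherapy", "pfs"): ("log_logistic", {"shape": 1.724, "scale": 4.995}),
    ("high", "chemotherapy", "os"): ("log_logistic", {"shape": 1.407, "scale": 11.610}),
    ("high_or_intermediate", "atezolizumab", "pfs"): ("log_normal", {"meanlog": 1.971, "sdlog": 1.312}),
    ("high_or_intermediate", "atezolizumab", "os"): ("gompertz", {"shape": -0.020, "rate": 0.043}),
    ("high_or_intermediate", "chemotherapy", "pfs"): ("log_logistic", {"shape": 1.902, "scale": 5.188}),
    ("high_or_intermediate", "chemotherapy", "os"): ("log_logistic", {"shape": 1.538, "scale": 13.316}),
    ("any", "atezolizumab", "pfs"): ("log_normal", {"meanlog": 1.798, "sdlog": 1.321}),
    ("any", "atezolizumab", "os"): ("log_logistic", {"shape": 1.117, "scale": 17.245}),
    ("any", "chemotherapy", "pfs"): ("log_logistic", {"shape": 1.919, "scale": 5.279}),
    ("any", "chemotherapy", "os"): ("log_logistic", {"shape": 1.503, "scale": 13.17}),
}

#: health-state utilities (PFS, progressed disease, death)
UTILITY_PFS = 0.804
UTILITY_PD = 0.321

#: annual discount rate for costs and QALYs (Chinese pharmacoeconomic guideline)
DISCOUNT_RATE_ANNUAL = 0.05

#: willingness-to-pay threshold, USD/QALY (3× China 2019 per-capita GDP)
WTP_USD_PER_QALY = 30828.0

#: 2019 exchange rate used to convert local charges
CNY_PER_USD = 6.899

#: body surface area of the reference patient, m² (165 cm / 65 kg)
BSA_M2 = 1.72


def survival_model(population: str, arm: str, endpoint: str) -> ParametricSurvival:
    """The published best-fitting curve for (population, arm, endpoint)."""
    if population not in POPULATIONS:
        raise KeyError(f"population must be one of {POPULATIONS}")
    if arm not in ARMS:
        raise KeyError(f"arm must be one of {ARMS}")
    family, params = SURVIVAL_PARAMS[(population, arm, endpoint)]
    return ParametricSurvival(family, dict(params))


def curves(population: str, arm: str) -> tuple[ParametricSurvival, ParametricSurvival]:
    """(PFS, OS) curve pair for one arm of one population."""
    return (
        survival_model(population, arm, "pfs"),
        survival_model(population, arm, "os"),
    )
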