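from dataclasses import replace

import numpy as np
import pytest

from nsclc_cea import impower110
from nsclc_cea.economics import (
    SAE,
    ICERResult,
    PAPSchedule,
    StrategyConfig,
    UtilitySet,
    accumulate,
    chemo_dose_mg,
    drug_cost_at_cycle,
    icer,
    sae_filter,
    with_pap,
)
from nsclc_cea.markov import ModelSettings, trace_from_curves


@pytest.fixture(scope="module")
def chemo_trace():
    return trace_from_curves(*impower110.curves("high", "chemotherapy"))


def _cfg(**kw):
    base = dict(arm_label="t", drug_cost_per_cycle=100.0)
    base.update(kw)
    return StrategyConfig(**base)


# -- SAE rule ----------------------------------------------------------------


def test_sae_filter_threshold():
    keep = SAE("a", 0.10, 0.05, 1000.0)
    drop = SAE("b", 0.04, 0.02, 1000.0)
    edge = SAE("c", 0.06, 0.03, 1000.0)  # difference exactly 3%
    out = sae_filter([keep, drop, edge])
    assert [s.name for s in out] == ["a", "c"]
    assert len(sae_filter([keep, drop, edge], threshold=0.0)) == 3


# -- dosing / PAP schedule ---------------------------------------------------


def test_bsa_dosing_helper():
    assert chemo_dose_mg(75.0) == pytest.approx(129.0)  # cisplatin 75 mg/m² × 1.72
    with pytest.raises(ValueError):
        chemo_dose_mg(-1.0)


def test_pap_pattern_two_paid_three_free():
    cfg = _cfg(pap=PAPSchedule())
    costs = [drug_cost_at_cycle(cfg, k) for k in range(1, 11)]
    assert costs == [100, 100, 0, 0, 0, 100, 100, 0, 0, 0]


def test_no_pap_charges_every_cycle():
    cfg = _cfg()
    assert all(drug_cost_at_cycle(cfg, k) == 100.0 for k in range(1, 11))


def test_max_treatment_cycles_caps_cost():
    cfg = _cfg(max_treatment_cycles=4)
    assert drug_cost_at_cycle(cfg, 4) == 100.0
    assert drug_cost_at_cycle(cfg, 5) == 0.0


def test_nonrepeating_pap_stops_after_one_period():
    cfg = _cfg(pap=PAPSchedule(repeating=False))
    costs = [drug_cost_at_cycle(cfg, k) for k in range(1, 8)]
    assert costs == [100, 100, 0, 0, 0, 0, 0]


# -- accumulation ------------------------------------------------------------


def test_zero_discount_equals_plain_sums(chemo_trace):
    cfg = _cfg(supportive_care_cost_per_cycle=50.0, end_of_life_cost=500.0)
    res = accumulate(chemo_trace, cfg, UtilitySet(), discount_rate=0.0)
    mu = chemo_trace.settings.cycle_length
    occ0 = chemo_trace.n_pfs[:-1]
    expected_drug = float(np.sum(100.0 * occ0))
    assert res.breakdown["drug"].sum() == pytest.approx(expected_drug)
    q = chemo_trace.n_pfs * 0.804 + chemo_trace.n_pd * 0.321
    expected_qaly = float(np.sum((q[:-1] + q[1:]) / 2 * mu / 12))
    assert res.total_qaly == pytest.approx(expected_qaly)


def test_cost_linearity(chemo_trace):
    cfg = _cfg(
        supportive_care_cost_per_cycle=50.0,
        followup_cost_per_cycle=20.0,
        end_of_life_cost=500.0,
        second_line_fraction=0.5,
        second_line_cost_per_cycle=40.0,
        sae_incidences=(0.1,),
        sae_costs=(1000.0,),
        sae_disutilities=(0.0,),
    )
    doubled = replace(
        cfg,
        drug_cost_per_cycle=200.0,
        supportive_care_cost_per_cycle=100.0,
        followup_cost_per_cycle=40.0,
        end_of_life_cost=1000.0,
        second_line_cost_per_cycle=80.0,
        sae_costs=(2000.0,),
    )
    a = accumulate(chemo_trace, cfg, UtilitySet())
    b = accumulate(chemo_trace, doubled, UtilitySet())
    assert b.total_cost == pytest.approx(2 * a.total_cost, rel=1e-12)
    assert b.total_qaly == pytest.approx(a.total_qaly)


def test_qaly_bounded_by_ly_and_discounting_shrinks(chemo_trace):
    cfg = _cfg()
    res = accumulate(chemo_trace, cfg, UtilitySet(), discount_rate=0.05)
    undisc = accumulate(chemo_trace, cfg, UtilitySet(), discount_rate=0.0)
    assert res.total_qaly <= res.total_ly
    assert res.total_qaly < undisc.total_qaly


def test_full_utility_no_discount_makes_qaly_equal_ly(chemo_trace):
    res = accumulate(chemo_trace, _cfg(), UtilitySet(1.0, 1.0), discount_rate=0.0)
    assert res.total_qaly == pytest.approx(res.total_ly, rel=1e-12)


def test_sae_disutility_reduces_qaly_once(chemo_trace):
    base = accumulate(chemo_trace, _cfg(), UtilitySet(), 0.0)
    hit = accumulate(
        chemo_trace,
        _cfg(sae_incidences=(0.5,), sae_costs=(0.0,), sae_disutilities=(0.1,)),
        UtilitySet(),
        0.0,
    )
    assert base.total_qaly - hit.total_qaly == pytest.approx(0.05)


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        _cfg(drug_cost_per_cycle=-1.0)
    with pytest.raises(ValueError):
        UtilitySet(1.2, 0.3)


# -- ICER --------------------------------------------------------------------


def _res(cost, qaly):
    from nsclc_cea.economics import EconomicResult

    return EconomicResult("x", cost, qaly, qaly)


def test_icer_arithmetic():
    r = icer(_res(100.0, 1.0), _res(50.0, 0.5))
    assert r.icer == pytest.approx(100.0)
    assert not r.dominant and not r.dominated


def test_icer_undefined_for_equal_qalys():
    r = icer(_res(100.0, 1.0), _res(50.0, 1.0))
    assert r.icer is None and r.delta_qaly == 0.0


def test_dominance_flags():
    assert icer(_res(40.0, 1.0), _res(50.0, 0.5)).dominant
    assert icer(_res(60.0, 0.4), _res(50.0, 0.5)).dominated


def test_icer_invariant_to_shared_cost_stream(chemo_trace):
    """A cost hitting both arms identically (same SAE, same incidence and
    price) cancels in the increments and leaves the ICER unchanged."""
    pfs, os_ = impower110.curves("high", "atezolizumab")
    tr_t = trace_from_curves(pfs, os_)
    util = UtilitySet()
    results = []
    for shared_cost in (0.0, 5000.0):
        sae = dict(sae_incidences=(0.4,), sae_costs=(shared_cost,),
                   sae_disutilities=(0.0,))
        cfg_t = _cfg(arm_label="t", drug_cost_per_cycle=500.0, **sae)
        cfg_c = _cfg(arm_label="c", drug_cost_per_cycle=100.0, **sae)
        results.append(
            icer(accumulate(tr_t, cfg_t, util), accumulate(chemo_trace, cfg_c, util))
        )
    base, shifted = results
    assert shifted.delta_cost == pytest.approx(base.delta_cost, abs=1e-9)
    assert shifted.icer == pytest.approx(base.icer, rel=1e-12)


def test_with_pap_lowers_treatment_cost(chemo_trace):
    base = accumulate(chemo_trace, _cfg(), UtilitySet())
    papped = accumulate(chemo_trace, with_pap(_cfg()), UtilitySet())
    assert papped.total_cost < base.total_cost


def test_nmb():
    r = ICERResult(delta_cost=100.0, delta_qaly=0.01, icer=10000.0)
    assert r.nmb(30828.0) == pytest.approx(30828.0 * 0.01 - 100.0)
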