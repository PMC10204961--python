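"""Per-condition proteome/physiology integration: f-factor, direct
enzyme bounds with pool subtraction, flexibilization, exchange windows."""

import numpy as np
import pandas as pd
import pytest

from ecflux import ec, optimize
from ecflux.condition import (
    DEFAULT_TOLERANCES,
    PhysiologyData,
    compute_f_factor,
    constrain_enzymes,
    flexibilize,
    select_constrained_enzymes,
    set_exchange_windows,
)
from ecflux.ec import POOL_RXN
from ecflux.proteomics import MSRecord, tpa_quantify


def _sample(conc):
    heavy = 1e6
    recs = [
        MSRecord(pid, ibaq_heavy=heavy, ratio_hl=heavy / (c * 100.0), mw=50.0)
        for pid, c in conc.items()
    ]
    return tpa_quantify(recs)


def test_f_is_one_when_everything_is_model_enzyme():
    sample = _sample({"E_A": 1.0, "E_B": 3.0})
    assert compute_f_factor(sample, ["E_A", "E_B"]) == pytest.approx(1.0)


def test_f_is_the_enzyme_mass_share():
    # enzymes hold 250,000 ug/g of the quantified proteome -> f = 0.25
    sample = _sample({"E_A": 1.0, "other": 3.0})
    assert compute_f_factor(sample, ["E_A"]) == pytest.approx(0.25)


def test_f_unchanged_by_downstream_sd_filtering(glucose_proteome, glucose_model):
    """f is computed on the unfiltered quantification, so dropping noisy
    records afterwards cannot change it."""
    ids = [e.id for e in glucose_model.enzymes]
    before = compute_f_factor(glucose_proteome, ids)
    filtered = glucose_proteome
    keep = filtered.sd <= filtered.conc  # the SD-based record filter
    assert compute_f_factor(glucose_proteome, ids) == before
    assert before == pytest.approx(0.2, abs=0.05)


# -- constrain_enzymes -----------------------------------------------------

def test_pool_is_direct_subtraction(conditioned_ec):
    cov = conditioned_ec["coverage"]
    assert cov["pool_ub_g_gdcw"] == pytest.approx(
        cov["enzyme_budget_g_gdcw"] - cov["measured_mass_g_gdcw"]
    )


def test_mass_identity_holds_exactly(conditioned_ec):
    """sum(measured bound * MW) + pool_ub == sigma * f * Ptot."""
    ecm = conditioned_ec["ec"]
    enz_map = ecm.model.enzyme_map
    measured_mass = sum(b * enz_map[e].mw for e, b in ecm.measured.items())
    # the pool reaction carries the +-10% sampling window; the identity is
    # against the pre-window pool bound recorded in the coverage report
    pool = conditioned_ec["coverage"]["pool_ub_g_gdcw"]
    flex_released = sum(
        r.old_bound * enz_map[r.enzyme_id].mw
        for r in conditioned_ec["flex"] if r.action == "release"
    )
    assert measured_mass + pool + flex_released == pytest.approx(
        ecm.sigma * ecm.f * ecm.ptot, rel=1e-12
    )


def test_no_measured_enzymes_degenerates_to_pure_pool(glucose_truth, conditioned_ec):
    physiology, truth = glucose_truth
    base_ec = conditioned_ec["ec"]
    fresh, cov = constrain_enzymes(
        base_ec, {}, ptot=physiology.ptot, f=truth.f
    )
    assert cov["n_measured"] == 0
    assert cov["pool_ub_g_gdcw"] == pytest.approx(cov["enzyme_budget_g_gdcw"])


def test_overbudget_measurements_raise(glucose_truth, conditioned_ec):
    physiology, truth = glucose_truth
    huge = {e: 1.0 for e in conditioned_ec["ec"].enzyme_ids}
    with pytest.raises(ValueError, match="rescale Ptot|sigma"):
        constrain_enzymes(conditioned_ec["ec"], huge, ptot=physiology.ptot,
                          f=truth.f)


def test_selection_respects_budget_fraction(glucose_truth, glucose_proteome,
                                            conditioned_ec):
    physiology, truth = glucose_truth
    ecm = conditioned_ec["ec"]
    from ecflux.proteomics import to_molar

    molar = to_molar(glucose_proteome, ptot=physiology.ptot,
                     proteins=[e for e in ecm.enzyme_ids
                               if e in glucose_proteome.conc.index])
    chosen = select_constrained_enzymes(molar, ecm, f=truth.f,
                                        ptot=physiology.ptot,
                                        budget_fraction=0.5)
    enz_map = ecm.model.enzyme_map
    mass = sum(c * enz_map[e].mw for e, c in chosen.items())
    assert mass <= 0.5 * ecm.sigma * truth.f * physiology.ptot + 1e-12


# -- flexibilization -------------------------------------------------------

def test_planted_single_limitation_needs_one_record(conditioned_ec):
    """Cutting one measured bound below its flux demand forces exactly one
    relaxation, and undoing it makes the target infeasible again
    (minimal-greedy property)."""
    ecm = conditioned_ec["ec_prewindow"].copy()
    physiology = conditioned_ec["physiology"]
    sol = ecm.fba()
    # pick a measured enzyme whose usage is substantial
    usage = {e: sol.flux["usage_" + e] for e in ecm.measured}
    enz = max(usage, key=usage.get)
    rxn = ecm.usage_reaction(enz)
    rxn.ub = 0.5 * usage[enz]
    ecm.measured[enz] = rxn.ub
    capped_mu = ecm.fba().objective_value
    assert capped_mu < physiology.mu * 0.99
    relaxed, records = flexibilize(ecm, physiology.mu * 0.995)
    assert len(records) == 1 and records[0].enzyme_id == enz
    assert relaxed.fba().objective_value >= physiology.mu * 0.99
    # undoing the relaxation restores the infeasibility
    assert capped_mu < physiology.mu * 0.99


def test_feasible_target_needs_no_relaxation(conditioned_ec):
    ecm = conditioned_ec["ec"]
    _, records = flexibilize(ecm, 1e-6)
    assert records == []


def test_flexibilization_never_lowers_bounds():
    from ecflux.condition import FlexibilizationRecord

    with pytest.raises(ValueError):
        FlexibilizationRecord("E", old_bound=1.0, new_bound=0.5, step=1,
                              action="sd")


# -- exchange windows ------------------------------------------------------

def test_window_arithmetic(conditioned_ec):
    """1% on uptake: 10 mmol/gDCW/h -> [9.9, 10.1]; 10% on byproducts."""
    assert DEFAULT_TOLERANCES["uptake"] == 0.01
    assert DEFAULT_TOLERANCES["byproduct"] == 0.10
    ecm = conditioned_ec["ec"]
    physiology = conditioned_ec["physiology"]
    uptake = physiology.uptake["EX_glc"]
    rev = ecm.model.get_reaction("EX_glc_REV")
    assert rev.lb == pytest.approx(uptake * 0.99)
    assert rev.ub == pytest.approx(uptake * 1.01)
    co2 = ecm.model.get_reaction("EX_co2")
    assert co2.lb == pytest.approx(physiology.co2 * 0.90)
    assert co2.ub == pytest.approx(physiology.co2 * 1.10)
    growth = ecm.model.get_reaction(ecm.model.objective)
    assert growth.lb == pytest.approx(physiology.mu * 0.99)


def test_windows_do_not_cross_zero(conditioned_ec):
    ecm = conditioned_ec["ec"]
    for rid in ("EX_glc_REV", "EX_co2", "EX_o2_REV", POOL_RXN):
        rxn = ecm.model.get_reaction(rid)
        assert rxn.lb > 0.0


def test_missing_exchange_rate_raises(conditioned_ec):
    physiology = PhysiologyData(condition="x", mu=0.1,
                                uptake={"EX_missing": 1.0}, ngam=1.0)
    with pytest.raises(KeyError, match="EX_missing"):
        set_exchange_windows(conditioned_ec["ec"], physiology)
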