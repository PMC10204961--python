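"""Derived quantities: normalised fluxes, apparent turnover, cofactor
turnover and the NADPH trade-off table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecflux.analysis import (
    cofactor_turnover,
    compute_kapp,
    normalize_by_uptake,
    tradeoff_report,
)
from ecflux.sampling import map_to_base
from ecflux.model import MetabolicModel, Metabolite, Reaction


def test_normalized_flux_percentage():
    assert normalize_by_uptake({"r": 7.2}, 10.0)["r"] == pytest.approx(72.0)
    assert normalize_by_uptake({"r": 0.0}, 10.0)["r"] == 0.0


@settings(max_examples=25, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1e3))
def test_normalization_invariant_to_joint_scaling(c):
    base = normalize_by_uptake({"a": 3.0, "b": -1.5}, 6.0)
    scaled = normalize_by_uptake({"a": 3.0 * c, "b": -1.5 * c}, 6.0 * c)
    for k in base:
        assert scaled[k] == pytest.approx(base[k])


def test_substrate_exchange_normalizes_to_100(conditioned_ec,
                                              glucose_sample_2000):
    physiology = conditioned_ec["physiology"]
    net = map_to_base(glucose_sample_2000, conditioned_ec["ec"])
    values = normalize_by_uptake(net.median(axis=0).to_dict(),
                                 physiology.uptake["EX_glc"])
    assert abs(values["EX_glc"]) == pytest.approx(100.0, rel=0.02)


def test_kapp_inverse_of_capacity_example(conditioned_ec):
    """v = 0.36 mmol/gDCW/h at E = 1e-5 mmol/gDCW gives k_app = 10 1/s."""
    ecm = conditioned_ec["ec"]
    table = compute_kapp({"HXK": 0.36}, ecm, {"E_HXK": 1e-5})
    got = table[table["reaction"] == "HXK"]["kapp_per_s"]
    assert len(got) and np.allclose(got, 10.0)


def test_kapp_zero_flux_and_unmeasured_exclusion(conditioned_ec):
    ecm = conditioned_ec["ec"]
    table = compute_kapp({}, ecm, {"E_XPK": 1e-5})
    measured = table[table["enzyme"] == "E_XPK"]
    assert (measured["kapp_per_s"] == 0.0).all()
    others = table[table["enzyme"] != "E_XPK"]
    assert (others["excluded"] == "unmeasured").all()
    assert others["kapp_per_s"].isna().all()


def test_kapp_never_exceeds_kcat_on_sampled_medians(conditioned_ec,
                                                    glucose_sample_2000,
                                                    glucose_proteome):
    from ecflux.proteomics import to_molar

    ecm = conditioned_ec["ec"]
    physiology = conditioned_ec["physiology"]
    truth = conditioned_ec["truth"]
    net = map_to_base(glucose_sample_2000, ecm).median(axis=0)
    molar = to_molar(glucose_proteome, ptot=physiology.ptot,
                     proteins=truth.measured_ids)
    table = compute_kapp(net.to_dict(), ecm, molar).dropna(subset=["kapp_per_s"])
    assert (table["kapp_per_s"] <= table["kcat_per_s"] + 1e-9).all()


# -- cofactor turnover -----------------------------------------------------

def _cofactor_model():
    return MetabolicModel(
        id="cf",
        metabolites=[Metabolite("nadph_c", "NADPH", "c"),
                     Metabolite("s_c", "s", "c")],
        reactions=[
            Reaction("P1", {"s_c": -1, "nadph_c": 1}, lb=0.0),
            Reaction("P2", {"s_c": -1, "nadph_c": 1}, lb=0.0),
            Reaction("C1", {"nadph_c": -1, "s_c": 1}, lb=0.0),
            Reaction("EX_s", {"s_c": -1}, lb=-10.0, ub=10.0),
        ],
        compartments={"c": "c"},
    )


def test_turnover_shares_and_yield():
    report = cofactor_turnover({"P1": 3.0, "P2": 2.0, "C1": 5.0},
                               _cofactor_model(), "nadph", uptake=10.0)
    assert report.turnover == pytest.approx(5.0)
    assert report.yield_per_substrate == pytest.approx(0.5)
    prod = report.shares[report.shares["side"] == "production"]
    assert sorted(prod["pct_of_turnover"]) == pytest.approx([40.0, 60.0])


def test_no_cofactor_reactions_means_zero_turnover():
    report = cofactor_turnover({"EX_s": 1.0}, _cofactor_model(), "atp",
                               uptake=1.0)
    assert report.turnover == 0.0


def test_production_equals_consumption_on_every_sampled_row(
        conditioned_ec, glucose_sample_2000):
    ecm = conditioned_ec["ec"]
    net = map_to_base(glucose_sample_2000, ecm)
    for i in range(0, len(net), 200):
        row = net.iloc[i].to_dict()
        for met in ("nadph", "nadh", "atp"):
            report = cofactor_turnover(row, ecm.base, met, uptake=1.0)
            prod = report.shares.query("side == 'production'")["rate"].sum()
            cons = -report.shares.query("side == 'consumption'")["rate"].sum()
            assert prod == pytest.approx(cons, abs=1e-6)


def test_turnover_invariant_to_forward_reverse_representation():
    model = _cofactor_model()
    rep_net = cofactor_turnover({"P1": 3.0, "C1": 3.0}, model, "nadph", 1.0)
    # the same physiology written with P2 as a "reverse" of C1 (flux signs)
    rep_alt = cofactor_turnover({"P1": 3.0, "P2": 0.0, "C1": 3.0}, model,
                                "nadph", 1.0)
    assert rep_net.turnover == pytest.approx(rep_alt.turnover)


# -- trade-off table -------------------------------------------------------

def _planted_turnover(gdh_share, fas_share):
    """A flux vector whose NADPH consumption shares are exactly planted."""
    model = MetabolicModel(
        id="t",
        metabolites=[Metabolite("nadph_c", "NADPH", "c"),
                     Metabolite("x_c", "x", "c")],
        reactions=[
            Reaction("ZWF", {"x_c": -1, "nadph_c": 1}, lb=0.0),
            Reaction("GDH1", {"nadph_c": -1, "x_c": 1}, lb=0.0),
            Reaction("FAS", {"nadph_c": -1, "x_c": 1}, lb=0.0),
            Reaction("OTHER", {"nadph_c": -1, "x_c": 1}, lb=0.0),
        ],
        compartments={"c": "c"},
    )
    total = 100.0
    flux = {"ZWF": total, "GDH1": gdh_share, "FAS": fas_share,
            "OTHER": total - gdh_share - fas_share}
    return cofactor_turnover(flux, model, "nadph", uptake=10.0)


def test_planted_exp_like_shares_recovered():
    """Nutrient-excess-like allocation: 46% of NADPH to glutamate
    dehydrogenase, 13% to fatty-acid synthase."""
    report = _planted_turnover(46.0, 13.0)
    table = tradeoff_report({"exp": report}, ["GDH1", "FAS"])
    assert table.loc[0, "GDH1"] == pytest.approx(46.0)
    assert table.loc[0, "FAS"] == pytest.approx(13.0)
    assert table.loc[0, "dominant_consumer"] == "GDH1"


def test_dominant_consumer_switch_flagged():
    table = tradeoff_report(
        {"exp": _planted_turnover(46.0, 13.0),
         "nlim": _planted_turnover(12.0, 75.0)},
        ["GDH1", "FAS"],
    )
    assert not table.loc[0, "dominant_switched"]
    assert bool(table.loc[1, "dominant_switched"])
    assert table.loc[1, "dominant_consumer"] == "FAS"


def test_single_consumer_gets_all():
    model = _cofactor_model()
    report = cofactor_turnover({"P1": 5.0, "C1": 5.0}, model, "nadph", 1.0)
    table = tradeoff_report({"c": report}, ["C1"])
    assert table.loc[0, "C1"] == pytest.approx(100.0)


def test_consumption_shares_sum_to_100(conditioned_ec, glucose_sample_2000):
    ecm = conditioned_ec["ec"]
    net = map_to_base(glucose_sample_2000, ecm).median(axis=0).to_dict()
    report = cofactor_turnover(net, ecm.base, "nadph", uptake=1.0)
    cons = report.shares.query("side == 'consumption'")["pct_of_turnover"].sum()
    assert cons == pytest.approx(100.0, abs=0.1)
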