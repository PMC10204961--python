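"""GECKO-style transforms: reversibility splitting, isozyme expansion,
stepwise kcat matching, pool construction, sensitivity and curation."""

import numpy as np
import pytest

from ecflux import ec, optimize
from ecflux.ec import (
    CurationEntry,
    KcatRecord,
    apply_kcat_curation,
    build_ec_model,
    db_max_kcat,
    expand_isozymes,
    match_kcats,
    sensitivity_top_kcat,
    split_reversible,
    top_used_enzymes,
)
from ecflux.model import Enzyme, MetabolicModel, Metabolite, Reaction
from ecflux.synthetic import ToySpec, kcat_database, make_toy_network, simulate_condition
from ecflux.biomass import rescale_biomass

ORGANISM = "Rhodotorula toruloides"


def test_split_reversible_bounds_and_counts(glucose_model):
    split = split_reversible(glucose_model)
    assert all(r.lb >= 0 for r in split.reactions)
    pgi_f = split.get_reaction("PGI")
    pgi_r = split.get_reaction("PGI_REV")
    assert (pgi_f.lb, pgi_f.ub) == (0.0, 1000.0)
    assert (pgi_r.lb, pgi_r.ub) == (0.0, 1000.0)
    assert pgi_r.stoich == {k: -v for k, v in pgi_f.stoich.items()}
    n_reversible = sum(1 for r in glucose_model.reactions if r.lb < 0 and r.ub > 0)
    assert len(split.reactions) == len(glucose_model.reactions) + n_reversible


def test_split_is_identity_on_irreversible_model(chain_model):
    split = split_reversible(chain_model)
    # the chain's substrate exchange has lb < 0 (uptake); everything else stays
    rev = [r for r in chain_model.reactions if r.lb < 0]
    assert len(split.reactions) == len(chain_model.reactions) + sum(
        1 for r in rev if r.ub > 0
    )


def test_split_preserves_fba_optimum(glucose_model):
    before = optimize.fba(glucose_model).objective_value
    after = optimize.fba(split_reversible(glucose_model)).objective_value
    assert after == pytest.approx(before, rel=1e-6)


def test_expand_isozymes_counts(glucose_model):
    split = split_reversible(glucose_model)
    expanded = expand_isozymes(split)
    # ACO (2 isozymes, reversible -> 2 copies each direction): per direction
    # +1 arm, +1 pseudo-metabolite, 2 copies replacing the original
    multi = [r for r in split.reactions if len(r.gene_rule) >= 2]
    extra_rxns = sum(len(r.gene_rule) for r in multi)  # arm + N copies - original
    assert len(expanded.reactions) == len(split.reactions) + extra_rxns
    assert len(expanded.metabolites) == len(split.metabolites) + len(multi)
    assert "arm_ACO" in expanded.reaction_ids
    assert {"ACO_No1", "ACO_No2"} <= set(expanded.reaction_ids)
    single = expanded.get_reaction("XPK")
    assert single.gene_rule == [["E_XPK"]]


def test_arm_flux_equals_sum_of_copies(glucose_model):
    expanded = expand_isozymes(split_reversible(glucose_model))
    sol = optimize.fba(expanded)
    assert sol.status == "optimal"
    assert sol.flux["arm_ACO"] == pytest.approx(
        sol.flux["ACO_No1"] + sol.flux["ACO_No2"], abs=1e-8
    )


# -- kcat matching ---------------------------------------------------------

def _one_reaction_model(ec_number="1.1.1.1"):
    return MetabolicModel(
        id="m",
        metabolites=[Metabolite("s_c", "substrate A", "c"),
                     Metabolite("p_c", "product", "c")],
        reactions=[Reaction("R", {"s_c": -1, "p_c": 1}, lb=0.0,
                            gene_rule=[["E1"]])],
        enzymes=[Enzyme("E1", ["g1"], mw=50.0, ec_numbers=[ec_number])],
        objective="R",
        compartments={"c": "c"},
    )


def test_exact_match_beats_larger_generic_hit():
    model = _one_reaction_model()
    db = [
        KcatRecord("1.1.1.1", "substrate A", ORGANISM, 50.0),
        KcatRecord("1.1.1.1", "other", "Escherichia coli", 500.0),
    ]
    kcats, prov = match_kcats(model, db, ORGANISM)
    assert kcats["R"]["E1"] == 50.0
    assert prov["R"]["E1"] == "ec+substrate+organism"


def test_cross_organism_hits_take_level_maximum():
    model = _one_reaction_model()
    db = [
        KcatRecord("1.1.1.1", "substrate A", "Yarrowia lipolytica", 3.0),
        KcatRecord("1.1.1.1", "substrate A", "Escherichia coli", 7.0),
    ]
    kcats, prov = match_kcats(model, db, ORGANISM)
    # exhaustive check: both records sit at the EC+substrate level; max wins
    assert kcats["R"]["E1"] == max(r.kcat for r in db)
    assert prov["R"]["E1"] == "ec+substrate"


def test_wildcard_level_matches_first_three_ec_fields():
    model = _one_reaction_model("1.1.1.1")
    db = [KcatRecord("1.1.1.99", "x", "y", 11.0)]
    kcats, prov = match_kcats(model, db, ORGANISM)
    assert kcats["R"]["E1"] == 11.0
    assert prov["R"]["E1"] == "ec-wildcard"


def test_no_shared_ec_class_leaves_enzyme_unconstrained():
    model = _one_reaction_model("1.1.1.1")
    db = [KcatRecord("2.7.1.1", "x", "y", 11.0)]
    kcats, _ = match_kcats(model, db, ORGANISM)
    assert "R" not in kcats


# -- EC model construction -------------------------------------------------

def _ec_toy(kcat=10.0, sigma=0.35, f=0.5, ptot=0.4):
    model = _one_reaction_model()
    model.reactions.append(Reaction("EX_s", {"s_c": 1}, lb=0.0, ub=1000.0))
    model.reactions.append(Reaction("EX_p", {"p_c": -1}, lb=0.0, ub=1000.0))
    return build_ec_model(model, {"R": {"E1": kcat}}, sigma=sigma, f=f, ptot=ptot)


def test_flux_cap_is_abundance_times_kcat():
    """E = 1e-5 mmol/gDCW at kcat 10 1/s caps the flux at 0.36 mmol/gDCW/h."""
    ecm = _ec_toy(kcat=10.0)
    usage = ecm.usage_reaction("E1")
    usage.stoich = {"prot_E1": 1.0}
    usage.ub = 1e-5
    sol = ecm.fba(objective="R")
    assert sol.objective_value == pytest.approx(1e-5 * 10.0 * 3600.0)


def test_pool_bound_is_sigma_f_ptot():
    ecm = _ec_toy(sigma=0.35, f=0.5, ptot=0.4)
    assert ecm.pool_ub == pytest.approx(0.07)


def test_infinite_pool_recovers_base_optimum(glucose_model):
    expanded = expand_isozymes(split_reversible(glucose_model))
    kcats, prov = match_kcats(expanded, kcat_database(), ORGANISM)
    ecm = build_ec_model(expanded, kcats, sigma=0.35, f=0.2, ptot=0.45)
    base_opt = optimize.fba(glucose_model).objective_value
    limited = ecm.fba().objective_value
    assert limited <= base_opt + 1e-9
    ecm.pool_ub = 1e6
    # the pathological fructose-bisphosphatase kcat still caps growth on
    # its own; lift it so only the pool limit is probed
    relaxed = apply_kcat_curation(ecm, [CurationEntry("E_FBP", 127.0)])
    assert relaxed.fba().objective_value == pytest.approx(base_opt, rel=1e-6)


def test_raising_kcat_never_decreases_optimum(conditioned_ec):
    ecm = conditioned_ec["ec"]
    before = ecm.fba().objective_value
    boosted = apply_kcat_curation(
        ecm, [CurationEntry("E_ACC", 2.0 * ecm.kcat_map["ACC"]["E_ACC"])]
    )
    assert boosted.fba().objective_value >= before - 1e-9


# -- curation --------------------------------------------------------------

def test_curation_rescales_coefficient_by_kcat_ratio():
    ecm = _ec_toy(kcat=0.002)
    coef_before = ecm.model.get_reaction("R").stoich["prot_E1"]
    cured = apply_kcat_curation(ecm, [CurationEntry("E1", 127.0)])
    coef_after = cured.model.get_reaction("R").stoich["prot_E1"]
    assert coef_before / coef_after == pytest.approx(127.0 / 0.002)
    assert cured.provenance["R"]["E1"] == "curated"


def test_empty_curation_is_identity():
    ecm = _ec_toy()
    cured = apply_kcat_curation(ecm, [])
    assert cured.kcat_map == ecm.kcat_map
    assert cured.model == ecm.model


def test_curation_commutes_with_build(glucose_model):
    """Curating the built model equals building from a curated database."""
    expanded = expand_isozymes(split_reversible(glucose_model))
    db = kcat_database()
    kcats, _ = match_kcats(expanded, db, ORGANISM)
    built_then_cured = apply_kcat_curation(
        build_ec_model(expanded, kcats, sigma=0.35, f=0.2, ptot=0.45),
        [CurationEntry("E_FBP", 127.0)],
    )
    kcats2 = {r: dict(per) for r, per in kcats.items()}
    for rid, per in kcats2.items():
        if "E_FBP" in per:
            per["E_FBP"] = 127.0
    cured_then_built = build_ec_model(expanded, kcats2, sigma=0.35, f=0.2, ptot=0.45)
    assert built_then_cured.kcat_map == cured_then_built.kcat_map
    for r1, r2 in zip(built_then_cured.model.reactions,
                      cured_then_built.model.reactions):
        assert r1.stoich == pytest.approx(r2.stoich)


# -- sensitivity loop ------------------------------------------------------

@pytest.fixture(scope="module")
def acetate_ec():
    spec = ToySpec(variant="acetate", phase="exp", seed=5,
                   proteomics_cv=0.0, rate_cv=0.0)
    model = make_toy_network(spec)
    physiology, truth = simulate_condition(model, spec)
    base = rescale_biomass(model, truth.composition)
    base.get_reaction("BIOMASS").stoich["atp_c"] = -truth.gam
    ex = base.get_reaction("EX_ac")
    ex.lb = ex.ub = -physiology.uptake["EX_ac"]
    expanded = expand_isozymes(split_reversible(base))
    db = kcat_database()
    kcats, prov = match_kcats(expanded, db, ORGANISM)
    ecm = build_ec_model(expanded, kcats, sigma=spec.sigma, f=truth.f,
                         ptot=physiology.ptot, provenance=prov)
    return ecm, truth, db


def test_limiting_kcat_identified_and_relaxed(acetate_ec):
    """Gluconeogenic growth is capped by the pathological 0.002 1/s
    fructose-bisphosphatase kcat; the sensitivity loop ranks it first and
    restores growth by raising it to the database maximum (127 1/s)."""
    ecm, truth, db = acetate_ec
    assert ecm.fba().objective_value < 0.1 * truth.mu
    relaxed, trace = sensitivity_top_kcat(ecm, truth.mu, db)
    assert trace and trace[0]["enzyme"] == "E_FBP"
    assert trace[0]["old_kcat"] == pytest.approx(0.002)
    assert trace[0]["new_kcat"] == pytest.approx(127.0)
    assert relaxed.fba().objective_value >= truth.mu * (1 - 1e-6)


def test_sensitivity_on_satisfied_target_is_empty(acetate_ec):
    ecm, truth, db = acetate_ec
    _, trace = sensitivity_top_kcat(ecm, 1e-6, db)
    assert trace == []


def test_equally_limiting_enzymes_tie_break_lexicographically():
    model = MetabolicModel(
        id="tie",
        metabolites=[Metabolite("s_c", "s", "c"), Metabolite("i_c", "i", "c"),
                     Metabolite("p_c", "p", "c")],
        reactions=[
            Reaction("EX_s", {"s_c": 1}, lb=0.0, ub=1000.0),
            Reaction("R1", {"s_c": -1, "i_c": 1}, lb=0.0, gene_rule=[["EA"]]),
            Reaction("R2", {"i_c": -1, "p_c": 1}, lb=0.0, gene_rule=[["EB"]]),
            Reaction("EX_p", {"p_c": -1}, lb=0.0, ub=1000.0),
        ],
        enzymes=[Enzyme("EA", mw=50.0, ec_numbers=["1.1.1.1"]),
                 Enzyme("EB", mw=50.0, ec_numbers=["1.1.1.2"])],
        objective="EX_p",
        compartments={"c": "c"},
    )
    db = [KcatRecord("1.1.1.1", "x", "y", 100.0), KcatRecord("1.1.1.2", "x", "y", 100.0)]
    ecm = build_ec_model(model, {"R1": {"EA": 1.0}, "R2": {"EB": 1.0}},
                         sigma=1.0, f=1.0, ptot=1e-4)
    _, trace = sensitivity_top_kcat(ecm, 1e9, db)
    assert trace[0]["enzyme"] == "EA"  # alphabetical among equal sensitivities


def test_db_max_kcat_uses_wildcarded_ec_class():
    enz = Enzyme("E", mw=1.0, ec_numbers=["1.1.1.1"])
    db = [KcatRecord("1.1.1.7", "x", "y", 42.0), KcatRecord("2.1.1.1", "x", "y", 99.0)]
    assert db_max_kcat(enz, db) == 42.0


# -- usage reporting -------------------------------------------------------

def test_top_used_enzymes_orders_and_flags(conditioned_ec):
    ecm = conditioned_ec["ec"]
    sol = ecm.fba()
    table = top_used_enzymes(ecm, sol, n=10)
    masses = table["mass_g_gdcw"].to_numpy()
    assert np.all(np.diff(masses) <= 1e-15)
    assert (table["flagged"] == (table["pct_of_pool"] > 1.0)).all()


def test_top_used_enzymes_handles_oversized_n(conditioned_ec):
    ecm = conditioned_ec["ec"]
    table = top_used_enzymes(ecm, ecm.fba(), n=10_000)
    assert len(table) == len(ecm.enzyme_ids)
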