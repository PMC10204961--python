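"""Shared fixtures: toy models, a fully conditioned EC model, and one
2000-iteration flux sample reused by the heavier suites."""

from __future__ import annotations

import numpy as np
import pytest

from ecflux import ec, condition as cond, proteomics as prot, sampling
from ecflux.biomass import rescale_biomass
from ecflux.model import MetabolicModel, Metabolite, Reaction
from ecflux.synthetic import (
    ToySpec,
    kcat_database,
    make_chain_model,
    make_toy_network,
    simulate_condition,
    simulate_proteomics,
)

ORGANISM = "Rhodotorula toruloides"


@pytest.fixture(scope="session")
def glucose_spec():
    return ToySpec(variant="glucose", phase="exp", seed=11,
                   proteomics_cv=0.0, rate_cv=0.0)


@pytest.fixture(scope="session")
def glucose_model(glucose_spec):
    return make_toy_network(glucose_spec)


@pytest.fixture(scope="session")
def glucose_truth(glucose_spec, glucose_model):
    physiology, truth = simulate_condition(glucose_model, glucose_spec)
    return physiology, truth


@pytest.fixture(scope="session")
def glucose_proteome(glucose_spec, glucose_truth):
    physiology, truth = glucose_truth
    records = simulate_proteomics(truth, glucose_spec)
    return prot.tpa_quantify(records, ptot=physiology.ptot)


@pytest.fixture(scope="session")
def conditioned_ec(glucose_spec, glucose_model, glucose_truth, glucose_proteome):
    """Glucose exp condition carried through the full integration chain."""
    physiology, truth = glucose_truth
    base = rescale_biomass(glucose_model, truth.composition)
    base.get_reaction("BIOMASS").stoich["atp_c"] = -truth.gam
    ngam = base.get_reaction("ATPM")
    ngam.lb = ngam.ub = truth.ngam
    irreversible = ec.expand_isozymes(ec.split_reversible(base))
    db = kcat_database()
    kcats, provenance = ec.match_kcats(irreversible, db, ORGANISM)
    ec_model = ec.build_ec_model(
        irreversible, kcats, sigma=glucose_spec.sigma, f=truth.f,
        ptot=physiology.ptot, provenance=provenance, base=base,
    )
    ec_model, _ = ec.sensitivity_top_kcat(ec_model, truth.mu, db)
    molar = prot.to_molar(glucose_proteome, ptot=physiology.ptot,
                          proteins=truth.measured_ids)
    ec_model, coverage = cond.constrain_enzymes(
        ec_model, molar, ptot=physiology.ptot, f=truth.f, sigma=glucose_spec.sigma
    )
    ec_model, flex = cond.flexibilize(ec_model, physiology.mu)
    prewindow = ec_model
    ec_model = cond.set_exchange_windows(ec_model, physiology)
    return {"ec": ec_model, "ec_prewindow": prewindow, "coverage": coverage,
            "flex": flex, "physiology": physiology, "truth": truth}


@pytest.fixture(scope="session")
def glucose_sample_2000(conditioned_ec):
    """One 2000-iteration sample of the conditioned glucose model."""
    return sampling.sample_fluxes(conditioned_ec["ec"], n_iter=2000, seed=17)


@pytest.fixture(scope="session")
def chain_model():
    return make_chain_model(n=4, uptake=10.0, yield_per_substrate=0.5)


def random_small_model(rng: np.random.Generator, n_rxns: int) -> MetabolicModel:
    """Random bounded model with <= 12 reactions, always feasible (v=0)."""
    n_mets = max(2, n_rxns // 2)
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        stoich = {}
        for i in rng.choice(n_mets, size=rng.integers(1, min(3, n_mets) + 1),
                            replace=False):
            coef = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            stoich[f"m{i}"] = float(coef)
        lb = 0.0 if rng.random() < 0.5 else -10.0
        rxns.append(Reaction(f"r{j}", stoich, lb=lb, ub=10.0))
    obj = f"r{int(rng.integers(0, n_rxns))}"
    model = MetabolicModel(id="rand", metabolites=mets, reactions=rxns,
                          objective=obj, compartments={"c": "c"})
    model.validate()
    return model
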