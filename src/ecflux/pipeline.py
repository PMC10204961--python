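"""End-to-end per-condition workflow.

Composes the stages — load, scenario, biomass rescaling, maintenance
fitting, structural EC transforms, kcat matching and curation, proteome
quantification and integration, flexibilization, exchange windows,
sampling, statistics, base-formalism mapping and derived analyses — and
writes the report TSVs plus a JSON run manifest. Identical config + seed
reproduce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import analysis, condition as cond, ec, optimize, proteomics as prot, sampling
from .biomass import BiomassComposition, fit_gam_ngam, rescale_biomass
from .io import load_model
from .model import apply_scenario

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    model_path: str
    kcat_db_path: str
    proteomics_path: str
    physiology_path: str
    condition: str = ""
    organism: str = "Rhodotorula toruloides"
    sigma: float = 0.35
    tolerances: Dict[str, float] = field(default_factory=dict)
    n_iter: int = 2000
    seed: int = 0
    scenario: str = "none"
    curation_path: Optional[str] = None
    gam: Optional[float] = None  # fitted from physiology when absent
    out_dir: str = "ecflux_out"
    turnover_metabolites: tuple = ("atp", "nadh", "nadph")
    tradeoff_reactions: tuple = ("GDH1", "FAS160", "FAS180")

    def validate(self) -> None:
        for name in ("model_path", "kcat_db_path", "proteomics_path",
                     "physiology_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _feasible(ec_model) -> bool:
    m = ec_model.model
    res = optimize.solve_lp(
        np.zeros(len(m.reactions)), m.stoichiometric_matrix(),
        np.zeros(len(m.metabolites)), *m.bounds_arrays(),
    )
    return res.status == 0


def _with_simulated_gas(ec_model, physiology: cond.PhysiologyData
                        ) -> cond.PhysiologyData:
    """Replace measured gas rates by the rates an FBA at the measured
    growth and uptake predicts."""
    import dataclasses

    probe = cond.set_exchange_windows(
        ec_model, dataclasses.replace(physiology, co2=0.0, o2=0.0)
    )
    sol = optimize.pfba(probe.model)
    if sol.status != "optimal":
        raise RuntimeError(
            "condition infeasible even without gas constraints; check the "
            "physiology and enzyme bounds"
        )
    net = sampling.map_to_base(sol, probe)
    return dataclasses.replace(
        physiology, co2=float(net["EX_co2"]), o2=float(-net["EX_o2"])
    )


def run_condition(config: RunConfig) -> Dict[str, object]:
    """Run the full per-condition workflow; returns the artifact bundle
    (paths of written reports and the key in-memory results)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = load_model(config.model_path)
    if config.scenario != "none":
        model = apply_scenario(model, config.scenario)
    physiology = cond.PhysiologyData.from_yaml(config.physiology_path)
    comp = BiomassComposition(
        protein=physiology.ptot, lipid=physiology.lipid,
        acyl_profile=dict(physiology.acyl_profile),
    )
    model = rescale_biomass(model, comp)

    if config.gam is None:
        gam, ngam = fit_gam_ngam(model, physiology)
    else:
        gam, ngam = config.gam, physiology.ngam
    biomass = model.get_reaction(model.objective)
    biomass.stoich["atp_c"] = -gam
    ngam_rxn = model.get_reaction("ATPM")
    ngam_rxn.lb = ngam_rxn.ub = ngam

    irreversible = ec.expand_isozymes(ec.split_reversible(model))
    kcat_db = ec.read_kcat_tsv(config.kcat_db_path)
    kcats, provenance = ec.match_kcats(irreversible, kcat_db, config.organism)

    records = prot.read_proteomics_tsv(config.proteomics_path)
    sample = prot.tpa_quantify(records, ptot=physiology.ptot)
    f_factor = cond.compute_f_factor(sample, model.enzymes)

    ec_model = ec.build_ec_model(
        irreversible, kcats, sigma=config.sigma, f=f_factor,
        ptot=physiology.ptot, provenance=provenance, base=model,
    )
    if config.curation_path:
        entries = ec.read_curation_tsv(config.curation_path)
        ec_model = ec.apply_kcat_curation(ec_model, entries)
    ec_model, kcat_trace = ec.sensitivity_top_kcat(ec_model, physiology.mu, kcat_db)

    molar_all = prot.to_molar(
        sample, ptot=physiology.ptot,
        proteins=[e for e in ec_model.enzyme_ids if e in sample.conc.index],
    )
    molar = cond.select_constrained_enzymes(
        molar_all, ec_model, f=f_factor, ptot=physiology.ptot, sigma=config.sigma
    )
    sd_molar = {
        e: sample.sd[e] / 1e6 * physiology.ptot / ec_model.model.get_enzyme(e).mw
        for e in molar
        if e in sample.sd.index
    }
    ec_model, coverage = cond.constrain_enzymes(
        ec_model, molar, ptot=physiology.ptot, f=f_factor, sigma=config.sigma,
        sd=sd_molar, ptot_sd=physiology.ptot_sd,
    )
    ec_model, flex_records = cond.flexibilize(ec_model, physiology.mu)
    windowed = cond.set_exchange_windows(ec_model, physiology, config.tolerances)
    gas_simulated = False
    if not _feasible(windowed):
        # measured gas rates can be inconsistent with the tight growth and
        # uptake windows; fall back to model-simulated gas exchange
        logger.warning(
            "windows infeasible with measured gas rates; constraining gas "
            "exchange with simulated values"
        )
        physiology = _with_simulated_gas(ec_model, physiology)
        windowed = cond.set_exchange_windows(ec_model, physiology, config.tolerances)
        gas_simulated = True
    ec_model = windowed

    flux_sample = sampling.sample_fluxes(
        ec_model, n_iter=config.n_iter, seed=config.seed
    )
    stats = sampling.flux_statistics(flux_sample)
    net_matrix = sampling.map_to_base(flux_sample, ec_model)
    net_median = net_matrix.median(axis=0)

    substrate_ex = next(iter(physiology.uptake))
    uptake = physiology.uptake[substrate_ex]
    normalized = analysis.normalize_by_uptake(net_median.to_dict(), uptake)
    kapp = analysis.compute_kapp(net_median.to_dict(), ec_model, molar_all)
    turnovers = {}
    for met in config.turnover_metabolites:
        turnovers[met] = analysis.cofactor_turnover(
            net_median.to_dict(), ec_model.base, met, uptake
        )
    condition_name = config.condition or physiology.condition
    tradeoff = analysis.tradeoff_report(
        {condition_name: turnovers["nadph"]}, list(config.tradeoff_reactions)
    )

    # -- reports ----------------------------------------------------------
    paths: Dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = out_dir / name
        df.to_csv(p, sep="\t", float_format=FLOAT_FMT, index=index)
        paths[name] = p

    proteome_df = pd.DataFrame(
        {"conc_ug_per_g": sample.conc, "sd_ug_per_g": sample.sd}
    )
    write("proteome.tsv", proteome_df)
    write("flux_summary.tsv", stats)
    net_df = pd.DataFrame(
        {"net_flux": net_median,
         "pct_of_uptake": pd.Series(normalized)}
    )
    write("normalized_flux.tsv", net_df)
    write("kapp.tsv", kapp, index=False)
    for met, rep in turnovers.items():
        df = rep.shares.copy()
        df.insert(0, "metabolite", met)
        df["turnover"] = rep.turnover
        df["yield_per_substrate"] = rep.yield_per_substrate
        write(f"turnover_{met}.tsv", df, index=False)
    write("tradeoff.tsv", tradeoff, index=False)

    manifest = {
        "condition": condition_name,
        "scenario": config.scenario,
        "seed": config.seed,
        "n_iter": config.n_iter,
        "sigma": config.sigma,
        "f_factor": f_factor,
        "gam_mmol_per_gdcw": gam,
        "ngam_mmol_per_gdcw_h": ngam,
        "tolerances": {**cond.DEFAULT_TOLERANCES, **config.tolerances},
        "gas_constrained_from_simulation": gas_simulated,
        "solver": optimize.SOLVER_SETTINGS,
        "n_reactions_constrained": len(ec_model.kcat_map),
        "n_enzymes_constrained": len(ec_model.enzyme_ids),
        "n_enzymes_measured": coverage["n_measured"],
        "pool_ub_g_gdcw": coverage["pool_ub_g_gdcw"],
        "kcat_sensitivity_trace": kcat_trace,
        "flexibilized_enzymes": [
            {"enzyme": r.enzyme_id, "old_bound": r.old_bound,
             "new_bound": r.new_bound, "step": r.step, "action": r.action}
            for r in flex_records
        ],
        "n_flexibilized": len(flex_records),
        "sampling_rows": int(flux_sample.matrix.shape[0]),
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    paths["manifest.json"] = manifest_path
    logger.info(
        "condition %s: %d enzymes constrained on %d reactions, %d measured, "
        "%d flexibilized",
        condition_name, len(ec_model.enzyme_ids), len(ec_model.kcat_map),
        coverage["n_measured"], len(flex_records),
    )
    return {
        "paths": paths,
        "ec_model": ec_model,
        "sample": flux_sample,
        "statistics": stats,
        "net_median": net_median,
        "turnovers": turnovers,
        "flexibilization": flex_records,
        "manifest": manifest,
    }


def write_simulation_bundle(spec, out_dir) -> Dict[str, Path]:
    """Generate a synthetic study bundle: model.json, physiology.yaml,
    proteomics.tsv, kcat_db.tsv, truth.json."""
    from . import synthetic
    from .io import write_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = synthetic.make_toy_network(spec)
    physiology, truth = synthetic.simulate_condition(model, spec)
    records = synthetic.simulate_proteomics(truth, spec)
    paths = {}
    write_model(model, out / "model.json")
    paths["model.json"] = out / "model.json"
    physiology.to_yaml(out / "physiology.yaml")
    paths["physiology.yaml"] = out / "physiology.yaml"
    synthetic.write_proteomics_tsv(records, out / "proteomics.tsv")
    paths["proteomics.tsv"] = out / "proteomics.tsv"
    ec.write_kcat_tsv(synthetic.kcat_database(), out / "kcat_db.tsv")
    paths["kcat_db.tsv"] = out / "kcat_db.tsv"
    truth_doc = {
        "mu": truth.mu,
        "f": truth.f,
        "gam": truth.gam,
        "ngam": truth.ngam,
        "translation_rate_aa_s": truth.translation_rate,
        "n_rib_mol_gdcw": truth.n_rib,
        "flux": truth.flux,
        "enzyme_conc_mmol_gdcw": truth.enzyme_conc,
        "measured_ids": truth.measured_ids,
        "ribosomal_ids": truth.ribosomal_ids,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    paths["truth.json"] = out / "truth.json"
    return paths
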