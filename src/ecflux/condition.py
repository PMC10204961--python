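"""Per-condition integration of proteomics and physiology into an EC model.

Covers the sample-specific f-factor (enzyme mass share of the quantified
proteome), direct enzyme-concentration bounds with pool subtraction
(pool = sigma*f*Ptot - measured enzyme mass), greedy automatic
flexibilization of measured bounds when the observed growth rate is
infeasible, and the exchange-flux variability windows used during
sampling (1% growth/uptake/NGAM, 10% gas/byproducts/pool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import yaml

from .ec import DEFAULT_BOUND, ECModel, POOL_MET, POOL_RXN, PROT_PREFIX, USAGE_PREFIX
from .model import MetabolicModel
from .proteomics import MICROGRAM_PER_GRAM, ProteomeSample
from . import optimize

logger = logging.getLogger(__name__)


@dataclass
class PhysiologyData:
    """Measured rates and biomass composition for one condition/phase.

    Rates are positive magnitudes in mmol/gDCW/h keyed by the *base-model*
    exchange reaction id; sign conventions (uptake negative) are applied
    when bounds are written.
    """

    condition: str
    mu: float  # 1/h
    uptake: Dict[str, float] = field(default_factory=dict)
    co2: float = 0.0  # production
    o2: float = 0.0  # consumption
    byproducts: Dict[str, float] = field(default_factory=dict)
    ptot: float = 0.5  # g protein/gDCW
    ptot_sd: float = 0.0
    lipid: float = 0.1  # g/gDCW
    acyl_profile: Dict[str, float] = field(default_factory=dict)
    ngam: float = 0.0  # mmol ATP/gDCW/h

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("growth rate must be non-negative")
        rates = [self.co2, self.o2, self.ngam, *self.uptake.values(),
                 *self.byproducts.values()]
        if not all(np.isfinite(r) for r in rates):
            raise ValueError("all rates must be finite")

    @classmethod
    def from_yaml(cls, path) -> "PhysiologyData":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {
            "condition": self.condition,
            "mu": float(self.mu),
            "uptake": {k: float(v) for k, v in self.uptake.items()},
            "co2": float(self.co2),
            "o2": float(self.o2),
            "byproducts": {k: float(v) for k, v in self.byproducts.items()},
            "ptot": float(self.ptot),
            "ptot_sd": float(self.ptot_sd),
            "lipid": float(self.lipid),
            "acyl_profile": {k: float(v) for k, v in self.acyl_profile.items()},
            "ngam": float(self.ngam),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class FlexibilizationRecord:
    enzyme_id: str
    old_bound: float  # mmol/gDCW
    new_bound: float
    step: int
    action: str  # "sd" (raised to E+SD) or "release" (returned to pool)

    def __post_init__(self):
        if self.new_bound < self.old_bound:
            raise ValueError("flexibilization never lowers a bound")


#: sampling variability windows (fractions) around the measured rates
DEFAULT_TOLERANCES: Dict[str, float] = {
    "growth": 0.01,
    "uptake": 0.01,
    "gas": 0.10,
    "byproduct": 0.10,
    "pool": 0.10,
    "ngam": 0.01,
}


def compute_f_factor(
    proteome: ProteomeSample, model_enzymes: Iterable
) -> float:
    """Mass fraction of the quantified proteome covered by model enzymes.

    Computed on the unfiltered quantification (before any SD-based record
    filtering), as a share of total proteome mass: sum of model-enzyme
    concentrations / 1e6 ug/g.
    """
    ids = {getattr(e, "id", e) for e in model_enzymes}
    members = [p for p in proteome.conc.index if p in ids]
    f = float(proteome.conc.loc[members].sum() / MICROGRAM_PER_GRAM)
    if not (0 < f <= 1):
        raise ValueError(f"f-factor {f} outside (0, 1]: check protein/enzyme ids")
    return f


def constrain_enzymes(
    ec: ECModel,
    molar: Mapping[str, float],
    ptot: float,
    f: float,
    sigma: Optional[float] = None,
    sd: Optional[Mapping[str, float]] = None,
    ptot_sd: float = 0.0,
) -> Tuple[ECModel, Dict[str, float]]:
    """Apply measured enzyme concentrations and recompute the pool bound.

    Measured enzymes get a usage upper bound equal to their molar
    abundance (mmol/gDCW) and stop draining the shared pool; the pool
    bound becomes enzymeConc - Pmeasured, where enzymeConc =
    sigma * f * (Ptot + Ptot_SD) and Pmeasured is the summed mass of the
    measured enzymes. The identity
    sum(measured bound * MW) + pool_ub == sigma * f * Ptot_rescaled
    holds exactly afterwards.
    """
    sigma = ec.sigma if sigma is None else sigma
    out = ec.copy()
    enz_map = out.model.enzyme_map
    ptot_rescaled = ptot + ptot_sd
    enzyme_conc = sigma * f * ptot_rescaled
    measured = {e: molar[e] for e in out.enzyme_ids if e in molar}
    p_measured = sum(conc * enz_map[e].mw for e, conc in measured.items())
    if p_measured > enzyme_conc:
        raise ValueError(
            f"measured enzyme mass {p_measured:.4f} g/gDCW exceeds the total "
            f"enzyme budget sigma*f*Ptot = {enzyme_conc:.4f}; rescale Ptot "
            "(add assay SD) or increase sigma"
        )
    for enz_id, conc in measured.items():
        usage = out.usage_reaction(enz_id)
        usage.stoich = {PROT_PREFIX + enz_id: 1.0}  # decouple from the pool
        usage.ub = conc
        out.measured[enz_id] = conc
    out.model.meta.setdefault("measured_sd", {}).update(
        {e: float(sd[e]) for e in measured if sd and e in sd}
    )
    out.pool_ub = enzyme_conc - p_measured
    out.sigma, out.f, out.ptot = sigma, f, ptot_rescaled
    coverage = {
        "n_measured": len(measured),
        "n_model_enzymes": len(out.enzyme_ids),
        "measured_mass_g_gdcw": p_measured,
        "enzyme_budget_g_gdcw": enzyme_conc,
        "pool_ub_g_gdcw": out.pool_ub,
        "measured_mass_fraction": p_measured / enzyme_conc if enzyme_conc else np.nan,
    }
    return out, coverage


def select_constrained_enzymes(
    molar: Mapping[str, float],
    ec: ECModel,
    f: float,
    ptot: float,
    sigma: Optional[float] = None,
    budget_fraction: float = 0.5,
) -> Dict[str, float]:
    """Pick the quantified enzymes whose direct bounds fit the pool budget.

    The saturation-discounted enzyme budget sigma*f*Ptot must hold both
    the directly bounded (measured) enzyme mass and the pool for everyone
    else, so direct bounds are granted most-abundant-first (mass-wise,
    ties by id) while their summed mass stays within ``budget_fraction``
    of the budget; the remaining quantified enzymes stay pool-allocated.
    """
    sigma = ec.sigma if sigma is None else sigma
    enz_map = ec.model.enzyme_map
    budget = sigma * f * ptot * budget_fraction
    candidates = [
        (conc * enz_map[e].mw, e, conc)
        for e, conc in molar.items()
        if e in set(ec.enzyme_ids)
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    chosen: Dict[str, float] = {}
    mass = 0.0
    for m_e, e, conc in candidates:
        if mass + m_e <= budget:
            chosen[e] = conc
            mass += m_e
        else:
            logger.info("enzyme %s stays pool-allocated (budget exhausted)", e)
    return chosen


def _release_to_pool(ec: ECModel, enz_id: str) -> None:
    """Return a measured enzyme to the shared pool (and grow the pool by
    the mass its bound held, keeping the mass identity)."""
    enz = ec.model.get_enzyme(enz_id)
    usage = ec.usage_reaction(enz_id)
    usage.stoich = {POOL_MET: -enz.mw, PROT_PREFIX + enz_id: 1.0}
    usage.ub = DEFAULT_BOUND
    bound = ec.measured.pop(enz_id)
    ec.pool_ub = ec.pool_ub + bound * enz.mw


def flexibilize(
    ec: ECModel,
    target_mu: float,
    objective: Optional[str] = None,
    max_steps: int = 200,
) -> Tuple[ECModel, List[FlexibilizationRecord]]:
    """Greedy two-stage relaxation of measured enzyme bounds.

    While the maximal growth rate is below the target: the measured enzyme
    whose bound increase yields the largest growth gain (finite
    difference; ties broken by enzyme id) is relaxed, first to
    concentration + SD, then released to the pool entirely. Stops when the
    target is reached, all bounds are released, or no single relaxation
    helps; in the failing cases the remaining gap is logged and visible by
    comparing the returned model's optimum to the target.
    """
    out = ec.copy()
    records: List[FlexibilizationRecord] = []
    sd_map: Mapping[str, float] = out.model.meta.get("measured_sd", {})
    step = 0
    while step < max_steps:
        sol = out.fba(objective)
        mu = sol.objective_value if sol.status == "optimal" else 0.0
        if sol.status == "optimal" and mu >= target_mu * (1 - 1e-6):
            return out, records
        candidates = []
        for enz_id in sorted(out.measured):
            usage = out.usage_reaction(enz_id)
            conc = out.measured[enz_id]
            old_ub = usage.ub
            with_sd = conc + sd_map.get(enz_id, 0.0)
            # stage 1 (raise to concentration + SD) is preferred whenever
            # it helps; otherwise the enzyme is a candidate for release
            if old_ub < with_sd - 1e-15:
                usage.ub = with_sd
                trial = out.fba(objective)
                usage.ub = old_ub
                gain = (trial.objective_value if trial.status == "optimal" else 0.0) - mu
                if gain > 1e-9:
                    candidates.append((gain, enz_id, "sd", with_sd, old_ub))
                    continue
            probe = out.copy()
            _release_to_pool(probe, enz_id)
            trial = probe.fba(objective)
            gain = (trial.objective_value if trial.status == "optimal" else 0.0) - mu
            candidates.append((gain, enz_id, "release", None, old_ub))
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], t[1]))
        gain, enz_id, action, trial_ub, old_ub = candidates[0]
        if gain <= 1e-9:
            logger.warning(
                "flexibilization stalled at growth %.4g (target %.4g); "
                "no single relaxation helps", mu, target_mu,
            )
            break
        step += 1
        if action == "sd":
            out.usage_reaction(enz_id).ub = trial_ub
            records.append(
                FlexibilizationRecord(enz_id, old_ub, trial_ub, step, "sd")
            )
        else:
            _release_to_pool(out, enz_id)
            records.append(
                FlexibilizationRecord(enz_id, old_ub, DEFAULT_BOUND, step, "release")
            )
    sol = out.fba(objective)
    mu = sol.objective_value if sol.status == "optimal" else 0.0
    if mu < target_mu * (1 - 1e-6):
        logger.warning(
            "flexibilization finished with gap %.4g (reached %.4g of target %.4g)",
            target_mu - mu, mu, target_mu,
        )
    return out, records


def _split_components(model: MetabolicModel, base_id: str) -> Dict[str, int]:
    """Ids and signs of the irreversible copies of a base reaction."""
    split_map = model.meta.get("split_map", {})
    out = {
        new_id: sign for new_id, (bid, sign) in split_map.items() if bid == base_id
    }
    if not out and base_id in {r.id for r in model.reactions}:
        out = {base_id: 1}
    return out


def set_exchange_windows(
    ec: ECModel,
    physiology: PhysiologyData,
    tol: Optional[Mapping[str, float]] = None,
) -> ECModel:
    """Fix measured quantities to windows around their values.

    Growth and substrate uptake get 1% windows, gas exchange and
    byproducts 10%, the protein pool 10%, NGAM 1% (all configurable via
    ``tol``). Windows for strictly positive rates never cross zero.
    """
    tol = {**DEFAULT_TOLERANCES, **(tol or {})}
    out = ec.copy()
    model = out.model

    def window(rxn_id: str, value: float, frac: float) -> None:
        rxn = model.get_reaction(rxn_id)
        rxn.lb = value * (1 - frac)
        rxn.ub = value * (1 + frac)

    def constrain_base(base_id: str, rate: float, frac: float, direction: str) -> None:
        comps = _split_components(model, base_id)
        if not comps:
            raise KeyError(f"exchange reaction {base_id!r} missing from model")
        want = -1 if direction == "uptake" else 1
        for rxn_id, sign in comps.items():
            rxn = model.get_reaction(rxn_id)
            if sign == want:  # the copy carrying the measured direction
                window(rxn_id, rate, frac)
            else:
                rxn.lb = rxn.ub = 0.0

    window(model.objective, physiology.mu, tol["growth"])
    for ex_id, rate in physiology.uptake.items():
        constrain_base(ex_id, rate, tol["uptake"], "uptake")
    if physiology.co2:
        constrain_base("EX_co2", physiology.co2, tol["gas"], "production")
    if physiology.o2:
        constrain_base("EX_o2", physiology.o2, tol["gas"], "uptake")
    for ex_id, rate in physiology.byproducts.items():
        constrain_base(ex_id, rate, tol["byproduct"], "production")
    window(POOL_RXN, out.pool_ub, tol["pool"])
    if physiology.ngam:
        ngam_comps = _split_components(model, "ATPM")
        for rxn_id, sign in ngam_comps.items():
            if sign == 1:
                window(rxn_id, physiology.ngam, tol["ngam"])
    return out
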