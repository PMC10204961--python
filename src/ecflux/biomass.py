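"""Biomass equation rescaling and maintenance-energy fitting.

The biomass reaction consumes pseudo-components (protein, lipid,
carbohydrate) whose unit mass is 1 g/mmol, so their coefficients are the
measured g/gDCW contents and the biomass molar mass stays 1 g/mmol when
the coefficients sum to one. The lipid pseudo-reaction follows the SLIME
convention: one backbone pseudo-metabolite plus acyl-chain species whose
molar coefficients are computed from the measured chain mass fractions and
tabulated chain molar masses. Growth-associated maintenance (GAM) is the
ATP coefficient of the biomass reaction and is fitted by bisection against
the measured growth rate at the measured uptake.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

from .model import MetabolicModel
from . import optimize

logger = logging.getLogger(__name__)

# conventional pseudo-metabolite ids of the packaged networks
PROTEIN_PSEUDO = "protein_c"
LIPID_PSEUDO = "lipid_c"
CARB_PSEUDO = "carbohydrate_c"
BACKBONE_MET = "lipid_backbone_c"
ATP_MET = "atp_c"
NGAM_RXN = "ATPM"

#: free fatty acid molar masses, g/mol
CHAIN_MW: Dict[str, float] = {
    "C16:0": 256.43,
    "C18:0": 284.48,
    "C18:1": 282.47,
    "C18:2": 280.45,
    "C18:3": 278.44,
}
#: glycerol backbone molar mass, g/mol; backbone share of lipid mass
BACKBONE_MW = 92.09
BACKBONE_MASS_FRACTION = 0.10

#: typical fitted maintenance windows for R. toruloides batch data,
#: kept as config defaults:
#: GAM 124.4-140.0 mmol ATP/gDCW, NGAM 0-3.65 mmol ATP/gDCW/h
GAM_DEFAULT_RANGE: Tuple[float, float] = (124.4, 140.0)
NGAM_DEFAULT_RANGE: Tuple[float, float] = (0.0, 3.65)


@dataclass
class BiomassComposition:
    """Measured biomass composition for one condition (g/gDCW)."""

    protein: float
    lipid: float
    acyl_profile: Dict[str, float] = field(default_factory=dict)
    other: Dict[str, float] = field(default_factory=dict)  # e.g. RNA, g/gDCW

    def __post_init__(self):
        for name, val in [("protein", self.protein), ("lipid", self.lipid)]:
            if not (0 <= val <= 1):
                raise ValueError(f"{name} fraction {val} outside [0, 1]")
        if self.acyl_profile:
            total = sum(self.acyl_profile.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"acyl profile sums to {total}, expected 1")
            unknown = set(self.acyl_profile) - set(CHAIN_MW)
            if unknown:
                raise ValueError(f"unknown acyl chains: {sorted(unknown)}")


def chain_met_id(chain: str) -> str:
    """Acyl-chain metabolite id, e.g. 'C18:1' -> 'acyl_c18_1_c'."""
    return "acyl_" + chain.lower().replace(":", "_") + "_c"


def rescale_biomass(
    model: MetabolicModel, comp: BiomassComposition
) -> MetabolicModel:
    """Rescale the biomass reaction to a measured composition.

    Protein and lipid pseudo-component coefficients are set to the measured
    g/gDCW; the carbohydrate component absorbs the residual so the biomass
    molar mass stays 1 g/mmol. The lipid pseudo-reaction is rewritten from
    the acyl profile (SLIME split). Idempotent for identical composition.
    """
    out = model.copy()
    biomass = out.get_reaction(out.objective)
    for pseudo in (PROTEIN_PSEUDO, LIPID_PSEUDO, CARB_PSEUDO):
        if pseudo not in biomass.stoich or biomass.stoich[pseudo] >= 0:
            raise ValueError(
                f"biomass reaction lacks consumed pseudo-component {pseudo!r}"
            )
    other_mass = sum(comp.other.values())
    residual = 1.0 - comp.protein - comp.lipid - other_mass
    if residual < -1e-9:
        raise ValueError(
            "measured components exceed 1 g/gDCW by "
            f"{-residual:.4f} g; no residual left for carbohydrate"
        )
    biomass.stoich[PROTEIN_PSEUDO] = -comp.protein
    biomass.stoich[LIPID_PSEUDO] = -comp.lipid
    biomass.stoich[CARB_PSEUDO] = -residual
    for met_id, mass in comp.other.items():
        if met_id in biomass.stoich:
            biomass.stoich[met_id] = -mass
    if comp.acyl_profile:
        _rewrite_lipid_reaction(out, comp.acyl_profile)
    out.validate()
    return out


def _rewrite_lipid_reaction(model: MetabolicModel, profile: Mapping[str, float]) -> None:
    producers = [
        r for r in model.reactions
        if r.stoich.get(LIPID_PSEUDO, 0) > 0 and len(r.stoich) > 1
    ]
    if len(producers) != 1:
        raise ValueError(
            f"expected exactly one lipid pseudo-reaction, found {len(producers)}"
        )
    rxn = producers[0]
    stoich: Dict[str, float] = {LIPID_PSEUDO: 1.0}
    # per mmol lipid (1 g): backbone mass + acyl mass
    stoich[BACKBONE_MET] = -BACKBONE_MASS_FRACTION / (BACKBONE_MW / 1000.0)
    acyl_mass = 1.0 - BACKBONE_MASS_FRACTION
    for chain, frac in profile.items():
        if frac <= 0:
            continue
        stoich[chain_met_id(chain)] = -acyl_mass * frac / (CHAIN_MW[chain] / 1000.0)
    rxn.stoich = stoich


def biomass_molar_mass(model: MetabolicModel) -> float:
    """Mass of biomass per unit growth flux, g/mmol.

    Sums coefficient x component mass over the consumed pseudo-components
    (each carrying 1 g/mmol). Equals 1 after a valid rescaling.
    """
    biomass = model.get_reaction(model.objective)
    mass = 0.0
    for met_id, coef in biomass.stoich.items():
        if coef < 0 and met_id in (PROTEIN_PSEUDO, LIPID_PSEUDO, CARB_PSEUDO):
            mass += -coef
        elif coef < 0 and met_id.endswith("_pseudo"):
            mass += -coef
    return mass


def fit_gam_ngam(
    model: MetabolicModel,
    physiology,
    gam_bracket: Tuple[float, float] = (0.0, 300.0),
    steps: int = 40,
    rel_tol: float = 1e-3,
    ngam_rxn: str = NGAM_RXN,
) -> Tuple[float, float]:
    """Fit GAM (mmol ATP/gDCW) by bisection at fixed NGAM.

    NGAM (mmol ATP/gDCW/h) is taken from the physiology record (its
    non-growth ATP hydrolysis rate) and fixed; GAM is the ATP coefficient
    of the biomass reaction, found so that the predicted maximal growth at
    the measured uptake matches the measured growth rate within
    ``rel_tol`` relative. Predicted growth decreases monotonically with
    GAM, so plain bisection applies.

    ``physiology`` needs attributes ``mu`` (1/h), ``uptake`` (map exchange
    reaction id -> positive uptake rate, mmol/gDCW/h) and ``ngam``.
    """
    mu_target = physiology.mu
    if mu_target <= 0:
        raise ValueError("measured growth rate must be positive")
    work = model.copy()
    for ex_id, rate in physiology.uptake.items():
        rxn = work.get_reaction(ex_id)
        rxn.lb, rxn.ub = -rate, -rate
    ngam = physiology.ngam
    ngam_reaction = work.get_reaction(ngam_rxn)
    ngam_reaction.lb = ngam_reaction.ub = ngam

    biomass = work.get_reaction(work.objective)
    if ATP_MET not in biomass.stoich:
        raise ValueError("biomass reaction carries no ATP (GAM) term")

    def mu_at(gam: float) -> float:
        biomass.stoich[ATP_MET] = -gam
        sol = optimize.fba(work)
        return sol.objective_value if sol.status == "optimal" else 0.0

    lo, hi = gam_bracket
    mu_lo, mu_hi = mu_at(lo), mu_at(hi)
    if mu_lo < mu_target * (1 - rel_tol):
        raise ValueError(
            f"measured growth {mu_target} unattainable even at GAM={lo} "
            f"(predicted {mu_lo:.4f})"
        )
    if mu_hi > mu_target * (1 + rel_tol):
        raise ValueError(
            f"bracketing failure: predicted growth {mu_hi:.4f} at GAM={hi} "
            f"still exceeds measured {mu_target}"
        )
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        if mu_at(mid) >= mu_target:
            lo = mid
        else:
            hi = mid
    gam = 0.5 * (lo + hi)
    mu_fit = mu_at(gam)
    if abs(mu_fit - mu_target) > rel_tol * mu_target:
        logger.warning(
            "GAM fit residual %.3g relative exceeds %.3g",
            abs(mu_fit - mu_target) / mu_target, rel_tol,
        )
    return gam, ngam
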