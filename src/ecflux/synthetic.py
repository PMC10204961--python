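"""Synthetic study generator: toy metabolic networks with the organism's
characteristic pathway motifs, per-condition physiology, and MS-level
proteomics with a heavy-labelled internal standard — all with known ground
truth for recovery testing.

The toy network (40-70 reactions depending on variant) contains lumped
glycolysis, the oxidative PPP, the phosphoketolase (XPK) route to
cytosolic acetyl-CoA, the PDC/ALD/ACS bypass and ATP-citrate lyase as its
alternatives, a TCA cycle with glyoxylate shunt, a carnitine shuttle,
malic enzyme, NADPH-dependent glutamate dehydrogenase for nitrogen
assimilation, fatty-acid synthesis spending 1 ATP + 2 NADPH per C2
elongation, desaturases, a lumped electron transport chain, and a
biomass reaction over protein/lipid/carbohydrate pseudo-components. The
xylose variant adds XR/XDH/XK and (optionally) the D-arabinitol bypass
(DAD-4, DAD-2/LXR with configurable cofactor, ribulokinase). Cofactors
are lumped single species (no ADP/NAD+/NADP+ mirrors, no water/proton
balancing); carbon is balanced in every non-pseudo reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomass import (
    BiomassComposition,
    CHAIN_MW,
    chain_met_id,
    rescale_biomass,
)
from .condition import PhysiologyData
from .ec import KcatRecord
from .model import Enzyme, MetabolicModel, Metabolite, Reaction
from .proteomics import MSRecord, MEAN_AA_MASS
from . import optimize

ORGANISM = "Rhodotorula toruloides"

#: ceiling on the planted in-vivo saturation of flux-carrying enzymes;
#: apparent activities are then ~10-15% of kcat, inside the 0.1-100 1/s
#: bulk reported for in-vivo apparent turnover.
DEFAULT_SATURATION = 0.15
#: model-enzyme mass share of the proteome planted by the generator
DEFAULT_F_TARGET = 0.20
#: share of the sigma-discounted enzyme budget that measured bounds may
#: occupy when the generator picks the measured subset
MEASURED_POOL_SAFETY = 0.9

N_RIBOSOMAL = 40
N_BACKGROUND = 60


@dataclass
class ToySpec:
    """Configuration of one synthetic study condition."""

    variant: str = "glucose"  # glucose | xylose | acetate
    phase: str = "exp"  # exp | nlim
    include_xpk: bool = True
    include_dad_bypass: bool = True
    dad2_cofactor: str = "nadph"  # nadph | nadh
    seed: int = 0
    proteomics_cv: float = 0.10
    rate_cv: float = 0.05
    n_replicates: int = 2
    sigma: float = 0.35
    saturation: float = DEFAULT_SATURATION
    f_target: float = DEFAULT_F_TARGET

    def __post_init__(self):
        if self.variant not in ("glucose", "xylose", "acetate"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.phase not in ("exp", "nlim"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.dad2_cofactor not in ("nadph", "nadh"):
            raise ValueError("dad2_cofactor must be 'nadph' or 'nadh'")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    flux: Dict[str, float]  # base-model reference flux, mmol/gDCW/h
    mu: float
    enzyme_conc: Dict[str, float]  # mmol/gDCW
    kcats: Dict[str, float]  # enzyme -> kcat 1/s
    conc_ug_per_g: pd.Series  # full proteome, ug/g protein
    composition: BiomassComposition
    physiology: PhysiologyData  # noise-free rates
    f: float  # model-enzyme mass share of the proteome
    measured_ids: List[str]  # enzymes the study applies bounds to
    ribosomal_ids: List[str]
    n_rib: float  # mol/gDCW
    translation_rate: float  # aa/s
    gam: float
    ngam: float
    protein_mw: Dict[str, float]  # g/mmol, full proteome


# -- enzyme catalogue ------------------------------------------------------
# id, MW (g/mmol = kDa), EC number, reference kcat (1/s)
_ENZYMES: List[Tuple[str, float, str, float]] = [
    ("E_HXK", 54, "2.7.1.1", 180.0),
    ("E_PGI", 61, "5.3.1.9", 200.0),
    ("E_PFK", 110, "2.7.1.11", 150.0),
    ("E_GLY", 70, "1.2.1.12", 100.0),
    ("E_FBP", 38, "3.1.3.11", 127.0),
    ("E_ZWF", 57, "1.1.1.49", 120.0),
    ("E_RPE", 25, "5.1.3.1", 300.0),
    ("E_RPI", 29, "5.3.1.6", 250.0),
    ("E_TKL", 74, "2.2.1.1", 90.0),
    ("E_XPK", 92, "4.1.2.9", 60.0),
    ("E_PTA", 77, "2.3.1.8", 150.0),
    ("E_PDC", 62, "4.1.1.1", 150.0),
    ("E_ALD6", 54, "1.2.1.4", 30.0),
    ("E_ACS", 73, "6.2.1.1", 55.0),
    ("E_ACL", 120, "2.3.3.8", 30.0),
    ("E_PDH", 160, "1.2.4.1", 486.0),
    ("E_CIT", 52, "2.3.3.1", 540.0),
    ("E_ACO1", 85, "4.2.1.3", 80.0),
    ("E_ACO2", 83, "4.2.1.3", 65.0),
    ("E_IDH", 48, "1.1.1.41", 70.0),
    ("E_AKGD", 115, "1.2.4.2", 60.0),
    ("E_SDH", 70, "1.3.5.1", 90.0),
    ("E_FUM", 53, "4.2.1.2", 400.0),
    ("E_MDH1", 35, "1.1.1.37", 900.0),
    ("E_MDH2", 36, "1.1.1.37", 900.0),
    ("E_ICL", 60, "4.1.3.1", 50.0),
    ("E_MLS", 63, "2.3.3.9", 40.0),
    ("E_PYC", 130, "6.4.1.1", 60.0),
    ("E_ME", 65, "1.1.1.40", 45.0),
    ("E_CRC", 33, "2.3.1.7", 120.0),
    ("E_GNG", 60, "4.1.1.49", 38.0),
    ("E_GDH1", 49, "1.4.1.4", 230.0),
    ("E_ACC", 250, "6.4.1.2", 20.0),
    ("E_FAS1", 230, "2.3.1.86", 35.0),
    ("E_FAS2", 210, "2.3.1.86", 35.0),
    ("E_OLE1", 55, "1.14.19.1", 15.0),
    ("E_FAD2", 52, "1.14.19.6", 12.0),
    ("E_FAD3", 52, "1.14.19.35", 10.0),
    ("E_XR", 36, "1.1.1.307", 40.0),
    ("E_XDH", 38, "1.1.1.9", 50.0),
    ("E_XK", 58, "2.7.1.17", 35.0),
    ("E_DAD4", 40, "1.1.1.11", 45.0),
    ("E_DAD2", 30, "1.1.1.10", 50.0),
    ("E_RK", 45, "2.7.1.47", 30.0),
]

TRUE_KCATS: Dict[str, float] = {eid: k for eid, _, _, k in _ENZYMES}

#: representative substrate (metabolite name) per enzyme, used to build
#: exact-match kcat records
_ENZYME_SUBSTRATE: Dict[str, str] = {
    "E_HXK": "D-glucose",
    "E_PGI": "D-glucose 6-phosphate",
    "E_PFK": "D-fructose 6-phosphate",
    "E_GLY": "glyceraldehyde 3-phosphate",
    "E_FBP": "glyceraldehyde 3-phosphate",
    "E_ZWF": "D-glucose 6-phosphate",
    "E_XPK": "D-xylulose 5-phosphate",
    "E_PDH": "pyruvate",
    "E_CIT": "acetyl-CoA",
    "E_GDH1": "2-oxoglutarate",
    "E_XR": "D-xylose",
    "E_DAD2": "D-arabinitol",
}


def kcat_database() -> List[KcatRecord]:
    """Synthetic kcat table emulating a BRENDA extract.

    For enzymes with a representative substrate there is an exact
    (EC, substrate, organism) record at the reference kcat plus a laxer
    cross-organism decoy at a higher value, so the stepwise matcher must
    prefer the stricter level; the rest match at the EC-only level. The
    fructose-bisphosphatase entry emulates the well-known pathological
    case: the strictest match yields 0.002 1/s (far below the enzyme's
    actual capacity of 127 1/s, which is only available cross-organism),
    so gluconeogenic conditions over-constrain until the kcat curation
    loop raises it.
    """
    records: List[KcatRecord] = []
    for eid, _mw, ec, kcat in _ENZYMES:
        sub = _ENZYME_SUBSTRATE.get(eid)
        if eid == "E_FBP":
            records.append(KcatRecord(ec, sub, ORGANISM, 0.002))
            records.append(KcatRecord(ec, sub, "Saccharomyces cerevisiae", kcat))
        elif sub is not None:
            records.append(KcatRecord(ec, sub, ORGANISM, kcat))
            records.append(KcatRecord(ec, sub, "Saccharomyces cerevisiae", kcat * 3.0))
        else:
            records.append(KcatRecord(ec, "generic substrate", "Escherichia coli", kcat))
    return records


def enzyme_table() -> List[Enzyme]:
    return [
        Enzyme(id=eid, genes=["g_" + eid[2:].lower()], mw=mw, ec_numbers=[ec])
        for eid, mw, ec, _k in _ENZYMES
    ]


def _met(mid: str, name: str, comp: str, carbons: int = 0) -> Metabolite:
    formula = f"C{carbons}" if carbons else None
    return Metabolite(mid, name, comp, formula)


def _rxn(rid, stoich, name="", lb=0.0, ub=1000.0, enzymes: Optional[List[List[str]]] = None,
         subsystem="") -> Reaction:
    return Reaction(rid, dict(stoich), name=name, lb=lb, ub=ub,
                    gene_rule=enzymes or [], subsystem=subsystem)


def dad_bypass_pathway(cofactor: str = "nadph") -> Tuple[List[Metabolite], List[Reaction]]:
    """The 3-reaction D-arabinitol xylose bypass (2 new metabolites).

    D-xylulose -> D-arabinitol (DAD-4, NADH-consuming), D-arabinitol ->
    D-ribulose (DAD-2/LXR, producing NADPH or NADH per ``cofactor``),
    D-ribulose + ATP -> D-ribulose 5-phosphate (ribulokinase).
    """
    red = "nadph_c" if cofactor == "nadph" else "nadh_c"
    mets = [
        _met("abt_c", "D-arabinitol", "c", 5),
        _met("rbu_c", "D-ribulose", "c", 5),
    ]
    rxns = [
        _rxn("DAD4", {"xlu_c": -1, "nadh_c": -1, "abt_c": 1},
             "D-arabinitol 4-dehydrogenase", enzymes=[["E_DAD4"]],
             subsystem="xylose assimilation"),
        _rxn("DAD2", {"abt_c": -1, "rbu_c": 1, red: 1},
             "D-arabinitol 2-dehydrogenase (LXR)", enzymes=[["E_DAD2"]],
             subsystem="xylose assimilation"),
        _rxn("RK", {"rbu_c": -1, "atp_c": -1, "ru5p_c": 1},
             "D-ribulokinase", enzymes=[["E_RK"]],
             subsystem="xylose assimilation"),
    ]
    return mets, rxns


def make_toy_network(spec: ToySpec) -> MetabolicModel:
    """Build the toy network for one substrate variant.

    Biomass coefficients start at the exponential-phase defaults; use
    :func:`ecflux.biomass.rescale_biomass` for condition-specific
    composition. Growth is feasible in every variant.
    """
    m: List[Metabolite] = [
        _met("glc_e", "D-glucose", "e", 6),
        _met("glc_c", "D-glucose", "c", 6),
        _met("g6p_c", "D-glucose 6-phosphate", "c", 6),
        _met("f6p_c", "D-fructose 6-phosphate", "c", 6),
        _met("g3p_c", "glyceraldehyde 3-phosphate", "c", 3),
        _met("pyr_c", "pyruvate", "c", 3),
        _met("pyr_m", "pyruvate", "m", 3),
        _met("ru5p_c", "D-ribulose 5-phosphate", "c", 5),
        _met("x5p_c", "D-xylulose 5-phosphate", "c", 5),
        _met("r5p_c", "D-ribose 5-phosphate", "c", 5),
        _met("acp_c", "acetyl phosphate", "c", 2),
        _met("acald_c", "acetaldehyde", "c", 2),
        _met("ac_c", "acetate", "c", 2),
        _met("accoa_c", "acetyl-CoA", "c", 2),
        _met("accoa_m", "acetyl-CoA", "m", 2),
        _met("oaa_m", "oxaloacetate", "m", 4),
        _met("oaa_c", "oxaloacetate", "c", 4),
        _met("cit_m", "citrate", "m", 6),
        _met("cit_c", "citrate", "c", 6),
        _met("icit_m", "isocitrate", "m", 6),
        _met("akg_m", "2-oxoglutarate", "m", 5),
        _met("akg_c", "2-oxoglutarate", "c", 5),
        _met("succ_m", "succinate", "m", 4),
        _met("fum_m", "fumarate", "m", 4),
        _met("mal_m", "(S)-malate", "m", 4),
        _met("mal_c", "(S)-malate", "c", 4),
        _met("glx_m", "glyoxylate", "m", 2),
        _met("malcoa_c", "malonyl-CoA", "c", 3),
        _met("glu_c", "L-glutamate", "c", 5),
        _met("nh4_e", "ammonium", "e"),
        _met("nh4_c", "ammonium", "c"),
        _met("co2_c", "carbon dioxide", "c", 1),
        _met("co2_e", "carbon dioxide", "e", 1),
        _met("o2_e", "oxygen", "e"),
        _met("o2_c", "oxygen", "c"),
        _met("atp_c", "ATP", "c"),
        _met("nadh_c", "NADH", "c"),
        _met("nadph_c", "NADPH", "c"),
        _met("acyl_c16_0_c", "palmitate chain", "c", 16),
        _met("acyl_c18_0_c", "stearate chain", "c", 18),
        _met("acyl_c18_1_c", "oleate chain", "c", 18),
        _met("acyl_c18_2_c", "linoleate chain", "c", 18),
        _met("acyl_c18_3_c", "linolenate chain", "c", 18),
        _met("lipid_backbone_c", "glycerol backbone", "c", 3),
        _met("protein_c", "protein pseudo-component", "c"),
        _met("lipid_c", "lipid pseudo-component", "c"),
        _met("carbohydrate_c", "carbohydrate pseudo-component", "c"),
        _met("biomass_c", "biomass", "c"),
    ]
    glu_per_g = 1.0 / 0.129  # mmol glutamate residue per g protein (129 g/mol residue)
    carb_per_g = 1.0 / 0.162  # mmol glucan residue per g carbohydrate
    r: List[Reaction] = [
        # exchanges (negative flux = uptake)
        _rxn("EX_glc", {"glc_e": -1}, "glucose exchange", lb=0.0, ub=0.0),
        _rxn("EX_o2", {"o2_e": -1}, "oxygen exchange", lb=-1000.0, ub=0.0),
        _rxn("EX_co2", {"co2_e": -1}, "CO2 exchange", lb=0.0, ub=1000.0),
        _rxn("EX_nh4", {"nh4_e": -1}, "ammonium exchange", lb=-1000.0, ub=0.0),
        _rxn("EX_biomass", {"biomass_c": -1}, "biomass drain", lb=0.0, ub=1000.0),
        # transport
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, "glucose transport"),
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, "oxygen diffusion"),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, "CO2 diffusion"),
        _rxn("NH4t", {"nh4_e": -1, "nh4_c": 1}, "ammonium transport"),
        # glycolysis (lumped) + gluconeogenesis
        _rxn("HXK", {"glc_c": -1, "atp_c": -1, "g6p_c": 1}, "hexokinase",
             enzymes=[["E_HXK"]], subsystem="glycolysis"),
        _rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, "glucose-6-phosphate isomerase",
             lb=-1000.0, enzymes=[["E_PGI"]], subsystem="glycolysis"),
        _rxn("PFK", {"f6p_c": -1, "atp_c": -1, "g3p_c": 2},
             "phosphofructokinase + aldolase (lumped)", enzymes=[["E_PFK"]],
             subsystem="glycolysis"),
        _rxn("FBP", {"g3p_c": -2, "f6p_c": 1}, "fructose-bisphosphatase (lumped)",
             enzymes=[["E_FBP"]], subsystem="gluconeogenesis"),
        _rxn("GLY", {"g3p_c": -1, "pyr_c": 1, "nadh_c": 1, "atp_c": 2},
             "lower glycolysis (lumped GAPDH..PYK)", enzymes=[["E_GLY"]],
             subsystem="glycolysis"),
        _rxn("GNG", {"oaa_c": -1, "atp_c": -2, "nadh_c": -1, "g3p_c": 1, "co2_c": 1},
             "gluconeogenesis upper (lumped PEPCK..GAPDH)", enzymes=[["E_GNG"]],
             subsystem="gluconeogenesis"),
        # pentose phosphate pathway
        _rxn("ZWF", {"g6p_c": -1, "ru5p_c": 1, "co2_c": 1, "nadph_c": 2},
             "oxidative PPP (lumped G6PDH+GND)", enzymes=[["E_ZWF"]],
             subsystem="pentose phosphate pathway"),
        _rxn("RPE", {"ru5p_c": -1, "x5p_c": 1}, "ribulose-phosphate epimerase",
             lb=-1000.0, enzymes=[["E_RPE"]], subsystem="pentose phosphate pathway"),
        _rxn("RPI", {"ru5p_c": -1, "r5p_c": 1}, "ribose-5-phosphate isomerase",
             lb=-1000.0, enzymes=[["E_RPI"]], subsystem="pentose phosphate pathway"),
        _rxn("TKL", {"x5p_c": -2, "r5p_c": -1, "f6p_c": 2, "g3p_c": 1},
             "transketolase/transaldolase (lumped)", lb=-1000.0,
             enzymes=[["E_TKL"]], subsystem="pentose phosphate pathway"),
        # phosphoketolase route and alternatives
        _rxn("XPK", {"x5p_c": -1, "acp_c": 1, "g3p_c": 1}, "phosphoketolase",
             ub=1000.0 if spec.include_xpk else 0.0,
             enzymes=[["E_XPK"]], subsystem="phosphoketolase"),
        _rxn("PTA", {"acp_c": -1, "accoa_c": 1}, "phosphotransacetylase",
             enzymes=[["E_PTA"]], subsystem="phosphoketolase"),
        _rxn("PDC", {"pyr_c": -1, "acald_c": 1, "co2_c": 1}, "pyruvate decarboxylase",
             enzymes=[["E_PDC"]], subsystem="pyruvate metabolism"),
        _rxn("ALD6", {"acald_c": -1, "ac_c": 1, "nadph_c": 1},
             "acetaldehyde dehydrogenase (NADP)", enzymes=[["E_ALD6"]],
             subsystem="pyruvate metabolism"),
        _rxn("ACS", {"ac_c": -1, "atp_c": -2, "accoa_c": 1}, "acetyl-CoA synthetase",
             enzymes=[["E_ACS"]], subsystem="pyruvate metabolism"),
        _rxn("ACL", {"cit_c": -1, "atp_c": -1, "accoa_c": 1, "oaa_c": 1},
             "ATP-citrate lyase", enzymes=[["E_ACL"]], subsystem="pyruvate metabolism"),
        # TCA cycle + glyoxylate shunt (mitochondrial, lumped)
        _rxn("PYRt", {"pyr_c": -1, "pyr_m": 1}, "pyruvate mitochondrial carrier"),
        _rxn("PDH", {"pyr_m": -1, "accoa_m": 1, "co2_c": 1, "nadh_c": 1},
             "pyruvate dehydrogenase", enzymes=[["E_PDH"]], subsystem="TCA cycle"),
        _rxn("CIT", {"accoa_m": -1, "oaa_m": -1, "cit_m": 1}, "citrate synthase",
             enzymes=[["E_CIT"]], subsystem="TCA cycle"),
        _rxn("ACO", {"cit_m": -1, "icit_m": 1}, "aconitase", lb=-1000.0,
             enzymes=[["E_ACO1"], ["E_ACO2"]], subsystem="TCA cycle"),
        _rxn("IDH", {"icit_m": -1, "akg_m": 1, "co2_c": 1, "nadh_c": 1},
             "isocitrate dehydrogenase", enzymes=[["E_IDH"]], subsystem="TCA cycle"),
        _rxn("AKGD", {"akg_m": -1, "succ_m": 1, "co2_c": 1, "nadh_c": 1, "atp_c": 1},
             "2-oxoglutarate dehydrogenase + succinyl-CoA synthetase (lumped)",
             enzymes=[["E_AKGD"]], subsystem="TCA cycle"),
        _rxn("SDH", {"succ_m": -1, "fum_m": 1, "nadh_c": 1},
             "succinate dehydrogenase (FADH2 as NADH equivalent)",
             enzymes=[["E_SDH"]], subsystem="TCA cycle"),
        _rxn("FUM", {"fum_m": -1, "mal_m": 1}, "fumarase", lb=-1000.0,
             enzymes=[["E_FUM"]], subsystem="TCA cycle"),
        _rxn("MDH1", {"mal_m": -1, "oaa_m": 1, "nadh_c": 1}, "malate dehydrogenase",
             lb=-1000.0, enzymes=[["E_MDH1"]], subsystem="TCA cycle"),
        _rxn("ICL", {"icit_m": -1, "succ_m": 1, "glx_m": 1}, "isocitrate lyase",
             enzymes=[["E_ICL"]], subsystem="glyoxylate shunt"),
        _rxn("MLS", {"glx_m": -1, "accoa_m": -1, "mal_m": 1}, "malate synthase",
             enzymes=[["E_MLS"]], subsystem="glyoxylate shunt"),
        _rxn("PYC", {"pyr_m": -1, "co2_c": -1, "atp_c": -1, "oaa_m": 1},
             "pyruvate carboxylase", enzymes=[["E_PYC"]], subsystem="anaplerosis"),
        _rxn("ME", {"mal_m": -1, "pyr_m": 1, "co2_c": 1, "nadph_c": 1},
             "malic enzyme (NADP)", enzymes=[["E_ME"]], subsystem="anaplerosis"),
        # carriers and cytosolic TCA-adjacent reactions
        _rxn("CRC", {"accoa_c": -1, "accoa_m": 1}, "carnitine shuttle (lumped)",
             enzymes=[["E_CRC"]], subsystem="transport"),
        _rxn("AKGt", {"akg_m": -1, "akg_c": 1}, "oxoglutarate carrier", lb=-1000.0),
        _rxn("CITt", {"cit_m": -1, "cit_c": 1}, "citrate carrier", lb=-1000.0),
        _rxn("MALt", {"mal_c": -1, "mal_m": 1}, "malate carrier", lb=-1000.0),
        _rxn("MDH2", {"oaa_c": -1, "nadh_c": -1, "mal_c": 1},
             "cytosolic malate dehydrogenase", lb=-1000.0, enzymes=[["E_MDH2"]],
             subsystem="gluconeogenesis"),
        # nitrogen assimilation and polymer synthesis
        _rxn("GDH1", {"akg_c": -1, "nh4_c": -1, "nadph_c": -1, "glu_c": 1},
             "glutamate dehydrogenase (NADP)", enzymes=[["E_GDH1"]],
             subsystem="nitrogen assimilation"),
        _rxn("PROTSYN", {"glu_c": -glu_per_g, "atp_c": -4.0 * glu_per_g,
                         "protein_c": 1},
             "protein pseudo-synthesis (4 ATP per residue)",
             subsystem="biomass"),
        _rxn("CARBSYN", {"g6p_c": -carb_per_g, "atp_c": -carb_per_g,
                         "carbohydrate_c": 1},
             "carbohydrate pseudo-synthesis", subsystem="biomass"),
        # lipid synthesis: 1 ATP + 2 NADPH per C2 elongation step
        _rxn("ACC", {"accoa_c": -1, "co2_c": -1, "atp_c": -1, "malcoa_c": 1},
             "acetyl-CoA carboxylase", enzymes=[["E_ACC"]],
             subsystem="fatty acid synthesis"),
        _rxn("FAS160", {"accoa_c": -1, "malcoa_c": -7, "nadph_c": -14,
                        "acyl_c16_0_c": 1, "co2_c": 7},
             "fatty acid synthase to C16:0", enzymes=[["E_FAS1", "E_FAS2"]],
             subsystem="fatty acid synthesis"),
        _rxn("FAS180", {"accoa_c": -1, "malcoa_c": -8, "nadph_c": -16,
                        "acyl_c18_0_c": 1, "co2_c": 8},
             "fatty acid synthase to C18:0", enzymes=[["E_FAS1", "E_FAS2"]],
             subsystem="fatty acid synthesis"),
        _rxn("OLE1", {"acyl_c18_0_c": -1, "o2_c": -1, "nadh_c": -1,
                      "acyl_c18_1_c": 1},
             "delta-9 desaturase", enzymes=[["E_OLE1"]],
             subsystem="fatty acid synthesis"),
        _rxn("FAD2", {"acyl_c18_1_c": -1, "o2_c": -1, "nadh_c": -1,
                      "acyl_c18_2_c": 1},
             "delta-12 desaturase", enzymes=[["E_FAD2"]],
             subsystem="fatty acid synthesis"),
        _rxn("FAD3", {"acyl_c18_2_c": -1, "o2_c": -1, "nadh_c": -1,
                      "acyl_c18_3_c": 1},
             "omega-3 desaturase", enzymes=[["E_FAD3"]],
             subsystem="fatty acid synthesis"),
        _rxn("LIPBB", {"g3p_c": -1, "atp_c": -1, "nadh_c": -1,
                       "lipid_backbone_c": 1},
             "glycerol backbone synthesis", subsystem="fatty acid synthesis"),
        # rewritten by rescale_biomass from the acyl profile:
        _rxn("LIPSYN", {"lipid_backbone_c": -1.0, "lipid_c": 1},
             "lipid pseudo-synthesis (SLIME)", subsystem="biomass"),
        # energy
        _rxn("ETC", {"nadh_c": -1, "o2_c": -0.5, "atp_c": 2.5},
             "electron transport chain (lumped, P/O 2.5)", subsystem="energy"),
        _rxn("ATPM", {"atp_c": -1}, "non-growth maintenance ATP hydrolysis",
             lb=0.0, subsystem="energy"),
        _rxn("BIOMASS", {"protein_c": -0.45, "lipid_c": -0.10,
                         "carbohydrate_c": -0.45, "atp_c": -130.0,
                         "biomass_c": 1},
             "biomass equation (coefficients g/gDCW; ATP term = GAM)",
             subsystem="biomass"),
    ]
    if spec.variant == "glucose":
        ex = next(x for x in r if x.id == "EX_glc")
        ex.lb = -10.0
    if spec.variant == "xylose":
        m += [
            _met("xyl_e", "D-xylose", "e", 5),
            _met("xyl_c", "D-xylose", "c", 5),
            _met("xylitol_c", "xylitol", "c", 5),
            _met("xlu_c", "D-xylulose", "c", 5),
        ]
        r += [
            _rxn("EX_xyl", {"xyl_e": -1}, "xylose exchange", lb=-10.0, ub=0.0),
            _rxn("XYLt", {"xyl_e": -1, "xyl_c": 1}, "xylose transport"),
            _rxn("XR", {"xyl_c": -1, "nadph_c": -1, "xylitol_c": 1},
                 "xylose reductase", enzymes=[["E_XR"]],
                 subsystem="xylose assimilation"),
            _rxn("XDH", {"xylitol_c": -1, "xlu_c": 1, "nadh_c": 1},
                 "xylitol dehydrogenase", enzymes=[["E_XDH"]],
                 subsystem="xylose assimilation"),
            _rxn("XK", {"xlu_c": -1, "atp_c": -1, "x5p_c": 1}, "xylulokinase",
                 enzymes=[["E_XK"]], subsystem="xylose assimilation"),
            _rxn("EX_xylitol", {"xylitol_c": -1}, "xylitol secretion",
                 lb=0.0, ub=1000.0),
        ]
    if spec.variant == "acetate":
        m += [_met("ac_e", "acetate", "e", 2)]
        r += [
            _rxn("EX_ac", {"ac_e": -1}, "acetate exchange", lb=-20.0, ub=0.0),
            _rxn("ACt", {"ac_e": -1, "ac_c": 1}, "acetate diffusion"),
            _rxn("EX_cit", {"cit_c": -1}, "citrate secretion", lb=0.0, ub=1000.0),
        ]
    model = MetabolicModel(
        id=f"toy_{spec.variant}",
        metabolites=m,
        reactions=r,
        enzymes=enzyme_table(),
        objective="BIOMASS",
        compartments={"c": "cytosol", "m": "mitochondrion", "e": "extracellular"},
        meta={"variant": spec.variant},
    )
    if spec.variant == "xylose" and spec.include_dad_bypass:
        from .model import add_pathway

        mets, rxns = dad_bypass_pathway(spec.dad2_cofactor)
        rxns = rxns + [
            _rxn("EX_abt", {"abt_c": -1}, "D-arabinitol secretion", lb=0.0, ub=1000.0)
        ]
        model = add_pathway(model, mets, rxns, check_balance=False)
    # default (exp-phase) acyl profile for the initial LIPSYN stoichiometry
    model = rescale_biomass(model, _composition(spec.variant, "exp"))
    model.id = f"toy_{spec.variant}"
    return model


def make_chain_model(n: int = 4, uptake: float = 10.0, yield_per_substrate: float = 0.5
                     ) -> MetabolicModel:
    """A fully determined linear chain: fixed uptake forces a unique flux.

    a0_e -> a1 -> ... -> a{n} -> product exchange, with the terminal step
    producing ``yield_per_substrate`` product per substrate.
    """
    mets = [_met("a0_e", "substrate", "e", 1)]
    rxns = [_rxn("EX_sub", {"a0_e": -1}, lb=-uptake, ub=-uptake)]
    for i in range(1, n + 1):
        mets.append(_met(f"a{i}_c", f"intermediate {i}", "c", 1))
        rxns.append(_rxn(f"R{i}", {("a0_e" if i == 1 else f"a{i-1}_c"): -1,
                                   f"a{i}_c": 1}))
    mets.append(_met("prod_c", "product", "c", 1))
    rxns.append(_rxn("RP", {f"a{n}_c": -1, "prod_c": yield_per_substrate}))
    rxns.append(_rxn("EX_prod", {"prod_c": -1}, lb=0.0, ub=1000.0))
    model = MetabolicModel(
        id="chain", metabolites=mets, reactions=rxns, objective="EX_prod",
        compartments={"c": "cytosol", "e": "extracellular"},
    )
    model.validate()
    return model


# -- condition simulation --------------------------------------------------

_PHASE_TABLE = {
    # variant -> phase -> settings
    ("glucose", "exp"): dict(uptake=4.4, protein=0.45, lipid=0.10, gam=130.0,
                             ngam=1.0, translation=3.5),
    ("glucose", "nlim"): dict(uptake=1.6, protein=0.16, lipid=0.40, gam=135.0,
                              ngam=3.0, translation=1.0),
    ("xylose", "exp"): dict(uptake=3.0, protein=0.42, lipid=0.12, gam=128.0,
                            ngam=1.0, translation=2.5),
    ("xylose", "nlim"): dict(uptake=1.2, protein=0.18, lipid=0.38, gam=132.0,
                             ngam=2.5, translation=0.9),
    ("acetate", "exp"): dict(uptake=8.0, protein=0.40, lipid=0.14, gam=126.0,
                             ngam=1.2, translation=2.2),
    ("acetate", "nlim"): dict(uptake=3.5, protein=0.20, lipid=0.34, gam=130.0,
                              ngam=2.8, translation=0.8),
}

_ACYL_EXP = {"C16:0": 0.22, "C18:0": 0.05, "C18:1": 0.38, "C18:2": 0.25,
             "C18:3": 0.10}
_ACYL_NLIM = {"C16:0": 0.24, "C18:0": 0.06, "C18:1": 0.52, "C18:2": 0.14,
              "C18:3": 0.04}

_SUBSTRATE_EXCHANGE = {"glucose": "EX_glc", "xylose": "EX_xyl", "acetate": "EX_ac"}


def _composition(variant: str, phase: str) -> BiomassComposition:
    cfg = _PHASE_TABLE[(variant, phase)]
    profile = _ACYL_EXP if phase == "exp" else _ACYL_NLIM
    return BiomassComposition(protein=cfg["protein"], lipid=cfg["lipid"],
                              acyl_profile=dict(profile))


def simulate_condition(
    model: MetabolicModel, spec: ToySpec
) -> Tuple[PhysiologyData, GroundTruth]:
    """Simulate one batch phase: reference fluxes, physiology, proteome truth.

    The reference flux is the parsimonious FBA solution at the phase's
    substrate uptake (with forced byproduct secretion where the emulated
    condition excretes byproducts); enzyme concentrations are planted as
    flux demand / saturation, scaled so model enzymes hold ``f_target`` of
    the proteome; exchange rates get multiplicative lognormal noise at
    ``rate_cv``; the nitrogen-limited phase lowers protein and raises
    lipid in the planted composition.
    """
    cfg = _PHASE_TABLE[(spec.variant, spec.phase)]
    comp = _composition(spec.variant, spec.phase)
    work = rescale_biomass(model, comp)
    biomass = work.get_reaction(work.objective)
    bm_rxn = work.get_reaction("BIOMASS")
    bm_rxn.stoich["atp_c"] = -cfg["gam"]
    ngam_rxn = work.get_reaction("ATPM")
    ngam_rxn.lb = ngam_rxn.ub = cfg["ngam"]
    ex_id = _SUBSTRATE_EXCHANGE[spec.variant]
    ex = work.get_reaction(ex_id)
    ex.lb = ex.ub = -cfg["uptake"]
    byproducts: Dict[str, float] = {}
    if spec.variant == "xylose" and spec.phase == "exp":
        byproducts["EX_xylitol"] = 0.20 * cfg["uptake"]
        if spec.include_dad_bypass:
            byproducts["EX_abt"] = 0.12 * cfg["uptake"]
    if spec.variant == "acetate" and spec.phase == "exp":
        byproducts["EX_cit"] = 0.02 * cfg["uptake"] * 2.0 / 6.0
    for rid, rate in byproducts.items():
        rx = work.get_reaction(rid)
        rx.lb = rx.ub = rate
    sol = optimize.pfba(work)
    if sol.status != "optimal":
        raise RuntimeError(f"toy condition infeasible: {sol.status}")
    flux = sol.flux
    mu = flux["BIOMASS"]
    co2 = flux["EX_co2"]
    o2 = -flux["EX_o2"]

    enzyme_conc, f_true, measured = _plant_enzymes(work, flux, spec, cfg)
    conc_table, ribo_ids, n_rib, mw_table = _plant_proteome(
        work, enzyme_conc, mu, cfg, spec
    )
    physiology_true = PhysiologyData(
        condition=f"{spec.variant}_{spec.phase}",
        mu=mu,
        uptake={ex_id: cfg["uptake"]},
        co2=co2,
        o2=o2,
        byproducts=dict(byproducts),
        ptot=cfg["protein"],
        ptot_sd=0.0,
        lipid=cfg["lipid"],
        acyl_profile=dict(comp.acyl_profile),
        ngam=cfg["ngam"],
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))

    def noisy(x: float) -> float:
        if spec.rate_cv <= 0:
            return x
        sigma = math.sqrt(math.log(1 + spec.rate_cv ** 2))
        return x * rng.lognormal(-0.5 * sigma ** 2, sigma)

    physiology = PhysiologyData(
        condition=physiology_true.condition,
        mu=noisy(mu),
        uptake={k: noisy(v) for k, v in physiology_true.uptake.items()},
        co2=noisy(co2),
        o2=noisy(o2),
        byproducts={k: noisy(v) for k, v in byproducts.items()},
        ptot=noisy(cfg["protein"]),
        ptot_sd=0.0,
        lipid=noisy(cfg["lipid"]),
        acyl_profile=dict(comp.acyl_profile),
        ngam=cfg["ngam"],
    )
    demand = mu * cfg["protein"] / MEAN_AA_MASS  # mol aa/gDCW/h
    truth = GroundTruth(
        flux=flux,
        mu=mu,
        enzyme_conc=enzyme_conc,
        kcats=dict(TRUE_KCATS),
        conc_ug_per_g=conc_table,
        composition=comp,
        physiology=physiology_true,
        f=f_true,
        measured_ids=measured,
        ribosomal_ids=ribo_ids,
        n_rib=n_rib,
        translation_rate=demand / n_rib / 3600.0,
        gam=cfg["gam"],
        ngam=cfg["ngam"],
        protein_mw=mw_table,
    )
    return physiology, truth


def _plant_enzymes(model, flux, spec: ToySpec, cfg) -> Tuple[Dict[str, float], float, List[str]]:
    """Plant enzyme concentrations from flux demand and pick the measured set."""
    enz_map = model.enzyme_map
    need: Dict[str, float] = {e.id: 0.0 for e in model.enzymes}
    for r in model.reactions:
        if not r.gene_rule:
            continue
        v = abs(flux.get(r.id, 0.0))
        if v <= 0:
            continue
        n_iso = len(r.gene_rule)
        for iso in r.gene_rule:
            for enz_id in iso:
                # isozymes share the flux equally; complex subunits each
                # carry the full flux
                need[enz_id] += v / n_iso / (TRUE_KCATS[enz_id] * 3600.0)
    floor = 0.01 * max(need.values())
    conc = {e: max(n / spec.saturation, floor) for e, n in need.items()}
    mass = sum(c * enz_map[e].mw for e, c in conc.items())
    target_mass = spec.f_target * cfg["protein"]
    # scale up to the target proteome share when there is room (adds slack,
    # lowering effective saturation); never scale below the flux demand
    scale = max(1.0, target_mass / mass)
    conc = {e: c * scale for e, c in conc.items()}
    f_true = sum(c * enz_map[e].mw for e, c in conc.items()) / cfg["protein"]
    # measured subset: most abundant (mass-wise) first, while the
    # sigma-discounted budget keeps covering the unmeasured demand
    budget = spec.sigma * f_true * cfg["protein"]
    order = sorted(conc, key=lambda e: (-conc[e] * enz_map[e].mw, e))
    unmeas_need_mass = sum(need[e] * enz_map[e].mw for e in conc)
    measured: List[str] = []
    p_measured = 0.0
    for e in order:
        m_e = conc[e] * enz_map[e].mw
        n_e = need[e] * enz_map[e].mw
        if (budget - (p_measured + m_e)) * MEASURED_POOL_SAFETY >= unmeas_need_mass - n_e:
            measured.append(e)
            p_measured += m_e
            unmeas_need_mass -= n_e
    return conc, f_true, sorted(measured)


def _plant_proteome(model, enzyme_conc, mu, cfg, spec: ToySpec):
    """Full proteome truth table in ug/g protein, plus the ribosome block."""
    enz_map = model.enzyme_map
    ptot = cfg["protein"]
    rows = {}
    mw_table: Dict[str, float] = {}
    for e, c in enzyme_conc.items():
        rows[e] = c * enz_map[e].mw / ptot * 1e6
        mw_table[e] = enz_map[e].mw
    # ribosome block sized to the planted translation rate
    n_rib = mu * ptot / (MEAN_AA_MASS * 3600.0 * cfg["translation"])  # mol/gDCW
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    ribo_ids = [f"RIB_{i:03d}" for i in range(N_RIBOSOMAL)]
    for rid in ribo_ids:
        mw = float(rng.uniform(12.0, 45.0))  # g/mmol
        mw_table[rid] = mw
        rows[rid] = n_rib * 1000.0 * mw / ptot * 1e6  # mmol/gDCW * g/mmol
    # background proteome fills the remaining mass
    bg_ids = [f"BG_{i:03d}" for i in range(N_BACKGROUND)]
    sizes = rng.lognormal(0.0, 1.0, size=N_BACKGROUND)
    used = sum(rows.values())
    residual = 1e6 - used
    if residual <= 0:
        raise RuntimeError("planted enzyme+ribosome mass exceeds the proteome")
    for bid, s in zip(bg_ids, sizes):
        mw_table[bid] = float(rng.uniform(20.0, 120.0))
        rows[bid] = residual * s / sizes.sum()
    conc = pd.Series(rows, name="conc_ug_per_g").sort_index()
    return conc, ribo_ids, n_rib, mw_table


def simulate_proteomics(truth: GroundTruth, spec: ToySpec) -> List[MSRecord]:
    """MS-level records consistent with the planted proteome.

    Heavy-channel iBAQ intensities emulate the heavy-labelled internal
    standard (fixed per protein across replicates); light intensities are
    proportional to the true concentrations with multiplicative lognormal
    noise; H/L ratios are the quotient, so total-protein-approach
    quantification recovers the truth exactly at zero noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    condition = truth.physiology.condition
    proteins = list(truth.conc_ug_per_g.index)
    is_abund = {p: float(rng.lognormal(13.0, 1.0)) for p in proteins}
    scale = 2.0e3  # arbitrary intensity units per ug/g
    sigma = (
        math.sqrt(math.log(1 + spec.proteomics_cv ** 2))
        if spec.proteomics_cv > 0
        else 0.0
    )
    records: List[MSRecord] = []
    for rep in range(1, spec.n_replicates + 1):
        for p in proteins:
            light = truth.conc_ug_per_g[p] * scale
            if sigma > 0:
                light *= rng.lognormal(-0.5 * sigma ** 2, sigma)
            records.append(
                MSRecord(
                    protein_id=p,
                    ibaq_heavy=is_abund[p],
                    ratio_hl=is_abund[p] / light,
                    mw=truth.protein_mw[p],
                    replicate=rep,
                    condition=condition,
                )
            )
    return records


def write_proteomics_tsv(records: Sequence[MSRecord], path) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "condition": [r.condition for r in records],
            "replicate": [r.replicate for r in records],
            "ibaq_heavy": [r.ibaq_heavy for r in records],
            "ratio_hl": [r.ratio_hl for r in records],
            "mw_g_per_mol": [r.mw * 1000.0 for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
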