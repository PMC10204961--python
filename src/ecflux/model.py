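"""Stoichiometric model data structures, validation and editing.

The in-memory representation is deliberately light: plain dataclasses plus
index dictionaries, with the stoichiometric matrix built on demand by the
optimisation layer. Flux units are mmol/gDCW/h throughout; the default
"unbounded" magnitude is 1000 mmol/gDCW/h. Uptake is a negative flux on
exchange reactions.
"""

from __future__ import annotations

import copy as _copy
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chem import parse_formula

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0


class ValidationError(ValueError):
    """A model violates a structural invariant; lists offending ids."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None

    def copy(self) -> "Metabolite":
        return _copy.deepcopy(self)


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds.

    ``gene_rule`` is a list of isozymes; each isozyme is a list of enzyme
    ids that are all required (AND within an isozyme, OR across isozymes).
    """

    id: str
    stoich: Dict[str, float]
    name: str = ""
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    gene_rule: List[List[str]] = field(default_factory=list)
    subsystem: str = ""

    def copy(self) -> "Reaction":
        return _copy.deepcopy(self)

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoich) == 1


@dataclass
class Enzyme:
    """Annotation row for one enzyme: genes, molecular weight, EC numbers.

    ``mw`` is in g/mmol (i.e. kDa): a 50 kDa protein has mw = 50.0.
    """

    id: str
    genes: List[str] = field(default_factory=list)
    mw: float = 0.0
    ec_numbers: List[str] = field(default_factory=list)


@dataclass
class FluxDistribution:
    flux: Dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.flux[rxn_id]


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    enzymes: List[Enzyme] = field(default_factory=list)
    objective: str = ""
    compartments: Dict[str, str] = field(default_factory=dict)
    meta: Dict = field(default_factory=dict)  # opaque annotations, preserved

    # -- indexing ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def met_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def rxn_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def get_enzyme(self, enz_id: str) -> Enzyme:
        for e in self.enzymes:
            if e.id == enz_id:
                return e
        raise KeyError(enz_id)

    @property
    def enzyme_map(self) -> Dict[str, Enzyme]:
        return {e.id: e for e in self.enzymes}

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every violated invariant."""
        problems: List[str] = []
        met_ids = self.metabolite_ids
        seen = set()
        for mid in met_ids:
            if mid in seen:
                problems.append(f"duplicate metabolite id {mid!r}")
            seen.add(mid)
        seen = set()
        for rid in self.reaction_ids:
            if rid in seen:
                problems.append(f"duplicate reaction id {rid!r}")
            seen.add(rid)
        met_set = set(met_ids)
        if self.compartments:
            for m in self.metabolites:
                if m.compartment not in self.compartments:
                    problems.append(
                        f"metabolite {m.id!r} in undeclared compartment {m.compartment!r}"
                    )
        for r in self.reactions:
            if not r.stoich:
                problems.append(f"reaction {r.id!r} has empty stoichiometry")
            if r.lb > r.ub:
                problems.append(f"reaction {r.id!r} has lb > ub ({r.lb} > {r.ub})")
            for mid in r.stoich:
                if mid not in met_set:
                    problems.append(
                        f"reaction {r.id!r} references missing metabolite {mid!r}"
                    )
        if self.objective and self.objective not in set(self.reaction_ids):
            problems.append(f"objective {self.objective!r} is not a reaction id")
        if problems:
            raise ValidationError("; ".join(problems))

    # -- matrix -----------------------------------------------------------
    def stoichiometric_matrix(self):
        """Dense S matrix (metabolites x reactions), numpy array."""
        import numpy as np

        midx = self.met_index()
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoich.items():
                S[midx[mid], j] = coef
        return S

    def bounds_arrays(self):
        import numpy as np

        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub


# -- editing operations ---------------------------------------------------

def add_pathway(
    model: MetabolicModel,
    new_mets: Sequence[Metabolite],
    new_rxns: Sequence[Reaction],
    check_balance: bool = True,
) -> MetabolicModel:
    """Return a copy of *model* extended with new metabolites and reactions.

    Collisions with existing ids raise ``ValueError``. When formulas are
    available for every participant of a new reaction, an elemental
    imbalance is reported as a warning (pseudo-reactions commonly carry
    lumped species, so imbalance is not an error).
    """
    out = model.copy()
    met_set = set(out.metabolite_ids)
    rxn_set = set(out.reaction_ids)
    for m in new_mets:
        if m.id in met_set:
            raise ValueError(f"metabolite id collision: {m.id!r}")
        met_set.add(m.id)
        out.metabolites.append(m.copy())
    for r in new_rxns:
        if r.id in rxn_set:
            raise ValueError(f"reaction id collision: {r.id!r}")
        rxn_set.add(r.id)
        out.reactions.append(r.copy())
    out.validate()
    if check_balance:
        met_map = {m.id: m for m in out.metabolites}
        for r in new_rxns:
            _warn_if_unbalanced(r, met_map)
    return out


def _warn_if_unbalanced(rxn: Reaction, met_map: Dict[str, Metabolite]) -> None:
    formulas = {mid: met_map[mid].formula for mid in rxn.stoich}
    if any(f is None for f in formulas.values()):
        return
    balance: Dict[str, float] = {}
    for mid, coef in rxn.stoich.items():
        for elem, n in parse_formula(formulas[mid] or "").items():
            balance[elem] = balance.get(elem, 0.0) + coef * n
    imbalance = {e: v for e, v in balance.items() if abs(v) > 1e-6}
    if imbalance:
        logger.warning("reaction %s is elementally unbalanced: %s", rxn.id, imbalance)


#: Conventional reaction/metabolite ids targeted by the scenario toggles.
#: These follow the packaged toy-network naming; override for other models.
SCENARIO_IDS = {
    "xpk": "XPK",
    "pta": "PTA",
    "ack": "ACK",
    "acs": "ACS",
    "dad2": "DAD2",
    "acp": "acp_c",
    "ac": "ac_c",
    "atp": "atp_c",
    "accoa": "accoa_c",
    "nadph": "nadph_c",
    "nadh": "nadh_c",
}

SCENARIOS = ("none", "block_xpk", "swap_pta_to_ack", "dad2_nad_cofactor")


def apply_scenario(
    model: MetabolicModel, scenario: str, ids: Optional[Dict[str, str]] = None
) -> MetabolicModel:
    """Return a copy of *model* with one of the what-if scenarios applied.

    - ``block_xpk``: phosphoketolase bounds set to zero, forcing the
      alternative cytosolic acetyl-CoA routes.
    - ``swap_pta_to_ack``: the phosphotransacetylase route is removed and
      the acetate-kinase route (ACK + ACS) added in its place.
    - ``dad2_nad_cofactor``: the D-arabinitol 2-dehydrogenase (LXR)
      reaction produces NADH instead of NADPH.
    - ``none``: deep copy, unchanged.
    """
    ids = {**SCENARIO_IDS, **(ids or {})}
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out = model.copy()
    if scenario == "none":
        return out
    if scenario == "block_xpk":
        rxn = out.get_reaction(ids["xpk"])
        rxn.lb = rxn.ub = 0.0
        return out
    if scenario == "swap_pta_to_ack":
        try:
            pta = out.get_reaction(ids["pta"])
        except KeyError:
            raise KeyError(f"scenario target reaction {ids['pta']!r} missing")
        pta.lb = pta.ub = 0.0
        new_mets = []
        if ids["ac"] not in set(out.metabolite_ids):
            new_mets.append(Metabolite(ids["ac"], "acetate", "c", "C2H4O2"))
        new_rxns = []
        existing = set(out.reaction_ids)
        if ids["ack"] not in existing:
            new_rxns.append(
                Reaction(
                    ids["ack"],
                    {ids["acp"]: -1, ids["ac"]: 1, ids["atp"]: 1},
                    name="acetate kinase",
                    lb=0.0,
                    subsystem="pyruvate metabolism",
                )
            )
        if ids["acs"] not in existing:
            new_rxns.append(
                Reaction(
                    ids["acs"],
                    {ids["ac"]: -1, ids["atp"]: -2, ids["accoa"]: 1},
                    name="acetyl-CoA synthetase",
                    lb=0.0,
                    subsystem="pyruvate metabolism",
                )
            )
        return add_pathway(out, new_mets, new_rxns, check_balance=False)
    if scenario == "dad2_nad_cofactor":
        rxn = out.get_reaction(ids["dad2"])
        if ids["nadph"] not in rxn.stoich:
            raise ValueError(
                f"reaction {rxn.id!r} carries no NADPH; cofactor swap undefined"
            )
        coef = rxn.stoich.pop(ids["nadph"])
        rxn.stoich[ids["nadh"]] = rxn.stoich.get(ids["nadh"], 0.0) + coef
        if math.isclose(rxn.stoich[ids["nadh"]], 0.0, abs_tol=1e-12):
            del rxn.stoich[ids["nadh"]]
        return out
    raise AssertionError("unreachable")
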