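"""GECKO-style enzyme-constrained model construction.

The enzyme-capacity constraint v <= E * kcat (E in mmol/gDCW, kcat in 1/s)
is encoded, as in the GECKO toolbox, by giving every enzyme a
pseudo-metabolite that each catalysed reaction consumes with coefficient
-1/(kcat*3600) (converting 1/s to 1/h) and that a usage reaction produces.
Unmeasured enzymes draw their mass (usage * MW) from a shared protein pool
bounded by sigma * f * Ptot g/gDCW; measured enzymes are bounded directly
by their concentration.

Reversible reactions are split into forward/reverse pairs and reactions
with multiple isozymes are expanded into per-isozyme copies behind an
"arm" reaction, so that every enzymatic flux is non-negative and carries
exactly one isozyme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DEFAULT_BOUND, Enzyme, MetabolicModel, Metabolite, Reaction
from . import optimize

logger = logging.getLogger(__name__)

PROT_PREFIX = "prot_"
USAGE_PREFIX = "usage_"
POOL_MET = "prot_pool"
POOL_RXN = "prot_pool_exchange"
ARM_PREFIX = "arm_"
PMET_PREFIX = "pmet_"
REV_SUFFIX = "_REV"
SECONDS_PER_HOUR = 3600.0


@dataclass
class KcatRecord:
    ec_number: str
    substrate: str
    organism: str
    kcat: float  # 1/s

    def __post_init__(self):
        if self.kcat <= 0:
            raise ValueError(f"kcat must be positive, got {self.kcat}")


@dataclass
class CurationEntry:
    enzyme_id: str
    new_kcat: float  # 1/s
    reaction_id: Optional[str] = None  # None: all reactions of the enzyme
    old_kcat: Optional[float] = None
    rationale: str = ""

    def __post_init__(self):
        if self.new_kcat <= 0:
            raise ValueError(f"new_kcat must be positive, got {self.new_kcat}")


@dataclass
class ECModel:
    """An enzyme-constrained model plus the bookkeeping to map back."""

    model: MetabolicModel
    base: MetabolicModel
    kcat_map: Dict[str, Dict[str, float]]  # reaction -> enzyme -> kcat (1/s)
    provenance: Dict[str, Dict[str, object]] = field(default_factory=dict)
    sigma: float = 0.35
    f: float = 0.5
    ptot: float = 0.5
    measured: Dict[str, float] = field(default_factory=dict)  # enzyme -> mmol/gDCW

    @property
    def pool_ub(self) -> float:
        return self.model.get_reaction(POOL_RXN).ub

    @pool_ub.setter
    def pool_ub(self, value: float) -> None:
        self.model.get_reaction(POOL_RXN).ub = value

    @property
    def enzyme_ids(self) -> List[str]:
        out = sorted({e for per in self.kcat_map.values() for e in per})
        return out

    def usage_reaction(self, enzyme_id: str) -> Reaction:
        return self.model.get_reaction(USAGE_PREFIX + enzyme_id)

    def copy(self) -> "ECModel":
        import copy as _c

        return _c.deepcopy(self)

    def fba(self, objective: Optional[str] = None, sense: str = "max"):
        return optimize.fba(self.model, objective, sense)


# -- structural transforms ------------------------------------------------

def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Make every reaction irreversible (lb >= 0).

    Each reversible reaction becomes a forward copy (original id) and a
    reverse copy (id + "_REV") with negated stoichiometry. The mapping to
    the base formalism is kept in ``meta["split_map"]`` as
    ``new_id -> [base_id, sign]``.
    """
    out = model.copy()
    split_map: Dict[str, List] = {}
    new_reactions: List[Reaction] = []
    for r in out.reactions:
        if r.lb >= 0:
            split_map[r.id] = [r.id, 1]
            new_reactions.append(r)
            continue
        if r.ub > 0:
            fwd = r.copy()
            fwd.lb = 0.0
            new_reactions.append(fwd)
            split_map[fwd.id] = [r.id, 1]
        rev = r.copy()
        rev.id = r.id + REV_SUFFIX
        rev.stoich = {k: -v for k, v in r.stoich.items()}
        rev.lb = max(0.0, -r.ub)
        rev.ub = -r.lb
        new_reactions.append(rev)
        split_map[rev.id] = [r.id, -1]
    out.reactions = new_reactions
    out.meta = dict(out.meta)
    out.meta["split_map"] = split_map
    out.validate()
    return out


def expand_isozymes(model: MetabolicModel) -> MetabolicModel:
    """Expand multi-isozyme reactions into per-isozyme copies + arm reaction.

    A reaction with N >= 2 isozymes becomes an arm reaction converting its
    substrates into an intermediate pseudo-metabolite and N copies
    converting the intermediate into the products, so copy fluxes sum to
    the arm flux. Requires an irreversible model.
    """
    if any(r.lb < 0 for r in model.reactions):
        raise ValueError("expand_isozymes requires an irreversible model")
    out = model.copy()
    iso_map: Dict[str, str] = {}
    arms: List[str] = []
    new_reactions: List[Reaction] = []
    for r in out.reactions:
        if len(r.gene_rule) < 2:
            new_reactions.append(r)
            continue
        pmet_id = PMET_PREFIX + r.id
        out.metabolites.append(
            Metabolite(pmet_id, name=f"intermediate of {r.id}", compartment="c")
        )
        subs = {m: c for m, c in r.stoich.items() if c < 0}
        prods = {m: c for m, c in r.stoich.items() if c > 0}
        arm = Reaction(
            ARM_PREFIX + r.id,
            {**subs, pmet_id: 1.0},
            name=f"arm of {r.name or r.id}",
            lb=r.lb,
            ub=r.ub,
            subsystem=r.subsystem,
        )
        arms.append(arm.id)
        new_reactions.append(arm)
        for i, iso in enumerate(r.gene_rule, start=1):
            copy_id = f"{r.id}_No{i}"
            new_reactions.append(
                Reaction(
                    copy_id,
                    {pmet_id: -1.0, **prods},
                    name=f"{r.name or r.id} (isozyme {i})",
                    lb=0.0,
                    ub=r.ub,
                    gene_rule=[list(iso)],
                    subsystem=r.subsystem,
                )
            )
            iso_map[copy_id] = r.id
    out.reactions = new_reactions
    out.meta = dict(out.meta)
    out.meta["isozyme_map"] = iso_map
    out.meta["arm_reactions"] = arms
    out.validate()
    return out


# -- kcat matching ---------------------------------------------------------

#: relaxation levels, in strictly decreasing stringency
MATCH_LEVELS = (
    "ec+substrate+organism",
    "ec+substrate",
    "ec+organism",
    "ec",
    "ec-wildcard",
)


def _ec_wildcard_match(query: str, record: str) -> bool:
    """Match on the first three EC fields (last field wildcarded)."""
    q = query.split(".")[:3]
    r = record.split(".")[:3]
    return len(q) == 3 and q == r


def match_kcats(
    model: MetabolicModel,
    kcat_db: Sequence[KcatRecord],
    organism: str,
    aggregation: str = "max",
) -> Tuple[Dict[str, Dict[str, float]], Dict[str, Dict[str, object]]]:
    """Assign a kcat to every (reaction, enzyme) pair with stepwise relaxation.

    Levels, in order: exact EC + substrate + organism; EC + substrate (any
    organism); EC + organism (any substrate); EC alone; EC with the last
    field wildcarded. Within a level the maximum (or median, per
    ``aggregation``) kcat is taken. Enzymes with no match at any level are
    left unconstrained and logged.
    """
    if aggregation not in ("max", "median"):
        raise ValueError("aggregation must be 'max' or 'median'")
    enz_map = model.enzyme_map
    assignment: Dict[str, Dict[str, float]] = {}
    provenance: Dict[str, Dict[str, object]] = {}
    org = organism.lower()
    met_names = {m.id: (m.name or m.id).lower() for m in model.metabolites}
    for r in model.reactions:
        if not r.gene_rule:
            continue
        substrates = {
            met_names[mid]
            for mid, coef in r.stoich.items()
            if coef < 0 and not mid.startswith((PMET_PREFIX, PROT_PREFIX))
        }
        for iso in r.gene_rule:
            for enz_id in iso:
                enz = enz_map.get(enz_id)
                if enz is None or not enz.ec_numbers:
                    logger.info("enzyme %s lacks EC annotation; unconstrained", enz_id)
                    continue
                hit = _match_one(enz.ec_numbers, substrates, org, kcat_db, aggregation)
                if hit is None:
                    logger.info(
                        "no kcat for enzyme %s (EC %s); left unconstrained",
                        enz_id,
                        ",".join(enz.ec_numbers),
                    )
                    continue
                kcat, level = hit
                assignment.setdefault(r.id, {})[enz_id] = kcat
                provenance.setdefault(r.id, {})[enz_id] = level
    return assignment, provenance


def _match_one(
    ec_numbers: Sequence[str],
    substrates: set,
    organism: str,
    kcat_db: Sequence[KcatRecord],
    aggregation: str,
) -> Optional[Tuple[float, str]]:
    for level in MATCH_LEVELS:
        hits: List[float] = []
        for rec in kcat_db:
            if level == "ec-wildcard":
                ec_ok = any(_ec_wildcard_match(q, rec.ec_number) for q in ec_numbers)
            else:
                ec_ok = rec.ec_number in ec_numbers
            if not ec_ok:
                continue
            sub_ok = rec.substrate.lower() in substrates
            org_ok = rec.organism.lower() == organism
            if level == "ec+substrate+organism" and not (sub_ok and org_ok):
                continue
            if level == "ec+substrate" and not sub_ok:
                continue
            if level == "ec+organism" and not org_ok:
                continue
            hits.append(rec.kcat)
        if hits:
            value = max(hits) if aggregation == "max" else float(np.median(hits))
            return value, level
    return None


# -- EC model construction -------------------------------------------------

def build_ec_model(
    model: MetabolicModel,
    kcats: Dict[str, Dict[str, float]],
    sigma: float,
    f: float,
    ptot: float,
    provenance: Optional[Dict[str, Dict[str, object]]] = None,
    base: Optional[MetabolicModel] = None,
) -> ECModel:
    """Build the enzyme-constrained model from an irreversible,
    isozyme-expanded model and a kcat assignment.

    Every constrained reaction r with enzyme e gains stoichiometry
    -1/(kcat*3600) on e's pseudo-metabolite; usage reactions produce the
    pseudo-metabolites while draining MW gram of the shared pool per mmol.
    The pool exchange is bounded by sigma * f * ptot (g/gDCW).
    """
    if not (0 < sigma <= 1):
        raise ValueError(f"sigma must be in (0, 1], got {sigma}")
    if not (0 < f <= 1):
        raise ValueError(f"f must be in (0, 1], got {f}")
    if any(r.lb < 0 for r in model.reactions):
        raise ValueError("build_ec_model requires an irreversible model")
    ec = model.copy()
    enz_map = ec.enzyme_map
    used_enzymes = sorted({e for per in kcats.values() for e in per})
    for rid, per in kcats.items():
        for enz_id, kcat in per.items():
            if kcat <= 0:
                raise ValueError(f"kcat for ({rid}, {enz_id}) must be positive")
            if enz_id not in enz_map:
                raise ValueError(f"enzyme {enz_id!r} missing from enzyme table")
            if enz_map[enz_id].mw <= 0:
                raise ValueError(f"enzyme {enz_id!r} has no molecular weight")
    ec.metabolites.append(Metabolite(POOL_MET, "shared enzyme pool", "c"))
    ec.reactions.append(
        Reaction(
            POOL_RXN,
            {POOL_MET: 1.0},
            name="protein pool exchange (g/gDCW)",
            lb=0.0,
            ub=sigma * f * ptot,
        )
    )
    for enz_id in used_enzymes:
        ec.metabolites.append(
            Metabolite(PROT_PREFIX + enz_id, f"enzyme {enz_id}", "c")
        )
        ec.reactions.append(
            Reaction(
                USAGE_PREFIX + enz_id,
                {POOL_MET: -enz_map[enz_id].mw, PROT_PREFIX + enz_id: 1.0},
                name=f"usage of {enz_id} (mmol/gDCW)",
                lb=0.0,
                ub=DEFAULT_BOUND,
            )
        )
    ridx = {r.id: r for r in ec.reactions}
    for rid, per in kcats.items():
        for enz_id, kcat in per.items():
            ridx[rid].stoich[PROT_PREFIX + enz_id] = -1.0 / (kcat * SECONDS_PER_HOUR)
    ec.validate()
    return ECModel(
        model=ec,
        base=base if base is not None else model,
        kcat_map={r: dict(p) for r, p in kcats.items()},
        provenance={r: dict(p) for r, p in (provenance or {}).items()},
        sigma=sigma,
        f=f,
        ptot=ptot,
    )


def set_reaction_kcat(ec: ECModel, rxn_id: str, enz_id: str, kcat: float) -> None:
    """Update one (reaction, enzyme) kcat in place (coefficient + map)."""
    if kcat <= 0:
        raise ValueError("kcat must be positive")
    rxn = ec.model.get_reaction(rxn_id)
    key = PROT_PREFIX + enz_id
    if key not in rxn.stoich:
        raise KeyError(f"reaction {rxn_id!r} is not constrained by enzyme {enz_id!r}")
    rxn.stoich[key] = -1.0 / (kcat * SECONDS_PER_HOUR)
    ec.kcat_map[rxn_id][enz_id] = kcat


def apply_kcat_curation(ec: ECModel, entries: Sequence[CurationEntry]) -> ECModel:
    """Return a copy with manually curated kcat values applied."""
    out = ec.copy()
    for entry in entries:
        targets = []
        for rid, per in out.kcat_map.items():
            if entry.enzyme_id in per and (
                entry.reaction_id is None or entry.reaction_id == rid
            ):
                targets.append(rid)
        if not targets:
            raise KeyError(
                f"curation target ({entry.enzyme_id}, {entry.reaction_id}) not found"
            )
        for rid in targets:
            set_reaction_kcat(out, rid, entry.enzyme_id, entry.new_kcat)
            out.provenance.setdefault(rid, {})[entry.enzyme_id] = "curated"
    return out


# -- sensitivity / curation loop ------------------------------------------

def _enzyme_shadow_prices(ec: ECModel, objective: Optional[str] = None) -> Dict[str, float]:
    """Shadow prices of the enzyme pseudo-metabolite balances at max growth."""
    model = ec.model
    objective = objective or model.objective
    ridx = model.rxn_index()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(model.reactions))
    c[ridx[objective]] = -1.0
    res = optimize.solve_lp(c, S, np.zeros(S.shape[0]), lb, ub)
    if res.status != 0:
        return {}
    marg = res.eqlin.marginals
    midx = model.met_index()
    out = {}
    for enz_id in ec.enzyme_ids:
        key = PROT_PREFIX + enz_id
        if key in midx:
            out[enz_id] = float(marg[midx[key]])
    return out


def db_max_kcat(enzyme: Enzyme, kcat_db: Sequence[KcatRecord]) -> Optional[float]:
    """Largest kcat in the database sharing the first three EC fields."""
    hits = [
        rec.kcat
        for rec in kcat_db
        if any(_ec_wildcard_match(q, rec.ec_number) for q in enzyme.ec_numbers)
    ]
    return max(hits) if hits else None


def sensitivity_top_kcat(
    ec: ECModel,
    target_growth: float,
    kcat_db: Sequence[KcatRecord],
    max_rounds: int = 50,
) -> Tuple[ECModel, List[Dict]]:
    """Iteratively relax the most limiting kcat until growth is reached.

    Each round solves max growth, ranks enzymes by |shadow price of their
    balance| / kcat (ties broken by enzyme id), and replaces the top
    enzyme's kcats with the database maximum for its EC class. Returns the
    relaxed model and the replacement trace; if the target remains
    unreachable the trace's last entry carries the final gap.
    """
    out = ec.copy()
    trace: List[Dict] = []
    enz_map = out.model.enzyme_map
    replaced = set()
    for _ in range(max_rounds):
        sol = out.fba()
        mu = sol.objective_value if sol.status == "optimal" else 0.0
        if sol.status == "optimal" and mu >= target_growth * (1 - 1e-6):
            return out, trace
        prices = _enzyme_shadow_prices(out)
        candidates = []
        for enz_id, price in prices.items():
            if enz_id in replaced or abs(price) < 1e-12:
                continue
            kmin = min(
                per[enz_id] for per in out.kcat_map.values() if enz_id in per
            )
            candidates.append((abs(price) / kmin, enz_id, kmin))
        if not candidates:
            trace.append({"enzyme": None, "gap": target_growth - mu, "note": "no limiting kcat"})
            return out, trace
        candidates.sort(key=lambda t: (-t[0], t[1]))
        _, enz_id, old_kcat = candidates[0]
        new_kcat = db_max_kcat(enz_map[enz_id], kcat_db)
        replaced.add(enz_id)
        if new_kcat is None or new_kcat <= old_kcat:
            continue
        for rid, per in out.kcat_map.items():
            if enz_id in per:
                set_reaction_kcat(out, rid, enz_id, new_kcat)
                out.provenance.setdefault(rid, {})[enz_id] = "sensitivity-relaxed"
        trace.append(
            {"enzyme": enz_id, "old_kcat": old_kcat, "new_kcat": new_kcat,
             "growth_before": mu}
        )
    sol = out.fba()
    mu = sol.objective_value if sol.status == "optimal" else 0.0
    if mu < target_growth * (1 - 1e-6):
        trace.append({"enzyme": None, "gap": target_growth - mu, "note": "max rounds"})
    return out, trace


def read_kcat_tsv(path) -> List[KcatRecord]:
    """kcat database TSV: ec_number, substrate, organism, kcat_per_s[, source]."""
    df = pd.read_csv(path, sep="\t")
    required = {"ec_number", "substrate", "organism", "kcat_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kcat TSV missing columns: {sorted(missing)}")
    return [
        KcatRecord(str(r.ec_number), str(r.substrate), str(r.organism),
                   float(r.kcat_per_s))
        for r in df.itertuples()
    ]


def write_kcat_tsv(records: Sequence[KcatRecord], path, source: str = "synthetic") -> None:
    pd.DataFrame(
        {
            "ec_number": [r.ec_number for r in records],
            "substrate": [r.substrate for r in records],
            "organism": [r.organism for r in records],
            "kcat_per_s": [r.kcat for r in records],
            "source": source,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_curation_tsv(path) -> List[CurationEntry]:
    """Curation TSV: enzyme_id, reaction_id (optional), new_kcat_per_s, rationale."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for r in df.itertuples():
        rid = getattr(r, "reaction_id", None)
        if rid is not None and (pd.isna(rid) or rid == ""):
            rid = None
        entries.append(
            CurationEntry(
                enzyme_id=str(r.enzyme_id),
                new_kcat=float(r.new_kcat_per_s),
                reaction_id=rid,
                rationale=str(getattr(r, "rationale", "")),
            )
        )
    return entries


def top_used_enzymes(ec: ECModel, solution, n: int = 10) -> pd.DataFrame:
    """Mass-wise enzyme usages (g/gDCW and % of the total enzyme budget),
    sorted descending; entries above 1% of the budget are flagged."""
    enz_map = ec.model.enzyme_map
    budget = ec.sigma * ec.f * ec.ptot
    rows = []
    for enz_id in ec.enzyme_ids:
        usage = solution.flux.get(USAGE_PREFIX + enz_id, 0.0)
        mass = usage * enz_map[enz_id].mw
        rows.append(
            {
                "enzyme": enz_id,
                "usage_mmol_gdcw": usage,
                "mass_g_gdcw": mass,
                "pct_of_pool": 100.0 * mass / budget if budget > 0 else np.nan,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["mass_g_gdcw", "enzyme"], ascending=[False, True]
    )
    df["flagged"] = df["pct_of_pool"] > 1.0
    return df.head(n).reset_index(drop=True)
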