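"""Random sampling of the constrained flux solution space.

Each iteration draws three distinct interior reactions (no exchanges,
enzyme-usage reactions or pool drain), gives them i.i.d. uniform (0, 1]
weights, maximises the weighted flux sum, and then — holding that
objective within 1e-6 relative — minimises the total flux of the
irreversible model (the parsimonious step). The per-reaction summary is
median, SD and variability% = 100 * SD / |median|, with the variability
left undefined (NaN) for reactions whose median is numerically zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ec import ARM_PREFIX, ECModel, POOL_RXN, USAGE_PREFIX
from .model import FluxDistribution, MetabolicModel
from . import optimize

logger = logging.getLogger(__name__)

ZERO_MEDIAN = 1e-9


@dataclass
class FluxSample:
    """Sampled flux distributions: iterations x reactions, mmol/gDCW/h."""

    matrix: pd.DataFrame
    seed: Optional[int]
    n_iter: int

    @property
    def summary(self) -> pd.DataFrame:
        return flux_statistics(self)


def eligible_objective_reactions(model: MetabolicModel) -> List[str]:
    """Interior reactions eligible as random objectives."""
    out = []
    for r in model.reactions:
        if r.is_exchange or r.id == POOL_RXN or r.id.startswith(USAGE_PREFIX):
            continue
        out.append(r.id)
    return out


def sample_fluxes(
    model: Union[ECModel, MetabolicModel],
    n_iter: int = 2000,
    seed: Optional[int] = None,
    n_objective: int = 3,
    rel_tol: float = 1e-6,
) -> FluxSample:
    """Sample the solution space with random parsimonious objectives.

    Reproducible: the master seed spawns one deterministic stream per
    iteration. An iteration whose LP fails is retried once with fresh
    draws, then logged and skipped.
    """
    m = model.model if isinstance(model, ECModel) else model
    if any(r.lb < 0 for r in m.reactions):
        raise ValueError("sampling requires an irreversible model")
    ridx = m.rxn_index()
    S = m.stoichiometric_matrix()
    lb, ub = m.bounds_arrays()
    b_eq = np.zeros(S.shape[0])
    feas = optimize.solve_lp(np.zeros(len(m.reactions)), S, b_eq, lb, ub)
    if feas.status != 0:
        raise RuntimeError(
            f"model infeasible under current constraints (HiGHS status {feas.status})"
        )
    eligible = eligible_objective_reactions(m)
    if len(eligible) < n_objective:
        raise ValueError("not enough interior reactions for random objectives")
    eligible_idx = np.array([ridx[r] for r in eligible])
    n = len(m.reactions)
    ones = np.ones(n)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_iter)]
    rows = []
    kept = []
    for it, rng in enumerate(streams):
        row = None
        for _attempt in range(2):
            chosen = rng.choice(eligible_idx, size=n_objective, replace=False)
            weights = 1.0 - rng.random(n_objective)  # uniform on (0, 1]
            c = np.zeros(n)
            c[chosen] = -weights
            res1 = optimize.solve_lp(c, S, b_eq, lb, ub)
            if res1.status != 0:
                continue
            achieved = -res1.fun
            slack = abs(achieved) * rel_tol + 1e-9
            res2 = optimize.solve_lp(
                ones, S, b_eq, lb, ub,
                A_ub=c[None, :], b_ub=np.array([-(achieved - slack)]),
            )
            if res2.status != 0:
                continue
            row = res2.x
            break
        if row is None:
            logger.warning("sampling iteration %d failed twice; skipped", it)
            continue
        rows.append(row)
        kept.append(it)
    matrix = pd.DataFrame(np.array(rows), index=kept, columns=m.reaction_ids)
    return FluxSample(matrix=matrix, seed=seed, n_iter=n_iter)


def flux_statistics(sample: FluxSample) -> pd.DataFrame:
    """Median, SD and variability% per reaction over the sampled rows."""
    if sample.matrix.shape[0] < 2:
        raise ValueError("flux statistics need at least 2 sampled rows")
    median = sample.matrix.median(axis=0)
    sd = sample.matrix.std(axis=0, ddof=1)
    variability = pd.Series(np.nan, index=median.index)
    nonzero = median.abs() >= ZERO_MEDIAN
    variability[nonzero] = 100.0 * sd[nonzero] / median[nonzero].abs()
    return pd.DataFrame(
        {"median": median, "sd": sd, "variability_pct": variability}
    )


def _base_mapping(model: MetabolicModel) -> Dict[str, tuple]:
    """reaction id in the EC/irreversible model -> (base id, sign)."""
    split_map = model.meta.get("split_map", {})
    iso_map = model.meta.get("isozyme_map", {})
    arms = set(model.meta.get("arm_reactions", []))
    out: Dict[str, tuple] = {}
    for r in model.reactions:
        rid = r.id
        if rid in arms or rid == POOL_RXN or rid.startswith(USAGE_PREFIX):
            continue
        parent = iso_map.get(rid, rid)
        if parent in split_map:
            base_id, sign = split_map[parent]
        else:
            base_id, sign = parent, 1
        out[rid] = (base_id, sign)
    return out


def map_to_base(
    fluxes: Union[FluxSample, FluxDistribution, dict, pd.DataFrame],
    ec: Union[ECModel, MetabolicModel],
    base: Optional[MetabolicModel] = None,
) -> Union[pd.DataFrame, Dict[str, float]]:
    """Convert EC-formalism fluxes to net fluxes on base reaction ids.

    Forward minus reverse copies, isozyme copies summed into their parent,
    arm/usage/pool reactions dropped. Accepts a sample matrix (returns a
    DataFrame) or a single distribution/dict (returns a dict).
    """
    model = ec.model if isinstance(ec, ECModel) else ec
    if base is None and isinstance(ec, ECModel):
        base = ec.base
    mapping = _base_mapping(model)
    base_ids = sorted({bid for bid, _ in mapping.values()})
    if base is not None:
        known = [r.id for r in base.reactions if r.id in set(base_ids)]
        base_ids = known + [b for b in base_ids if b not in set(known)]
    if isinstance(fluxes, FluxSample):
        frame = fluxes.matrix
    elif isinstance(fluxes, pd.DataFrame):
        frame = fluxes
    else:
        flux_map = fluxes.flux if isinstance(fluxes, FluxDistribution) else fluxes
        net = {bid: 0.0 for bid in base_ids}
        for rid, (bid, sign) in mapping.items():
            net[bid] += sign * flux_map.get(rid, 0.0)
        return net
    out = pd.DataFrame(0.0, index=frame.index, columns=base_ids)
    for rid, (bid, sign) in mapping.items():
        if rid in frame.columns:
            out[bid] += sign * frame[rid]
    return out
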