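"""Derived flux quantities: uptake-normalised fluxes, apparent catalytic
activities (k_app = v / E), cofactor turnover/yield and the NADPH
trade-off table.

Turnover of a cofactor is computed as the production half-sum over every
reaction carrying the metabolite (summing max(0, s*v)); at steady state
this equals the consumption half-sum, which avoids the double counting a
literal "sum of fluxes involving the metabolite" would entail. All
compartment instances of the cofactor are pooled by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ec import ECModel, PROT_PREFIX, SECONDS_PER_HOUR, USAGE_PREFIX
from .model import MetabolicModel


def normalize_by_uptake(
    net_fluxes: Mapping[str, float], uptake: float
) -> Dict[str, float]:
    """Fluxes as % of the substrate uptake rate (mole-based)."""
    if uptake <= 0:
        raise ValueError("uptake rate must be positive")
    return {rid: 100.0 * v / uptake for rid, v in net_fluxes.items()}


def compute_kapp(
    net_fluxes: Mapping[str, float],
    ec: ECModel,
    abundance: Mapping[str, float],
) -> pd.DataFrame:
    """Apparent catalytic activities k_app = v / (E * 3600) in 1/s.

    ``net_fluxes`` are base-formalism net fluxes (mmol/gDCW/h),
    ``abundance`` molar enzyme abundances (mmol/gDCW). Enzyme-reaction
    pairs without a measured abundance are excluded with a reason column.
    """
    from .sampling import _base_mapping

    base_of = _base_mapping(ec.model)
    rows = []
    seen = set()
    for rid, per in ec.kcat_map.items():
        base_id, _sign = base_of.get(rid, (rid, 1))
        for enz_id, kcat in per.items():
            key = (base_id, enz_id)
            if key in seen:
                continue
            seen.add(key)
            v = abs(net_fluxes.get(base_id, 0.0))
            e_conc = abundance.get(enz_id)
            if e_conc is None or not np.isfinite(e_conc):
                rows.append(
                    dict(reaction=base_id, enzyme=enz_id, flux=v, E=np.nan,
                         kcat_per_s=kcat, kapp_per_s=np.nan, excluded="unmeasured")
                )
                continue
            if e_conc <= 0:
                rows.append(
                    dict(reaction=base_id, enzyme=enz_id, flux=v, E=e_conc,
                         kcat_per_s=kcat, kapp_per_s=np.nan, excluded="zero abundance")
                )
                continue
            kapp = v / (e_conc * SECONDS_PER_HOUR)
            rows.append(
                dict(reaction=base_id, enzyme=enz_id, flux=v, E=e_conc,
                     kcat_per_s=kcat, kapp_per_s=kapp, excluded="")
            )
    return pd.DataFrame(rows)


@dataclass
class TurnoverReport:
    """Cofactor turnover with per-reaction production/consumption shares."""

    metabolite: str
    turnover: float  # mmol/gDCW/h, production half-sum
    yield_per_substrate: float  # mmol per mmol substrate
    shares: pd.DataFrame  # reaction, flux, side, pct_of_turnover


def cofactor_turnover(
    net_fluxes: Mapping[str, float],
    model: MetabolicModel,
    metabolite: str,
    uptake: float,
    compartment: Optional[str] = None,
) -> TurnoverReport:
    """Turnover, per-reaction shares and yield of a cofactor.

    ``metabolite`` is matched against metabolite ids stripped of their
    compartment suffix (e.g. "nadph" matches nadph_c and nadph_m), pooling
    compartments unless one is named.
    """
    if uptake <= 0:
        raise ValueError("uptake rate must be positive")
    target = metabolite.lower()
    met_ids = []
    for m in model.metabolites:
        stem = m.id.lower()
        if stem.endswith("_" + m.compartment.lower()):
            stem = stem[: -(len(m.compartment) + 1)]
        if stem == target and (compartment is None or m.compartment == compartment):
            met_ids.append(m.id)
    rows = []
    production = 0.0
    consumption = 0.0
    for r in model.reactions:
        coef = sum(r.stoich.get(mid, 0.0) for mid in met_ids)
        if coef == 0.0:
            continue
        v = net_fluxes.get(r.id, 0.0)
        rate = coef * v  # >0 production, <0 consumption
        if rate > 0:
            production += rate
            rows.append(dict(reaction=r.id, rate=rate, side="production"))
        elif rate < 0:
            consumption += -rate
            rows.append(dict(reaction=r.id, rate=rate, side="consumption"))
    turnover = production
    shares = pd.DataFrame(rows, columns=["reaction", "rate", "side"])
    if not shares.empty and turnover > 0:
        shares["pct_of_turnover"] = 100.0 * shares["rate"].abs() / turnover
    else:
        shares["pct_of_turnover"] = np.nan
    return TurnoverReport(
        metabolite=metabolite,
        turnover=turnover,
        yield_per_substrate=turnover / uptake,
        shares=shares.sort_values("pct_of_turnover", ascending=False).reset_index(drop=True),
    )


def tradeoff_report(
    turnovers: Mapping[str, TurnoverReport],
    reactions_of_interest: Sequence[str],
) -> pd.DataFrame:
    """Consumption shares of named reactions across conditions.

    One row per condition with the % of cofactor turnover consumed by each
    named reaction (typically glutamate dehydrogenase vs fatty-acid
    synthase for NADPH) plus a flag marking conditions where the dominant
    consumer among them switched relative to the first condition.
    """
    rows = []
    for condition, report in turnovers.items():
        cons = report.shares[report.shares["side"] == "consumption"]
        row = {"condition": condition}
        for rid in reactions_of_interest:
            hit = cons[cons["reaction"] == rid]
            row[rid] = float(hit["pct_of_turnover"].iloc[0]) if len(hit) else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and len(reactions_of_interest):
        dominant = df[list(reactions_of_interest)].idxmax(axis=1)
        df["dominant_consumer"] = dominant
        df["dominant_switched"] = dominant != dominant.iloc[0]
    return df
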