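"""Absolute proteome quantification and downstream proteome analyses.

Implements the total protein approach (TPA): light-channel MS intensities
are reconstructed from the heavy-labelled internal standard (iBAQ heavy /
ratio H/L), normalised by the mean internal-standard abundance, adjusted
for sample recovery, and converted to shares of total protein mass
(ug per g of total protein, summing to 1e6 by construction). Downstream:
conversion to molar abundances (mmol/gDCW), Welch differential expression
with Benjamini-Hochberg correction, GO-group mass allocation, and the
per-ribosome translation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MICROGRAM_PER_GRAM = 1.0e6
MEAN_AA_MASS = 110.0  # g/mol per amino-acid residue


@dataclass
class MSRecord:
    """One protein in one replicate of one condition, at MS-intensity level."""

    protein_id: str
    ibaq_heavy: float  # internal-standard intensity, arbitrary units
    ratio_hl: float  # heavy/light ratio
    mw: float  # g/mmol
    replicate: int = 1
    condition: str = ""

    def __post_init__(self):
        if self.ibaq_heavy < 0:
            raise ValueError(f"{self.protein_id}: ibaq_heavy must be >= 0")


@dataclass
class ProteomeSample:
    """Per-condition absolute protein concentrations (ug/g total protein)."""

    condition: str
    conc: pd.Series  # mean over replicates, ug/g
    sd: pd.Series  # SD over replicates, ug/g
    replicates: pd.DataFrame  # proteins x replicate columns, ug/g
    ptot: float = float("nan")  # g protein / gDCW
    mw: Optional[pd.Series] = None  # g/mmol

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]


def tpa_quantify(
    records: Sequence[MSRecord],
    recovery: float = 0.80,
    ptot: float = float("nan"),
) -> ProteomeSample:
    """Total-protein-approach quantification of one condition.

    Light intensity I_i = ibaq_heavy_i / ratio_hl_i, normalised by the mean
    internal-standard abundance and scaled by 1/recovery; the absolute
    concentration is the share I_i / sum(I) * 1e6 ug per g total protein
    (so any global rescaling of intensities, and the recovery factor
    itself, cancel). Records with a missing/invalid ratio are excluded
    with a log entry.
    """
    if not records:
        raise ValueError("no MS records given")
    conditions = {r.condition for r in records}
    if len(conditions) > 1:
        raise ValueError(f"records span several conditions: {sorted(conditions)}")
    condition = next(iter(conditions))
    rows = []
    for rec in records:
        if not np.isfinite(rec.ratio_hl) or rec.ratio_hl <= 0:
            logger.info("excluding %s (replicate %d): invalid H/L ratio %r",
                        rec.protein_id, rec.replicate, rec.ratio_hl)
            continue
        rows.append(
            (rec.protein_id, rec.replicate, rec.ibaq_heavy / rec.ratio_hl, rec.mw)
        )
    if not rows:
        raise ValueError("no usable MS records after ratio filtering")
    df = pd.DataFrame(rows, columns=["protein_id", "replicate", "intensity", "mw"])
    mean_is = np.mean([r.ibaq_heavy for r in records])
    rep_conc = {}
    for rep, grp in df.groupby("replicate"):
        inten = grp.set_index("protein_id")["intensity"]
        inten = inten / mean_is / recovery  # cancels in the share; kept for clarity
        total = inten.sum()
        if total <= 0:
            raise ValueError(f"replicate {rep}: total intensity is zero")
        rep_conc[rep] = inten / total * MICROGRAM_PER_GRAM
    replicates = pd.DataFrame(rep_conc).sort_index()
    mw = df.groupby("protein_id")["mw"].first().reindex(replicates.index)
    return ProteomeSample(
        condition=condition,
        conc=replicates.mean(axis=1),
        sd=replicates.std(axis=1, ddof=1) if replicates.shape[1] > 1
        else pd.Series(0.0, index=replicates.index),
        replicates=replicates,
        ptot=ptot,
        mw=mw,
    )


def to_molar(
    sample: ProteomeSample,
    mw: Optional[Mapping[str, float]] = None,
    ptot: Optional[float] = None,
    proteins: Optional[Iterable[str]] = None,
) -> Dict[str, float]:
    """Convert mass shares to molar abundances E_i in mmol/gDCW.

    E_i = conc_i (g/g protein) * Ptot (g/gDCW) / MW_i (g/mmol).
    """
    ptot = sample.ptot if ptot is None else ptot
    if not np.isfinite(ptot):
        raise ValueError("total protein content Ptot is required")
    mw_map: Mapping[str, float]
    if mw is not None:
        mw_map = mw
    elif sample.mw is not None:
        mw_map = sample.mw.to_dict()
    else:
        raise ValueError("molecular weights are required")
    ids = list(proteins) if proteins is not None else list(sample.conc.index)
    out: Dict[str, float] = {}
    for pid in ids:
        if pid not in sample.conc.index:
            continue
        if pid not in mw_map or not np.isfinite(mw_map[pid]) or mw_map[pid] <= 0:
            raise KeyError(f"missing molecular weight for protein {pid!r}")
        grams_per_gprot = sample.conc[pid] / MICROGRAM_PER_GRAM
        out[pid] = grams_per_gprot * ptot / mw_map[pid]
    return out


def differential_expression(
    a: ProteomeSample,
    b: ProteomeSample,
    fc_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test on log2 concentrations between two conditions.

    Proteins whose replicate SD exceeds the replicate mean in either
    condition are excluded before testing; p-values are Benjamini-Hochberg
    adjusted over all tested proteins; significance requires
    |log2FC| > fc_cut and adjusted p < alpha.
    """
    for s in (a, b):
        if s.n_replicates < 2:
            raise ValueError(f"condition {s.condition!r} needs >= 2 replicates")
    shared = a.replicates.index.intersection(b.replicates.index)
    keep = []
    for pid in shared:
        ok = True
        for s in (a, b):
            m = s.replicates.loc[pid].mean()
            sd = s.replicates.loc[pid].std(ddof=1)
            if m <= 0 or sd > m:
                ok = False
        if ok:
            keep.append(pid)
    if not keep:
        raise ValueError("no proteins pass the SD <= mean replicate filter")
    la = np.log2(a.replicates.loc[keep])
    lb = np.log2(b.replicates.loc[keep])
    log2fc = lb.mean(axis=1) - la.mean(axis=1)
    tstat, pval = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    pval = np.where(np.isnan(pval), 1.0, pval)
    padj = benjamini_hochberg(pval)
    df = pd.DataFrame(
        {
            "protein_id": keep,
            "log2fc": log2fc.values,
            "p": pval,
            "p_adj": padj,
        }
    )
    df["significant"] = (df["log2fc"].abs() > fc_cut) & (df["p_adj"] < alpha)
    return df


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (statsmodels fdr_bh)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def allocate_go(
    sample: ProteomeSample, go_map: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Proteome mass share (%) per GO group.

    Groups may overlap: a protein counts in every group containing it, so
    shares need not sum to 100%.
    """
    rows = []
    for group, members in go_map.items():
        members = [m for m in members if m in sample.conc.index]
        share = sample.conc.loc[members].sum() / MICROGRAM_PER_GRAM * 100.0
        rows.append({"group": group, "n_proteins": len(members), "pct_mass": share})
    return pd.DataFrame(rows)


def translation_rate(
    sample: ProteomeSample,
    ribosomal_ids: Sequence[str],
    mu: float,
    ptot: Optional[float] = None,
    mean_aa_mass: float = MEAN_AA_MASS,
    estimator: str = "median",
) -> float:
    """Protein synthesis rate per ribosome (amino acids per second).

    The ribosome abundance N_rib (mol/gDCW) is estimated from the molar
    abundances of the detected ribosomal proteins (median by default,
    robust to missing subunits); the proteome-wide synthesis demand is
    mu * Ptot / mean_aa_mass (mol aa/gDCW/h), giving
    rate = demand / N_rib / 3600 aa/s.
    """
    ptot = sample.ptot if ptot is None else ptot
    detected = [p for p in ribosomal_ids if p in sample.conc.index]
    if not detected:
        raise ValueError("no ribosomal proteins detected in the sample")
    molar = to_molar(sample, ptot=ptot, proteins=detected)  # mmol/gDCW
    values = np.array([molar[p] for p in detected]) * 1e-3  # mol/gDCW
    if estimator == "median":
        n_rib = float(np.median(values))
    elif estimator == "mean":
        n_rib = float(np.mean(values))
    elif estimator == "min":
        n_rib = float(np.min(values))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if n_rib <= 0:
        raise ValueError("estimated ribosome abundance is zero")
    demand = mu * ptot / mean_aa_mass  # mol aa / gDCW / h
    return demand / n_rib / 3600.0


def read_proteomics_tsv(path) -> List[MSRecord]:
    """Read MS records from TSV with columns protein_id, condition,
    replicate, ibaq_heavy, ratio_hl, mw_g_per_mol."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "condition", "replicate", "ibaq_heavy", "ratio_hl",
                "mw_g_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"proteomics TSV missing columns: {sorted(missing)}")
    return [
        MSRecord(
            protein_id=row.protein_id,
            ibaq_heavy=float(row.ibaq_heavy),
            ratio_hl=float(row.ratio_hl),
            mw=float(row.mw_g_per_mol) / 1000.0,  # g/mol -> g/mmol
            replicate=int(row.replicate),
            condition=str(row.condition),
        )
        for row in df.itertuples()
    ]
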