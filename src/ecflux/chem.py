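"""Elemental formula handling and medium composition arithmetic.

Small self-contained helpers used for element-balance warnings in model
editing and for molar carbon/nitrogen bookkeeping of growth media.
"""

from __future__ import annotations

import re
from typing import Dict, Mapping

# IUPAC 2021 standard atomic weights (abridged), g/mol.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "Na": 22.990,
    "Mg": 24.305,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cl": 35.45,
    "Zn": 65.38,
    "Mn": 54.938,
    "Cu": 63.546,
    "Co": 58.933,
    "Mo": 95.95,
    "B": 10.81,
    "I": 126.904,
}

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse a flat elemental formula like ``C6H12O6`` into element counts.

    Counts may be non-integer (pseudo-species). Parentheses are not
    supported; write hydrates and salts in expanded form (e.g. ammonium
    sulfate as ``H8N2O4S``).
    """
    if not formula:
        return {}
    counts: Dict[str, float] = {}
    pos = 0
    for m in _ELEMENT_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        counts[elem] = counts.get(elem, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a flat elemental formula."""
    counts = parse_formula(formula)
    if not counts:
        raise ValueError("empty formula has no molar mass")
    return sum(ATOMIC_WEIGHTS[e] * n for e, n in counts.items())


def element_count(formula: str, element: str) -> float:
    return parse_formula(formula).get(element, 0.0)


def molar_cn_ratio(components: Mapping[str, float]) -> float:
    """Molar carbon-to-nitrogen ratio of a medium.

    Parameters
    ----------
    components:
        Map of elemental formula -> concentration in g/L. Both carbon and
        nitrogen are summed over *all* components (urea, for instance,
        contributes to both).

    Returns
    -------
    float
        mol C / mol N.
    """
    carbon = 0.0
    nitrogen = 0.0
    for formula, grams_per_l in components.items():
        counts = parse_formula(formula)
        mol = grams_per_l / molar_mass(formula)
        carbon += mol * counts.get("C", 0.0)
        nitrogen += mol * counts.get("N", 0.0)
    if nitrogen == 0:
        raise ValueError("medium contains no nitrogen source")
    return carbon / nitrogen


#: Seed-culture media (chemically defined, Verduyn trace/vitamin base not
#: carrying C or N in relevant amounts): carbon source + 5 g/L ammonium
#: sulfate. Formulas: xylose C5H10O5, acetic acid C2H4O2, glucose C6H12O6,
#: ammonium sulfate (NH4)2SO4 = H8N2O4S.
SEED_MEDIA: Dict[str, Dict[str, float]] = {
    "xylose": {"C5H10O5": 20.0, "H8N2O4S": 5.0},
    "acetate": {"C2H4O2": 20.0, "H8N2O4S": 5.0},
    "glucose": {"C6H12O6": 18.2, "H8N2O4S": 5.0},
}
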