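"""Formula-based masses, ionization state, and permeability classification.

Covers the arithmetic around a degrader series' physicochemical profile:

* exact (monoisotopic) and average masses from a molecular formula, with the
  ``[M+H]+`` convention of adding one proton mass (electron mass neglected);
* Henderson–Hasselbalch uncharged fraction of a monobasic amine at a given
  pH, ``f = 1 / (1 + 10^(pKa − pH))``;
* the in-cellulo/in-vitro potency ratio used as a cell-permeability
  surrogate, binned into four classes — high (< 40), medium–high (40–100),
  medium–low (100–200) and low (> 200);
* gating of 2D descriptors against the outer limits of oral druggable
  space for PROTACs (MW 950, cLogP 7, HBD 4, HBA 15, TPSA 200, NRotB 14)
  and for the wider beyond-rule-of-5 space (1000/10/6/15/250/20); limits
  are inclusive.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass

from rdkit import Chem

__all__ = [
    "MolecularFormula",
    "PermClass",
    "PermeabilityRecord",
    "DruggableSpaceLimits",
    "PROTAC_LIMITS",
    "BRO5_LIMITS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "fraction_uncharged_base",
    "permeability_ratio_and_class",
    "classify_ratio",
    "gate_druggable_space",
]

_PT = Chem.GetPeriodicTable()
PROTON_MASS = 1.00728  # Da

MolecularFormula = dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style molecular formula string such as ``C49H58N8O9F3S``."""
    text = text.strip()
    pos = 0
    out: MolecularFormula = {}
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        try:
            known = bool(m) and _PT.GetAtomicNumber(m.group(1)) > 0
        except RuntimeError:
            known = False
        if not known:
            raise ValueError(f"unparseable formula at {text[pos:]!r}")
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if not out:
        raise ValueError("empty molecular formula")
    return out


def _as_formula(f: MolecularFormula | str) -> MolecularFormula:
    if isinstance(f, str):
        return parse_formula(f)
    if not f or any(n < 0 or n != int(n) for n in f.values()):
        raise ValueError("formula counts must be non-negative integers")
    return f


def monoisotopic_mass(
    f: MolecularFormula | str,
    species: str = "neutral",
    formula_is_ion: bool = False,
) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da.

    ``species="M_plus_H"`` adds one proton mass to the neutral formula;
    with ``formula_is_ion`` the formula is interpreted as the protonated
    composition as printed in HRMS listings, so no proton is added.
    Electron mass is neglected (≤ 0.0006 Da effect).
    """
    formula = _as_formula(f)
    mass = sum(
        count * _PT.GetMostCommonIsotopeMass(el) for el, count in formula.items()
    )
    if species == "M_plus_H" and not formula_is_ion:
        mass += PROTON_MASS
    elif species not in ("neutral", "M_plus_H"):
        raise ValueError(f"unknown species {species!r}")
    return mass


def average_mass(f: MolecularFormula | str) -> float:
    """Average molecular mass (standard atomic weights) in Da."""
    formula = _as_formula(f)
    return sum(count * _PT.GetAtomicWeight(el) for el, count in formula.items())


def fraction_uncharged_base(pka: float, ph: float) -> float:
    """Uncharged fraction of a monobasic amine at the given pH
    (Henderson–Hasselbalch): ``1 / (1 + 10^(pKa − pH))``."""
    if not (0.0 <= pka <= 14.0 and 0.0 <= ph <= 14.0):
        raise ValueError("pKa and pH must lie within [0, 14]")
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


# ---------------------------------------------------------------------------
# Permeability surrogate
# ---------------------------------------------------------------------------


class PermClass(str, enum.Enum):
    H = "H"
    M_H = "M-H"
    M_L = "M-L"
    L = "L"


@dataclass
class PermeabilityRecord:
    compound_id: str
    ic50_cell: float  # μM
    ic50_biochem: float  # μM
    ratio: float
    perm_class: PermClass
    pampa_logpe: float | None = None


def _round_sigfig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def classify_ratio(ratio: float) -> PermClass:
    """Bin a positive in-cellulo/in-vitro ratio: [0, 40) H, [40, 100] M–H,
    (100, 200] M–L, (200, ∞) L.  The half-open boundaries make the bins a
    partition of (0, ∞)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio < 40:
        return PermClass.H
    if ratio <= 100:
        return PermClass.M_H
    if ratio <= 200:
        return PermClass.M_L
    return PermClass.L


def permeability_ratio_and_class(
    ic50_cell: float,
    ic50_biochem: float,
    compound_id: str = "",
    pampa_logpe: float | None = None,
) -> PermeabilityRecord:
    """In-cellulo/in-vitro potency ratio (reported to 3 significant figures,
    as in assay tables) and its permeability class.  A low ratio means the
    compound reaches the intracellular target easily, i.e. high passive
    permeability."""
    if ic50_cell <= 0 or ic50_biochem <= 0:
        raise ValueError("potencies must be positive")
    raw = ic50_cell / ic50_biochem
    return PermeabilityRecord(
        compound_id=compound_id,
        ic50_cell=ic50_cell,
        ic50_biochem=ic50_biochem,
        ratio=_round_sigfig(raw, 3),
        perm_class=classify_ratio(raw),
        pampa_logpe=pampa_logpe,
    )


# ---------------------------------------------------------------------------
# Oral druggable space gating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DruggableSpaceLimits:
    """Inclusive outer limits on the six 2D descriptors."""

    name: str
    mw: float
    clogp: float
    hbd: float
    hba: float
    tpsa: float
    nrotb: float

    def as_dict(self) -> dict[str, float]:
        return {
            "MW": self.mw, "cLogP": self.clogp, "HBD": self.hbd,
            "HBA": self.hba, "TPSA": self.tpsa, "NRotB": self.nrotb,
        }


PROTAC_LIMITS = DruggableSpaceLimits("PROTAC", 950, 7, 4, 15, 200, 14)
BRO5_LIMITS = DruggableSpaceLimits("bRo5", 1000, 10, 6, 15, 250, 20)


def gate_druggable_space(
    descriptors: dict[str, float], limits: DruggableSpaceLimits = PROTAC_LIMITS
) -> dict[str, dict]:
    """Flag each descriptor as within or beyond its outer limit (inclusive);
    returns per-descriptor verdicts plus the sorted list of violated names
    under ``"violations"``."""
    lim = limits.as_dict()
    unknown = set(descriptors) - set(lim)
    if unknown:
        raise ValueError(f"unknown descriptor names: {sorted(unknown)}")
    verdicts = {
        name: {"value": val, "limit": lim[name], "within": val <= lim[name]}
        for name, val in descriptors.items()
    }
    verdicts["violations"] = sorted(
        name for name, v in verdicts.items() if isinstance(v, dict) and not v["within"]
    )
    return verdicts
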