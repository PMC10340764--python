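"""Residue metadata shared by every other module.

One table holds, per canonical amino acid: masses, hydrophobicity,
essentiality, flavour class, medicinal membership and (where established)
the taste threshold used for taste-activity values (TAV).

Flavour classes follow the convention used in cereal-protein flavour
analysis: "fresh" (umami) residues are Glu and Asp; "bitter" residues are
Val, Met, Ile, Leu, Phe, His and Arg; the sweet *content* class is Thr,
Ser, Gly and Ala.  Taste thresholds are in mg per 100 g sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ResidueInfo",
    "RESIDUES",
    "ALPHABET",
    "HYDROPHOBIC",
    "ESSENTIAL",
    "FRESH",
    "BITTER",
    "SWEET_CONTENT",
    "SWEET_TAV",
    "MEDICINAL",
    "TASTE_THRESHOLDS",
    "WATER_MONO",
    "WATER_AVG",
    "monoisotopic_mass",
    "average_mass",
]

#: mass of one water molecule, added once per peptide chain (Da)
WATER_MONO = 18.010565
WATER_AVG = 18.01528


@dataclass(frozen=True)
class ResidueInfo:
    one_letter: str
    three_letter: str
    monoisotopic_mass: float  # residue (dehydrated) mass, Da
    average_mass: float  # residue (dehydrated) mass, Da
    hydrophobic: bool
    essential: bool
    flavour_class: str  # one of {"fresh", "bitter", "sweet", "none"}
    medicinal: bool
    taste_threshold: Optional[float]  # mg / 100 g, None where not established


def _r(one, three, mono, avg, hyd, ess, flav, med, thr):
    return ResidueInfo(one, three, mono, avg, hyd, ess, flav, med, thr)


# Residue (monomer minus water) masses: standard monoisotopic and average
# values, identical to those used by proteomics mass calculators.
RESIDUES: dict[str, ResidueInfo] = {
    "G": _r("G", "Gly", 57.02146, 57.0519, False, False, "sweet", False, 110.0),
    "A": _r("A", "Ala", 71.03711, 71.0788, True, False, "sweet", True, 60.0),
    "S": _r("S", "Ser", 87.03203, 87.0782, False, False, "sweet", False, 150.0),
    "P": _r("P", "Pro", 97.05276, 97.1167, True, False, "none", False, None),
    "V": _r("V", "Val", 99.06841, 99.1326, True, True, "bitter", False, 150.0),
    "T": _r("T", "Thr", 101.04768, 101.1051, False, True, "sweet", False, 260.0),
    "C": _r("C", "Cys", 103.00919, 103.1388, False, False, "none", False, None),
    "L": _r("L", "Leu", 113.08406, 113.1594, True, True, "bitter", True, 380.0),
    "I": _r("I", "Ile", 113.08406, 113.1594, True, True, "bitter", False, 90.0),
    "N": _r("N", "Asn", 114.04293, 114.1038, False, False, "none", False, None),
    "D": _r("D", "Asp", 115.02694, 115.0886, False, False, "fresh", True, 100.0),
    "Q": _r("Q", "Gln", 128.05858, 128.1307, False, False, "none", False, None),
    "K": _r("K", "Lys", 128.09496, 128.1741, False, True, "none", True, None),
    "E": _r("E", "Glu", 129.04259, 129.1155, False, False, "fresh", True, 30.0),
    "M": _r("M", "Met", 131.04049, 131.1926, True, True, "bitter", True, 30.0),
    "H": _r("H", "His", 137.05891, 137.1411, False, False, "bitter", False, 20.0),
    "F": _r("F", "Phe", 147.06841, 147.1766, True, True, "bitter", True, 150.0),
    "R": _r("R", "Arg", 156.10111, 156.1875, False, False, "bitter", True, 10.0),
    "Y": _r("Y", "Tyr", 163.06333, 163.1760, False, False, "none", True, None),
    "W": _r("W", "Trp", 186.07931, 186.2132, False, True, "none", False, 90.0),
}

ALPHABET = frozenset(RESIDUES)

HYDROPHOBIC = frozenset(r for r, i in RESIDUES.items() if i.hydrophobic)
ESSENTIAL = frozenset(r for r, i in RESIDUES.items() if i.essential)
FRESH = frozenset(r for r, i in RESIDUES.items() if i.flavour_class == "fresh")
BITTER = frozenset(r for r, i in RESIDUES.items() if i.flavour_class == "bitter")
SWEET_CONTENT = frozenset(r for r, i in RESIDUES.items() if i.flavour_class == "sweet")
#: residues whose TAVs are summed into the sweet class total.  Ala, although
#: a sweet residue by content class, is excluded here because sweet-TAV
#: totals in the flavour literature this package follows sum only
#: Thr/Ser/Gly; the set is configurable in :func:`coixpep.nutrition.tav`.
SWEET_TAV = frozenset({"T", "S", "G"})
MEDICINAL = frozenset(r for r, i in RESIDUES.items() if i.medicinal)

TASTE_THRESHOLDS: dict[str, float] = {
    r: i.taste_threshold for r, i in RESIDUES.items() if i.taste_threshold is not None
}

THREE_TO_ONE = {i.three_letter: r for r, i in RESIDUES.items()}


def monoisotopic_mass(residue: str) -> float:
    """Monoisotopic residue mass in Da (dehydrated monomer)."""
    return RESIDUES[residue].monoisotopic_mass


def average_mass(residue: str) -> float:
    """Average residue mass in Da (dehydrated monomer)."""
    return RESIDUES[residue].average_mass
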