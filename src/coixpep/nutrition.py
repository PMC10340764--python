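"""Amino-acid-derived nutritional and flavour quality indices.

Given a per-residue composition (g amino acid / 100 g sample) this module
computes:

* **AAS** (amino acid score): 100 x content / reference content against a
  FAO/WHO scoring pattern, with the lowest-scoring residues reported as
  limiting amino acids;
* **PER** (protein efficiency ratio) by three literature regressions on
  Leu, Pro, Tyr, Met and His contents (g/100 g):

  - PER1 = -0.684 + 0.456*Leu - 0.047*Pro
  - PER2 = -0.468 + 0.454*Leu - 0.105*Tyr
  - PER3 = -1.816 + 0.435*Met + 0.78*Leu + 0.211*His - 0.944*Tyr

* class sums (total, essential, non-essential, hydrophobic, fresh/umami,
  bitter, sweet, medicinal amino acids) and their percentages of total;
* **TAV** (taste activity value): 1000 x content(g/100 g) / taste
  threshold(mg/100 g) per flavour residue, with fresh, bitter and sweet
  class totals.  TAV > 1 marks a flavour-relevant residue.

A PER above 2 conventionally indicates good protein quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .residues import (
    ALPHABET,
    BITTER,
    ESSENTIAL,
    FRESH,
    HYDROPHOBIC,
    MEDICINAL,
    SWEET_CONTENT,
    SWEET_TAV,
    TASTE_THRESHOLDS,
)

__all__ = [
    "AminoAcidProfile",
    "ReferencePattern",
    "FAO_WHO_ADULT",
    "NutritionReport",
    "aas",
    "per",
    "class_sums",
    "tav",
    "nutrition_report",
]


@dataclass(frozen=True)
class AminoAcidProfile:
    """Per-residue content of a sample, in g amino acid per 100 g.

    Residues missing from ``content`` are treated as zero (with a warning
    at construction).  A zero entry is interpreted as "not detected":
    acid hydrolysis destroys Trp, so compositional tables routinely
    report it as 0 even though it may be present.
    """

    sample_id: str
    content: Mapping[str, float]

    def __post_init__(self):
        bad = set(self.content) - ALPHABET
        if bad:
            raise ValueError(f"{self.sample_id}: unknown residues {sorted(bad)}")
        neg = {r: v for r, v in self.content.items() if v < 0}
        if neg:
            raise ValueError(f"{self.sample_id}: negative contents {neg}")
        missing = ALPHABET - set(self.content)
        if missing:
            warnings.warn(
                f"{self.sample_id}: residues {sorted(missing)} absent, treated as 0",
                stacklevel=2,
            )

    def get(self, residue: str) -> float:
        return float(self.content.get(residue, 0.0))

    @property
    def total(self) -> float:
        return float(sum(self.content.values()))


#: FAO/WHO/UNU adult indispensable-amino-acid scoring pattern,
#: mg per g protein.  Sulfur (Met+Cys) and aromatic (Phe+Tyr) residues are
#: scored as pairs.
FAO_WHO_ADULT: dict[str, float] = {
    "H": 15.0,
    "I": 30.0,
    "L": 59.0,
    "K": 45.0,
    "M+C": 22.0,
    "F+Y": 38.0,
    "T": 23.0,
    "W": 6.0,
    "V": 39.0,
}


@dataclass(frozen=True)
class ReferencePattern:
    """A scoring pattern: residue (or '+'-joined residue pair) -> reference
    content, plus a provenance note."""

    pattern: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self):
        bad = {k: v for k, v in self.pattern.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive reference contents {bad}")


FAO_WHO_ADULT_PATTERN = ReferencePattern(
    FAO_WHO_ADULT, provenance="FAO/WHO/UNU adult pattern (mg/g protein)"
)


def _group_content(profile: AminoAcidProfile, key: str) -> float:
    return sum(profile.get(r) for r in key.split("+"))


def aas(
    profile: AminoAcidProfile,
    reference: ReferencePattern = FAO_WHO_ADULT_PATTERN,
    normalise: bool = True,
) -> dict[str, float]:
    """Amino acid score per reference entry: 100 x content / reference.

    With ``normalise`` (the default) the profile is first converted to mg
    amino acid per g total amino acids so that it is commensurate with
    mg/g-protein scoring patterns; ``normalise=False`` divides raw
    contents by the reference directly (unit-agnostic ratio mode).

    Entries whose sample content is zero ("not detected", e.g. Trp after
    acid hydrolysis) are excluded from the returned scores: a score for
    an unmeasured residue would be meaningless and would spuriously
    dominate the limiting-amino-acid ranking.
    """
    scale = 1000.0 / profile.total if normalise else 1.0
    if normalise and profile.total == 0:
        raise ValueError("cannot normalise an all-zero profile")
    scores = {}
    for key, ref in reference.pattern.items():
        content = _group_content(profile, key)
        if content == 0:
            continue
        scores[key] = 100.0 * content * scale / ref
    return scores


def limiting_order(scores: Mapping[str, float]) -> list[str]:
    """Reference entries sorted by ascending score (most limiting first)."""
    return sorted(scores, key=lambda k: (scores[k], k))


def per(profile: AminoAcidProfile) -> tuple[float, float, float]:
    """The three PER regression estimates from g/100 g contents."""
    leu, pro, tyr = profile.get("L"), profile.get("P"), profile.get("Y")
    met, his = profile.get("M"), profile.get("H")
    per1 = -0.684 + 0.456 * leu - 0.047 * pro
    per2 = -0.468 + 0.454 * leu - 0.105 * tyr
    per3 = -1.816 + 0.435 * met + 0.78 * leu + 0.211 * his - 0.944 * tyr
    return per1, per2, per3


def class_sums(profile: AminoAcidProfile) -> dict[str, float]:
    """Class sums (g/100 g) and their percentages of total amino acids.

    Keys: taa, eaa, neaa, haa, f (fresh/umami), b (bitter), s (sweet),
    d (medicinal), and ratios eaa_taa, eaa_neaa, f_t, b_t, s_t, d_t in %.
    """
    def total(residues: Iterable[str]) -> float:
        return sum(profile.get(r) for r in residues)

    taa = profile.total
    eaa = total(ESSENTIAL)
    sums = {
        "taa": taa,
        "eaa": eaa,
        "neaa": taa - eaa,
        "haa": total(HYDROPHOBIC),
        "f": total(FRESH),
        "b": total(BITTER),
        "s": total(SWEET_CONTENT),
        "d": total(MEDICINAL),
    }
    if taa > 0:
        sums["eaa_taa"] = 100.0 * eaa / taa
        sums["f_t"] = 100.0 * sums["f"] / taa
        sums["b_t"] = 100.0 * sums["b"] / taa
        sums["s_t"] = 100.0 * sums["s"] / taa
        sums["d_t"] = 100.0 * sums["d"] / taa
    if sums["neaa"] > 0:
        sums["eaa_neaa"] = 100.0 * eaa / sums["neaa"]
    return sums


def tav(
    profile: AminoAcidProfile,
    thresholds: Mapping[str, float] = TASTE_THRESHOLDS,
    sweet_set: frozenset[str] = SWEET_TAV,
) -> dict:
    """Taste activity values and flavour-class totals.

    TAV = 1000 x content(g/100 g) / threshold(mg/100 g).  Returns per-
    residue TAVs, a ``significant`` flag per residue (TAV strictly > 1),
    and the class totals ``tft`` (fresh), ``tbt`` (bitter) and ``tst``
    (sweet, by default Thr/Ser/Gly only — Ala is a sweet residue by
    content but is conventionally excluded from the sweet TAV total; pass
    a different ``sweet_set`` to change this).
    """
    values: dict[str, float] = {}
    for residue in sorted(FRESH | BITTER | SWEET_CONTENT):
        if residue not in thresholds:
            raise ValueError(f"no taste threshold for flavour residue {residue}")
        values[residue] = 1000.0 * profile.get(residue) / thresholds[residue]
    return {
        "tav": values,
        "significant": {r: v > 1.0 for r, v in values.items()},
        "tft": sum(values[r] for r in FRESH),
        "tbt": sum(values[r] for r in BITTER),
        "tst": sum(values[r] for r in sweet_set),
    }


@dataclass(frozen=True)
class NutritionReport:
    """Full index report for one amino-acid profile."""

    sample_id: str
    aas: dict[str, float]
    limiting: list[str]
    per1: float
    per2: float
    per3: float
    sums: dict[str, float]
    tav: dict[str, float]
    significant: dict[str, bool]
    tft: float
    tbt: float
    tst: float

    def as_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "aas": self.aas,
            "limiting": self.limiting,
            "per1": self.per1,
            "per2": self.per2,
            "per3": self.per3,
            "tav": self.tav,
            "tft": self.tft,
            "tbt": self.tbt,
            "tst": self.tst,
        }
        d.update(self.sums)
        return d


def nutrition_report(
    profile: AminoAcidProfile,
    reference: ReferencePattern = FAO_WHO_ADULT_PATTERN,
) -> NutritionReport:
    """Compute every index for one profile in a single report."""
    scores = aas(profile, reference)
    per1, per2, per3 = per(profile)
    flavour = tav(profile)
    return NutritionReport(
        sample_id=profile.sample_id,
        aas=scores,
        limiting=limiting_order(scores),
        per1=per1,
        per2=per2,
        per3=per3,
        sums=class_sums(profile),
        tav=flavour["tav"],
        significant=flavour["significant"],
        tft=flavour["tft"],
        tbt=flavour["tbt"],
        tst=flavour["tst"],
    )
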