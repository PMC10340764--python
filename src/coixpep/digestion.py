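"""In silico gastrointestinal proteolysis.

Cleavage is rule-based: an enzyme cuts the peptide bond C-terminal to any
residue in its P1 set unless the following (P1') residue is in its blocker
set.  Shipped defaults cover the two gastrointestinal proteases used for
simulated digestion of storage proteins:

* trypsin (EC 3.4.21.4): after Lys or Arg, blocked by a following Pro;
* pepsin at pH > 2 (EC 3.4.23.1): after Phe, Leu, Trp or Tyr, blocked by
  a following Pro.

Both tables are plain data and can be overridden to match any published
specificity dialect.  The degree of hydrolysis (DH) is the percentage of
peptide bonds cleaved out of all peptide bonds in the parent protein.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .residues import ALPHABET
from .seqio import ProteinRecord

__all__ = [
    "CleavageRule",
    "TRYPSIN",
    "PEPSIN_PH_GT2",
    "DEFAULT_RULES",
    "rule_from_dict",
    "DigestResult",
    "LengthCensus",
    "cleavage_sites",
    "digest",
    "census",
]


@dataclass(frozen=True)
class CleavageRule:
    """Specificity of one protease, in P1/P1' notation."""

    enzyme_name: str
    p1_residues: frozenset[str]
    p1prime_blockers: frozenset[str] = frozenset()
    ec_number: str = ""

    def __post_init__(self):
        if not self.p1_residues:
            raise ValueError(f"{self.enzyme_name}: empty P1 residue set")
        bad = (set(self.p1_residues) | set(self.p1prime_blockers)) - ALPHABET
        if bad:
            raise ValueError(f"{self.enzyme_name}: non-canonical residues {sorted(bad)}")


TRYPSIN = CleavageRule(
    enzyme_name="trypsin",
    p1_residues=frozenset("KR"),
    p1prime_blockers=frozenset("P"),
    ec_number="3.4.21.4",
)

PEPSIN_PH_GT2 = CleavageRule(
    enzyme_name="pepsin_ph_gt2",
    p1_residues=frozenset("FLWY"),
    p1prime_blockers=frozenset("P"),
    ec_number="3.4.23.1",
)

DEFAULT_RULES: dict[str, CleavageRule] = {
    "trypsin": TRYPSIN,
    "pepsin": PEPSIN_PH_GT2,
    "pepsin_ph_gt2": PEPSIN_PH_GT2,
}


def rule_from_dict(d: Mapping) -> CleavageRule:
    """Build a rule from a config mapping, e.g. parsed YAML/JSON.

    Expected keys: ``enzyme_name``, ``p1_residues`` (string or list),
    optional ``p1prime_blockers`` and ``ec_number``.
    """
    return CleavageRule(
        enzyme_name=d["enzyme_name"],
        p1_residues=frozenset(d["p1_residues"]),
        p1prime_blockers=frozenset(d.get("p1prime_blockers", "")),
        ec_number=d.get("ec_number", ""),
    )


@dataclass(frozen=True)
class DigestResult:
    """Peptides produced from one protein, with cut-site bookkeeping.

    ``peptides`` holds (sequence, start, end) in 0-based half-open parent
    coordinates; concatenating them reproduces the parent sequence.
    """

    source_id: str
    peptides: tuple[tuple[str, int, int], ...]
    cleaved_bonds: int
    total_bonds: int

    @property
    def dh_percent(self) -> float:
        """Degree of hydrolysis: 100 x cleaved bonds / total bonds."""
        if self.total_bonds == 0:
            return 0.0
        return 100.0 * self.cleaved_bonds / self.total_bonds

    @property
    def sequences(self) -> list[str]:
        return [p[0] for p in self.peptides]


def cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """Bond indices cut by ``rule`` in ``sequence``.

    Index ``i`` (1 <= i <= len-1) marks the bond between positions i-1 and
    i; it is cut iff residue i-1 is in the P1 set and residue i is not a
    blocker.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in rule.p1_residues
        and sequence[i] not in rule.p1prime_blockers
    ]


def _fragments(sequence: str, sites: Iterable[int]) -> list[tuple[str, int, int]]:
    bounds = [0, *sorted(set(sites)), len(sequence)]
    return [
        (sequence[a:b], a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]


def digest(
    protein: ProteinRecord,
    rules: Sequence[CleavageRule],
    mode: str = "concurrent",
) -> DigestResult:
    """Digest one protein with one or more proteases.

    ``concurrent`` cuts at the union of all rules' sites in a single pass
    (a one-pot multi-enzyme digest).  ``sequential`` applies each rule to
    the fragments left by the previous one, mirroring the gastric
    (pepsin) then intestinal (trypsin) phases of gastrointestinal
    digestion; pass rules in that physiological order.  For P1/P1' rules,
    whose sites depend only on a residue and its successor, the two modes
    yield identical peptide sets.
    """
    if not rules:
        raise ValueError("at least one cleavage rule is required")
    seq = protein.sequence

    if mode == "concurrent":
        sites: set[int] = set()
        for rule in rules:
            sites.update(cleavage_sites(seq, rule))
    elif mode == "sequential":
        frags = [(seq, 0, len(seq))]
        for rule in rules:
            nxt = []
            for s, a, b in frags:
                for fs, fa, fb in _fragments(s, cleavage_sites(s, rule)):
                    nxt.append((fs, a + fa, a + fb))
            frags = nxt
        sites = {a for _, a, _ in frags if a > 0}
    else:
        raise ValueError(f"unknown digestion mode {mode!r}")

    peptides = tuple(_fragments(seq, sites))
    return DigestResult(
        source_id=protein.id,
        peptides=peptides,
        cleaved_bonds=len(peptides) - 1,
        total_bonds=len(seq) - 1,
    )


@dataclass(frozen=True)
class LengthCensus:
    """Pooled peptide-length census over one or more digests."""

    total_peptides: int
    length_histogram: Mapping[int, int] = field(default_factory=dict)

    def fraction_below(self, k: int) -> float:
        """Percentage of peptides with chain length < k."""
        if self.total_peptides == 0:
            return 0.0
        n = sum(c for length, c in self.length_histogram.items() if length < k)
        return 100.0 * n / self.total_peptides


def census(results: Sequence[DigestResult]) -> LengthCensus:
    """Pool peptides from several digests and count by length.

    Duplicate sequences are counted separately: the census describes the
    digest output, not the unique sequence set.
    """
    if not results:
        raise ValueError("census needs at least one digest result")
    hist: Counter[int] = Counter()
    for r in results:
        hist.update(len(p) for p in r.sequences)
    return LengthCensus(total_peptides=sum(hist.values()), length_histogram=dict(hist))
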