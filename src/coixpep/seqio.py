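"""Sequence and table I/O.

FASTA goes through Biopython; tabular fixtures are plain UTF-8 CSV with a
mandatory header row, comma separators and '.' decimals so they survive
byte-exact round trips.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from os import PathLike
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .residues import ALPHABET

PathType = Union[str, PathLike]

__all__ = [
    "ProteinRecord",
    "SequenceValidationError",
    "read_fasta",
    "write_fasta",
    "write_peptide_table",
    "read_peptide_table",
    "load_table2_scores",
    "load_table3_profiles",
]


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the 20-letter alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical one-letter amino acids.

    Sequences are uppercased on construction; any character outside the
    canonical alphabet (including B/J/O/U/X/Z and gap or stop symbols)
    raises :class:`SequenceValidationError` naming every offending
    position, because downstream mass and motif arithmetic is undefined
    for non-canonical residues.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(seq) if c not in ALPHABET]
        if bad:  # positions reported 1-based
            detail = ", ".join(f"{c!r} at position {i}" for i, c in bad)
            raise SequenceValidationError(
                f"record {self.id!r}: illegal residue(s): {detail}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: PathType) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Order is preserved; sequences are uppercased and validated against the
    canonical 20-letter alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathType) -> None:
    """Write records to FASTA, inverse of :func:`read_fasta`."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# stable column order for peptide tables
PEPTIDE_COLUMNS = [
    "sequence",
    "length",
    "mono_mass",
    "avg_mass",
    "hydrophobic_fraction",
    "n_term_hydrophobic",
    "pro_n_terminal",
    "pro_penultimate",
    "pro_c_terminal",
]


def write_peptide_table(peptides: Iterable, path: PathType) -> None:
    """Write peptide records to CSV with a stable column order.

    Accepts :class:`coixpep.peptides.PeptideRecord` objects.  An empty
    list produces a header-only file.  Masses are written at full float
    precision so the table round-trips losslessly through
    :func:`read_peptide_table`.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEPTIDE_COLUMNS)
        for p in peptides:
            writer.writerow(
                [
                    p.sequence,
                    p.length,
                    repr(p.mono_mass),
                    repr(p.avg_mass),
                    repr(p.hydrophobic_fraction),
                    p.n_term_hydrophobic,
                    p.pro_n_terminal,
                    p.pro_penultimate,
                    p.pro_c_terminal,
                ]
            )


def read_peptide_table(path: PathType) -> list:
    """Read a CSV written by :func:`write_peptide_table`."""
    from .peptides import PeptideRecord

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[0] != "sequence":
            raise ValueError(f"{path}: not a peptide table (missing header)")
        for row in reader:
            out.append(PeptideRecord.from_sequence(row["sequence"]))
    return out


def _data_path(name: str):
    return resources.files("coixpep.data").joinpath(name)


def load_table2_scores() -> pd.DataFrame:
    """Packaged predictor-score table for the 47 digestion-derived peptides.

    Columns: sequence, mol_weight (printed monoisotopic Da), bioactivity
    (Peptide Ranker score), dppiv_probability, allergen_mark, caco2_log,
    mdck_cm_s, hia_band, ppb_percent, bbb_band, fu_percent.  Missing
    predictor values are NaN.
    """
    from .peptides import read_score_table

    with resources.as_file(_data_path("table2_peptides.csv")) as p:
        return read_score_table(p)


def load_table3_profiles() -> pd.DataFrame:
    """Packaged amino-acid composition table (g/100 g) for raw, stir-fried
    (SF) and bran-stir-fried (BSF) coix seed prolamin, indexed by
    one-letter residue code."""
    with resources.as_file(_data_path("table3_profiles.csv")) as p:
        return pd.read_csv(p, index_col="residue")
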