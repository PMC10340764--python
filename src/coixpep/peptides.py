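"""Peptide physicochemistry, external predictor scores and screening.

Masses are residue-mass sums plus one water.  Motif flags capture the
structural features associated with DPP-IV inhibitory peptides: hydrophobic
residue content, a hydrophobic N-terminal residue, and Pro at the
N-terminus, penultimate position or C-terminus.

Predictor scores (Peptide Ranker bioactivity, DPP-IV target probability,
ADMET descriptors, allergenicity marks) come from external tools and are
*ingested* from score tables, never recomputed here.  Screening retains
peptides whose bioactivity score exceeds a threshold and ranks them by
DPP-IV inhibition probability.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .residues import HYDROPHOBIC, RESIDUES, WATER_AVG, WATER_MONO
from .seqio import SequenceValidationError

__all__ = [
    "PeptideRecord",
    "PredictorScores",
    "ScreenConfig",
    "peptide_mass",
    "motif_flags",
    "read_score_table",
    "ingest_scores",
    "classify_permeability",
    "screen",
]


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in RESIDUES]
    if not seq or bad:  # positions reported 1-based
        detail = ", ".join(f"{c!r} at position {i}" for i, c in bad) or "empty"
        raise SequenceValidationError(f"invalid peptide sequence: {detail}")
    return seq


def peptide_mass(sequence: str, kind: str = "monoisotopic") -> float:
    """Peptide mass in Da: residue-mass sum plus one water.

    ``kind`` selects monoisotopic or average residue masses.  Full float
    precision is returned; round to 2 decimals for table comparison.
    """
    seq = _validate(sequence)
    if kind == "monoisotopic":
        return sum(RESIDUES[r].monoisotopic_mass for r in seq) + WATER_MONO
    if kind == "average":
        return sum(RESIDUES[r].average_mass for r in seq) + WATER_AVG
    raise ValueError(f"unknown mass kind {kind!r}")


def motif_flags(sequence: str) -> dict:
    """Structure-activity motif flags for a peptide.

    Positional flags are False for single-residue peptides, for which
    "penultimate" and "terminal" are not distinct positions;
    ``hydrophobic_fraction`` is defined for any length.
    """
    seq = _validate(sequence)
    n = len(seq)
    positional = n >= 2
    return {
        "hydrophobic_fraction": sum(r in HYDROPHOBIC for r in seq) / n,
        "n_term_hydrophobic": positional and seq[0] in HYDROPHOBIC,
        "pro_n_terminal": positional and seq[0] == "P",
        "pro_penultimate": positional and seq[n - 2] == "P",
        "pro_c_terminal": positional and seq[n - 1] == "P",
    }


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide with derived masses and motif flags."""

    sequence: str
    length: int
    mono_mass: float
    avg_mass: float
    hydrophobic_fraction: float
    n_term_hydrophobic: bool
    pro_n_terminal: bool
    pro_penultimate: bool
    pro_c_terminal: bool

    @classmethod
    def from_sequence(cls, sequence: str) -> "PeptideRecord":
        seq = _validate(sequence)
        flags = motif_flags(seq)
        return cls(
            sequence=seq,
            length=len(seq),
            mono_mass=peptide_mass(seq, "monoisotopic"),
            avg_mass=peptide_mass(seq, "average"),
            **flags,
        )


@dataclass(frozen=True)
class PredictorScores:
    """Ingested external predictor outputs for one peptide.

    Absent values are ``None`` (numeric fields surface as NaN in tabular
    form), never silently zero.  ``allergenic`` reflects the score table's
    allergenicity mark; ``mdck_cm_s`` is apparent MDCK permeability in
    cm/s; ``caco2_log`` is log-unit Caco-2 permeability.
    """

    bioactivity: float
    dppiv_probability: Optional[float] = None
    allergenic: Optional[bool] = None
    caco2_log: Optional[float] = None
    mdck_cm_s: Optional[float] = None
    hia_band: Optional[str] = None
    ppb_percent: Optional[float] = None
    bbb_band: Optional[str] = None
    fu_percent: Optional[float] = None

    def __post_init__(self):
        for name in ("bioactivity", "dppiv_probability"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


_MISSING = {"", "-", "--", "na", "nan", "none"}

# "8.90 × 10^-6" (and unicode minus / "x" variants) -> 8.90e-6
_SCI = re.compile(r"^([0-9.]+)\s*[×xX*]\s*10\^?\s*([+-]?[0-9]+)$")


def _parse_number(raw) -> Optional[float]:
    """Parse a score-table numeric cell; None for declared-missing cells.

    Accepts plain and E-notation floats, the spelled-out scientific
    notation used in publication tables, unicode minus signs, and
    trailing percent signs.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip().replace("−", "-").replace("–", "-")
    if s.lower() in _MISSING:
        return None
    s = s.rstrip("%").strip()
    m = _SCI.match(s)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    return float(s)


def read_score_table(path) -> pd.DataFrame:
    """Read a predictor score table CSV into a typed DataFrame.

    Expected columns: ``sequence`` plus any of ``mol_weight``,
    ``bioactivity``, ``dppiv_probability``, ``allergen_mark``,
    ``caco2_log``, ``mdck_cm_s``, ``hia_band``, ``ppb_percent``,
    ``bbb_band``, ``fu_percent``.  ``NA`` and ``-`` mark absent values;
    MDCK permeabilities may use publication-style scientific notation.
    Raises on unparseable numerics (with the line number) and on
    duplicate sequences.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing 'sequence' column")
    dupes = df["sequence"][df["sequence"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sequence(s) {dupes}")

    numeric = [
        "mol_weight",
        "bioactivity",
        "dppiv_probability",
        "caco2_log",
        "mdck_cm_s",
        "ppb_percent",
        "fu_percent",
    ]
    out = {"sequence": df["sequence"].str.strip().str.upper()}
    for col in numeric:
        if col in df.columns:
            vals = []
            for i, raw in enumerate(df[col]):
                try:
                    v = _parse_number(raw)
                except ValueError as e:
                    raise ValueError(f"{path}, line {i + 2}, column {col}: {e}") from e
                vals.append(math.nan if v is None else v)
            out[col] = vals
    for col in ("allergen_mark", "hia_band", "bbb_band"):
        if col in df.columns:
            out[col] = [s.strip() if s.strip() else None for s in df[col]]
    return pd.DataFrame(out)


def ingest_scores(path) -> dict[str, PredictorScores]:
    """Read a score table into a sequence -> :class:`PredictorScores` map."""
    return ingest_from_frame(read_score_table(path))


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for peptide screening and ADMET banding.

    ``bioactivity_min``: retain peptides with Peptide Ranker score
    strictly above this.  ``caco2_optimal_log``: Caco-2 log-permeability
    above which absorption is considered optimal.  ``mdck_low``/
    ``mdck_high``: MDCK band boundaries in cm/s (boundaries belong to the
    medium band).  ``hia_cut``: %HIA below which intestinal absorption is
    flagged poor.
    """

    bioactivity_min: float = 0.5
    caco2_optimal_log: float = -5.15
    mdck_low: float = 2e-6
    mdck_high: float = 20e-6
    hia_cut: float = 30.0

    def __post_init__(self):
        if not self.mdck_low < self.mdck_high:
            raise ValueError("mdck_low must be < mdck_high")


def classify_permeability(mdck_cm_s: float, config: ScreenConfig = ScreenConfig()) -> str:
    """Band an MDCK apparent permeability as low / medium / high.

    Band boundaries are assigned to the medium band.
    """
    if mdck_cm_s < 0:
        raise ValueError(f"negative permeability {mdck_cm_s}")
    if mdck_cm_s < config.mdck_low:
        return "low"
    if mdck_cm_s <= config.mdck_high:
        return "medium"
    return "high"


def screen(
    scores: Mapping[str, PredictorScores] | pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Apply the bioactivity filter and rank by DPP-IV probability.

    Retains peptides with bioactivity strictly greater than
    ``config.bioactivity_min``; sorts by DPP-IV inhibition probability
    descending with absent probabilities last, ties broken by bioactivity
    descending then sequence ascending.  The output carries masses, motif
    flags and ADMET band classifications per retained peptide.  No DPP-IV
    probability cut-off is applied: the probability is reported and any
    cut is left to the caller.
    """
    if isinstance(scores, pd.DataFrame):
        scores = ingest_from_frame(scores)

    rows = []
    for seq, s in scores.items():
        if s.bioactivity is None or math.isnan(s.bioactivity):
            raise ValueError(f"{seq}: bioactivity score required for screening")
        if not s.bioactivity > config.bioactivity_min:
            continue
        rec = PeptideRecord.from_sequence(seq)
        mdck_band = (
            None if s.mdck_cm_s is None else classify_permeability(s.mdck_cm_s, config)
        )
        rows.append(
            {
                "sequence": seq,
                "length": rec.length,
                "mono_mass": rec.mono_mass,
                "avg_mass": rec.avg_mass,
                "bioactivity": s.bioactivity,
                "dppiv_probability": s.dppiv_probability,
                "allergenic": s.allergenic,
                "caco2_log": s.caco2_log,
                "caco2_optimal": (
                    None if s.caco2_log is None else s.caco2_log > config.caco2_optimal_log
                ),
                "mdck_cm_s": s.mdck_cm_s,
                "mdck_band": mdck_band,
                "hia_band": s.hia_band,
                "ppb_percent": s.ppb_percent,
                "bbb_band": s.bbb_band,
                "fu_percent": s.fu_percent,
                "hydrophobic_fraction": rec.hydrophobic_fraction,
                "n_term_hydrophobic": rec.n_term_hydrophobic,
                "pro_n_terminal": rec.pro_n_terminal,
                "pro_penultimate": rec.pro_penultimate,
                "pro_c_terminal": rec.pro_c_terminal,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["_dppiv_key"] = df["dppiv_probability"].fillna(-math.inf)
    df = df.sort_values(
        ["_dppiv_key", "bioactivity", "sequence"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_dppiv_key")
    return df.reset_index(drop=True)


def ingest_from_frame(df: pd.DataFrame) -> dict[str, PredictorScores]:
    """Convert a :func:`read_score_table`-style DataFrame to a score map."""

    def opt(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    out = {}
    for _, row in df.iterrows():
        mark = opt(row, "allergen_mark")
        out[row["sequence"]] = PredictorScores(
            bioactivity=row["bioactivity"],
            dppiv_probability=opt(row, "dppiv_probability"),
            allergenic=None if mark is None else mark == "*",
            caco2_log=opt(row, "caco2_log"),
            mdck_cm_s=opt(row, "mdck_cm_s"),
            hia_band=opt(row, "hia_band"),
            ppb_percent=opt(row, "ppb_percent"),
            bbb_band=opt(row, "bbb_band"),
            fu_percent=opt(row, "fu_percent"),
        )
    return out
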