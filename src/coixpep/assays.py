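"""Deterministic calculators for the wet-assay arithmetic.

Covers the four calculations attached to the bench protocols: DPP-IV
percent inhibition from plate absorbances, biuret peptide quantitation
through a linear standard curve, ANS surface hydrophobicity as the fitted
slope of fluorescence intensity on protein concentration, and the
prolamin extraction rate.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from scipy import stats

__all__ = [
    "PlateReadings",
    "StandardCurve",
    "BIURET_CURVE",
    "HydrophobicityFit",
    "dppiv_inhibition",
    "peptide_content",
    "surface_hydrophobicity",
    "extraction_rate",
    "read_plate_csv",
]


@dataclass(frozen=True)
class PlateReadings:
    """One DPP-IV assay plate layout, as role-averaged absorbances.

    ``a_s``: sample; ``a_sb``: sample blank (buffer instead of enzyme);
    ``a_c``: control (buffer instead of sample); ``a_cb``: control blank.
    """

    a_s: float
    a_sb: float
    a_c: float
    a_cb: float


def dppiv_inhibition(readings: PlateReadings) -> float:
    """Percent DPP-IV inhibition: 100 x (1 - (As - Asb)/(Ac - Acb)).

    The control window Ac - Acb must be non-zero.  Negative values
    (apparent activation) are returned as-is with a warning, not clamped.
    """
    window = readings.a_c - readings.a_cb
    if window == 0:
        raise ZeroDivisionError("control window Ac - Acb is zero")
    value = 100.0 * (1.0 - (readings.a_s - readings.a_sb) / window)
    if value < 0:
        warnings.warn(
            f"negative inhibition ({value:.2f}%): apparent enzyme activation",
            stacklevel=2,
        )
    return value


@dataclass(frozen=True)
class StandardCurve:
    """A linear absorbance standard curve y = slope*x + intercept."""

    slope: float
    intercept: float
    r2: float = float("nan")

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("standard curve slope must be non-zero")

    def forward(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


#: biuret peptide standard curve (absorbance at 540 nm vs mg/mL)
BIURET_CURVE = StandardCurve(slope=0.0721, intercept=0.069, r2=0.9987)


def peptide_content(
    absorbance: float,
    curve: StandardCurve = BIURET_CURVE,
    dilution: float = 1.0,
) -> float:
    """Invert a standard curve: concentration = (y - b)/m, times dilution.

    A below-blank absorbance yields a negative concentration, which is
    returned with a warning rather than clipped.
    """
    if dilution <= 0:
        raise ValueError(f"dilution must be positive, got {dilution}")
    value = (absorbance - curve.intercept) / curve.slope * dilution
    if value < 0:
        warnings.warn(f"absorbance below blank: content {value:.4g} mg/mL", stacklevel=2)
    return value


@dataclass(frozen=True)
class HydrophobicityFit:
    """OLS fit of fluorescence intensity on protein concentration."""

    h0: float  # slope = surface hydrophobicity index
    intercept: float
    r2: float


def surface_hydrophobicity(
    points: Sequence[tuple[float, float]],
    n_lowest: int | None = None,
) -> HydrophobicityFit:
    """Surface hydrophobicity H0 as the initial slope of FI vs concentration.

    Ordinary least squares over the supplied dilution series
    (concentration in mg/mL, fluorescence intensity in arbitrary units).
    ``n_lowest`` restricts the fit to the k lowest concentrations, for
    series that curve at high concentration.
    """
    pts = sorted(points)
    if n_lowest is not None:
        pts = pts[:n_lowest]
    if len({x for x, _ in pts}) < 2:
        raise ValueError("need at least two distinct concentrations")
    x, y = zip(*pts)
    fit = stats.linregress(x, y)
    return HydrophobicityFit(h0=fit.slope, intercept=fit.intercept, r2=fit.rvalue**2)


def extraction_rate(extract_protein: float, seed_prolamin: float) -> float:
    """Prolamin extraction rate: 100 x protein in extract / prolamin in seed."""
    if seed_prolamin <= 0:
        raise ValueError("seed prolamin content must be positive")
    return 100.0 * extract_protein / seed_prolamin


def read_plate_csv(path) -> PlateReadings:
    """Read plate absorbances from a well-level CSV.

    Columns: ``well``, ``role`` in {sample, sample_blank, control,
    control_blank}, ``absorbance``.  Replicates are aggregated by
    averaging absorbances per role before the inhibition arithmetic.
    """
    roles: dict[str, list[float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            roles.setdefault(row["role"].strip(), []).append(float(row["absorbance"]))
    required = {"sample", "sample_blank", "control", "control_blank"}
    missing = required - set(roles)
    if missing:
        raise ValueError(f"{path}: missing plate roles {sorted(missing)}")
    return PlateReadings(
        a_s=fmean(roles["sample"]),
        a_sb=fmean(roles["sample_blank"]),
        a_c=fmean(roles["control"]),
        a_cb=fmean(roles["control_blank"]),
    )
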