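"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of the configuration seed and returns
both the synthetic input and its ground truth, so every pipeline stage can
be tested for parameter recovery without downloads.  Ground truths are
computed by straight-line arithmetic *inside this module* (hard-coded
residue sets, thresholds and window tables, independent of the modules
under test) so they remain valid oracles.

Each generator draws from its own named RNG stream derived from the
single seed, so adding a generator never shifts another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .assays import PlateReadings
from .nutrition import AminoAcidProfile
from .seqio import ProteinRecord
from .spectra import Spectrum

__all__ = [
    "GeneratorConfig",
    "PROLAMIN_WEIGHTS",
    "gen_proteins",
    "gen_profile",
    "gen_spectrum",
    "gen_plate",
]

# per-generator RNG stream tags (spawned from [seed, tag])
_STREAMS = {"proteins": 1, "profile": 2, "spectrum": 3, "plate": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


#: prolamin-like residue sampling weights: cereal storage proteins are
#: dominated by Gln, Pro, Leu, Ala and Phe, and nearly devoid of Lys and Trp.
PROLAMIN_WEIGHTS: dict[str, float] = {
    "Q": 0.14, "P": 0.09, "L": 0.13, "A": 0.12, "F": 0.05,
    "E": 0.06, "S": 0.05, "G": 0.03, "V": 0.05, "I": 0.03,
    "T": 0.03, "Y": 0.03, "N": 0.03, "M": 0.015, "H": 0.012,
    "R": 0.02, "D": 0.03, "K": 0.003, "C": 0.015, "W": 0.002,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared configuration for all generators.

    ``length_range`` is inclusive; the default 120-260 residues brackets
    the ~20-30 kDa chains typical of cereal prolamin subunits.
    ``spectrum_bands`` is a list of (center cm^-1, sigma cm^-1, area)
    triples; ``None`` draws one band per amide I structure window with
    class areas spread around the beta-sheet-dominated composition seen
    in cereal prolamins.  ``spectrum_noise`` is the noise standard
    deviation as a fraction of the peak maximum (0.005 = 46 dB SNR).
    ``assay_truth`` is the true DPP-IV inhibition in percent and
    ``assay_noise`` the absorbance noise s.d. per well.
    """

    seed: int = 0
    n_proteins: int = 6
    length_range: tuple[int, int] = (120, 260)
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(PROLAMIN_WEIGHTS)
    )
    spectrum_bands: Optional[Sequence[tuple[float, float, float]]] = None
    spectrum_noise: float = 0.005
    spectrum_baseline: tuple[float, float] = (0.0, 0.0)  # (offset, slope/cm^-1)
    assay_truth: float = 50.0
    assay_noise: float = 0.0

    def __post_init__(self):
        weights = np.array(list(self.composition.values()), dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("composition weights must be >= 0 and not all zero")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length range {self.length_range}")
        if self.spectrum_noise < 0 or self.assay_noise < 0:
            raise ValueError("noise levels must be >= 0")


# --- proteins ---------------------------------------------------------------

# independent (naive) cleavage tables for ground-truth sites
_TRUTH_RULES = {
    "trypsin": ({"K", "R"}, {"P"}),
    "pepsin": ({"F", "L", "W", "Y"}, {"P"}),
}


def _naive_sites(sequence: str, p1: set, blockers: set) -> list[int]:
    out = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in p1 and sequence[i] not in blockers:
            out.append(i)
    return out


def gen_proteins(
    config: GeneratorConfig,
) -> tuple[list[ProteinRecord], dict[str, dict[str, list[int]]]]:
    """Sample i.i.d.-residue proteins plus true cleavage-site lists.

    Returns (records, truth) where ``truth[protein_id][enzyme]`` is the
    sorted bond-index list under the default trypsin/pepsin tables,
    computed by an independent naive scan.
    """
    rng = _rng(config.seed, "proteins")
    letters = list(config.composition)
    weights = np.array([config.composition[r] for r in letters], dtype=float)
    weights = weights / weights.sum()

    records, truth = [], {}
    for k in range(config.n_proteins):
        n = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=n, p=weights))
        rec = ProteinRecord(id=f"synthetic_prolamin_{k + 1}", sequence=seq,
                            description="synthetic prolamin-like sequence")
        records.append(rec)
        truth[rec.id] = {
            enzyme: _naive_sites(seq, p1, blk)
            for enzyme, (p1, blk) in _TRUTH_RULES.items()
        }
    return records, truth


# --- amino-acid profiles ----------------------------------------------------

# naive copies of the flavour/essential arithmetic used for profile truths
_T_ESSENTIAL = "TVMILFKW"
_T_THRESH = {"E": 30.0, "D": 100.0, "R": 10.0, "H": 20.0, "M": 30.0, "I": 90.0,
             "L": 380.0, "F": 150.0, "W": 90.0, "V": 150.0, "A": 60.0,
             "G": 110.0, "S": 150.0, "T": 260.0}


def gen_profile(config: GeneratorConfig) -> tuple[AminoAcidProfile, dict]:
    """Random non-negative g/100 g contents plus naively computed truths.

    Truth keys: taa, eaa, per1, per2, per3, tft, tbt, tst, tav.
    """
    rng = _rng(config.seed, "profile")
    residues = list(PROLAMIN_WEIGHTS)
    content = {r: float(rng.uniform(0.0, 15.0)) for r in residues}
    profile = AminoAcidProfile(sample_id=f"synthetic_{config.seed}", content=content)

    g = content.get
    truth = {
        "taa": sum(content.values()),
        "eaa": sum(g(r, 0.0) for r in _T_ESSENTIAL),
        "per1": -0.684 + 0.456 * g("L", 0.0) - 0.047 * g("P", 0.0),
        "per2": -0.468 + 0.454 * g("L", 0.0) - 0.105 * g("Y", 0.0),
        "per3": (-1.816 + 0.435 * g("M", 0.0) + 0.78 * g("L", 0.0)
                 + 0.211 * g("H", 0.0) - 0.944 * g("Y", 0.0)),
        "tft": 1000.0 * (g("E", 0.0) / 30.0 + g("D", 0.0) / 100.0),
        "tbt": 1000.0 * sum(g(r, 0.0) / _T_THRESH[r] for r in "VMILFHR"),
        "tst": 1000.0 * sum(g(r, 0.0) / _T_THRESH[r] for r in "TSG"),
        "tav": {r: 1000.0 * g(r, 0.0) / t for r, t in _T_THRESH.items()},
    }
    return profile, truth


# --- spectra ----------------------------------------------------------------

# naive amide I windows for truth assignment (half-open)
_T_WINDOWS = {
    "beta_sheet": ((1615.0, 1637.0), (1682.0, 1700.0)),
    "random_coil": ((1637.0, 1645.0),),
    "alpha_helix": ((1646.0, 1664.0),),
    "beta_turn": ((1664.0, 1681.0),),
}
# interior sampling windows (3 cm^-1 margin) for random band placement
_DRAW_WINDOWS = {
    "beta_sheet": (1618.0, 1634.0),
    "random_coil": (1639.0, 1643.0),
    "alpha_helix": (1649.0, 1661.0),
    "beta_turn": (1667.0, 1678.0),
}
# Dirichlet concentration proportional to a beta-sheet-dominated
# prolamin-like composition (~48/11/21/20), total concentration 20
_AREA_ALPHA = {"beta_sheet": 9.6, "random_coil": 2.2, "alpha_helix": 4.2, "beta_turn": 4.0}


def _truth_structure(center: float) -> Optional[str]:
    for s, intervals in _T_WINDOWS.items():
        for lo, hi in intervals:
            if lo <= center < hi:
                return s
    return None


def gen_spectrum(config: GeneratorConfig) -> tuple[Spectrum, dict[str, float]]:
    """Sum-of-Gaussians amide I spectrum plus true structure fractions.

    The spectrum is built on a 0.5 cm^-1 grid over 1580-1720 cm^-1, with
    seeded Gaussian noise and an optional linear baseline.  True
    fractions are band areas pooled by the structure window of each
    centre and normalised to 100.
    """
    rng = _rng(config.seed, "spectrum")
    x = np.arange(1580.0, 1720.0 + 0.25, 0.5)

    bands = config.spectrum_bands
    if bands is None:
        areas = rng.dirichlet([_AREA_ALPHA[s] for s in _DRAW_WINDOWS])
        bands = [
            (float(rng.uniform(lo, hi)), float(rng.uniform(5.0, 7.0)), float(a))
            for (lo, hi), a in zip(_DRAW_WINDOWS.values(), areas)
        ]
    for center, _, _ in bands:
        if not x[0] <= center <= x[-1]:
            raise ValueError(f"band centre {center} outside the wavenumber grid")

    y = np.zeros_like(x)
    for center, sigma, area in bands:
        amp = area / (sigma * np.sqrt(2.0 * np.pi))
        y += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    peak = float(np.max(y)) or 1.0
    y = y + rng.normal(0.0, config.spectrum_noise * peak, size=x.size)
    offset, slope = config.spectrum_baseline
    y = y + offset + slope * (x - x[0])

    pooled: dict[str, float] = {s: 0.0 for s in _T_WINDOWS}
    for center, _, area in bands:
        s = _truth_structure(center)
        if s is not None:
            pooled[s] += area
    total = sum(pooled.values())
    if total <= 0:
        raise ValueError("no band centre falls inside a structure window")
    truth = {s: 100.0 * a / total for s, a in pooled.items()}
    return Spectrum(x, y, kind="ftir"), truth


# --- plates -----------------------------------------------------------------


def gen_plate(config: GeneratorConfig) -> tuple[PlateReadings, float]:
    """Plate absorbances consistent with a chosen true inhibition.

    Built around a control window of 0.8 absorbance units (Acb = 0.100,
    Ac = 0.900) with per-well Gaussian noise of s.d. ``assay_noise``.
    Returns (readings, true inhibition percent).
    """
    rng = _rng(config.seed, "plate")
    truth = config.assay_truth
    a_cb, a_c, a_sb = 0.100, 0.900, 0.100
    a_s = a_sb + (1.0 - truth / 100.0) * (a_c - a_cb)
    noise = rng.normal(0.0, config.assay_noise, size=4)
    return (
        PlateReadings(
            a_s=float(a_s + noise[0]), a_sb=float(a_sb + noise[1]),
            a_c=float(a_c + noise[2]), a_cb=float(a_cb + noise[3]),
        ),
        truth,
    )
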