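# Methods

## Proteolysis model

Digestion is rule-based and exhaustive: a protease cuts the bond
C-terminal to any residue in its P1 set unless the next (P1') residue is
in its blocker set.  Bond *i* (1 ≤ i ≤ n−1) separates positions i−1 and
i in 0-based coordinates; peptides are reported as half-open intervals so
that concatenation exactly reconstructs the parent.  Shipped defaults:
trypsin (EC 3.4.21.4) cuts after Lys/Arg, blocked by Pro; pepsin at
pH > 2 (EC 3.4.23.1) cuts after Phe/Leu/Trp/Tyr, blocked by Pro.  These
are the most widely used dialect of the two specificities; published
rule tables differ between tools, so both tables are overridable from
config (`cleavage_rules` in the YAML/JSON config, or
`digestion.rule_from_dict`).

Two application modes are provided.  *Concurrent* cuts at the union of
all enzymes' sites in one pass (a one-pot digest); *sequential* applies
each enzyme to the fragments left by the previous one, mirroring the
gastric-then-intestinal order of gastrointestinal digestion.  For P1/P1'
rules the site predicate depends only on a residue and its successor, so
the two modes provably coincide; the equality is asserted as a property
test rather than assumed.

Degree of hydrolysis is 100 × cleaved bonds / total bonds per protein.
No kinetic or partial-digestion model is attempted: every matching site
is cut.  Real digests cleave a site fraction that depends on enzyme
dose, time and substrate folding, so absolute peptide counts from this
model are upper bounds, not predictions.

## Peptide screening

Peptide masses are residue-mass sums plus one water, using the standard
monoisotopic and average residue masses.  Motif flags record the
structure–activity features associated with DPP-IV inhibition:
hydrophobic fraction over {A,V,I,L,F,M,P}, hydrophobic N-terminal
residue, and Pro at the N-terminus, penultimate position or C-terminus.
Positional flags are False for single-residue peptides.

Predictor outputs (Peptide Ranker bioactivity, DPP-IV target
probability, Caco-2/MDCK permeability, %HIA, PPB, BBB, unbound fraction,
allergenicity marks) come from external tools and are *ingested* from
CSV only — this package does not reimplement or approximate those
models.  The score reader accepts publication-style scientific notation
("8.90 × 10⁻⁶") alongside E-notation, treats "NA"/"-" as explicitly
missing (never silently zero), and rejects duplicate sequences.

Screening retains peptides with bioactivity strictly above the threshold
(default 0.5) and sorts by DPP-IV probability descending, absent values
last, ties broken by bioactivity then sequence, which makes the ranking
a total order.  No DPP-IV probability cut-off is applied by default:
none is established, so the probability is reported and any cut is the
caller's choice.  MDCK permeability is banded low / medium / high at
2×10⁻⁶ and 20×10⁻⁶ cm/s with boundaries assigned to the medium band.

## Nutritional and flavour indices

All indices consume g amino acid per 100 g sample.  Class sets: fresh
(umami) {Glu, Asp}; bitter {Val, Met, Ile, Leu, Phe, His, Arg}; sweet
content {Thr, Ser, Gly, Ala}; medicinal {Met, Leu, Phe, Lys, Asp, Tyr,
Glu, Ala, Arg}; hydrophobic {Ala, Val, Ile, Leu, Phe, Met, Pro};
essential {Thr, Val, Met, Ile, Leu, Phe, Lys, Trp}.  Taste thresholds
(mg/100 g): Glu 30, Asp 100, Arg 10, His 20, Met 30, Ile 90, Leu 380,
Phe 150, Trp 90, Val 150, Ala 60, Gly 110, Ser 150, Thr 260.
TAV = 1000 × content / threshold; the significance flag is strict
(TAV > 1).  Two deliberate asymmetries, both configurable, follow the
conventions of the source composition table rather than the class sets:
the sweet TAV total sums only {Thr, Ser, Gly} (including Ala, whose
threshold is low, would triple the total), and reference composition
tables sometimes report the fresh *content* row as Asp alone — this
package consistently uses {Glu, Asp} for the fresh sum and documents the
discrepancy instead of matching it.

AAS divides the profile, first normalised to mg per g total amino acids
(a raw-ratio mode is available), by a scoring pattern; the shipped
default is the FAO/WHO/UNU adult pattern with Met+Cys and Phe+Tyr scored
as pairs.  Residues with zero measured content are excluded from
scoring: acid hydrolysis destroys Trp, so a zero means "not measured",
and scoring it would spuriously rank Trp first-limiting.  PER uses the
three literature regressions on Leu, Pro, Tyr, Met, His; these are
affine, so they scale neither with profile normalisation nor with
content scaling — they must be fed g/100 g contents.

## Assay calculators

DPP-IV inhibition is 100 × (1 − (As−Asb)/(Ac−Acb)); the expression is
invariant to adding a constant to all four absorbances and to scaling
all four by a non-zero factor (asserted as property tests).  Negative
values (apparent activation) are returned with a warning, not clamped.
Plate CSVs are aggregated by averaging absorbances per role before the
arithmetic.  Biuret quantitation inverts a linear standard curve
(default y = 0.0721x + 0.069, R² = 0.9987); below-blank absorbances
yield negative contents with a warning.  Surface hydrophobicity H0 is
the ordinary least-squares slope of fluorescence intensity on protein
concentration over the supplied dilution series; "initial slope" is not
a defined term, so an `n_lowest` option restricts the fit to the k
lowest concentrations for saturating series.

## Amide I deconvolution

The analysis window is 1600–1700 cm⁻¹.  A linear baseline through the
window endpoints (3-point averages) is subtracted and the signal is
normalised to its maximum; the normalised signal is quantised to float32
so the fit is bit-identical under positive intensity scaling.

Band positions are first sought as minima of the Savitzky–Golay-smoothed
second derivative (≈9 cm⁻¹ window, cubic, prominence 2% of the derivative
range).  Second-derivative seeding alone cannot set the band count: two
sub-bands closer than roughly one bandwidth produce a single curvature
minimum even without noise, and leaving the optimizer free to place
extra bands lets fitted centres drift across window boundaries, flipping
whole areas between structures.  The fit is therefore *window-anchored*:
each structure window contributes one Gaussian whose centre is
constrained to that window — placed at a second-derivative seed when the
window contains one (within ±4 cm⁻¹ of it) and free within the window
otherwise.  Widths are bounded to σ 4–9 cm⁻¹ (FWHM ≈ 9–21 cm⁻¹), the
physical range of amide I sub-bands; amplitudes are non-negative.  If
the converged model leaves a residual above the noise floor (estimated
from the smoothing residual), an unanchored component is added at the
largest residual and the fit repeated, so spectra with more sub-bands
than windows are still representable.  Non-convergence triggers seeded,
jittered restarts.

Structure fractions are fitted areas pooled by the window containing
each fitted centre, normalised to 100 over assigned area; peaks falling
in the small unassigned gaps (1645–1646, 1681–1682 cm⁻¹) are reported
but excluded from the total.  Gaussian lineshapes only: the classic
amide I fitting protocol this module follows uses Gaussian components,
and a Voigt option was judged not worth the extra degeneracy.

The Raman classifiers are deliberately simple: the tyrosine Fermi
doublet ratio takes baseline-corrected local maxima within ±8 cm⁻¹ of
850 and 830 cm⁻¹ (exposed iff I850/I830 ≥ 1), and the disulfide rotamer
bands are g-g-g [500, 516), g-g-t [516, 531), t-g-t [531, 545] — the
g-g-g band is widened from its nominal 510 cm⁻¹ position so the
classification is total on 500–545, and 531 belongs to t-g-t.

## Synthetic data

Each generator is a pure function of a single integer seed; every
generator draws from its own named RNG stream derived from that seed, so
adding a generator never shifts another's draws.  Ground truths are
computed by straight-line arithmetic inside the generator module with
hard-coded residue sets, thresholds and window tables — independent of
the modules under test, so they are valid oracles.

Defaults emulate the study system: proteins of 120–260 residues sampled
i.i.d. from prolamin-like weights (Gln+Pro+Leu+Ala+Phe ≈ 57% of mass,
Lys and Trp nearly absent); amide I spectra on a 0.5 cm⁻¹ grid over
1580–1720 cm⁻¹ with one band per structure window, centres drawn ≥3 cm⁻¹
inside the windows (2 cm⁻¹ for the narrow coil window), σ 5–7 cm⁻¹,
areas Dirichlet-distributed around the β-sheet-dominated composition
measured for cereal prolamins (≈48/21/20/11 β/α/turn/coil,
concentration 20), and Gaussian noise of 0.5% of the peak (≈46 dB SNR);
plates built around a 0.8-absorbance control window.

What the generators do *not* emulate bounds what passing tests show:
real protein sequences are not i.i.d. (prolamins carry long Pro/Gln-rich
repeats), real amide I bands are Voigt-like with sloping, curved
baselines and correlated noise, and real digests are kinetically
incomplete.  Recovery results on synthetic data therefore validate the
estimators' correctness, not instrument-grade accuracy on wet spectra;
published secondary-structure percentages from wet FTIR/Raman data are
not reproducible from code and are not used as test targets.

## Problem sizes and numerical choices

The test suite uses 1000 random sequences for the digestion oracle and
conservation suites, 100 synthetic spectra for fraction-recovery
statistics (mean absolute error target < 2 percentage points), and 1000
noisy plate replicates for the inhibition-recovery check; all run in
well under a minute on one core.  Ties in screening are broken
deterministically (bioactivity, then sequence).  Degenerate inputs
(empty sequences, all-zero profiles, zero control windows, zero-slope
curves, non-monotonic wavenumber grids) raise typed errors rather than
returning sentinel values; below-blank and activation outcomes warn but
return the computed number.
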