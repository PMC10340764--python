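"""Nutritional and flavour indices for the raw prolamin composition.

Loads the packaged amino-acid composition table (g amino acid per 100 g)
and prints the protein efficiency ratio regressions, class sums and
taste-activity totals for the unprocessed sample.  A PER above 2 marks
good protein quality; a TAV above 1 marks a flavour-relevant residue.
"""

import warnings

from coixpep import AminoAcidProfile, load_table3_profiles, nutrition_report

table = load_table3_profiles()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # only 17 of 20 residues are measured
    profile = AminoAcidProfile(sample_id="raw", content=table["raw"].to_dict())

report = nutrition_report(profile)
s = report.sums
print(f"PER1 {report.per1:.2f}, PER2 {report.per2:.2f}, PER3 {report.per3:.2f}")
print(f"TAA {s['taa']:.2f}  EAA {s['eaa']:.2f}  EAA/TAA {s['eaa_taa']:.2f}%")
print(f"hydrophobic residues (HAA) {s['haa']:.2f} g/100 g")
print(f"medicinal residues D/T {s['d_t']:.2f}%")
print(f"flavour TAV totals: fresh {report.tft:.2f}, bitter {report.tbt:.2f}, "
      f"sweet {report.tst:.2f}")
print(f"limiting amino acids (ascending score): {', '.join(report.limiting[:2])}")
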