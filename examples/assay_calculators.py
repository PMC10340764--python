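"""The four wet-assay calculators on worked inputs.

DPP-IV percent inhibition from plate absorbances, biuret peptide
quantitation through the linear standard curve, ANS surface
hydrophobicity (H0) as the fitted slope of fluorescence on protein
concentration, and the prolamin extraction rate.
"""

from coixpep import (
    PlateReadings,
    dppiv_inhibition,
    extraction_rate,
    peptide_content,
    surface_hydrophobicity,
)

# sample window half the control window -> 50% inhibition
inhibition = dppiv_inhibition(PlateReadings(a_s=0.5, a_sb=0.1, a_c=0.9, a_cb=0.1))
print(f"DPP-IV inhibition: {inhibition:.1f}%")

# absorbance 0.790 on the curve y = 0.0721 x + 0.069 -> 10 mg/mL
content = peptide_content(0.790)
print(f"peptide content at A540 = 0.790: {content:.2f} mg/mL")

fit = surface_hydrophobicity([(0.2, 52.0), (0.4, 101.0), (0.6, 153.0), (0.8, 198.0)])
print(f"surface hydrophobicity H0 = {fit.h0:.1f} (R^2 = {fit.r2:.4f})")

rate = extraction_rate(extract_protein=0.42, seed_prolamin=0.60)
print(f"extraction rate: {rate:.1f}%")
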