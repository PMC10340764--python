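"""Screen digestion-derived peptides by ingested predictor scores.

Loads the packaged 47-peptide predictor-score table, keeps peptides whose
Peptide Ranker bioactivity exceeds 0.5 and ranks them by DPP-IV
inhibition probability.  The top of the ranking carries the classic
DPP-IV inhibitor motifs: hydrophobic N-terminus and Pro at the
penultimate position.
"""

from coixpep import load_table2_scores, screen
from coixpep.peptides import ingest_from_frame

table = load_table2_scores()
result = screen(ingest_from_frame(table))

print(f"{len(result)} of {len(table)} peptides pass the bioactivity > 0.5 filter")
print("top five by DPP-IV inhibition probability:")
for row in result.head(5).itertuples():
    print(
        f"  {row.sequence:6s} p(DPP-IV)={row.dppiv_probability:.3f} "
        f"bioactivity={row.bioactivity:.3f} "
        f"mono_mass={row.mono_mass:.2f} Da "
        f"Pro-penultimate={row.pro_penultimate}"
    )
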