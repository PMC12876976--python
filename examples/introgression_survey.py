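"""Introgression rates from the packaged published frequency survey.

Loads the survey of lessonae-specific nucleotide frequencies at 16
species-specific SNPs across 11 P. ridibundus (RR) and 3 P. lessonae (LL)
population units, infers each SNP's expected fixed state from the pooled
species means, and summarizes the departures as introgression rates.
"""

from pelopop import datasets, introgression

freq = datasets.load_diagnostic_frequencies()
classification = datasets.diagnostic_classification(freq)

for species in ("RR", "LL"):
    cells = introgression.introgression_cells(
        freq[freq["species"] == species], classification, species
    )
    s = introgression.ir_summaries(cells)
    print(f"\n{species}: {s.cells.shape[0]} SNPs x {s.cells.shape[1]} units "
          f"({s.n_cells} sampled cells)")
    print(f"  IR_mean = {s.ir_mean:.4f} +/- {s.ir_sd_sample:.4f}")
    top = s.ir_pop.sort_values(ascending=False).head(3)
    print("  highest per-population rates:")
    for unit, val in top.items():
        print(f"    {unit}: {val:.3f}")
# IR_mean is the mean frequency of foreign-species alleles over all
# SNP x population cells: about 1% of RR allele copies and 0.3% of LL
# copies carry the other species' diagnostic allele.
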