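"""End-to-end convenience workflows chaining the pipeline stages."""

from __future__ import annotations

from .genotyping import CallThresholds, call_table
from .introgression import IntrogressionSummary, estimate_from_frequencies
from .popfreq import allele_frequencies, classification_from_panel, pool_populations
from .simdata import SimulationConfig, simulate_cohort


def ir_from_simulated_cohort(
    config: SimulationConfig,
    focal_species: str = "RR",
    thresholds: CallThresholds | None = None,
) -> IntrogressionSummary:
    """Simulate a cohort and run it through calling, pooling and IR estimation.

    The SNP classification is taken from the simulated diagnostic panel
    (designated nucleotide = the L allele, fixed at 1 in LL and 0 in RR),
    mirroring an analysis in which the species-specific panel is known.
    """
    counts, metadata, _ = simulate_cohort(config)
    calls = call_table(counts, thresholds)
    units = pool_populations(metadata, focal_species)
    designated = {(s.name, 1): s.l_base for s in config.snp_panel}
    freq = allele_frequencies(calls, metadata, units, designated, focal_species)
    classification = classification_from_panel(config.snp_panel)
    return estimate_from_frequencies(freq, classification, focal_species)
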