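import numpy as np
import pandas as pd
import pytest

from pelopop import simdata


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free mixed cohort: all five genotype classes, two populations."""
    config = simdata.SimulationConfig(
        snp_panel=simdata.default_panel(8),
        populations=(
            simdata.PopulationSpec(
                "PopA", "L-E", "west", 52.0, 13.0,
                {"LL": 10, "LR": 10, "LLR": 4},
            ),
            simdata.PopulationSpec(
                "PopB", "R-E", "east", 52.5, 14.5,
                {"RR": 10, "LR": 10, "RRL": 4},
            ),
        ),
        error_rate=0.0,
        coverage_mean=100.0,
        coverage_dispersion=50.0,
        seed=11,
    )
    counts, meta, truth = simdata.simulate_cohort(config)
    return config, counts, meta, truth


def unit_frequency_frame(rng, popsys_f, n_units_per_level=6, n_alleles=40,
                         lat_by_level=None):
    """Unit-level frequency table for association tests.

    ``popsys_f`` maps POPSYS level -> true designated-allele frequency; unit
    frequencies are binomial draws over ``n_alleles`` allele copies.
    """
    rows = []
    for level, f_true in popsys_f.items():
        base_lat = (lat_by_level or {}).get(level, 50.0)
        for u in range(n_units_per_level):
            f = rng.binomial(n_alleles, f_true) / n_alleles
            rows.append({
                "unit": f"{level}_{u}",
                "f": f,
                "n": n_alleles,
                "popsys": level,
                "lat": base_lat + rng.normal(0, 1.0),
                "lon": 10.0 + rng.normal(0, 2.0),
            })
    return pd.DataFrame(rows)
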