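"""Synthetic GT-Seq cohorts with known ground truth.

The generator emulates the data the downstream pipeline consumes: a cohort of
water frogs (parental species LL and RR, diploid hybrids LR, triploids LLR
and RRL) sampled from populations belonging to different population systems
(POPSYS), genotyped at a panel of amplicon SNPs.  For each individual and
SNP it draws a true ordered allele multiset (dosage) and then simulates read
counts with negative-binomial coverage and uniform base-miscall error.

Key levers:

* ``introgression_rate_rr`` / ``introgression_rate_ll`` — per-allele-copy
  probability that a parental individual carries the other species' allele
  at a species-specific SNP (the quantity the introgression module
  estimates).
* ``popsys_effect`` — per-SNP, per-POPSYS frequency of the SNP's L-allele,
  used to plant population-system associations for power testing.

With a fixed seed the output is bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotyping import BASES, PLOIDY_BY_TAXON, read_count_columns

GENOME_COPIES: Mapping[str, str] = {
    "LL": "LL", "RR": "RR", "LR": "LR", "LLR": "LLR", "RRL": "LRR",
}

POPSYS_LEVELS = ("L-E", "R-E", "E", "all-R")

METADATA_COLUMNS = (
    "individual", "taxon", "population", "popsys", "region",
    "lat", "lon", "sex", "ploidy",
)
TRUTH_COLUMNS = ("individual", "marker", "pos", "true_alleles", "introgressed")


@dataclass(frozen=True)
class SnpSpec:
    """One SNP marker of the panel.

    ``l_base``/``r_base`` are the alleles characteristic of the L and R
    genomes; ``species_specific`` marks SNPs fixed (up to introgression)
    between the parental species.
    """

    name: str
    gene: str = ""
    species_specific: bool = True
    l_base: str = "A"
    r_base: str = "G"

    def __post_init__(self) -> None:
        if self.l_base not in BASES or self.r_base not in BASES:
            raise ValueError("alleles must be one of A/C/G/T")
        if self.l_base == self.r_base:
            raise ValueError(f"SNP {self.name}: identical L and R alleles")


@dataclass(frozen=True)
class PopulationSpec:
    """A sampled population with its system, region and sample sizes."""

    name: str
    popsys: str
    region: str
    latitude: float
    longitude: float
    n_by_genotype: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.popsys not in POPSYS_LEVELS:
            raise ValueError(f"unknown POPSYS {self.popsys!r}")
        for taxon, n in self.n_by_genotype.items():
            if taxon not in GENOME_COPIES:
                raise ValueError(f"unknown genotype class {taxon!r}")
            if n < 0:
                raise ValueError("sample sizes must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    snp_panel: tuple[SnpSpec, ...]
    populations: tuple[PopulationSpec, ...]
    introgression_rate_rr: float = 0.0
    introgression_rate_ll: float = 0.0
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    error_rate: float = 0.001
    #: snp name -> POPSYS -> frequency of the SNP's l_base allele.
    popsys_effect: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.snp_panel) == 0:
            raise ValueError("configuration error: empty SNP panel")
        if len(self.populations) == 0:
            raise ValueError("configuration error: no populations")
        for p in (self.introgression_rate_rr, self.introgression_rate_ll,
                  self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for snp, shifts in self.popsys_effect.items():
            for f in shifts.values():
                if not 0.0 <= f <= 1.0:
                    raise ValueError("popsys_effect frequencies must be in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")


def default_panel(n_snps: int = 16, species_specific: bool = True) -> tuple[SnpSpec, ...]:
    """A convenience panel of alternating-allele diagnostic SNPs."""
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    return tuple(
        SnpSpec(
            name=f"snp{i + 1:03d}",
            gene=f"gene{i + 1:02d}",
            species_specific=species_specific,
            l_base=pairs[i % 4][0],
            r_base=pairs[i % 4][1],
        )
        for i in range(n_snps)
    )


def _true_alleles(
    rng: np.random.Generator,
    snp: SnpSpec,
    taxon: str,
    popsys: str,
    config: SimulationConfig,
) -> tuple[list[str], bool]:
    """Draw the ordered allele multiset for one individual x SNP."""
    copies = GENOME_COPIES[taxon]
    shifts = config.popsys_effect.get(snp.name)
    alleles: list[str] = []
    introgressed = False
    if shifts is not None or not snp.species_specific:
        # frequency-model SNP: each genome copy carries the L-allele with a
        # POPSYS-dependent probability (default 0.5 for intraspecific SNPs)
        f = 0.5 if shifts is None else shifts.get(popsys, 0.5)
        for _ in copies:
            alleles.append(snp.l_base if rng.random() < f else snp.r_base)
        return alleles, False
    for lineage in copies:
        base = snp.l_base if lineage == "L" else snp.r_base
        if taxon == "RR" and config.introgression_rate_rr > 0:
            if rng.random() < config.introgression_rate_rr:
                base = snp.l_base
                introgressed = True
        elif taxon == "LL" and config.introgression_rate_ll > 0:
            if rng.random() < config.introgression_rate_ll:
                base = snp.r_base
                introgressed = True
        alleles.append(base)
    return alleles, introgressed


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate read counts, sample metadata, and the ground-truth table.

    Returns ``(read_counts, metadata, truth)``: one read-count row per
    individual x SNP, one metadata row per individual, one truth row per
    individual x SNP.
    """
    rng = np.random.default_rng(config.seed)
    base_index = {b: i for i, b in enumerate(BASES)}
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)

    count_rows: list[tuple] = []
    meta_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for pop in config.populations:
        for taxon in ("LL", "RR", "LR", "LLR", "RRL"):
            n = pop.n_by_genotype.get(taxon, 0)
            for i in range(n):
                ind = f"{pop.name}_{taxon}_{i + 1:03d}"
                sex = "F" if i % 2 == 0 else "M"
                meta_rows.append(
                    (ind, taxon, pop.name, pop.popsys, pop.region,
                     pop.latitude, pop.longitude, sex, PLOIDY_BY_TAXON[taxon])
                )
                for s, snp in enumerate(config.snp_panel):
                    alleles, intro = _true_alleles(rng, snp, taxon, pop.popsys, config)
                    pos = 1  # one marker-local site per SNP
                    truth_rows.append(
                        (ind, snp.name, pos, "".join(sorted(alleles)), intro)
                    )
                    cov = int(rng.negative_binomial(k, p_nb))
                    probs = np.zeros(4)
                    for a in alleles:
                        probs[base_index[a]] += 1.0 / len(alleles)
                    e = config.error_rate
                    probs = probs * (1.0 - e) + (1.0 - probs) * (e / 3.0)
                    counts = rng.multinomial(cov, probs) if cov > 0 else np.zeros(4, int)
                    count_rows.append((ind, snp.name, pos, *counts.tolist()))

    read_counts = pd.DataFrame(count_rows, columns=list(read_count_columns()))
    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return read_counts, metadata, truth


# ---------------------------------------------------------------------------
# fixture round-trip


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["snp_panel"] = [dataclasses.asdict(s) for s in config.snp_panel]
    d["populations"] = [
        {**dataclasses.asdict(p), "n_by_genotype": dict(p.n_by_genotype)}
        for p in config.populations
    ]
    d["popsys_effect"] = {k: dict(v) for k, v in config.popsys_effect.items()}
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    return SimulationConfig(
        snp_panel=tuple(SnpSpec(**s) for s in d["snp_panel"]),
        populations=tuple(PopulationSpec(**p) for p in d["populations"]),
        introgression_rate_rr=d.get("introgression_rate_rr", 0.0),
        introgression_rate_ll=d.get("introgression_rate_ll", 0.0),
        coverage_mean=d.get("coverage_mean", 100.0),
        coverage_dispersion=d.get("coverage_dispersion", 5.0),
        error_rate=d.get("error_rate", 0.001),
        popsys_effect=d.get("popsys_effect", {}),
        seed=d.get("seed", 0),
    )


def write_fixture(
    directory: str | Path,
    read_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort as TSV files (+ config YAML) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.tsv",
    }
    read_counts.to_csv(paths["counts"], sep="\t", index=False)
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if config is not None:
        paths["config"] = directory / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
    return paths


def read_fixture(
    directory: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationConfig | None]:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    read_counts = pd.read_csv(
        directory / "counts.tsv", sep="\t", dtype={"individual": str, "marker": str}
    )
    metadata = pd.read_csv(
        directory / "metadata.tsv", sep="\t",
        dtype={"individual": str, "population": str},
    )
    truth = pd.read_csv(
        directory / "truth.tsv", sep="\t",
        dtype={"individual": str, "marker": str, "true_alleles": str},
    )
    config = None
    config_path = directory / "config.yaml"
    if config_path.exists():
        with open(config_path) as fh:
            config = config_from_dict(yaml.safe_load(fh))
    return read_counts, metadata, truth, config
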