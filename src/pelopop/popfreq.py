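"""Allele frequencies per population unit and species-specific SNP calling.

Workflow: filter out SNPs with too few called individuals per taxon, pool
small populations of the same population system and geographic region into
population units, compute per-unit allele frequencies of each SNP's
designated nucleotide over diploid individuals (triploids are excluded), and
classify SNPs as species-specific or intraspecific from the pooled parental
frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARENTAL_TAXA = ("LL", "RR")
DIPLOID_TAXA = ("LL", "RR", "LR")


@dataclass(frozen=True)
class PopulationUnit:
    """A population or a pool of small same-system, same-region populations."""

    unit_id: str
    members: tuple[str, ...]
    popsys: str
    region: str
    latitude: float
    longitude: float
    n_individuals: int
    pooled: bool = False
    flagged: bool = False  # still under the size threshold after pooling


@dataclass(frozen=True)
class SnpClassification:
    """Category of one SNP based on pooled parental frequencies.

    ``expected_ll``/``expected_rr`` give the fixed state (0 or 1) of the
    designated nucleotide in each parental species when that species is at
    or beyond the 0.95/0.05 fixation band, else ``None``.
    """

    snp: str
    category: str  # species_specific | intraspecific_L | intraspecific_R | uninformative
    designated: str = ""
    expected_ll: int | None = None
    expected_rr: int | None = None
    polymorphic_in: tuple[str, ...] = field(default_factory=tuple)

    def expected_state(self, species: str) -> int | None:
        return self.expected_ll if species == "LL" else self.expected_rr


def filter_markers(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    min_individuals: int = 5,
    taxa: Sequence[str] = DIPLOID_TAXA,
) -> tuple[set[tuple[str, int]], pd.DataFrame]:
    """Retain SNPs called in at least ``min_individuals`` of every taxon.

    Returns the retained (marker, pos) set and a report of removed SNPs with
    per-taxon called counts.
    """
    merged = calls.merge(metadata[["individual", "taxon"]], on="individual")
    if merged.empty:
        raise ValueError("empty join between calls and metadata")
    taxa = [t for t in taxa if t in set(metadata["taxon"])]
    called = merged[merged["status"] == "called"]
    counts = (
        called.groupby(["marker", "pos", "taxon"])["individual"]
        .nunique()
        .unstack("taxon", fill_value=0)
        .reindex(columns=taxa, fill_value=0)
    )
    all_snps = set(map(tuple, calls[["marker", "pos"]].drop_duplicates().values))
    ok = counts[(counts[taxa] >= min_individuals).all(axis=1)]
    retained = set(ok.index)
    removed = counts.loc[sorted(all_snps - retained - (all_snps - set(counts.index)))]
    # SNPs never called at all
    never = sorted(all_snps - set(counts.index))
    if never:
        extra = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(never), columns=taxa)
        removed = pd.concat([removed, extra])
    if not retained:
        logger.warning("no SNP passed the per-taxon sample-size filter")
    report = removed.reset_index().rename(columns={"level_0": "marker", "level_1": "pos"})
    return retained, report


def pool_populations(
    metadata: pd.DataFrame,
    genotype_class: str,
    min_n: int = 4,
) -> list[PopulationUnit]:
    """Build population units for one genotype class.

    Populations with at least ``min_n`` individuals of the class stand alone.
    Smaller populations are pooled with the other small populations of the
    same POPSYS and region; a small population without such a partner is
    flagged and excluded from the unit list.
    """
    sub = metadata[metadata["taxon"] == genotype_class]
    if sub.empty:
        return []
    required = {"population", "popsys", "region", "lat", "lon"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    if sub["popsys"].isna().any() or sub["region"].isna().any():
        bad = sub.loc[sub["popsys"].isna() | sub["region"].isna(), "population"].unique()
        raise ValueError(f"populations lacking POPSYS/region: {list(bad)}")

    stats = (
        sub.groupby("population")
        .agg(
            n=("individual", "nunique"),
            popsys=("popsys", "first"),
            region=("region", "first"),
            lat=("lat", "mean"),
            lon=("lon", "mean"),
        )
        .sort_index()
    )
    units: list[PopulationUnit] = []
    for (popsys, region), grp in stats.groupby(["popsys", "region"], sort=True):
        big = grp[grp["n"] >= min_n]
        small = grp[grp["n"] < min_n]
        for pop, row in big.iterrows():
            units.append(
                PopulationUnit(
                    unit_id=str(pop), members=(str(pop),), popsys=popsys,
                    region=region, latitude=row["lat"], longitude=row["lon"],
                    n_individuals=int(row["n"]),
                )
            )
        if len(small) >= 2:
            members = tuple(str(p) for p in small.index)
            total = int(small["n"].sum())
            units.append(
                PopulationUnit(
                    unit_id="+".join(members), members=members, popsys=popsys,
                    region=region,
                    latitude=float(np.average(small["lat"], weights=small["n"])),
                    longitude=float(np.average(small["lon"], weights=small["n"])),
                    n_individuals=total, pooled=True, flagged=total < min_n,
                )
            )
        elif len(small) == 1:
            pop = str(small.index[0])
            logger.warning(
                "population %s (%s/%s) has < %d %s individuals and no pooling "
                "partner; excluded", pop, popsys, region, min_n, genotype_class,
            )
    return units


def designate_alleles(
    calls: pd.DataFrame, metadata: pd.DataFrame
) -> dict[tuple[str, int], str]:
    """Pick the designated nucleotide per SNP: the major allele in LL.

    Falls back to the overall major allele for SNPs with no called LL
    individual.  Allele counts are 2 per homozygote and 1 per heterozygote
    allele.
    """
    merged = calls[calls["status"] == "called"].merge(
        metadata[["individual", "taxon"]], on="individual"
    )
    designated: dict[tuple[str, int], str] = {}
    for key, grp in merged.groupby(["marker", "pos"]):
        ll = grp[grp["taxon"] == "LL"]
        use = ll if len(ll) else grp
        tally: dict[str, int] = {}
        for alleles in use["alleles"]:
            if len(alleles) == 1:
                tally[alleles] = tally.get(alleles, 0) + 2
            else:
                for a in alleles:
                    tally[a] = tally.get(a, 0) + 1
        designated[key] = min(tally, key=lambda a: (-tally[a], a))
    return designated


def allele_frequencies(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    units: Iterable[PopulationUnit],
    designated: Mapping[tuple[str, int], str],
    genotype_class: str,
    snps: Iterable[tuple[str, int]] | None = None,
    sex_separated: bool = False,
) -> pd.DataFrame:
    """Designated-allele frequency per (SNP, population unit).

    Only diploid individuals of ``genotype_class`` contribute; triploids in
    the metadata are dropped with a logged count.  A homozygote for the
    designated allele contributes 2 allele copies, a heterozygote carrying
    it contributes 1; uncalled sites are excluded from both numerator and
    denominator.  Units with no called individual are flagged missing
    (f = NaN).

    With ``sex_separated=True`` additional rows per unit and sex are emitted
    (unit ids suffixed ``/F`` and ``/M``), mirroring the dual computation
    used for populations with ambiguous system assignment.
    """
    n_triploid = int((metadata["ploidy"] > 2).sum()) if "ploidy" in metadata else 0
    if n_triploid:
        logger.info("excluding %d triploid individuals", n_triploid)
        metadata = metadata[metadata["ploidy"] <= 2]
    meta = metadata[metadata["taxon"] == genotype_class]
    merged = calls.merge(
        meta[["individual", "population"] + (["sex"] if sex_separated else [])],
        on="individual",
    )
    merged = merged[merged["status"] == "called"]
    if snps is not None:
        keep = set(snps)
        merged = merged[
            [tuple(k) in keep for k in merged[["marker", "pos"]].values]
        ]

    rows = []
    for unit in units:
        in_unit = merged[merged["population"].isin(unit.members)]
        groups = [(unit.unit_id, in_unit)]
        if sex_separated:
            groups += [
                (f"{unit.unit_id}/{sx}", in_unit[in_unit["sex"] == sx])
                for sx in ("F", "M")
            ]
        for unit_id, sub in groups:
            for (marker, pos), grp in sub.groupby(["marker", "pos"]):
                des = designated[(marker, pos)]
                n_ind = grp["individual"].nunique()
                num = 0
                for alleles in grp["alleles"]:
                    if len(alleles) == 1:
                        num += 2 if alleles == des else 0
                    else:
                        num += 1 if des in alleles else 0
                rows.append(
                    (marker, pos, unit_id, genotype_class,
                     num / (2 * n_ind), n_ind, 2 * n_ind, False)
                )
            # units with zero called individuals at every SNP never appear in
            # the loop above; emit explicit missing rows for known SNPs
            if sub.empty and snps is not None:
                for marker, pos in snps:
                    rows.append(
                        (marker, pos, unit_id, genotype_class,
                         np.nan, 0, 0, True)
                    )
    freq = pd.DataFrame(
        rows,
        columns=["marker", "pos", "unit", "genotype_class",
                 "f", "n_individuals", "n_alleles", "missing"],
    )
    return freq


def species_mean_frequencies(freq: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of per-unit frequencies across units, per SNP."""
    return freq.groupby(["marker", "pos"])["f"].mean()


def classify_snp(
    snp: str,
    f_ll: float,
    f_rr: float,
    designated: str = "",
    threshold: float = 0.95,
) -> SnpClassification:
    """Classify one SNP from its pooled parental frequencies.

    Species-specific: the designated allele is (near-)fixed in both species
    but on opposite states, i.e. its frequency is >= 0.95 in exactly one of
    them.  Polymorphic in exactly one species -> intraspecific for that
    species.  Missing parental data or polymorphism in both -> uninformative.
    """
    if f_ll is None or f_rr is None or np.isnan(f_ll) or np.isnan(f_rr):
        return SnpClassification(snp=snp, category="uninformative", designated=designated)

    def fixed_state(f: float) -> int | None:
        if f >= threshold:
            return 1
        if f <= 1.0 - threshold:
            return 0
        return None

    e_ll, e_rr = fixed_state(f_ll), fixed_state(f_rr)
    poly = tuple(
        sp for sp, e in (("LL", e_ll), ("RR", e_rr)) if e is None
    )
    if e_ll is not None and e_rr is not None and e_ll != e_rr:
        category = "species_specific"
    elif poly == ("LL",):
        category = "intraspecific_L"
    elif poly == ("RR",):
        category = "intraspecific_R"
    else:
        category = "uninformative"
    return SnpClassification(
        snp=snp, category=category, designated=designated,
        expected_ll=e_ll, expected_rr=e_rr, polymorphic_in=poly,
    )


def classify_snps(
    freq_ll: pd.DataFrame,
    freq_rr: pd.DataFrame,
    designated: Mapping[tuple[str, int], str] | None = None,
) -> dict[tuple[str, int], SnpClassification]:
    """Classify every SNP from the LL and RR frequency tables."""
    mean_ll = species_mean_frequencies(freq_ll)
    mean_rr = species_mean_frequencies(freq_rr)
    out = {}
    for key in sorted(set(mean_ll.index) | set(mean_rr.index)):
        f_ll = mean_ll.get(key, np.nan)
        f_rr = mean_rr.get(key, np.nan)
        des = designated.get(key, "") if designated else ""
        out[key] = classify_snp(f"{key[0]}:{key[1]}", f_ll, f_rr, designated=des)
    return out


def classification_from_panel(panel) -> dict[tuple[str, int], SnpClassification]:
    """Build classifications directly from a known diagnostic panel.

    For simulated cohorts the species alleles are known by construction:
    the designated nucleotide is the L allele, fixed at 1 in LL and 0 in RR.
    ``panel`` is an iterable of simdata ``SnpSpec``.
    """
    out = {}
    for spec in panel:
        if not spec.species_specific:
            continue
        key = (spec.name, 1)
        out[key] = SnpClassification(
            snp=spec.name, category="species_specific", designated=spec.l_base,
            expected_ll=1, expected_rr=0,
        )
    return out
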