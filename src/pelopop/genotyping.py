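"""Genotype calling from amplicon read counts.

GT-Seq produces, per individual and per marker site, the number of reads
supporting each of the four bases.  This module converts those counts into
diploid genotype calls (IUPAC-coded), builds per-individual consensus
sequences over a SNP panel, and assigns a taxon/ploidy class from the pooled
read fraction of species-diagnostic alleles.

The calling rule is deliberately simple and coverage-driven: a site needs a
minimum total coverage to be called at all, and the second-most-abundant base
is accepted as a heterozygous allele only when it reaches a minimum relative
coverage.  Both thresholds are explicit parameters (defaults: 10 reads and
20% of the site total).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ("nA", "nC", "nG", "nT")

#: IUPAC code for every non-empty subset of {A,C,G,T} of size 1 or 2.
IUPAC_BY_ALLELES: Mapping[frozenset, str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
}

#: Inverse map, including the 3- and 4-base codes needed for distance math.
ALLELES_BY_IUPAC: Mapping[str, frozenset] = {
    **{code: alleles for alleles, code in IUPAC_BY_ALLELES.items()},
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Expected diagnostic-allele dosage per taxon class (fraction of genome
#: copies that are L-derived).
TAXON_DOSAGE: Mapping[str, float] = {
    "RR": 0.0,
    "RRL": 1.0 / 3.0,
    "LR": 0.5,
    "LLR": 2.0 / 3.0,
    "LL": 1.0,
}

PLOIDY_BY_TAXON: Mapping[str, int] = {
    "LL": 2, "RR": 2, "LR": 2, "LLR": 3, "RRL": 3,
}


@dataclass(frozen=True)
class AlleleCounts:
    """Read counts for the four bases at one (individual, marker, pos) site."""

    nA: int
    nC: int
    nG: int
    nT: int

    def __post_init__(self) -> None:
        for base, n in zip(BASES, self.as_tuple()):
            if n < 0:
                raise ValueError(f"negative read count for {base}: {n}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.nA, self.nC, self.nG, self.nT)

    @property
    def cov_tot(self) -> int:
        """Total site coverage (sum of the four base counts)."""
        return sum(self.as_tuple())


@dataclass(frozen=True)
class CallThresholds:
    """Coverage thresholds of the genotype caller.

    min_total_coverage
        Minimum total reads at a site for any call to be made.
    min_relative_coverage
        Minimum fraction of the site total that the second base must reach
        to be accepted as a heterozygous allele (boundary inclusive).
    """

    min_total_coverage: int = 10
    min_relative_coverage: float = 0.20

    def __post_init__(self) -> None:
        if self.min_total_coverage < 1:
            raise ValueError("min_total_coverage must be >= 1")
        if not 0.0 < self.min_relative_coverage <= 0.5:
            raise ValueError("min_relative_coverage must be in (0, 0.5]")


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype call at one site."""

    status: str  # "called" | "no_call"
    alleles: frozenset = field(default_factory=frozenset)
    iupac: str = "N"

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2


NO_CALL = GenotypeCall(status="no_call")


def parse_pileup(source: str | TextIO) -> pd.DataFrame:
    """Read a per-site base-count table (``ReadCountTable``).

    Expects a TSV with columns individual, marker, pos, nA, nC, nG, nT.
    Header optional if the columns appear in this order.  Malformed lines
    are reported with their 1-based line number.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return parse_pileup(fh)

    text = source.read()
    if not text.strip():
        warnings.warn("empty pileup input: returning empty ReadCountTable")
        return empty_read_count_table()

    first = text.lstrip().splitlines()[0]
    has_header = "individual" in first
    table = pd.read_csv(
        io.StringIO(text),
        sep="\t",
        header=0 if has_header else None,
        names=None if has_header else list(read_count_columns()),
        dtype={"individual": str, "marker": str},
    )
    missing = set(read_count_columns()) - set(table.columns)
    if missing:
        raise ValueError(f"pileup is missing columns: {sorted(missing)}")
    offset = 2 if has_header else 1
    for col in ("pos", *COUNT_COLUMNS):
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values != values.round())
        if bad.any():
            line = int(bad.idxmax()) + offset
            raise ValueError(
                f"invalid value in column {col!r} at line {line}: "
                f"{table[col].iloc[int(bad.idxmax())]!r}"
            )
        table[col] = values.astype(int)
    return table[list(read_count_columns())]


def read_count_columns() -> tuple[str, ...]:
    return ("individual", "marker", "pos", *COUNT_COLUMNS)


def empty_read_count_table() -> pd.DataFrame:
    return pd.DataFrame(columns=list(read_count_columns()))


def call_site(counts: AlleleCounts, thresholds: CallThresholds | None = None) -> GenotypeCall:
    """Call one site from its base counts.

    A site below ``min_total_coverage`` is a no-call.  Otherwise the top base
    is always an allele; the runner-up becomes the second allele when its
    relative coverage is at least ``min_relative_coverage`` of the total.
    Any third or fourth base is treated as sequencing error and ignored.
    Ties are broken alphabetically (A < C < G < T).
    """
    t = thresholds or CallThresholds()
    total = counts.cov_tot
    if total < t.min_total_coverage:
        return NO_CALL
    # sort by (-count, base): deterministic alphabetical tie-break
    ranked = sorted(zip(counts.as_tuple(), BASES), key=lambda cn: (-cn[0], cn[1]))
    (n1, b1), (n2, b2) = ranked[0], ranked[1]
    if n2 / total >= t.min_relative_coverage:
        alleles = frozenset((b1, b2))
    else:
        alleles = frozenset((b1,))
    return GenotypeCall(status="called", alleles=alleles, iupac=IUPAC_BY_ALLELES[alleles])


def call_table(table: pd.DataFrame, thresholds: CallThresholds | None = None) -> pd.DataFrame:
    """Call every row of a ReadCountTable.

    Returns a calls table with columns individual, marker, pos, status,
    alleles (sorted string, '' when no-call), iupac, cov_tot.
    """
    t = thresholds or CallThresholds()
    records = []
    for row in table.itertuples(index=False):
        counts = AlleleCounts(row.nA, row.nC, row.nG, row.nT)
        call = call_site(counts, t)
        records.append(
            (row.individual, row.marker, row.pos, call.status,
             "".join(sorted(call.alleles)), call.iupac, counts.cov_tot)
        )
    return pd.DataFrame(
        records,
        columns=["individual", "marker", "pos", "status", "alleles", "iupac", "cov_tot"],
    )


def consensus_sequences(
    table: pd.DataFrame,
    panel: Sequence[tuple[str, int]],
    thresholds: CallThresholds | None = None,
) -> dict[str, str]:
    """Build one IUPAC consensus string per individual over an ordered panel.

    ``panel`` is an ordered list of (marker, pos) keys.  Sites absent or
    uncalled for an individual are written as 'N'.
    """
    if len(panel) == 0:
        warnings.warn("empty SNP panel: consensus sequences are empty strings")
    calls = call_table(table, thresholds)
    if calls["individual"].duplicated().any():
        dups = calls.groupby(["individual", "marker", "pos"]).size()
        if (dups > 1).any():
            key = dups[dups > 1].index[0]
            raise ValueError(f"duplicate record for individual/site {key}")
    by_key = {
        (row.individual, row.marker, row.pos): row.iupac
        for row in calls.itertuples(index=False)
    }
    individuals = pd.unique(calls["individual"]) if len(calls) else []
    return {
        ind: "".join(by_key.get((ind, m, p), "N") for m, p in panel)
        for ind in individuals
    }


def consensus_fasta(sequences: Mapping[str, str], path: str) -> None:
    """Write consensus sequences to FASTA (record id = individual id)."""
    records = [
        SeqRecord(Seq(seq), id=ind, description="") for ind, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def assign_taxon(
    table: pd.DataFrame,
    diagnostic_panel: Iterable[tuple[str, int, str, str]],
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Assign taxon/ploidy class from pooled diagnostic read fractions.

    ``diagnostic_panel`` lists (marker, pos, l_base, r_base) for
    species-specific SNPs.  For each individual, reads supporting the L and R
    bases are pooled across panel sites with adequate total coverage; the
    pooled L fraction is matched to the nearest expected dosage among
    0 (RR), 1/3 (RRL), 1/2 (LR), 2/3 (LLR) and 1 (LL).

    Returns a DataFrame with columns individual, l_fraction, taxon,
    dosage_distance, n_sites.  Individuals with no covered diagnostic site
    get taxon 'unassigned' and NaN fractions.
    """
    t = thresholds or CallThresholds()
    panel = {(m, p): (lb, rb) for m, p, lb, rb in diagnostic_panel}
    idx = {b: i for i, b in enumerate(BASES)}
    acc: dict[str, list[float]] = {}
    for row in table.itertuples(index=False):
        key = (row.marker, row.pos)
        if key not in panel:
            continue
        counts = (row.nA, row.nC, row.nG, row.nT)
        if sum(counts) < t.min_total_coverage:
            continue
        l_base, r_base = panel[key]
        nl, nr = counts[idx[l_base]], counts[idx[r_base]]
        if nl + nr == 0:
            continue
        rec = acc.setdefault(row.individual, [0.0, 0.0, 0])
        rec[0] += nl
        rec[1] += nr
        rec[2] += 1

    rows = []
    for ind in pd.unique(table["individual"]):
        if ind in acc:
            nl, nr, n_sites = acc[ind]
            frac = nl / (nl + nr)
            taxon, dist = min(
                ((tx, abs(frac - d)) for tx, d in TAXON_DOSAGE.items()),
                key=lambda td: td[1],
            )
            rows.append((ind, frac, taxon, dist, int(n_sites)))
        else:
            rows.append((ind, np.nan, "unassigned", np.nan, 0))
    return pd.DataFrame(
        rows, columns=["individual", "l_fraction", "taxon", "dosage_distance", "n_sites"]
    )
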