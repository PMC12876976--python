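"""Descriptive statistics and divergence analyses for coding sequences.

Per-CDS length (CDSL), GC content and ambiguous-base fraction (records over
5% N are excluded from analysis), uncorrected nucleotide and amino-acid
p-distances between aligned alleles, flagging of genes whose intraspecific
divergence range exceeds the distribution's 95th percentile (candidate
introgression events), and simple OLS regressions between sequence features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

N_FRACTION_EXCLUSION = 5.0  # percent


@dataclass(frozen=True)
class CdsRecord:
    gene: str
    species: str
    allele: str
    sequence: str
    cdsl: int
    gc_percent: float
    n_frac_percent: float
    excluded: bool


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    gene = parts[0]
    species = parts[1] if len(parts) > 1 else ""
    allele = parts[2] if len(parts) > 2 else ""
    return gene, species, allele


def cds_stats(fasta: str | Iterable) -> pd.DataFrame:
    """Per-record CDS statistics from a FASTA file or SeqRecord iterable.

    Headers may follow the ``gene|species|allele`` convention.  GC percent
    is computed over non-N positions; records whose N fraction exceeds 5%
    are flagged excluded.
    """
    records = SeqIO.parse(fasta, "fasta") if isinstance(fasta, str) else fasta
    rows = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        gene, species, allele = _parse_header(rec.id)
        length = len(seq)
        n_count = seq.count("N")
        denom = length - n_count
        gc = 100.0 * (seq.count("G") + seq.count("C")) / denom if denom else np.nan
        n_frac = 100.0 * n_count / length
        rows.append(
            (gene, species, allele, seq, length, gc, n_frac,
             n_frac > N_FRACTION_EXCLUSION)
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "species", "allele", "sequence", "cdsl",
                 "gc_percent", "n_frac_percent", "excluded"],
    )


def p_distance(aln_a: str, aln_b: str, level: str = "nt") -> float:
    """Uncorrected p-distance (%) between two aligned sequences.

    Gaps and Ns (X at the amino-acid level) are deleted pairwise.  At
    ``level="aa"`` both sequences are translated in frame 1 with the
    standard genetic code first; their lengths must be divisible by 3.
    """
    if len(aln_a) != len(aln_b):
        raise ValueError(f"aligned length mismatch: {len(aln_a)} vs {len(aln_b)}")
    a, b = aln_a.upper(), aln_b.upper()
    if level == "aa":
        if len(a) % 3:
            raise ValueError("length not divisible by 3 for amino-acid distance")
        a = str(Seq(a.replace("-", "N")).translate())
        b = str(Seq(b.replace("-", "N")).translate())
        skip = "X*"
    elif level == "nt":
        skip = "N-"
    else:
        raise ValueError("level must be 'nt' or 'aa'")
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x in skip or y in skip:
            continue
        compared += 1
        mismatches += x != y
    return 100.0 * mismatches / compared if compared else 0.0


def intraspecific_ranges(
    distances: Mapping[str, Sequence[float]]
) -> pd.Series:
    """Per-gene divergence range (max - min of pairwise distances)."""
    return pd.Series(
        {gene: (max(d) - min(d)) if len(d) else 0.0 for gene, d in distances.items()}
    ).sort_index()


def divergence_outliers(ranges: pd.Series, percentile: float = 95.0) -> pd.Series:
    """Flag genes whose divergence range exceeds the given percentile.

    The threshold is the empirical percentile of the ranges themselves; the
    flag is strict (>), so a flat distribution flags nothing.  Flagging is
    invariant to gene ordering.
    """
    threshold = float(np.percentile(ranges.to_numpy(float), percentile))
    flags = ranges > threshold
    return flags.sort_index()


def simple_ols(y: Sequence[float], x: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares of y on x: (R-squared, two-sided slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)
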