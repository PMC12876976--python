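"""Introgression-rate estimation from species-specific SNP frequencies.

In a pure parental population every species-specific SNP sits at its fixed
state (designated-allele frequency 0 or 1).  Any departure of an observed
per-unit frequency from that fixed state measures the frequency of
foreign-species alleles, i.e. introgression.  The per-cell rates are
summarized per SNP (IR_SNP, mean over units), per population unit (IR_POP,
mean over SNPs) and overall (IR_mean +/- SD over all non-missing cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .popfreq import SnpClassification

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntrogressionSummary:
    """Per-SNP, per-unit and overall introgression rates.

    ``ir_sd`` is the population SD (denominator N) over all non-missing
    cells; ``ir_sd_sample`` the N-1 variant, reported alongside.
    """

    cells: pd.DataFrame  # SNPs x units, NaN = missing
    ir_snp: pd.Series
    ir_pop: pd.Series
    ir_mean: float
    ir_sd: float
    ir_sd_sample: float
    n_cells: int


def introgression_cells(
    freq: pd.DataFrame,
    classification: Mapping,
    focal_species: str,
) -> pd.DataFrame:
    """Per-cell introgressed-allele frequencies |f - expected state|.

    ``freq`` is a long table with columns marker, pos, unit, f (NaN allowed);
    ``classification`` maps (marker, pos) to a :class:`SnpClassification`.
    Only species-specific SNPs with a defined expected state for
    ``focal_species`` enter; others are excluded with a warning.
    Returns a SNP x unit matrix with NaN for missing frequencies.
    """
    if focal_species not in ("LL", "RR"):
        raise ValueError("focal_species must be 'LL' or 'RR'")
    rows = []
    skipped = []
    for key, cls in classification.items():
        if cls.category != "species_specific":
            continue
        expected = cls.expected_state(focal_species)
        if expected is None:
            skipped.append(key)
            continue
        sub = freq[(freq["marker"] == key[0]) & (freq["pos"] == key[1])]
        for row in sub.itertuples(index=False):
            rows.append((f"{key[0]}:{key[1]}", row.unit, abs(row.f - expected)))
    if skipped:
        logger.warning(
            "%d species-specific SNPs lack a defined expected state for %s "
            "and were excluded: %s", len(skipped), focal_species, skipped,
        )
    if not rows:
        return pd.DataFrame()
    long = pd.DataFrame(rows, columns=["snp", "unit", "ir"])
    return long.pivot_table(index="snp", columns="unit", values="ir", dropna=False)


def ir_summaries(cells: pd.DataFrame) -> IntrogressionSummary:
    """Row, column and grand means of the introgression cell matrix.

    Missing cells are skipped in every mean; the SD is computed over all
    non-missing cells.
    """
    values = cells.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    if cells.empty or not mask.any():
        raise ValueError("all-missing introgression matrix")
    flat = values[mask]
    return IntrogressionSummary(
        cells=cells,
        ir_snp=cells.mean(axis=1, skipna=True),
        ir_pop=cells.mean(axis=0, skipna=True),
        ir_mean=float(flat.mean()),
        ir_sd=float(flat.std(ddof=0)),
        ir_sd_sample=float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        n_cells=int(flat.size),
    )


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal rounding with ties away from zero, for table comparisons."""
    factor = 10 ** decimals
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


def estimate_from_frequencies(
    freq: pd.DataFrame,
    classification: Mapping,
    focal_species: str,
) -> IntrogressionSummary:
    """Convenience wrapper: cells + summaries in one call."""
    return ir_summaries(introgression_cells(freq, classification, focal_species))
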