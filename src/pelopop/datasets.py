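"""Packaged reference data.

``load_diagnostic_frequencies`` returns the published survey of
*lessonae*-specific nucleotide frequencies at 16 species-specific SNPs
(13 gametogenic genes) across 11 European *P. ridibundus* (RR) and three
*P. lessonae* (LL) population units — the worked example the introgression
estimator is validated against.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .popfreq import SnpClassification

#: RR population units of the survey (all-R and R-E systems).
RR_UNITS = ("Cit", "Zel", "Sur", "Kap", "Bul", "Olt", "Alb", "Dol", "Kos", "Kar", "Leb")
#: LL population units of the survey (L-E systems).
LL_UNITS = ("Trn", "Cet", "Ger")


def load_diagnostic_frequencies() -> pd.DataFrame:
    """Load the packaged frequency survey in long form.

    Columns: marker (gene:snp id), pos (always 1), nucleotide, gene,
    species ('RR' or 'LL'), unit, f (NaN for unsampled cells).
    """
    with resources.files("pelopop.data").joinpath(
        "waterfrog_snp_frequencies.tsv"
    ).open() as fh:
        wide = pd.read_csv(fh, sep="\t", na_values=["n.a."])
    rows = []
    for rec in wide.itertuples(index=False):
        marker = f"{rec.gene}_snp{rec.snp}"
        for species, units in (("RR", RR_UNITS), ("LL", LL_UNITS)):
            for unit in units:
                rows.append(
                    (marker, 1, rec.nucleotide, rec.gene, species, unit,
                     getattr(rec, unit))
                )
    return pd.DataFrame(
        rows, columns=["marker", "pos", "nucleotide", "gene", "species", "unit", "f"]
    )


def diagnostic_classification(
    freq: pd.DataFrame,
) -> dict[tuple[str, int], SnpClassification]:
    """Classify the survey's SNPs from their pooled species means.

    The expected fixed state per species is inferred from the species-wide
    arithmetic mean frequency, which makes the downstream introgression
    estimate invariant to which physical allele a row happens to track.
    """
    from .popfreq import classify_snp

    out = {}
    for (marker, pos), grp in freq.groupby(["marker", "pos"]):
        f_ll = grp.loc[grp["species"] == "LL", "f"].mean()
        f_rr = grp.loc[grp["species"] == "RR", "f"].mean()
        out[(marker, pos)] = classify_snp(
            marker, f_ll, f_rr, designated=str(grp["nucleotide"].iloc[0])
        )
    return out
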