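"""Multilocus genotypes: clustering and discriminant classification.

An individual's multilocus genotype (MLG) is its concatenated IUPAC genotype
string over a panel of SNPs (heterozygotes as ambiguity codes, missing sites
as N).  Identical strings within a genotype class collapse into one MLG with
a multiplicity.  MLGs are compared by an ambiguity-averaged uncorrected
p-distance, clustered by UPGMA, and classified into population systems by a
stepwise linear discriminant analysis on an atomic-number encoding of the
bases (proton counts A=70, T=66, C=58, G=78; ambiguity codes take the mean
of their constituents, so dosage ordering is preserved, e.g. A 70 < R 74 <
G 78).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotyping import ALLELES_BY_IUPAC

logger = logging.getLogger(__name__)

#: proton counts of the four nucleotides
ATOMIC_NUMBER: Mapping[str, float] = {"A": 70.0, "T": 66.0, "C": 58.0, "G": 78.0}


@dataclass(frozen=True)
class MultilocusGenotype:
    mlg_id: str
    sequence: str
    genotype_class: str
    multiplicity: int
    popsys_labels: tuple[str, ...]
    popsys: str  # modal system label among carriers


# ---------------------------------------------------------------------------
# construction


def sequences_from_calls(
    calls: pd.DataFrame, panel: Sequence[tuple[str, int]]
) -> dict[str, str]:
    """Per-individual IUPAC string over an ordered (marker, pos) panel."""
    by_key = {
        (r.individual, r.marker, r.pos): r.iupac
        for r in calls.itertuples(index=False)
    }
    return {
        ind: "".join(by_key.get((ind, m, p), "N") for m, p in panel)
        for ind in pd.unique(calls["individual"])
    }


def build_mlgs(
    calls: pd.DataFrame,
    panel: Sequence[tuple[str, int]],
    metadata: pd.DataFrame,
    diploid_only: bool = True,
) -> list[MultilocusGenotype]:
    """Collapse identical panel strings (within genotype class) into MLGs.

    Each MLG records its multiplicity (number of carrier individuals) and
    the population-system labels of its carriers; ``popsys`` is the modal
    label (alphabetical tie-break).
    """
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    meta = metadata
    if diploid_only and "ploidy" in meta.columns:
        meta = meta[meta["ploidy"] <= 2]
    seqs = sequences_from_calls(calls, panel)
    info = meta.set_index("individual")
    groups: dict[tuple[str, str], list[str]] = {}
    for ind, seq in seqs.items():
        if ind not in info.index:
            continue
        key = (str(info.loc[ind, "taxon"]), seq)
        groups.setdefault(key, []).append(str(info.loc[ind, "popsys"]))
    mlgs = []
    for i, ((taxon, seq), labels) in enumerate(sorted(groups.items())):
        counts = pd.Series(labels).value_counts()
        modal = sorted(counts[counts == counts.max()].index)[0]
        mlgs.append(
            MultilocusGenotype(
                mlg_id=f"MLG{i + 1:03d}",
                sequence=seq,
                genotype_class=taxon,
                multiplicity=len(labels),
                popsys_labels=tuple(sorted(set(labels))),
                popsys=modal,
            )
        )
    return mlgs


def read_mlgs_fasta(
    path: str, labels: Mapping[str, str] | None = None
) -> list[MultilocusGenotype]:
    """Read MLGs from a FASTA file (one record per MLG).

    ``labels`` optionally maps record id to a POPSYS label; otherwise the
    label is parsed from a ``|``-separated header (id|class|popsys) when
    present.
    """
    mlgs = []
    for i, rec in enumerate(SeqIO.parse(path, "fasta")):
        parts = rec.id.split("|")
        taxon = parts[1] if len(parts) > 1 else ""
        popsys = labels.get(rec.id, "") if labels else (
            parts[2] if len(parts) > 2 else ""
        )
        mlgs.append(
            MultilocusGenotype(
                mlg_id=parts[0] or f"MLG{i + 1:03d}",
                sequence=str(rec.seq).upper(),
                genotype_class=taxon,
                multiplicity=1,
                popsys_labels=(popsys,) if popsys else (),
                popsys=popsys,
            )
        )
    return mlgs


# ---------------------------------------------------------------------------
# distances and trees


def ambiguity_pdistance(a: str, b: str) -> float:
    """Uncorrected p-distance with ambiguity codes as average states.

    Identical symbols (including identical ambiguity codes) score 0.  A
    differing pair scores the mean mismatch over the Cartesian product of
    the two codes' resolutions, ``1 - |A ∩ B| / (|A| |B|)``.  Sites where
    either symbol is N (or a gap) are excluded pairwise.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    total = 0.0
    scored = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "N-" or y in "N-":
            continue
        scored += 1
        if x == y:
            continue
        rx, ry = ALLELES_BY_IUPAC[x], ALLELES_BY_IUPAC[y]
        total += 1.0 - len(rx & ry) / (len(rx) * len(ry))
    return total / scored if scored else 0.0


def pdistance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of pairwise ambiguity-averaged p-distances."""
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ambiguity_pdistance(sequences[i], sequences[j])
    return d


def upgma(distance: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """UPGMA tree (average linkage, node height = cluster distance / 2).

    Returns a rooted ultrametric :class:`skbio.TreeNode` with branch
    lengths; serialize with ``str(tree)`` or ``tree.write``.
    """
    distance = np.asarray(distance, dtype=float)
    if np.isnan(distance).any():
        raise ValueError("NaN in distance matrix")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    linkage = _average_linkage(squareform(distance, checks=False))
    nodes: list[TreeNode] = [TreeNode(name=str(lab)) for lab in labels]
    heights = [0.0] * n
    for left, right, dist, _ in linkage:
        height = dist / 2.0
        children = []
        for idx in (int(left), int(right)):
            child = nodes[idx]
            child.length = height - heights[idx]
            children.append(child)
        parent = TreeNode(children=children)
        nodes.append(parent)
        heights.append(height)
    root = nodes[-1]
    root.length = None
    return root


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return (max(depths) - min(depths)) <= tol


# ---------------------------------------------------------------------------
# atomic-number encoding and discriminant analysis


def atomic_encode(sequence: str) -> np.ndarray:
    """Encode an IUPAC string as atomic numbers (NaN marks missing sites).

    Ambiguity codes map to the mean of their constituent values (R ->
    (70+78)/2 = 74); N and gaps map to NaN.
    """
    out = np.empty(len(sequence))
    for i, ch in enumerate(sequence.upper()):
        if ch in "N-":
            out[i] = np.nan
        elif ch in ATOMIC_NUMBER:
            out[i] = ATOMIC_NUMBER[ch]
        elif ch in ALLELES_BY_IUPAC:
            bases = ALLELES_BY_IUPAC[ch]
            out[i] = float(np.mean([ATOMIC_NUMBER[b] for b in bases]))
        else:
            raise ValueError(f"unknown character {ch!r} at position {i}")
    return out


def encode_mlgs(mlgs: Iterable[MultilocusGenotype]) -> tuple[np.ndarray, list[str]]:
    """Stack encoded MLGs into a cases x sites matrix; mean-impute missing.

    Imputation is per site (column mean over non-missing cases); the number
    of imputed cells is logged.
    """
    X = np.vstack([atomic_encode(m.sequence) for m in mlgs])
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("mean-imputing %d missing MLG sites before LDA", n_missing)
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    y = [m.popsys for m in mlgs]
    return X, y


def _wilks_lambda(X: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> float:
    Xs = X[:, list(cols)]
    centered = Xs - Xs.mean(axis=0)
    T = centered.T @ centered
    W = np.zeros_like(T)
    for level in np.unique(y):
        Xc = Xs[y == level]
        c = Xc - Xc.mean(axis=0)
        W += c.T @ c
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return np.nan
    return float(np.exp(logdet_w - logdet_t))


@dataclass
class DiscriminantResult:
    selected: list[int]
    accuracy: float          # resubstitution % correctly classified
    cv_accuracy: float | None
    confusion: pd.DataFrame  # rows: true class, cols: predicted
    model: LinearDiscriminantAnalysis
    entry_f: list[float]


def stepwise_lda(
    X: np.ndarray,
    y: Sequence[str],
    f_enter: float = 4.0,
    max_steps: int = 50,
    cv_folds: int = 5,
) -> DiscriminantResult:
    """Forward stepwise linear discriminant analysis.

    Variables enter one at a time by the partial F computed from the
    one-step change in Wilks' lambda,
    ``F = (lambda_p / lambda_{p+1} - 1) * (n - g - p) / (g - 1)``;
    a variable enters while its F is the largest and at least ``f_enter``,
    up to ``max_steps`` entries.  The final discriminant functions are fitted
    on the selected variables from the pooled within-class covariance;
    reported accuracy is resubstitution (% correctly classified), with a
    stratified k-fold cross-validated accuracy alongside when feasible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    g = len(classes)
    if g < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 cases")
    n = len(y)

    selected: list[int] = []
    entry_f: list[float] = []
    lam_current = 1.0
    while len(selected) < min(max_steps, X.shape[1]):
        p = len(selected)
        df2 = n - g - p
        if df2 <= 0:
            break
        best: tuple[float, int] | None = None
        for j in range(X.shape[1]):
            if j in selected:
                continue
            lam = _wilks_lambda(X, y, selected + [j])
            if not np.isfinite(lam) or lam <= 0:
                continue
            f_stat = (lam_current / lam - 1.0) * df2 / (g - 1)
            if best is None or f_stat > best[0] or (
                f_stat == best[0] and j < best[1]
            ):
                best = (f_stat, j)
        if best is None or best[0] < f_enter:
            break
        selected.append(best[1])
        entry_f.append(best[0])
        lam_current = _wilks_lambda(X, y, selected)

    if not selected:
        raise ValueError(
            f"no variable reached the F-to-enter threshold {f_enter}"
        )
    Xs = X[:, selected]
    # guard: singular pooled covariance (collinear selected variables)
    pooled_rank = np.linalg.matrix_rank(
        np.vstack([Xs[y == c] - Xs[y == c].mean(axis=0) for c in classes])
    )
    if pooled_rank < len(selected):
        raise ValueError(
            f"singular pooled covariance among selected variables {selected}"
        )
    model = LinearDiscriminantAnalysis()
    model.fit(Xs, y)
    pred = model.predict(Xs)
    accuracy = 100.0 * float(np.mean(pred == y))
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    )

    cv_accuracy = None
    folds = min(cv_folds, int(counts.min()))
    if folds >= 2:
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        try:
            scores = cross_val_score(
                LinearDiscriminantAnalysis(), Xs, y,
                cv=StratifiedKFold(n_splits=folds, shuffle=False),
            )
            cv_accuracy = 100.0 * float(scores.mean())
        except ValueError:
            cv_accuracy = None

    return DiscriminantResult(
        selected=selected,
        accuracy=accuracy,
        cv_accuracy=cv_accuracy,
        confusion=confusion,
        model=model,
        entry_f=entry_f,
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


def pairwise_ld(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    taxon: str,
    designated: Mapping[tuple[str, int], str],
    pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> pd.DataFrame:
    """Composite genotypic correlation r per SNP pair within one taxon.

    Unphased diploid genotypes are coded as designated-allele dosage
    (0/1/2); r is the Pearson correlation of dosages over individuals called
    at both SNPs (the Burrows composite-disequilibrium correlation, no
    phasing).  Monomorphic SNPs yield a missing r.
    """
    inds = set(metadata.loc[metadata["taxon"] == taxon, "individual"])
    sub = calls[(calls["status"] == "called") & calls["individual"].isin(inds)]
    dosage: dict[tuple[str, int], pd.Series] = {}
    for key, grp in sub.groupby(["marker", "pos"]):
        des = designated[key]
        d = grp["alleles"].map(
            lambda a: 2 if a == des else (1 if des in a and len(a) == 2 else 0)
        )
        dosage[key] = pd.Series(d.values, index=grp["individual"].values)
    snps = sorted(dosage)
    if pairs is None:
        pairs = [(snps[i], snps[j]) for i in range(len(snps))
                 for j in range(i + 1, len(snps))]
    rows = []
    for s1, s2 in pairs:
        d1, d2 = dosage.get(s1), dosage.get(s2)
        if d1 is None or d2 is None:
            rows.append((s1, s2, np.nan, 0))
            continue
        joined = pd.concat([d1, d2], axis=1, join="inner").dropna()
        n = len(joined)
        a, b = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
        if n < 2 or a.std() == 0 or b.std() == 0:
            rows.append((s1, s2, np.nan, n))
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append((s1, s2, r, n))
    return pd.DataFrame(rows, columns=["snp1", "snp2", "r", "n"])
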