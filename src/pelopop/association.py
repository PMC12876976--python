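"""Association of SNP frequencies with population systems.

Per-unit allele frequencies are tested against the categorical predictor
POPSYS and the geographic covariates latitude and longitude:

* Kruskal-Wallis rank tests on the raw per-unit frequencies, as a
  distribution-free screen;
* logistic regression fitted by weighted least squares on the empirical
  logits, the standard approach for grouped proportions
  (minimum-logit-chi-square / Berkson weighting ``w = n * f * (1 - f)``
  with ``n`` the allele count behind each frequency);
* per-predictor F tests from type III (marginal) sums of squares,
  a goodness-of-fit chi-square on binned fitted logits, and forward
  stepwise selection of significant predictors.

Frequencies of 0 or 1 have infinite logits; they are clamped to
``[f_floor, 1 - f_floor]`` (default 1e-10) before transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

PREDICTORS = ("POPSYS", "LAT", "LON")


@dataclass
class AssociationRecord:
    """Results of one weighted logistic fit for one SNP."""

    predictors: tuple[str, ...]
    coefficients: pd.Series
    model_f: float
    model_p: float
    r2: float       # percent
    r2_adj: float   # percent
    gof_chi2: float
    gof_p: float
    type3: pd.DataFrame  # index: predictor; columns: F, df_num, df_den, p
    n_units: int
    stepwise: bool = False
    fitted_logit: np.ndarray = field(default_factory=lambda: np.array([]))
    fitted_f: np.ndarray = field(default_factory=lambda: np.array([]))


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate input (all observations identical) yields H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    samples = []
    for level in levels:
        sample = values[groups == level]
        if sample.size == 0:
            raise ValueError(f"group {level!r} has no observations")
        samples.append(sample)
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def popsys_medians(values: Sequence[float], groups: Sequence) -> pd.Series:
    """Median frequency per POPSYS level; empty or all-NaN groups -> NaN."""
    df = pd.DataFrame({"f": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    return df.groupby("g")["f"].median()


def _design_matrix(
    data: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build intercept + dummy/covariate design; returns column groups."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["const"]
    groups: dict[str, list[int]] = {}
    for pred in predictors:
        if pred == "POPSYS":
            levels = sorted(pd.unique(data["popsys"]))
            idxs = []
            for level in levels[1:]:  # reference = first level
                cols.append((data["popsys"] == level).to_numpy(float))
                names.append(f"POPSYS[{level}]")
                idxs.append(len(names) - 1)
            groups["POPSYS"] = idxs
        elif pred == "LAT":
            cols.append(data["lat"].to_numpy(float))
            names.append("LAT")
            groups["LAT"] = [len(names) - 1]
        elif pred == "LON":
            cols.append(data["lon"].to_numpy(float))
            names.append("LON")
            groups["LON"] = [len(names) - 1]
        else:
            raise ValueError(f"unknown predictor {pred!r}")
    return np.column_stack(cols), names, groups


def _weighted_fit(y, X, w):
    res = sm.WLS(y, X, weights=w).fit()
    resid = y - X @ res.params
    sse = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - ybar) ** 2))
    return res, sse, sst


def wls_logistic(
    data: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    f_floor: float = 1e-10,
    weights: str = "berkson",
) -> AssociationRecord:
    """Weighted-least-squares logistic regression of grouped frequencies.

    ``data`` needs columns f (frequency), n (allele count) and, per
    requested predictor, popsys / lat / lon.  ``weights`` is ``"berkson"``
    (``n f (1-f)``, the minimum-logit-chi-square weight) or ``"n"``.
    """
    data = data.reset_index(drop=True)
    f = np.clip(data["f"].to_numpy(float), f_floor, 1.0 - f_floor)
    n = data["n"].to_numpy(float)
    y = np.log(f / (1.0 - f))
    if weights == "berkson":
        w = n * f * (1.0 - f)
    elif weights == "n":
        w = n.copy()
    else:
        raise ValueError("weights must be 'berkson' or 'n'")

    X, names, groups = _design_matrix(data, predictors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns): "
            f"check aliased terms among {names[1:]}"
        )
    if "POPSYS" in predictors:
        sizes = data.groupby("popsys").size()
        if (sizes == 1).any():
            import warnings

            warnings.warn(
                "POPSYS level(s) with a single unit: "
                f"{list(sizes[sizes == 1].index)} (F degrees of freedom fragile)"
            )

    res, sse, sst = _weighted_fit(y, X, w)
    n_obs, n_par = X.shape
    df_model, df_resid = n_par - 1, n_obs - n_par
    ssr = sst - sse
    if df_model > 0 and df_resid > 0 and sse > 0:
        model_f = (ssr / df_model) / (sse / df_resid)
        model_p = float(stats.f.sf(model_f, df_model, df_resid))
    else:
        model_f, model_p = np.inf, 0.0
    r2 = 100.0 * (1.0 - sse / sst) if sst > 0 else 100.0
    r2_adj = (
        100.0 * (1.0 - (sse / df_resid) / (sst / (n_obs - 1)))
        if df_resid > 0 and sst > 0
        else r2
    )

    # type III: drop each predictor group, same weights, compare SSE
    t3_rows = []
    for pred in predictors:
        keep = [i for i in range(n_par) if i not in groups[pred]]
        _, sse_r, _ = _weighted_fit(y, X[:, keep], w)
        q = len(groups[pred])
        if df_resid > 0 and sse > 0:
            f_stat = ((sse_r - sse) / q) / (sse / df_resid)
            p_val = float(stats.f.sf(f_stat, q, df_resid))
        else:
            f_stat, p_val = np.inf, 0.0
        t3_rows.append((pred, f_stat, q, df_resid, p_val))
    type3 = pd.DataFrame(
        t3_rows, columns=["predictor", "F", "df_num", "df_den", "p"]
    ).set_index("predictor")

    fitted_logit = X @ res.params
    fitted_f = 1.0 / (1.0 + np.exp(-fitted_logit))
    gof_chi2, gof_p = _gof_chi2(data["f"].to_numpy(float), fitted_f, n,
                                fitted_logit, n_par)

    return AssociationRecord(
        predictors=tuple(predictors),
        coefficients=pd.Series(res.params, index=names),
        model_f=float(model_f),
        model_p=float(model_p),
        r2=float(r2),
        r2_adj=float(r2_adj),
        gof_chi2=gof_chi2,
        gof_p=gof_p,
        type3=type3,
        n_units=n_obs,
        fitted_logit=fitted_logit,
        fitted_f=fitted_f,
    )


def _gof_chi2(
    f_obs: np.ndarray,
    f_fit: np.ndarray,
    n: np.ndarray,
    fitted_logit: np.ndarray,
    n_params: int,
    n_classes: int = 5,
) -> tuple[float, float]:
    """Chi-square comparing observed and fitted counts in fitted-logit bins."""
    n_classes = min(n_classes, len(f_obs))
    order = np.argsort(fitted_logit, kind="stable")
    bins = np.array_split(order, n_classes)
    chi2 = 0.0
    for idx in bins:
        if len(idx) == 0:
            continue
        obs_succ = float(np.sum(n[idx] * f_obs[idx]))
        exp_succ = float(np.sum(n[idx] * f_fit[idx]))
        total = float(np.sum(n[idx]))
        exp_fail = total - exp_succ
        if exp_succ > 0:
            chi2 += (obs_succ - exp_succ) ** 2 / exp_succ
        if exp_fail > 0:
            chi2 += ((total - obs_succ) - exp_fail) ** 2 / exp_fail
    df = max(n_classes - n_params, 1)
    return chi2, float(stats.chi2.sf(chi2, df))


def stepwise_select(
    data: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    alpha: float = 0.05,
    f_floor: float = 1e-10,
    weights: str = "berkson",
) -> AssociationRecord:
    """Forward selection over the predictor set.

    At each round, every remaining candidate is added to the current model
    and its type III F-test p-value recorded; the smallest p enters if
    <= ``alpha`` (ties broken by the fixed predictor order).  Returns the
    final fitted model (intercept-only results when nothing enters) with
    ``stepwise=True``.
    """
    selected: list[str] = []
    remaining = list(predictors)
    while remaining:
        best: tuple[float, int, str] | None = None
        for j, cand in enumerate(remaining):
            trial = selected + [cand]
            rec = wls_logistic(data, trial, f_floor=f_floor, weights=weights)
            p = float(rec.type3.loc[cand, "p"])
            if best is None or (p, j) < (best[0], best[1]):
                best = (p, j, cand)
        if best is None or best[0] > alpha:
            break
        selected.append(best[2])
        remaining.remove(best[2])
    if selected:
        record = wls_logistic(data, selected, f_floor=f_floor, weights=weights)
    else:
        record = _intercept_only(data, f_floor, weights)
    record.stepwise = True
    return record


def _intercept_only(data: pd.DataFrame, f_floor: float, weights: str) -> AssociationRecord:
    f = np.clip(data["f"].to_numpy(float), f_floor, 1.0 - f_floor)
    n = data["n"].to_numpy(float)
    y = np.log(f / (1.0 - f))
    w = n * f * (1.0 - f) if weights == "berkson" else n
    mean = float(np.sum(w * y) / np.sum(w))
    fitted = np.full(len(y), mean)
    return AssociationRecord(
        predictors=(),
        coefficients=pd.Series({"const": mean}),
        model_f=0.0,
        model_p=1.0,
        r2=0.0,
        r2_adj=0.0,
        gof_chi2=np.nan,
        gof_p=np.nan,
        type3=pd.DataFrame(columns=["F", "df_num", "df_den", "p"]),
        n_units=len(y),
        fitted_logit=fitted,
        fitted_f=1.0 / (1.0 + np.exp(-fitted)),
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (reported alongside raw ones, never gating)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def association_scan(
    freq_by_snp: Mapping[str, pd.DataFrame],
    predictors: Sequence[str] = PREDICTORS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full per-SNP battery and tabulate the results.

    ``freq_by_snp`` maps SNP id to a unit-level frame with columns
    f, n, popsys, lat, lon.  Output mirrors the shape of a per-SNP summary
    table: K-W H/p, model F/p, R2s, GOF p, selected predictors, medians.
    """
    rows = []
    for snp, df in freq_by_snp.items():
        h, kw_p = kruskal_wallis(df["f"], df["popsys"])
        full = wls_logistic(df, predictors)
        red = stepwise_select(df, predictors, alpha=alpha)
        med = popsys_medians(df["f"], df["popsys"])
        rows.append({
            "snp": snp,
            "kw_H": h,
            "kw_p": kw_p,
            "model_F": full.model_f,
            "model_p": full.model_p,
            "r2": full.r2,
            "r2_adj": full.r2_adj,
            "gof_p": full.gof_p,
            "popsys_p": float(full.type3.loc["POPSYS", "p"])
            if "POPSYS" in full.type3.index else np.nan,
            "selected": "+".join(red.predictors) if red.predictors else "",
            **{f"median_{k}": v for k, v in med.items()},
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["kw_p_bh"] = benjamini_hochberg(out["kw_p"])
    return out
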