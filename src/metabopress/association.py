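"""Per-feature association of metabolite intensities with blood pressure.

The outcome is the ordinal blood-pressure code (default the 5-level code)
treated as a continuous response in ordinary least squares. The analysis
follows a discovery-validation replication design:

* screening — in the discovery cohort each reduced feature is fit with the
  model ``bp ~ feature + CKD stage + feature:CKD stage``; the interaction
  term absorbs the coupling between metabolite abundance and disease
  severity, and significance is read from the feature main-effect p-value.
  Features below ``alpha`` are re-fit in the validation cohort; a feature
  significant in both cohorts is flagged replicated.
* combined model — replicated features are re-fit on the pooled cohorts,
  adjusting for CKD stage, eGFR, age, weight and BMI (no interaction), and
  the combined p-values are Benjamini-Hochberg adjusted across the
  replicated set.

Also provided: the cumulative adjusted-R-squared trajectory of nested models
(covariates first, then features added in combined-p order) and a midrank
Mann-Whitney ROC AUC for the dichotomized (normal vs high) outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FitResult",
    "ols_fit",
    "bh_adjust",
    "screen_features",
    "combined_fit",
    "cumulative_r2",
    "roc_auc",
    "evaluate_recovery",
    "SCREEN_COVARIATES",
    "COMBINED_COVARIATES",
]

#: screening adjusts for CKD stage only, with a feature x stage interaction
SCREEN_COVARIATES = ("ckd_stage",)
#: the pooled model adds the remaining hypertension risk factors
COMBINED_COVARIATES = ("ckd_stage", "egfr", "age", "weight", "bmi")


@dataclass
class FitResult:
    """Slopes, standard errors and fit statistics of one OLS model."""

    estimate: pd.Series
    stderr: pd.Series
    p: pd.Series
    r2: float
    adj_r2: float
    n: int


def _design(
    data: pd.DataFrame,
    predictors: Sequence[str],
    interaction: tuple[str, str] | None,
) -> pd.DataFrame:
    missing = [c for c in predictors if c not in data.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    X = data.loc[:, list(predictors)].astype(float)
    if interaction is not None:
        a, b = interaction
        if a not in X.columns or b not in X.columns:
            raise ValueError("interaction terms must be among the predictors")
        # the product is formed from mean-centered factors so that the main
        # effects keep their average-association interpretation (and are not
        # collinear with the product of two all-positive columns)
        X[f"{a}:{b}"] = (X[a] - X[a].mean()) * (X[b] - X[b].mean())
    return sm.add_constant(X, has_constant="add")


def ols_fit(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    interaction: tuple[str, str] | None = None,
) -> FitResult:
    """Ordinary least squares of ``outcome`` on ``predictors`` (+ intercept).

    ``interaction=(a, b)`` appends the product column ``a:b``. Standard
    errors use the unbiased residual variance; p-values are two-sided
    t-tests. Raises on rank-deficient designs (naming the collinear columns)
    and on n < predictors + 2.
    """
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not in data")
    X = _design(data, predictors, interaction)
    y = data[outcome].astype(float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples for {p - 1} predictors, got {n}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify offending columns by pivoted QR on the standardized design
        r = np.linalg.qr(X.to_numpy(), mode="r")
        dep = [X.columns[k] for k in range(p) if abs(r[k, k]) < 1e-10 * max(1, abs(r[0, 0]))]
        raise np.linalg.LinAlgError(f"singular design; dependent columns: {dep or list(X.columns)}")
    res = sm.OLS(y, X).fit()
    return FitResult(
        estimate=res.params,
        stderr=res.bse,
        p=res.pvalues,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=n,
    )


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_i = min over j with p_j >= p_i of (m * p_j / rank_j), capped at
    1; monotone in the raw p-values, ties share adjusted values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def _fit_feature(
    data: pd.DataFrame,
    feature: str,
    outcome: str,
    covariates: Sequence[str],
    interaction: bool,
) -> tuple[float, float]:
    inter = (feature, "ckd_stage") if interaction else None
    res = ols_fit(data, outcome, [feature, *covariates], interaction=inter)
    return float(res.estimate[feature]), float(res.p[feature])


def screen_features(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    feature_ids: Sequence[str],
    outcome: str = "bp_code5",
    covariates: Sequence[str] = SCREEN_COVARIATES,
    alpha: float = 0.05,
    interaction: bool = True,
) -> pd.DataFrame:
    """Discovery screen + validation replication for each reduced feature.

    Returns one row per feature with discovery estimate/p, validation
    estimate/p (NaN when not re-fit), and the ``replicated`` flag
    (main-effect p < alpha in BOTH cohorts).
    """
    for f in feature_ids:
        if f not in discovery.columns or f not in validation.columns:
            raise ValueError(f"feature {f!r} missing from a cohort table")
    rows = []
    for f in feature_ids:
        est_d, p_d = _fit_feature(discovery, f, outcome, covariates, interaction)
        est_v, p_v = (np.nan, np.nan)
        if p_d < alpha:
            est_v, p_v = _fit_feature(validation, f, outcome, covariates, interaction)
        rows.append(
            {
                "feature": f,
                "estimate_discovery": est_d,
                "p_discovery": p_d,
                "estimate_validation": est_v,
                "p_validation": p_v,
                "replicated": bool(p_d < alpha and p_v < alpha),
            }
        )
    return pd.DataFrame(rows)


def combined_fit(
    assoc: pd.DataFrame,
    pooled: pd.DataFrame,
    outcome: str = "bp_code5",
    covariates: Sequence[str] = COMBINED_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled-cohort model for the replicated features, with BH correction.

    Adds ``estimate_combined`` / ``p_combined`` (NaN for non-replicated
    features), ``p_adjusted`` (BH across the replicated set), and the two
    significance flags used for headline reporting: combined raw p < alpha
    and BH-adjusted p < alpha.
    """
    out = assoc.copy()
    out["estimate_combined"] = np.nan
    out["p_combined"] = np.nan
    out["p_adjusted"] = np.nan
    mask = out["replicated"].to_numpy(dtype=bool)
    for idx in out.index[mask]:
        f = out.at[idx, "feature"]
        res = ols_fit(pooled, outcome, [f, *covariates])
        out.at[idx, "estimate_combined"] = float(res.estimate[f])
        out.at[idx, "p_combined"] = float(res.p[f])
    if mask.any():
        out.loc[mask, "p_adjusted"] = bh_adjust(out.loc[mask, "p_combined"])
    out["sig_combined_raw"] = out["p_combined"] < alpha
    out["sig_combined_adj"] = out["p_adjusted"] < alpha
    return out


def cumulative_r2(
    pooled: pd.DataFrame,
    ranked_features: Sequence[str],
    outcome: str = "bp_code5",
    covariates: Sequence[str] = COMBINED_COVARIATES,
) -> np.ndarray:
    """Adjusted R-squared of nested models: covariates only, then adding
    ``ranked_features`` (combined-p ascending) one at a time.

    Length is ``1 + len(ranked_features)``.
    """
    trajectory = [ols_fit(pooled, outcome, list(covariates)).adj_r2]
    for k in range(1, len(ranked_features) + 1):
        preds = list(covariates) + list(ranked_features[:k])
        trajectory.append(ols_fit(pooled, outcome, preds).adj_r2)
    return np.asarray(trajectory)


def roc_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    ``labels`` are binary (0 = normal, 1 = high); ties in ``values`` are
    handled by midranks. Raises if only one class is present.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.shape != y.shape:
        raise ValueError("values and labels must have the same length")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    pos = y == classes.max()
    n1 = int(pos.sum())
    n0 = x.size - n1
    from scipy.stats import rankdata

    ranks = rankdata(x, method="average")
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_recovery(
    assoc: pd.DataFrame,
    causal_features: Sequence[str],
    cluster_of: dict[str, str],
) -> dict[str, float]:
    """Cluster-level sensitivity and false-discovery proportion.

    The reducer keeps one representative (pivot) per collinearity cluster, so
    a planted feature counts as recovered if the representative of ITS
    cluster replicates, and a replicated representative is a false discovery
    if its cluster contains no planted feature. ``cluster_of`` maps feature
    IDs to their cluster's pivot (``ClusterSet.cluster_of()``).
    """
    replicated = set(assoc.loc[assoc["replicated"], "feature"])
    causal_pivots = {cluster_of[f] for f in causal_features}
    hits = len(causal_pivots & replicated)
    sensitivity = hits / len(causal_pivots) if causal_pivots else float("nan")
    false = len(replicated - causal_pivots)
    fdp = false / len(replicated) if replicated else 0.0
    return {
        "sensitivity": sensitivity,
        "fdp": fdp,
        "n_replicated": float(len(replicated)),
        "replication_rate": len(replicated) / len(assoc) if len(assoc) else 0.0,
    }
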