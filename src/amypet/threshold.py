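"""Amyloid-positivity cut-offs: ROC derivation, classification, harmonization.

The cut-off for calling a scan amyloid positive is the composite
neocortical ratio (CCTXR) threshold on the empirical HC-vs-AD ROC curve
closest to the ideal corner (0, 1) — the point with sensitivity and
specificity jointly nearest 1. Cut-offs are tracer specific; a cut-off
established for one tracer is mapped onto another tracer's scale through
the fitted linear relation between the tracers' regional mean SUVRs
(dynamic-range compression), e.g. the PIB cut-off 1.42 maps through
y = 1.13 x - 0.28 to 1.32 on the Florbetapir scale.

Positivity is strict: a value exactly at the cut-off is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohortstats import spearman

__all__ = [
    "RocResult",
    "LinearMap",
    "roc_curve",
    "optimal_cutoff",
    "classify_amyloid",
    "rank_roi_discrimination",
    "fit_cross_tracer_line",
    "convert_cutoff",
]


@dataclass
class RocResult:
    thresholds: np.ndarray  # candidate cut-offs ("positive" means score > t)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    positive_label: str = "AD"
    cutoff: float | None = None
    cutoff_sensitivity: float | None = None
    cutoff_specificity: float | None = None


@dataclass(frozen=True)
class LinearMap:
    """Fitted linear relation between two tracers' regional mean SUVRs."""

    slope: float
    intercept: float
    rho: float = float("nan")
    p_value: float = float("nan")
    r_squared: float = float("nan")
    group: str = ""
    n: int = 0


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95 % CI for the AUC via midrank placements."""

    def placements(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # P(b_j < a_i) + 0.5 P(b_j == a_i) for each a_i
        order = np.concatenate([a, b])
        ranks_all = stats.rankdata(order)
        ranks_a = stats.rankdata(a)
        return (ranks_all[: len(a)] - ranks_a) / len(b)

    v10 = placements(pos, neg)
    v01 = 1.0 - placements(neg, pos)
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    se = np.sqrt(s10 / len(pos) + s01 / len(neg))
    z = stats.norm.ppf(0.975)
    return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))


def _bootstrap_ci(
    pos: np.ndarray, neg: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, len(pos))
        n = rng.choice(neg, len(neg))
        aucs[i] = _auc_mann_whitney(p, n)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_curve(
    scores,
    labels,
    positive_label: str = "AD",
    ci_method: str = "delong",
    seed: int = 0,
) -> RocResult:
    """Empirical ROC of ``scores`` for separating ``positive_label`` from the rest.

    The threshold grid is the midpoints between adjacent distinct pooled
    scores plus -inf/+inf sentinels; a subject is called positive when its
    score is strictly above the threshold. The AUC is the Mann-Whitney
    statistic with ties counted 1/2 (identical to the trapezoid over the
    empirical curve); the 95 % CI uses DeLong by default, bootstrap
    percentile via ``ci_method="bootstrap"``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive_label
    pos, neg = scores[is_pos], scores[~is_pos]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    auc = _auc_mann_whitney(pos, neg)
    if ci_method == "delong":
        ci = _delong_ci(pos, neg, auc)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci(pos, neg, seed=seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(thresholds, sens, spec, auc, ci, positive_label)


def optimal_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Threshold closest to the ideal corner (0, 1) in ROC space.

    Minimizes sqrt((1-sens)^2 + (1-spec)^2); distance ties prefer higher
    sensitivity, then the lower threshold. For perfectly separated classes
    this lands on the midpoint of the separating gap with sens = spec = 1.
    The result is also written back onto ``roc``.
    """
    d2 = (1 - roc.sensitivity) ** 2 + (1 - roc.specificity) ** 2
    # lexicographic: distance, then -sensitivity, then threshold
    order = np.lexsort((roc.thresholds, -roc.sensitivity, np.round(d2, 12)))
    i = order[0]
    roc.cutoff = float(roc.thresholds[i])
    roc.cutoff_sensitivity = float(roc.sensitivity[i])
    roc.cutoff_specificity = float(roc.specificity[i])
    return roc.cutoff, roc.cutoff_sensitivity, roc.cutoff_specificity


def classify_amyloid(
    values,
    cutoff: float,
    strata: Sequence | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag amyloid positivity (value strictly above ``cutoff``) and count by stratum.

    Returns the boolean flags and a table of n, positive count and positive
    percentage, overall or per stratum when ``strata`` labels are given.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    values = np.asarray(values, dtype=float)
    flags = values > cutoff
    if strata is None:
        strata = np.repeat("all", len(values))
    df = pd.DataFrame({"stratum": np.asarray(strata), "positive": flags})
    counts = df.groupby("stratum", sort=False).agg(
        n=("positive", "size"), n_positive=("positive", "sum")
    )
    counts["pct_positive"] = 100.0 * counts["n_positive"] / counts["n"]
    return flags, counts.reset_index()


def rank_roi_discrimination(
    scores_a: pd.DataFrame,
    labels,
    scores_b: pd.DataFrame | None = None,
    positive_label: str = "AD",
) -> pd.DataFrame:
    """Rank ROIs by HC-vs-AD AUC; optionally report rank shifts under a second tracer.

    ``scores_a``/``scores_b`` hold one column per ROI. The table is sorted
    by descending tracer-A AUC (ties broken by ROI name); ``rank_shift``
    is tracer-A rank minus tracer-B rank (positive = the ROI ranks better
    under tracer B).
    """
    if scores_a.shape[1] < 2:
        raise ValueError("need at least 2 ROIs")
    rows = []
    for roi in scores_a.columns:
        r = roc_curve(scores_a[roi].to_numpy(), labels, positive_label)
        rows.append({"roi": roi, "auc": r.auc, "ci_low": r.auc_ci[0],
                     "ci_high": r.auc_ci[1]})
    table = pd.DataFrame(rows).sort_values(
        ["auc", "roi"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if scores_b is not None:
        if set(scores_b.columns) != set(scores_a.columns):
            raise ValueError("both tracers must cover the same ROI set")
        aucs_b = {
            roi: roc_curve(scores_b[roi].to_numpy(), labels, positive_label).auc
            for roi in scores_b.columns
        }
        b = pd.Series(aucs_b).sort_values(ascending=False, kind="mergesort")
        rank_b = {roi: i + 1 for i, roi in enumerate(b.index)}
        table["auc_b"] = table["roi"].map(aucs_b)
        table["rank_shift"] = table["rank"] - table["roi"].map(rank_b)
    return table


def fit_cross_tracer_line(
    means_a: Mapping[str, float] | pd.Series,
    means_b: Mapping[str, float] | pd.Series,
    group: str = "",
) -> LinearMap:
    """Fit tracer-B regional means on tracer-A means: OLS line + Spearman rho + R^2.

    Both inputs map the same ROI set to that tracer's group-mean SUVR. This
    is the ROI-mean-level relation (n = number of ROIs), not a
    subject-level fit.
    """
    a = pd.Series(means_a).sort_index()
    b = pd.Series(means_b).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("ROI sets differ between tracers")
    if len(a) < 3:
        raise ValueError("need at least 3 ROIs")
    x = a.to_numpy(float)
    y = b.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in tracer-A means")
    fit = stats.linregress(x, y)
    rho, p = spearman(x, y)
    return LinearMap(
        slope=float(fit.slope), intercept=float(fit.intercept), rho=rho,
        p_value=p, r_squared=float(fit.rvalue**2), group=group, n=len(a),
    )


def convert_cutoff(mapping: LinearMap, cutoff: float) -> tuple[float, float]:
    """Carry a cut-off across tracers: slope * cutoff + intercept.

    Returns (full precision, two-decimal display value, half-even rounding).
    """
    exact = mapping.slope * cutoff + mapping.intercept
    return float(exact), float(round(exact, 2))
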