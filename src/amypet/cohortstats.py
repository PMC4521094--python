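"""Cohort construction and group-level inference.

Covers the statistical toolkit used around the imaging measures: seeded
nearest-neighbour cohort matching, two-way ANOVA (age group x ApoE4 carrier
status) with Type III sums of squares, Pearson chi-squared tests, Spearman
rank correlation (exact permutation null for small n), Cohen's kappa,
percent agreement, and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchResult",
    "AnovaTable",
    "match_cohorts",
    "two_way_anova",
    "chi_squared_test",
    "spearman",
    "cohens_kappa",
    "percent_agreement",
    "cohens_d",
]


# ---------------------------------------------------------------------------
# Matching


@dataclass
class MatchResult:
    """Ids of the matched pool subjects plus balance diagnostics."""

    selected_ids: list
    pairs: pd.DataFrame  # reference_id, pool_id, distance
    balance: pd.DataFrame  # per nearest-var standardized mean difference
    seed: int


def match_cohorts(
    pool: pd.DataFrame,
    reference: pd.DataFrame,
    exact_vars: Sequence[str] = ("sex",),
    nearest_vars: Sequence[str] = ("age", "mmse"),
    seed: int = 0,
    id_col: str = "subject_id",
) -> MatchResult:
    """1:1 greedy nearest-neighbour matching of ``pool`` subjects to ``reference``.

    Reference subjects are visited in seeded random order; each draws the
    closest unused pool subject agreeing exactly on ``exact_vars`` and
    minimizing the scaled (pool-SD standardized) Euclidean distance on
    ``nearest_vars``. Without replacement; a stratum that runs out of pool
    candidates raises with the stratum named.
    """
    if len(pool) < len(reference):
        raise ValueError("pool smaller than reference; 1:1 matching impossible")
    rng = np.random.default_rng(seed)
    scales = {
        v: (pool[v].std(ddof=1) or 1.0) for v in nearest_vars
    }
    pool_x = np.column_stack([pool[v].to_numpy(float) / scales[v] for v in nearest_vars])
    ref_x = np.column_stack(
        [reference[v].to_numpy(float) / scales[v] for v in nearest_vars]
    )
    pool_keys = list(zip(*(pool[v] for v in exact_vars))) if exact_vars else [()] * len(pool)
    ref_keys = list(zip(*(reference[v] for v in exact_vars))) if exact_vars else [()] * len(reference)
    used = np.zeros(len(pool), dtype=bool)
    order = rng.permutation(len(reference))
    rows = []
    for i in order:
        key = ref_keys[i]
        cand = np.flatnonzero(
            ~used & np.fromiter((k == key for k in pool_keys), bool, len(pool))
        )
        if cand.size == 0:
            raise ValueError(
                f"pool exhausted for stratum {dict(zip(exact_vars, key))}"
            )
        d = np.linalg.norm(pool_x[cand] - ref_x[i], axis=1)
        j = cand[np.argmin(d)]
        used[j] = True
        rows.append(
            {"reference_id": reference[id_col].iloc[i],
             "pool_id": pool[id_col].iloc[j], "distance": float(d.min())}
        )
    pairs = pd.DataFrame(rows)
    matched = pool[used]
    bal = []
    for v in nearest_vars:
        sd = np.sqrt((matched[v].var(ddof=1) + reference[v].var(ddof=1)) / 2.0)
        smd = (matched[v].mean() - reference[v].mean()) / sd if sd > 0 else 0.0
        bal.append({"variable": v, "smd": float(smd)})
    return MatchResult(matched[id_col].tolist(), pairs, pd.DataFrame(bal), seed)


# ---------------------------------------------------------------------------
# Two-way ANOVA


@dataclass
class AnovaTable:
    """Type III two-way ANOVA results plus cell summaries."""

    effects: pd.DataFrame  # index: factor names + interaction; F, df_num, df_den, p
    cell_means: pd.DataFrame  # per cell: n, mean, sd
    interaction_estimable: bool = True


def two_way_anova(
    response,
    factor_a,
    factor_b,
    names: tuple[str, str] = ("age_group", "apoe4"),
) -> AnovaTable:
    """2x2 ANOVA with Type III sums of squares (sum-to-zero contrasts).

    Type III SS keep main effects interpretable in unbalanced designs — the
    situation of observational strata with unequal carrier counts. An empty
    cell makes the interaction inestimable; main effects then come from the
    additive model, with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(response, dtype=float)
    a = np.asarray(factor_a).astype(str)
    b = np.asarray(factor_b).astype(str)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("response and factors must have equal length")
    df = pd.DataFrame({"y": y, "A": a, "B": b})
    cells = df.groupby(["A", "B"])["y"].agg(["size", "mean", "std"])
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("both factors need at least two observed levels")
    n_nonempty = (cells["size"] > 0).sum()
    if n_nonempty < 3 or (cells["size"] >= 2).sum() < 3:
        raise ValueError("need >=2 observations in >=3 cells")
    full_cells = len(np.unique(a)) * len(np.unique(b))
    estimable = n_nonempty == full_cells
    formula = (
        "y ~ C(A, Sum) * C(B, Sum)" if estimable else "y ~ C(A, Sum) + C(B, Sum)"
    )
    if not estimable:
        warnings.warn(
            "empty cell: interaction inestimable, main effects from additive model"
        )
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(fit, typ=3)
    rename = {"C(A, Sum)": names[0], "C(B, Sum)": names[1],
              "C(A, Sum):C(B, Sum)": f"{names[0]}:{names[1]}"}
    eff = table.rename(index=rename).loc[list(rename.values())[: 3 if estimable else 2]]
    out = pd.DataFrame({
        "F": eff["F"], "df_num": eff["df"].astype(int),
        "df_den": int(fit.df_resid), "p": eff["PR(>F)"],
    })
    cm = cells.rename(columns={"size": "n", "std": "sd"}).reset_index()
    cm.columns = [names[0], names[1], "n", "mean", "sd"]
    return AnovaTable(out, cm, estimable)


# ---------------------------------------------------------------------------
# Contingency / correlation


def chi_squared_test(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared on a contingency table of counts.

    No continuity correction by default; set ``yates=True`` for the
    corrected 2x2 statistic.
    """
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=yates)
    return float(stat), int(dof), float(p)


@lru_cache(maxsize=None)
def _spearman_s_distribution(n: int) -> np.ndarray:
    """Exact permutation distribution of S = sum d_i^2 for untied ranks.

    Counts over all n! permutations by dynamic programming over subsets of
    already-used ranks; feasible through n = 12.
    """
    smax = n * (n * n - 1) // 3
    counts = [None] * (1 << n)
    counts[0] = np.zeros(smax + 1, dtype=float)
    counts[0][0] = 1.0
    masks_by_pop: list[list[int]] = [[] for _ in range(n + 1)]
    for m in range(1 << n):
        masks_by_pop[bin(m).count("1")].append(m)
    for pop in range(n):
        for m in masks_by_pop[pop]:
            src = counts[m]
            if src is None:
                continue
            i = pop  # next position to fill
            for j in range(n):
                if m & (1 << j):
                    continue
                d2 = (i - j) * (i - j)
                tgt = m | (1 << j)
                if counts[tgt] is None:
                    counts[tgt] = np.zeros(smax + 1, dtype=float)
                if d2 == 0:
                    counts[tgt] += src
                else:
                    counts[tgt][d2:] += src[:-d2]
            counts[m] = None  # free
    return counts[(1 << n) - 1]


def spearman(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    For n <= ``exact_max_n`` and untied data the two-sided p comes from the
    exact permutation distribution of the rank-discrepancy statistic
    S = sum d_i^2; otherwise from the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tied = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if n <= exact_max_n and not tied:
        s = int(round(np.sum((rx - ry) ** 2)))
        dist = _spearman_s_distribution(n)
        total = dist.sum()
        smax = n * (n * n - 1) // 3
        s_tail = min(s, smax - s)  # |rho| >= |rho_obs| <=> S in either tail
        p = (dist[: s_tail + 1].sum() + dist[smax - s_tail:].sum()) / total
        p = float(min(1.0, p))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# Agreement and effect size


def cohens_kappa(rater1, rater2) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e uses the product of marginal label frequencies.
    Returns NaN (with a warning) when p_e = 1, i.e. both raters constant.
    """
    r1 = np.asarray(rater1)
    r2 = np.asarray(rater2)
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) == 0:
        raise ValueError("raters must be equal-length non-empty vectors")
    cats = np.union1d(r1, r2)
    if len(cats) < 2:
        warnings.warn("fewer than 2 categories observed: kappa undefined")
        return float("nan")
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(r1, r2, labels=cats))


def percent_agreement(rater1, rater2) -> float:
    """Fraction of identically labeled items."""
    r1 = np.asarray(rater1)
    r2 = np.asarray(rater2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("raters must be equal-length vectors")
    if len(r1) == 0:
        raise ValueError("empty input")
    return float(np.mean(r1 == r2))


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD (n-1 weighting)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        warnings.warn("zero pooled SD: d undefined")
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)
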