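"""Gaussian-mixture decomposition of composite amyloid-score distributions.

The composite neocortical ratio (CCTXR) of an age-stratified cohort is
either unimodal (one Gaussian) or a superposition of a low- and a
high-amyloid subpopulation (two Gaussians). This module tests a sample
against normality (one-sample Kolmogorov-Smirnov statistic with a
Lilliefors-style Monte-Carlo null, since location and scale are estimated
from the data), fits 1- and 2-component Gaussian mixtures by
expectation-maximisation, selects between them by BIC, hard-assigns
subjects to the low/high-amyloid subpopulation, and compares the resulting
subgroups on demographic covariates.

EM details: best of ``n_restarts`` starts (deterministic median split,
quantile split, then random pairs of observations as seeds); convergence
when the log-likelihood gain drops below 1e-8 or after 500 iterations;
component variances are floored at 1e-4 x sample variance to keep
singletons from collapsing; components are reported in ascending mean
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixtureFit",
    "ModelChoice",
    "test_normality",
    "fit_gaussian_mixture",
    "select_model",
    "assign_components",
    "characterize_subgroups",
]

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Normality


def _ks_statistic_estimated(x: np.ndarray) -> float:
    """max |ECDF - Phi((x-m)/s)| with m, s the sample estimates."""
    x = np.sort(x)
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def test_normality(
    values, n_mc: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean and SD.

    The naive KS p-value is far too conservative once the null parameters
    are estimated from the same sample; the p returned here is the
    Lilliefors-corrected one, from a seeded Monte-Carlo null of ``n_mc``
    standard-normal samples of the same size (each re-standardized by its
    own estimates). Returns ``(D, p)``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample")
    d_obs = _ks_statistic_estimated(x)
    rng = np.random.default_rng(seed)
    i = np.arange(1, n + 1)
    exceed = 0
    chunk = max(1, min(n_mc, 5_000_000 // max(n, 1)))
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        sims = rng.standard_normal((m, n))
        sims.sort(axis=1)
        mu = sims.mean(axis=1, keepdims=True)
        sd = sims.std(axis=1, ddof=1, keepdims=True)
        cdf = stats.norm.cdf((sims - mu) / sd)
        d_plus = (i / n - cdf).max(axis=1)
        d_minus = (cdf - (i - 1) / n).max(axis=1)
        exceed += int(np.sum(np.maximum(d_plus, d_minus) >= d_obs))
        done += m
    p = (exceed + 1) / (n_mc + 1)
    return d_obs, float(p)


# ---------------------------------------------------------------------------
# EM fitting


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    responsibilities: np.ndarray  # (n, k)
    n_iterations: int
    converged: bool
    seed: int
    n: int
    ll_trajectory: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_parameters(self) -> int:
        return 3 * self.k - 1  # k means + k sds + (k-1) free weights


def _loglik(x: np.ndarray, w, mu, sd) -> tuple[float, np.ndarray]:
    logp = (
        np.log(w)[None, :]
        - np.log(sd)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
    )
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    return float(lse.sum()), np.exp(logp - lse[:, None])


def _em_once(
    x: np.ndarray, mu0, sd0, w0, var_floor: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, int, bool, list]:
    w = np.asarray(w0, dtype=float)
    mu = np.asarray(mu0, dtype=float)
    sd = np.maximum(np.asarray(sd0, dtype=float), np.sqrt(var_floor))
    ll_prev = -np.inf
    traj: list[float] = []
    converged = False
    resp = None
    for it in range(1, max_iter + 1):
        ll, resp = _loglik(x, w, mu, sd)
        traj.append(ll)
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, var_floor))
    ll, resp = _loglik(x, w, mu, sd)
    return w, mu, sd, ll, resp, it, converged, traj


def fit_gaussian_mixture(
    values,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture fit (k in {1, 2}) by EM.

    k = 1 is closed form (sample mean, ML standard deviation). k = 2 runs
    EM from ``n_restarts`` initializations and keeps the best converged
    log-likelihood. Components come back sorted by ascending mean. A
    constant sample is refused for k = 2 and returns a degenerate
    (variance-floored) fit with a warning for k = 1.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if n <= 3 * k:
        raise ValueError(f"need more than {3 * k} observations for k={k}")
    sample_var = float(x.var())
    var_floor = max(1e-4 * sample_var, 1e-12)
    if sample_var == 0:
        if k == 2:
            raise ValueError("all values identical: 2-component fit refused")
        warnings.warn("all values identical: degenerate single-component fit")
    if k == 1:
        mu = np.array([x.mean()])
        sd = np.array([max(np.sqrt(sample_var), np.sqrt(var_floor))])
        w = np.array([1.0])
        ll, resp = _loglik(x, w, mu, sd)
        bic = -2.0 * ll + 2 * np.log(n)
        return MixtureFit(1, w, mu, sd, ll, bic, resp, 0, True, seed, n,
                          np.array([ll]))

    rng = np.random.default_rng(seed)
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    inits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    # deterministic: median split
    if len(lo) and len(hi):
        inits.append((
            np.array([lo.mean(), hi.mean()]),
            np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)]),
            np.array([len(lo) / n, len(hi) / n]),
        ))
    # deterministic: quantile seeds
    q1, q3 = np.quantile(x, [0.25, 0.75])
    inits.append((
        np.array([q1, q3]),
        np.full(2, max(x.std() / 2, 1e-3)),
        np.array([0.5, 0.5]),
    ))
    while len(inits) < n_restarts:
        pair = np.sort(rng.choice(x, size=2, replace=False))
        w0 = rng.uniform(0.15, 0.85)
        inits.append((
            pair.astype(float),
            np.full(2, max(x.std() * rng.uniform(0.3, 1.0), 1e-3)),
            np.array([w0, 1 - w0]),
        ))

    best = None
    for mu0, sd0, w0 in inits[:n_restarts]:
        res = _em_once(x, mu0, sd0, w0, var_floor, tol, max_iter)
        if best is None or res[3] > best[3]:
            best = res
    w, mu, sd, ll, resp, n_iter, converged, traj = best  # type: ignore[misc]
    order = np.argsort(mu)
    w, mu, sd, resp = w[order], mu[order], sd[order], resp[:, order]
    bic = -2.0 * ll + 5 * np.log(n)
    return MixtureFit(2, w, mu, sd, ll, bic, resp, n_iter, converged, seed, n,
                      np.asarray(traj))


@dataclass
class ModelChoice:
    k: int
    delta_bic: float  # BIC(k=2) - BIC(k=1); negative favours two components
    fit1: MixtureFit
    fit2: MixtureFit

    @property
    def chosen(self) -> MixtureFit:
        return self.fit2 if self.k == 2 else self.fit1


def select_model(fit1: MixtureFit, fit2: MixtureFit) -> ModelChoice:
    """Pick the mixture order with lower BIC; ties go to the smaller model."""
    if fit1.n != fit2.n:
        raise ValueError("fits must come from the same data")
    delta = fit2.bic - fit1.bic
    k = 2 if delta < 0 else 1
    return ModelChoice(k, float(delta), fit1, fit2)


def assign_components(fit: MixtureFit) -> np.ndarray:
    """Hard low/high-amyloid labels (0 = low, 1 = high) from responsibilities.

    Responsibility ties go to the high component.
    """
    if fit.k != 2:
        raise ValueError("component assignment requires a 2-component fit")
    return (fit.responsibilities[:, 1] >= fit.responsibilities[:, 0]).astype(int)


def characterize_subgroups(
    labels,
    cohort: pd.DataFrame,
    categorical: Sequence[str] = ("apoe4", "sex"),
    continuous: Sequence[str] = ("age", "education", "mmse"),
) -> pd.DataFrame:
    """Compare low- vs high-amyloid subgroups on demographic covariates.

    Categorical covariates get a Pearson chi-squared test on the 2 x L
    contingency table; continuous ones a two-sample t test. Subgroups of
    size < 2 get summaries only (tests suppressed, p = NaN).
    """
    from .cohortstats import chi_squared_test

    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels and cohort length mismatch")
    low = cohort[labels == 0]
    high = cohort[labels == 1]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both subgroups must be non-empty")
    testable = len(low) >= 2 and len(high) >= 2
    rows = []
    for var in categorical:
        tab = pd.crosstab(labels, cohort[var])
        if var == "apoe4" or cohort[var].dtype == bool:
            frac_l = float(np.mean(low[var].astype(bool)))
            frac_h = float(np.mean(high[var].astype(bool)))
            summary_l, summary_h = f"{frac_l:.0%}", f"{frac_h:.0%}"
        else:
            summary_l = "/".join(str(v) for v in tab.iloc[0])
            summary_h = "/".join(str(v) for v in tab.iloc[1])
        p = stat = float("nan")
        if testable and tab.shape[1] >= 2 and (tab.to_numpy().sum(axis=0) > 0).all():
            stat, _, p = chi_squared_test(tab.to_numpy())
        rows.append({"covariate": var, "kind": "categorical", "low": summary_l,
                     "high": summary_h, "statistic": stat, "p": p})
    for var in continuous:
        p = stat = float("nan")
        if testable:
            t = stats.ttest_ind(low[var], high[var])
            stat, p = float(t.statistic), float(t.pvalue)
        rows.append({
            "covariate": var, "kind": "continuous",
            "low": f"{low[var].mean():.2f}±{low[var].std(ddof=1):.2f}",
            "high": f"{high[var].mean():.2f}±{high[var].std(ddof=1):.2f}",
            "statistic": stat, "p": p,
        })
    return pd.DataFrame(rows)
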