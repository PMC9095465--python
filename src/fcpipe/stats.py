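"""Cohort-level inference.

Kruskal–Wallis and chi-square tests for demographics, ANCOVA adjusting
for age and sex (optionally mean framewise displacement) with pairwise
post-hoc contrasts and Cohen's d, partial correlation, and
Benjamini–Hochberg FDR control.

Post-hoc p-values are unadjusted pairwise contrasts inside the full
ANCOVA model; Cohen's d is computed on covariate-residualized values so
the effect size matches the adjusted comparison.  Kruskal–Wallis post-hocs
are pairwise Mann–Whitney tests with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AncovaResult",
    "PartialCorrelationResult",
    "kruskal_wallis",
    "kruskal_wallis_posthoc",
    "chi_square_independence",
    "ancova_group_effect",
    "partial_correlation",
    "fdr_bh",
    "cohens_d",
]


@dataclass(frozen=True)
class AncovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_residual: int
    group_means: dict
    posthoc: list  # (pair, p_value, cohens_d)


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p_value: float
    df: int


def kruskal_wallis(samples: Sequence[np.ndarray]) -> tuple[float, float]:
    """Rank-based Kruskal–Wallis H with tie correction; chi-square p.

    Degenerate input (every value identical) returns (0, 1).
    """
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def kruskal_wallis_posthoc(
    samples: Sequence[np.ndarray], names: Sequence[str], q: float = 0.05
) -> list:
    """Pairwise Mann–Whitney tests with BH correction across the pairs."""
    pairs, pvals = [], []
    for (i, a), (j, b) in combinations(enumerate(samples), 2):
        a, b = np.asarray(a, float), np.asarray(b, float)
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p = 1.0
        else:
            _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        pairs.append((names[i], names[j]))
        pvals.append(float(p))
    reject, p_adj = fdr_bh(np.array(pvals), q)
    return [
        {"pair": pair, "p_value": p, "q_value": float(pa), "reject": bool(r)}
        for pair, p, pa, r in zip(pairs, pvals, p_adj, reject)
    ]


def chi_square_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of independence, (r-1)(c-1) df, no Yates."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a nonnegative 2-D count matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero row or column margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def _design(group: np.ndarray, covariates: np.ndarray | None):
    """Full and reduced design matrices; group coded by treatment dummies."""
    group = np.asarray(group)
    levels = list(dict.fromkeys(group))
    n = len(group)
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    if covariates is None or np.size(covariates) == 0:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float).reshape(n, -1)
    ones = np.ones((n, 1))
    x_full = np.hstack([ones, dummies, covariates])
    x_red = np.hstack([ones, covariates])
    return levels, x_full, x_red, dummies.shape[1]


def _ols(y: np.ndarray, x: np.ndarray):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid), resid


def ancova_group_effect(
    y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> AncovaResult:
    """Group F-test in a linear model with covariates, plus post-hocs.

    The F statistic compares the full model (group dummies + covariates)
    against the covariates-only model.  Post-hoc pairwise p-values come
    from contrast t-tests in the full model; Cohen's d is computed on
    covariate-residualized y for each pair.
    """
    y = np.asarray(y, dtype=float)
    levels, x_full, x_red, df_b = _design(group, covariates)
    n = len(y)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    p_full = x_full.shape[1]
    if n <= p_full:
        raise ValueError("too few observations for the model")
    rank = np.linalg.matrix_rank(x_full)
    if rank < p_full:
        raise ValueError(
            "rank-deficient design: a covariate is collinear with the "
            "intercept or group dummies"
        )

    degenerate = np.ptp(y) == 0  # constant response: no effect by definition
    if degenerate:
        group_arr = np.asarray(group)
        return AncovaResult(
            f_stat=0.0,
            p_value=1.0,
            df_between=df_b,
            df_residual=n - p_full,
            group_means={g: float(y[group_arr == g].mean()) for g in levels},
            posthoc=[
                ((levels[gi], levels[gj]), 1.0, 0.0)
                for gi, gj in combinations(range(len(levels)), 2)
            ],
        )

    beta_f, ssr_f, resid_f = _ols(y, x_full)
    _, ssr_r, _ = _ols(y, x_red)
    df_r = n - p_full
    num = max(ssr_r - ssr_f, 0.0) / df_b
    den = ssr_f / df_r
    if den <= 1e-300:
        f = 0.0 if num <= 1e-300 else np.inf
    else:
        f = num / den
    p = float(sps.f.sf(f, df_b, df_r)) if np.isfinite(f) else 0.0

    # covariance of coefficients for contrast tests
    xtx_inv = np.linalg.inv(x_full.T @ x_full)
    sigma2 = ssr_f / df_r if df_r > 0 else 0.0
    group_arr = np.asarray(group)

    # residualize y on covariates only (with intercept) for effect sizes
    _, _, resid_y = _ols(y, x_red)

    posthoc = []
    for gi, gj in combinations(range(len(levels)), 2):
        c = np.zeros(p_full)
        if gi > 0:
            c[gi] = 1.0  # dummy columns start at index 1
        if gj > 0:
            c[gj] = -1.0
        est = float(c @ beta_f)
        se = float(np.sqrt(max(sigma2 * (c @ xtx_inv @ c), 0.0)))
        if se <= 1e-300:
            t_pair = 0.0 if abs(est) <= 1e-300 else np.inf
            p_pair = 1.0 if t_pair == 0.0 else 0.0
        else:
            t_pair = est / se
            p_pair = float(2.0 * sps.t.sf(abs(t_pair), df_r))
        a = resid_y[group_arr == levels[gi]]
        b = resid_y[group_arr == levels[gj]]
        try:
            d = cohens_d(a, b)
        except ValueError:
            d = 0.0  # both samples constant and equal after residualization
        posthoc.append(((levels[gi], levels[gj]), p_pair, d))

    group_means = {g: float(y[group_arr == g].mean()) for g in levels}
    return AncovaResult(
        f_stat=float(f),
        p_value=p,
        df_between=df_b,
        df_residual=df_r,
        group_means=group_means,
        posthoc=posthoc,
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> PartialCorrelationResult:
    """Correlation of x and y residuals after regressing out covariates.

    p-value from the t distribution with df = n - 2 - (#covariates).
    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or np.size(covariates) == 0:
        z = np.ones((n, 1))
        n_cov = 0
    else:
        cov = np.asarray(covariates, dtype=float).reshape(n, -1)
        z = np.hstack([np.ones((n, 1)), cov])
        n_cov = cov.shape[1]
    if n <= n_cov + 3:
        raise ValueError("too few observations for partial correlation")
    _, _, rx = _ols(x, z)
    _, _, ry = _ols(y, z)
    # residual variation below numerical noise relative to the input scale
    if (
        rx.std() <= 1e-10 * max(1.0, float(np.std(x)))
        or ry.std() <= 1e-10 * max(1.0, float(np.std(y)))
    ):
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - n_cov
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p_value=p, df=df)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (reject mask, adjusted q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean_a - mean_b) / pooled sd, pooled with n_a + n_b - 2 df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    na, nb = len(a), len(b)
    ssa = ((a - a.mean()) ** 2).sum()
    ssb = ((b - b.mean()) ** 2).sum()
    pooled = np.sqrt((ssa + ssb) / (na + nb - 2))
    if pooled <= 1e-300:
        raise ValueError("zero pooled standard deviation; d undefined")
    return float((a.mean() - b.mean()) / pooled)
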