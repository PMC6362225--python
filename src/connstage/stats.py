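"""Statistical toolbox for covariate-adjusted cohort comparisons.

Contents: least-squares covariate residualisation, ANCOVA group effects
with Cohen's d on covariate-adjusted residuals, the Jonckheere-Terpstra
(JT) test for ordered alternatives (exact by complete enumeration on
small problems, tie-corrected normal approximation otherwise),
Benjamini-Hochberg FDR, Pearson correlation, chi-square contingency and
one-way ANOVA (raw samples or (n, mean, sd) summaries), and logistic
models of cognitive-domain impairment.

Conventions, fixed package-wide:

* Cohen's d = (mean(first) - mean(second)) / pooled SD with
  (n_a - 1, n_b - 1) weighting, computed on residuals from the
  covariate-only model (two-step adjustment).
* Categorical covariates are 0/1 indicators; reference levels are
  gender F, handedness L, scanner pre-upgrade.
* JT ties contribute one half to the statistic; the normal
  approximation uses the tie-corrected variance, no continuity
  correction; the reported p is one-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AdjustedEffect",
    "JTResult",
    "residualize",
    "cohens_d_residuals",
    "ancova_group_effect",
    "jonckheere_terpstra",
    "bh_fdr",
    "pearson_correlation",
    "chi_square_contingency",
    "oneway_anova",
    "logistic_domain_impairment",
]


# ---------------------------------------------------------------------
# Covariate adjustment and effect sizes
# ---------------------------------------------------------------------

def _design_with_intercept(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    names = ["intercept"] + list(covariates.columns)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify the columns that fail to extend the rank of their predecessors
    bad = []
    r = 0
    for j in range(X.shape[1]):
        rj = np.linalg.matrix_rank(X[:, : j + 1])
        if rj == r:
            bad.append(names[j])
        r = rj
    raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def residualize(y, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of y regressed on an intercept plus the covariates.

    The group factor is deliberately absent: these residuals are the
    covariate-adjusted values used for effect sizes and trend tests.
    Residuals are exactly orthogonal to every covariate column.
    """
    y = np.asarray(y, dtype=float)
    if covariates.shape[0] != y.shape[0]:
        raise ValueError("y and covariates length mismatch")
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    X, names = _design_with_intercept(covariates)
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def cohens_d_residuals(a, b) -> float:
    """Cohen's d between two residual samples (first minus second).

    Pooled SD uses (n_a - 1, n_b - 1) weighting. Returns NaN when the
    pooled SD is zero (undefined, flagged rather than raised).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


@dataclass
class AdjustedEffect:
    """Covariate-adjusted group comparison: ANCOVA p plus Cohen's d."""

    p_value: float
    cohens_d: float
    group_sizes: tuple[int, ...]
    residuals: np.ndarray


def ancova_group_effect(
    y, group, covariates: pd.DataFrame, order: list[str] | None = None
) -> AdjustedEffect:
    """F-test of the group factor in ``y ~ group + covariates``.

    The p-value comes from the nested-model F-test (full model with
    group indicators vs covariates only). Cohen's d is computed on the
    covariate-only residuals between the first two groups of ``order``
    (first minus second); NaN when more than two groups are compared.
    """
    y = np.asarray(y, dtype=float)
    group = pd.Series(group).reset_index(drop=True)
    if order is None:
        order = list(dict.fromkeys(group))
    if len(order) < 2:
        raise ValueError("need at least 2 groups")
    sizes = tuple(int((group == g).sum()) for g in order)
    if any(s < 2 for s in sizes):
        raise ValueError(f"every group needs >= 2 subjects, got sizes {sizes}")

    Xr, names_r = _design_with_intercept(covariates)
    dummies = np.column_stack([(group == g).astype(float) for g in order[1:]])
    Xf = np.column_stack([Xr, dummies])
    names_f = names_r + [f"group_{g}" for g in order[1:]]
    _check_full_rank(Xr, names_r)
    try:
        _check_full_rank(Xf, names_f)
    except ValueError as exc:
        raise ValueError(f"group confounded with covariates: {exc}") from exc

    def ssr(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ssr_r, ssr_f = ssr(Xr), ssr(Xf)
    df_num = len(order) - 1
    df_den = len(y) - Xf.shape[1]
    if df_den <= 0:
        raise ValueError("not enough observations for the full model")
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((ssr_r - ssr_f) / df_num) / (ssr_f / df_den)
    p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else float("nan")

    resid = residualize(y, covariates)
    if len(order) == 2:
        d = cohens_d_residuals(resid[(group == order[0]).to_numpy()],
                               resid[(group == order[1]).to_numpy()])
    else:
        d = float("nan")
    return AdjustedEffect(p_value=p, cohens_d=d, group_sizes=sizes, residuals=resid)


# ---------------------------------------------------------------------
# Jonckheere-Terpstra
# ---------------------------------------------------------------------

@dataclass
class JTResult:
    statistic: float
    null_mean: float
    null_sd: float
    p_value: float
    method: str  # "exact" | "asymptotic"
    direction: str  # "increasing" | "decreasing"


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """JT count: pairs (x in earlier group, y in later group) with x < y,
    plus half the ties."""
    stat = 0.0
    for gi, gj in combinations(range(len(groups)), 2):
        x, y = groups[gi][:, None], groups[gj][None, :]
        stat += np.sum(x < y) + 0.5 * np.sum(x == y)
    return float(stat)


def _jt_null_moments(sizes: np.ndarray, pooled: np.ndarray) -> tuple[float, float]:
    """Mean and tie-corrected SD of the JT statistic under the null."""
    N = int(sizes.sum())
    mean = (N * N - np.sum(sizes**2)) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    n = sizes.astype(float)
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = 0.0
    term3 = 0.0
    if N > 2:
        term2 = (
            np.sum(n * (n - 1) * (n - 2)) * np.sum(t * (t - 1) * (t - 2))
        ) / (36.0 * N * (N - 1) * (N - 2))
    term3 = (np.sum(n * (n - 1)) * np.sum(t * (t - 1))) / (8.0 * N * (N - 1))
    var = term1 + term2 + term3
    return float(mean), float(math.sqrt(max(var, 0.0)))


def _multinomial(sizes) -> int:
    total = int(sum(sizes))
    out = math.factorial(total)
    for s in sizes:
        out //= math.factorial(int(s))
    return out


def _enumerate_stats(pooled: np.ndarray, sizes: list[int]):
    """Yield the JT statistic of every distinct assignment of the pooled
    values to groups of the given sizes (complete label enumeration)."""
    n = len(pooled)
    less = (pooled[:, None] < pooled[None, :]).astype(float)
    less += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(less, 0.0)

    def rec(remaining: tuple, k: int, partial: float, chosen: list):
        if k == len(sizes):
            yield partial
            return
        for combo in combinations(remaining, sizes[k]):
            combo_set = set(combo)
            rest = tuple(i for i in remaining if i not in combo_set)
            # pairs between this group (earlier) and all later indices
            add = sum(less[i, j] for i in combo for j in rest)
            yield from rec(rest, k + 1, partial + add, chosen + [combo])

    yield from rec(tuple(range(n)), 0, 0.0, [])


def jonckheere_terpstra(
    samples,
    direction: str = "increasing",
    enumeration_cap: int = 10**6,
) -> JTResult:
    """Jonckheere-Terpstra test against an ordered alternative.

    Parameters
    ----------
    samples : sequence of 1-d arrays
        Groups in the hypothesised order.
    direction : {"increasing", "decreasing"}
        Alternative: values tend to increase (or decrease) along the
        group order. Decreasing alternatives are evaluated by reversing
        the group order.
    enumeration_cap : int
        Exact p by complete enumeration of group-label assignments when
        the multinomial count of assignments is at most this; otherwise
        the tie-corrected normal approximation (no continuity
        correction).

    Notes
    -----
    When the null SD is zero (constant data) the test carries no
    information and p = 0.5 is returned.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    groups = [np.asarray(g, dtype=float).ravel() for g in samples]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    eval_groups = groups[::-1] if direction == "decreasing" else groups
    stat = _jt_statistic(eval_groups)
    sizes = np.array([len(g) for g in eval_groups])
    pooled = np.concatenate(eval_groups)
    mean, sd = _jt_null_moments(sizes, pooled)

    if sd == 0.0:
        return JTResult(stat, mean, sd, 0.5, "degenerate", direction)

    if _multinomial(sizes) <= enumeration_cap:
        stats_iter = _enumerate_stats(pooled, [int(s) for s in sizes])
        ge = 0
        total = 0
        for s in stats_iter:
            total += 1
            if s >= stat - 1e-9:
                ge += 1
        p = ge / total
        method = "exact"
    else:
        z = (stat - mean) / sd
        p = float(sps.norm.sf(z))
        method = "asymptotic"
    return JTResult(stat, mean, sd, float(p), method, direction)


# ---------------------------------------------------------------------
# Multiplicity, correlation, contingency, ANOVA
# ---------------------------------------------------------------------

def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q.

    Returns ``(significant_flags, adjusted_p)``; empty input gives empty
    outputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with two-sided t-based p; NaN pair on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def chi_square_contingency(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def oneway_anova(groups, summaries: bool | None = None) -> tuple[float, float]:
    """One-way ANOVA from raw samples or (n, mean, sd) summary triplets.

    Summary triplets are passed as *tuples* (or force the mode with
    ``summaries=True``); summary mode reconstructs the between/within
    sums of squares and agrees exactly with raw mode when the summaries
    come from the raw samples. Returns NaN F (flagged) when the
    within-group variance is zero and the means are equal.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")

    def is_summary(g):
        return isinstance(g, tuple) and len(g) == 3 and all(np.isscalar(v) for v in g)

    if summaries is None:
        summaries = all(is_summary(g) for g in groups)
    if summaries:
        n = np.array([g[0] for g in groups], dtype=float)
        m = np.array([g[1] for g in groups], dtype=float)
        sd = np.array([g[2] for g in groups], dtype=float)
        if (n < 2).any():
            raise ValueError("summary mode requires n >= 2 per group")
        N = n.sum()
        grand = np.sum(n * m) / N
        ssb = np.sum(n * (m - grand) ** 2)
        ssw = np.sum((n - 1) * sd**2)
        df_b = len(groups) - 1
        df_w = N - len(groups)
        if ssw == 0:
            if ssb == 0:
                return float("nan"), float("nan")
            return float("inf"), 0.0
        F = (ssb / df_b) / (ssw / df_w)
        return float(F), float(sps.f.sf(F, df_b, df_w))

    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 observations")
    if all(a.var() == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        return float("nan"), float("nan")
    F, p = sps.f_oneway(*arrays)
    return float(F), float(p)


# ---------------------------------------------------------------------
# Logistic impairment models
# ---------------------------------------------------------------------

def _ridge_irls_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-4,
    tol: float = 1e-8, max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """L2-penalised logistic fit by IRLS; returns (beta, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    penalty = ridge * np.eye(p)
    penalty[0, 0] = 0.0  # leave the intercept unpenalised
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + penalty
        beta = np.linalg.solve(H, XtW @ z)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))) - 0.5 * ridge * beta[1:] @ beta[1:])
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X + penalty)
    return beta, cov, converged


def logistic_domain_impairment(
    scores: pd.DataFrame, status, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-domain logistic models of patient status on cognitive scores.

    Each column of ``scores`` (a cognitive domain) is standardised and
    entered, with the covariates, in a logistic regression of status
    (EPP = 1, HC = 0). Returns one row per domain with the odds ratio
    per SD, Wald p and a flag for separation-fallback fits, ranked by
    |log OR| (most impaired domain first).
    """
    import statsmodels.api as sm

    status = pd.Series(status).reset_index(drop=True)
    levels = set(status)
    if not levels <= {"HC", "EPP"}:
        raise ValueError(f"status levels must be HC/EPP, got {sorted(levels)}")
    if len(levels) < 2:
        raise ValueError("both statuses must be present")
    y = (status == "EPP").to_numpy(dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else np.empty((len(y), 0))

    rows = []
    for domain in scores.columns:
        v = scores[domain].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            rows.append({"domain": domain, "odds_ratio": float("nan"),
                         "log_or": float("nan"), "p_value": float("nan"),
                         "fallback": False})
            continue
        z = (v - v.mean()) / sd
        X = np.column_stack([np.ones(len(y)), z, cov])
        fallback = False
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False) or not np.isfinite(fit.bse[1]):
                raise ValueError("non-convergence")
            log_or, p = float(fit.params[1]), float(fit.pvalues[1])
        except Exception:
            beta, covm, _ = _ridge_irls_logistic(X, y)
            log_or = float(beta[1])
            se = math.sqrt(covm[1, 1])
            p = float(2 * sps.norm.sf(abs(log_or) / se))
            fallback = True
        rows.append({"domain": domain, "odds_ratio": math.exp(log_or),
                     "log_or": log_or, "p_value": p, "fallback": fallback})
    out = pd.DataFrame(rows)
    out["rank"] = out["log_or"].abs().rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank").reset_index(drop=True)
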