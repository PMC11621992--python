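"""Stratified conditional logistic regression for matched case-control data.

The conditional likelihood eliminates the per-stratum intercepts by
conditioning on the number of cases in each stratum: with linear predictors
``eta_i`` and ``d`` cases among ``n`` subjects, a stratum contributes

    log [ exp(sum_{cases} eta) / sum_{|S| = d} exp(sum_{i in S} eta_i) ]

where the denominator runs over all ``C(n, d)`` subsets of size ``d``.  The
denominator and its first two derivatives in the coefficients are computed
by the elementary-symmetric-function recursion

    f(j, r) = f(j-1, r) + f(j-1, r-1) * exp(eta_j)

carrying alongside it the weighted sums of ``x_S`` and ``x_S x_S'`` over
subsets, so one pass yields log-likelihood, score and observed information.
Linear predictors are centered within stratum (the likelihood is invariant
to a per-stratum shift) and the accumulators are rescaled on the fly, which
keeps the recursion stable without leaving linear space.

Strata with zero cases or zero controls carry no information and are
dropped with a logged count.  A Breslow approximation (Cox partial
likelihood with Breslow ties) is available as an alternative; the exact
likelihood is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .errors import DataError, NotConvergedError

_RESCALE_AT = 1e250


def _esf_pass(eta: np.ndarray, X: np.ndarray, d: int, order: int = 2):
    """One pass of the subset-sum recursion.

    Works on within-stratum *centered* linear predictors.  Returns
    ``(log_denom, mean, second)`` where ``mean = E[x_S]`` and ``second =
    E[x_S x_S']`` under the subset distribution with weights proportional to
    ``exp(sum_{i in S} eta_i)`` over subsets of size ``d``; ``log_denom``
    refers to the centered predictors.  ``order`` limits which derivative
    accumulators are carried (0: none, 1: mean only).
    """
    n, p = X.shape
    w = np.exp(eta)
    f = np.zeros(d + 1)
    f[0] = 1.0
    g = np.zeros((d + 1, p)) if order >= 1 else None
    h = np.zeros((d + 1, p, p)) if order >= 2 else None
    offset = 0.0
    for j in range(n):
        wj = w[j]
        x = X[j]
        if order >= 2:
            gx = g[:-1, :, None] * x[None, None, :]
            h[1:] += wj * (h[:-1] + gx + gx.transpose(0, 2, 1)
                           + f[:-1, None, None] * np.outer(x, x))
        if order >= 1:
            g[1:] += wj * (g[:-1] + f[:-1, None] * x[None, :])
        f[1:] += wj * f[:-1]
        fmax = f.max()
        if fmax > _RESCALE_AT or 0.0 < fmax < 1.0 / _RESCALE_AT:
            f /= fmax
            offset += np.log(fmax)
            if order >= 1:
                g /= fmax
            if order >= 2:
                h /= fmax
    log_denom = np.log(f[d]) + offset
    mean = g[d] / f[d] if order >= 1 else None
    second = h[d] / f[d] if order >= 2 else None
    return log_denom, mean, second


def _stratum_contrib(eta: np.ndarray, X: np.ndarray, case: np.ndarray, order: int = 2):
    """(loglik, score, information) contribution of one informative stratum."""
    d = int(case.sum())
    eta = eta - eta.max()  # likelihood invariant to per-stratum shift
    log_denom, mean, second = _esf_pass(eta, X, d, order=order)
    ll = float(eta[case].sum() - log_denom)
    if order == 0:
        return ll, None, None
    score = X[case].sum(axis=0) - mean
    if order == 1:
        return ll, score, None
    info = second - np.outer(mean, mean)
    return ll, score, info


def _log_esf_prefix(eta: np.ndarray, d: int) -> np.ndarray:
    """Table ``T[j, r] = log ESF_r(exp(eta[:j]))`` built by the recursion
    ``f(j, r) = f(j-1, r) + f(j-1, r-1) exp(eta_j)`` carried in log space."""
    n = eta.size
    T = np.full((n + 1, d + 1), -np.inf)
    T[:, 0] = 0.0
    for j in range(1, n + 1):
        T[j, 1:] = np.logaddexp(T[j - 1, 1:], T[j - 1, :-1] + eta[j - 1])
    return T


def stratum_loglik(eta, case_flags) -> tuple[float, np.ndarray]:
    """Exact conditional log-likelihood of one stratum and its gradient in eta.

    Computed entirely in log space (forward-backward over the subset-sum
    recursion), so it is stable for strata of any size and predictor range.
    The gradient component for subject i is ``case_i - P(i in S)`` with the
    inclusion probability assembled from prefix and suffix tables.  A
    stratum with no cases or no controls is non-informative: contribution 0
    with zero gradient.
    """
    eta = np.asarray(eta, dtype=float)
    case = np.asarray(case_flags, dtype=bool)
    n = eta.size
    d = int(case.sum())
    if d == 0 or d == n:
        return 0.0, np.zeros(n)
    F = _log_esf_prefix(eta, d)
    B = _log_esf_prefix(eta[::-1], d)[::-1]  # B[i, r] = log ESF_r of eta[i:]
    log_denom = F[n, d]
    ll = float(eta[case].sum() - log_denom)
    # P(i in S) = w_i * sum_r ESF_r(before i) * ESF_{d-1-r}(after i) / ESF_d
    r = np.arange(d)
    log_p = np.array([
        eta[i] + special.logsumexp(F[i, r] + B[i + 1, d - 1 - r]) - log_denom
        for i in range(n)
    ])
    return ll, case.astype(float) - np.exp(log_p)


def _breslow_contrib(eta: np.ndarray, X: np.ndarray, case: np.ndarray):
    d = int(case.sum())
    lse = special.logsumexp(eta)
    pr = np.exp(eta - lse)
    mean = pr @ X
    ll = float(eta[case].sum() - d * lse)
    score = X[case].sum(axis=0) - d * mean
    info = d * ((X.T * pr) @ X - np.outer(mean, mean))
    return ll, score, info


@dataclass
class ClogitFit:
    """Result of a stratified conditional logistic fit."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_informative_strata: int
    n_dropped_strata: int
    converged: bool
    iterations: int
    monotone_likelihood: bool = False
    names: list[str] = field(default_factory=list)
    method: str = "exact"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _group_strata(X, y, strata):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=bool)
    strata = np.asarray(strata)
    if not (len(X) == len(y) == len(strata)):
        raise DataError("X, y and strata must have equal length")
    groups = []
    dropped = 0
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        d = int(y[idx].sum())
        if d == 0 or d == len(idx):
            dropped += 1
            continue
        groups.append((X[idx], y[idx]))
    return X.shape[1], groups, dropped


def fit_clogit(X, y, strata, method: str = "exact", max_iter: int = 50,
               ll_tol: float = 1e-8, score_tol: float = 1e-6,
               names: list[str] | None = None) -> ClogitFit:
    """Maximize the stratified conditional likelihood by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) design matrix (p may be 0 for the null model).
    y : case indicator per subject.
    strata : stratum label per subject (matching-factor cross-classification).
    method : "exact" conditional likelihood or the "breslow" approximation.

    Convergence requires a relative log-likelihood change below ``ll_tol``
    and a maximal absolute score below ``score_tol``.  Separation shows up
    as a monotone likelihood (coefficients diverging); the fit is then
    returned flagged and non-converged rather than silently.
    """
    if method not in ("exact", "breslow"):
        raise DataError(f"unknown method {method!r}")
    p, groups, dropped = _group_strata(X, y, strata)
    if not groups:
        raise DataError("no informative strata (each needs >= 1 case and 1 control)")
    contrib = _stratum_contrib if method == "exact" else _breslow_contrib

    def evaluate(beta):
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for Xs, ys in groups:
            eta = Xs @ beta
            c_ll, c_sc, c_in = contrib(eta, Xs, ys)
            ll += c_ll
            score += c_sc
            info += c_in
        return ll, score, info

    def loglik_only(beta):
        total = 0.0
        for Xs, ys in groups:
            eta = Xs @ beta
            if method == "exact":
                c_ll, _, _ = _stratum_contrib(eta, np.empty((len(eta), 0)), ys, order=0)
                total += c_ll
            else:
                total += float(eta[ys].sum() - int(ys.sum()) * special.logsumexp(eta))
        return total

    beta = np.zeros(p)
    ll, score, info = evaluate(beta)
    converged = p == 0 or bool(np.max(np.abs(score)) < score_tol)
    iterations = 0
    monotone = False
    for iterations in range(1, max_iter + 1):
        if converged:
            break
        try:
            delta = linalg.solve(info, score, assume_a="pos")
        except linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
        step = 1.0
        new_beta = beta + delta
        new_ll = loglik_only(new_beta)
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step /= 2.0
            if step < 1e-8:
                break
            new_beta = beta + step * delta
            new_ll = loglik_only(new_beta)
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta = new_beta
        ll, score, info = evaluate(beta)
        if rel_change < ll_tol and np.max(np.abs(score)) < score_tol:
            converged = True
    if p > 0 and np.max(np.abs(beta)) > 10.0:
        # a log-OR beyond ~10 is a separation artifact, not an estimate,
        # even when the score happens to vanish numerically
        monotone = True
        converged = False
    elif not converged and p > 0:
        monotone = bool(np.max(np.abs(beta)) > 10.0)

    if p > 0:
        try:
            cov = linalg.inv(info)
        except linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            converged = False
    else:
        cov = np.zeros((0, 0))
    return ClogitFit(
        beta=beta, cov=cov, loglik=ll,
        n_informative_strata=len(groups), n_dropped_strata=dropped,
        converged=converged, iterations=iterations,
        monotone_likelihood=monotone,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        method=method,
    )


def null_loglik(y, strata) -> float:
    """Closed-form conditional log-likelihood of the covariate-free model:
    sum over informative strata of log(1 / C(n_k, d_k))."""
    y = np.asarray(y, dtype=bool)
    strata = np.asarray(strata)
    total = 0.0
    for s in pd.unique(strata):
        idx = strata == s
        n, d = int(idx.sum()), int(y[idx].sum())
        if 0 < d < n:
            total -= np.log(special.comb(n, d, exact=True))
    return total


def odds_ratios(fit: ClogitFit, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios exp(beta) with Wald confidence intervals.

    Refuses a non-converged fit: silent estimates from a diverged model are
    worse than no estimates.
    """
    if not fit.converged:
        raise NotConvergedError(
            "fit did not converge"
            + (" (monotone likelihood: possible separation)"
               if fit.monotone_likelihood else "")
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se
    return pd.DataFrame(
        {
            "term": fit.names,
            "OR": np.exp(fit.beta),
            "CI_low": np.exp(fit.beta - z * se),
            "CI_high": np.exp(fit.beta + z * se),
        }
    )


@dataclass
class TrendTest:
    """Wald test of a single ordinal exposure score (0..4)."""

    beta: float
    se: float
    z: float
    p_value: float
    fit: ClogitFit | None


def _score_varies_within_strata(score, y, strata) -> bool:
    score = np.asarray(score, float)
    y = np.asarray(y, bool)
    strata = np.asarray(strata)
    for s in pd.unique(strata):
        idx = strata == s
        d = int(y[idx].sum())
        if 0 < d < idx.sum() and np.ptp(score[idx]) > 0:
            return True
    return False


def trend_test(score, y, strata, covariates=None) -> TrendTest:
    """Replace category indicators by one ordinal score and Wald-test it.

    ``score`` is the ordinal exposure level per subject (0 = unexposed
    through 4 = highest); ``covariates`` are optional adjustment columns
    (e.g. education indicators).  A score with no within-stratum variation
    carries no conditional information: the coefficient is 0 and p = 1 by
    symmetry.
    """
    if not _score_varies_within_strata(score, y, strata):
        return TrendTest(beta=0.0, se=np.inf, z=0.0, p_value=1.0, fit=None)
    score = np.asarray(score, dtype=float)[:, None]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        X = np.hstack([score, covariates])
    else:
        X = score
    fit = fit_clogit(X, y, strata, names=["trend"] + [
        f"c{i}" for i in range(X.shape[1] - 1)
    ])
    if not fit.converged:
        raise NotConvergedError("trend model did not converge")
    beta = float(fit.beta[0])
    se = float(fit.se[0])
    if se == 0.0 or not np.isfinite(se):
        return TrendTest(beta=beta, se=se, z=0.0, p_value=1.0, fit=fit)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TrendTest(beta=beta, se=se, z=z, p_value=p, fit=fit)


def education_indicators(education: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Two adjustment indicators with high-school-or-less as the reference."""
    edu = pd.Series(education).astype(str)
    X = np.column_stack([
        (edu == "medium_technical").to_numpy(float),
        (edu == "university").to_numpy(float),
    ])
    return X, ["edu_medium_technical", "edu_university"]
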