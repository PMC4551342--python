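"""Inference machinery: exact binomial CIs, Mann-Whitney, Firth logistic.

Firth's penalized likelihood maximizes l*(b) = l(b) + 0.5 log det I(b); the
penalty removes the O(1/n) bias of the MLE and keeps estimates finite under
complete or quasi-complete separation, which is exactly the situation when a
biomarker splits recurrence outcomes almost perfectly.  The implementation is
a damped Newton iteration on the Firth-modified score

    U*_r(b) = sum_i [y_i - pi_i + h_i (1/2 - pi_i)] x_ir,

with h_i the leverages of the weighted hat matrix, step-halving on
non-increase of l*, and standard errors from the inverse penalized
information at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit

# ---------------------------------------------------------------- binomial CI


@dataclass
class ExactBinomialCI:
    x: int
    n: int
    level: float
    sidedness: str  # 'two_sided' | 'one_sided_lower'
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.x / self.n


def clopper_pearson(
    x: int, n: int, level: float = 0.95, sidedness: str = "two_sided"
) -> ExactBinomialCI:
    """Exact (conservative) binomial CI from beta-distribution quantiles.

    Two-sided: lower = Q_beta(alpha/2; x, n-x+1), upper = Q_beta(1-alpha/2;
    x+1, n-x), with the conventional endpoints at x = 0 and x = n.
    ``one_sided_lower`` returns [Q_beta(alpha; x, n-x+1), 1].
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if sidedness not in ("two_sided", "one_sided_lower"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    alpha = 1.0 - level
    if sidedness == "one_sided_lower":
        lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha, x, n - x + 1))
        upper = 1.0
    else:
        lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
        upper = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ExactBinomialCI(x, n, level, sidedness, lower, upper)


# --------------------------------------------------------------- Mann-Whitney


def mann_whitney_u(a: Sequence[float], b: Sequence[float], exact: bool | None = None):
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample is small (n_a + n_b <= 12) and
    tie-free, otherwise the normal approximation with tie correction.  Pass
    ``exact`` to override.  Returns (U, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if exact is None:
        exact = (a.size + b.size) <= 12 and not has_ties
    method = "exact" if (exact and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ------------------------------------------------------------- Firth logistic


@dataclass
class FirthFit:
    coef: np.ndarray  # intercept first
    se: np.ndarray
    odds_ratios: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    loglik_penalized: float
    converged: bool
    n_iter: int
    profile_ci: list[tuple[float, float]] | None = None


def _firth_parts(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    eta = X @ beta
    pi = expit(eta)
    w = pi * (1.0 - pi)
    XtW = X.T * w
    info = XtW @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return pi, info, -np.inf, None
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta))) + 0.5 * logdet
    # leverages of W^(1/2) X (X' W X)^-1 X' W^(1/2)
    sqw = np.sqrt(w)
    Xs = X * sqw[:, None]
    h = np.einsum("ij,ij->i", Xs @ np.linalg.inv(info), Xs)
    return pi, info, ll, h


def firth_logistic(
    y: Sequence[int],
    X: np.ndarray,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 10,
    profile_ci_level: float | None = None,
) -> FirthFit:
    """Fit a Firth-penalized logistic regression.

    ``X`` is the covariate matrix without intercept column unless
    ``add_intercept=False``.  Convergence is declared when the largest
    modified-score component falls below ``tol``.  With ``profile_ci_level``
    set, penalized-likelihood profile CIs are computed per coefficient
    (bounds that never cross the chi-square cutoff are reported infinite).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if y.min() == y.max():
        raise ValueError("outcome is constant")

    beta = np.zeros(X.shape[1])
    pi, info, ll, h = _firth_parts(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score = X.T @ (y - pi + h * (0.5 - pi))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = np.linalg.solve(info, score)
        new_beta = beta + step
        new_pi, new_info, new_ll, new_h = _firth_parts(X, y, new_beta)
        halv = 0
        while new_ll < ll and halv < max_halvings:
            step *= 0.5
            new_beta = beta + step
            new_pi, new_info, new_ll, new_h = _firth_parts(X, y, new_beta)
            halv += 1
        beta, pi, info, ll, h = new_beta, new_pi, new_info, new_ll, new_h
    else:
        it = max_iter
    # final score check (loop may exit by exhaustion)
    score = X.T @ (y - pi + h * (0.5 - pi))
    converged = bool(np.max(np.abs(score)) < tol)

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    fit = FirthFit(
        coef=beta,
        se=se,
        odds_ratios=np.exp(beta),
        wald_z=z,
        wald_p=p,
        loglik_penalized=ll,
        converged=converged,
        n_iter=it,
    )
    if profile_ci_level is not None:
        fit.profile_ci = [
            _profile_ci(X, y, beta, ll, j, profile_ci_level) for j in range(len(beta))
        ]
    return fit


def _profile_loglik(X: np.ndarray, y: np.ndarray, j: int, value: float) -> float:
    """Maximized penalized log-likelihood with coefficient j fixed."""
    free = [k for k in range(X.shape[1]) if k != j]
    offset_col = X[:, j] * value
    Xf = X[:, free]

    beta_f = np.zeros(len(free))
    for _ in range(200):
        eta = Xf @ beta_f + offset_col
        pi = expit(eta)
        w = pi * (1.0 - pi)
        info = (Xf.T * w) @ Xf
        sign, logdet_f = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        sqw = np.sqrt(w)
        Xs = Xf * sqw[:, None]
        h = np.einsum("ij,ij->i", Xs @ np.linalg.inv(info), Xs)
        score = Xf.T @ (y - pi + h * (0.5 - pi))
        if np.max(np.abs(score)) < 1e-7:
            break
        beta_f = beta_f + np.linalg.solve(info, score)
    # penalty uses the information of the FULL design at the profiled point
    eta = Xf @ beta_f + offset_col
    pi = expit(eta)
    w = pi * (1.0 - pi)
    full_info = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(full_info)
    if sign <= 0:
        return -np.inf
    return float(np.sum(y * eta - np.logaddexp(0.0, eta))) + 0.5 * logdet


def _profile_ci(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, ll_max: float, j: int, level: float
) -> tuple[float, float]:
    cutoff = ll_max - 0.5 * sps.chi2.ppf(level, 1)

    def bound(direction: float) -> float:
        lo, hi = 0.0, 1.0
        # expand until the profile drops below the cutoff, or declare infinite
        for _ in range(60):
            if _profile_loglik(X, y, j, beta[j] + direction * hi) < cutoff:
                break
            hi *= 2.0
            if hi > 1e4:
                return direction * math.inf
        else:
            return direction * math.inf
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _profile_loglik(X, y, j, beta[j] + direction * mid) < cutoff:
                hi = mid
            else:
                lo = mid
        return beta[j] + direction * 0.5 * (lo + hi)

    return (bound(-1.0), bound(+1.0))


# -------------------------------------------------- covariates and transforms


@dataclass
class CovariateTransform:
    """A monotone transform of the ctDNA percentage, with zero handling."""

    name: str
    func: Callable[[np.ndarray], np.ndarray]
    floor: float = 0.0  # values below are raised to the floor before transform

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.floor > 0:
            v = np.maximum(v, self.floor)
        return self.func(v)


def default_transforms(floor: float = 0.01) -> list[CovariateTransform]:
    """identity / log2-with-floor / sqrt candidates (floor in ctDNA percent)."""
    return [
        CovariateTransform("identity", lambda v: v),
        CovariateTransform("log2", np.log2, floor=floor),
        CovariateTransform("sqrt", np.sqrt),
    ]


def aic_firth(fit: FirthFit, k: int | None = None) -> float:
    """AIC = -2 l*(beta-hat) + 2k, using the penalized log-likelihood."""
    if k is None:
        k = len(fit.coef)
    return -2.0 * fit.loglik_penalized + 2.0 * k


def select_transform(
    ctdna_percent: Sequence[float],
    outcomes: dict[str, Sequence[int]],
    candidates: list[CovariateTransform] | None = None,
) -> tuple[CovariateTransform, "dict[str, float]"]:
    """Pick the transform minimizing summed AIC over the outcome models.

    Fits one univariable Firth model per outcome (typically recurrence and
    death) for each candidate transform and returns the candidate with the
    smallest summed AIC; ties break to the earlier candidate.
    """
    if candidates is None:
        candidates = default_transforms()
    if not candidates:
        raise ValueError("need at least one candidate transform")
    sums: dict[str, float] = {}
    best: CovariateTransform | None = None
    n_failed = 0
    for cand in candidates:
        x = cand.apply(ctdna_percent)
        total = 0.0
        try:
            for y in outcomes.values():
                total += aic_firth(firth_logistic(y, x[:, None]))
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        sums[cand.name] = total
        if best is None or total < sums[best.name] - 1e-12:
            best = cand
    if best is None:
        raise ValueError("all candidate transforms failed to fit")
    return best, sums


def ctdna_covariate(
    records,
    event_time_attr: str,
    transform: CovariateTransform | None = None,
    floor: float = 0.01,
) -> dict[str, float]:
    """Per-patient covariate: ctDNA percent of the last pre-event sample.

    For each patient, take the most recent post-surgery sample strictly
    before the event/censoring time (each sample already represents its
    time-point by the maximal-percentage rearrangement), floor zeros, and
    apply the transform (default log2 with the given floor).  Patients with
    no eligible sample are omitted.
    """
    if transform is None:
        transform = CovariateTransform("log2", np.log2, floor=floor)
    out: dict[str, float] = {}
    for rec in records:
        event_time = getattr(rec, event_time_attr)
        if event_time is None:
            event_time = rec.time_to_last_followup
        eligible = [
            s for s in rec.samples if 0 < s.time_months <= event_time
        ]
        if not eligible:
            continue
        last = max(eligible, key=lambda s: s.time_months)
        out[rec.patient_id] = float(transform.apply([last.ctdna_percent])[0])
    return out
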