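"""Interaction-model fitting: Cox proportional hazards and linear regression.

Both analysis models regress the outcome on {GRS, arm, GRS x arm} -- the
aggregate risk score, not the individual SNPs, even though data are
generated per SNP.  That generation/analysis mismatch is deliberate: it is
how such trials are analysed in practice.

The Cox fit is a purpose-built Newton-Raphson maximizer of the partial
likelihood (Breslow handling of tied event times) with Wald standard errors
from the inverse observed information.  It is written directly in numpy
because a power run performs thousands of fits; its correctness is pinned in
the test suite against both a brute-force partial-likelihood oracle and an
independent Cox implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InfeasibleFitError

__all__ = ["FitSummary", "fit_cox_interaction", "fit_linear_interaction"]

_MAX_NEWTON_ITER = 40
_GRAD_TOL = 1e-9
_BETA_BOUND = 50.0  # |beta| beyond this signals monotone likelihood / separation


@dataclass(frozen=True)
class FitSummary:
    """Interaction coefficient, its standard error and Wald p-value.

    ``gamma`` is on the log-hazard scale for survival fits and in outcome
    units for linear fits.  Non-converged fits carry NaN estimates and are
    excluded from power tallies by the caller.
    """

    gamma: float
    se_gamma: float
    p_value: float
    converged: bool
    model: str  # "survival" | "linear"


def _suffix(arr: np.ndarray) -> np.ndarray:
    return np.cumsum(arr[::-1], axis=0)[::-1]


def _cox_newton(x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Newton-Raphson Cox partial-likelihood fit, Breslow ties.

    Returns (beta, covariance, converged).  Observations are sorted by
    time; risk-set sums are suffix sums, with tied times sharing the risk
    set of the first member of the tie group (Breslow).
    """
    n, p = x.shape
    order = np.argsort(time, kind="stable")
    x = x[order]
    time = time[order]
    ev = event[order].astype(bool)
    # risk set of observation i = all j with time_j >= time_i; under the
    # ascending sort that is the suffix starting at the first index whose
    # time equals time_i
    first_idx = np.searchsorted(time, time, side="left")
    ev_first = first_idx[ev]
    x_ev = x[ev]
    d = len(x_ev)
    if d == 0:
        return None, None, False

    def loglik_of(beta: np.ndarray) -> float:
        eta = x @ beta
        shift = eta.max()
        s0 = _suffix(np.exp(eta - shift))[ev_first]
        return float(np.sum(eta[ev]) - np.sum(np.log(s0)) - d * shift)

    beta = np.zeros(p)
    loglik = loglik_of(beta)
    converged = False
    grad = None
    info = None
    for _ in range(_MAX_NEWTON_ITER):
        eta = x @ beta
        shift = eta.max()  # partial likelihood is shift-invariant
        w = np.exp(eta - shift)
        s0_e = _suffix(w)[ev_first]
        s1_e = _suffix(x * w[:, None])[ev_first]
        s2_e = _suffix(np.einsum("ij,ik,i->ijk", x, x, w))[ev_first]
        mean1 = s1_e / s0_e[:, None]
        grad = x_ev.sum(axis=0) - mean1.sum(axis=0)
        info = (
            np.einsum("ijk->jk", s2_e / s0_e[:, None, None])
            - np.einsum("ij,ik->jk", mean1, mean1)
        )
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return None, None, False
        # step-halving if the update does not improve the partial likelihood
        step = 1.0
        while step > 1e-4:
            cand_ll = loglik_of(beta + step * delta)
            if cand_ll >= loglik - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        if np.any(np.abs(beta) > _BETA_BOUND) or not np.all(np.isfinite(beta)):
            return None, None, False
        new_ll = loglik_of(beta)
        if np.max(np.abs(step * delta)) < _GRAD_TOL or abs(new_ll - loglik) < 1e-12:
            converged = True
            loglik = new_ll
            break
        loglik = new_ll
    if not converged:
        # accept if the gradient is essentially zero anyway
        converged = grad is not None and bool(np.max(np.abs(grad)) < 1e-6)
    if not converged:
        return None, None, False
    # re-expand at the final beta so the information matrix matches it
    eta = x @ beta
    w = np.exp(eta - eta.max())
    s0_e = _suffix(w)[ev_first]
    s1_e = _suffix(x * w[:, None])[ev_first]
    s2_e = _suffix(np.einsum("ij,ik,i->ijk", x, x, w))[ev_first]
    mean1 = s1_e / s0_e[:, None]
    info = (
        np.einsum("ijk->jk", s2_e / s0_e[:, None, None])
        - np.einsum("ij,ik->jk", mean1, mean1)
    )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None, None, False
    if np.any(np.diag(cov) <= 0):
        return None, None, False
    return beta, cov, True


def fit_cox_interaction(
    time: np.ndarray,
    event: np.ndarray,
    grs: np.ndarray,
    arm: np.ndarray,
) -> FitSummary:
    """Cox fit of {GRS, arm, GRS x arm}; returns the interaction term.

    The p-value is a two-sided Wald test of the interaction coefficient
    against zero.  Separation / monotone likelihood is reported as a
    non-converged summary rather than an exception so Monte-Carlo loops can
    tally it.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    grs = np.asarray(grs, dtype=float)
    arm = np.asarray(arm, dtype=float)
    if event[arm == 1].sum() < 1 or event[arm == 0].sum() < 1:
        raise InfeasibleFitError("need at least one event in each arm")
    if np.var(grs) == 0:
        raise InfeasibleFitError("GRS has no variance in the cohort")
    x = np.column_stack([grs, arm, grs * arm])
    beta, cov, ok = _cox_newton(x, time, event)
    if not ok:
        return FitSummary(np.nan, np.nan, np.nan, False, "survival")
    gamma = float(beta[2])
    se = float(np.sqrt(cov[2, 2]))
    z = gamma / se
    p = 2.0 * stats.norm.sf(abs(z))
    return FitSummary(gamma, se, float(p), True, "survival")


def fit_linear_interaction(
    y_obs: np.ndarray,
    grs: np.ndarray,
    arm: np.ndarray,
) -> FitSummary:
    """OLS fit of y on {1, GRS, arm, GRS x arm}; returns the interaction.

    Standard error uses the usual unbiased residual-variance estimator and
    the p-value the t reference with n - 4 degrees of freedom.
    """
    import statsmodels.api as sm

    y = np.asarray(y_obs, dtype=float)
    grs = np.asarray(grs, dtype=float)
    arm = np.asarray(arm, dtype=float)
    n = len(y)
    if n <= 4:
        raise InfeasibleFitError("need more observations than parameters")
    x = np.column_stack([np.ones(n), grs, arm, grs * arm])
    if np.linalg.matrix_rank(x) < 4:
        raise InfeasibleFitError(
            "design matrix is rank deficient (constant GRS or single-arm cohort)"
        )
    res = sm.OLS(y, x).fit()
    return FitSummary(
        gamma=float(res.params[3]),
        se_gamma=float(res.bse[3]),
        p_value=float(res.pvalues[3]),
        converged=True,
        model="linear",
    )
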