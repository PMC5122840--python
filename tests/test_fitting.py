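"""Interaction-model fits against independent oracles.

The Cox fit is checked two ways: against a brute-force maximization of a
naively written-out Breslow partial likelihood on tiny datasets, and
against lifelines' CoxPHFitter on a moderate dataset.  The linear fit is
checked against the explicit normal-equations solution.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from gbrpower import (
    InfeasibleFitError,
    fit_cox_interaction,
    fit_linear_interaction,
)


def _naive_negative_partial_loglik(beta, x, time, event):
    """Breslow partial likelihood written directly from its definition."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = time >= time[i]
        ll += x[i] @ beta - np.log(np.sum(np.exp(x[risk] @ beta)))
    return -ll


def _brute_force_cox(x, time, event, span=5.0):
    """Coarse grid scan over [-span, span]^3, then simplex refinement."""
    grid = np.linspace(-span, span, 9)
    best, best_val = None, np.inf
    for b0 in grid:
        for b1 in grid:
            for b2 in grid:
                v = _naive_negative_partial_loglik(
                    np.array([b0, b1, b2]), x, time, event)
                if v < best_val:
                    best, best_val = np.array([b0, b1, b2]), v
    res = minimize(_naive_negative_partial_loglik, best,
                   args=(x, time, event), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000})
    return res.x


def _tiny_dataset(seed, n):
    rng = np.random.default_rng(seed)
    grs = rng.integers(0, 3, n).astype(float)
    arm = np.tile([0, 1], n)[:n].astype(float)
    time = rng.exponential(2.0, n)
    event = np.ones(n, dtype=int)
    return time, event, grs, arm


class TestCoxInteraction:
    @pytest.mark.parametrize("seed,n", [(1, 6), (2, 7), (5, 8), (9, 8)])
    def test_matches_brute_force_partial_likelihood(self, seed, n):
        """n <= 8: Newton fit equals grid+simplex maximization to 1e-4."""
        time, event, grs, arm = _tiny_dataset(seed, n)
        fs = fit_cox_interaction(time, event, grs, arm)
        if not fs.converged:
            pytest.skip("tiny dataset produced a monotone likelihood")
        x = np.column_stack([grs, arm, grs * arm])
        beta_oracle = _brute_force_cox(x, time, event)
        assert fs.gamma == pytest.approx(beta_oracle[2], abs=1e-4)

    def test_matches_lifelines(self):
        """Coefficient and Wald SE agree with an independent implementation."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(11)
        n = 400
        grs = rng.binomial(2, 0.4, n).astype(float)
        arm = (np.arange(n) % 2).astype(float)
        xb = -0.4 * grs * arm
        time = -np.log(rng.uniform(size=n)) / (0.12 * np.exp(xb))
        event = (time <= 4).astype(int)
        time = np.minimum(time, 4.0)
        fs = fit_cox_interaction(time, event, grs, arm)
        df = pd.DataFrame({"t": time, "e": event, "g": grs, "a": arm,
                           "ga": grs * arm})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        assert fs.gamma == pytest.approx(cph.summary.loc["ga", "coef"], abs=1e-4)
        assert fs.se_gamma == pytest.approx(
            cph.summary.loc["ga", "se(coef)"], rel=1e-3)

    def test_null_recovery(self):
        """Zero interaction: mean fitted gamma over 300 trials is ~0."""
        rng = np.random.default_rng(21)
        gammas = []
        for _ in range(300):
            n = 400
            grs = rng.binomial(2, 0.4, n).astype(float)
            arm = rng.permutation(np.arange(n) % 2).astype(float)
            time = -np.log(rng.uniform(size=n)) / 0.12
            event = (time <= 4).astype(int)
            time = np.minimum(time, 4.0)
            fs = fit_cox_interaction(time, event, grs, arm)
            if fs.converged:
                gammas.append(fs.gamma)
        se = np.std(gammas) / np.sqrt(len(gammas))
        assert np.mean(gammas) == pytest.approx(0.0, abs=3 * se)

    def test_preconditions(self):
        with pytest.raises(InfeasibleFitError):  # no events in one arm
            fit_cox_interaction(np.array([1.0, 2.0]), np.array([1, 0]),
                                np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(InfeasibleFitError):  # constant GRS
            fit_cox_interaction(np.array([1.0, 2.0, 3.0, 4.0]),
                                np.array([1, 1, 1, 1]),
                                np.ones(4), np.array([0.0, 1.0, 0.0, 1.0]))


def _normal_equations(y, x):
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    sigma2 = resid @ resid / (len(y) - x.shape[1])
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    return beta, se


class TestLinearInteraction:
    def test_perfect_fit(self):
        rng = np.random.default_rng(3)
        grs = rng.integers(0, 5, 40).astype(float)
        arm = (np.arange(40) % 2).astype(float)
        y = 0.1 * grs * arm
        fs = fit_linear_interaction(y, grs, arm)
        assert fs.gamma == pytest.approx(0.1, abs=1e-12)

    def test_single_arm_design_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(InfeasibleFitError):
            fit_linear_interaction(rng.normal(size=30),
                                   rng.integers(0, 3, 30), np.zeros(30))

    def test_matches_normal_equations(self):
        """Seeded n=30 dataset: OLS equals (X'X)^-1 X'y to 1e-10."""
        rng = np.random.default_rng(30)
        grs = rng.integers(0, 7, 30).astype(float)
        arm = rng.permutation(np.arange(30) % 2).astype(float)
        y = 0.2 * grs - 0.3 * arm + 0.05 * grs * arm + rng.normal(size=30)
        fs = fit_linear_interaction(y, grs, arm)
        x = np.column_stack([np.ones(30), grs, arm, grs * arm])
        beta, se = _normal_equations(y, x)
        assert fs.gamma == pytest.approx(beta[3], abs=1e-10)
        assert fs.se_gamma == pytest.approx(se[3], abs=1e-10)

    def test_se_matches_sampling_spread(self):
        """Mean reported SE tracks the replicate SD of gamma within 10%."""
        rng = np.random.default_rng(55)
        gammas, ses = [], []
        for _ in range(400):
            n = 200
            grs = rng.binomial(2, 0.4, n).astype(float)
            arm = rng.permutation(np.arange(n) % 2).astype(float)
            y = 0.05 * grs * arm + rng.normal(size=n)
            fs = fit_linear_interaction(y, grs, arm)
            gammas.append(fs.gamma)
            ses.append(fs.se_gamma)
        assert np.mean(ses) == pytest.approx(np.std(gammas), rel=0.10)
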