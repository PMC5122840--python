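"""Monte-Carlo power estimation and minimum-sample-size search.

One scenario = one genetic architecture (a fixed SNP panel) + one trial
design (frame size, recruitment design, trial size, outcome model).  Power
is estimated by simulating the whole pipeline -- frame, recruitment,
randomization, outcome, interaction fit -- many times and tallying
significant interaction tests:

* **Zero/One method**: the fraction of iterations whose two-sided Wald
  p-value for the interaction falls strictly below alpha.  Primary
  estimator for both model families.
* **Standard-Error method** (linear models): average the fitted interaction
  effect and its standard error across iterations, then evaluate
  ``Phi(|mean gamma| / mean SE - z_{1-alpha/2})``.

Frame genotypes are re-simulated each iteration so the Monte-Carlo error
reflects both frame and trial sampling; the panel and the calibrated
baseline hazard are fixed per scenario.  Iteration seeds are derived from
the scenario seed by a counter-based scheme, so results are independent of
execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression

from .errors import InvalidConfigurationError
from .fitting import FitSummary, fit_cox_interaction, fit_linear_interaction
from .genetics import SNPPanel, draw_panel
from .outcomes import (
    add_measurement_error,
    calibrate_baseline_hazard,
    linear_predictor,
    simulate_quantitative,
    simulate_survival,
)
from .recruitment import (
    build_frame,
    randomize_arms,
    recruit_conventional,
    recruit_gbr,
)

__all__ = [
    "ScenarioConfig",
    "PowerEstimate",
    "SampleSizeResult",
    "power_zero_one",
    "power_se",
    "estimate_power",
    "find_sample_size",
    "search_sample_size",
]

# spawn-key namespaces for deterministic, order-independent child streams
_KEY_PANEL = 0
_KEY_CALIBRATION = 1
_KEY_ITERATION = 2


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one power scenario.

    Panel: either pass an explicit ``panel`` or the (k, maf_range,
    effect_range, direction) quadruple from which one panel is drawn with a
    scenario-level seed and reused across iterations.
    """

    frame_size: int
    n_trial: int
    design: str = "conventional"          # "conventional" | "gbr"
    outcome: str = "survival"             # "survival" | "quantitative"
    panel: SNPPanel | None = None
    k: int = 20
    maf_range: tuple[float, float] = (0.2, 0.5)
    effect_range: tuple[float, float] = (0.15, 0.30)
    direction: str = "protective"
    followup: float = 4.0
    target_incidence: float = 0.37
    treatment_main: float = 0.0
    resid_sd: float = 1.0
    r2_error: float = 1.0
    alpha: float = 0.05
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("conventional", "gbr"):
            raise InvalidConfigurationError(f"unknown design {self.design!r}")
        if self.outcome not in ("survival", "quantitative"):
            raise InvalidConfigurationError(f"unknown outcome {self.outcome!r}")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigurationError("alpha must be in (0, 1)")
        if self.iterations < 1:
            raise InvalidConfigurationError("iterations must be >= 1")
        if self.n_trial > self.frame_size:
            raise InvalidConfigurationError(
                f"n_trial {self.n_trial} exceeds frame_size {self.frame_size}"
            )

    def resolve_panel(self) -> SNPPanel:
        """The scenario's fixed panel (drawing it if not explicit)."""
        if self.panel is not None:
            return self.panel
        return draw_panel(
            self.k,
            self.maf_range,
            self.effect_range,
            direction=self.direction,
            rng=_child_rng(self.seed, _KEY_PANEL),
        )


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo power with its binomial uncertainty.

    ``mc_se = sqrt(power (1-power) / n_used)`` for the Zero/One method;
    ``mean_gamma`` / ``mean_se_gamma`` are across-iteration averages of the
    fitted interaction effect and its standard error.  ``unreliable`` flags
    scenarios where more than 20% of fits failed to converge.
    """

    power: float
    mc_se: float
    n_used: int
    method: str
    mean_gamma: float = math.nan
    mean_se_gamma: float = math.nan
    n_nonconverged: int = 0
    unreliable: bool = False


def power_zero_one(p_values: Sequence[float], alpha: float) -> PowerEstimate:
    """Power as the fraction of p-values strictly below alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidConfigurationError("empty p-value vector")
    power = float(np.mean(p < alpha))
    mc_se = math.sqrt(power * (1.0 - power) / p.size)
    return PowerEstimate(power=power, mc_se=mc_se, n_used=p.size, method="zero_one")


def power_se(mean_gamma: float, mean_se_gamma: float, alpha: float) -> PowerEstimate:
    """Analytic power from Monte-Carlo-averaged effect and standard error.

    ``power = Phi(|gamma| / SE(gamma) - z_{1-alpha/2})`` with gamma and
    SE(gamma) averaged separately across iterations before forming the
    ratio.
    """
    if not mean_se_gamma > 0:
        raise InvalidConfigurationError("mean_se_gamma must be positive")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    power = float(stats.norm.cdf(abs(mean_gamma) / mean_se_gamma - z_crit))
    return PowerEstimate(
        power=power,
        mc_se=0.0,
        n_used=0,
        method="se",
        mean_gamma=mean_gamma,
        mean_se_gamma=mean_se_gamma,
    )


def _calibrate_for_scenario(cfg: ScenarioConfig, panel: SNPPanel):
    """Calibrate lambda0 once per scenario on a dedicated calibration frame.

    Incidence is treated as a population property: every member of a
    calibration frame contributes a placebo and an active linear predictor
    with equal weight (a hypothetical 50/50 allocation of the population).
    """
    rng = _child_rng(cfg.seed, _KEY_CALIBRATION)
    frame = build_frame(panel, cfg.frame_size, rng)
    xb0 = linear_predictor(frame.genotypes, np.zeros(frame.frame_size), panel,
                           cfg.treatment_main)
    xb1 = linear_predictor(frame.genotypes, np.ones(frame.frame_size), panel,
                           cfg.treatment_main)
    return calibrate_baseline_hazard(
        np.concatenate([xb0, xb1]), cfg.followup, cfg.target_incidence
    )


def simulate_one_trial(
    cfg: ScenarioConfig,
    panel: SNPPanel,
    hazard,
    rng: np.random.Generator,
) -> FitSummary:
    """Run one full frame -> recruit -> randomize -> outcome -> fit cycle."""
    frame = build_frame(panel, cfg.frame_size, rng)
    if cfg.design == "gbr":
        cohort = recruit_gbr(frame, cfg.n_trial)
    else:
        cohort = recruit_conventional(frame, cfg.n_trial, rng)
    cohort = randomize_arms(cohort, rng)
    if cfg.outcome == "survival":
        time, event = simulate_survival(cohort, panel, hazard,
                                        cfg.treatment_main, rng)
        return fit_cox_interaction(time, event, cohort.grs, cohort.arm)
    y = simulate_quantitative(cohort, panel, cfg.treatment_main,
                              cfg.resid_sd, rng)
    if cfg.r2_error < 1.0:
        y = add_measurement_error(y, cfg.r2_error, rng)
    return fit_linear_interaction(y, cohort.grs, cohort.arm)


def iterate_fits(cfg: ScenarioConfig) -> pd.DataFrame:
    """Per-iteration fit log: iter, gamma, se, p, converged."""
    panel = cfg.resolve_panel()
    hazard = (
        _calibrate_for_scenario(cfg, panel) if cfg.outcome == "survival" else None
    )
    rows = []
    for i in range(cfg.iterations):
        rng = _child_rng(cfg.seed, _KEY_ITERATION, i)
        try:
            fs = simulate_one_trial(cfg, panel, hazard, rng)
        except Exception:  # infeasible draws count as non-converged
            fs = FitSummary(math.nan, math.nan, math.nan, False,
                            "survival" if cfg.outcome == "survival" else "linear")
        rows.append((i, fs.gamma, fs.se_gamma, fs.p_value, fs.converged))
    return pd.DataFrame(rows, columns=["iter", "gamma", "se", "p", "converged"])


def estimate_power(cfg: ScenarioConfig) -> PowerEstimate:
    """Monte-Carlo power (Zero/One method) for one scenario.

    Non-converged fits are excluded from both numerator and denominator;
    their count is reported and the estimate flagged unreliable when they
    exceed 20% of iterations.  Fully reproducible given ``cfg.seed``.
    """
    fits = iterate_fits(cfg)
    ok = fits[fits["converged"]]
    n_bad = int(len(fits) - len(ok))
    if len(ok) == 0:
        return PowerEstimate(math.nan, math.nan, 0, "zero_one",
                             n_nonconverged=n_bad, unreliable=True)
    est = power_zero_one(ok["p"].to_numpy(), cfg.alpha)
    return replace(
        est,
        mean_gamma=float(ok["gamma"].mean()),
        mean_se_gamma=float(ok["se"].mean()),
        n_nonconverged=n_bad,
        unreliable=n_bad > 0.2 * len(fits),
    )


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a minimum-sample-size search.

    ``reached`` is False when the target power is unattainable within the
    bracket (e.g. at the full frame); ``n`` then holds the largest size
    evaluated.  ``evaluations`` records every (n, power) pair measured.
    """

    n: int
    power: float
    mc_se: float
    target_power: float
    reached: bool
    evaluations: pd.DataFrame = field(repr=False, default=None)


def _snap(value: float, resolution: int, lo: int, hi: int) -> int:
    n = int(round(value / resolution)) * resolution
    return max(lo, min(hi, n))


def _smoothed(ns: list[int], powers: list[float], weights: list[float]) -> np.ndarray:
    """Isotonic (monotone non-decreasing in n) smoothing of a power curve."""
    order = np.argsort(ns)
    res = isotonic_regression(np.asarray(powers)[order],
                              weights=np.asarray(weights)[order], increasing=True)
    out = np.empty(len(ns))
    out[order] = res.x
    return out


def search_sample_size(
    power_fn: Callable[[int], PowerEstimate],
    bracket: tuple[int, int],
    target_power: float,
    resolution: int | None = None,
    grid_points: int = 8,
) -> SampleSizeResult:
    """Coarse grid + bisection search for the smallest n reaching a power.

    Evaluates ``power_fn`` on a geometric grid across ``bracket``, smooths
    the Monte-Carlo power curve isotonically (power cannot genuinely fall
    as n grows), then bisects between the last sub-target and first
    at-target grid points down to ``resolution`` (default: 2% of the
    bracket width, floor 10).  All evaluated sizes are snapped to multiples
    of the resolution; the reported n is the smallest evaluated size whose
    smoothed power reaches the target.
    """
    if not 0.0 < target_power < 1.0:
        if target_power <= 0.0:
            est = power_fn(bracket[0])
            return SampleSizeResult(bracket[0], est.power, est.mc_se,
                                    target_power, True,
                                    pd.DataFrame({"n": [bracket[0]],
                                                  "power": [est.power]}))
        raise InvalidConfigurationError("target_power must be in (0, 1)")
    lo, hi = int(bracket[0]), int(bracket[1])
    if hi <= lo:
        raise InvalidConfigurationError("bracket must satisfy lo < hi")
    if resolution is None:
        # 2% of the bracket width, floored at 10 and rounded to tens
        resolution = max(10, int(round(0.02 * (hi - lo) / 10.0)) * 10)

    ns: list[int] = []
    powers: list[float] = []
    ses: list[float] = []
    weights: list[float] = []

    def evaluate(n: int) -> None:
        if n in ns:
            return
        est = power_fn(n)
        ns.append(n)
        powers.append(est.power)
        ses.append(est.mc_se)
        weights.append(max(est.n_used, 1))

    grid = np.unique(
        [_snap(v, resolution, lo, hi)
         for v in np.geomspace(max(lo, resolution), hi, grid_points)]
        + [lo, hi]
    )
    for n in grid:
        evaluate(int(n))

    def crossing() -> tuple[int | None, int | None]:
        smooth = _smoothed(ns, powers, weights)
        order = np.argsort(ns)
        sorted_ns = np.asarray(ns)[order]
        sorted_sm = smooth[order]
        above = np.flatnonzero(sorted_sm >= target_power)
        if len(above) == 0:
            return None, None
        k = above[0]
        hi_n = int(sorted_ns[k])
        lo_n = int(sorted_ns[k - 1]) if k > 0 else None
        return lo_n, hi_n

    lo_n, hi_n = crossing()
    if hi_n is None:
        smooth = _smoothed(ns, powers, weights)
        i_max = int(np.argmax(ns))
        return SampleSizeResult(
            n=max(ns), power=float(smooth[i_max]), mc_se=ses[i_max],
            target_power=target_power, reached=False,
            evaluations=pd.DataFrame({"n": ns, "power": powers, "mc_se": ses}),
        )
    while lo_n is not None and hi_n - lo_n > resolution:
        mid = _snap((lo_n + hi_n) / 2.0, resolution, lo, hi)
        if mid <= lo_n or mid >= hi_n:
            break
        evaluate(mid)
        lo_n, hi_n = crossing()
        if hi_n is None:  # smoothing moved the crossing beyond the bracket
            lo_n, hi_n = max(ns), None
            break
    smooth = _smoothed(ns, powers, weights)
    evals = pd.DataFrame({"n": ns, "power": powers, "mc_se": ses,
                          "smoothed": smooth}).sort_values("n", ignore_index=True)
    if hi_n is None:
        i_max = evals["n"].idxmax()
        return SampleSizeResult(
            n=int(evals.loc[i_max, "n"]), power=float(evals.loc[i_max, "smoothed"]),
            mc_se=float(evals.loc[i_max, "mc_se"]), target_power=target_power,
            reached=False, evaluations=evals,
        )
    row = evals[evals["n"] == hi_n].iloc[0]
    return SampleSizeResult(
        n=int(hi_n), power=float(row["smoothed"]), mc_se=float(row["mc_se"]),
        target_power=target_power, reached=True, evaluations=evals,
    )


def find_sample_size(
    cfg: ScenarioConfig,
    target_power: float = 0.8,
    bracket: tuple[int, int] | None = None,
    iterations_per_point: int | None = None,
    resolution: int | None = None,
) -> SampleSizeResult:
    """Smallest trial size whose Monte-Carlo power reaches ``target_power``.

    Wraps :func:`search_sample_size` around :func:`estimate_power`,
    re-estimating power at each candidate n with ``iterations_per_point``
    iterations (default: the scenario's iteration count).  The bracket
    defaults to (50, frame_size); an unreachable target is reported in the
    result, not raised.
    """
    if bracket is None:
        bracket = (min(50, cfg.frame_size), cfg.frame_size)
    iters = iterations_per_point or cfg.iterations

    def power_fn(n: int) -> PowerEstimate:
        return estimate_power(replace(cfg, n_trial=n, iterations=iters))

    return search_sample_size(power_fn, bracket, target_power,
                              resolution=resolution)
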