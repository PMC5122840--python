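"""Genotype simulation under Hardy-Weinberg equilibrium and unweighted
genetic risk scores.

A trial scenario is built around a fixed panel of unlinked SNPs
(:class:`SNPPanel`): each locus has an effect-allele frequency, a marginal
effect on the outcome, and a gene x treatment interaction effect.  Genotypes
are simulated as effect-allele counts, ``Binomial(2, p_j)`` per locus
(Hardy-Weinberg), and the genetic risk score (GRS) of an individual is the
unweighted sum of effect-allele counts across the panel, so a k-SNP GRS
ranges over 0..2k.

Effects are interpreted on the scale of the outcome model that consumes
them: log-hazard units per allele for time-to-event outcomes, outcome units
per allele for quantitative outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError

__all__ = [
    "SNPPanel",
    "draw_panel",
    "sample_genotypes",
    "compute_grs",
    "load_panel",
    "save_panel",
]


@dataclass(frozen=True)
class SNPPanel:
    """A fixed panel of unlinked SNPs with per-allele effects.

    Parameters
    ----------
    freqs
        Effect-allele frequencies, one per SNP, each strictly in (0, 1).
        The effect allele is the risk/response allele.
    beta_main
        Per-allele marginal effects (log-hazard or outcome units).
    beta_int
        Per-allele gene x treatment interaction effects, same scale.
    """

    freqs: np.ndarray
    beta_main: np.ndarray
    beta_int: np.ndarray

    def __post_init__(self):
        freqs = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        beta_main = np.atleast_1d(np.asarray(self.beta_main, dtype=float))
        beta_int = np.atleast_1d(np.asarray(self.beta_int, dtype=float))
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "beta_main", beta_main)
        object.__setattr__(self, "beta_int", beta_int)
        if freqs.ndim != 1 or len(freqs) < 1:
            raise InvalidConfigurationError("panel must contain at least one SNP")
        if not (len(freqs) == len(beta_main) == len(beta_int)):
            raise InvalidConfigurationError(
                "freqs, beta_main and beta_int must have equal length"
            )
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise InvalidConfigurationError(
                "allele frequencies must lie strictly in (0, 1)"
            )
        if not (np.all(np.isfinite(beta_main)) and np.all(np.isfinite(beta_int))):
            raise InvalidConfigurationError("effect sizes must be finite")

    @property
    def k(self) -> int:
        """Number of SNPs in the panel."""
        return len(self.freqs)

    @property
    def grs_mean(self) -> float:
        """Population mean of the unweighted GRS, sum of 2 p_j."""
        return float(np.sum(2.0 * self.freqs))

    @property
    def grs_var(self) -> float:
        """Population variance of the GRS, sum of 2 p_j (1 - p_j)."""
        return float(np.sum(2.0 * self.freqs * (1.0 - self.freqs)))


def _check_interval(name: str, interval, lo_open: float | None = None,
                    hi: float | None = None) -> tuple[float, float]:
    a, b = float(interval[0]), float(interval[1])
    if b < a:
        raise InvalidConfigurationError(f"{name} interval {interval} is inverted")
    if lo_open is not None and a <= lo_open:
        raise InvalidConfigurationError(f"{name} lower bound must exceed {lo_open}")
    if hi is not None and b >= hi:
        raise InvalidConfigurationError(f"{name} upper bound must be below {hi}")
    return a, b


def draw_panel(
    k: int,
    maf_range: tuple[float, float],
    effect_range: tuple[float, float],
    direction: str = "protective",
    rng: np.random.Generator | None = None,
    beta_main: float | np.ndarray = 0.0,
) -> SNPPanel:
    """Draw a random SNP panel for a scenario family.

    Frequencies are drawn uniformly within ``maf_range`` and absolute
    interaction effects uniformly within ``effect_range``, independently per
    SNP.  ``direction='protective'`` makes interactions negative (treatment
    benefit grows with allele count, hazard ratio < 1); ``'adverse'`` makes
    them positive.  Marginal effects default to 0 so the interaction is the
    only genetic signal; pass ``beta_main`` to override.

    The panel is intended to be drawn once per scenario and held fixed
    across Monte-Carlo iterations: power is conditional on one hypothesized
    genetic architecture.
    """
    if k < 1:
        raise InvalidConfigurationError("k must be >= 1")
    if direction not in ("protective", "adverse"):
        raise InvalidConfigurationError(
            f"direction must be 'protective' or 'adverse', got {direction!r}"
        )
    lo_f, hi_f = _check_interval("maf_range", maf_range, lo_open=0.0, hi=1.0)
    lo_e, hi_e = _check_interval("effect_range", effect_range)
    if rng is None:
        rng = np.random.default_rng()
    freqs = rng.uniform(lo_f, hi_f, size=k)
    effects = rng.uniform(lo_e, hi_e, size=k)
    sign = -1.0 if direction == "protective" else 1.0
    beta_main_vec = np.broadcast_to(np.asarray(beta_main, dtype=float), (k,)).copy()
    return SNPPanel(freqs=freqs, beta_main=beta_main_vec, beta_int=sign * effects)


def sample_genotypes(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate an ``n x k`` matrix of effect-allele counts under HWE.

    Each entry is Binomial(2, p_j): the sum of two independent allele draws,
    which is exactly the Hardy-Weinberg genotype distribution
    (q^2, 2pq, p^2).  Columns (loci) are mutually independent, i.e. loci are
    unlinked.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if n < 1:
        raise InvalidConfigurationError("n must be >= 1")
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise InvalidConfigurationError(
            "allele frequencies must lie strictly in (0, 1)"
        )
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)


def compute_grs(genotypes: np.ndarray) -> np.ndarray:
    """Unweighted genetic risk score: per-individual sum of allele counts."""
    genotypes = np.asarray(genotypes)
    if genotypes.size == 0:
        raise InvalidConfigurationError("genotype matrix is empty")
    return genotypes.sum(axis=1, dtype=np.int64)


_PANEL_COLUMNS = ["snp_id", "eaf", "beta_main", "beta_int"]


def load_panel(path: str | Path) -> SNPPanel:
    """Load a panel from a tab-separated file.

    Expected header: ``snp_id  eaf  beta_main  beta_int``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidConfigurationError(
            f"panel file {path} is missing columns {missing}"
        )
    return SNPPanel(
        freqs=df["eaf"].to_numpy(float),
        beta_main=df["beta_main"].to_numpy(float),
        beta_int=df["beta_int"].to_numpy(float),
    )


def save_panel(panel: SNPPanel, path: str | Path) -> None:
    """Write a panel as the tab-separated interchange format."""
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(panel.k)],
            "eaf": panel.freqs,
            "beta_main": panel.beta_main,
            "beta_int": panel.beta_int,
        }
    )
    df.to_csv(path, sep="\t", index=False)
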