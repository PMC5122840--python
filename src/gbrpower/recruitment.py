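"""Sampling frames and trial recruitment.

Two recruitment designs are compared throughout the package:

* **conventional** -- a simple random sample from the genotyped frame, the
  usual RCT situation where genotype plays no role in who is enrolled;
* **genotype-based recall (GBR)** -- participants are recalled from the two
  extremes of the frame's GRS distribution, taking the single most extreme
  individual from each tail first and working inwards until the target size
  is reached, so no explicit GRS cut-point exists.

Recalled cohorts are then randomized 1:1 to active treatment and placebo;
GBR cohorts are randomized within each tail so that tail membership cannot
confound the arm contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InfeasibleDesignError, InvalidConfigurationError
from .genetics import SNPPanel, compute_grs, sample_genotypes

__all__ = [
    "SamplingFrame",
    "TrialCohort",
    "build_frame",
    "recruit_conventional",
    "recruit_gbr",
    "randomize_arms",
    "cohort_table",
]

TAIL_NA, TAIL_LOW, TAIL_HIGH = 0, 1, 2
_TAIL_LABEL = {TAIL_NA: "na", TAIL_LOW: "low", TAIL_HIGH: "high"}


@dataclass(frozen=True)
class SamplingFrame:
    """A genotyped population from which trials recruit.

    ``genotypes`` is the frame_size x k allele-count matrix and ``grs`` the
    per-individual unweighted risk score (recomputable from the genotypes).
    """

    genotypes: np.ndarray
    grs: np.ndarray

    @property
    def frame_size(self) -> int:
        return self.genotypes.shape[0]


@dataclass(frozen=True)
class TrialCohort:
    """Participants selected from a frame, optionally randomized to arms.

    ``indices`` are unique frame row numbers; ``tail`` marks GBR tail
    membership (low/high) or ``na`` for conventional recruits; ``arm`` is
    None before randomization, afterwards a 0/1 vector (1 = active).
    """

    indices: np.ndarray
    genotypes: np.ndarray
    grs: np.ndarray
    tail: np.ndarray
    arm: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.indices)


def build_frame(
    panel: SNPPanel, frame_size: int, rng: np.random.Generator
) -> SamplingFrame:
    """Simulate a sampling frame of HWE genotypes with precomputed GRS."""
    if frame_size < 2:
        raise InvalidConfigurationError("frame_size must be >= 2")
    genotypes = sample_genotypes(panel.freqs, frame_size, rng)
    return SamplingFrame(genotypes=genotypes, grs=compute_grs(genotypes))


def _check_n(frame: SamplingFrame, n: int) -> None:
    if n < 1:
        raise InfeasibleDesignError("trial size must be >= 1")
    if n > frame.frame_size:
        raise InfeasibleDesignError(
            f"trial size {n} exceeds sampling frame of {frame.frame_size}"
        )


def recruit_conventional(
    frame: SamplingFrame, n: int, rng: np.random.Generator
) -> TrialCohort:
    """Simple random sample of ``n`` individuals without replacement.

    The cohort's GRS distribution is an unbiased draw from the frame's.
    """
    _check_n(frame, n)
    idx = rng.choice(frame.frame_size, size=n, replace=False)
    return TrialCohort(
        indices=idx,
        genotypes=frame.genotypes[idx],
        grs=frame.grs[idx],
        tail=np.full(n, TAIL_NA, dtype=np.int8),
    )


def recruit_gbr(frame: SamplingFrame, n: int) -> TrialCohort:
    """Recall the ``n`` most extreme individuals from the GRS tails.

    Takes ceil(n/2) from the low tail and floor(n/2) from the high tail,
    starting at the most extreme point of each tail and working inwards; no
    explicit cut-point is used.  Ties at equal GRS are broken by frame index
    (stable sort), so the operation is deterministic and idempotent given a
    frame.  For a single-SNP panel the "GRS" is the allele count, so the
    recall recruits homozygotes first from each end, equilibrating allele
    frequencies in the cohort.
    """
    _check_n(frame, n)
    order = np.argsort(frame.grs, kind="stable")
    n_low = (n + 1) // 2
    n_high = n // 2
    low = order[:n_low]
    high = order[len(order) - n_high:] if n_high else order[:0]
    idx = np.concatenate([low, high])
    tail = np.concatenate(
        [np.full(n_low, TAIL_LOW, dtype=np.int8), np.full(n_high, TAIL_HIGH, dtype=np.int8)]
    )
    return TrialCohort(
        indices=idx,
        genotypes=frame.genotypes[idx],
        grs=frame.grs[idx],
        tail=tail,
    )


def randomize_arms(cohort: TrialCohort, rng: np.random.Generator) -> TrialCohort:
    """1:1 permuted allocation to active treatment (1) and placebo (0).

    Overall arm sizes differ by at most one.  GBR cohorts are randomized
    within each tail so each tail is itself split 1:1 between arms;
    leftover participants from odd-sized strata are alternated between arms
    to preserve the overall balance.
    """
    if cohort.n < 2:
        raise InvalidConfigurationError("cannot randomize fewer than 2 participants")
    arm = np.zeros(cohort.n, dtype=np.int8)
    strata = [TAIL_LOW, TAIL_HIGH] if np.any(cohort.tail != TAIL_NA) else [TAIL_NA]
    extra_to_active = True
    for s in strata:
        members = np.flatnonzero(cohort.tail == s)
        if len(members) == 0:
            continue
        n_active = len(members) // 2
        if len(members) % 2 == 1:
            if extra_to_active:
                n_active += 1
            extra_to_active = not extra_to_active
        chosen = rng.permutation(members)[:n_active]
        arm[chosen] = 1
    return replace(cohort, arm=arm)


def cohort_table(cohort: TrialCohort) -> pd.DataFrame:
    """Cohort as the tab-separable export table: id, grs, tail, arm."""
    return pd.DataFrame(
        {
            "id": cohort.indices,
            "grs": cohort.grs,
            "tail": [_TAIL_LABEL[t] for t in cohort.tail],
            "arm": cohort.arm if cohort.arm is not None else np.full(cohort.n, -1),
        }
    )


def export_cohort(cohort: TrialCohort, path: str | Path) -> None:
    cohort_table(cohort).to_csv(path, sep="\t", index=False)
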