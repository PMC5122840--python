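"""Scenario presets emulating the Diabetes Prevention Program (DPP) examples.

Two published gene-treatment interactions anchor the package's worked
examples:

* ``dpp-metformin-slc47a1`` -- the rs8065082 variant at *SLC47A1* (a
  metformin-transporter locus), effect-allele frequency 0.44, per-allele
  interaction hazard ratio 0.68 with metformin vs placebo on type 2
  diabetes incidence; 37% overall incidence by the 4-year study endpoint;
  sampling frame of 31,000 (the number screened for the DPP); trial size
  2,155 (the metformin + placebo arms).
* ``dpp-ili-grs32`` -- a 32-SNP unweighted genetic risk score interacting
  with intensive lifestyle intervention (vs placebo) on 1-year change in
  small LDL particles, 0.03 nmol/l per risk allele.  The source
  publication does not list the 32 risk-allele frequencies, so the preset
  draws them uniformly from [0.2, 0.5] with a fixed panel seed; the
  residual SD of the outcome is likewise unpublished and defaults to 1.0
  nmol/l.

Marginal SNP effects and the treatment main effect default to zero in both
presets (interaction-only generation); both are ordinary config knobs.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InvalidConfigurationError
from .genetics import SNPPanel, draw_panel
from .power import ScenarioConfig

__all__ = ["PRESETS", "get_preset", "list_presets"]

_GRS32_PANEL_SEED = 320044  # fixes the stand-in frequency draw


def _dpp_metformin(design: str = "conventional", **overrides) -> ScenarioConfig:
    base = dict(
        frame_size=31_000,
        n_trial=2_155,
        design=design,
        outcome="survival",
        panel=SNPPanel(
            freqs=np.array([0.44]),
            beta_main=np.array([0.0]),
            beta_int=np.array([math.log(0.68)]),
        ),
        followup=4.0,
        target_incidence=0.37,
        treatment_main=0.0,
        alpha=0.05,
        iterations=1000,
        seed=0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def _dpp_ili_grs32(design: str = "conventional", **overrides) -> ScenarioConfig:
    panel = draw_panel(
        k=32,
        maf_range=(0.2, 0.5),
        effect_range=(0.03, 0.03),
        direction="adverse",
        rng=np.random.default_rng(_GRS32_PANEL_SEED),
    )
    base = dict(
        frame_size=31_000,
        n_trial=1_909,
        design=design,
        outcome="quantitative",
        panel=panel,
        treatment_main=0.0,
        resid_sd=1.0,
        alpha=0.05,
        iterations=1000,
        seed=0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


PRESETS = {
    "dpp-metformin-slc47a1": _dpp_metformin,
    "dpp-ili-grs32": _dpp_ili_grs32,
}

_DESCRIPTIONS = {
    "dpp-metformin-slc47a1": (
        "Single SNP (EAF 0.44) x metformin on diabetes incidence; "
        "interaction HR 0.68; 37% incidence over 4 y; frame 31,000; n 2,155"
    ),
    "dpp-ili-grs32": (
        "32-SNP GRS x intensive lifestyle on 1-yr small-LDL change; "
        "0.03 nmol/l per allele; frame 31,000"
    ),
}


def get_preset(name: str, **overrides) -> ScenarioConfig:
    """Instantiate a preset scenario, optionally overriding any field."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise InvalidConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory(**overrides)


def list_presets() -> dict[str, str]:
    """Preset names with one-line descriptions."""
    return dict(_DESCRIPTIONS)
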