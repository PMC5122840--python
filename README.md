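# gbrpower

Monte-Carlo power and sample-size calculations for gene × treatment
interaction tests in randomized controlled trials (RCTs), comparing two
recruitment designs:

* **conventional recruitment** — participants are randomly sampled from a
  genotyped sampling frame, as in an ordinary trial, and genotype is only
  used at analysis time;
* **genotype-based recall (GBR)** — participants are recalled from the two
  extremes of the frame's genetic-risk-score (GRS) distribution, starting
  from the single most extreme individual in each tail and working inwards,
  which maximizes the genetic contrast between the recalled groups.

The package is aimed at trialists and genetic epidemiologists designing
validation studies of gene–drug or gene–lifestyle interactions (e.g.
pharmacogenetic effects on type 2 diabetes incidence), where conventional
Phase III trials are typically underpowered for the interaction term.

## Model

A scenario fixes a panel of *k* unlinked SNPs with effect-allele
frequencies *p_j*, marginal per-allele effects *β_main,j* and per-allele
interaction effects *β_int,j*. Genotypes *g_ij* ∈ {0, 1, 2} are simulated
under Hardy-Weinberg equilibrium (Binomial(2, *p_j*)) and the unweighted
GRS is Σ_j *g_ij* ∈ [0, 2k]. Each Monte-Carlo iteration simulates a fresh
frame, recruits a trial of size *n* by one of the two designs, randomizes
1:1 (stratified by GRS tail under GBR), and generates the outcome from the
linear predictor

    xβ_i = β_trt·arm_i + Σ_j β_main,j·g_ij + Σ_j β_int,j·g_ij·arm_i

**Time-to-event outcomes** use the inverse-cumulative-hazard transform with
an exponential baseline: *T_i* = −ln(*U_i*) / (λ₀·e^{xβ_i}), administrative
censoring at end of follow-up, and λ₀ calibrated so the population event
proportion at the study endpoint matches a target incidence (default 37% at
4 years). The analysis model is a Cox proportional-hazards regression on
{GRS, arm, GRS × arm} (Breslow ties, Wald test of the interaction).

**Quantitative outcomes** are generated linearly with Gaussian noise and
analysed by OLS on {1, GRS, arm, GRS × arm}; outcome measurement error is
additive classical error tuned to a reliability r² (the squared correlation
between the error-prone and criterion measure).

Power is estimated by the **Zero/One method** — the fraction of iterations
with interaction p < α — and, for linear models, cross-checked by the
**Standard-Error method**, Φ(|γ̄|/SE(γ)̄ − z₁₋α/₂) with the effect and its
standard error averaged across iterations. Minimum sample sizes are found
by a coarse-grid + bisection search on *n* with isotonic smoothing of the
Monte-Carlo power curve.

## Worked example

The `dpp-metformin-slc47a1` preset encodes a published single-SNP
pharmacogenetic scenario: effect-allele frequency 0.44, per-allele
interaction hazard ratio 0.68 between the variant and metformin (vs
placebo) on diabetes incidence, 37% overall incidence over 4 years of
follow-up, a sampling frame of 31,000 and a trial of 2,155.

```sh
gbr-power run -c examples/dpp_metformin.yaml -o out/
```

prints nothing on success and writes `out/power_curve.tsv`:

```
scenario   design        n     power  mc_se   mean_gamma  mean_se_gamma
dpp_power  conventional  2155  0.967  0.0056  -0.390      0.104
```

i.e. at the trial's actual size the interaction test has 96.7% ± 0.6%
simulated power; the mean fitted interaction log-hazard −0.390 recovers the
generating value ln(0.68) = −0.386. `out/sample_size.tsv` holds the
80%-power sample-size searches from the same run:

```
scenario              design        n     power_at_n  reached
dpp_gbr_n80           gbr           620   0.83        True
dpp_conventional_n80  conventional  1240  0.82        True
```

Recalling from the extremes of the genotype distribution roughly halves the
required trial (620 vs 1,240 participants) because the recalled cohort is
enriched for homozygotes, doubling the genotype variance that the
interaction test feeds on. `examples/cox_grid.yaml` shows the grid runner
crossing both designs with the four MAF × effect-size scenario families.

Python API equivalent:

```python
from gbrpower import get_preset, estimate_power, find_sample_size

est = estimate_power(get_preset("dpp-metformin-slc47a1", seed=1))
res = find_sample_size(get_preset("dpp-metformin-slc47a1", design="gbr", seed=1),
                       target_power=0.8, iterations_per_point=300)
```

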