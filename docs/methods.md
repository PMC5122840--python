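# Methods

## The estimand

For a two-arm RCT testing a gene × treatment interaction, the quantity of
interest is the Monte-Carlo power of the two-sided Wald test of the
interaction coefficient γ at significance level α (default 0.05), and its
inverse: the smallest trial size *n* whose power reaches a target (default
80%). Power is always conditional on one hypothesized genetic architecture
— a fixed SNP panel — exactly as a real recall trial is designed around one
pre-specified score.

## Genetic model

Genotypes are effect-allele counts simulated under Hardy-Weinberg
equilibrium, Binomial(2, p_j) per locus, loci unlinked. The GRS is the
unweighted allele-count sum, so for k SNPs it ranges over 0..2k with
population mean Σ2p_j and variance Σ2p_j(1−p_j); for 20 common SNPs it is
close to normal (the test suite checks |skew| < 0.1 at n = 10⁵). Linkage
disequilibrium with an untyped functional variant is not modelled; recalling
on a proxy behaves like exposure measurement error and is out of scope.

Panels for scenario families are drawn once per scenario — frequencies
uniform in the family's MAF range, |interaction| uniform in its effect
range, signed protective (hazard ratio < 1 under treatment) unless
configured otherwise — and reused across all iterations. Marginal SNP
effects and the treatment main effect default to 0 so the interaction is the
only signal; both are ordinary configuration knobs. This interaction-only
default is the most reproducible null choice and isolates the quantity
under test, but it matters when comparing against published figures (see
Limitations).

## Recruitment designs

*Conventional*: simple random sampling without replacement from the frame.
*GBR*: the ⌈n/2⌉ lowest-GRS and ⌊n/2⌋ highest-GRS members of the frame
(ties broken by frame index; the extra participant under odd n goes to the
low tail — an arbitrary but fixed convention). The selection is
deterministic given the frame, which makes the design's power gain purely a
function of frame size: a larger frame has more extreme tails, so the
recalled groups are more genetically distinct. Randomization is 1:1
permuted allocation, stratified by tail for GBR so tail membership cannot
confound the arm contrast (odd strata alternate their leftover between
arms). Eligibility screening and genotype-associated dropout are not
modelled; every frame member is assumed recruitable.

## Outcome models

**Survival.** Event times follow T = −ln(U)/(λ₀·e^{xβ}) with U ~ U(0,1) —
the inverse-transform construction for a proportional-hazards model with
exponential baseline — and administrative censoring at end of follow-up
(default 4.0 years; no dropout, so event = 0 iff time = follow-up). The
exponential family is the canonical choice here: it has a closed-form
inverse and is exactly identified by the single calibration constraint.
λ₀ is calibrated by Brent root-finding (relative tolerance 10⁻⁸) so that
the mean event probability at end of follow-up equals the target incidence
(default 0.37), evaluated on a dedicated calibration frame with every
member counted once per arm at equal weight. Incidence is thus a population
property: λ₀ is fixed per scenario, and a GBR cohort's realized event
fraction may legitimately differ from the target.

**Quantitative.** y = xβ + ε with ε ~ N(0, resid_sd²). The residual SD
defaults to 1.0 outcome-unit; any absolute sample-size figure for a
quantitative scenario is only meaningful relative to this choice.
resid_sd = 0 is accepted as the noiseless limit. Measurement error is
additive classical error on the outcome only, with variance
Var(y_true)·(1−r²)/r² so the squared observed-true correlation equals r²
(0.8 / 0.6 / 0.4 ≈ high / moderate / low assessment precision).

## Analysis models

Both analysis models use the aggregate GRS — covariates {GRS, arm,
GRS × arm} — even though data are generated per SNP. The mismatch is
intentional: it mirrors how such trials are analysed. The Cox partial
likelihood is maximized by a vectorized Newton-Raphson solver (Breslow
ties, step-halving, convergence when the update falls below 10⁻⁹;
|β| > 50 is treated as monotone likelihood). Wald SEs come from the inverse
observed information, re-expanded at the final estimate. Ties among event
times are measure-zero under the continuous-time generator, so the Breslow
choice is inconsequential but fixed. The linear model is OLS (statsmodels)
with the usual unbiased residual-variance SE and a t-reference p-value.
Fits that fail (non-convergence, separation, no events in an arm,
zero-variance GRS) are dropped from both numerator and denominator of
power; their count is reported, and a scenario with > 20% such fits is
flagged unreliable.

## Power estimation and sample-size search

The Zero/One estimator counts iterations with p strictly below α; its
Monte-Carlo SE is binomial. 1,000 iterations is the default; searches use
fewer per grid point (the acceptance script uses 300) since the isotonic
smoothing pools information across grid points. The Standard-Error method
averages γ and SE(γ) separately across iterations before forming
Φ(|γ̄|/SE̅ − z₁₋α/₂), following the method's literal description; for linear
models the two estimators agree within Monte-Carlo error and the test suite
asserts agreement within 0.02 at 1,000 iterations.

The minimum-n search evaluates a geometric grid across the bracket
(default 50..frame size), applies weighted isotonic regression to the
(n, power) points — power is monotone in n, so smoothing strictly reduces
Monte-Carlo noise without bias at the crossing — then bisects between the
bracketing grid points to a resolution of 2% of the bracket width (floored
at 10 and rounded to tens). Candidate sizes are snapped to multiples of the
resolution; the reported n is the smallest evaluated size whose smoothed
power reaches the target. An unreachable target is reported as a flagged
result, not an exception.

## Randomness and reproducibility

One master seed per scenario; the panel draw, the calibration frame and
each iteration get independent child streams via numpy `SeedSequence`
spawn keys (a counter-based derivation), so results are independent of
execution order and bit-reproducible for a fixed seed — the CLI manifest
plus seed reproduces every output file identically.

## What the simulations do and do not show

The generator emulates the study conditions of the motivating trial
scenarios: HWE genotypes, interaction-only effects, exponential event
times calibrated to an overall incidence, administrative censoring,
classical outcome error. It does not emulate staggered entry or
interval-detected events, competing risks, eligibility screening (a real
frame of 31,000 yielded only ~10% eligible participants),
genotype-associated retention, LD, or non-additive genotype coding.
Passing tests therefore demonstrate the *comparative* properties of the
designs — GBR ≥ conventional power at matched size, GBR's gain growing
with frame size, conventional power invariant to frame size, power
degrading with outcome reliability — and internal statistical correctness
(type-I error at α, estimator consistency, oracle-verified fits), not that
any absolute sample size transfers to a specific real trial.

On that last point: with additive (0/1/2) genotype coding and
interaction-only generation, these simulations are systematically more
optimistic than the published power figures for the same named scenarios
(e.g. ~96% rather than ~61% power for the single-SNP metformin scenario at
n = 2,155, and correspondingly smaller minimum sample sizes, roughly a
factor 2.5–3 in n). A Fisher-information calculation shows the published
figures correspond to an interaction SE of ≈ 0.17 at that size, which an
additive per-allele contrast with ~800 events cannot produce; a
lower-variance genotype contrast (dominant or recessive coding) does.
Since the additive allele-count score is the package's specified and
documented model, the discrepancy is reported rather than papered over:
the comparative conclusions are unaffected (the GBR-to-conventional
sample-size ratios agree), but absolute published sample sizes for the
small-effect scenario families are outside this package's reproduction
tolerance. The large-effect family sizes (e.g. ~390 GBR / ~650
conventional at frame 10,000) do reproduce approximately.

## Problem sizes

Defaults were chosen so a full acceptance run is a desk-scale computation:
1,000 iterations for single power estimates, 300 per grid point in
searches, frames of 10,000–31,000, trials up to the frame size. All
figures in the README come from runs at exactly these sizes.
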