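# Methods

This note documents the models, numerical choices and known limitations of
`rlddm`, in the spirit of a model-documentation page for a statistical
package: what is computed, under which assumptions, and what the synthetic
benchmarks do and do not establish.

## Task and generative model

The simulated task is a stationary probabilistic selection task: 60 trials,
two stimulus pairs interleaved in randomized order (30 trials per pair),
one option per pair reinforced on 80% of its choices and the other on 20%,
binary feedback (reward coded 1, no reward 0), and a 3-second response
deadline. Rewards are drawn i.i.d. Bernoulli per trial; there is no yoked
feedback across participants. A simulated decision slower than the deadline
is recorded as a non-response with no feedback and no value update.

Agents learn Q-values (initialized at 0.5, the midpoint of the unit reward
scale) by the delta rule, with either one learning rate or two (split by
prediction-error sign). Learning rates live on a raw standard-normal scale
in [−3, 3] and are mapped to (0, 1) through the standard-normal CDF Φ — the
usual probit device that keeps the sampled space unbounded-ish while the
effective rate stays a probability. Decisions come from a Wiener diffusion
with unit noise (s = 1; all parameter magnitudes presuppose this scale),
start fraction fixed at z = 0.5 (options appear on randomized sides, so an
a-priori bias toward the optimal boundary is not meaningful), drift linear
in the Q-value difference, and optional power-function trajectories
`x_t = x0 * t^x_exp` for boundary separation and non-decision time. The
power functions use the global 1-based trial index — they model
time-on-task effects (fatigue, impatience, practice) that accrue over the
whole experiment, so excluded trials advance the clock but contribute no
likelihood term.

### Group presets

The two generating presets encode the qualitative group structure the
package is designed to study — the gambling preset has a lower non-decision
offset (0.37 vs 0.50 s), a more negative threshold decay exponent (−0.16 vs
−0.08) and a weaker drift scaling (2.7 vs 4.5) than the control preset, with
small differences in the same direction for the remaining parameters. The
values were chosen once, before any test was frozen, to produce realistic
behavior (≈ 0.79 vs ≈ 0.67 accuracy, sub-second median RTs, < 0.1%
non-response) while staying inside all prior supports. Subject-level
parameters are drawn from Gaussians truncated to the admissible supports so
that simulation and inference share identical supports.

## Preprocessing

Suboptimal-choice RTs are multiplied by −1 (the signed-RT convention: the
likelihood's upper boundary is the optimal choice). Non-response trials are
excluded, and per participant the fastest `floor(0.05 * n_responded)`
responded trials are discarded, ties broken by stable trial order. The
filter protects the non-decision time from leading-edge outliers; it also
truncates the likelihood's left tail without renormalization, which is a
deliberate property of the procedure being modeled — large-n profile checks
show the small resulting biases (a few percent on `t0`/`a0`). The filter is
applied among responded trials only, is idempotent (it recomputes from raw
columns), and excluded-but-responded trials still drive Q-value updates by
default (the participant saw that feedback); this is configurable.

## First-passage density and samplers

The signed-RT log density uses the standard dual series representation of
the Wiener first-passage density (small-time and large-time expansions),
choosing per evaluation the expansion needing fewer terms for a truncation
error ≤ 1e-10 in normalized time — well below 1e-7 absolute over the
supports used here. Lower-boundary densities are obtained from the
reflection identity (v → −v, z → 1 − z). RTs at or below the non-decision
time have density zero (log density −inf) by default; a configurable tiny
density floor exists for sampler robustness and is off by default. During
fitting, chains are initialized with each subject's `t0` below their minimum
retained |RT|, which is what the fastest-5% filter is there to protect.

Two samplers are provided. The default inverse-CDF sampler draws the
boundary from the closed-form absorption probability
(P(upper) = 1/(1+e^{−αv}) at z = 0.5) and inverts the conditional CDF by
trapezoid integration of the density (step ≈ α²/400, clamped to
[1e-6, 1e-2]); it is exact up to quadrature error (KS distance ~3e-3 at
n = 10⁵ against the integrated density). The independent oracle is an
Euler–Maruyama path simulator (default dt = 1e-4) with the
Broadie–Glasserman–Kou continuity correction (boundaries shifted inward by
0.5826·√dt) to remove the O(√dt) discrete-monitoring bias; the two routes
agree in distribution and against the density.

## Hierarchical estimation

Each group is fit separately (never pooled): subject parameters are
Normal(μ_p, σ_p) truncated to the admissible supports; group means and SDs
have uniform priors — α₀: U(.01, 5); α_exp, τ_exp, η±: U(−3, 3); τ₀:
U(0.1, 2); v_coeff: U(−100, 100); σ priors U(.0001, 2) (U(.0001, 10) for
v_coeff, U(.0001, 4) for η±). The null model's constant drift uses the
v_coeff support. The subject-level truncation for τ₀ is (0.01, 2), slightly
wider than the group-mean prior. The subject-level link (truncation rather
than transformation) is the minimal-assumption reading of a bounded
Gaussian hierarchy and is recorded as a config switch.

The sampler is a seeded adaptive Metropolis-within-Gibbs kernel
(JIT-compiled): per sweep it updates every active scalar subject parameter,
then three kinds of correlated subject-level moves, then the group means
and SDs (whose truncated-normal normalization term is included, as it
depends on μ and σ). The correlated moves address the posterior's known
ridges at this trial count:

- anchored (offset, exponent) moves for the two power-function pairs —
  shift the exponent and rescale the offset so the trajectory value at the
  log-mean trial index stays fixed (Jacobian included);
- a (learning-rate, drift-scaling) ridge move — shift the raw learning
  rate(s) and rescale v_coeff by the inverse ratio of the transformed
  rates (small rates produce small Q-differences that large scalings
  compensate);
- a blocked proposal over all active parameters with covariance adapted
  from the chain history (Haario-style), scaled toward ~23% acceptance.

Scalar proposal scales adapt toward ~44% acceptance during burn-in only;
retained draws come from a fixed kernel. Initialization is data-informed
(τ0 below min |RT|, drift from accuracy, a coarse per-subject likelihood
grid over (v, η, α₀)), with bounded retries shrinking τ0 if any subject's
initial likelihood is non-finite.

The default configuration is 2 chains, 50k burn-in, thinning 2, 10k
retained draws. The package's scaled-down default for tests and demos
(`MCMCConfig.short()`) is 2 chains, 2k burn-in, 1k retained; the full
configuration is plain config, not different code.

### Known ridge behavior

For noisy, low-accuracy groups the (η, v_coeff) ridge is nearly flat over a
long range under the flat v_coeff prior: chains can equilibrate at very
small learning rates compensated by large drift scalings, and two chains
may disagree (R-hat ≫ 1.01) within short budgets — occasionally even at
20k burn-in. The fits flag this honestly via R-hat; recovery reports
record per-simulation convergence. This is a genuine property of the
model-plus-priors at 57 retained trials per subject, not a numerical
defect; analyses should treat unconverged fits as such.

## Diagnostics and comparison

Split-chain Gelman–Rubin R-hat (no rank normalization) with 1 ≤ R̂ ≤ 1.01
acceptable; bit-identical chains and zero-variance draws return exactly 1
(a duplicated chain carries no between-chain information), and the
statistic is floored at 1. elpd uses PSIS-smoothed importance-sampling LOO
(smoothing via arviz's `psislw`; the lppd/WAIC arithmetic is computed
directly), with WAIC reported on the deviance scale. Comparison tables rank
by −elpd; difference CIs are `diff ± 1.96·SE` over pointwise elpd
differences, omitted for the best model. The HDI is the shortest contiguous
sample interval at the requested mass; for near-flat densities its location
is unstable by nature (only the width is well determined).

Group differences are summarized draw-wise on group-level means (control −
gambling): posterior mean, 95% and 85% HDIs, P(diff > 0), and a directed
Bayes factor defined as the posterior mass ratio P(>0)/P(<0). The source
conventions for the dBF direction conflict between text and table; the
table's direction is the default and the other is available via an
argument.

## Posterior predictive checks

Group-level checks simulate full datasets from randomly selected posterior
draws on each participant's observed pair order (rewards redrawn from the
scheduled rates), then compare binned mean accuracy and RT (bins of ten
trials, pooled over participants) with 2.5/97.5 percentile bands taken
across simulated datasets' bin means — the band construction matches the
way such figures are drawn. Individual-level checks use five equal trial
bins per participant. Empirically the 95% bands capture ~92–93% of observed
bin means when the model is correctly specified at 12 subjects; band
coverage statements in the tests therefore aggregate over several simulated
datasets.

## Recovery harnesses

Parameter recovery simulates datasets from known group-level parameters,
re-fits them with the same machinery, and reports (a) correlations between
generating and estimated subject-level values — pooled across simulations
(default) and per simulation, since pooling across fits that settled at
different ridge positions can understate within-fit recovery — and (b) the
fraction of group-level 95% HDIs containing the generating values. The
subject-level point estimate is the posterior mean (configurable). Model
recovery simulates from one generating model, fits every candidate on
identical trials, ranks by −elpd and counts wins; convergence failures are
recorded per cell, never silently dropped.

## Problem sizes

The test suite and the acceptance script run the full procedures at reduced
scale as the package's own default benchmark conditions: 12 subjects per
group, 60 trials (57 retained), 2 chains with 2k burn-in / 1k retained
(1k/500 for the multi-model recovery sweeps), 3 parameter-recovery and 5
model-recovery simulations, and 300-draw predictive checks. At this scale
the drift scaling, threshold offset and non-decision offset recover with
correlations ≈ 0.5–0.9 and group-mean HDI coverage ≈ 80–90%; learning-rate
parameters are noisier, as expected from 57 trials. The full-scale
configuration (23 subjects, 50k burn-in, 10 and 20 recovery simulations,
1k predictive draws) is reachable through `RunConfig` defaults.

## What the synthetic benchmarks do not show

The generator emulates the task's structure, not real participants: RTs
contain no contaminant processes (lapses, fast guesses beyond the DDM), no
session drift other than the power trajectories, no left/right response
structure, and reward sequences are not yoked across participants. Passing
recovery and predictive checks on these data therefore establishes the
estimation machinery's internal validity — not that the model family is
adequate for any particular empirical dataset. Inter-trial variability
parameters (sv, st, sz), non-linear drift linkages and loss conditions are
out of scope by design.
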