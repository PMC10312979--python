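# Methods

## Model and estimation procedure

Smoking prevalence dynamics are a deterministic cohort-component recursion
on single ages 25–100: each year the entry cohort is seeded as
C[25,t] = γ_t·P[25,t], and every older cohort is last year's cohort one age
younger thinned by smoker mortality μ and the net cessation rate θ
(quits minus relapses). Smokers reaching age 100 exit; there is no terminal
open-ended bin, and no initiation after age 25 (its contribution to adult
prevalence is negligible). Grouped prevalence is smokers over population
summed within each age group.

The three group rates η = (η₁, η₂, η₃) are the hidden state. They follow a
zero-mean random walk; instead of a fixed process-noise covariance we use a
forgetting factor λ: the prior covariance for year t+1 is the year-t
posterior covariance divided by λ (equivalently Q = (1/λ−1)·posterior).
This keeps the filter adaptive to slow drift without committing to a drift
scale.

The measurement update is the second-order Central Difference Kalman
Filter: evaluate the model-to-prevalence map at the prior mean and at
mean ± h·L_i (L a Cholesky factor of the prior covariance), form the
Stirling-interpolation predicted-measurement mean, its covariance plus the
diagonal observation-noise covariance built from the survey standard
errors, and the state–measurement cross covariance, then apply the Kalman
gain. Holding the current smoker counts fixed, the one-year
counts-to-prevalence map is exactly affine in η (every age term is linear
in exactly one η_k), so within a year the CDKF coincides with the exact
Kalman update; nonlinearity enters the problem only through the propagation
of counts with previously estimated rates (dual estimation: counts are
advanced between years with the posterior-mean rates and treated as known).

Timing: the rate labelled year t governs the t→t+1 transition, so its
update consumes the year-(t+1) observation; N observation years produce
N−1 estimated years. A year with no observation gets a predict-only step,
flagged in the trace.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| λ (forgetting factor) | 0.98 | covariance inflation per year; 1 = static parameters. Sensitivity: at the information rate of annual grouped surveys the steady-state measurement weight is ≈1−λ, so λ=0.98 adapts slowly (mean absolute tracking error on a planted ramp roughly halves at λ=0.9); λ is the main dial for drift tracking and is exposed in `FilterConfig`. |
| h (sigma-point step) | √3 | optimal for Gaussian priors in the central-difference family. |
| prior mean / SD | 0.04 / 0.02 per group | weakly informative: annual net cessation rates of a few percent; diagonal. |
| parameter space | natural | rates filtered as proportions, faithful to the additive random walk; sigma points falling outside [0,1] are clipped before evaluation (logged). A logit option exists (`param_space="logit"`) and gives estimates within ~0.01 on the default scenarios. |
| observation noise | diagonal R from the per-group SEs | group estimates come from disjoint respondents, so cross-covariances are taken as zero. |
| weighted-average SD | delta method | Var = wᵀΣw with w the start-of-year smoker shares treated as known; posterior cross-covariances between groups are included via Σ. |
| projection interval | Monte-Carlo percentiles | draws of η from the final posterior, clipped to [0,1], held constant over the horizon; γ held at its last value; schedules flat-extrapolated with a logged warning. A delta-method band would be an alternative; percentiles respect the [0,1] clipping. |

Numerical choices: covariance square roots by Cholesky with escalating
diagonal jitter (logged) and a hard failure beyond 1e-8·scale; posterior
covariances re-symmetrized and eigenvalue-clipped at zero after every
update (repairs logged); rates stored as proportions everywhere and
rendered as percent (two decimals) only in the report table.

## Synthetic data

The generator emulates the structure, not the numeric values, of the real
inputs: an exponentially declining population pyramid (4.2M at 25, ~1.2%/age,
0.3%/yr growth), Gompertz smoker mortality (0.4% at 25, log-slope
0.065/age, clipped at 1), entry-age prevalence starting at 20% drifting
−0.4 pp/yr, initial single-age prevalence log-linear from 21% (25) to 8%
(100), and Gaussian observation noise truncated to [0,1] (truncations
logged; rare at realistic SEs) with per-group SEs of 0.4–0.5 percentage
points — the scale of national-survey grouped prevalence errors. The
default ground truth mirrors the regime of interest: ten observation years,
rates starting near (5.0%, 2.5%, 4.9%) with the middle group ramping
2.5%→4.2% over the nine estimated years. Replicate r of a recovery suite
uses the derived seed SeedSequence([master, r]), recorded in the bundle
metadata; truth is identical across replicates.

What passing recovery tests show — and what they do not: the synthetic
world satisfies the model exactly (no model misspecification, exact
schedules, independent Gaussian noise with known SEs). Success there
demonstrates the estimator's correctness and calibration, not robustness
to survey redesign, correlated sampling error, migration, or mortality
misspecification in real data.

## Identifiability and known limitations

One year of cessation changes grouped prevalence by only about R·Δη, so a
single observation measures a group's rate with standard deviation
≈ SE/R — roughly 2.5 percentage points at a 0.4 pp survey SE and ~16%
prevalence. Consequently single-year estimates lean substantially on the
accumulated prior, the 65+ rate (high mortality, smaller smoker counts,
lower prevalence) is the most weakly identified and shows the strongest
shrinkage toward the prior, and trend detection over a decade is
information-limited: even an oracle straight-line fit to the decade's
yearly measurements detects a 1.7-pp-over-9-years ramp in well under 95%
of replicates at these SEs. The filter's tracking lag scales with 1/(1−λ).

Other limitations: no never/former-smoker compartments and no explicit
relapse (rates are net of relapse by definition); no smoother pass — 
estimates are filtered, real-time quantities; the projection holds rates
and initiation fixed, so its interval understates long-horizon uncertainty.

## Problem sizes

Defaults throughout use the study-scale problem: 76 single ages, 3 groups,
10 observation years; Monte-Carlo checks use 200 replicates (coverage,
trend) or 20 scenarios (fit), and the CDKF–KF equivalence check uses 500
random affine problems of dimension ≤5. The full test suite and the
acceptance script each complete in seconds.
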