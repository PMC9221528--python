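# Methods

## Model

Go reaction times in each trial-type cluster are modelled as Ex-Gaussian,
`ExG(μ, σ, τ) = N(μ, σ²) + Exp(τ)` with all parameters in milliseconds
and `τ` the exponential *mean* (not rate). Under two assumptions —
independence of the type-A and type-B go-RT variables, and the ExG form
for both — the difference `GORT_B − GORT_A` is distributed as the
Asymmetric Laplace Gaussian

`ALG(α1, α2, μ, σ) = AL(α1, α2) + N(μ, σ²)`,  `AL(α1, α2) = Exp(α2) − Exp(α1)`,

with `α1 = τ_A`, `α2 = τ_B`, `μ = μ_B − μ_A`, `σ² = σ_A² + σ_B²`. The
identification argument is through moment generating functions: the MGF
of the difference factors into the AL and Gaussian MGFs on a common open
interval around zero, and an MGF finite on such an interval determines
the law. The same factorisation shows the map is many-to-one: any equal
shift of both `μ`s, or any re-allocation of `σ_A², σ_B²` with the same
sum, yields the identical ALG (`components_equivalent` exercises this).
Consequently the component pair is not recoverable from difference data;
only the four ALG functionals are.

Because the type-A and type-B samples come from different trials, the
independence assumption is a modelling postulate, not a design guarantee;
it cannot be checked from unmatched clusters. This is the model's main
caveat and is inherited by everything downstream.

## Closed forms and numerical policy

The ALG density and CDF used here are the normal-Laplace convolution
forms, derived directly from `∫ f_AL(t−y) φ_{μ,σ}(y) dy`. With
`z = (t−μ)/σ`, both reduce to combinations of the kernel

`T(z, r) = exp(r²/2 − z·r) · Φ(z − r)`, `r = σ/α`,

one term per Laplacian tail. `T` is evaluated piecewise: for `z ≤ r` via
`exp(−z²/2)·erfcx((r−z)/√2)/2` (bounded, no overflow), otherwise via
`r²/2 − z·r + log_ndtr(z − r)` (no cancellation). This keeps log-density,
CDF and survival exact into regions where naive evaluation overflows at
`exp(σ²/2α²)` or underflows the Gaussian tail. Correctness is established
against an independent adaptive-quadrature convolution oracle in the test
suite (agreement to ~1e-10 absolute across randomised RT-scale
parameters) and, for the ExG special case, against
`scipy.stats.exponnorm`.

Other numerical choices:

- `α1 = 0` is a first-class boundary: AL becomes `Exp(α2)` and ALG
  delegates exactly to the ExG code path rather than approximating.
- Hazards are `exp(log f − log S)` with the log-survival computed by a
  signed log-sum-exp of its three terms. Where the survival underflows
  even in log space (beyond ~700·α2 past the mean) the exact exponential
  asymptote `1/α2` (ExG: `1/τ`) is returned; the hazard is then continuous
  and never NaN. ExG and ALG densities are log-concave, so the hazards
  are non-decreasing and saturate at the asymptote.
- Quantiles invert the CDF by Brent root finding (bracket mean ± 12 sd,
  widened geometrically; tolerance 1e-9 ms); the mode is a bounded line
  search on the log-density, valid by unimodality; the median is the 0.5
  quantile. None of these has a closed form.
- Shape-class ties (`α1 = α2`; the kurtosis inequality at equality) are
  decided with a configurable relative tolerance, default 1e-9.

Kurtosis is carried in both conventions — full (Gaussian = 3) and excess
(`κ4/κ2²`, Gaussian = 0) — because the ExG literature usually prints the
former and the ALG cumulant expression is the latter. The
leptokurtic/platykurtic classification of the ALG uses the dedicated
inequality `√(2(α1⁴+α2⁴)) − (α1²+α2²) ⋛ σ²`, which is the convention of
the source analyses this package follows (algebraically it compares the
excess kurtosis to 3, not to 0; with `α1 = α2` the left side vanishes, so
any Gaussian admixture is platykurtic under it). The sign convention for
skewness classes is `α2 ⋛ α1`.

## Synthetic sessions

`simulate` draws complete SST sessions under the independent race model:

- Design: 4 blocks × 24 trials, 25% stop trials (exactly 24, never
  stochastic), stop positions uniformly random subject to constraints;
  block-final positions are excluded by default so every stop trial has a
  within-block follower and the type-B cluster is exactly the stop count.
  An optional `adjacency_target` fixes how many stops immediately follow
  a stop (stops are then laid out as runs via a stars-and-bars
  construction), which reproduces cohorts selected for 10–14 type-B go
  trials per session.
- Go process: `Tgo ~ ExG(θ_A)` or `ExG(θ_B)` according to the previous
  within-block trial's type (block-initial → type A). Proactive slowing
  is therefore injected mechanically as a trial-type-dependent go
  distribution, matching the measurement model, not a process theory of
  preparation. Defaults are the cluster group means of the motivating
  dataset: `θ_A = (478.8, 109.9, 104.2)`, `θ_B = (532.8, 133.1, 142.4)`.
- Stop process: `Tstop ~ ExG(200, 30, 40)` by default (the stop-side
  parameters are not constrained by the data this package emulates; any
  valid ExG is accepted). A stop trial is successfully inhibited iff
  `Tgo > Tstop + SSD`. Contextual independence holds by construction.
- Staircase: SSD +50 ms after a success, −50 ms after a failure, floored
  at 0, carried across blocks. By default the staircase *starts at the
  generating model's own 50% point* — the delay at which
  `P(Tgo > Tstop + s) = 1/2` under the session's stop-context mixture,
  computed in closed form from the race-margin ALG (`Tgo − Tstop` is
  itself an ALG). Starting at equilibrium is what makes the mean success
  proportion over a whole short session track the designed 50% (measured
  0.498–0.502 over 500-session cohorts); a fixed numeric start such as
  250 ms is honoured if configured, at the cost of a warm-up transient
  (~+0.04 with the defaults) over the first few stop trials.
- Go omissions are off by default (`p_go_omission = 0`); choice errors
  are not modelled.

What the generator deliberately does *not* emulate: sequential RT
autocorrelation beyond the one-trial type rule, fatigue or practice
drifts, SSD-dependent go distributions, and between-participant
heterogeneity unless a `theta_sampler` is supplied. Tests passing on this
generator therefore validate the estimation machinery under the model's
own assumptions; they do not validate the assumptions against real
behaviour.

## Clustering

A trial is type B iff its immediate within-block predecessor is a stop
trial; block-initial trials are type A. Labels cover stop trials too, but
the GORT vectors contain only responded *go* trials — responses on failed
stop trials are excluded by default (a switch re-includes them for
sensitivity analysis). Missing or non-positive RTs are dropped and
counted; no other trimming is applied. The partition is deterministic and
idempotent, and the type-B trial count equals the number of non-final
stop trials by construction.

## Estimation

- **ExG maximum likelihood**: Nelder-Mead followed by BFGS polish on
  `(μ, log σ, log τ)`, method-of-moments initialisation
  (`τ0 = sd·(skew/2)^{1/3}` clipped into validity). Floor of 10
  observations; fits on fewer than 30 carry a small-sample flag.
- **ExG posterior means**: adaptive random-walk Metropolis on
  `(μ, σ, τ)` under independent `U[10, 2000]` priors, component-wise
  proposals with scales adapted during burn-in toward 20–50% acceptance.
  The "ibpa_paper" profile (3 chains, 20,000 iterations, 5,000 burn-in)
  mirrors the posterior-mean procedure of the motivating analysis;
  "ci_fast" (2 chains, 2,000/500) is the scaled-down profile used in the
  tests, where it agrees with the MLE to <3% at n = 5000. Diagnostics:
  per-chain means, acceptance rates, split-chain potential scale
  reduction (flag at 1.2), and a pinned-at-bound flag when the prior
  excludes the data's support.
- **Plug-in ALG**: the component map applied to two converged ExG fits;
  it carries no likelihood of its own (it is model-implied).
- **Differencing**: the distributional index is defined on the product
  space of the two clusters, which prescribes no finite-sample pairing.
  Both options are provided: `all_pairs` (all |B|×|A| differences,
  dependent, mean identical to the constant index) and `random_pairs`
  (a seeded random bijection of size min(|A|, |B|), independent; the
  default when standard errors matter).
- **Direct ALG maximum likelihood** on differences: Nelder-Mead + BFGS on
  `(log α1, log α2, μ, log σ)`, initialised by matching sample cumulants.
  The log parameterisation lets fits approach the `α1 → 0` ExG boundary
  smoothly; such fits are reported with a boundary flag rather than
  failing. A condition number of the numerical information matrix above
  1e8 raises a weak-identifiability flag. Near the ridge `α1 ↑, μ ↑`
  (the non-identifiability direction) `μ` has an asymptotic SE of ~4 ms
  at n = 20,000 for the reference parameter set, so recovery checks
  average replicate fits rather than trusting one draw.
- **Posterior propagation**: posterior `(μ, σ, τ)` draw pairs are pushed
  through the plug-in map and summarised as means and central 95%
  intervals of the ALG mean, sd, skewness and excess kurtosis.

## Pipeline and reporting

Per participant: partition → ExG fit per cluster → plug-in ALG.
Participants with fewer than 8 type-B (10 type-A) usable go RTs are
skipped with a logged reason, not imputed. Group tables report, for every
parameter and statistic, the across-participant mean with a t-based 95%
CI and two-sided paired t-tests for the B−A contrasts (no multiplicity
correction by default, matching the reporting style it emulates; the CI
flavour is t-based, bootstrap was not used). Degenerate rows (n = 1, or
zero across-participant variance) produce point rows with undefined t
statistics rather than errors.

## Problem sizes used in the checks

The shipped verification suite uses: 25–50 randomised parameter sets for
the oracle and hazard sweeps; 10⁷ draws for the moment Monte-Carlo
(batched into 100 groups for assumption-free standard errors); n = 5,000
for ExG recovery and MLE/Bayes agreement; 5 replicates of n = 20,000 for
ALG recovery; 500 sessions for the staircase tracking proportion; and
cohorts of 10–44 participants for pipeline-level checks. These sizes make
the full suite run in about a minute while keeping every Monte-Carlo
comparison at 3 standard errors or better.

## Known limitations

- The independence of `GORT_A` and `GORT_B` is untestable from unmatched
  clusters; if violated, the ALG form no longer follows.
- Proactive slowing is non-negative conceptually, but the ALG has support
  on all of ℝ; the model describes the *difference statistic*, not a
  latent non-negative slowing time.
- The monotone hazard excludes peaked-hazard RT phenomena by
  construction.
- Only the go-RT side is estimated: no SSRT estimation, no joint
  go/stop race likelihood, no hierarchical pooling across participants,
  and no multi-arm (varying stop probability) designs.
- Components other than ExG (Gamma, Weibull, lognormal, Wald, Ex-Wald)
  admit no known closed-form difference distribution and are out of
  scope.
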