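# Methods

## Model

Each stop-signal trial is a race between an ex-Gaussian go process and an
ex-Gaussian stop process launched SSD ms after the go stimulus; with
probability P(TF) the stop process is never launched and the go process runs
unopposed.  All times share one origin (go-stimulus onset); the SSRT
distribution itself is SSD-invariant, so the stop finishing-time density and
distribution function are evaluated at t − SSD.  Three trial types
contribute to the likelihood:

* go trials: f_go(t);
* signal-respond trials: P(TF)·f_go(t) + (1 − P(TF))·(1 − F_stop(t − SSD))·f_go(t);
* inhibitions: (1 − P(TF))·∫ (1 − F_go(t))·f_stop(t − SSD) dt.

The inhibition integral is the normalising constant of the defective
signal-respond density, so at every (parameter, SSD) pair the signal-respond
mass and inhibition probability sum to one; the test suite checks this to
1e−6.  The `standard` variant pins P(TF) = 0 and is the exact nested
restriction used for bias comparisons; the `hierarchical` variant draws
subject-level parameters from truncated normals ([0, 1000] ms for the six RT
parameters, ±6 on the probit scale for P(TF)).

Assumptions worth stating: go and stop finishing times are independent;
trigger failures are independent of SSD; go RTs on signal-respond trials
follow the unconditional go distribution (context independence); choice
errors and go omissions are out of scope.

## Priors

Individual-level priors are weakly informative uniforms, wide enough for
human RT data and config-overridable:
μ_go, μ_stop ~ U(1, 1000) ms; σ and τ parameters ~ U(1, 500) ms;
P(TF) ~ U(0, 1).  Group-level means carry the same ranges; group SDs
~ U(0.01, 500) ms; the probit-scale P(TF) group mean has a standard-normal
prior truncated at ±6 and its group SD ~ U(0.01, 3).  The upper [0, 1000]
truncation is applied to all six RT-parameter group distributions (it is a
numerical convenience, not a substantive constraint).

## Numerics

**Ex-Gaussian kernels.**  pdf/cdf are computed through the scaled
complementary error function: f(t) = erfcx((u − z)/√2)·exp(−z²/2)/(2τ) with
z = (t − μ)/σ, u = σ/τ, which never overflows for realistic stop parameters;
F(t) = Φ(z) − τ f(t), and the survival function is evaluated as
Φ(−z) + τ f(t) so the right tail never cancels.  Below a relative component
ratio of 1e−4 the pure-Gaussian / pure-exponential limit is used; deep in
the right tail (erfcx argument < −25) the exponential-tail asymptote takes
over in log space.

**Inhibition integral.**  Default: 128-node Gauss–Legendre on the window
[SSD + μ_stop − 12σ_stop, SSD + μ_stop + 16(σ_stop + τ_stop)], plus analytic
corrections for the stop-density mass the window clips off (bounded by the
product of the two tail masses).  An adaptive Gauss–Kronrod route
(`LikelihoodSettings(method="adaptive")`) serves as the reference; the two
agree to ~1e−9 and the fixed rule is what the sampler uses.  Per-trial
likelihoods are floored at 1e−300 before the log so a pathological proposal
is (effectively always) rejected rather than poisoning the Metropolis ratio
with −inf.

**Sampler.**  Metropolis-within-Gibbs: one Gaussian random-walk block per
scalar parameter, with proposal SDs adapted toward 0.44 acceptance during
burn-in and frozen afterwards.  The six RT parameters are sampled on the
millisecond scale; P(TF) on the probit scale in every variant (the uniform
prior transforms to a standard-normal density on z), which gives the walk
sensible geometry near 0.  Because the ex-Gaussian posterior is strongly
correlated (μ vs τ in particular), each sweep additionally makes one joint
multivariate-normal proposal whose covariance is estimated from the burn-in
history (scaled 2.38²/d, acceptance steered toward 0.23); without it the
scalar-only sampler's effective sample size for the stop parameters
collapsed to ~10 per 6,000 retained draws at large n, versus ~300–500 with
it.  Adaptation of every proposal freezes at the end of burn-in, so retained
draws target the exact posterior.  Defaults: 3 chains, 2,000 burn-in, 2,000
retained per chain (6,000 total), no thinning.  Start values come from
data-informed moment heuristics (go triple from go-RT moments; stop triple
from the mean-method SSRT; P(TF) near 0.08), jittered per chain, because
uniform random starts routinely land in likelihood floors.  Convergence is
assessed with the classic between/within Gelman–Rubin R-hat (< 1.1).

**DIC.**  Classic Spiegelhalter form, pD = D̄ − D(θ̄), with θ̄ the posterior
mean on the sampling scale (probit for P(TF)) and deviance −2× the full
likelihood including go trials; hierarchical deviance conditions on the
subject-level parameters.  A variance-based pD would be a one-line change
but is not the default.  **PPC** replays the observed SSD sequence (it
conditions on the realized design rather than re-running the staircase);
the per-SSD p value is the fraction of replicated signal-respond rates
strictly above the observed rate, except at observed rate 1 where
greater-or-equal is used (a strictly-greater count is impossible there);
cells with ≥ 10 stop trials form the reported set.

**Classic estimators.**  Mean method: mean go RT − mean SSD.  Integration
method: go-RT quantile at the signal-respond rate minus the SSD, pooled over
levels by trial count by default (per-level available); quantiles use linear
interpolation of order statistics; levels with respond rate 0 or 1 are
excluded and flagged.

## Simulator

The generator emulates ex-Gaussian go RTs and SSRTs, Bernoulli trigger
failures independent of SSD, and three SSD schedules: fixed levels,
one-up/one-down staircase tracking (defaults: start 200 ms, step 50 ms,
clamps [0, 1000] ms — field-standard values, config-exposed), and a
relative mode yoking stop signals to the running mean go RT.  It does *not*
emulate choice errors, go omissions, parameter drift across a session, or
violations of context independence, so passing recovery tests demonstrate
internal consistency of estimator and generative model, not robustness to
those real-data features.

Default generating values used throughout the tests: go (μ, σ, τ) =
(440, 80, 60) ms (mean 500 ms) and stop (190, 40, 50) ms (mean SSRT
240 ms) — typical of healthy adult stop-signal data; the fixed-SSD design
uses delays {50, 150, 250, 350, 450} ms, which spans the inhibition function
and yields overall signal-respond rates close to the staircase's 0.50 at
P(TF) = 0.1.

## Study scales used by the tests

Simulation sizes are the package's own choices: asymptotic recovery uses one
subject with 12,500 stop and 3,000 go trials per dataset (both SSD modes,
P(TF) ∈ {0.1, 0.2}); realistic-scale coverage uses 10 replications of
750 go / 250 stop trials, and the hierarchical run 8 subjects × 150 go /
50 stop; DIC model recovery uses 2,000 go / 2,500 stop trials with the
fixed-SSD design, because early SSDs are where trigger failures are
identifiable — with staircase tracking at a few hundred stop trials the two
models are near-indistinguishable, consistent with the tracking procedure's
tendency to avoid early SSDs.

## Known limitations

* Marginal 95% intervals are exactly that: with 28 intervals checked across
  four asymptotic datasets, one or two legitimate ~2σ misses are expected
  even with perfectly calibrated posteriors (posterior SDs were verified
  against numerical Fisher standard errors, and the ML estimator against its
  sampling distribution across replications).
* The scalar+joint sampler is robust but not fast by HMC standards; a
  hierarchical fit with many subjects is minutes, not seconds.
* P(TF) and the stop parameters are weakly identified under pure staircase
  tracking with few trials; the estimator is honest about this (wide
  posteriors) but cannot beat the design.  A hybrid design with a share of
  early fixed SSDs identifies P(TF) far better.
* Alternative RT families (Wald, lognormal) and Bayes-factor model selection
  are out of scope.
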