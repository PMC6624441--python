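# Methods

## Model

One go-trial latency is modelled by the LATER rise-to-threshold process: a
decision signal rises linearly from a fixed start point at a trial-random
rate `z ~ N(v, 1)` until it crosses the caution threshold `θ > 0`. Two
likelihood forms are supported and tested as first-class citizens:

* **direct** (default): the latency itself is Gaussian,
  `y = z/θ ~ N(v/θ, 1/θ²)`. This form is consistent with the headline
  calibration that accretion 1 with caution 4 implies a 250 ms mean latency,
  and with person-level caution estimates in the 2–6 range for sub-second go
  responses.
* **reciprocal** (classic recinormal): `1/y ~ N(v/θ, 1/θ²)`; latency
  densities include the Jacobian `|d(1/y)/dy| = 1/y²`. Both forms share the
  Gaussian kernel `θ·u − v ~ N(0, 1)` with `u = y` or `u = 1/y`, which is
  what the sampler exploits.

The hierarchy:

* Person level: `v_p = x_p'β_v + ε_{p,v}`, `θ_p = x_p'β_θ + ε_{p,θ}`, with
  `x_p` the person covariate vector (leading 1 for the intercept; covariates
  centred and scaled to unit sample SD before fitting, so coefficients are
  reported per SD of the predictor). The residuals are independent
  `N(0, σ_v²)` and `N(0, σ_θ²)` by default; `correlated_effects=True`
  switches to a bivariate normal with an estimated correlation `ρ`
  (Uniform(−1,1) prior). Independence is the default because the model is
  usually stated with separate residual terms and the correlation is weakly
  identified with few persons.
* Condition level: dummy indicators `g_n` (baseline smoke-as-usual/neutral =
  all zeros; `g1` neutral–abstinent, `g2` reward–smoke-as-usual, `g3`
  reward–abstinent) shift both parameters additively:
  `v_n = v_p + g_n'δ_v`, `θ_n = θ_p + g_n'δ_θ`.
* Priors (weakly informative, all overridable): `N(0, 10²)` on every `β` and
  `δ` component, half-`N(0, 5²)` on `σ_v` and `σ_θ`. With thousands of
  trials per person these priors are effectively flat relative to the
  likelihood.

Positivity: the additive composition can produce `θ_n ≤ 0`. Rather than a
constrained transform — which would change the additive parameterisation —
the joint log-posterior returns `−∞` there (a soft rejection that samplers
handle gracefully). The trial-random rate `z` is marginalised analytically
everywhere; it appears only in the generative simulator.

## Sampler

No general-purpose probabilistic-programming backend is used; the posterior
is sampled by a Metropolis-within-Gibbs scheme designed around the
likelihood's structure:

* Conditional on the caution side, `w_n = θ_n·u_n` satisfies
  `w_n − v_n ~ N(0, 1)`, so the accretion side is a linear-Gaussian
  hierarchy: person accretion rates, the three `δ_v` components (their
  condition cells are disjoint) and `β_v` are drawn from exact Gaussian full
  conditionals.
* Person thresholds `θ_p`, the `δ_θ` components, and the scales `σ_v`, `σ_θ`
  (and `ρ` when enabled) are updated by univariate stepping-out slice
  sampling (Neal 2003, width 0.1–0.5, random stepping-out budget), which is
  rejection-free and requires no tuning runs.
* Every conditional is evaluated through per-(person × condition-cell)
  sufficient statistics `(N, Σu, Σu²)`, so one sweep costs O(persons), not
  O(trials); a full 6-chain × 2,000-iteration fit of a 25,500-trial dataset
  takes well under a minute on one core.

Initialisation is method-of-moments per person (`θ ≈ 1/sd(u)`,
`v ≈ mean(u)·θ`, clipped to [0.3, 30]) with per-chain jitter; prior-mean
initialisation is not viable because a zero caution intercept lies outside
the likelihood support. A single integer seed drives a `SeedSequence` that
spawns one stream per chain, so identical settings reproduce draws bitwise.
Because the Gibbs sweep draws person effects from their *exact* full
conditionals, the centred parameterisation is used directly; the non-centred
reparameterisation that helps gradient-based samplers in funnel geometries
would add nothing here.

Convergence is monitored with the classic split-chain Gelman–Rubin statistic
(each chain halved; `R̂ = sqrt(((n−1)/n·W + B/n)/W)`), not the
rank-normalised variant; the implementation agrees with ArviZ's
`method="split"` to machine precision (tested). Runs are failed at
`R̂ ≥ 1.1` and flagged (logged) at `R̂ ≥ 1.01`. Default run shape: 6 chains
× 2,000 iterations, first 1,000 discarded, 6,000 retained draws.

## Synthetic data

`StudyDesign` defaults emulate a two-session (smoke-as-usual vs. ≥12 h
abstinent), incentivised Go/No-Go study: 17 persons × 10 runs × 100 trials
per session, 75% frequent-go trials, half the runs rewarded — i.e. 750
modelled frequent-go latencies per person-session (375 reward / 375
neutral), 25,500 in total. Covariates (age 31.06 ± 13.82, age of first use
19.63 ± 5.34, FTND 2.61 ± 2.35, 11.08 cigarettes/day) are Gaussian draws
re-centred/re-scaled so the *sample* moments match those values exactly; no
SD is published for cigarettes/day, so 6.0 was chosen as realistic for that
mean. Default group truth: accretion intercept 1.15 and caution intercept
4.0 (centres of the reported person-estimate ranges 0.7–1.6 and 2–6),
residual SDs 0.2 and 0.9 (so ±2 SD spans those ranges), zero covariate
weights (no predictor explained differences in either parameter), and
condition deviations at the reported posterior means
`δ_v = (−0.3638, 0.1231, −0.2494)`, `δ_θ = (−0.0655, 0.0835, −0.0068)`.

**Windowing and its mismatch.** Responses are observable only within
150–800 ms, and the simulator redraws latencies into that window by default
(reporting the redraw fraction). The Gaussian likelihood itself does not
model this truncation. At the default truth the implied
`N(v/θ ≈ 0.29, 1/θ ≈ 0.25)` places roughly a third of its mass outside the
window, so (a) the redraw fraction for the default fixture is ~0.4, and (b)
fitting the untruncated likelihood to windowed data biases the person-level
parameters upward — a genuine model–data mismatch that the package surfaces
rather than hides. Convergence and predictive-calibration claims are
therefore tested on windowed data, while *recovery* claims (estimates vs.
generating truth) use `make_recovery_fixture`, which replaces the window by
a vanishing positivity guard and uses truth with accretion mean 3.0 and
caution mean 10.0 — latencies of 300 ± 100 ms with negative-latency mass
below 0.2% — so that recovery measures the estimator, not truncation bias.
Passing recovery tests consequently demonstrate correctness of the
inference machinery, not that window truncation is ignorable for real,
windowed data at caution ≈ 4.

## Validation surface

* Exact oracles: closed-form density values against `scipy.stats.norm`;
  reciprocal↔direct Jacobian identities to 1e−10; quadrature normalisation
  of the latency density to 1e−6; the sufficient-statistics data term
  against the per-trial log-density sum.
* Conjugate oracle: with one person and caution fixed, the model is
  Normal-Normal conjugate; slice-sampled posterior mean/SD must match the
  closed form within 3 Monte-Carlo SEs (effective sample size via ArviZ).
* Recovery: single replication at 15 persons × 300 trials/session — every
  condition deviation within 3 posterior SDs of truth; plus a 20-replication
  credible-interval coverage check (≥ 80%) at a reduced size (12 persons ×
  100 trials/cell, 3 chains × 1,000/500) chosen to keep the default test run
  fast.
* Calibration: observed dataset mean inside the central 95% of 100 replicate
  means; ≤ 25% of ~22 summary statistics outside their replicate intervals.
* Monotonicity properties: posterior spread of person effects shrinks with
  the true heterogeneity SD and with increasing trial counts.

## Posterior predictive checks

Replicates take parameter draws equally spaced across the pooled retained
draws (deterministic given the fit; the seed only drives trial noise) —
thinning rather than random selection makes PPC output reproducible
draw-for-draw. Overlay exports bin the observed data (counts summing to the
retained trial count) and smooth each replicate with a Gaussian KDE using
Silverman's bandwidth on a common latency grid, at whole-dataset or
per-person level.

## Numerical and edge-case choices

* RT exactly at the 150 ms exclusion threshold is retained (the rule
  excludes strictly faster responses); RTs above the 800 ms window are an
  ingestion error by default (`max_rt_policy="warn"` drops them instead,
  with a count in the exclusion log).
* Latencies are stored and modelled in seconds; `rt_unit="ms"` converts on
  ingestion.
* `R̂` is reported unrounded (display convention: 4 decimals); zero
  within-chain variance yields NaN with a warning rather than an exception.
* Degenerate simulation with `σ = 0` is allowed in the generator (it
  reproduces the covariate-predicted means exactly) even though fitted
  scales are always positive.
* Standardisation uses the sample SD (ddof = 1); constant covariate columns
  are rejected.

## Problem sizes in the default test run

The suite fits: the full emulated study (17 × 25,500 trials, default 6 ×
2,000/1,000 sampler) once; the recovery benchmark (15 persons × 600 trials)
once at default sampler settings; 20 reduced-size replications for coverage;
and several miniature fits for interface tests — about 2½ minutes end to
end on one core. These sizes are the package's own validation choices; all
full-size settings remain the defaults users get.

## Known limitations

* The response window is not part of the likelihood (see above); a truncated
  likelihood variant would be the principled extension for windowed data.
* No modelling of No-Go/inhibition accuracy, infrequent-go trials, lapse or
  express-response mixtures.
* The group model assumes Gaussian random effects; with very few persons the
  scale posteriors are prior-sensitive.
* Slice sampling mixes more slowly than gradient-based samplers would for
  strongly correlated caution-side blocks; the defaults compensate with
  cheap iterations.
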