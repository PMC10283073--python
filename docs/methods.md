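# Methods

## Data model

A trial is one laser irradiation of one cell: power (mW), duration (s),
target-cell area (µm², optional), tissue label, and one of six categorical
outcomes describing where VENUS (recombination reporter) and PI (death
stain) appeared.  Analyses run on four binary endpoints derived from the
category: `target`, `neighboring`, `local = target OR neighboring`, and
`death`.  The encoding is *marginal*: each VENUS bit records whether that
compartment fluoresced regardless of the other.  That is the only encoding
under which the union identity for `local` holds, and it fixes the
death-with-expression category to (1, 1, 1, 1) — its description places
VENUS in both the irradiated and other cells.

Cell sizes are z-scored with the sample SD (n−1); the mean/SD pair is stored
with the dataset and with every fitted curve so size-aware curves can be
evaluated on raw areas.  At c = 0 every size-aware model reduces exactly to
its size-free counterpart, so the size-free fits describe a cell of average
area (≈3,000 µm² under the calibrated generator).

## Response families

Four logistic families in power x and normalized size c (see README for the
formulas): `simple`, `bounded` (upper asymptote lim ∈ (0,1]), `size`, and
`bounded_size`, whose numerator lim·(1 + a₄c) makes the plateau vary
linearly with size.  That parse is this package's reading of the bounded
size-included model: it is the unique linear-in-c plateau form that nests
the size-free bounded model at c = 0, and a₄ then has the natural role of a
plateau modifier.  The effective limit lim·(1 + a₄c) must stay in (0, 1]
over the observed c range; fits enforce it, predictions raise a domain
error outside it.

Numerics: linear predictors are clamped to ±35 before exponentiation
(exact to double precision in range, saturating outside).  Probabilities
are floored/ceiled at 1e-12 inside the log-likelihood only — never in
predictions — so optimizers always see finite objectives; an exact 0/1
prediction contradicted by an observation is additionally flagged.

## Estimation

**Unbounded families** (`simple`, `size`) are fitted by damped Newton/IRLS
with analytic gradient and Hessian: step-halving keeps the ascent monotone,
gradient tolerance 1e-8, at most 200 iterations.  The likelihood is concave,
so multistart is unnecessary (the test suite verifies jittered restarts
agree to 1e-6, and coefficients match statsmodels GLM to 1e-6).
Quasi-complete separation is detected (|linear predictor| > 30 at the
optimum, or diverging coefficients) and reported via a flag — never
repaired by penalization, which is out of scope.

**Bounded families** are estimated by MCMC.  Priors: lim ~ Uniform(0, 1);
slope and intercept coefficients ~ Normal(0, 10) on the standardized-power
scale; a₄ ~ Normal(0, 2) truncated to keep the effective limit valid over
the observed c range.  Power is standardized internally (so the same priors
and step sizes serve the 10–24 mW and 5.5–20 mW designs) and every draw is
back-transformed to natural units.  The sampler is emcee's affine-invariant
ensemble with an 0.8/0.2 mixture of differential-evolution and DE-snooker
moves, which mix far better than the default stretch move on this strongly
correlated (lim, slope, intercept) posterior.  Two independent ensembles of
16 walkers run 1,200 warmup + 2,000 kept iterations by default; walkers are
started in a small ball around the constrained-MLE solution (an
initialization aid only), with ball samples resampled into the prior
support.  Each walker is treated as a chain for split-R̂ and effective
sample size; a fit is accepted only if every parameter has R̂ ≤ 1.01 and
ESS ≥ 400, otherwise a diagnostic-carrying error is raised.  Runs are fully
reproducible: the seed determines walker initialization and the sampler's
random state bit-for-bit.

Point estimates are per-parameter posterior medians, assembled into a
response curve.  A constrained maximum-likelihood fit of the same families
(L-BFGS-B over the standardized parameterization, lim bounded in (0, 1],
five seeded multistarts) serves as an independent cross-check; with lim
fixed at 1 it reproduces the plain logistic fit.  When no design power
reaches the plateau, lim is weakly identified: the profile likelihood is
nearly flat in lim, and the MLE may sit anywhere on the ridge (the suite
checks flatness rather than a boundary value).

## Hypothesis tests

Cell-size effects are tested by likelihood-ratio tests of size-included
against size-ignored models on identical records (records lacking sizes
must be excluded from both sides; mismatched record sets are rejected).
For the unbounded pair the statistic is 2Δℓ at the MLEs with df = 2
(a₂, a₃ added).  For the bounded pair, where the fits are Bayesian, the
statistic is the deviance difference evaluated at each model's posterior
medians, df = 3 (a₂, a₃, a₄; lim and b exist in both models).  Medians are
the package's point estimate throughout, so the deviance is evaluated
there; under near-flat priors and informative data this statistic tracks
the bounded-MLE statistic closely (within ~2% in the validation suite).
Negative statistics are clipped at zero; a pre-clip value below −1e-6
signals a convergence failure and raises instead.

Type-I error is calibrated: under a size-free truth the df = 2 test rejects
at 0.05 in about 4–5% of replicates and its p-values are near-uniform
(checked by Kolmogorov–Smirnov distance).

## Dose selection

`compose_local` is the inclusion–exclusion union under independence of the
target and neighbor events: p_t + p_n − p_t·p_n.  The two objectives are
condition 1 = P_target·(1 − P_neighboring) and condition 2 =
P_local·(1 − P_death), with P_local composed when not fitted directly.
Optimization evaluates a 0.01-mW grid (ties to the lowest power — less
heat, less damage) and refines the best cell by bounded golden-section
search; the suite verifies agreement with a 0.001-mW exhaustive scan to
0.01 mW.  Powers are reported rounded to 0.1 mW, full precision retained.
`raising_point` solves curve(x) = threshold (default 10%) by Brent
bisection to 1e-6, requires a positive effective slope, and returns an
unreachable flag when the curve never crosses the threshold in range (e.g.
a plateau below it).  `local_consistency_check` reports the maximum
absolute gap between a directly fitted local curve and the composition on
a 0.1-mW grid — the empirical price of the independence assumption.
Size-conditional recommendations repeat the optimization at chosen c
values; |c| > 2 (beyond ±2 SD of cell size) attaches an extrapolation
warning.

## Synthetic-data generator

The generator emulates the root irradiation study's statistical structure:

* **Designs.**  1 s: bins 10.0–16.0 (n = 20), 17.0–19.0 (n = 30),
  20.0–24.0 mW (n = 40).  60 s: 5.5–8.0 (n = 50), 8.5–11.0 (n = 40),
  11.5–14.0 (n = 30), 15.0–20.0 mW (n = 9).  Trial powers sit on a 0.5-mW
  lattice cycled round-robin within each bin (the real per-power allocation
  is not published; the lattice is a stand-in).
* **Cell sizes.**  Lognormal with mean 3,000 µm² and CV 0.5
  (meanlog = ln 3000 − ½·ln 1.25, sdlog = √ln 1.25).  The mean is the
  study's reported average; the CV is this package's choice of a realistic
  spread and is recorded in the truth sidecar.
* **Outcomes.**  Per trial, three latent Bernoulli events — T (target
  VENUS), N (neighbor VENUS), D (death) — are drawn from the true curves,
  independently by default (exactly the assumption the union formula
  makes), or through a Gaussian copula on a shared latent heat variable for
  the dependence stress test.  The triple maps to the observable category;
  all D = 1 combinations with any expression collapse into the single
  death-with-expression category because the observable taxonomy has no
  finer classes.  This collapse is *lossy*: the observable target marginal
  is P(T) + (1−P(T))·P(D)·P(N), which exceeds P(T) wherever death and
  neighbor expression are both common.  Consequences are discussed under
  limitations.
* **Default truth.**  60 s: target bounded(lim 0.40, a 1.5, b −12) —
  plateau 0.40 with 10% raising point at 7.3 mW; neighboring
  logistic(0.9, −11) — 10% at 9.8 mW; death logistic(0.8, −13.5) — 50% at
  16.9 mW, matching the reported >50% death above 17 mW.  1 s: shallower
  curves with 10% raising points at 16.0/18.6/19.1 mW and 50% death near
  24 mW — the reported compressed separation of short irradiation.  With
  `size_effect=True` every curve gains a negative size main effect
  (≈ −0.5 to −0.6 per size SD: smaller cells respond at lower power) and
  the bounded target a small negative a₄ (higher plateau for smaller
  cells), emulating the study's significant size effects; the size-free
  curves are exactly the c = 0 sections.  These values were fixed once from
  the published qualitative facts; the printed 8.5/11.5 mW optima cannot be
  reproduced exactly under them because those depend on the authors' raw
  data (with the anchored target curve, forcing the 8.5-mW optimum would
  require P_neighboring above 0.4 at 8.5 mW, contradicting the published
  raising-point ordering).
* **Single-endpoint draws.**  `simulate_endpoint_trials` draws one
  endpoint's Bernoulli outcomes directly from its curve with no categorical
  collapse — the generative route for parameter-recovery checks, where the
  quantity of interest is the curve itself.
* The in-study leaf example ships as a deterministic 20-trial fixture
  (4 single-cell successes at the root-optimized 60-s condition).

The generator does *not* model space (neighbors are one aggregate event),
heat diffusion, duration as a covariate, or death–expression exclusivity in
real tissue.  Passing recovery tests therefore demonstrate correctness of
the estimation and optimization machinery under the stated stochastic
model, not fidelity to any particular tissue.

## Validation suite and problem sizes

The acceptance-level checks use: 1,000 random draws for the reduction
identities (tolerance 1e-12); a 100×100 grid for the union identity; 5,000
trials per design power for the direct-vs-composed local check (asserted
under independent events, where the residual ≈0.02 gap is the logistic
misspecification of a union of two logistics); 50 random curve sets for
the optimizer and raising-point oracles; 200 replicates at n = 2,000 for
simple-logistic recovery (within 3 SE) and 20 MCMC replicates at 2,000
trials per power for plateau recovery (lim within ±0.05 of 0.40); 500 null
replicates at n = 400 for LRT calibration; and 20 replicates of the
10×-inflated 60-s design for full-pipeline recovery.  These sizes keep the
full suite within a few minutes on one CPU while leaving Monte-Carlo noise
well below the asserted margins.

## Known limitations

* **Collapse-induced bias in the full pipeline.**  Because
  death-with-expression trials carry every VENUS bit, the observable target
  marginal climbs toward 1 at powers where death and neighbor expression
  are both common, even when the underlying target curve plateaus at 0.40.
  A bounded logistic fitted to the full categorical simulation is pulled
  toward lim ≈ 1 (its likelihood genuinely beats the truth curve's there),
  which biases the recovered condition-1 optimum upward by ≈ +0.6 mW on the
  10×-inflated design.  The full-pipeline recovery test documents this
  honestly: with the true target curve substituted, recovery is exact, so
  the bias is entirely attributable to the encoding, not to the fitting or
  optimization machinery.  On the *real* design the distortion is mild —
  only 9 of 129 trials (60 s) sit in the death-heavy range — which is
  consistent with the original study fitting a 0.40 plateau.
* The independence composition for P_local is an approximation; its error
  is reported, not hidden, and grows under positive event dependence.
* The bounded-model LRT evaluates deviance at posterior medians; it is a
  pragmatic mirror of the original procedure, not a calibrated Bayesian
  test, and its null distribution is only asymptotically χ²(3).
* Published headline numbers that depend on the authors' raw per-trial data
  (fitted optimal powers 20.0/8.5/22.5/11.5 mW, the exact LRT p-values)
  are reference points, not targets: they are not recoverable from printed
  information alone.
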