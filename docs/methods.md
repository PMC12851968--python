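# Methods

## The cardiac autonomic signature (CAS)

A short bout of exercise perturbs the beat-to-beat R–R interval (RRi)
series in a characteristic U-shape: a drop at exercise onset (vagal
withdrawal plus sympathetic activation) followed by a partial recovery
after exertion ends (vagal reactivation).  `cardiocas` parameterizes a
recording spanning rest, a two-minute stepping task and five minutes of
recovery with the dual-logistic curve

    f(t) = α − β·S(t; λ, τ) + c·β·S(t; φ, τ + δ),
    S(t; r, t0) = 1 / (1 + exp(−r (t − t0))),

and models each observed interval as `RRi ~ Normal(f(t), σ²)`.

| parameter | units  | meaning |
|-----------|--------|---------|
| α         | ms     | resting baseline RRi (vagal tone at rest) |
| β         | ms     | magnitude of the exercise-induced drop |
| c         | —      | recovery proportion relative to β; post-recovery level is α − β(1 − c) |
| λ         | min⁻¹  | steepness of the drop transition |
| φ         | min⁻¹  | steepness of the recovery transition |
| τ         | min    | drop onset time on the recording clock |
| δ         | min    | lag from drop onset to recovery onset |
| σ         | ms     | beat-to-beat Gaussian noise SD |

**Sign convention.** The same curve is often written with positive rates
inside the exponentials, which places the *rest* plateau at α + β(1 − c)
and the *end* plateau at α.  We use the rising-smooth-step form above so
that α is literally the resting baseline, matching how the parameters
are interpreted (α = baseline vagal tone, c < 1 = incomplete recovery).
The two forms are a bijection — shift the baseline by β(1 − c) — which
`evaluate_model_reflected` implements and the test suite verifies.

Invariants: β ≥ 0, λ > 0, φ > 0, δ ≥ 0, and α − β > 0 so the curve can
never cross zero at the nadir.

## Preprocessing

1. **Ectopic rejection.**  A single-pass local polynomial regression
   (quadratic, tricube weights, span 0.25 of the series) is fitted to
   interval-vs-beat-index; beats whose residuals exceed twice the scaled
   MAD (×1.4826, so the threshold is ≈2σ under Gaussian noise) are
   masked, never interpolated.  Raw (unscaled) MAD would reject ≈18% of
   clean beats; the scaled default rejects the expected 4.55% Gaussian
   tail.  On long series the local fit is evaluated at 400 anchor
   indices and interpolated — the trend varies over minutes, the anchor
   spacing over fractions of a second of beat index, so the error is
   negligible.  Applying the rule twice on clean Gaussian data removes a
   further ≈1.3% (the first pass truncates the residual distribution at
   2σ, shrinking the MAD to ≈0.95σ); this is a property of the rule
   itself, not of the implementation.
2. **Smoothing.**  A zero-phase Butterworth low-pass (order 3, cutoff
   0.10 of the beat-index Nyquist; `filtfilt` with reflective padding)
   suppresses beat-to-beat fluctuation while passing the minute-scale
   trend.  Filtering operates in the beat-index domain, where the series
   is uniformly sampled by construction.
3. **Order.**  Spikes are rejected *before* filtering (default): a
   linear-phase smoother applied to a series still containing ectopic
   spikes smears each spike across its neighbours and hides it from the
   MAD rule.  The reverse order is available via
   `preprocess(order="filter_first")`.

Known small bias: near the steep transitions the local trend used for
rejection lags the true curve, so a few legitimate transition beats are
trimmed.  At the reference conditions (σ = 30 ms) this leaves the mean
recovered rates λ and φ ≈2–3% low and β ≈1% high — well inside the
recovery tolerances, and absent when rejection is skipped on clean data.

## Robust per-subject fitting

The first stage is deliberately a point-estimation step.  The objective
is the Huber loss of the beat residuals, minimized over the 7 parameters
with L-BFGS-B inside physiologic box constraints (α ∈ [300, 1500] ms,
β ∈ [0, 1000] ms, c ∈ [0, 2], λ, φ ∈ [0.1, 20] min⁻¹, τ ∈ [0, span],
δ ∈ [0, 10] min), using analytic gradients.

* **Initialization.**  α₀ = median interval of the first minute; β₀ =
  α₀ minus the smoothed minimum (floored at 10 ms with a warning for
  flat series); τ₀ = time of steepest smoothed descent; δ₀ = exercise
  duration; c₀ = 0.8; λ₀ = φ₀ = 2 min⁻¹.  Five starts by default: the
  heuristic plus four 10%-jittered copies, deterministic given the seed.
* **Huber threshold.**  1.345 × the scaled MAD of residuals from the
  local polynomial trend, then held fixed.  The trend-based scale
  estimates the beat noise without committing to curve parameters;
  deriving it from start-point residuals instead would inflate the
  threshold several-fold with model mismatch and forfeit the robustness
  the loss exists for (we measured exactly that failure mode).  1.345
  robust SDs is the standard 95%-efficiency constant.
* **Convergence.**  Optimizer success plus a projected-gradient check
  (max |g| ≤ 10⁻³·(1 + loss), bound-active components excluded).  A fit
  that converges on no start returns `converged=False` with
  diagnostics, never a silent estimate.
* **σ** is estimated post hoc as the scaled MAD of the final residuals.
  After low-pass filtering this is the *smoothed-series* residual scale,
  substantially below the raw beat noise.

A least-squares variant (`loss="squared"`) shares all machinery and
exists to quantify the robustness gain: with 5% uncorrected ectopic
spikes the Huber fit's across-seed RMSE is smaller for every parameter.
Because the injected contamination alternates short/long (mean-zero, as
real detection artifacts roughly are), least squares is unbiased and
fails only occasionally-but-catastrophically; per-seed comparisons are
therefore near coin-flips even though the aggregate strongly favours
Huber.

## Second stage: Bayesian regression

Each CAS parameter k, estimated per subject, is regressed on the six
immune predictors (absolute lymphocyte count, total B cells, and the
four CD21/CD11c B-cell subset counts):

    μ_{k,i} = β_{k,0} + Σ_p β_{k,p} x_{p,i},

optionally extended with age, sex, body-fat % and muscle-mass terms
(model 2).  Continuous predictors **and the seven responses** are
centered and scaled, so coefficients are standardized effect sizes and
the ROPE of ±0.1 is exactly 0.1 response SDs; sex stays 0/1.  Priors:
Normal(0, 3) on every coefficient, half-Student-t(3, 0, 2.5) on the
residual SD (weakly informative on the standardized scale).  The seven
responses are fitted as independent Gaussian models inside one wrapper;
residual correlation among them is not modelled.

**Sampler.**  No probabilistic-programming backend is assumed: the
log-posterior and gradient of the Gaussian linear model are available in
closed form (O(p²) per evaluation after caching X'X, X'y), and a
self-contained Hamiltonian Monte Carlo sampler drives them — all chains
advanced in parallel as one state matrix, ~16 leapfrog steps with ±20%
jitter, dual-averaging step-size adaptation to a 0.8 acceptance target,
and a diagonal mass matrix estimated over the middle warmup window with
step-size re-adaptation afterwards.  σ is sampled on the log scale with
the Jacobian included.  Defaults: 5 chains × (2,000 warmup + 2,000
sampling) = 10,000 post-warmup draws per parameter.  The posterior is
log-concave and well conditioned after standardization, so this plain
HMC mixes with near-independent draws; correctness is pinned by a
conjugate closed-form oracle (fixed-σ case) and per-run diagnostics.

**Reporting (SEXIT).**  Per coefficient: posterior median; 95% highest-
density interval (shortest contiguous window over the sorted draws);
probability of direction pd = max(P(>0), P(<0)) with pd = 0.5 for an
all-zero point mass; practical significance ps = posterior mass outside
the ROPE.

**Diagnostics.**  Rank-normalized split R̂ and bulk effective sample
size per parameter (via arviz), flagged at R̂ ≥ 1.01 or ESS ≤ 1,000;
posterior predictive checks compare mean, SD and quartiles of replicated
vs observed responses.  A design-matrix condition number above 30 emits
a collinearity warning (total lymphocytes, total B cells and the four
subsets are intentionally all included; no remedy is applied).

## The synthetic cohort generator

The generator is the package's stand-in for the (non-public) study data
and carries full ground truth.

* **Trajectories** are generated beat by beat: the interval observed at
  time t is f(t) + Normal(0, σ) ms and the clock advances by it, so beat
  density itself tracks heart rate.  Nonpositive draws are redrawn
  (bounded retries); with a positive curve mean each redraw succeeds
  with p > 0.5, so the truncation is essentially free.
* **Protocol**: 7 min rest + 2 min exercise + 5 min recovery (14 min).
  The rest length is a design choice consistent with a drop onset
  estimated near 6.9 min on the recording clock.
* **Immune counts** are independent log-normals moment-matched to the
  reference cohort's marginal means/SDs; age, body fat and muscle mass
  are Gaussian, sex Bernoulli(0.31 male).  Only marginals are emulated:
  the compositional constraint (subsets summing to total B cells) and
  real between-marker correlations are not.
* **Between-subject CAS variation.**  Cohort SDs are recovered by
  inverting the reference cohort's 95% intervals on the means
  (SD = width/3.92·√81).  Subject parameters are
  mean_k + SD_k·(Σ_p coeff[k,p]·x_p) + Normal(0, resid_k) with
  standardized predictors.  By default resid_k = SD_k·√(1 − Σ coeff²),
  so the total SD equals SD_k and each requested coefficient **is** the
  population standardized effect the pipeline estimates — the natural
  parameterization for recovery experiments.  A `residual_scale`
  override forces resid_k = scale·SD_k instead.
* **Truncation.**  Draws violating the invariants (or τ + δ beyond the
  protocol span) are redrawn; a *deterministic* mean vector violating
  them raises, naming the subject.  With the implied SDs the positivity
  constraint bites for the rate parameters (e.g. φ has mean 2.18 and
  implied SD 2.48), so realized cohort means of λ and φ sit above the
  nominal values when the full between-subject SD is used.  Recovery
  experiments therefore pin trajectories at the fixed reference vector
  rather than at cohort draws.
* **Ectopic injection** multiplies intervals by 1 ± u (u uniform in the
  magnitude range, signs alternating short/long) while leaving beat
  times fixed — a detection artifact, not physiology.

What passing tests on synthetic data do *not* show: robustness to
respiratory sinus arrhythmia structure, circadian drift, recording
dropouts, or the real cohort's predictor correlations — none of which
the generator emulates.

## Problem sizes and numerical conventions

* Recovery experiments: 20 trajectories at σ = 30 ms (≈1,100 beats
  each); robustness comparison: 20 paired fits; end-to-end effect
  recovery: one 500-subject cohort through the full two-step pipeline
  with the default sampler; null calibration: 200 replicate analyses at
  n = 81 with a reduced 2-chain × (500 + 500) sampler, which keeps the
  whole suite in the minutes range while preserving ≥1,000 draws.
* Determinism: every stochastic component takes an integer seed;
  identical seeds give bit-identical trajectories, cohorts, fits and
  draws.  Derived seeds stay below 2³¹.
* Time is minutes and intervals milliseconds everywhere; conversion
  happens only at I/O boundaries.
* Degenerate inputs: flat series floor β₀ at 10 ms with a warning; a
  zero residual MAD flags only nonzero residuals; an all-flagged series
  is an error; zero-SD columns fail standardization by name.

## Limitations

Two-step inference does not propagate first-stage uncertainty into the
regression (a joint hierarchical model would); responses are residually
independent; no model comparison (LOO/WAIC) is provided; collinear
predictors are warned about, not remedied; the CLI supports only the two
text layouts for recordings.
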