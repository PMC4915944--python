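# Methods

## Observer model

Perceived speed is modelled as the mode of a Gaussian posterior obtained by
combining a Gaussian sensory likelihood with a locally log-linear prior over
speed, p(ν) ∝ exp(aν + b) within a narrow speed range. Because the posterior
is Gaussian its mode and mean coincide, and

    E(ν̂)   = ν + a(ν) σ²(ν, c)
    Var(ν̂) = σ²(ν, c)

The local log-slope a(ν) (units 1/(deg/s)) is specified at knot speeds
{1, 4, 8, 12} deg/s — the experiment's reference speeds — and linearly
interpolated in between. Outside the knot range the slope (and likewise the
width knot g) is clamped to the nearest knot value: extracted slope functions
tend to flatten at the extreme speeds, and staircases routinely place test
speeds outside the knot range, so constant extrapolation is both the
conservative and the necessary choice. The intercept b is never stored; it is
absorbed into the integration constant of the prior reconstruction.

The likelihood width is separable, σ(ν, c) = g(ν)·h(c), with
h(c) = 1 / (r_max·cᑫ/(cᑫ + c50ᑫ) + r_base): the reciprocal of a
hyperbolic-ratio contrast-response function, so noise shrinks as the contrast
response saturates. r_max = 1 and r_base = 0.2 are fixed by convention,
bounding h in (1/1.2, 5]; q and c50 are fitted. Contrasts are Michelson
fractions in [0, 1] everywhere inside the library; percent values are
converted at I/O boundaries only. We implement the reciprocal of the
hyperbolic ratio as the printed form of this model family; some physiological
treatments use an inverse square root instead, which would change h's shape
but not the structure of anything downstream.

A 2-AFC decision is modelled by sampling each grating's posterior once and
choosing the faster sample, giving the closed-form choice probability
P(ν̂₂ > ν̂₁) = Φ((E₂ − E₁)/√(Var₁ + Var₂)). The closed form is the
implementation; numeric double integration is retained in the test suite as
an independent oracle (agreement to 1e-6 over 100 random stimulus pairs).
The Gaussian posteriors are supported on the whole real line; the sampling
rule does not truncate at zero speed.

## Ratio-model front end

The combined model replaces the veridical likelihood mean with the output of
a temporal-filter ratio stage operating on temporal frequency ω = ν·sf (Hz):

    p̄(ω) = √(A² + B²),  A = ((2πωτ₁)² + 1)^(−9/2),  B = ((2πωτ₂)² + 1)^(−10/2)
    m̄(ω) = k·ω·p̄(ω)
    p(ω, c) = p̄c / (p̄c + s_p),   m(ω, c) = m̄c / (m̄c + s_m)
    f = m/p

A and B are amplitude responses of 9- and 10-stage exponential low-pass
cascades; the band-pass amplitude is the temporal-derivative form k·ω·p̄(ω)
(the product reading: only this makes the unsaturated ratio equal k·ω and
hence approximately veridical speed at k ≈ 1/sf). In the unsaturated regime
(p̄c ≪ s_p, always reached at high ω because p̄ falls off steeply) the output
is k·ω at every contrast; at low speeds the low-pass filter saturates first
and the output *decreases* with contrast — for s_p = s_m this reversal
occurs exactly where k·ω > 1. Zero contrast is a domain error (both filter
outputs vanish; the c → 0⁺ limit is k·ω·s_p/s_m).

Default constants are the combined-model values τ₁ = 0.0353 s,
τ₂ = 0.0211 s, k = 0.55, s_p = s_m = 0.5; `RatioParams.literature()` gives
the original filter-literature values (0.0072, 0.0043, k = 4). A caveat
worth stating: with the combined-model constants, the speed below which
contrast depresses the output by more than 1% evaluates to ≈ 6.6 deg/s at
2 cycles/deg (the deficit peaks near 29% at 2 deg/s and falls below 1% only
above ~6.6 deg/s). Descriptions of this front end sometimes place the
contrast-dependent region below ~2 deg/s; that characterisation is not
reproducible from these equations under any reading we tried (percent-scale
contrast, complex filter sums, swapped time constants, squared-modulus
exponents), so the package implements the equations as written and reports
the computed crossover honestly.

## Experiment simulator

The design crosses contrast pairs {3/15, 3/95, 15/95 %} with reference speeds
{1, 4, 8, 12} deg/s (12 conditions; reference is always the lower-contrast
grating). Speeds 1 and 4 form the low-speed block (2 staircases per condition
per session, 420 trials/session); 8 and 12 the high-speed block (8 per
condition per session, 1680 trials/session). Five sessions pool to 10 and 40
staircases per condition respectively. Sessions are retained in the trial
logs but pooled by the summary, and the randomized reference side is logged
but does not influence the simulated observer.

Each staircase is a QUEST run of 35 trials: a posterior over candidate PSEs
is maintained on a 201-point log-spaced grid (0.05–40 deg/s), each trial is
placed at the posterior mode (ties toward the lower speed), and the final
mode is the recorded PSE. The update kernel is a Weibull (Gumbel) in log10
speed with slope β = 3.5 and lapse rate δ = 0.01, *re-centred so its median
sits at the candidate PSE*: in a matching task the estimand is the 50% point,
and an uncentred 2-AFC Weibull (γ = 0.5) would converge to the ~81% point and
bias the PSE upward by a substantial fraction of the discrimination
threshold. The chance level γ = 0.5 is kept in the config as documentation
of the task structure and validated, but does not shift the kernel. The
initial QUEST prior is Gaussian in log10 speed, centred on the condition's
reference speed with SD 0.5 log10 units (wide enough to be quickly
overwhelmed). Simulated staircases are unbiased against the analytic PSE
(checked over 100 seeded runs per condition).

Randomness: one `numpy.random.SeedSequence` child per staircase, spawned from
the master seed in a fixed schedule order, so any staircase is reproducible
in isolation and datasets are byte-identical under a repeated seed.

The default generative observer has slopes (−0.3, −0.15, −0.08, −0.05) —
negative and flattening with speed, i.e. a slow-speed prior of plausible
magnitude — width knots g = (0.2, 0.8, 1.6, 2.4) (roughly Weber-like growth
with speed), q = 2, c50 = 0.1. What the simulator does **not** emulate:
lapses and response biases, learning or session effects, left/right position
effects, and any deviation of real observers from the Gaussian-posterior
sampling rule. Passing recovery tests therefore show that the fitting method
inverts the model under its own assumptions at realistic trial counts and
noise levels — not that human data obey those assumptions.

## Fast fitting method

Input: one mean PSE and one across-staircase variance per condition. We take
σ²_PSE to be the squared standard error of a *single* staircase's PSE
estimate, i.e. the sample variance across the pooled staircases (ddof = 1),
not the squared SEM of their mean: the variance relation
σ²_PSE = α(σ₁² + σ₂²)/N contains the number of trials per staircase N but not
the staircase count, and only the sample-variance reading keeps its
proportionality constant comparable between the 10-staircase and 40-staircase
blocks (simulation confirms: the fitted constant varies by less than a factor
of 2 across the 12 conditions, with α_sim ≈ 2 at the default observer —
same order as the human-calibrated default α = 6.6). α is exposed in
`FitConfig` (default 6.6) and N as `n_trials` (default 35), so the divisor is
N/α rather than a hard-coded constant.

The objective stacks mean-PSE residuals in deg/s with log-variance residuals
(weight 1 by default; the log scale makes the variance residuals
scale-free). Predicted PSEs solve the posterior-mean equality by bisection
over [10⁻³, 200] deg/s, vectorised across conditions; σ₂ is evaluated at the
predicted (not observed) test speed, keeping the forward model self-contained
(the difference is second order near the PSE). Conditions where the equality
has no root in the bracket are flagged non-invertible; inside the optimizer
they contribute a penalty proportional to the bracket violation, which gives
the search a slope back into the feasible region (a constant penalty was
found to stall single-start fits).

Optimization is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) with 20 seeded multistarts: a neutral start (slopes
−0.1, g = 1, q = 2, c50 = 0.1) plus ±50% multiplicative jitters, clipped to
the box bounds (slopes [−3, 1], g [10⁻³, 20], q [0.5, 8], c50 [0.005, 0.9]).
Fits are deterministic given `master_seed`.

Identifiability: g and h share an overall scale, and a(ν) multiplies σ², so
the identifiable quantities are the products a(ν)·σ²(ν, c). On noise-free
model-generated tables the fit recovers these products to machine precision
(tested at ≤ 0.5%). On simulated data, a mismatch between the configured α
and the simulator's actual proportionality constant rescales all fitted σ²
by a common factor and the slopes by its inverse — signs, ordering and all
CDB predictions are unaffected, which is why recovered slopes are reported by
sign and rank.

Goodness of fit (SSE, R²) is computed on CDB ratios (predicted and observed
PSE divided by reference speed), the dimensionless quantity the data are
plotted in; the residual space of R² is otherwise a matter of convention and
ours is stated here.

## Trial-level reference method and combined fit

`fit_full_likelihood` maximizes the Bernoulli log-likelihood of every 2-AFC
response under the closed-form choice probability, over the same 10
parameters (L-BFGS-B, same multistart scheme). It uses N times more data per
staircase and serves as the reference: on a common synthetic dataset the two
methods reconstruct priors with identical density rank order at the knot
speeds.

`fit_combined` fits the ratio front end's shared constants by nested
optimization: the outer search adjusts (s = s_p = s_m, k, a common scale on
the literature time constants) over a coarse geometric grid — always
including the published optimum (0.5, 0.55, 4.9) as a start — followed by
Nelder–Mead refinement, while the inner problem refits the 10 Bayesian
parameters per candidate (so the combined model has the same per-subject
parameter count as the plain one). Multiple subject tables share one set of
ratio constants. Passing `ratio_candidates=[None]` makes the front end absent
and reproduces `fit_model` exactly, which pins the nesting property in tests.

## Prior reconstruction

p(ν) = exp(∫a(ν)dν), by cumulative trapezoidal integration of the
interpolated slope from the lowest grid speed, with density 1 there
(integration-constant convention absorbing the log-linear intercept).
Trapezoidal integration is exact between knots because the integrand is
piecewise linear; grids intended for quantitative use should include the knot
speeds.

## Numerical and scale choices

- PSE solver: 70 bisection halvings (relative bracket ~2e-19); the scalar
  API uses Brent's method with xtol 1e-12 and raises on a non-bracketing
  interval to flag non-identifiable conditions.
- Choice probabilities are clipped to [1e-12, 1 − 1e-12] inside likelihoods.
- QUEST ties at the posterior mode break toward the lower speed
  (first-maximum convention on the ascending grid).
- Test-suite problem sizes: recovery and method-agreement checks run on one
  full default-design dataset (300 staircases, 10,500 trials); the
  variance-proportionality check scales sessions to 25 (1,500 staircases) so
  each per-condition variance estimate has relative SD ≤ 20%, small against
  its factor-2 acceptance band. These sizes are the package's validation
  conditions, chosen once.

## Known limitations

- The semi-parametric prior is only as fine as its four knots; speeds outside
  [1, 12] deg/s inherit the boundary slopes.
- α is treated as a configuration constant; its default (6.6) comes from a
  human-data calibration that the simulator does not reproduce exactly
  (simulated α ≈ 2 under the lapse-free ideal observer). Only products
  a·σ² should be interpreted quantitatively.
- The ratio front end admits no parameter set in which contrast *increases*
  output at high speeds, so the combined model improves fits only at low
  speeds; this is a property of the model family, not of the fitter.
- No per-contrast priors, no session/learning effects, no alternative
  adaptive procedures (PEST, Psi), no population encoding stage.
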