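# Methods

## Model

Two fingers, one per hand, jointly hold an isometric force target *g*
(Newtons). Finger *i*'s force is a Gaussian random variable with mean
equal to its motor command *u<sub>i</sub>* and standard deviation
*k<sub>i</sub> u<sub>i</sub>* (signal-dependent noise; *k* is the
finger's coefficient of variation, a dimensionless fraction). The
command pair is assumed to minimize

J = ν̃ E[(x<sub>i</sub> + x<sub>j</sub> − g)²]
  + λ̃ (u<sub>i</sub>² + u<sub>j</sub>²)
  + μ̃ ((u<sub>i</sub>/MVC<sub>i</sub>)² + (u<sub>j</sub>/MVC<sub>j</sub>)²),

a static, per-level trade-off between accuracy, absolute effort and
strength-normalized effort. The raw weights (ν, λ, μ) live on the unit
simplex; each is divided by a normalization constant — the population
means of (k<sub>i</sub>² + k<sub>j</sub>²), the constant 2, and
(1/MVC<sub>i</sub>² + 1/MVC<sub>j</sub>²) respectively — so equal raw
weights mean equal influence on the optimum. Taking expectations turns
J into a quadratic with effective coefficients
a = ν̃k² + λ̃ + μ̃/MVC², minimized at

u<sub>i</sub>\* = g a<sub>j</sub> / (a<sub>i</sub> + a<sub>j</sub> +
a<sub>i</sub>a<sub>j</sub>/ν̃),  u<sub>j</sub>\* =
(a<sub>i</sub>/a<sub>j</sub>) u<sub>i</sub>\*.

We re-derived this from the stationarity conditions: the denominator
carries the *normalized* error weight ν̃ and the numerator a factor of
*g*, which is the unique dimensionally consistent form and the one an
independent numeric minimizer confirms to 1e-8 (the tests enforce
this). The optimal share c\* = a<sub>j</sub>/(a<sub>i</sub>+a<sub>j</sub>)
is independent of *g* and of common rescaling of the raw weights; it is
the quantity the data constrain. Whether absolute predicted forces use
ν or ν̃ in the denominator cannot be settled from shares alone; we use
ν̃ throughout for consistency with the quadratic being minimized.

## Calibration

Unimanual force holds (nominally 7 s at 200 Hz per target level)
calibrate each finger. The analysis window is the middle 5 s —
fractions (1.5/7, 6.5/7) of the recording — dropping the ramp-up and
the final settling; the window is configurable because no canonical
choice exists. Within-trial SD uses the n−1 denominator.

*k* is the slope of a no-intercept regression of within-trial SD on
within-trial mean (the noise model has no intercept by construction),
fitted robustly by iteratively re-weighted least squares with a Tukey
bisquare weight, tuning constant 4.685 (the standard 95%-efficiency
value), convergence 1e-8 on coefficients, at most 100 iterations
(statsmodels RLM provides the IRLS engine). A perfectly linear
(zero-residual) dataset short-circuits to the exact least-squares
slope, where the robust scale estimate would be undefined.

MVC is operationalized as the highest target whose windowed mean
reaches 95% of the target — a maintained-force criterion standing in
for "the largest force the participant could hold"; the threshold is
configurable. The k–MVC association is an ordinary least-squares fit of
*k* on MVC with intercept; the slope's t statistic has n−2 degrees of
freedom and Pearson r is reported alongside.

## Inference

At each force level *l*, observed shares y<sub>lm</sub>(n) ∈ (0,1) for
participant *m* are Gaussian around the participant's c\* with variance
σ²<sub>y,lm</sub>. Priors: uniform on the weight simplex, and the
scale-invariant π(σ²) ∝ 1/σ² (inverse-gamma InvGa(0,0); the flat-prior
variant InvGa(−1,0) is a configuration switch and behaves essentially
identically). The simplex is sampled through the stick-breaking map
ν = w, λ = (1−w)z, μ = (1−w)(1−z), under which w and z have independent
U(0,1) priors.

One sampler cycle: adaptive random-walk Metropolis on w, then on z,
deterministic recomputation of μ, then an exact Gibbs draw of every
σ²<sub>y,lm</sub> from InvGa(N<sub>lm</sub>/2, RSS<sub>lm</sub>/2).
Proposals are Gaussian steps on the logit scale with the Jacobian
x(1−x) in the acceptance ratio, so bounded support never truncates the
proposal; the proposal log-SD adapts after every batch of 50 proposals
by ±min(0.01, b<sup>−1/2</sup>) toward a 0.44 acceptance rate
(diminishing adaptation, so ergodicity is preserved). Initialization:
w = z = 0.5, variances at per-participant sample variances. Default run
length is 90 000 cycles with a 40 000 burn-in; the bundled pipeline
configuration and most tests use 9 000/4 000, which the grid-quadrature
and recovery checks show is ample for these posteriors (single-level
fits have 2 + M parameters and well-behaved, unimodal posteriors).

Reduced models pin stick coordinates rather than adding samplers: ν = 0
fixes w = 0 (z parameterizes λ vs μ); λ = 0 fixes z = 0; μ = 0 fixes
z = 1; single-term models fix both coordinates at a simplex vertex and
sample only variances. Participants with constant shares are rejected
at fit time — their variance conditional would be improper.

Levels are fitted independently; chains are pure functions of
(data, model, constants, T, burn-in, seed), and per-level seeds are
derived deterministically so joint and single-level runs coincide.

## Model comparison

The primary fit score is the data log-likelihood averaged over
posterior samples. This is *not* an integrated (marginal) likelihood;
we implement the quantity as historically defined for this analysis and
label it accordingly. Log Bayes factors are differences of these
scores; AIC = −2·max log-likelihood + 2d, with the maximum taken over
posterior samples (no separate optimizer — adequate because the
averaged score, not the maximum, carries the comparisons) and d
counting free weight parameters (2 full, 1 pairs, 0 singles) plus
variance parameters (M per level, or 1 pooled), summed over levels.
Per-level maxima sum to the joint maximum because per-level parameters
are disjoint.

## Synthetic data

The generator emulates the study design: 14 participants; weak-finger
(left little) profiles k = 2.38 ± 1.2 %, MVC = 12.71 ± 2.30 N and
strong-finger (right index) profiles k = 1.62 ± 0.59 %,
MVC = 23.29 ± 5.18 N, drawn from normals truncated at zero (published
group means and SDs; truncation shifts means by well under one
percent); force levels 4–28 N in steps of 4; 50 share observations per
participant per level. Share noise is additive Gaussian on the share
scale — the direct generative reading of the likelihood — with
per-participant SDs drawn from 0.05 ± 0.015 (floored at 0.005), a
dispersion consistent with shares measured to a few percent; draws
outside (0,1) are redrawn, and the generator warns if truncation alters
more than 0.1% of draws. Unimanual trials ramp linearly to target over
1.5 s (matching the analysis window) and hold; targets above MVC
plateau at MVC, so they fail the maintained-force criterion. The
default level-dependent ground truth moves λ from 0.75 to 0.30 and μ
from 0.15 to 0.60 with ν = 0.10 throughout, reproducing the reported
qualitative pattern (absolute effort dominates at low force; normalized
effort catches up at high force).

What the generator does *not* emulate: within-trial autocorrelation
(samples are i.i.d. given the command), fatigue or learning across
trials, trajectory-level dynamics, and any mismatch between the
Gaussian share model and real share distributions. Passing recovery
tests therefore certify the estimation machinery under the model's own
assumptions, not robustness to model misspecification.

## Numerical choices and edge cases

- Sufficient statistics (N, Σy, Σy²) per participant make each
  likelihood evaluation O(M) regardless of the number of observations.
- Logit saturation in proposals (expit rounding to exactly 0 or 1) is
  treated as a rejection.
- Weight validation tolerates simplex deviations up to 1e-9;
  stick-breaking outputs satisfy the constraint exactly by
  construction.
- CSVs are written with pandas' shortest round-trip float repr and read
  with `float_precision="round_trip"`, so write→read is bit-exact.
- The quadrature oracle used in tests integrates the variances out of
  the posterior analytically (inverse-gamma normalizers) and evaluates
  the (w, z) marginal on a uniform grid — an independent path that
  never touches the sampler.

## Known limitations

- The posterior-averaged log-likelihood rewards fit only; its use for
  model selection inherits whatever biases that historical choice has.
- The maximum over MCMC samples underestimates the true maximum
  likelihood slightly, so AIC values are conservative for
  better-mixing models.
- With a single participant or strongly overlapping profiles, the three
  weights are only weakly identified from shares; intervals widen
  accordingly but no warning is raised.
- Association statistics assume independent (k, MVC) points; fingers
  nested within participants violate independence, as in the original
  analysis design.
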