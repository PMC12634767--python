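# Methods

## Model and procedure

`fosmod` fits a function-on-scalar regression pointwise: at each of K
normalized times t_k the response vector (one curve value per observation)
is regressed by OLS on a shared design X = [1 | ndi | age | neck_length |
sex] (p = 5 with the intercept).  Because the design is common to all
times, a single QR factorization serves every fit; β̂(t_k) is the least
squares solution, s²(t_k) the residual sum of squares over d = n − p, and
v_jj the j-th diagonal entry of (XᵀX)⁻¹ (time-invariant).  Ordinary
inference uses t = β̂_j/(s·√v_jj) with d degrees of freedom.  Errors are
treated as independent across observations; the motivating study design
(two sessions per subject) would support a random-effect extension, but
the pointwise model is implemented exactly as stated, without one.

Variance moderation follows the empirical-Bayes scheme of the limma
method.  The prior 1/σ²(t_k) ~ χ²_{d₀}/(d₀·s₀²) has its hyperparameters
estimated once per fitted response model by moment matching on
z_k = log s²(t_k):

* E z = log s₀² + log(d₀/2) − ψ(d₀/2) + ψ(d/2) − log(d/2)
* Var z = ψ′(d₀/2) + ψ′(d/2)

so d₀ = 2·ψ′⁻¹(v − ψ′(d/2)) with v the sample variance of z, and s₀²
follows from the mean equation.  When v ≤ ψ′(d/2) the prior spread is
indistinguishable from zero and d₀ = +∞ is stored explicitly (the
posterior variance is then s₀² everywhere and the null law is standard
normal).  ψ′⁻¹ is computed by a Newton iteration on the near-linear map
x ↦ 1/ψ′(x), started at 0.5 + 1/y, at most 50 steps, relative tolerance
1e-8; the implementation agrees with Bioconductor `limma::squeezeVar` to
six significant digits on shared fixtures (asserted in the test suite).

The squeezed variance is the posterior mean
s̃² = (d₀s₀² + d·s²)/(d₀ + d); the moderated statistic divides β̂ by
s̃·√v_jj — the square root of the squeezed variance, which is what makes
the statistic reduce exactly to the ordinary t as d₀ → 0 — and is referred
to a t distribution with d + d₀ degrees of freedom.  Moderation touches
only the variance estimate: coefficients, fitted means and effect curves
are bitwise unaffected, and a regression test locks this in.

Raw p-value functions (one per non-intercept coefficient and method) are
adjusted across their own K times only — never pooled across coefficients,
methods or responses; a test locks this scoping too.  BH is the classic
step-up adjustment (sort, scale by K/i, cumulative minimum from the top,
cap at 1); BY multiplies by c(K) = Σ 1/i before the same steps, hence
BY ≥ BH ≥ raw elementwise.  Significance regions are maximal runs of grid
times with adjusted p ≤ α, reported as [t_first, t_last] without sub-grid
interpolation.

## Preprocessing

Raw recordings (long CSV: id, time_s, angle_deg) are segmented into
complete cycles between consecutive angle minima (maximum flexion) found
with a prominence threshold defaulting to 20% of the recording's angle
range; the first and last cycles are discarded (movement onset and
termination are atypical), each kept cycle is resampled onto the [0, 1]
grid with a natural cubic spline mapped linearly over the cycle's real
duration, and the kept cycles are averaged pointwise.  Velocity and
acceleration differentiate the spline representation with respect to real
time via the chain rule d/dt = (1/T)·d/ds using the per-observation mean
cycle duration T, so units advance deg → deg/s → deg/s².  Natural end
conditions leave a localized O(h²) derivative error at the two boundary
points when the curve's second derivative does not vanish there; interior
accuracy is better than 0.1% for harmonic signals at K = 100.
Differentiation before or after averaging commutes exactly for splines on
a common grid; the per-cycle route is the default when raw recordings are
available.

## Synthetic data generator

The generator is exactly the model assumed by the inference stages, so
pipeline runs on its output are correctly specified problems with recorded
ground truth.  Defaults describe one study-like condition and are not
tuning knobs:

| quantity | default | rationale |
|---|---|---|
| n, K | 55, 100 | study sample size and grid |
| NDI | trunc-normal(10.11, 4.76²) on [0, 50], rounded | sample descriptives |
| age (yr) | trunc-normal(34.67, 12.45²), positive | sample descriptives |
| neck length (cm) | normal(14.98, 1.81²) | sample descriptives |
| sex | Bernoulli(20/55), 0 = female reference | sample composition |
| amplitude_base | 52.1 deg | population range of motion 2A ≈ 104.2 deg |
| duration_base | 3.71 s | harmonic range of velocity 4πA/T ≈ 176 deg/s |
| prior (d₀, s₀²) | (4, 25 deg²) | heterogeneous noise, error SD ≈ 5% of amplitude |
| NDI effect | raised-cosine bump, −0.6 deg/unit on [0.1, 0.4] | a detectable disability effect on 30% of the grid |

The cycle template is A·(−cos 2πt) (flexion → extension → flexion); the
velocity and acceleration response templates are its real-time
derivatives.  A harmonic cycle calibrated to the observed angle and
velocity ranges yields a range of acceleration of ≈ 300 deg/s², below the
≈ 423 deg/s² a real (non-harmonic) movement shows; no result depends on
the acceleration scale.  Covariate effects enter centered at the
configured covariate means, y = template + Σ_j (x_j − μ_j)·β_j(t) + ε, so
the template alone fixes the population-mean curve; the stored truth is
re-expressed in the raw-design parameterization (the intercept absorbs
−Σ μ_j β_j) and a zero-noise fit recovers it to machine precision.  The
default NDI bump is centered where the template crosses zero so it leaves
the population range of motion untouched.

Noise is drawn independently across times by default ("iid"), matching the
pointwise model; variances come from the prior unless a fixed σ²(t)
profile is supplied.  A "smooth" mode instead draws standard-normal values
at a configurable number of spline knots and evaluates the resulting
continuous noise paths on any requested grid — this makes the *same*
continuous dataset samplable at several resolutions, which the
grid-robustness analysis requires, at the cost of the marginal variance
only approximately tracking σ²(t) between knots.  An optional hook adds
the longer necks observed in men (`neck_length_sex_shift`), off by
default since no covariance structure is part of the default condition.

What the generator does **not** emulate: subject-specific phase
variability (cycles are phase-locked; registration is assumed upstream),
within-subject correlation between repeated sessions, non-harmonic
waveform detail, and smooth measurement noise in the iid mode —
differentiating iid per-point noise amplifies it roughly K-fold, which is
why derived velocity/acceleration curve sets are meaningful mainly for
noise-free or smooth-noise configurations, and why velocity-response
analyses generate velocity curves directly from the velocity template.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not robustness to the registration
and dependence issues real recordings add.

## Numerical choices and edge cases

* QR-based solves everywhere (shared design factorized once); rank
  deficiency is a hard error naming the offending column.
* An optional covariate-centering flag exists for conditioning; it
  provably changes neither t nor p and a test asserts this.
* se = 0 with β̂ = 0 yields t = 0, p = 1; se = 0 with β̂ ≠ 0 yields p = 0
  with a warning (perfect fit contradicting the null).
* Non-positive residual variances (possible only for degenerate synthetic
  input) are excluded from hyperparameter estimation with a warning and
  squeezed normally afterwards.
* d₀ = 0 returns the ordinary statistics exactly (special-cased to avoid
  a rounding step); d₀ = +∞ is represented as `math.inf`, not capped.
* BH/BY ties are handled naturally by the cumulative minimum; sorting is
  stable, so adjustment is permutation-equivariant.
* CSV numerics are written at full double precision and parsed with
  round-trip float handling; curve-matrix round trips are bitwise.

## Design decisions taken where the method statement was open

* The moderated statistic divides by s̃ (not s̃²): the variance form fails
  the d₀ → 0 reduction and contradicts the method's source; treated as a
  typographical slip.
* Hyperparameters are estimated per response model, never pooled across
  the angle/velocity/acceleration models, whose variance scales differ by
  orders of magnitude.
* Sex is coded 0/1 with female (the majority group) as reference.
* Time normalization is per cycle; acceleration is obtained by
  differentiating the velocity spline (the alternative — a separate
  estimator — is not specified anywhere).
* Effect displays default to the moderated, BH-adjusted p-value function
  at α = 0.05 for their significance shading, with BY available
  throughout.

## Known limitations

* The within-subject dependence of repeated sessions is ignored by design
  (the pointwise model treats all observations as independent).
* BH-adjusted values near a p-curve's *minimum* are intrinsically
  sensitive to grid resolution when that minimum is borderline: the
  adjustment scales by K/rank, and the empirical rank of a shallow dip
  shifts between grids.  Grid-size robustness (the 100 vs 1000 vs 10000
  point comparison in `analysis/05_grid_robustness.py`) therefore holds
  for datasets whose p-value functions are well separated from the
  threshold — the regime of the motivating data — and cannot be expected
  for borderline null effects.
* The moment-matching hyperparameter estimator assumes all K variances
  follow one prior; no robustified variant is implemented (documented
  extension point).
* Problem sizes in the test suite and acceptance script (replicate counts
  of 20–200, grids up to 10⁴ points) were chosen as the smallest sizes at
  which the stochastic properties stabilize.
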