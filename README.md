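# fosmod

Function-on-scalar regression with empirical-Bayes variance moderation and
FDR-controlled p-value functions, built for cyclic kinematic curves such as
neck flexion-extension recordings.

## The problem

Clinical movement analyses often reduce a whole movement cycle to scalars
(range of motion, peak velocity), discarding *where* in the cycle a
clinical score such as the Neck Disability Index (NDI, 0–50) matters.
`fosmod` instead treats each time-normalized curve — angle (deg), angular
velocity (deg/s) or angular acceleration (deg/s²) on a common grid
t ∈ [0, 1] — as the response of a pointwise linear model with scalar
predictors (NDI, age, neck length, sex):

```
Y_i(t_k) = x_iᵀ β(t_k) + ε_i(t_k),   ε_i(t_k) ~ N(0, σ²(t_k)),   k = 1..K
```

Fitting K regressions (default K = 100) raises two statistical problems
this package solves the way the omics literature does:

1. **Variance moderation (limma).** With few observations per fit, the
   per-time residual variances s²(t_k) are noisy.  Assuming the precisions
   follow a scaled inverse-χ² prior, 1/σ² ~ χ²_{d₀}/(d₀·s₀²), the
   hyperparameters (d₀, s₀²) are estimated from all K fits by moment
   matching on log s², and each variance is squeezed toward the prior
   scale: s̃²(t_k) = (d₀s₀² + d·s²(t_k)) / (d₀ + d), with d = n − p.  The
   moderated statistic t̃_j(t_k) = β̂_j(t_k)/(s̃(t_k)·√v_jj) is
   t-distributed with d + d₀ degrees of freedom under the null — extra
   degrees of freedom borrowed across time.
2. **Multiple testing across time.** The raw p-value function p_j(t_k) of
   each coefficient is adjusted over its K times by Benjamini–Hochberg
   (BH) and by Benjamini–Yekutieli (BY, valid under the positive
   dependence between nearby times), and maximal grid intervals with
   adjusted p ≤ α become the significant movement phases.

The package also contains the upstream preprocessing (cycle segmentation
of raw recordings, discarding first/last cycles, spline time
normalization, cycle averaging, spline differentiation to velocity and
acceleration) and a synthetic study generator with known ground truth,
calibrated to realistic ranges (~104 deg range of motion, ~176 deg/s range
of velocity) — the model's exact data-generating law, so every stage is
testable without access to clinical recordings.

## Worked example

```python
import fosmod as fm

study = fm.simulate_study(fm.GeneratorConfig(seed=1))      # n=55, K=100
fit = fm.fit_pointwise(study.curves, fm.build_design(study.covariates))
mod = fm.moderated_inference(fit)                          # estimates (d0, s02)
print(mod.params)
pf = next(p for p in fm.assemble_pvalue_functions(fit, mod)
          if p.coefficient_name == "ndi" and p.method == "moderated")
print(fm.significant_regions(pf, "bh", 0.05).intervals)
```

prints

```
ModerationParams(d0=4.886002423858601, s02=25.723410685449494)
[(0.21212121212121213, 0.21212121212121213), (0.23232323232323235, 0.26262626262626265), (0.2828282828282829, 0.2828282828282829), (0.5252525252525253, 0.5252525252525253)]
```

The estimated prior degrees of freedom (≈4.9) and scale (≈25.7 deg²) sit
close to the generating values (4, 25); the BH-significant region for NDI
concentrates inside the true effect window [0.1, 0.4] — the phase of the
cycle where the generator makes disability reduce the movement — plus one
isolated false time, consistent with FDR (not familywise) control.

The same workflow is available from the shell:

```sh
fosmod simulate --out study/ --seed 1
fosmod fit --curves study/curves_angle.csv --covariates study/covariates.csv --out fit/
fosmod effects --curves study/curves_velocity.csv --covariates study/covariates.csv \
       --response velocity --vary ndi --out effects.csv
```

The numbered scripts under `analysis/` run the complete study narrative
(simulate → fit three responses → effect curves → FDR calibration → grid
robustness) and write their tables under `results/`.

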