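# proxylearn

Trial-by-trial modelling of visuomotor skill acquisition under
**error-augmentation (EA)** training with **intermittent feedback**.

## The problem

In reaching experiments with error-augmented cursor feedback, the learner's
signed error is measurable only on occasional *no-vision catch trials*
(roughly one in four, never two in a row). Classical trial-by-trial learning
models need an error term on every trial, so gaps in the observations must
be bridged. This package implements the *proxy-process* approach: an
autoregressive model of the signed error

    e_{n+1} = e_n + f(e_n, ..., e_{n-k+1}) + sigma * dz_n,   dz ~ N(0, 1)

forward-predicts an error estimate across trials without feedback. Eleven
drift structures `f` compete: linear `1.1L` (f = b·e), affine `1.1`
(a + b·e), quadratic `1.2`, cubic `1.3`, and the k-th order linear-history
family `k.1` (a + b₁e_n + … + b_k e_{n−k+1}) for k = 2…8. The winning
structure is then embedded in a **two-rate state-space learner** (fast and
slow states x_f, x_s with retention rates A_f, A_s and learning rates
B_f, B_s; prediction ŷ = x_f + x_s) whose error drive ê_n is the
observation when available and the second-order proxy prediction otherwise.

The package provides, for users studying motor learning, feedback-schedule
design, or EA-based training:

* a **synthetic experiment generator** reproducing the study design
  (15 subjects, 8 tasks × 250 trials + 30-trial washout, 6 reach directions
  on a 15 cm equilateral triangle, 74 non-adjacent catch trials per phase,
  EA gain ∈ {0..3} × offset ∈ {0..2} with control {1, 0}), with known
  ground-truth dynamics;
* statsmodels-style model classes — `ProxyProcessModel`, `MultiRateModel`,
  `WashoutDecayModel` — whose `fit()` returns a results object with
  estimates, SSE/RMSE/R²/R²adj, residuals, a `summary()` and a `plot()`;
* **exhaustive cross-validation model selection** (4/5–1/5 splits over
  subjects per EA coordinate, or over tasks within control subjects;
  KDE-mode RMSE per partition; left-tailed Wilcoxon signed-rank over all
  110 ordered model pairs with Bonferroni correction; model score =
  wins − losses);
* **weighted-bootstrap inference** (resampling weighted by 1/RMSE of each
  curve's fit): sign tests, rank-sum tests vs the control coordinate,
  bootstrap medians with 95% CIs, steady-state-error and washout
  time-constant tables;
* a CLI (`proxylearn simulate|fit|select|retention|stats|report|all`)
  running the whole pipeline reproducibly from one seed.

## Worked example

```python
import numpy as np
import proxylearn as pl

# one control learning curve from the synthetic experiment
design = pl.DesignConfig(n_subjects=1, n_control=1, n_tasks=1, n_directions=1)
data = pl.generate_dataset(design, rng=np.random.default_rng(7))
curve = data[(data.task == 1) & (data.direction == 1) & (data.phase == "learning")]

model = pl.ProxyProcessModel.from_curve(curve, "2.1")
result = model.fit(pl.FitConfig(n_starts=50, seed=0))
print(result.summary())

ss = pl.steady_state_error(result.params.spec, result.params, model.e0)
print(f"steady-state error at trial 250: {ss.value:.3f} cm")
```

prints

```
Proxy-process fit: structure 2.1 (order 2, 3 drift coefficients)
  observations: 74 no-vision trials of 250; e0 = -4.629
     a = -0.019561
    b1 =  0.241768
    b2 = -0.537236
  sigma = 0.000842625
  SSE = 3.28383  RMSE = 0.210656  R2 = 0.8677  R2adj = 0.8620
steady-state error at trial 250: -0.066 cm
```

The fit recovers the damped-oscillatory second-order dynamics of this
curve's ground truth (b₁ = 0.2, b₂ = −0.48): errors shrink from a ≈ 4.6 cm
first exposure towards a steady state near zero, with b₂ < 0 expressing the
reduction in the rate of change of error driven by the previous trial's
error. `sigma` is the estimated Wiener inter-trial noise scale (residual
standard deviation normalized by the 250 learning-curve trials), and the
negative steady state means slight overcompensation at the end of training.

Running the full pipeline from a shell:

```bash
proxylearn all --test-scale --seed 3 --out runs/demo
```

writes the trial table, per-curve proxy and two-rate fits, cross-validation
matrices, bootstrap statistics tables, washout fits and a run manifest to
`runs/demo/`.

## Layout

| module | contents |
| --- | --- |
| `proxylearn.structures` | the 11 proxy-process drift structures, simulation, steady state |
| `proxylearn.multirate` | two-rate learner dynamics with proxy-bridged gaps |
| `proxylearn.fitting` | `ProxyProcessModel`, `MultiRateModel`, `WashoutDecayModel` + results |
| `proxylearn.simulate` | synthetic experiment generator (geometry, schedules, EA, errors) |
| `proxylearn.selection` | exhaustive CV, KDE-mode scoring, pairwise significance, model scores |
| `proxylearn.stats` | weighted-bootstrap sign/rank-sum tests, medians, figure-style tables |
| `proxylearn.io` / `.pipeline` / `.cli` | trial-table I/O, configs, staged pipeline, CLI |
| `proxylearn.validation` | end-to-end recovery/calibration experiments |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
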