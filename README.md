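# flutterpath

Movement analysis for ground-tracked butterflies along rural–urban
gradients: from second-resolution DGPS point tracks to mixed-model
inference about how urbanization and nectar-plant availability shape
mobility and flight-path tortuosity.

The package is written for movement ecologists who record butterfly
(or other slow insect) trajectories by following individuals with a
high-accuracy GPS and noting stops on a field sheet. It covers the
full chain:

1. **Track processing** — CSV/GeoJSON readers, local metric
   projection, gap detection and gap-aware segmentation, consolidation
   of annotated stop point-clouds onto their geometric median
   (Weiszfeld), and the two derived views of a track (mobility /
   tortuosity).
2. **Metrics** — mean flight speed (flying-time based), time-budget
   shares (stopping, nectaring, resting), and Benhamou's corrected
   sinuosity

   Sin = 2 · [ p · ( (1+c)/(1−c) + b² ) ]^(−1/2)

   with p the mean step length, c the mean cosine of turning angles,
   b the step-length CV — weighted across gap-split segments by
   relative segment length.
3. **Covariates** — transect nectar coverage (mean percent cover per
   1-m segment), biotope-class imputation of partially covered
   imperviousness rasters, zonal mean sealing within 500/1000/2000 m
   buffers, habitat polygon area.
4. **Inference** — statsmodels-style model objects:
   `MovementGLMM(...).fit()` returns a results object with estimates,
   Wald z/p, random-intercept variances, AIC, `summary()`,
   `simulate()`, and DHARMa-style randomized-quantile residual
   diagnostics (KS uniformity + Monte-Carlo dispersion). Families:
   beta (logit) and lognormal (log); random intercepts for habitat
   area, track duration and site.
5. **Synthetic data** — correlated-random-walk tracks with annotated
   stop bouts and GPS dropout, transects, landscapes, and a
   study-level generator with known regression coefficients, so every
   stage can be validated against ground truth.

## Worked example

```python
import numpy as np
from flutterpath import (consolidate, summarize_track)
from flutterpath.simulate import TrackSimConfig, simulate_track

cfg = TrackSimConfig(n_steps=336, turn_kappa=1.1589, step_cv_b=0.5,
                     stop_rate=2.0, seed=1)   # ~5.6 min track, c ~ 0.5
traj, events, truth = simulate_track(cfg)
pt = consolidate(traj, events)                # stop clouds -> medians
s = summarize_track(pt)
print(f"speed {s.flight_speed:.2f} m/s (true {truth['speed']:.2f})")
print(f"stopping {s.stopping:.3f} (true {truth['stopping_share']:.3f})")
print(f"sinuosity {s.sinuosity:.2f} (theory {truth['sinuosity']:.2f})")
```

prints

```
speed 0.99 m/s (true 1.00)
stopping 0.263 (true 0.263)
sinuosity 1.08 (theory 1.11)
```

— the time-budget share is recovered exactly (the event log is
authoritative), speed to within the stop-jitter noise, and the
sinuosity estimate scatters around the closed-form CRW value.

Fitting the study's model to a simulated study with known
coefficients:

```python
from flutterpath.glmm import MovementGLMM
from flutterpath.simulate import StudySimConfig, simulate_study
from flutterpath.stats import scale_predictors

cfg = StudySimConfig(n_sites=29, n_per_site=5,
                     true_coefs={"np_cov": 0.15, "urbanization": -0.15})
summaries, covariates, truth = simulate_study(cfg, seed=1)
table = summaries.merge(covariates.drop(columns=["habitat_area", "np_cov"]),
                        left_on="site", right_on="site_id")
table = table.rename(columns={"urbanization_2000": "urbanization"})
table, _ = scale_predictors(table, ["np_cov", "urbanization"])
fit = MovementGLMM.from_dataframe(
    table, "stopping", fixed=["np_cov", "urbanization"],
    random=["habitat_area", "duration_s", "site"], family="beta_logit",
).fit()
print(fit.summary())
```

```
Movement mixed model (Laplace ML)
================================================================
family: beta_logit    n: 145    residual df: 139
logLik: 136.185    AIC: -258.369    phi: 38.91
----------------------------------------------------------------
fixed effect            estimate   std.err       z         p
Intercept                -0.1304    0.0445  -2.932  0.003372
np_cov                    0.1736    0.0317   5.469 4.518e-08
urbanization             -0.1711    0.0440  -3.888 0.0001009
----------------------------------------------------------------
random intercept variances:
  habitat_area        0.024077
  duration_s          0.029223
  site                0.0053099
```

Both estimates sit within one standard error of the generating values
(+0.15 / −0.15). Nectar coverage varies per individual (one transect
per tracked butterfly), urbanization per site, which is why the
site-level coefficient carries the larger standard error.

## Command line

```bash
flutterpath simulate track|transect|landscape|study --seed 1 --out dir/
flutterpath run --config run.yaml        # full pipeline from files
flutterpath reproduce --data table.csv   # inference on a pre-derived table
```

`run` writes `summaries.csv`, `covariates.csv`, `models.csv/json`,
`diagnostics.csv`, `descriptives.csv`, `report.md` and `run.log`
(config hash, versions, warnings) into the output directory, and is
byte-deterministic given config + seed. `reproduce` accepts a
per-individual table (responses and predictors already derived, the
shape data archives deposit) and skips the trajectory stages.

## Layout

```
src/flutterpath/
  trajectory.py   # domain types, readers/writers, gaps
  projection.py   # local tangent-plane projection (WGS84)
  stops.py        # geometric median, stop consolidation, views
  metrics.py      # sinuosity, speed, time budgets
  raster.py       # ASCII-grid raster container, rasterization
  covariates.py   # transect coverage, imputation, zonal stats, areas
  glmm.py         # MovementGLMM / MovementGLMMResults (Laplace ML)
  stats.py        # scaling, screening, transforms, radius choice
  diagnostics.py  # randomized-quantile residual checks
  simulate.py     # CRW tracks, transects, landscapes, studies
  experiments.py  # the validation experiments
  pipeline.py     # orchestration, reproduction mode, report
  cli.py          # click entry points
```

See `docs/methods.md` for the model details, parameter defaults and
the reasoning behind the design choices.
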