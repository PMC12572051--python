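# shockpanel

Doubly robust estimation of how physical and mental health shocks change
health behaviors, packaged as a tested pipeline on synthetic survey panels
with known causal ground truth.

The package has two halves:

1. **A synthetic panel generator** that mimics the structure of a biannual
   household health survey: two latent health domains followed as AR(1)
   processes, component summary scores normalized to mean 50 / SD 10 at the
   baseline wave, three binary lifestyle outcomes (not smoking, healthy diet,
   doing sports) on different availability grids, ~40 mostly binary baseline
   covariates, confounded latent-health drop events that surface as score
   shocks, absorbing attrition plus transient non-response — and a truth
   table of both potential outcomes per individual so every estimator can be
   validated against a known oracle.
2. **The estimation and diagnostic stack**: the 25%-drop shock definition,
   timing-structured estimation samples (including placebo, full-history and
   attrition-as-outcome variants), cross-fitted propensity and per-arm
   outcome models (tuned random forests or L1 logistic regression), the
   augmented inverse-probability-weighting (AIPW) ATE with R-resample median
   aggregation and influence-function 90% intervals, covariate balance
   (ASMD), threshold sensitivity, subgroup ATEs and squared semi-partial
   correlation (SPC²) heterogeneity screening.

## Quick start (library)

```python
from shockpanel import (GeneratorConfig, generate_panel, oracle_ate,
                        build_sample, TimingSpec, LearnerSpec, ddml_ate)

profile = {("smoke", "physical", 0): 0.05}          # true +5pp effect at lag 0
cfg = GeneratorConfig(n_individuals=20_000, effect_profile=profile, seed=7)
panel, truth = generate_panel(cfg, seed=7)
print(oracle_ate(truth, "smoke", "physical", 0))    # ground truth ~ 0.05

sample = build_sample(panel, TimingSpec("smoke", "physical", 2004, 0))
est = ddml_ate(sample, LearnerSpec(kind="lasso"), K=5, R=3, seed=11)
print(est.estimate, (est.ci_low, est.ci_high))
```

## Command line

```bash
shockpanel simulate --n 5000 --seed 0 --out runs/sim
shockpanel estimate --panel runs/sim/panel.csv --outcome smoke \
    --domain physical --learner rf --out runs/est
shockpanel placebo --panel runs/sim/panel.csv --outcome smoke \
    --domain physical --placebo-shift 2012 --out runs/placebo
shockpanel sensitivity --panel runs/sim/panel.csv --outcome smoke \
    --domain physical --out runs/sens
shockpanel heterogeneity --panel runs/sim/panel.csv --outcome smoke \
    --domain mental --out runs/het
shockpanel attrition --panel runs/sim/panel.csv --outcome smoke \
    --domain physical --out runs/attr
shockpanel report --panel runs/sim/panel.csv --results runs/est --out runs/report
```

Defaults are desk-scale (small forests, a two-value depth grid, R=3);
`--paper-scale` restores the full configuration (500 trees, depth grid
3–20 with 3-fold CV tuning per split, R=15), which takes hours for the full
outcome × domain × lag grid.

Every command writes comma-separated tables plus a YAML manifest with the
effective configuration, its hash, and row counts; reruns with the same seed
are byte-identical.

## Layout

| Path | Contents |
| --- | --- |
| `src/shockpanel/generator.py` | synthetic panel + truth table + calibration |
| `src/shockpanel/shocks.py` | shock indicators, repeat counts, correlation |
| `src/shockpanel/samples.py` | estimation samples, placebo/history/attrition |
| `src/shockpanel/nuisance.py` | cross-fitted propensity/outcome learners |
| `src/shockpanel/aipw.py` | AIPW summands, DDML ATE, subgroup/naive |
| `src/shockpanel/diagnostics.py` | ASMD, chi², sensitivity, attrition |
| `src/shockpanel/heterogeneity.py` | SPC², stratified effects |
| `src/shockpanel/cli.py` | `shockpanel` command group |
| `tests/` | unit, property, and acceptance suites |
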