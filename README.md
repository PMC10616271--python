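# landclim

Linking long-term **land conversion** and **climate warming** to species'
square-level **persistence or extirpation** across a gridded landscape — a
reusable, fully tested pipeline for macroecological range-change analysis
from opportunistic occurrence records.

The package is aimed at ecologists and biostatisticians who hold (a)
two-epoch categorical land-use rasters, (b) per-square temperature series,
and (c) presence records of many species in two recording periods, and who
want to ask: *did warming and habitat conversion act singly, additively, or
interactively on each species' persistence?* Because real national datasets
of this kind are usually restricted, the package ships a synthetic-world
generator with known parameters, so every stage can be validated end to end
by parameter recovery.

## The model

For each species *j*, squares occupied in the first period contribute a
binary outcome (1 = persisted, 0 = extirpated, with an apparent loss only
accepted when another species of the taxon was recorded there in period 2).
Five logistic formulations are fitted per species and compared by AIC:

```
1  y ~ E + M + PCNM1 + PCNM2                 (controls only)
2  y ~ L + controls
3  y ~ ΔT + controls
4  y ~ L + ΔT + controls                     (additive)
5  y ~ L * ΔT + controls                     (interactive)
```

where `L` is land conversion (fraction of fine pixels in the square whose
harmonized category changed between epochs), `ΔT` the OLS temperature trend
in °C/decade, `E` Frescalo recorder effort (1/α), `M` a microclimate
covariate and PCNM1/2 spatial eigenvector controls. Per taxon the same
formulations are fitted with a species random intercept (maximum likelihood
via adaptive Gauss–Hermite quadrature). Effect sizes are average marginal
effects (AME) per 0.1 °C/decade and per 10 percentage points of conversion.
Species whose best model is interactive are assessed on an 11 × 11 decile
prediction grid (121 paired predictions, paired *t* test,
Bonferroni-corrected); the rest are sorted into sign cohorts (T±, L±, and
the four additive sign pairs) and tested for association with
effort-corrected (Frescalo) distribution trends by chi-square.

## Worked example

```python
from landclim import RunConfig, run_all

cfg = RunConfig(seed=1, synth={"seed": 1}, min_squares=30)
report = run_all(cfg, "runs/demo")
print(report["n_species_analysed"])         # 100
print(report["best_model_tally"])           # {'1': 30, '2': 20, '3': 21, '4': 17, '5': 12}
print(round(report["median_ame_pct"]["temperature_trend"], 1))   # 20.2
print(round(report["median_ame_pct"]["land_conversion"], 1))     # -7.2
```

This generates a 16 × 16-square synthetic world (6 land categories,
semi-natural grassland starting at 65 % cover, conversion–warming
correlation 0.5), runs every stage, and reports: 100 species analysed; the
controls-only model wins for 30 of them and an environmental-change model
for 70; persistence probability rises by a median of 20.2 percentage points
per 0.1 °C/decade of warming among species whose best model includes
warming, and falls by 7.2 points per 10 % land converted among species
whose best model includes conversion (the generator's conversion effects
are negative on average). All intermediate artefacts (land-use change
table, outcome table, Frescalo effort and trends, per-species fits, the
interaction assessment and cohort table) are persisted as CSV/JSON in
`runs/demo/`.

The same stages are exposed on the command line:

```bash
landclim synth --out fixture/ --seed 7       # write a synthetic fixture
landclim run --config cfg.yaml --out runs/a  # full pipeline from YAML
landclim report --run runs/a                 # replay one stage
```

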