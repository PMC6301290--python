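# capturestress

Exercise intensity and physiological status of longline-captured sharks,
from 1-Hz tri-axial accelerometry and blood chemistry.

Sharks caught on longlines fight the gear in bouts: bursts of struggling,
aggravated swimming, and rest. How hard an individual exercises while hooked
is linked to its blood-based physiological status at landing — acid–base
state, lactate, glucose, haematocrit and plasma ions — and therefore to its
odds of a good outcome after release. This package implements the full
analysis chain for that question, for fisheries scientists and conservation
physiologists working with hook-timer longline deployments and
gangion-mounted accelerometers:

1. **Signal processing** — tri-axial logger CSVs are converted to the
   vectorial sum VS = √(x² + y² + z²) (in *g*), an orientation-free activity
   proxy, and summarised on sliding windows by *amplitude* (peak-to-trough
   range of VS, g) and *cycle* (mean period between oscillation peaks, s).
2. **Exercise-intensity classification** — each individual's windows are
   clustered with k-means (k = 3) and each cluster is assigned a level by
   cutoff rules: **high** if amplitude > 0.25 g with cycle < 5 s; **low**
   if amplitude < 0.05 g; **medium** otherwise (including amplitude > 0.25 g
   with cycle > 5 s). From the per-second levels come the activity budget
   (p_low, p_med, p_high) and mean fight intensity (ΣVS / capture duration,
   g·min⁻¹).
3. **Stress modelling** — each blood endpoint is regressed on
   logit(p_low), capture duration (min), sea-surface temperature (°C) and
   total length (cm), per species, on complete cases. 95% confidence
   intervals come from 1000 posterior simulations of the fitted linear
   model (σ² from its scaled inverse-χ² posterior, then β ~ N(β̂, σ²(XᵀX)⁻¹));
   a term is significant when its interval excludes zero.
4. **Synthetic studies with known truth** — a Markov bout model generates
   capture events with level-specific amplitude/cycle signatures, logger
   quantization (0.025 g) and ±3 g clipping, optional front-loaded
   struggling, and linked blood panels from linear response models
   calibrated to published descriptive statistics for nurse and Caribbean
   reef sharks — so every stage can be validated against ground truth.

The statistical core is exposed as scikit-learn-style estimators
(`IntensityClassifier`, `PosteriorLinearModel`) that compose with sklearn
pipelines; module-level functions wrap them for script use, and a
`capturestress` CLI drives the whole chain from one YAML config.

## Worked example

Simulate a 36-shark nurse-shark study and run the full pipeline:

```python
from capturestress import (BoutModelConfig, nurse_config, simulate_study,
                           PipelineConfig, run_pipeline)

simulate_study(36, BoutModelConfig(), nurse_config(), seed=7,
               out_dir="demo/data")
run_pipeline(PipelineConfig(data_dir="demo/data", out_dir="demo/out",
                            seed=7, n_sims=1000))
```

`demo/out/metrics.csv` then holds one row per shark:

```text
 event_id    p_low    p_med   p_high  capture_duration_min  mean_fight_intensity_g_min
event_001 0.726929 0.172685 0.100385            211.856443                   62.441636
event_002 0.581498 0.369914 0.048588            128.631466                   63.187932
event_003 0.725797 0.218274 0.055930            168.361523                   62.139681
```

Shark `event_001` spent 73% of its 212-min capture event resting, 10% in
burst struggling, and averaged 62.4 g of recorded acceleration per minute
on the line. `demo/out/model_report.txt` gives the endpoint models; the
blood-pH block of this run reads:

```text
nurse / ph37 (n=36)
  intercept                  7.0833  [    6.8741,     7.2851] *
  logit_p_low                0.0347  [   -0.0006,     0.0686]
  capture_duration_min       0.0010  [    0.0007,     0.0012] *
  sst_c                      0.0027  [   -0.0044,     0.0091]
  tl_cm                      0.0007  [    0.0000,     0.0014] *

* 95% posterior-simulation interval excludes zero
```

Blood pH rises by ~0.001 units per minute on the line (interval excludes
zero: sharks that rest through long capture events arrive less acidotic),
and the resting-proportion effect is positive, as the generator was
calibrated to produce. The same CSVs come from the CLI:
`capturestress simulate cfg.yaml`, `capturestress run-all cfg.yaml`, with
`cfg.yaml` holding `data_dir`, `out_dir` and a `cutoffs:` block
(`high_amp_g: 0.25`, `low_amp_g: 0.05`, `cycle_s: 5`).

## Layout

```
src/capturestress/
  io.py         logger CSV / deployment-table readers and writers
  features.py   vectorial sum, windowed amplitude & cycle features
  classify.py   IntensityClassifier, cutoff rules, exercise metrics
  physio.py     pH temperature correction, panel validation, hyperkalemia
  models.py     PosteriorLinearModel, log-ratio transform, report tables
  synthetic.py  bout-model and physiology generators with ground truth
  pipeline.py   config-driven orchestration of all stages
  cli.py        `capturestress` command-line interface
docs/methods.md model descriptions, parameter choices, limitations
```
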