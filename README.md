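# pedree — resting energy expenditure prediction in children

Estimating a child's resting energy expenditure (REE) is the first step of
any pediatric nutrition plan, but the classical prediction equations
(Harris–Benedict, the FAO/WHO/UNU and Schofield formulae, the Oxford
equations) are linear in weight and height and were fitted on historical
populations — at the individual level they routinely miss measured REE by
hundreds of kcal/day. `pedree` is a library for researchers and
biostatisticians who want to quantify that gap and test whether a small
neural network, fed richer anthropometry (arm areas, skinfolds, BMI), does
better against indirect calorimetry as ground truth.

The package implements the complete comparison pipeline:

* **Calorimetry reduction** — modified Weir formula
  `REE (kcal/day) = (3.941·V̇O₂ + 1.106·V̇CO₂) · 1440` (gas in L/min, no
  urinary-nitrogen term), steady-state detection (≥ 5 min with RQ variation
  < 5 %, V̇O₂ and V̇E variation < 10 %) and QC exclusion of records with
  RQ outside [0.67, 1.3].
* **Anthropometry** — BMI, LMS growth z-scores
  (`z = ((x/M)^L − 1)/(L·S)`), upper-arm areas
  (`TUA = C²/4π`, `UME = (C − πT)²/4π`, `UFE = TUA − UME`) and WHO
  nutritional classification (obese z ≥ +2, wasted z < −2).
* **Five prediction equations** — coefficient tables shipped as CSV data,
  MJ/day sources converted to kcal/day at transcription.
* **Auto Contractive Map** — an unsupervised contractive network whose
  trained weights encode variable association; a minimum spanning tree
  over `d = 1 − strength` gives the "semantic connectivity map" and its
  leaf-pruned central node.
* **TWIST** — a genetic-algorithm wrapper that jointly evolves an
  informative variable subset and a distribution-matched train/test split,
  scored by out-of-sample MLP accuracy.
* **Four-hidden-unit MLP** — sigmoid perceptron trained by online
  backpropagation, evaluated under a strict frozen-weights two-run
  protocol (train on A, freeze, score B with a virgin twin network; swap;
  average the two testing runs).
* **Synthetic cohort generator** — the study-scale cohort (561 children,
  2–17 y, ~67.5 % boys, ~20 % obese) with a known nonlinear latent REE law,
  so the whole pipeline is verifiable without any external data.

## Worked example

```python
from pedree import RunConfig, run_full_study
run_dir = run_full_study(RunConfig(out_dir="run_example", seed=1))
```

(or `python examples/05_full_study.py`), which prints:

```
selected variables: ['male', 'weight', 'triceps_sf', 'arm_fat_pct']
         method    mae  imprecision_pct  pearson_r2
 neural_network  79.02             5.62        0.94
harris_benedict 182.49            12.97        0.88
            who 270.70            19.24        0.84
    schofield_w 282.42            20.07        0.85
   schofield_wh 255.05            18.13        0.82
         oxford 255.93            18.19        0.81
```

Reading: on the default synthetic cohort (561 children, REE noise SD
90 kcal/day) the two-run neural network predicts held-out children with a
mean absolute error of 79 kcal/day — 5.6 % of mean measured REE — while
the best classical equation (Harris–Benedict) is off by 182 kcal/day, and
all equations carry large systematic bias. The run directory contains
every stage artifact: the cohort and feature CSVs, QC report, equation
predictions, the connectivity map (JSON + Graphviz DOT), the TWIST result,
per-record out-of-sample ANN predictions and the two comparison tables.

The same stages are exposed as a CLI for shell use:

```bash
pedree simulate --n 561 --seed 1 --out cohort.csv
pedree features cohort.csv --out features.csv
pedree qc cohort.csv --out qc.csv
pedree run --seed 1 --out run1          # full pipeline
```

`examples/` holds one short narrative script per capability (cohort
simulation, Weir + equations, connectivity map, variable selection, full
study).

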