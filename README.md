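# ocumet

Ocular video metrics and short-term visual-fatigue risk modelling.

`ocumet` turns per-frame ocular segmentation masks (or equivalent trace
tables) into objective eye-behaviour metrics — blink statistics, PERCLOS,
I-DT fixations, eye-movement distance, pupil constriction speeds and
windowed variability features — compares post-task minus pre-task changes
between symptom groups, and trains/evaluates risk classifiers with a
leakage-safe split / 5-fold CV / in-fold SMOTE / z-score protocol.
A synthetic binocular eye-signal simulator (with ground-truth event logs
and a frame renderer producing pixel-exact masks) makes the entire
pipeline testable without any recorded video.

## Layout

| module | purpose |
|---|---|
| `ocumet.trace` | per-frame trace data model + CSV round trip |
| `ocumet.synthetic` | trace/session/cohort simulator, frame + mask renderer |
| `ocumet.segeval` | Dice/IoU, Hungarian instance matching, COCO-style AP/AR, macro/micro aggregation, geometric stand-in segmenter, COCO JSON I/O |
| `ocumet.metrics` | blink/fixation/pupil/variability feature extraction, difference feature vectors |
| `ocumet.stats` | deterioration labelling, Shapiro-Wilk/paired-t/Wilcoxon/Mann-Whitney/McNemar, P<.05 feature selection |
| `ocumet.model` | stratified holdout, SMOTE, z-score, grid-search CV, fold/holdout evaluation, feature importance |
| `ocumet.report` | per-session risk classification and JSON session report |
| `ocumet.cli` | `ocumet` command-line interface |

## CLI

Every stage is a subcommand; `--seed` controls all randomness.

```sh
ocumet --seed 1 simulate --n 40 --prevalence 0.5 --out-dir cohort/
ocumet extract --traces-dir cohort/ --metadata cohort/cohort.csv --out features.csv
ocumet compare --features features.csv --out-stats stats.csv --out-selected selected.json
ocumet --seed 1 train --features features.csv --selected selected.json \
       --family random_forest --out-eval eval.json --out-model model.pkl
ocumet --seed 1 report --pre cohort/P001_pre.csv --post cohort/P001_post.csv \
       --model model.pkl --cff-pre 40 --cff-post 38 --out report.json
ocumet segeval --pred pred_masks.json --truth truth_masks.json --out scores.csv
```

Model families: `svm_rbf_pca` (PCA retaining 95% variance before an RBF
SVM), `decision_tree`, `random_forest`, `gradient_boosting` (alias:
`xgboost`). Hyperparameter grids are overridable via `--config` (JSON,
key `grids.<family>`).

## Conventions

* Recordings are 30 fps, 1800 frames (1 minute) by default; analysis uses
  frames [200, 1800) with variability windows [200, 600), [600, 1200),
  [1200, 1800) and [200, 1800).
* Closure: fissure length ≤ 20% of the 95th-percentile open baseline;
  blinks are ≥2-frame closure runs.
* Deterioration label: CVS-Q increase ≥ 3 points post vs pre.
* All difference features are post − pre; pupil and movement metrics are
  averaged over both eyes.

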