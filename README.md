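# calimb

Probability-calibration analysis for class-imbalanced binary medical
classifiers: synthetic imbalance-controlled score generation, Platt / beta /
spline calibration, reliability diagrams and expected calibration error
(ECE), precision-recall-guided threshold selection, and Wilson-score
confidence intervals — wired into a reproducible study pipeline.

## What it does

- **`calimb.synthetic`** — generates labelled score sets at controlled
  positive:negative ratios with a known ground truth: latent Gaussian
  class-conditionals whose Bayes posterior is logistic (calibrated by
  construction), plus strictly monotone miscalibration distortions
  (Platt-family, beta-family, and a "majority collapse" regime where every
  positive sample scores below 0.5).
- **`calimb.calibrators`** — fits and applies the three calibration maps
  (two-parameter Platt scaling with smoothed targets; three-parameter beta
  calibration with drop-and-refit non-negativity constraints; penalized
  Bernoulli-likelihood cubic smoothing splines on the logit scale with
  CV-selected smoothing), plus an identity baseline and JSON serialization.
- **`calimb.metrics`** — confusion counts under the `score >= threshold`
  rule, accuracy / precision / recall / F / MCC with NA propagation,
  step-wise AUPRC, equal-width reliability binning with ECE, and the
  F-maximizing PR threshold.
- **`calimb.stats`** — Wilson score intervals (with an affine transform for
  MCC's [-1, 1] range) and non-overlap significance calls.
- **`calimb.pipeline`** — the full imbalance-sweep experiment: per ratio it
  fits every method on a calibration split, ranks methods by test ECE,
  evaluates the best one at the default 0.5 and PR-guided thresholds, and
  writes CSV tables, per-cell reliability/PR-curve files and a manifest.

## CLI

```sh
# synthetic study data (fit + test splits)
calimb generate --n-negative 1000 --ratio 0.2 --distortion beta \
    --params a=2,b=1,c=0.5 --separability 2.0 --test-negative 300 \
    --seed 7 --out data/

# fit a calibration map and evaluate it
calimb calibrate --method platt --fit-scores data/cal.csv --out platt.json
calimb evaluate --scores data/test.csv --map platt.json --threshold pr \
    --bins 10 --out report

# full experiment from a YAML config
calimb experiment --config config.yaml --out results/ --seed 1
```

Example `config.yaml`:

```yaml
ratios: [0.2, 0.6, 1.0]
methods: [platt, beta, spline]
n_negative: 1000
test_negative: 300
seed: 7
distortion:
  family: majority_collapse
  params: {delta: auto}
  separability: 2.0
```

Score files are plain CSV (`id,label,score[,true_prob]`) with labels in
{0, 1} and probabilities in [0, 1], so any external classifier's predictions
can be dropped in via `external_scores` in the config.

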