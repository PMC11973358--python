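# histonet

Efficient residual classifiers for H&E histopathology patches, built around
two architectural modifications of a 50-layer residual backbone:

* **Split convolution** (`res_sp`): each bottleneck's 3×3 stage partitions
  its channels into a *representative* fraction (grouped 3×3 plus a parallel
  pointwise 1×1, summed and batch-normed) and a *redundant* remainder
  (cheap pointwise 1×1, batch-normed); the branches are fused by a
  parameter-free pooled soft-attention weighted sum.
* **Channel + spatial attention** (`res_cba`): a shared-MLP channel gate
  followed by a mean/max-map spatial gate, applied to the block output just
  before the residual addition.
* **Both together** (`htrec`): 1×1 → 3×3 split conv → 1×1 → attention →
  residual connection.  `baseline` is the plain backbone.

The package ships the surrounding experimental machinery: deterministic
preprocessing (adaptive gamma, median filter, resize), seeded stochastic
augmentation (elastic warp, flips, random crop-resize), an analytic
parameter/FLOP profiler that reproduces the published complexity table, a
multi-class evaluation suite (micro/macro precision-recall, F1, multiclass
MCC, ROC/PR AUCs), stratified five-fold cross-validation with early
stopping and hyperparameter search, Grad-CAM saliency with blue→red
overlays, and a seeded synthetic three-class H&E-palette image generator so
every stage runs offline.

Everything runs on a small NumPy reverse-mode autodiff engine
(`histonet.nn`) — no GPU or deep-learning framework required.

## CLI

```bash
histonet generate --out data --n 150 --seed 7        # synthetic dataset
histonet generate --out data --imbalance             # scaled cohort proportions
histonet preprocess data/hcc_like/*.png --out prep --size 224
histonet augment-preview data/hcc_like/hcc_like_00000.png --out grid.png
histonet profile                                     # complexity table (TSV)
histonet train --config run.yaml --data data --out runs/exp1
histonet evaluate --checkpoint runs/exp1/model.npz --data testdata \
    --train-manifest data/manifest.csv --out runs/exp1
histonet gradcam img.png --checkpoint runs/exp1/model.npz --out runs/exp1
```

`train`/`evaluate` accept a YAML config with sections `model`, `train`,
`augment`, `preprocess`, `synth` plus top-level `seed`, `folds`,
`output_dir`; unknown keys are rejected.  Every command writes a
`run_manifest.json` with the config hash, seed and package version.

Checkpoints are NumPy `.npz` archives containing every parameter and
batch-norm buffer by dotted module path, plus the architecture config as a
JSON blob (`experiment.save_checkpoint` / `load_checkpoint`).

## Complexity profiling

`histonet profile` emits the four-row Model/Params(M)/FLOPs(G) table.
Conventions: FLOPs = 2 × multiply-accumulates for conv/linear layers plus
2 × per-element costs for batch norm, activations and pooling; parameters
count all trainable tensors (the analytic totals are asserted equal to a
runtime enumeration of every instantiated tensor).  The attention MLP's
reduction ratio is not stated in the published table; scanning integer
ratios shows r=42 uniquely reproduces both attention-variant parameter
totals, so the CLI defaults to it (`--cbam-reduction` overrides, and
`complexity.calibrate_reduction` re-runs the scan).  The published
attention-variant FLOPs cells are mutually inconsistent (two different
deltas for the identical per-block insertion) and cannot be reproduced
under any single convention; the attention-free rows reproduce exactly.

## Layout

```
src/histonet/
  nn/            autodiff engine, layers, Adam
  arch.py        split conv, attention gates, bottleneck, variant builder
  complexity.py  analytic parameter/FLOP accounting + ratio calibration
  preprocess.py  gamma / median / resize
  augment.py     elastic warp, flips, crop-resize (seeded)
  metrics.py     confusion matrix, PR/ROC, MCC, micro/macro averaging
  experiment.py  stratified k-fold, training loop, search, external test
  saliency.py    Grad-CAM + overlays
  synthdata.py   synthetic three-class generator + separability guard
  cli.py         click entry point
```
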