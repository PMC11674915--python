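# amdnet

A lightweight convolutional classifier for age-related macular degeneration
(AMD) on retinal OCT B-scans, built from three parameter-efficient
components — a modified Inception module with depthwise separable branches,
a depthwise squeeze-and-excitation block (DSEB), and a ConvMixer stage — plus
the tooling a careful reader needs to audit it: closed-form per-layer
parameter accounting, reconciliation of under-determined hyperparameters
against a target parameter total, macro-averaged evaluation metrics,
reproducible 70/15/15 data splits, a seeded synthetic B-scan generator, and
a self-contained NumPy training runtime.

It is aimed at people studying parameter-efficient CNN designs for medical
imaging who want every trainable scalar accounted for, and at anyone who
needs a dependency-light, fully inspectable reimplementation of this family
of architectures.

## The architecture

```
input 224×224×3
  → stem: Conv5×5/32 → DConv3×3 → PConv1×1/32 → BN → maxpool3×3 (s2)
  → modified Inception (4 branches, depthwise-separable 3×3 and 5×5) → 256 ch
  → Conv3×3/128
  → DSEB: DConv5×5 → PConv/64 → DConv3×3 → PConv/64 → SE attention
  → ConvMixer (h=256, depth 16, kernel 5, patch 2)
  → GAP → FC → softmax (3 classes)
```

Parameter formulas are the standard ones: a k×k convolution with F filters
on C channels costs (k²C+1)·F, its depthwise separable replacement
(k²C+C) + (C+1)·F.  On the 3-channel input the standard Inception module
costs 15,488 parameters and the modified one 1,132 — a 13.7× reduction.

Metrics follow the macro-averaging convention: accuracy = trace/total,
precision and recall are unweighted means of one-vs-rest per-class values,
and F1 is the harmonic mean of the macro precision and macro recall.

## Worked example

```python
>>> from amdnet import ModelConfig, build_pm, count_trainable, audit
>>> from amdnet.blocks import build_mim, build_inception_standard
>>> from amdnet.specs import TensorShape
>>> from amdnet.assembly import audit_block

>>> shape = TensorShape(224, 224, 3)
>>> audit_block(build_inception_standard(shape, 64), shape).total
15488
>>> table = audit_block(build_mim(shape, 64), shape)
>>> table.param_column()
[256, 30, 256, 78, 256, 0, 256]
>>> table.total
1132

>>> model = build_pm(ModelConfig())      # full model, default configuration
>>> count_trainable(model)
1568103
```

The audit column above is the per-branch cost of the modified Inception
module (1×1 conv; 3×3 depthwise + pointwise; 5×5 depthwise + pointwise;
pool branch), and the final number is the full model's trainable-parameter
count under the shipped defaults.  Reconciling the open hyperparameters
against a published total of 1,650,020 finds no exact match in the
documented search space; the nearest configuration (SE ratio 2, one
256-unit hidden layer, post-Inception BatchNorm) counts 1,637,763, and the
full search report is committed at `configs/reconciliation.json`.

Evaluating the reference clinical confusion matrix:

```python
>>> import numpy as np
>>> from amdnet.metrics import ConfusionMatrix, report
>>> cm = ConfusionMatrix(np.array([[98, 1, 5], [0, 133, 0], [1, 0, 109]]),
...                      class_names=["dry_amd", "normal", "wet_amd"])
>>> report(cm).as_percentages()
{'accuracy': 97.98, 'precision': 97.95, 'recall': 97.77, 'f1': 97.86}
```

## Command line

```bash
amdnet synth --out data/ --n-per-class 32 --seed 0   # synthetic B-scans
amdnet split --data-dir data/ --seed 0 --out manifest.csv
amdnet build --audit audit.csv                       # per-layer audit table
amdnet reconcile --target 1650020 --out report.json
amdnet train --data-dir data/ --config cfg.yaml --out run/
amdnet eval --ckpt run/checkpoint.npz --data-dir data/ --out report.json
amdnet curves --history run/history.csv --out curves.png
```

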