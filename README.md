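# neoseg

Tissue segmentation of infant brain MRI with a (2+1)D-factorized volumetric
U-Net, written for researchers who need the full pipeline — intensity
standardization, network, training protocol, and evaluation statistics — on
one CPU and without access to restricted clinical data.

## The problem

Around six months of age the T1/T2 intensity distributions of gray matter
(GM) and white matter (WM) converge (the *isointense* stage), so infant
brain volumes cannot be segmented by thresholding; cerebro-spinal fluid
(CSF), GM and WM must be separated by a model that uses spatial context.
The classes are coded 0 = background, 1 = CSF, 2 = GM, 3 = WM.

## The method

1. **Intensity standardization.** For each record and modality, the 25th,
   50th and 75th foreground percentiles (plus robust 1st/99th outer
   anchors) are located; a cohort reference scale averages these landmarks
   across the training records, and each record is mapped onto it by the
   monotone piecewise-linear transfer sending landmark *k* exactly onto
   reference anchor *k*. Void voxels are repaired beforehand by an
   iterative 3×3×3 valid-neighborhood median fill.
2. **Network.** A four-level encoder/decoder U-Net whose every 3-D
   convolution is factorized (2+1)D-style into an in-plane 1×3×3 stage and
   an across-slice 3×1×1 stage, each with its own ELU. Encoder filter
   counts 65/32/16/8 (halved per level, 2×2×2 max-pooling), a 4-filter
   bridge, mirrored decoder with 2×2×2 transpose convolutions and skip
   concatenation, batch norm and dropout 0.2 throughout, and a 1×1×1
   softmax head over the 4 classes. On a 112×192×144 volume with 6 input
   channels (T1 and T2 each replicated ×3) the feature maps shrink to a
   7×12×9 bridge and the output is 112×192×144×4. The network, its
   backpropagation and the ADAM optimizer are implemented directly in
   numpy — whole volumes are processed as a batch of one.
3. **Training.** The cost is `0.5·CE + 0.5·(1 − mean soft Dice over the 4
   classes)` where CE is sparse categorical cross-entropy; ADAM with
   learning rate 1e-3; the lowest-cost model state over the run is kept.
   Evaluation is leave-one-out cross-validation: each record is the test
   set once, and the intensity reference scale is rebuilt from each fold's
   training records only.
4. **Metrics.** Per tissue τ: sensitivity TPR = |Γτ∩Λτ|/|Γτ|, precision
   PPV = |Γτ∩Λτ|/|Λτ|, Dice DSC = 2|Γτ∩Λτ|/(|Γτ|+|Λτ|) (Γ = truth,
   Λ = prediction voxel sets), plus overall accuracy ACC; cohort summaries
   report avg/std/min/Q1/Q2/Q3/max across records.
5. **Phantoms.** A built-in generator produces co-registered two-modality
   cohorts with ground truth: nested perturbed-ellipsoid CSF/GM/WM geometry
   (GM ≈ 2× WM voxels), isointense GM/WM intensities by default, inverted
   CSF contrast between T1 and T2, per-record global intensity jitter and
   sporadic void voxels — so the whole pipeline runs without any dataset.

## Worked example

Train the scaled-down architecture (filters 16/8/4/2) on one easy-regime
phantom and evaluate it on its own training volume:

```python
import numpy as np
from neoseg import (ArchitectureConfig, PhantomSpec, TrainConfig, build_model,
                    confusion_matrix, generate_cohort, metrics_from_confusion,
                    predict, train)
from neoseg.harness import prepare_fold

spec = PhantomSpec(extents=(32, 48, 32), seed=11, gm_wm_separation=8.0)
records = generate_cohort(1, spec)
inputs, _, _ = prepare_fold(records, records[0], replication=1)

arch = ArchitectureConfig(filters_per_level=(16, 8, 4, 2), bridge_filters=2,
                          in_channels=2)
model = build_model(arch, seed=100)
model, history = train(model, [(inputs[0], records[0].labels)],
                       TrainConfig(epochs=100, seed=5))
print(f"cost: {history[0]:.4f} -> {min(history):.4f}")

_, labels = predict(model, inputs[0])
report = metrics_from_confusion(confusion_matrix(labels, records[0].labels))
print(f"ACC {report.acc:.4f}")
for tissue, dsc in report.dsc.items():
    print(f"{tissue} DSC {dsc:.4f}")
```

Output (about two minutes on one CPU):

```
cost: 1.0453 -> 0.0814
ACC 0.9953
CSF DSC 0.9802
GM DSC 0.9907
WM DSC 0.9956
```

The cost falls from its initial value near `0.5·ln 4 + 0.5·0.75 ≈ 1.07`
(uninformed prediction) to 0.08; ACC is the fraction of correctly labeled
voxels, and the per-tissue Dice scores show all three tissues recovered
almost perfectly — expected here, because `gm_wm_separation=8` makes GM
and WM easily separable, unlike the isointense default of 0.5.

The same workflow is available from the shell:

```bash
neoseg phantom --n 10 --seed 7 --out cohort
neoseg crossval --config config.yaml --out results/
```

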