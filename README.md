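# octlite

Lightweight CNN tooling for classifying retinal optical coherence tomography
(OCT) B-scans into four categories — CNV (choroidal neovascularization), DME
(diabetic macular edema), DRUSEN and NORMAL — aimed at people who want to
study *small* separable-convolution models and heavy offline data
augmentation rather than large transfer-learning baselines.

The package reproduces, end to end and fully offline, the machinery of a
compact OCT classification system:

* **A 48× augmentation schema** built from six basic operators — horizontal
  mirror, rotations of ±5°/±10°/±15°, anisotropic aspect stretch
  (105–130%), histogram equalization, Gaussian blur with the normalized
  kernel G(x,y) = (1/2πσ²)·exp(−(x²+y²)/2σ²), and a fixed 3×3 sharpen —
  composed as a Cartesian product of stages
  ({identity, mirror} × 8 geometric variants × 3 photometric variants = 48
  outputs per input image).
* **A family of small CNNs** with 3/5/7/9/11 convolution layers, including
  a 5-layer "v2" variant that uses depthwise separable convolutions
  (parameter cost k²·c_in + c_in·c_out + c_out instead of k²·c_in·c_out +
  c_out) and whose per-layer output shapes and parameter counts are audited
  exactly: total 2,552,703 parameters = 2,549,951 trainable + 2,752
  batch-norm statistics at the native 128×128×3 input.
* **A training/prediction harness** (batch 32, Adam at 0.001/0.002,
  categorical cross-entropy, seeded under-/over-sampling for class
  balance), running on a self-contained numpy layer stack with exact
  backprop — no deep-learning framework required.
* **Evaluation** via confusion matrices and per-class/macro recall,
  precision, Fβ (F1 at β = 1), G-measure = √(precision·recall), and overall
  accuracy = trace/total.
* **Grad-CAM** saliency maps: channel weights are spatial means of the
  class-score gradient at a convolutional feature map; the rectified
  weighted activation sum is upsampled to input coordinates.
* **A seeded synthetic B-scan generator** that emulates speckled,
  curved-band retinal scans with class-specific lesions, so every component
  is testable with no dataset download. Real data in the public
  `split/CLASS/*.jpeg` OCT directory layout is supported by the same
  loaders.

## Worked example

```python
import octlite as ol

# Audit the separable-convolution 5-layer v2 model.
spec = ol.build_architecture("5-layer", "v2")
summary = ol.count_parameters(spec)
print(f"total={summary.total:,} trainable={summary.trainable:,} "
      f"non_trainable={summary.non_trainable:,}")

# Run the default 48x augmentation schema on a synthetic scan.
schema = ol.default_schema()
scan = ol.generate_bscan("DME", ol.SyntheticSpec(seed=1), 0)
outputs = ol.apply_schema(scan.pixels, schema)
print(f"multiplicity={schema.multiplicity} outputs={len(outputs)}")

# Score a small prediction run.
report = ol.evaluate(
    ["CNV", "CNV", "DME", "DRUSEN", "NORMAL"],
    ["CNV", "DME", "DME", "DRUSEN", "NORMAL"],
)
print(report.to_frame().to_string(index=False))
print(f"accuracy={report.accuracy:.4f}")
```

prints

```
total=2,552,703 trainable=2,549,951 non_trainable=2,752
multiplicity=48 outputs=48
 Class  Recall  Precision  F1-Score  G-Measure
   CNV   0.500      1.000    0.6667     0.7071
   DME   1.000      0.500    0.6667     0.7071
DRUSEN   1.000      1.000    1.0000     1.0000
NORMAL   1.000      1.000    1.0000     1.0000
 macro   0.875      0.875    0.8333     0.8536
accuracy=0.8000
```

The audit line is the v2 model's exact parameter budget; one of the two CNV
scans being predicted as DME costs CNV recall (1 of 2 found) and DME
precision (1 of 2 DME calls correct), and 4 of 5 correct labels give the
0.8000 accuracy.

## Command line

The `oct` command exposes the same functionality as subcommands:

```bash
oct synth --out data/ --n-per-class 50 --splits 30,10,10 --seed 1
oct augment --in data/ --out augmented/
oct summary --model 5-layer --variant v2
oct train --data data/ --model 5-layer --variant v2-small --input-size 32 \
    --epochs 5 --weights-out weights.npz
oct eval --weights weights.npz --data data/ --variant v2-small --input-size 32
oct gradcam --weights weights.npz --image data/test/CNV/CNV-00040.jpeg \
    --class CNV --variant v2-small --input-size 32 --out cam.png
```

`--variant v2-small` is a structure-preserving miniature of the v2 model
for small inputs (see `docs/methods.md`).

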