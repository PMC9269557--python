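# Methods

This note documents the models and procedures octlite implements, the
choices that were genuinely open, and what the synthetic-data experiments
do and do not establish.

## The classification problem

A retinal OCT B-scan is a 2-D cross-section showing the retina as a bright,
gently curved multi-layer band over a dark background, corrupted by
multiplicative speckle. The four target categories differ in localized
structure: DME shows dark intraretinal fluid cavities, drusen appear as
small bright bumps on the outer retinal band, CNV as a large irregular
hyperreflective subretinal mass, and normal scans show clean layers. The
package's premise is that a *small* CNN plus heavy offline augmentation is
competitive with much larger models on this task; everything here exists to
make that premise inspectable.

## Augmentation schema

Six operators are implemented on 8-bit grayscale images:

| operator | parameters | notes |
|---|---|---|
| mirror | — | vertical-axis reflection only; a horizontal-axis flip would invert the anatomical layer order and is deliberately unavailable in the schema |
| rotate | angle ∈ {±5°, ±10°, ±15°} (0° allowed as identity) | about the center, bilinear, output size preserved, revealed corners filled black (the OCT background) |
| aspect | per-axis scale 1.0 or [1.05, 1.30] | stretch then center-crop back to the input shape, so all outputs share one size |
| histogram equalization | — | classic CDF mapping onto [0, 255]; monotone; constant images pass through |
| Gaussian blur | kernel (5, 5) default | kernel from G(x,y) = (1/2πσ²)·e^(−(x²+y²)/2σ²) at integer offsets, normalized to sum 1; borders edge-replicated |
| sharpen | fixed 3×3 kernel [[−1,−1,−1],[−1,9,−1],[−1,−1,−1]] | borders edge-replicated, clipped to [0, 255] |

A schema is an ordered list of stages, each a set of alternative operators;
outputs are the Cartesian product of stage choices applied in stage order,
in lexicographic order. The default is

    {identity, mirror} (2)
    × {rotate ±5, ±10, ±15; aspect 1.15×1.0; aspect 1.0×1.15} (8)
    × {histeq; gblur(5,5); sharpen} (3)  =  48 outputs per input.

The 48× multiplicity is the fixed, externally given target; the exact
decomposition into stages was an open choice, and this one uses every
operator exactly once per path while remaining fully configurable.
Augmentation is always materialized to disk before training — the harness
never augments online — matching the workflow the package reproduces.

σ for a blur kernel given only its size follows the conventional rule
σ = 0.3·((size−1)/2 − 1) + 0.8, i.e. σ = 1.1 for 5×5.

## Model family

Models are described abstractly (`LayerSpec` lists), with valid padding and
stride 1 everywhere and pool stride equal to pool size. The 5-layer v2
model is fixed layer by layer: separable convolutions with kernels
3,3,5,3,5 and filters 128,128,128,256,256; batch normalization after every
convolution and dense layer; max pools 3×3 then 2×2 twice; dropouts 15%,
15%, 15% after the pools and 25%, 10%, 10%, 10% in the head; dense
256/128/64/32; softmax over 4 classes. Its audit — per-layer output shapes,
per-layer parameter counts, and the totals 2,552,703 / 2,549,951 / 2,752 —
is reproduced exactly by the closed-form counting rules

* standard conv: k²·c_in·c_out + c_out
* depthwise separable conv (multiplier 1): k²·c_in + c_in·c_out + c_out
* batch norm: 4·c (half trainable scale/shift, half moving statistics)
* dense: n_in·n_out + n_out

and cross-checked in tests against a brute-force oracle that instantiates
every weight array and sums element counts.

The v1-style members (3/5/7/9/11 convolutions) are only loosely
constrained by their filter tables, so the package fixes a canonical form:
MiniVGG-style conv+BN+ReLU blocks grouped by equal consecutive filter
widths, a 2×2 max pool after each group, dropout 25% after the last pool,
then flatten, dense 1024 (+BN+ReLU), dropout 50%, softmax. One refinement
makes all five members feasible at 128×128 under valid padding: a pool is
skipped when the remaining 3×3 convolutions would drive a spatial dimension
non-positive (this triggers only for the 11-layer member, whose last
three-conv group starts at spatial size 8). The 9- and 11-layer members use
separable convolutions; 3-, 5-(v1) and 7-layer use standard ones. ReLU is
applied after the batch normalization that follows each convolution/dense
layer; the alternative order (ReLU before BN) is not distinguishable from
the reproduced material and was fixed once.

`small_input_v2` is a structure-preserving miniature for desk-scale
experiments: the full v2 table cannot accept a 32×32 input under valid
padding (the spatial size reaches zero before the last convolution), so
the miniature keeps the conv/BN/pool/dropout ordering and dropout rates but
shrinks the 5×5 kernels to 3×3, scales the filter widths to 32/64, drops
the third pool and uses a 64/32 dense head (≈17.6k parameters).

## Numpy backend

No deep-learning framework is used: `octlite.nn` implements the layer
stack, exact backpropagation (verified against central differences in the
test suite) and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7). Conventions are
channels-last float32; convolutions run via sliding-window views and
einsum. Batch normalization uses ε = 1e-3 and momentum-0.9 moving
statistics — the momentum is a backend choice made for the run lengths this
package targets (hundreds of optimizer steps), where slower statistics lag
the batch distribution and degrade inference-mode accuracy. Max-pool
gradients are routed to window maxima (exact float ties share the
gradient); dropout is inverted; the softmax is fused with the
cross-entropy loss. The seed governs weight initialization, shuffling and
dropout; runs are bit-reproducible per seed on a fixed BLAS.

## Training protocol

Defaults: batch 32, 10 epochs, Adam at 0.001 (v1) / 0.002 (v2), categorical
cross-entropy, 128×128×3 inputs (grayscale replicated to 3 channels, scaled
to [0, 1], bilinear resize). Class balance is handled by seeded resampling
of the manifest to a uniform per-class target (default 7000): undersampling
draws without replacement and refuses short classes; oversampling draws
with replacement. A non-finite loss aborts with the partial report
attached. Validation uses fixed split directories; there is no
cross-validation, learning-rate schedule or early stopping.

## Metrics

Per class, from the one-vs-rest reduction of the 4×4 confusion matrix
(fixed order CNV, DME, DRUSEN, NORMAL): recall TP/(TP+FN), precision
TP/(TP+FP), Fβ = (1+β²)RP/(β²R+P) with F1 at β = 1, and G = √(P·R), the
geometric mean of precision and recall. Overall accuracy is trace/total.
Macro values are unweighted 4-class means, which is the averaging that
reproduces the reference macro tables. Zero-denominator metrics are
reported as NaN with a `defined=False` flag, never silently zeroed. Reports
round to 4 decimal places for printing; computations keep full precision.
When checking against printed tables, note that a mean of 4-dp values can
fall exactly on a rounding boundary (e.g. 0.96485), so comparisons are made
at the printed precision rather than assuming a rounding mode.

## Grad-CAM

For target class c and a convolutional feature map A: channel weights are
the spatial means of ∂y_c/∂A (y_c the pre-softmax score), the map is
ReLU(Σ_k w_k A_k), bilinearly upsampled to input coordinates and
max-normalized to [0, 1]. An all-zero map is returned flagged degenerate,
not raised. The default source layer is the deepest convolution whose
feature map retains spatial extent greater than 1×1 — in heavily pooled
miniatures the final convolution collapses to 1×1 and would upsample to a
constant — and any convolutional layer can be selected by name.

## Synthetic data

The generator is a pure function of (seed, class, index) producing 8-bit
scans: a parabolic band of six stacked reflectivity layers over a dark
background, clipped multiplicative gamma speckle (shape 4, mean 1, strength
`noise_level`, default 0.3), and one class-specific lesion with a recorded
bounding box — dark intraretinal ellipses (DME), 3–6 small bright bumps on
the lowest layer (DRUSEN), or a union of bright overlapping ellipses below
the band (CNV). Defaults are 256×256 written to disk as quality-95 JPEG
(the loader resizes to the model input, mirroring real archives whose
images vary in size); tests generate 64×64 and feed models at 32×32.

What it emulates: class-discriminative local structure, speckle rich enough
to make equalization and blur non-trivial (≥16 distinct intensities per
image), geometry variation across seeds. What it does not: physical speckle
statistics, vendor-specific artifacts, pathology co-occurrence, image
quality variation, or anything that would make the four classes hard to
separate. Consequently the desk-scale learning experiment — the 32×32
miniature trained 5 epochs on 800 synthetic images (200 per class, best of
at most three seeds) clearing 50% held-out accuracy against 25% chance —
demonstrates that the training loop optimizes and generalizes on separable
data; it says nothing about accuracy on real OCT scans, and the published
headline accuracy on the real test set is out of scope at desk scale.

## Numerical and degenerate-input choices

* Rotation fills revealed corners with 0 (the OCT background) and uses
  bilinear interpolation; round-trip fidelity (rotate +θ then −θ) is
  sub-intensity-level on smooth content but cannot reconstruct pixel-scale
  speckle or razor-sharp edges — a resampling property, not a bug.
* Aspect change is stretch + center-crop so every schema output keeps the
  input shape; scales below 1.05 (other than exactly 1.0 on one axis) or
  above 1.30 are rejected.
* Histogram equalization of a constant image returns it unchanged (the CDF
  mapping is degenerate there).
* Operator outputs are rounded and clipped to uint8 at each stage; schema
  outputs are therefore exactly reproducible run to run.
* Filenames of augmented images encode the stage choices
  (`<stem>__m<i>_g<j>_p<k>.jpeg`) for traceability.
* Tie-breaking: predicted label is the lowest class index among argmax
  probabilities.

## Problem sizes used by the test suite

The suite trains one-to-three 5-epoch runs of the ≈17.6k-parameter
miniature on 800 synthetic 32×32 images and evaluates on 200 held-out
images; the nearest-centroid separability check uses 400 images at 8×8
thumbnail resolution; all other tests are closed-form or operate on single
64×64 scans. These sizes were chosen so the full suite documents the
system's behavior in well under a minute of compute beyond the training
runs.
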