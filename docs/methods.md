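# Methods

## Model

The classifier is a two-pathway 3D convolutional network over feature
volumes with axes (batch N, frames T, channels C, height H, width W). The
spatial pathway runs a 3×3×3 stem (spatial stride 2) and four stages of
residual groups — (3, 5, 11, 7) groups in the full profile — with
depthwise-separable cores and an action-attention module after every group.
The fast pathway mirrors the stage layout at α× the frame rate with widths
scaled by β and R(2+1)D factorized cores. After each stage a lateral
connection downsamples the fast features in time (3D convolution, kernel
(5,1,1), stride (α,1,1), padding (2,0,0), output width 2·C_fast), passes
them through a 3D squeeze-and-excitation gate, and concatenates them onto
the spatial-pathway features, which feed the next stage. The predictor
global-average-pools both pathways' final volumes, concatenates them, and
applies Linear(·,256) → ReLU → Dropout(0.5) → Linear(256, M).

Residual groups are pre-activation in the sense that no nonlinearity
follows the shortcut sum: `y = shortcut(x) + BN(conv2(ReLU(BN(conv1(x)))))`.
A zeroed residual branch therefore passes its input through exactly, which
makes the identity contract of the groups directly testable. When stride
or channel extents change, the shortcut is a 1×1×1 projection + BN.

### Assumptions and fixed conventions

* "Same" padding everywhere, so stride-1 blocks preserve (T, H, W); kernels
  are odd.
* Convolutions followed by a normalization carry no bias; normalization is
  per-channel batch normalization (momentum 0.1, eps 1e-5) and the
  nonlinearity is the rectifier. Attention-branch convolutions, which feed
  sigmoids directly, do carry biases (zero-initialized).
* The R(2+1)D intermediate width solves the weight-budget equality
  `N_{i−1}·t·d²·N_i = N_{i−1}·d²·M_i + M_i·t·N_i`, floored and clamped to
  ≥ 1 so degenerate tiny-channel test profiles stay buildable.
* The three attention branches are independent (no shared squeeze) and are
  combined by an elementwise mean, which preserves activation scale; a sum
  variant is configurable. Compression ratio r = 16 in all branches with
  squeezed width ⌈C/r⌉ clamped to ≥ 1. The motion branch's frame
  difference applies its 3×3 convolution to the leading frame only, and the
  zero pad restoring clip length sits at the last temporal slot.
* Neither pathway ever changes T; all temporal alignment happens in the
  lateral connections. Spatial stride-2 downsampling sits in the stem and
  in the first group of stages 2–4.
* Ties in argmax resolve to the lowest class index; the metric functions
  validate probability rows to 1e-6 and clamp probabilities at 1e-12
  before logs.

## Parameters that matter

| parameter | default (full / tiny) | meaning |
|---|---|---|
| stage groups | (3,5,11,7) / (1,1,2,1) | residual groups per stage |
| stage widths | (24,48,96,192) / (8,16,24,32) | spatial-pathway channels |
| T (spatial) | 8 / 4 frames | frames the spatial pathway sees |
| α | 4 / 2 | fast-to-spatial frame-rate ratio |
| β | 1/8 / 1/4 | fast-to-spatial width ratio |
| lr, momentum | 0.01, 0.9 | SGD protocol, no schedule or decay |
| epochs | 256 (published protocol) / 15–30 desk scale | training length |
| batch size | 32 / 8 | clips per update |
| resize / crop | 256 / 224 (full), 36 / 32 (tiny) | short-side resize, square crop |
| normalization | mean 0.45, std 0.225 per channel | pinned in every checkpoint |

The published protocol names only plain SGD, lr 0.01 and 256 epochs;
momentum 0.9 is on by default and weight decay off, both configurable. The
pathway widths, α, β, the lateral geometry and the SE ratio (16) are not
stated by the source experiments; the defaults here are the canonical
values of the two-pathway/X3D model family and are all exposed in the YAML
profiles (`x3dfast/profiles/*.yaml`).

Desk-scale choices: the tiny profile (≈ 40k parameters), 64×64 synthetic
canvas at 12.5 fps, 32×32 crops and 15–30 epochs keep a full
train-validate cycle at a few minutes on one CPU while exercising every
architectural component; these sizes are the package's test defaults, not
part of the model definition.

## Synthetic clips

The simulator emulates the statistical structure of barn surveillance
clips, not their appearance. Classes are separable by exactly the cues the
real task turns on: standing and lying bodies are static and differ in
blob aspect (2.4 vs ≈ 1.2, ratio ≥ 1.5 enforced); walking uses the same
elongated body translating at ≥ 2 px/frame (enforced ≥ 2× the stationary
jitter, so the cue is temporal, not spatial); mounting renders two bodies
of different brightness whose vertical overlap oscillates, overlapping in
at least half the frames with brief separations. Backgrounds and bodies
are textured, distractor bodies sit below the oracle's intensity
threshold, and degradations (illumination gain, Gaussian blur, occluding
rectangles — in that order) mirror dim lighting, defocus and occlusion.
Per-class durations are uniform over 1–2 s (standing, lying), 1–3 s
(walking) and 2–4 s (mounting), and class-ratio sampling follows the
reference dataset's 1799 : 1947 : 1130 : 774 proportions. Every clip is a
pure function of its seed.

What the simulator does **not** reproduce: articulated shape, perspective
and camera angle variation, foreground-background visual similarity,
multi-animal clutter beyond dim distractors, or compression artifacts.
Passing the learning gates here shows the architecture and pipeline can
extract spatial and temporal class cues end to end; it says nothing about
accuracy on real farm footage.

A rule-based kinematic oracle (connected components above a fixed intensity
threshold, median centroid step, blob aspect) validates that the class
signal exists: ≥ 95 % accuracy on clean clips is the generator's acceptance
gate. A single-frame variant documents that walking is *not* spatially
separable from standing — it classifies walking clips as standing — which
is precisely the property that forces a model to use temporal features.

## Class-activation maps

`compute_cam` follows the gradient-weighted recipe: channel weights are the
target-class logit's gradients pooled over time and space, the heatmap is
the rectified weighted channel sum per frame, max-normalized frame-wise.
Because the predictor global-average-pools its input, the gradient is
constant over (t, h, w) per channel, so this coincides with the classic
weight-matrix formulation applied through the two-layer head. The default
hook is the final fused feature volume; `stage` selects earlier fused
volumes. Upsampled maps use cell-centered interpolation so the peak of a
coarse map stays at its source cell's center.

Localization evaluation (`cam_localization_rate`) deviates from the naive
"peak inside the instantaneous body mask" reading for two measured
reasons. First, at desk scale the last stages see the whole frame (the
final tiny-profile volume is 4×4 at 64-px input) and carry no stable
spatial signal: across training seeds the final-stage peak-hit rate swung
between 0.97 and 0.12, while the second fused stage stayed at 0.80–1.00.
The harness therefore evaluates at the second stage, the deepest volume
whose grid still resolves a body. Second, temporal same-padding
convolutions spread walking evidence along the walked path, so a peak is
scored against the *swept* mask — the union of foreground masks at the
frames the spatial pathway sampled — dilated by half a feature cell, the
peak's intrinsic localization uncertainty. Both choices are evaluation
design, not model changes; the spec-level CAM on the final volume remains
the default output of `compute_cam`.

## Numerical and engineering notes

* All layers run in float32; metric functions compute in float64. The
  sigmoid uses the numerically stable `expit`. Strict open-interval mask
  properties are exact in real arithmetic but a float32 sigmoid rounds
  saturated values to 1.0; property tests therefore check them in float64.
* The autodiff engine (`x3dfast.nn`) is a reverse-mode tape over numpy
  arrays. 3D convolution is computed as a sum over kernel offsets of
  channel-mixing einsums (no im2col buffer); its gradients, batch
  normalization and the softmax cross-entropy are verified against central
  finite differences in the test suite.
* Training aborts with a diagnostic on non-finite loss; the best-validation
  state is checkpointed (self-describing archive: config, weights, running
  statistics, seed, metric history).
* Clips shorter than the fast sampling grid are looped (wrap padding);
  uniform frame indexing is strictly increasing whenever enough frames
  exist. Short-side resizing rounds the long side half up.
* The stratified splitter floors the per-class train count, sending the
  remainder to validation, and is exhaustive and disjoint by construction.

## Known limitations

* Single-device, single-precision training only; no learning-rate
  schedule, early stopping, or augmentation beyond random cropping.
* Batch normalization statistics are computed over whatever batch size is
  configured; very small batches give noisy estimates (the desk-scale
  defaults are chosen accordingly).
* The motion-excitation branch requires T ≥ 2 and raises a bypass error on
  single-frame inputs rather than degrading silently.
* The CE-branch temporal convolution always uses symmetric padding; there
  is no unpadded mode, so clips shorter than the kernel are handled rather
  than rejected.
* Deep-stage activation maps are not reliable localization evidence at
  desk scale (see above); for visualization on small inputs prefer
  `stage=1` or `stage=0`.
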