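# x3dfast

Recognizing dairy-cow behaviors — **standing, lying, walking, mounting** —
from short surveillance-video clips with a lightweight two-pathway 3D
convolutional network. Mounting frequency signals estrus; standing/lying
patterns reflect comfort and health, so reliable clip-level behavior
classification is a building block for automated herd monitoring. The
package is aimed at researchers in animal-behavior computer vision who want
a fully inspectable, CPU-runnable implementation of the architecture plus a
deterministic synthetic-clip simulator, so every part of the system can be
trained and validated without access to restricted farm footage.

## The model

A clip is sampled at two rates and fed to two parallel pathways over
feature volumes `X ∈ R^(N×T×C×H×W)`:

* **X3D pathway** (spatial emphasis, `T` frames): four stages of 3/5/11/7
  residual convolution groups whose 3×3×3 cores are depthwise-separable
  (per-channel 3×3×3 + 1×1×1 pointwise: `C·27 + C·C'` weights instead of
  `C·C'·27`). After every group a three-branch *action attention* module is
  applied; each branch builds a sigmoid mask and rescales the features
  residually, `Y = X + X · Mask`:
  - **STE** (spatial-temporal): channel-mean → single 3D conv →
    `Mask ∈ (0,1)^(N×T×1×H×W)`;
  - **CE** (channel): global spatial pool → squeeze to `⌈C/r⌉` (r = 16) →
    1D temporal conv → expand → `Mask ∈ (0,1)^(N×T×C×1×1)`;
  - **ME** (motion): channel-squeezed adjacent-frame differences
    `F_m(t) = K·F_r[t+1] − F_r[t]`, zero-padded at the last slot, pooled
    and expanded to a channel mask.
* **Fast pathway** (temporal emphasis, `αT` frames, `β`-scaled widths,
  α = 4, β = 1/8 in the full profile): same stage layout with **R(2+1)D**
  cores — a `t×d×d` convolution factorized into `1×d×d` then `t×1×1` with
  intermediate width `M_i = ⌊ t d² N_{i−1} N_i / (d² N_{i−1} + t N_i) ⌋`,
  chosen so the pair carries exactly the full-3D weight budget while adding
  a second nonlinearity.
* **Lateral connections** after every stage move fast-pathway motion
  features into the X3D pathway: a time-strided 3D convolution (kernel
  (5,1,1), stride (α,1,1)) aligns the frame counts, a 3D
  squeeze-and-excitation block reweights channels, and the result is
  concatenated onto the X3D features.
* **Predictor**: global average pooling of both pathways' final features,
  concatenation, and a two-layer fully connected head over M = 4 classes.

Training minimizes the cross-entropy
`L = −(1/N) Σ_i Σ_c y_ic log p_ic` with plain SGD (lr 0.01), and quality is
reported as top-1 accuracy. Gradient-weighted class-activation maps
visualize which spatio-temporal regions drove a prediction.

Because real barn footage is not distributable, the package ships a
deterministic simulator that reproduces the cues that make the four
behaviors separable — elongated vs. round static bodies (standing/lying),
translating bodies (walking), two oscillating overlapping bodies
(mounting) — plus occlusion, blur and illumination degradations, with
per-frame foreground masks for validating the activation maps.

## Worked example

Train the desk-scale ("tiny") profile on 280 synthetic clips (200 train /
80 validation after a stratified 5/7 split) and inspect what it learned:

```python
from x3dfast import (TrainConfig, generate_dataset, stratified_split,
                     train, evaluate, cam_localization_rate,
                     generate_clip, SceneSpec)

records = generate_dataset(n_per_class=(70, 70, 70, 70), seed=123)
split = stratified_split([r.label for r in records], train_frac=5/7, seed=123)
cfg = TrainConfig(seed=1, epochs=15)   # lr 0.01, SGD momentum 0.9, batch 8
result = train([records[i] for i in split.train_indices],
               [records[i] for i in split.val_indices], cfg)
print(f"best validation top-1: {result.best_val_top1:.4f}")

report = evaluate(result.model, [records[i] for i in split.val_indices], cfg)
print(report["per_class"])

walking = [generate_clip(SceneSpec(behavior="walking", t_frames=24, seed=9000+i))
           for i in range(20)]
rate = cam_localization_rate(result.model, walking,
                             TrainConfig(seed=1, resize_short=64, crop=64),
                             target_class=2)
print(f"CAM peaks on the moving cow in {rate:.0%} of frames")
```

Output from this exact run:

```
best validation top-1: 0.9875
{'standing': 1.0, 'lying': 1.0, 'walking': 0.95, 'mounting': 1.0}
CAM peaks on the moving cow in 100% of frames
```

79 of the 80 held-out clips are classified correctly; the only error is one
walking clip — the class pair that requires temporal rather than spatial
cues — and the CAM rate means the attention heatmaps track the moving
animal rather than the background.

A command-line pipeline wraps the same functionality:

```
x3dfast simulate --out data/ --per-class 25 --seed 0
x3dfast train --manifest data/manifest.csv --checkpoint ck.npz --seed 1
x3dfast evaluate --manifest data/manifest.csv --checkpoint ck.npz \
    --out-json report.json --out-csv report.csv
x3dfast cam --manifest data/manifest.csv --index 0 --checkpoint ck.npz --out cam/
```

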