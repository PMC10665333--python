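x3d_profile:
  stage_groups:
  - 1
  - 1
  - 2
  - 1
  stage_channels:
  - 8
  - 16
  - 24
  - 32
  stem_channels: 8
  t_frames: 4
  spatial_strides:
  - 1
  - 2
  - 2
  - 2
  attention_enabled: true
  conv_style: depthwise_separable
  in_channels: 3
alpha: 2
beta: 0.25
num_classes: 4
predictor_hidden: 256
predictor_dropout: 0.5
lateral_kernel:
- 5
- 1
- 1
lateral_padding:
- 2
- 0
- 0
se_ratio: 16
use_lateral: true
use_r2plus1d: true
use_action: true
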