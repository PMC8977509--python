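# 32x32 RGB encoder: five 3x3 convolutions with three max-pools and a
# 64-dimensional linear projection head (flatten, no average pooling).
input_shape: [3, 32, 32]
layers:
  - {kind: conv, channels: 32, kernel: 3, stride: 1, activation: hardtanh}
  - {kind: conv, channels: 32, kernel: 3, stride: 1}
  - {kind: maxpool, size: 2}
  - {kind: conv, channels: 64, kernel: 3, stride: 1, activation: hardtanh}
  - {kind: conv, channels: 64, kernel: 3, stride: 1}
  - {kind: maxpool, size: 2}
  - {kind: conv, channels: 512, kernel: 3, stride: 1}
  - {kind: maxpool, size: 2}
  - {kind: flatten}
  - {kind: linear, width: 64}
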