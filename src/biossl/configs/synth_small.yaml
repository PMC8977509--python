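# Desk-scale 28x28 grayscale encoder used with the synthetic shape fixture:
# three conv/max-pool/tanh stages (16/32/64 channels) and a 64-d head.
input_shape: [1, 28, 28]
layers:
  - {kind: conv, channels: 16, kernel: 3, stride: 1}
  - {kind: maxpool, size: 2, activation: tanh}
  - {kind: conv, channels: 32, kernel: 3, stride: 1}
  - {kind: maxpool, size: 2, activation: tanh}
  - {kind: conv, channels: 64, kernel: 3, stride: 1}
  - {kind: maxpool, size: 2, activation: tanh}
  - {kind: flatten}
  - {kind: linear, width: 64}
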