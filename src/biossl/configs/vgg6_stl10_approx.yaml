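# APPROXIMATE VGG6-style encoder for 64x64 RGB crops, with a 2x2 average
# pool before the 64-d projection head. The exact six-convolution
# composition is defined in prior work and is not reproduced verbatim here;
# treat this as a best-effort stand-in.
input_shape: [3, 64, 64]
layers:
  - {kind: conv, channels: 128, activation: hardtanh}
  - {kind: maxpool, size: 2}
  - {kind: conv, channels: 256, activation: hardtanh}
  - {kind: maxpool, size: 2}
  - {kind: conv, channels: 256, activation: hardtanh}
  - {kind: maxpool, size: 2}
  - {kind: conv, channels: 512, activation: hardtanh}
  - {kind: maxpool, size: 2}
  - {kind: conv, channels: 1024, activation: hardtanh}
  - {kind: conv, channels: 1024, activation: hardtanh}
  - {kind: avgpool, size: 2}
  - {kind: flatten}
  - {kind: linear, width: 64}
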