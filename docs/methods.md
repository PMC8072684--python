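# Methods

## Data model

A recording is a continuous 6-channel inertial stream: accelerometer
Ax, Ay, Az and gyroscope Gx, Gy, Gz, in that fixed row order, sampled
at a constant rate (50 Hz for smartphone-style recordings, 100 Hz for
belt-mounted IMUs). Units are carried as metadata and never enforced —
the classifier is unit-agnostic because batch normalization absorbs
affine channel scaling. The unit of classification is a 6×128 matrix
cut from the stream.

Two segmentation regimes are supported:

- **Fixed-length**: windows of 128 samples, advancing by
  `stride = round(128 × (1 − overlap))`. Rounding (not flooring) is
  deliberate: it is the only rule under which all three conventional
  overlap settings (0, 50%, 61%) land on an integer grid — 61% gives
  stride 50. The window count is `floor((T − 128)/stride) + 1`; a
  stream shorter than one window yields an empty list rather than an
  error, and a configuration whose stride rounds to 0 is rejected.
- **Cycle-emulated**: spans of two gait cycles, linearly interpolated
  to 128 time steps. Cycle positions come from the generator's cadence
  metadata or from explicitly supplied boundaries; detecting cycles
  from a raw noisy signal is a hard problem in its own right and is
  deliberately out of scope, so a stream without cycle information is
  rejected. Overlap acts at cycle granularity (0.5 advances by one
  cycle instead of two).

Linear interpolation resamples each row independently onto a uniform
grid spanning the original index range, so endpoints are preserved
exactly, affine rows are reproduced exactly, and resampling a length-128
span is the identity.

Train/test separation is temporal: each stream is cut in time and the
two parts segmented independently, which guarantees no window of the
test set overlaps any training window.

No per-channel normalization is applied by default; `zscore_channels`
is available as an explicit opt-in.

## Synthetic generator

The generator emulates per-subject quasi-periodic walking: subject s
draws a cadence uniformly from 0.7–1.3 Hz (a normal adult walking
band); each channel is a sum of `n_harmonics` (default 4) harmonics of
that cadence with amplitudes decaying as 1/h scaled by a per-channel
uniform factor in [0.5, 1.5], uniform phases, plus i.i.d. Gaussian
noise of standard deviation `noise_sd` (default 0.1, relative to the
O(1) signal amplitude). All draws are pure functions of
(seed, subject, channel), so generation is bit-for-bit reproducible.

What this emulates: subjects distinguishable by their spectral
signature (cadence plus harmonic profile), realistic sampling rates and
window arithmetic. What it does not emulate: stride-to-stride cadence
variability, posture changes, device repositioning, gravity offsets,
non-walking segments, or inter-subject similarity structure. Passing
the end-to-end tests therefore demonstrates that the pipeline learns
and generalizes on separable quasi-periodic signals — not that any
particular accuracy carries over to field recordings.

## Architecture

Backbone (input 6×128×1, NHWC): Conv1 1×9/32 stride (1,2) same →
Pool 1×2 → BN → ReLU → Conv2 1×3/64 same → Conv3 1×3/128 same (no
BN/ReLU between Conv2 and Conv3) → Pool 1×2 → BN → ReLU → Conv4
6×1/128 valid → BN → ReLU, ending at a 1×16×128 map. Conv1's stride
(1,2) with same padding is the unique setting producing the 128→64
width reduction with a 1×9 kernel. Pooling is max by default with
average pooling as a config option. All convolutions carry biases.

CEDS attention on the 1×16×128 map:

- Context encoding with K = 1 codeword d ∈ R^128 (initialized uniform
  on (−0.5, 0.5); the smoothing factor, uniform on (0, 1), is carried
  as a learnable but is inert in both forward and gradient at K = 1,
  since the softmax over a single codeword is identically 1). The
  encoding is e = Σ_j (x_j − d) over the 16 spatial descriptors, and
  channel weights are w = e / Σ e.
- The divisive normalization is implemented literally, with one guard:
  when |Σ e| < 1e−8 the denominator is replaced by ±1e−8 preserving
  the sum's sign (+ at exactly zero). No squashing or absolute value is
  applied to w.
- Branch: depthwise 1×3 convolution with bias, valid padding
  (width 16 → 14), then BatchNorm + Sigmoid applied twice with two
  independent BN parameter sets; no pointwise 1×1 stage follows the
  depthwise filter. The output is the branch times w, broadcast per
  channel.

Valid padding in the depthwise stage, the depthwise-only (no pointwise)
design, and the 745-unit head for the largest-population setting are
each forced by the parameter-accounting identities below.

SE baseline: global average pool → dense 128→8 → ReLU → dense 8→128 →
Sigmoid → channel scaling, i.e. reduction r = 16, the convention of the
original squeeze-and-excitation design.

Head: flatten (2048, or 1792 after the CEDS width reduction) → dense →
softmax.

## Parameter accounting

Counting convention: conv = kH·kW·Cin·Cout + Cout; depthwise =
kH·kW·C + C; batch norm = 4 per channel (gamma, beta, moving mean,
moving variance — moving statistics are counted); CEL = K·C + K;
dense = in·out + out. Under this convention the totals are

| head | plain CNN | CNN+CEDS |
|------|-----------|----------|
| 118 | 372,598 | 344,055 |
| 20 | 171,796 | 168,341 |
| 745 | 1,657,321 | 1,468,266 |

with the identity `total(ceds, c) = total(none, c) + 1,665 − 256·c`
(module cost 129 + 512 + 2·512 = 1,665; head saving 256 per class from
the 2048 → 1792 flatten). The analytic accountant never touches weight
arrays; the engine's counter sums actual array sizes; the two are
asserted equal. The 745-unit head corresponds to 744 subjects plus one
unused label index.

## Training engine and protocol

The package ships its own numpy NHWC engine (convolution via
kernel-offset slicing and matmul, non-overlapping pooling, batch norm,
depthwise convolution, dense, Adam). Every analytic backward pass is
verified against central-difference gradients in float64 to 1e−7 in the
test suite; the attention modules additionally match scalar triple-loop
forward oracles to 1e−5. Default parameter dtype is float32.

Protocol: softmax cross-entropy, Adam at learning rate 1e−4, batch 512,
20% of the training data held out as a stratified validation split
(per-class counts rounded, singleton classes kept in training with a
warning), early stopping with patience 30 on the monitored metric
(validation loss by default, validation accuracy by config), strict
improvement with no minimum delta, `max_epochs` cap 500 for bounded
runs, and restoration of the best epoch's weights on return.

### A note on the stability of divisive channel weights

Because w = e / Σe is scale-free in e but not bounded, gradient descent
can inflate the channel weights by shrinking the encoding sum toward
zero; once |Σe| becomes small the weights blow up and training loss
spikes. This is an inherent property of the literal divisive form
(deliberately implemented without extra squashing) and is exactly the
failure mode that validation-monitored early stopping with best-weight
restoration is designed to absorb: the returned model is always the
validation optimum, cut out before the instability. On small synthetic
fixtures validation *accuracy* is the more faithful monitor, because
late small-loss epochs can coincide with degraded decisions; the
monitor is a config switch.

## Fixture scales

The seeded end-to-end fixtures use 10 subjects at 50 Hz with 50%
overlap windows: the easy task uses 325 s streams (~250 windows per
subject, ≥200 in training) at noise 0.05 and 15 epochs; the hard task
uses 100 s streams at noise 1.5 — noise well above every harmonic
amplitude — across 5 paired seeds. Batch size is 128 on these
fixtures: the reference batch of 512 would cover most of a fixture's
training split in a single step, which is a poor regime for
minibatch-statistics batch norm. The learning rate stays at the
reference 1e−4.

## Known limitations

- The engine is single-threaded numpy; it is built for exactness and
  small models, not throughput.
- K > 1 context encoding is available in the reference
  `context_encode` function but not as a trainable layer (configuration
  stub only).
- The cycle-emulated regime requires cadence metadata or explicit
  boundaries; there is no cycle detector.
- AUC is macro one-vs-rest over the softmax scores; labels absent from
  a test set are excluded from all macro averages, and a test set with
  a single class yields NaN AUC.
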