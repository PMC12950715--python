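# Methods

## The model

TinyWeedNet is a compact convolutional classifier for weed imagery designed
around the operator set that microcontroller inference toolchains execute
natively: standard, pointwise and depthwise convolutions, batch
normalization, ReLU and sigmoid, max and global pooling, concatenation,
element-wise add/multiply, and one fully connected layer. For an RGB input
`X ∈ R^{3×H×W}` (default `H = W = 224`) the pipeline is

```
stem:   F0 = ReLU(BN(Conv3x3, s=2 (X)))                     24×112×112
MSC:    Fmsc = Concat[B1..B4], Bi = ReLU(BN(conv_i(F0)))    36×112×112
IR#1–5: expand(1x1, E·Cin) → depthwise(3x3, s) → CA(R) →
        project(1x1, linear bottleneck); skip when s=1, Cin=Cout
head:   Conv1x1 → 240 → GAP → dropout(0.2) → FC → 9 logits
```

The multi-scale block (MSC) runs four stride-1 branches — 1×1, 3×3, 5×5,
and 3×3 max-pool followed by 1×1 — each Conv+BN+ReLU, concatenated on the
channel axis. The five inverted-residual (IR) stages use strides
2, 2, 2, 2, 1 and widths 48/72/96/120/120. Channel attention (CA) pools the
expanded feature map with both global average and global max pooling,
passes both descriptors through a *shared* two-layer 1×1 bottleneck of
hidden width `max(1, C//R)`, sums the two outputs and applies a sigmoid
gate multiplied back onto every channel. The projection convolution has no
activation (linear bottleneck); the single residual connection in the
default network sits around IR#5, the only stage where stride 1 and equal
widths permit it.

Three design knobs define the variant family: expand ratio `E ∈ {3, 4, 6}`,
attention reduction `R ∈ {4, 8, 16}` and stem width `S ∈ {8, 16, 24}` —
a 27-point full-factorial grid with identifiers `E{E}_R{R}_S{S}`; the
reference point is `E4_R8_S24`. For `S ≠ 24` the channel schedule scales
proportionally (`msc = 1.5 S`, `ir = [2S, 3S, 4S, 5S, 5S]`, `head = 10 S`),
which keeps every entry integral on the grid; `make_divisible` is available
for off-grid widths. Four ablations modify the reference point: `no_msc`
(single full-width 3×3 branch), `no_attention` (gates removed),
`no_depthwise` (standard 3×3 in place of each depthwise convolution) and
`no_final_projection` (classifier fed directly by the 120-channel GAP).

## Weight conventions and parameter accounting

The literature rarely prints bias/normalization conventions, yet the
parameter total depends on them. We resolved the convention by enumerating
the plausible policy space (per-layer-family conv biases, attention
bottleneck bias/rounding/normalization placement, branch-width splits)
against the published totals of this architecture family and froze the
single policy that reproduces the reference figures exactly:

* standard and pointwise convolutions carry biases; depthwise convolutions
  do not;
* every convolution is followed by affine BN (2 parameters/channel;
  running statistics are not counted);
* the CA squeeze layer is Conv1×1 (bias) + BN + ReLU; the excite layer is
  Conv1×1 (bias) feeding the sigmoid; hidden width is plain integer
  division `C//R`;
* the classifier is a biased fully connected layer.

Under this policy the reference network has **475,803** trainable
parameters (475.8K, 0.48 M; 1.815 MB at 4 bytes/parameter with
MB = 2²⁰ bytes) and the `no_final_projection` ablation has **445,203**
(445K). A pleasing internal consistency check: the single 3×3 full-width
branch of `no_msc` costs exactly as many parameters as the four parallel
branches it replaces (kernel elements 1 + 9 + 25 + 1 = 36 = 4 · 9), so its
total equals the baseline's — matching the published table, which prints
identical counts for both.

Two routes compute every count and must agree exactly: a walk over the
assembled network's weight arrays, and closed-form per-layer formulas
evaluated from the configuration alone. The headline MACC figure counts
convolution and fully-connected multiplies
(`output elements × k² × per-group input channels`); attention-MLP
multiplies are tabulated in a separate column (they do not scale with
image area), and BN/activation/pooling element-ops are reported as an
*unvalidated* approximation of what deployment profilers fold into their
own figures.

Known discrepancies, documented rather than reproduced:

* the published ablation table lists "w/o Attention" at a *larger*
  parameter count than the baseline (820K vs 475K). No architecture
  consistent with the stated description does this — removing a module with
  strictly positive parameter terms must shrink the count. The
  implementation follows the description literally (344,157 parameters)
  and the tests assert the decrease.
* the published 27-row grid is not exactly consistent with any single
  additive weight convention (some rows sit *below* the minimal
  closed-form count); the frozen policy reproduces the pinned reference
  totals exactly and the remaining rows within ~1.6%, and the row ordering
  (parameters increase with E and S, decrease with R) holds exactly.
* "w/o DepthwiseConv" computes to 5.13 M against a printed 5.10 M
  (treated as reporting noise; the order-of-magnitude growth is the
  validated property).

## Training and evaluation

The reference protocol is plain SGD (no momentum), learning rate 0.001,
batch size 32, cross-entropy loss, up to 100 epochs, with early stopping
when the monitored accuracy stops improving (patience 10 epochs,
min-delta 0). The protocol monitors held-out accuracy, which leaks the
test set into the stopping rule; a `train_accuracy` monitor is provided
and used in the smoke benchmark. Metrics are top-1 accuracy and
*unweighted macro* F1 in percent; repeated runs fix the data split and
re-seed only the weights (and the shuffling/dropout stream), reporting
mean ± SD.

The network, including backpropagation, is implemented in float32 numpy:
im2col + BLAS matmul for standard convolutions, shifted multiply-adds for
depthwise convolutions and pooling, standard train/eval batch
normalization, inverted dropout. Weight initialization is Kaiming-normal
(fan-out) for convolutions, `sqrt(2/fan_in)` for the classifier, unit-γ /
zero-β BN, all drawn from a single seeded generator, so identical seeds
give bitwise-identical networks. BN uses ε = 1e-5 and running-average
momentum 0.1. Max-pool gradient ties share the gradient equally among
maxima. The CA bottleneck processes the average- and max-pooled
descriptors as one stacked batch, so the shared BN sees both paths'
statistics jointly during training and uses the same running statistics
for both at inference.

## Synthetic data

The generator renders 256×256 RGB scenes: a soil-toned noisy background,
a few dozen random elliptical leaf elements at class-dependent scale, a
class-specific base hue (spaced around the hue wheel, jittered per leaf),
class-dependent sinusoidal texture frequency, and a global illumination
jitter of ±20%. Defaults are 9 classes and 30 images per class. This
emulates the statistical structure that makes weed classification
learnable — class-dependent foliage color, element scale and texture under
varying illumination — but none of the photographic nuisances of field
data: no occlusion by other species, no perspective or depth-of-field
effects, no seasonal or regional drift, no label noise. Passing the smoke
benchmark therefore demonstrates that the architecture, optimizer and
metric plumbing work end-to-end, not that field-grade accuracy is
attainable.

The desk-scale smoke benchmark trains the reference architecture at input
side 64 (stride arithmetic still yields a 2×2 final feature map; sides
below 32 are rejected) on the easy synthetic set with
momentum-accelerated SGD (lr 0.05, momentum 0.9), stopping once training
accuracy reaches 95%; this completes in a few minutes on one CPU and
typically fits the training set within 7–13 epochs with held-out macro-F1
near 98%.

## Corruption robustness

Six single-transform corruption families at three severities each operate
on the preprocessed [0, 1] image, labels untouched: additive brightness
β ∈ {0.10, 0.20, 0.30}; contrast rescale about the scalar image mean
α ∈ {0.8, 0.6, 0.4}; gamma `I^γ`, γ ∈ {0.8, 1.2, 1.6} (0.8 is listed as
severity 1 although it brightens rather than degrades monotonically —
kept as published); white-balance channel scales (1.1, 1.0, 0.9) /
(1.2, 1.0, 0.8) / (1.3, 1.0, 0.7); Gaussian blur with kernel k ∈ {3, 5, 7}
and σ = 0.3·((k−1)·0.5 − 1) + 0.8 (the conventional k→σ link; σ is not
specified independently), unit-sum kernel, reflective borders; and an HSV
hue rotation Δh ∈ {±5°, ±10°, ±15°}. Each signed hue shift is evaluated
separately and the row reports the mean of the two F1 scores — the
symmetric reading of a ± specification that prints one row per severity.
Clipping keeps every transform inside [0, 1]; the identity parameter
values (β = 0, α = 1, γ = 1, unit scales, Δh ∈ {0°, 360°}) are exact
identities (hue up to HSV round-trip tolerance).

The harness reports macro-F1 on the clean set and under each of the 18
corruptions, with ΔF1 computed exactly as F1 − clean F1.

## Export and embedded compatibility

The exchange artifact is a JSON text file: execution-ordered nodes, an
initializer table (float32, base64), explicit tensor names — the
information an ONNX protobuf carries, in a dependency-free encoding. The
inference graph strips dropout and preserves BN with running statistics
(deployment tools may fuse it; both forms are whitelisted). A reference
interpreter executes the graph with independently written numpy kernels;
round-tripping any variant reproduces native logits within 1e-4. The
operator linter inventories node types against the embedded whitelist
(convolutions including grouped/depthwise, BN, ReLU, sigmoid, pooling,
Gemm/MatMul, concat, add, multiply, reshape/flatten) and reports
violations. Note the exported default graph contains six element-wise
adds: one feature-map residual (IR#5) and five attention path-sums — the
gate equation itself sums two MLP outputs, so these adds are intrinsic,
not topology overhead.

## Not reproducible at desk scale

The package deliberately does not claim, and cannot verify on one CPU with
synthetic data: full-dataset (DeepWeeds) accuracy or F1 of any variant or
ablation; all hardware-dependent figures — inference latency, energy per
inference, flash and RAM footprints; the corruption-table F1 values
measured on a full-dataset-trained model; and the deployment tool's MACC
figure, whose op accounting is proprietary (our conv+FC figure for the
reference network is 2.77×10⁸; the tool prints ~3.12×10⁸ including
unspecified normalization/activation/pooling ops). What stands in for them
is exact structural reproduction: shape schedule, parameter totals, model
size, grid ordering, operator compatibility, and end-to-end training on
the synthetic benchmark.
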