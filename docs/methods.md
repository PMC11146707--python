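# Methods

## Dilation convention and receptive-field accounting

The dilation factor `d` in a branch tuple `(k, s, d, f)` follows the
convention in which `d = 0` denotes a plain contiguous convolution. The
effective spacing between consecutive kernel taps is therefore
`max(d, 1)`; `d = 0` and `d = 1` are the same geometry. This is the only
reading under which the canonical blocks' printed receptive fields for the
residual block (16) and MSDC blocks A (11) and C (8) all follow from their
branch tuples.

The receptive field of a block is counted as the number of **distinct**
input positions that influence one output unit: each branch contributes tap
offsets `{i · max(d, 1) : i < k}` anchored at a common origin, and the
block's value is the cardinality of the union. Two consequences are worth
stating:

* the count is bounded below by the largest branch kernel and above by the
  sum of branch kernels, and it never decreases when a branch is added;
* for MSDC block B the union of `{0,2,…,14}`, `{0,3,…,15}`, `{0}`, `{0}` has
  11 elements, not the 13 printed in the original comparison table. No tap
  spacing consistent with block B's printed parameter count (128) yields 13,
  so the analyzer returns 11 and attaches a discrepancy note to the report
  rather than reproducing an unreachable number.

Parameter counts are exposed under two conventions: the publication-style
`W = k · f` per branch (input channels and biases excluded), which
reproduces the printed 512 / 224 / 128 / 256 exactly, and the engineering
`in_channels · k · f + f`, which matches the engine's own enumeration of
trainable conv weights and is what real model sizing should use. The
network-level "millions of parameters" totals quoted alongside the original
tables are not derivable from 15-block stacks under either convention, so
only block-level counts are treated as ground truth here.

## Block and network construction

Blocks use pre-activation ordering — shared batchnorm and ReLU on the block
input, then the parallel dilated branch convolutions — matching the deep
1-D ResNet lineage these models descend from. Branch outputs are
concatenated on the channel axis; in every canonical block the branch
filter counts sum to 32, exactly the residual block's width, which is what
makes the MSDC block a drop-in replacement. A shortcut adds the block input
to the merged output: identity when shapes match, a pointwise (k = 1)
projection convolution when channel counts or temporal lengths differ.
Branches use same-length zero padding so concatenation is well defined;
`k = 1` branches are pointwise convolutions regardless of their nominal
dilation. Dropout is not used.

A network is: stem convolution (contiguous kernel 16, 32 filters, stride 2)
→ `n_blocks` identical blocks → batchnorm/ReLU → global average pooling
over time → linear head. The stride-2 stem halves the temporal axis once at
the input; with the analog bandwidth of ambulatory recordings at 0.1–40 Hz
and sampling rates of 250–300 Hz, the signal is heavily oversampled and the
early halving loses no usable band while halving all downstream compute.
Temporal halving thereafter follows the `downsample_schedule` (every fourth
block for the 15-block configuration; every block for the 4-block reduced
variants, keeping deep activations short). Global average pooling makes the
head length-agnostic, so the four-class variable-length regime needs no
architectural change; variable-length batches are zero-padded to the batch
maximum before pooling.

Weights use fan-in-scaled (He) normal initialization from an explicit
integer seed; two builds from the same seed are bit-identical. Checkpoints
are single `.npz` files holding every weight array, the batchnorm running
statistics, and the full network specification as embedded JSON, so a
checkpoint round-trips without external context.

The blocks and networks run on a small numpy engine written for this
package: dilated 1-D convolution is computed as one GEMM per kernel tap
(gradients are exact and finite-difference-verified in the test suite),
plus batchnorm, ReLU, global average pooling, a linear layer, softmax
cross-entropy, and Adam. Float32 is the working precision; float64 is used
in gradient-check tests.

## Synthetic rhythm generator

The generator emulates the two study regimes — fixed 10-s windows at 250 Hz
with binary labels, and variable 9–30 s records at 300 Hz with four labels —
and encodes exactly the class-conditional structure an AF detector must
learn:

* **RR interval law.** Sinus rhythm draws i.i.d. truncated-normal intervals
  (default mean 0.8 s, CV 0.05); AF draws i.i.d. lognormal intervals with
  CV 0.30 and mean 0.7 s — irregular and serially uncorrelated. The
  "other" class is sinus rhythm with premature-beat pairs (a 0.6× RR beat
  followed by a 1.4× compensatory pause, injection probability 0.18), one
  concrete mechanism for a heterogeneous class. Intervals are clipped to
  [0.25, 3] s.
* **Morphology.** A beat is a sum of Gaussian bumps for P, Q, R, S, T at
  fixed latencies; the P bump (default 0.15 mV) is present in sinus classes
  and absent in AF. This is a test-bench surrogate — it carries the features
  the classes are defined by, not the full morphological variability,
  electrode artifacts, or pathology spectrum of real ECG. Passing the
  learning tests therefore demonstrates that the architectures learn the
  class-defining structure, not clinical-grade performance.
* **Fibrillatory activity.** AF adds a frequency- and amplitude-jittered
  sinusoid at 6.5 Hz (within the 4–10 Hz fibrillatory band), amplitude
  0.10 mV.
* **Noise.** All classes carry additive band-limited (0.1–40 Hz, the Holter
  analog bandwidth) Gaussian sensor noise, default 0.03 mV; the "noise"
  class is pure band-limited noise at 0.35 mV with no beat structure.
  Samples are clipped to ±5 mV.

Every segment derives its seed deterministically from the dataset master
seed; identical arguments give bit-identical signals. A plain RR-interval
CV threshold separates the default AF/normal classes with ≥ 95% accuracy
(asserted in the suite), so the learning task posed to the networks is
well-defined before any network is trained.

## Windowing, labels, and splits

Long rhythm-annotated records are cut into non-overlapping windows that
must lie entirely within a single rhythm interval; windows restart at every
interval boundary, so an interval of `L` samples yields exactly
`floor(L / window_samples)` windows and no window ever straddles a rhythm
change. Non-overlap is the conservative reading of the published windowing
description; overlapping strides would inflate segment counts. The binary
AF label set is `{AFIB}` — atrial flutter and junctional rhythms count as
non-AF, consistent with an AF-vs-everything-else screening task. Intervals
use 0-based half-open `[start, end)` sample coordinates. The first lead is
used by default.

Splits are 8:1:1 with largest-remainder rounding under a seeded
permutation, segment-level by default (stratified per class on request).
Segment-level splitting mirrors the published protocol; note it allows
windows from one patient to appear in both train and test, so real-data
numbers under it are optimistic relative to record-level splits.

WFDB support is a minimal reader/writer pair written for this package:
text headers, format-16 signals, and MIT-format annotations whose AUX
strings carry rhythm labels. It covers the subset rhythm-interval
extraction needs and round-trips its own fixtures; it is not a general
WFDB implementation.

## Training protocol and metrics

Training uses Adam (β = 0.9/0.999) with softmax cross-entropy, batch
size 64, and early stopping: training stops when the best validation loss
has not strictly improved for 10 consecutive epochs (no minimum delta), and
the best-epoch weights are restored. The full-scale protocol is an initial
learning rate of 1e-4 for up to 100 epochs. The desk-scale demonstrations
(4-block networks, 800 training segments) use 1e-3 for up to 12 epochs with
patience 5: at ~360 optimizer steps total, the standard Adam default step
size is appropriate where 1e-4 is tuned for 82k-segment training runs. No
class weighting is applied. Each segment is normalized to zero mean and
unit variance before entering the network.

Metrics follow the standard definitions: sensitivity TP/(TP+FN) and
specificity TN/(TN+FP) on the binary task (AF positive); per-class
F1 = 2·diag / (row marginal + column marginal) on the 4×4 confusion matrix
and the unweighted macro mean F1all on the four-class task. Zero
denominators raise an explicit undefined-metric error naming the quantity
rather than silently reporting 0. The evaluation path is cross-checked in
the suite against independently tallied confusion matrices.

## Problem sizes used by the suite

The learning-sanity checks train 4-block variants of all three MSDC types
on 800/100/100 stratified splits of 1000 balanced synthetic AF/normal 10-s
segments (≤ 12 epochs each); end-to-end determinism is asserted on a
2-block network over 60 segments. These sizes exercise every code path —
simulation, splitting, batching, optimization, early stopping, checkpoint,
evaluation — at desk scale. They demonstrate that the architectures learn
the synthetic class structure to ≥ 95% validation accuracy; they say
nothing about performance on real ambulatory recordings, which requires
the external databases and full-scale training.

## Known limitations

* The numpy engine targets clarity and desk-scale workloads; a 15-block
  network at full sequence length trains, but slowly compared to GPU
  frameworks.
* The simulator's "other" class is a single mechanism (premature beats);
  real "other rhythm" classes are far more heterogeneous.
* Variable-length batches are zero-padded and pooled over the padded
  length; with highly disparate durations in one batch this slightly
  dilutes the pooled features of short records (batch size 1 evaluation
  avoids it entirely).
* The published network-level parameter totals and block B's printed
  receptive field are not reproducible from the published block
  descriptions; the analyzer documents rather than hides this.
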