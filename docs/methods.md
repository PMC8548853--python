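# Methods

## Problem setting

A nanopore sequencer digitizes the ionic current through each pore at
~4 kHz while DNA translocates at ~450 bases/s, so one second of signal
covers roughly 450 nucleotides at ~8.9 samples per base. `nanosieve`
classifies a read from its first ~4500 raw samples — 1000–1500 samples of
adapter/pore noise that are discarded plus a 3000-sample analysis window —
early enough for a Read-Until controller to eject non-target molecules and
re-use the pore.

## Preprocessing

Raw DAC counts are converted to picoamperes with the standard calibration
`pA = (raw + offset)·range/digitisation`. The analysis window is the
half-open sample range `[skip, skip+3000)`; `skip` defaults to 1500 for
training corpora (a deliberate overestimate of adapter length) and 1000 at
inference (earlier decisions). Reads too short to fill the window are
excluded with a logged reason rather than failing the batch.

Within the window, samples with modified z-score
`0.6745·|x − median|/MAD > 3.5` (the Iglewicz–Hoaglin rule) are replaced by
the mean of the nearest non-outlier neighbor on each side (one-sided at the
edges; runs of consecutive outliers all resolve to the bracketing inliers).
The window is then normalized to `(x − median)/MAD`, with median and MAD
recomputed on the repaired window. Repair-then-normalize ordering is a
deliberate choice: recomputing the statistics after repair means a single
extreme spike cannot perturb the scale estimate. Because the normalization
is affine-invariant, classification is insensitive to per-read gain and
baseline drift, and it is immaterial whether the input was DAC counts or pA
(a flag allows skipping calibration).

Degenerate (constant) windows have MAD 0 and are rejected explicitly; this
is distinct from the too-short exclusion path.

## Classifier

A compact 1D residual network over the normalized window, shaped
`(batch, 1, 3000)`:

- stem: Conv(1→20, kernel 19, stride 3), batch norm, ReLU;
- four layers of two bottleneck blocks each; layer widths are
  `round_half_up(20·1.5^i)` = 20, 30, 45, 68; every block strides by 2, so
  the trunk downsamples time by `3·2⁸ = 768` (a 3000-sample input leaves 4
  positions);
- each bottleneck: 1×1 conv halving the channel count → kernel-3 strided
  conv → 1×1 expansion back to layer width, batch norm + ReLU inside,
  post-activation ordering, and a strided 1×1 projection (with batch norm)
  on the shortcut whenever the shape changes;
- global average pooling over time, then a fully connected softmax head.

Convolutions carry no bias (batch norm supplies the shift). With the
default configuration the model stores 44,197 32-bit scalars — 172.6 KB
counting batch-norm running statistics — against a 304 KB budget.
Configuration knobs (stem width/kernel/stride, layers, blocks, growth
factor, striding policy, classes, input length) are exposed in
`ModelConfig`; a too-short `input_length` for the stride pyramid is
rejected naming the minimum (the total downsampling factor).

The bottleneck internals (reduce-by-half ratio, kernel 3, stride placed on
the middle conv, projection shortcuts) and the stem (kernel 19, stride 3)
are design choices made where only the block diagram is fixed; they satisfy
the memory budget with a wide margin.

Initialization is Kaiming fan-out for all convolutions, deterministic given
a seed. Two further standard choices materially help short training
budgets: the last batch-norm gain in each bottleneck starts at zero (each
block begins as a projection of the identity), and the head uses fan-in
scaling so initial logits are near zero and the first optimizer steps are
not spent undoing a large random head.

The network and its backpropagation are implemented directly on numpy
(im2col convolutions backed by BLAS matrix products). Input gradients were
validated against central finite differences (max relative error ~1e-4).

### Attribution

`integrated_gradients` computes a midpoint-rule Riemann sum of input
gradients of the target-class *pre-softmax* score along the straight path
from a baseline (default all-zeros) to the window, multiplied by the
displacement. The completeness identity
`sum(attributions) ≈ score(window) − score(baseline)` holds to quadrature
error (well under 1% at 256 steps; exact for a linear scorer).

## Training

Adam (β = 0.9/0.999), learning rate 1e-3, cross-entropy on 2-logit softmax,
batch size 1000 and 6 epochs by default — both reducible for smaller
corpora. Splits are label-stratified, disjoint, exhaustive, and
deterministic given the seed. Per-epoch shuffling is seeded; the state with
the best validation accuracy is retained (the selection rule is a design
choice; no learning-rate schedule or weight decay is used). After the best
state is restored, batch-norm running statistics are refreshed with one
pass over the training data, since with short runs the momentum-averaged
statistics lag the final weights. The loop is bit-reproducible on a fixed
BLAS build.

## Synthetic data

The simulator generates labelled two-class corpora with the statistical
structure the classifier relies on, so the whole stack is testable without
sequencing data. Per read:

1. a template sequence (random with configurable GC, or drawn from a
   supplied FASTA) of lognormal length, median 700 bases, σ = 0.2 — long
   enough that ≥99% of reads fill the default skip + window;
2. each of the `L−k+1` k-mers draws a current level from a k-mer table
   (means uniform in 60–120 pA, sds uniform in 0.5–3 pA, deterministic
   given a seed) plus per-event Gaussian noise;
3. a geometric dwell per k-mer with mean `sampling_rate/speed`
   (4000/450 ≈ 8.9 samples/base) — the simplest memoryless model of
   translocation-speed jitter;
4. per-sample Gaussian pore noise (sd 2 pA), a per-read gain (sd 5%) and
   baseline (sd 2 pA) — removed by robust normalization, but exercised by
   it;
5. an adapter-like prefix of 1000–1500 samples of high-variance noise
   (N(70, 20) pA), so the skip rule is meaningful;
6. quantisation to integer DAC counts with stored MinION-like calibration.

Class differences are injectable three ways: different template sources, GC
skew, or a current-level shift on a stated k-mer subset (a methylation-like
perturbation). The shift magnitude is stated in normalized units and
converted to pA via the MAD of the level table (~15 pA), i.e. Δ = 1.0 means
the shifted k-mers move by one robust standard deviation of the signal.

The default shifted subset is the top quartile of k-mers ranked by
unmodified level (`shift_mode="top"`). This choice is deliberate: a shift
applied to a subset spread across the whole level distribution moves the
per-read mean and median almost equally and is therefore *cancelled* by
median/MAD normalization, leaving only a weak distribution-shape signal.
Shifting the top quartile moves no probability mass across the median — and
for a uniform level distribution leaves the MAD exactly unchanged — so the
mean-level separation (0.25 normalized units at Δ = 1.0) survives
normalization and the task difficulty is controlled monotonically by Δ. The
`"leading_base"` mode (k-mers starting with a given base set) is retained
as the harder, shape-only variant.

What the simulator does *not* emulate: real pore-model sequence structure
(neighbouring k-mers sharing levels), event-boundary transients, pore
blocking and death, speed drift within a read, homopolymer dwell
pathologies, and RNA. Passing the synthetic recovery test therefore shows
the pipeline is correct and the optimizer adequate — not that any
particular accuracy carries over to real sequencing data.

## Read-Until throughput model

For target concentration `c`, mean target/non-target lengths `z̄`/`h̄`,
classifier rates TPR/TNR, and `b_d = speed·(t_signal + t_decide)` bases
consumed before a decision, the expected cost of `n` accepted targets is

- without Read-Until: `reads = n/c`,
  `bases = (n/c)·(c·z̄ + (1−c)·h̄)`;
- with Read-Until: `reads = n/(c·TPR)`,
  `bases/read = c·(TPR·z̄ + (1−TPR)·b_d) + (1−c)·((1−TNR)·h̄ + TNR·b_d)`.

Time is `bases/(speed·pores)`; the Read-Until arm is additionally charged
`t_decide` per read and `t_eject` (default 0.5 s, echoed in every result)
per ejected read — decision latency is charged as pore idle time, the
conservative accounting. Gains are without/with ratios and are independent
of `n`. In the reference regime (`h̄/z̄ = 20`, `c = 0.1`, TPR = TNR = 0.9,
450 bp/s, 500 pores, 1.0 s signal, 0.8 s decision, 0.5 s eject) the model
gives a 7.7× base-pair and 7.1× time gain.

A Monte-Carlo simulator with exponential read lengths (mean-matched) and
Bernoulli decisions checks the closed form; reads shorter than the decision
point still pay the full decision window, matching the closed form's
accounting (gains depend on the length means only). Standard errors come
from a 20-block jackknife.

## Numerical and scale choices

- Activations and parameters are float32; metrics and attributions are
  accumulated in float64.
- Argmax ties in prediction go to the lower class index; AUROC counts tied
  scores as 1/2 (Mann-Whitney convention).
- Metrics with an empty denominator (a class absent from the truth) are
  reported as NaN, never 0.
- The end-to-end recovery test uses 2000 reads per class, 3 epochs and
  batch size 8: batch 8 at learning rate 1e-3 was the most stable of the
  reduced-batch settings examined across seeds (batch 16 and 4 were
  noticeably noisier), and the corpus trains in about a minute on one core.
- Monte-Carlo cross-checks use 1–2·10⁵ simulated reads, giving standard
  errors around 1% of the gain values.

## Known limitations

- Batch-norm statistics make training-mode outputs batch-dependent;
  evaluation mode is deterministic and is used for all reported inference.
- The numpy training loop is single-device and unoptimized for large
  corpora; the reference recipe (batch 1000, 6 epochs, millions of reads)
  is expressible but not fast here.
- VBZ-compressed FAST5 and POD5 are unsupported (gzip/uncompressed HDF5
  only); live streaming from a sequencer is out of scope.
- The throughput model ignores pore death, recapture failure, and channel
  multiplexing; it is an expectation model, not a scheduler.
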