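# Methods

This note documents the models, conventions, and numerical choices behind
`hdseizure`, and what the synthetic experiments do and do not establish.

## Signal model and windowing

A recording is an M × T voltage matrix at sampling rate `fs` (nominally
512 Hz, 36–100 electrodes) with half-open ictal annotations
`[onset, offset)` in seconds. No filtering, re-referencing, or artifact
rejection is applied: the LBP front end consumes raw samples.

LBP codes are emitted with stride 1, so the code stream has T − 6
entries. Analysis windows tile the *code stream* in blocks of
`round(window_s · fs)` codes; the trailing partial window is dropped
rather than zero-padded (padding would bias the temporal majority). A
window's label is decided by its **center time**: ictal iff the center
lies inside an annotation. Center membership avoids double-labelling
windows straddling an onset, and the half-open intervals resolve exact
boundary ties toward the later interval. Window timestamps ignore the
6-sample LBP look-back (< 12 ms at 512 Hz).

Post-ictal windows (centers at or after the last annotation offset) are
excluded from the inter-ictal class by default, both in training and in
the specificity denominator, because the training protocol pairs each
seizure with its *pre-ictal* inter-ictal period and post-ictal activity
is physiologically ambiguous. This is configurable
(`exclude_postictal=False`).

## LBP conventions

Bit i (i = 1..6) of a code is `1{s[j+i] > s[j+i−1]}`; equality gives 0.
Bits are packed MSB-first — the earliest comparison is the most
significant bit. Any consistent order is equivalent up to a relabelling
of item-memory rows; the convention is recorded in saved model metadata
so serialized models are unambiguous. The encoder is a bijection from
the 2⁶ comparison outcomes onto [0, 63], and is exactly invariant to
additive offsets and positive rescaling.

## Hyperdimensional encoding

Item memories are drawn as (64 + M) × D standard-normal matrices from a
seeded generator, then binarized by sign (> 0 → 1). Binarization is
needed because binding is bit-wise XOR; thresholding a N(0, 1) draw at 0
gives i.i.d. Bernoulli(0.5) bits, which preserves the
quasi-orthogonality property that motivates the Gaussian construction
(pairwise cosine similarity of the raw Gaussian rows has SD ≈ 1/√D, and
the binarized rows concentrate at normalized Hamming distance 0.5). The
threshold (0) and convention (> 0 → 1) are fixed constants.

Both bundling stages use a **strict** majority (`sum > half`), so exact
ties — possible when M or the per-window step count is even — resolve to
0. Electrode vectors are per patient (M rows), making models
patient-specific. The windowed encoder precomputes the M × 64 × D
XOR-bound bank once per recording and processes time steps in chunks of
at most 2²⁵ gathered elements, which bounds peak memory near 32 MB
regardless of D and M.

## Classifier

Training is plain counting (class frequencies for priors, per-dimension
conditional frequencies for `p_{k,c}`), with **no smoothing**: the
LUT's additive offset guards empirical zeros at inference time, and the
float path applies the same guard (`p ← p + 0.001` when `p ≤ 0.99`) so
the two paths are comparable. Ties in the arg-max/arg-min resolve to the
inter-ictal class — the conservative direction with respect to false
alarms.

### LUT construction

Probabilities are discretized into 100 bins of width 0.01 (bin b covers
[(b−1)/100, b/100]; p = 1 lands in bin 100). The integer cost of a bin
at or below 0.99 is

    cost(b) = round(−128 · ln((b−1)/100 + 0.001)),

rounded half away from zero; bins above 0.99 clamp to cost 1. The
−128 = −2⁷ scale trades quantization fineness against integer width: the
largest cost is 884 < 2¹⁰, so a D = 10,000 accumulation stays below 2²⁴
and never approaches 32-bit overflow. The offset 0.001 both guards
ln(0) and makes the table match its reference values at their stated
precision (one interior entry differs by 1 count, consistent
with a rounding-mode difference; the constants are module-level and
visible). The default decision sum includes both the active
(`x_k = 1`) and inactive (`x_k = 0`) Bernoulli terms, mirroring the
exact log-posterior; an `active_only` switch restricts it to active
dimensions for hardware implementations that only accumulate set bits.
Empirically the LUT path reproduces ≥ 99% of float decisions, with
disagreements confined to log-posterior margins below 0.1 (the median
margin is ~30× larger).

### Voting

The vote at segment t is the label sum over the trailing
`k = round(vote_window_s / window_s)` segments (fewer during the initial
ramp), sliding one segment at a time; sliding rather than disjoint 5 s
blocks is what allows sub-second latency resolution. The default
threshold `t_p = k // 2` (5 at 0.5 s segments, 10 at 0.25 s) is a
starting point; `t_p` is genuinely patient-dependent and exposed
everywhere. Latency is floored at 0 and alarms before the onset segment
are counted as false alarms only.

## Evaluation protocol

Folds are leave-one-seizure-out: each fold trains on TrS recordings
(ictal plus their own inter-ictal windows) and tests on the rest.
One-shot (TrS = 1) with K = N folds trains on each seizure in turn;
few-shot folds draw TrS-subsets without replacement from a seeded
shuffle of all combinations. Sensitivity, specificity, and accuracy are
**window-level**, computed on raw pre-vote predictions; latency uses the
voted output. This split mirrors reporting sub-window latencies next to
window-level classification rates.

## Storage model

The storage report itemises a fixed-point implementation at the
reference design's bit widths: 16-bit ADC samples × 7 points × M electrodes; 6 one-bit LBP
comparison registers per electrode; the 64 × D code bank and M × D
electrode bank; 7-bit spatial-sum counters, 5-bit temporal counters and
6-bit histogram bins per dimension; 7-bit per-dimension costs plus
10-bit LUT entries; 10.5 bytes of miscellaneous state. Bytes are bits/8
throughout. The model reproduces the reference arithmetic exactly
rather than re-deriving an "optimal" layout; with M = 100, D = 1000 the
total is 25,235.5 bytes.

## Synthetic data

The generator emulates the structure of short-term clinical iEEG: per
recording, 180 s pre-ictal + one ictal period (uniform 10–60 s) + 180 s
post-ictal, 36 channels at 512 Hz by default. Background is unit-RMS
pink (1/f) noise with per-channel log-normal gains; the seizure is an
additive sinusoid at 3–8 Hz — amplitude `r ×` the channel's background
RMS (default r = 4), per-channel random phase, 1 s cosine ramps — on a
random 80% of channels. A slow, large oscillation lengthens monotone
sample runs, which is precisely the statistic the LBP front end
measures, so the surrogate exercises the real discriminative pathway
without claiming physiological realism.

Patient-level properties (channel gains, the affected-channel subset,
each channel's burst frequency) derive from the master seed and are
shared by all recordings of a surrogate patient; per-recording seeds
drive only the noise, burst phases, and ictal duration. This mirrors the
premise of one-shot learning — seizures of one patient share a
morphology — and is what makes cross-seizure generalization a meaningful
test. What passing synthetic tests does **not** show: robustness to
artifacts, evolving seizure morphologies, spatial propagation,
inter-patient transfer, or class imbalance as it occurs in long-term
recordings.

## Problem sizes used in the test suite

The end-to-end checks run the full pipeline at reduced recording lengths
(60 s pre/post for the recovery check, 40 s for the effect-size sweep;
2 recordings per seed) with all statistical generator parameters at
their defaults; sensitivity/specificity/latency are averaged over 10
seeds (recovery) or 5 seeds per amplitude ratio (monotonicity). The
monotonicity assertion allows 3σ paired sampling noise because r = 0 and
r = 1 share the no-signal floor, where exact ordering of two equal means
is a coin flip at any sample size.

## Known limitations

- Only binary (ictal / inter-ictal) classification; no multiclass or
  probability calibration.
- One ictal annotation per recording in the detection stage (the
  short-term recording layout); multi-seizure recordings would need a
  per-event latency loop.
- `t_p` is not auto-tuned; the half-window default is reasonable on the
  surrogate data but real deployments tune it per patient.
- The float path is "exact" only up to the shared zero guard; with the
  guard removed, empirical zero probabilities would produce −∞
  log-posteriors.
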