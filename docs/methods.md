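# Methods

## Model

The classifier is a binarized 1-D CNN over one heartbeat: a 180-sample,
signed 8-bit window with the R peak at sample 60. Each *unit* is a valid
(stride-1, unpadded) convolution or a fully connected layer with ±1
weights, an optional non-overlapping max-pool, and a batch-normalization
stage. During inference the batch norm of every hidden unit is folded into
an integer threshold on the raw convolution accumulator:

    sign(γ·(a − μ)/σ + β) = +1   ⇔   a ≥ ⌈μ − βσ/γ⌉          (γ > 0)
                                     a ≤ ⌊μ − βσ/γ⌋          (γ < 0)

with a constant ±1 channel when γ = 0 (sign(β), and sign(0) = +1, the
usual BNN convention). The ceiling/floor directions are what make the
integer comparison *exactly* equivalent to the real-valued sign for every
integer accumulator; this is property-tested by exhaustive sweeps over
a ∈ [−10⁴, 10⁴] under randomized (γ, β, μ, σ), not assumed. The max-pool
acts on raw accumulators *before* binarization (unit order: layer → pool →
batch norm), so it needs no tie rule. The last unit keeps its real-valued
per-class affine γᵢ(aᵢ−μᵢ)/σᵢ+βᵢ and the predicted class is its arg-max
(ties → lowest index); softmax is skipped because it is monotone.

The default architecture is fixed: conv 128@(1,180) → conv 64@(128,174) →
conv 128@(64,168) → conv 64@(128,162)+pool → fc 50@4992. The kernel size
(7) and pool window (2) are not free parameters — they are the only values
consistent with the published feature-map chain (180−174 = 6 ⇒ K = 7;
(162−6)/78 = 2) — and `default_ecg_id_bnet` asserts the full chain.

## Packed datapath

Weights are reordered from the conventional (x, c) to (c, x): flat index
x·Cin + c, channels fastest, packed 64 per 64-bit word with bit 0 the
lowest channel and +1 ↔ bit 1. Hidden feature maps use the same layout
(an (L, C/64) word array). Because every hidden channel count is a
multiple of 64, a conv filter's word sequence coincides with the word
sequence of its input window, and the fc unit's with the flattened map —
each hidden dot product is then `2·popcount(XNOR) − n` per word. The
first unit's input is multi-bit (signed 8-bit), so it runs a plain signed
add/subtract path against the unpacked ±1 weights; its 7 weights occupy
one padded word (`valid_lanes` = 7), the only packing consistent with a
16-byte filter. The two feature-map buffers alternate producer/consumer
roles every unit (ping-pong); an assertion forbids a unit from writing the
buffer it reads. The packed engine's contract with the reference engine is
bit-exactness — identical integer accumulator traces in every unit, not
merely the same class — and the test suite enforces it over 100+
randomized architectures plus the full default network.

Bit order within a word and the little-endian serialization are fixed,
documented conventions covered by round-trip tests. Word width 64 is not
configurable.

## Parameter file (EIBN v1)

Little-endian: magic `EIBN`, version u16, n_units u16, kernel_size u16,
n_classes u16; per unit a 16-byte record (type u8, has_pool u8, position
u16, in_channels u32, out_channels u32, out_length u32); then per filter
the weight words followed by an i64 threshold plus a u8 direction tag, or,
for the last unit, the per-class (γ, β, μ, σ) as 32-bit reals. Reading is
the exact inverse of writing, with offset-carrying errors for bad
magic/version/truncation. Two accounting conventions are deliberate:

- The *accounted* payload counts 8·(words per filter) + 8 bytes per filter
  — one 64-bit threshold block — which is the hardware memory model's
  convention; direction tags and headers are format metadata and excluded.
  This makes the serialized payload equal `memory_report`'s 57,200-byte
  total exactly (cross-checked in tests).
- The last unit's 200-byte output and 632-byte neurons are accounted at 4
  bytes per class score and 8 bytes per threshold block, while the engine
  computes scores in double precision; accounting and arithmetic are
  decoupled, and the arg-max is unaffected.

Format v1 fixes the pool window at 2 (the only pooling mode in this
architecture family); input lengths are reconstructed from out_length,
kernel and pooling, so arbitrary pool windows would need a format rev.

## Hardware co-model

`memory_report` computes per-unit feature-map bytes (binary maps:
C·L/8; the 8-bit input: 180 B; the score vector: 4·n_classes B) and
parameter bytes (n_filters × filter bytes). `bram_plan` sizes the
parameters RAM by ⌈bytes·8/36,864⌉ 36 kb BRAMs (13 for the default net)
and gives the input, output and per-PE weight RAMs one BRAM each in the
512×72 configuration (64 of 72 bits used), so a 50-BRAM device supports at
most 50 − 15 = 35 PEs. `schedule` assigns ⌈n_filters/N_PEs⌉ sessions per
unit — each PE computes one output feature map per session — and exposes
the even/odd session parity that drives the overlapped (ping-pong)
parameter download, which is also why each PE's weight buffer must hold
two filters (2 × 632 = 1,264 B). The default network needs 14 sessions at
32 PEs and still 14 at 35, which is the rationale for building 32.
`sram_brams` models the host SoC's byte-addressable SRAM (4k×9 BRAMs,
one byte per word): 128 kB → 32 BRAMs. `latency_budget` encodes the
real-time requirement beats·60/bpm (3 beats at 150 bpm = 1.2 s).
Firmware/stack sizes and anything timing- or netlist-related (LUT/FF
counts, cycle counts, wall-clock speedups) are outside the model's scope:
they are properties of a synthesis toolchain, not of this arithmetic.

## Synthetic data

Each subject is a PQRST template: five Gaussian bumps with amplitudes,
centers and widths drawn once per subject from fixed uniform ranges
(R dominant at 0.9–1.4 a.u.; centers as fractions of the RR interval), and
a base heart rate in 55–90 bpm. Recordings (default 200 Hz) repeat the
template at RR intervals with multiplicative Gaussian jitter (default
relative s.d. 0.04), plus white noise (default s.d. 0.02 a.u.) and a
0.25 Hz baseline-wander sinusoid (amplitude 0.05 a.u.). These defaults
were chosen once as plausible desk-scale stand-ins for clean single-lead
recordings and are not tuned. Segmentation cuts one window per R peak
(ground-truth positions, or a threshold-over-moving-average detector for
detector-path tests), drops edge-truncated windows, max-abs normalizes and
quantizes to int8 (peak → 127, round-half-even), which bounds the
dequantization error at half a step per sample.

What the generator does *not* emulate: arrhythmia, electrode artefacts,
drift between sessions, inter-subject similarity structure of real
populations. Passing tests therefore demonstrate the correctness of the
*engines and accounting*, and that the training/identification pipeline is
functional — not any clinical identification accuracy; the published
accuracies on real datasets are external-data results and are explicitly
not reproduced here.

`random_params` draws fair-coin ±1 weights and sets each hidden filter's
threshold at the median accumulator observed on 16 random 8-bit probe
inputs propagated through the already-parameterized prefix. This keeps
every hidden channel's +1 frequency near ½ (tested to stay in [0.2, 0.8]),
so random networks neither saturate nor collapse — important for the
equivalence sweeps to exercise non-trivial activity.

## Training

The straight-through-estimator trainer exists to demonstrate end-to-end
identification; it is a compact numpy implementation, not a replica of any
published recipe. Latent real weights are binarized with sign in the
forward pass; gradients pass through where the latent value (or, for
activations, the normalized accumulator) lies in [−1, 1] and are clipped
outside; latent weights are clipped to [−1, 1] after each Adam step
(lr 0.01, default batch 32). Batch norm uses batch statistics in training
and running statistics (momentum 0.9, ε = 10⁻⁵) for folding. Training
accumulators are exactly integer-valued (8-bit or ±1 inputs against ±1
weights), so the folded thresholds transfer to the integer engines without
approximation. The end-to-end check trains a two-unit network
(conv 64, kernel 7, pool 2 → fc) on 5 synthetic subjects × 50 beats
(35 train / 15 held out per subject, 30 epochs, ~20 s on one CPU) and
scores held-out triples by 3-beat majority vote (ties → highest mean
score); it reliably reaches 100% against a 20% chance level, reflecting
how separable the synthetic morphologies are.

## Numerical and degenerate-input choices

- All hidden arithmetic is int64; no floating point before the last affine.
- sign(0) = +1 everywhere (binarization, weight binarization).
- Arg-max ties break to the lowest class index; majority-vote ties break
  to the highest mean score.
- `infer_shapes` raises rather than truncating when a pooled length does
  not divide, and rejects hidden channel counts that are not multiples of
  64 (an `allow_unpacked` override exists for reference-engine-only
  experiments).
- An all-zero window quantizes to all zeros; records shorter than one
  window segment to an empty beat list; an empty network serializes to a
  header-only file.

## Problem sizes

The test suite checks engine equivalence on compact randomized
architectures (1–3 conv units, 64/128 channels, 180-sample input) plus the
full default network, and the training check uses the two-unit network
above; these sizes give sub-minute suites while exercising every datapath
branch (padded first-unit word, pooling, multi-word filters, fc
flattening).
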