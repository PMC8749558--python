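# ecgbnet

A software re-implementation of a binarized 1-D convolutional network
(BCNN) for ECG biometric identification, together with an analytical model
of the FPGA accelerator that runs it.

## The problem

"Invisible" ECG sensors — electrodes embedded in everyday objects such as
toilet seats or steering wheels — need to decide *whose* heartbeat they are
seeing, on the device, within the time a few beats take to arrive (3 beats
at 150 bpm ⇒ a 1.2 s budget). The classifier is a five-unit binarized CNN
over a single 180-sample, 8-bit beat window: four convolutional units
(kernel 7, valid convolution) and one fully connected unit, with feature
maps

```
(1,180) → (128,174) → (64,168) → (128,162) → (64,78) → 50 classes
```

where each unit is conv/fc → optional max-pool → batch-norm → sign.
Weights and hidden activations are ±1, so a hidden dot product of two
64-channel blocks is one XNOR plus a popcount:

```
a = Σᵢ xᵢ·wᵢ  =  2·popcount(XNOR(x, w)) − n        (xᵢ, wᵢ ∈ {−1, +1})
```

and the batch-norm-then-sign step folds into a single integer comparison
`a ≥ τ` with `τ = ⌈μ − βσ/γ⌉` (γ > 0; the comparator flips for γ < 0).
Classification is the arg-max of the last unit's batch-normalized outputs —
softmax is monotone, so the probability transform is skipped
("pseudo-softmax").

## What the package provides

- **`ecgbnet.model_spec`** — the architecture description and all shape
  arithmetic (`default_ecg_id_bnet`, `infer_shapes`), JSON-serializable.
- **`ecgbnet.reference_engine`** — a plain-integer oracle forward pass:
  `conv1d_valid`, `maxpool`, `fold_bn`, `pseudo_softmax_argmax`,
  `reference_forward`.
- **`ecgbnet.packed_engine`** — the bit-exact accelerated datapath:
  channel-major `(c,x)` 64-bit weight/feature-map packing, `xnor_dot`,
  ping-pong feature-map buffers, and the "EIBN v1" binary parameter file.
  `packed_forward` reproduces the reference engine's accumulators exactly.
- **`ecgbnet.hw_model`** — the accelerator's memory, block-RAM and session
  accounting as executable code: `memory_report`, `schedule`, `bram_plan`,
  `sram_brams`, `latency_budget`.
- **`ecgbnet.synthetic`** — multi-subject synthetic ECG (Gaussian PQRST
  templates), R-peak segmentation into quantized 180-sample beats, random
  balanced network parameters, 3-beat majority-vote `identify`.
- **`ecgbnet.train`** — a numpy straight-through-estimator trainer that
  produces deploy-ready folded parameters.
- **`ecgbnet.cli`** — the `ecgbnet` command: `synth`, `pack`, `infer`,
  `memreport`, `schedule`, `brams`, `selftest`.

## Worked example

```sh
$ ecgbnet memreport
Unit                   In fmap (B) Out fmap (B)  Params (B)  Filter (B)
-----------------------------------------------------------------------
Conv unit 1                    180        2,784       2,048          16
Conv unit 2                  2,784        1,344       7,680         120
Conv unit 3                  1,344        2,592       8,192          64
Conv unit 4                  2,592          624       7,680         120
FC unit 5                      624          200      31,600         632
-----------------------------------------------------------------------
Total params                                         57,200         632
Max fmap: 2,784 B  (two ping-pong buffers of at least this size)
```

The packed network needs 57,200 bytes of parameters and two feature-map
buffers of at least 2,784 bytes. With 36 kb block RAMs that is
⌈57,200·8/36,864⌉ = 13 BRAMs for the parameters; on a 50-BRAM part, after
13 + 2 fixed RAMs, at most 35 processing elements (PEs) fit — and 32 PEs
already reach the minimum total of 14 execution sessions:

```sh
$ ecgbnet schedule --pes 32
N_PEs = 32
  unit 1: 4 session(s)
  unit 2: 2 session(s)
  unit 3: 4 session(s)
  unit 4: 2 session(s)
  unit 5: 2 session(s)
  total: 14 sessions
  PE weight buffer >= 1,264 B (two filters, ping-pong download)
```

End-to-end, with synthetic subjects:

```sh
$ ecgbnet synth --seed 1 --subjects 3 --out beats.csv   # labelled beats
$ ecgbnet pack  --seed 1 --out net.eibn                 # 58,076-byte file
$ ecgbnet infer --engine packed --check --params net.eibn --beats beats.csv
infer: cross-check PASS (101/101 agree)
```

`--check` runs every beat through both engines and verifies the classes
and scores agree; `ecgbnet selftest` additionally re-derives the accounting
figures above and the bit-exact trace equivalence (13/13 targets).

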