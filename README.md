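# myograsp

Surface electromyography (sEMG) can drive an assistive hand exoskeleton for
people with cervical spinal cord injury (SCI): three electrodes over the
finger flexors (FDS), finger extensors (ED) and the thumb group (FPB/APB)
carry enough information to select among a small set of functional hand
poses. The hard part is not classifying a single sample — it is turning a
noisy per-sample classifier stream into pose commands that are safe to
execute on a robot physically coupled to a hand.

`myograsp` implements that full pipeline in pure Python, together with a
seeded synthetic sEMG generator so every stage is testable without hardware
or human recordings:

1. **Synthetic sEMG** (`myograsp.simulate`) — amplitude-modulated,
   band-limited (20–450 Hz) Gaussian carriers at 2 kHz over three channels,
   driven by a per-class activation table (fraction of MVIC), slow
   multiplicative jitter, inter-channel crosstalk and sensor noise; plus an
   SCI severity model that attenuates activations and destroys electrode
   selectivity.
2. **Linear envelope** (`myograsp.preprocess`) — offset removal against the
   relaxed state, full-wave rectification, a causal 3rd-order Butterworth
   low-pass at 4 Hz (step delay ≈ 85–100 ms at 2 kHz), and normalization by
   each channel's maximum voluntary isometric contraction (MVIC), measured
   as the 95th percentile of the calibration envelope.
3. **Pose classifier** (`myograsp.classifier`) — a two-layer feed-forward
   network (sigmoid hidden layer, softmax output) mapping each 3-vector
   envelope sample x(t) to one of five classes
   {R, TVG, LP, EG, E} = {relaxation, transverse volar grip, lateral pinch,
   extension grip, extension}, trained by Møller's scaled conjugate
   gradient (SCG) on cross-entropy:
   p(c | x) = softmax(W₂ σ(W₁x + b₁) + b₂)_c.
4. **Probabilistic pose controller** (`myograsp.controller`) — a sliding
   window of the last W = 100 classifications (0.05 s at 2 kHz); the
   commanded pose switches to class c only when its vote count reaches
   ⌈θW⌉ (threshold θ subject-specific, 0.8 or 0.6 in practice), with two
   safety rules: a winning R *holds* the current pose (relax-hold), and a
   grasp→grasp switch is refused unless the hand passes through the open
   extension pose E (extension gate).
5. **Evaluation** (`myograsp.evaluation`) — cue-referenced detection
   delays, involuntary-switch counts with a 2 s post-cue grace window, the
   three-mode ablation (RAW / MAJORITY / FULL), and Sollerman hand function
   test (SHFT) score aggregation (20 subtests × 0–4 points, maximum 80).

## Worked example

The `demo` subcommand runs the whole study end to end on synthetic data:
MVIC calibration, a three-trial five-pose training session (10 s task /
10 s rest, middle 6 s retained), a 70/30 split, SCG training, then the
dynamic six-object grasping scenario (cup, screwdriver, coin, key, pen,
envelope; 10 s grasp / 5 s extension / 5 s relax) classified per sample and
driven through all three controller modes:

```sh
$ myograsp demo --out demo_run --seed 11
held-out accuracy: 100.00%
  raw       events=  20 involuntary=0
  majority  events=  16 involuntary=0
  full      events=  12 involuntary=0
artifacts in demo_run
```

Reading the output: the classifier separates the five synthetic activation
patterns perfectly on held-out samples (122,400 of the 408,000 trimmed
samples), and the FULL controller issues exactly the 12 cued change events
(six grasp onsets, six returns to extension) with zero involuntary
switches. The per-cue detection delays in `demo_run/report.json` are
0.23–0.39 s — the sum of the envelope-filter lag (~0.085 s), the activation
ramp, and the vote latency ⌈0.8·100⌉/2000 = 0.04 s. With
`--severity 0.8` the same command emulates a severe SCI subject: weak,
poorly separated activations and visibly degraded grasp-class accuracy.

Each stage is also available separately (`simulate`, `preprocess`, `train`,
`classify`, `control`, `evaluate`, `shft`), reading and writing plain CSV
and JSON, and as library functions.

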