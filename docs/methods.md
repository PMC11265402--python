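# Methods

This note documents the models, numerical choices and open design
decisions behind `myograsp`, and what the synthetic data can and cannot
establish about behavior on real recordings.

## Synthetic sEMG model

Raw sEMG on channel k at time t is generated as

    raw(t,k) = b(k) + A(t,k)·c(t,k) + ε(t,k)

where `c` is a zero-mean, empirically unit-variance carrier obtained by
band-passing white Gaussian noise to 20–450 Hz (the usual surface-EMG
bandwidth; only the rectified envelope matters downstream, so no
motor-unit action-potential structure is modeled), `b` is a constant
per-channel baseline offset (default 0.02 signal units), and `ε` is white
sensor noise (default SD 0.01). The modulation amplitude is

    A(t,k) = MVIC(k) · [X μ(class(t))]ₖ · (1 + j(t,k)), floored at 0,

with μ the [class × channel] activation table (fractions of MVIC), X the
row-stochastic crosstalk matrix (identity by default), and `j` a slow
(≤ 1 Hz low-passed, SD 0.1) multiplicative jitter reproducing within-class
envelope variability. At class-block boundaries A ramps linearly over
0.3 s, since muscle state does not change instantaneously; ground-truth
labels carry the upcoming block's class through the ramp, consistent with
the 2 s trimming that later discards those samples. Identical (labels,
profile, MVIC, seed) produce bit-identical recordings; all draws come from
one `numpy` generator seeded per call.

Default healthy activation table for (FDS, ED, FPB_APB), chosen as a
plausible qualitative pattern — flexor-dominant volar grip, thumb-dominant
pinch, mixed extension grip, extensor-dominant open hand, near-silent
rest — not as measured values (no quantitative amplitude statistics exist
to fit against):

| class | FDS | ED | FPB_APB |
|-------|-----|----|---------|
| R    | 0.02 | 0.02 | 0.02 |
| TVG  | 0.60 | 0.10 | 0.30 |
| LP   | 0.30 | 0.10 | 0.70 |
| EG   | 0.20 | 0.40 | 0.40 |
| E    | 0.05 | 0.70 | 0.10 |

**SCI severity model.** `degrade_for_sci(profile, s)` scales all non-rest
activations by (1 − 0.8·s) and blends the crosstalk matrix toward uniform
mixing, X(s) = (1 − s)·X + s·U. The endpoint is meaningful: severity 1
means activations at 20% of their healthy fraction of MVIC *and* complete
loss of electrode selectivity. Attenuation alone cannot degrade a
scale-invariant classifier, so selectivity loss is the operative
mechanism: at severity 0.8, grasp-class accuracies fall to roughly 82–85%
while relaxation and extension stay near-perfect — the same confusion
structure reported for severely affected users, where extension remains
the most detectable pose. Overall five-class accuracy at severity 0.8 is
~95% (buoyed by R and E) versus 100% healthy. Sensor noise is unchanged by
severity. This one-parameter family was fixed once; it emulates weak,
poorly selective recordings, not any individual subject.

**What the generator does not emulate:** electrode shift and donning
variability, fatigue and spasticity dynamics, motion artifacts, power-line
interference, non-Gaussian MUAP statistics at low force, and
subject-to-subject anatomical variation. Passing tests therefore
demonstrate the correctness and robustness of the *pipeline mechanics*
(envelope timing, training behavior, vote/gate logic, latencies), not
field accuracy on human data — the reported human accuracies are not
reproducible without the original recordings, and no attempt is made to
match them numerically.

## Envelope chain

Offset removal subtracts the per-channel mean of the raw signal over
relaxation-labeled samples (the operationalization of "relative to the
relaxed state"); an explicit baseline can be supplied when no rest segment
exists. Rectification is |x|. The envelope filter is a causal single-pass
3rd-order Butterworth low-pass at 4 Hz, designed digitally at the
recording rate with unit DC gain and zero initial state; filter state can
be carried across chunks so streamed and batch processing agree
bit-for-bit. Causal filtering is the deployed semantics — the ~100 ms lag
is real and part of the control latency; a zero-phase option exists for
offline inspection only. The step-response 50% crossing at 2 kHz measures
85 ms; "delay" is operationalized as this 50% crossing since the lag of a
3rd-order IIR is not a single number. Transient undershoot after
rectification is floored at 0 before normalization so the envelope stays
interpretable as an activation magnitude.

MVIC is the 95th percentile of the calibration envelope pooled over each
channel's maximal-effort segments (≥ 1 s each) — a percentile rather than
the maximum for robustness to spikes. Normalized values above 1 are
preserved: effort can legitimately exceed the calibration percentile.
Note the envelope of a Gaussian carrier of amplitude a plateaus near
a·√(2/π); normalization is self-consistent because calibration and task
envelopes scale identically.

## Classifier and SCG

The network is intentionally minimal: 3 inputs → H sigmoid units → 5
softmax outputs, H = 10 by default (the input is 3-dimensional and the
class geometry nearly conical about the origin; larger H buys nothing).
Instantaneous envelope amplitudes are the only features — no windows or
spectral features — and classification runs at every envelope sample.

Training minimizes mean cross-entropy with Møller's scaled conjugate
gradient: curvature along the search direction from a one-sided gradient
difference (σ = 1e-4), kept positive by a Levenberg–Marquardt scale λ
(initial 1e-6, raised on failed steps, lowered when the quadratic model
fits), direction restart every |θ| iterations, termination at gradient
norm < 1e-6 or 500 iterations. Weights initialize uniformly in
[−0.5, 0.5] from a seed, so training is deterministic. The loss at
accepted steps is non-increasing by construction and asserted in tests.

Dataset assembly keeps, within every contiguous same-label block, only the
samples more than 2 s from either edge (so a 10 s task contributes its
middle 6 s); rest blocks are trimmed identically and contribute R samples.
Blocks are recovered by run-length segmentation of the label stream, so a
cued rest task adjacent to the protocol's rest period forms one block.
The 70/30 split is a seeded uniform sample-level split with
round(0.7·n) training samples. For speed, the pipeline fits SCG on a
seeded uniform subsample of the training split (40,000 samples by
default) — i.i.d. subsampling of an i.i.d. split — while accuracy is
always evaluated on the complete held-out split (~122,000 samples at the
default conditions). Argmax ties resolve to the fixed class order
R < TVG < LP < EG < E, which the controller tests rely on.

## Controller

The vote buffer holds the last W = round(0.05 s × rate) predictions
(100 at 2 kHz). A class wins when its count reaches ⌈θW⌉; the ceiling-count
form is fixed (with a 1e-9 guard against float artifacts like
0.8×100 = 80.000…01) so the clean-switch latency is *exactly* ⌈θW⌉ samples
after a unanimous change — 40 ms at θ = 0.8, 30 ms at θ = 0.6. For
θ > 0.5 at most one winner can exist; for smaller thresholds the highest
count wins, ties to the lowest class code. The window slides and is
evaluated every sample by default (minimal latency and exact latency
semantics); block-wise evaluation every W samples is available behind
`evaluate_every` since the deployed cadence is not documented. No switch
occurs before the buffer first fills (the first W samples hold the initial
pose); the initial pose is E, matching an experiment that begins relaxed
with an open hand — R is never commandable in any mode. When the i.i.d.
per-sample error rate is below 1 − θ, no erroneous class can reach quota
(up to astronomically unlikely fluctuations at W = 100), which is the
designed robustness of the vote.

RAW mode (the ablation baseline) maps each prediction directly to a
command with R meaning "hold", so all three traces are comparable
command streams. The incremental ring-buffer implementation is
cross-checked exactly — commands and events — against a from-scratch
window recount at every sample.

The pose → joint-angle map for the 8 actuated DoFs (four thumb, two index,
two middle) is carried as passive configuration data with synthetic
placeholder angles; no trajectory generation is implemented.

## Evaluation

Detection delay is the time from a cue to the first sample whose command
equals the cued pose (unreached cues are reported missing, not as a
number). Involuntary switches are change events whose destination differs
from the currently cued intended pose, excluding a 2 s grace window after
each cue (mirroring the 2 s transition trimming). The six-object scenario
maps cup→TVG, screwdriver→EG, coin/key/pen→LP, envelope→EG — the named
objects' natural grips — with 10 s grasp / 5 s extension / 5 s relax and a
5 s relaxed lead-in. On clean synthetic streams the measured cue-to-command
delay decomposes, within tolerance, into filter 50%-delay + ⌈θW⌉/rate
(plus the activation ramp when enabled); the human reaction-time component
of real deployments is deliberately not modeled. SHFT aggregation is a
pure scoring utility (20 subtests, 0–4 each, maximum 80); no clinical
outcomes are simulated.

## Problem sizes and determinism

Default study conditions are used throughout: 2 kHz, three channels, five
classes, 10 s task / 10 s rest, three trials, 2 s trim, 70/30 split. The
test suite and the acceptance script run these at full scale (the
complete pipeline takes ~10 s; the acceptance script ~30 s on one CPU);
unit tests use shorter protocols at 500 Hz where the property under test
is rate-independent. All randomness flows from named seeds; reruns with
identical configuration produce byte-identical artifact files.

## Known limitations

* Healthy-condition accuracy saturates at 100% because the default
  activation patterns are widely separated relative to the modeled
  variability; real healthy subjects show ~97% with class-specific
  confusions the generator does not reproduce.
* The severity scale is a modeling device; it is not calibrated to
  clinical injury levels (C5–C7).
* The vote-robustness guarantee assumes independent errors; correlated
  error bursts (e.g. a sustained wrong envelope during a real transition)
  can and should switch the command — only the extension gate limits the
  damage in that case.
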