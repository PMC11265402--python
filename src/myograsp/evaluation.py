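"""Evaluation utilities: cue-referenced detection delays, involuntary
switch counts across controller modes, the six-object grasping scenario,
and Sollerman hand function test (SHFT) score aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import (
    ControlMode,
    ControllerConfig,
    PoseCommandStream,
    run_controller,
)
from .poses import CLASS_ORDER, N_CLASSES, PoseClass


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cued sequences
# ---------------------------------------------------------------------------

@dataclass
class CuedSequence:
    """Visual-cue timeline: (cue time in s, intended commanded pose).
    Between cues the intended command is the most recent cue's pose (a
    relax period keeps the previous command, mirroring relax-hold)."""

    cues: list[tuple[float, PoseClass]]
    initial_pose: PoseClass = PoseClass.E

    def __post_init__(self) -> None:
        times = [t for t, _ in self.cues]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise EvaluationError("cue times must be strictly increasing")
        self.cues = [(float(t), PoseClass(p)) for t, p in self.cues]

    def intended_at(self, time_s: float) -> PoseClass:
        pose = self.initial_pose
        for t, p in self.cues:
            if t <= time_s:
                pose = p
            else:
                break
        return pose

    def expand(self, n_samples: int, rate: float) -> np.ndarray:
        """Per-sample intended commanded pose."""
        out = np.full(n_samples, int(self.initial_pose), dtype=np.int8)
        for t, p in self.cues:
            i = int(round(t * rate))
            if i < n_samples:
                out[i:] = int(p)
        return out


def detection_delay(
    commands: PoseCommandStream, cues: CuedSequence
) -> list[float | None]:
    """Per-cue delay: first time at or after the cue at which the commanded
    pose equals the intended pose, minus the cue time.  ``None`` marks a
    cue whose pose is never reached before the next cue era ends."""
    rate = commands.classification_rate
    n = len(commands.commands)
    delays: list[float | None] = []
    for idx, (t_cue, pose) in enumerate(cues.cues):
        start = int(round(t_cue * rate))
        end = n
        if idx + 1 < len(cues.cues):
            end = min(n, int(round(cues.cues[idx + 1][0] * rate)))
        if start >= n:
            delays.append(None)
            continue
        hit = np.flatnonzero(commands.commands[start:end] == int(pose))
        delays.append(hit[0] / rate if len(hit) else None)
    return delays


def involuntary_switches(
    commands: PoseCommandStream,
    cues: CuedSequence,
    grace: float = 2.0,
) -> int:
    """Count command-change events whose destination differs from the
    currently cued intended pose.  Events within ``grace`` seconds after
    a cue are excluded: that window covers the legitimate (reaction +
    filter + vote) transition to the newly cued pose."""
    cue_times = np.array([t for t, _ in cues.cues])
    count = 0
    for ev in commands.events:
        recent = cue_times[(cue_times <= ev.time_s)]
        if len(recent) and ev.time_s - recent[-1] < grace:
            continue
        if ev.dst != cues.intended_at(ev.time_s):
            count += 1
    return count


# ---------------------------------------------------------------------------
# six-object grasping scenario
# ---------------------------------------------------------------------------

#: Objects of the dynamic grasping test and the pose used to hold each:
#: a cylinder/cup is a transverse volar grip, flat objects (screwdriver
#: handle presented flat, envelope) take the extension grip, and small
#: objects (coin, key, pen) the lateral pinch.
SIX_OBJECT_POSES: tuple[tuple[str, PoseClass], ...] = (
    ("cup", PoseClass.TVG),
    ("screwdriver", PoseClass.EG),
    ("coin", PoseClass.LP),
    ("key", PoseClass.LP),
    ("pen", PoseClass.LP),
    ("envelope", PoseClass.EG),
)


def six_object_scenario(
    grasp_duration: float = 10.0,
    extension_duration: float = 5.0,
    relax_duration: float = 5.0,
    lead_in: float = 5.0,
) -> tuple[CuedSequence, list[tuple[float, float, PoseClass]]]:
    """Cue timeline for the dynamic grasping test: starting relaxed, each
    object is grasped for 10 s, then extension for 5 s, then 5 s of
    relaxation before the next object.

    Returns the cued (commanded-pose) sequence and the ground-truth muscle
    state as (start, end, pose) intervals, where relax periods are R.
    """
    cues: list[tuple[float, PoseClass]] = []
    truth: list[tuple[float, float, PoseClass]] = []
    t = 0.0
    truth.append((t, t + lead_in, PoseClass.R))
    t += lead_in
    for _name, pose in SIX_OBJECT_POSES:
        cues.append((t, pose))
        truth.append((t, t + grasp_duration, pose))
        t += grasp_duration
        cues.append((t, PoseClass.E))
        truth.append((t, t + extension_duration, PoseClass.E))
        t += extension_duration
        truth.append((t, t + relax_duration, PoseClass.R))
        t += relax_duration
    return CuedSequence(cues), truth


def truth_label_stream(
    truth: list[tuple[float, float, PoseClass]], rate: float
) -> np.ndarray:
    """Per-sample ground-truth muscle-state labels for interval truth."""
    n = int(round(truth[-1][1] * rate))
    out = np.full(n, int(PoseClass.R), dtype=np.int8)
    for t0, t1, pose in truth:
        out[int(round(t0 * rate)):int(round(t1 * rate))] = int(pose)
    return out


def noisy_label_stream(
    truth_labels: np.ndarray, noise_rate: float, seed: int
) -> np.ndarray:
    """Corrupt a label stream with i.i.d. classification errors: each
    sample is independently replaced, with probability ``noise_rate``, by
    a uniformly random *other* class — the error model under which the
    vote is provably robust when noise_rate < 1 - threshold."""
    if not 0.0 <= noise_rate < 1.0:
        raise EvaluationError("noise_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(truth_labels, dtype=np.int8).copy()
    flip = rng.random(len(labels)) < noise_rate
    offsets = rng.integers(1, N_CLASSES, size=len(labels))
    labels[flip] = (labels[flip] + offsets[flip]) % N_CLASSES
    return labels


# ---------------------------------------------------------------------------
# mode comparison (ablation of the probabilistic approach)
# ---------------------------------------------------------------------------

@dataclass
class ModeComparison:
    """Per-mode outcome of the same predicted-label stream: command
    streams, change-event lists, involuntary-switch counts and per-cue
    detection delays.  The ordering RAW >= MAJORITY >= FULL in switch
    counts is the designed behavior but is measured, not assumed."""

    streams: dict[str, PoseCommandStream]
    involuntary: dict[str, int]
    delays: dict[str, list[float | None]]

    def summary(self) -> dict:
        return {
            mode: {
                "n_events": len(self.streams[mode].events),
                "involuntary_switches": self.involuntary[mode],
                "delays_s": self.delays[mode],
            }
            for mode in self.streams
        }


def compare_modes(
    predicted_labels: np.ndarray,
    cues: CuedSequence,
    config: ControllerConfig,
    grace: float = 2.0,
) -> ModeComparison:
    """Run the same label stream through RAW, MAJORITY and FULL modes of
    an otherwise identical controller configuration."""
    from dataclasses import replace

    streams, invol, delays = {}, {}, {}
    for mode in (ControlMode.RAW, ControlMode.MAJORITY, ControlMode.FULL):
        cmd = run_controller(predicted_labels, replace(config, mode=mode))
        streams[mode.value] = cmd
        invol[mode.value] = involuntary_switches(cmd, cues, grace=grace)
        delays[mode.value] = detection_delay(cmd, cues)
    return ModeComparison(streams=streams, involuntary=invol, delays=delays)


def plot_mode_comparison(comparison: ModeComparison, cues: CuedSequence,
                         path: str | None = None):
    """Three-trace commanded-pose comparison plot (RAW / MAJORITY / FULL).
    Imports matplotlib lazily; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    styles = {"raw": ("lightblue", "-"), "majority": ("violet", "-"),
              "full": ("darkblue", "--")}
    for mode, stream in comparison.streams.items():
        color, ls = styles.get(mode, ("gray", "-"))
        ax.step(stream.times, stream.commands, where="post", label=mode.upper(),
                color=color, linestyle=ls)
    for t, pose in cues.cues:
        ax.axvline(t, color="0.85", zorder=0)
    ax.set_yticks(range(N_CLASSES))
    ax.set_yticklabels([c.code for c in CLASS_ORDER])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("commanded pose")
    ax.legend(loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


# ---------------------------------------------------------------------------
# Sollerman hand function test scoring
# ---------------------------------------------------------------------------

N_SUBTESTS: int = 20
MAX_SUBTEST_SCORE: int = 4
#: Maximum attainable SHFT total (20 subtests scored 0-4).
SHFT_MAX_TOTAL: int = N_SUBTESTS * MAX_SUBTEST_SCORE


@dataclass
class ShftRecord:
    """One administration of the SHFT: 20 subtest scores, each 0-4."""

    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        scores = tuple(int(s) for s in self.scores)
        if len(scores) != N_SUBTESTS:
            raise EvaluationError(
                f"SHFT requires exactly {N_SUBTESTS} subtest scores, "
                f"got {len(scores)}"
            )
        if any(s < 0 or s > MAX_SUBTEST_SCORE for s in scores):
            raise EvaluationError(
                f"subtest scores must lie in 0..{MAX_SUBTEST_SCORE}"
            )
        self.scores = scores

    @property
    def total(self) -> int:
        return shft_total(self)


def shft_total(record: ShftRecord) -> int:
    """Total SHFT score: the sum of the 20 subtest scores (0-80)."""
    return sum(record.scores)
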