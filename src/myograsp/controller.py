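"""Probabilistic pose controller: majority-vote smoothing over a sliding
window of per-sample classifications, plus two safety rules.

The raw classifier stream is far too noisy to drive an exoskeleton.  The
controller keeps the last ``window_samples`` predicted labels (0.05 s =
100 samples at the 2 kHz classification rate) and switches the commanded
pose only when one class accumulates at least ceil(threshold * window)
votes.  Two rules harden this further:

* relax-hold — a winning relaxation (R) vote holds the current pose
  instead of releasing it, so the user can rest without dropping objects;
* extension gate — a switch between two different grasp poses is refused
  unless the hand is currently in the open extension pose, preventing
  in-hand pose flips during manipulation.

Three modes expose the ablation ladder: RAW (per-sample classifier output,
R mapped to hold), MAJORITY (voting + relax-hold), FULL (voting +
relax-hold + extension gate).
"""

from __future__ import annotations

import enum
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .poses import CLASS_ORDER, N_CLASSES, PoseClass, is_grasp


class ControllerError(ValueError):
    pass


class ControlMode(enum.Enum):
    RAW = "raw"
    MAJORITY = "majority"
    FULL = "full"


def window_samples_for(window_duration: float, classification_rate: float) -> int:
    """Number of classification samples in the decision window."""
    n = int(round(window_duration * classification_rate))
    if n < 1:
        raise ControllerError("decision window must contain at least one sample")
    return n


def vote_quota(threshold: float, window_samples: int) -> int:
    """Votes required to win: ceil(threshold * window), with an epsilon
    guard so e.g. 0.8 * 100 (= 80.00000000000001 in floats) stays 80."""
    return int(math.ceil(threshold * window_samples - 1e-9))


@dataclass(frozen=True)
class ControllerConfig:
    window_duration: float = 0.05          # s
    classification_rate: float = 2000.0    # Hz; one classification per envelope sample
    threshold: float = 0.8                 # subject-specific (0.8 and 0.6 in practice)
    mode: ControlMode = ControlMode.FULL
    initial_pose: PoseClass = PoseClass.E
    window_samples: int | None = None      # derived from duration x rate if None
    evaluate_every: int = 1                # 1 = slide by one sample; window for block-wise

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ControllerError("threshold must lie in (0, 1]")
        if self.initial_pose == PoseClass.R:
            raise ControllerError("relaxation can never be a commanded pose")
        if self.window_samples is None:
            object.__setattr__(
                self, "window_samples",
                window_samples_for(self.window_duration, self.classification_rate),
            )
        if self.window_samples < 1 or self.evaluate_every < 1:
            raise ControllerError("window_samples and evaluate_every must be >= 1")
        object.__setattr__(self, "mode", ControlMode(self.mode))
        object.__setattr__(self, "initial_pose", PoseClass(self.initial_pose))

    @property
    def quota(self) -> int:
        return vote_quota(self.threshold, self.window_samples)


@dataclass
class ControllerState:
    """Incremental voting state: ring buffer of recent predictions,
    per-class counts, and the current commanded pose (never R)."""

    config: ControllerConfig
    buffer: deque = field(init=False)
    counts: np.ndarray = field(init=False)
    command: int = field(init=False)
    samples_seen: int = 0

    def __post_init__(self) -> None:
        self.buffer = deque(maxlen=self.config.window_samples)
        self.counts = np.zeros(N_CLASSES, dtype=np.int64)
        self.command = int(self.config.initial_pose)

    @property
    def filled(self) -> bool:
        return len(self.buffer) == self.config.window_samples


@dataclass(frozen=True)
class ChangeEvent:
    sample: int
    time_s: float
    src: PoseClass
    dst: PoseClass


@dataclass
class PoseCommandStream:
    """Per-sample commanded pose plus the (piecewise-constant) change
    events, one per actual command change."""

    commands: np.ndarray                  # [n] int codes, never R
    classification_rate: float
    events: list[ChangeEvent] = field(default_factory=list)
    initial_pose: PoseClass = PoseClass.E

    def __post_init__(self) -> None:
        self.commands = np.asarray(self.commands, dtype=np.int8)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.commands)) / self.classification_rate


def _winner(counts: np.ndarray, quota: int) -> int | None:
    """Class meeting the vote quota; among several (possible only when
    threshold <= 0.5) the highest count wins, ties to the lowest class
    code.  None if no class qualifies."""
    eligible = np.flatnonzero(counts >= quota)
    if len(eligible) == 0:
        return None
    return int(eligible[np.argmax(counts[eligible])])


def _apply_vote(command: int, winner: int | None, mode: ControlMode) -> int:
    """Voting-mode transition rule shared by MAJORITY and FULL."""
    if winner is None or winner == command:
        return command
    if winner == int(PoseClass.R):          # relax-hold
        return command
    if mode is ControlMode.FULL and is_grasp(winner) and is_grasp(command):
        return command                      # extension gate: must pass through E
    return winner


def step(
    state: ControllerState, predicted: int | PoseClass, config: ControllerConfig
) -> tuple[ControllerState, PoseClass]:
    """Feed one classification into the controller; returns the (mutated)
    state and the commanded pose after this sample.

    No mode switches before the vote buffer has filled once (warm-up);
    with ``evaluate_every`` > 1 the vote is re-evaluated only every that
    many samples (block-wise operation), otherwise at every sample.
    """
    predicted = int(predicted)
    if not 0 <= predicted < N_CLASSES:
        raise ControllerError(f"predicted label {predicted} outside pose classes")
    if state.filled:
        state.counts[state.buffer[0]] -= 1
    state.buffer.append(predicted)
    state.counts[predicted] += 1
    state.samples_seen += 1

    if state.filled and (state.samples_seen % config.evaluate_every == 0
                         or config.evaluate_every == 1):
        if config.mode is ControlMode.RAW:
            if predicted != int(PoseClass.R):
                state.command = predicted
        else:
            state.command = _apply_vote(
                state.command, _winner(state.counts, config.quota), config.mode
            )
    return state, PoseClass(state.command)


def run_controller(
    predicted_labels: np.ndarray, config: ControllerConfig
) -> PoseCommandStream:
    """Fold :func:`step` over a predicted-label stream from the initial
    pose; deterministic, emits one ChangeEvent per command change."""
    predicted_labels = np.asarray(predicted_labels)
    if len(predicted_labels) == 0:
        raise ControllerError("label stream must be non-empty")
    state = ControllerState(config)
    commands = np.empty(len(predicted_labels), dtype=np.int8)
    events: list[ChangeEvent] = []
    prev = int(config.initial_pose)
    rate = config.classification_rate
    for t, lab in enumerate(predicted_labels):
        state, cmd = step(state, int(lab), config)
        commands[t] = int(cmd)
        if int(cmd) != prev:
            events.append(ChangeEvent(t, t / rate, PoseClass(prev), cmd))
            prev = int(cmd)
    return PoseCommandStream(
        commands=commands,
        classification_rate=rate,
        events=events,
        initial_pose=config.initial_pose,
    )


def recount_oracle(
    predicted_labels: np.ndarray, config: ControllerConfig
) -> PoseCommandStream:
    """Reference controller that re-counts the full window from scratch at
    every sample (no incremental buffer state), for cross-validation of
    the incremental implementation.  Must agree with
    :func:`run_controller` exactly, event for event."""
    labels = np.asarray(predicted_labels, dtype=np.int64)
    if len(labels) == 0:
        raise ControllerError("label stream must be non-empty")
    n = len(labels)
    w = config.window_samples
    quota = config.quota
    # cumulative per-class counts so window counts come from one subtraction
    onehot = np.zeros((n + 1, N_CLASSES), dtype=np.int64)
    onehot[np.arange(1, n + 1), labels] = 1
    cum = np.cumsum(onehot, axis=0)

    commands = np.empty(n, dtype=np.int8)
    events: list[ChangeEvent] = []
    command = int(config.initial_pose)
    prev = command
    for t in range(n):
        seen = t + 1
        if seen >= w and (seen % config.evaluate_every == 0
                          or config.evaluate_every == 1):
            if config.mode is ControlMode.RAW:
                if labels[t] != int(PoseClass.R):
                    command = int(labels[t])
            else:
                counts = cum[seen] - cum[seen - w]
                qualified = [c for c in range(N_CLASSES) if counts[c] >= quota]
                if qualified:
                    best = max(qualified, key=lambda c: (counts[c], -c))
                    if best != command and best != int(PoseClass.R):
                        both_grasp = is_grasp(best) and is_grasp(command)
                        if not (config.mode is ControlMode.FULL and both_grasp):
                            command = best
        commands[t] = command
        if command != prev:
            events.append(ChangeEvent(t, t / config.classification_rate,
                                      PoseClass(prev), PoseClass(command)))
            prev = command
    return PoseCommandStream(
        commands=commands,
        classification_rate=config.classification_rate,
        events=events,
        initial_pose=config.initial_pose,
    )


#: Passive configuration: commanded joint-angle targets (degrees) for each
#: commandable pose over the actuated DoFs — four thumb (CMC abd/add, CMC
#: flex, MCP flex, IP flex) and two each for index and middle (MCP, PIP).
#: Carried as data only; no trajectory generation happens here, and the
#: values are synthetic placeholders to be recalibrated per subject.
GRASP_POSE_MAP: dict[PoseClass, dict[str, float]] = {
    PoseClass.E: {
        "thumb_cmc_abd": 20.0, "thumb_cmc_flex": 0.0, "thumb_mcp_flex": 0.0,
        "thumb_ip_flex": 0.0, "index_mcp_flex": 0.0, "index_pip_flex": 0.0,
        "middle_mcp_flex": 0.0, "middle_pip_flex": 0.0,
    },
    PoseClass.TVG: {
        "thumb_cmc_abd": 45.0, "thumb_cmc_flex": 30.0, "thumb_mcp_flex": 30.0,
        "thumb_ip_flex": 20.0, "index_mcp_flex": 60.0, "index_pip_flex": 60.0,
        "middle_mcp_flex": 60.0, "middle_pip_flex": 60.0,
    },
    PoseClass.LP: {
        "thumb_cmc_abd": 10.0, "thumb_cmc_flex": 20.0, "thumb_mcp_flex": 30.0,
        "thumb_ip_flex": 30.0, "index_mcp_flex": 45.0, "index_pip_flex": 45.0,
        "middle_mcp_flex": 45.0, "middle_pip_flex": 45.0,
    },
    PoseClass.EG: {
        "thumb_cmc_abd": 30.0, "thumb_cmc_flex": 20.0, "thumb_mcp_flex": 10.0,
        "thumb_ip_flex": 10.0, "index_mcp_flex": 20.0, "index_pip_flex": 10.0,
        "middle_mcp_flex": 20.0, "middle_pip_flex": 10.0,
    },
}
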