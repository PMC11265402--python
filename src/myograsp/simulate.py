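"""Synthetic surface-EMG generator.

Produces seeded, labeled raw sEMG recordings with the statistical structure
the grasp-intent pipeline assumes: an amplitude-modulated band-limited
Gaussian carrier per channel, where the modulation level is set by a
per-class activation table (fraction of MVIC), slow multiplicative jitter,
inter-channel crosstalk, additive sensor noise and a constant baseline
offset.  A severity knob emulates the weaker, less selective activations
seen after cervical spinal cord injury.

Only the rectified low-passed envelope of the signal matters downstream,
so the carrier is modeled as 20-450 Hz filtered noise (the usual surface
EMG band) rather than as motor-unit action-potential trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .poses import CLASS_ORDER, N_CLASSES, PoseClass


class SimulationError(ValueError):
    """Invalid generator configuration or inputs."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition front-end: 2 kHz sampling, x1000 amplification, three
    bipolar channels over FDS, ED and the FPB/APB thumb group."""

    sampling_rate: float = 2000.0
    gain: float = 1000.0
    channel_names: tuple[str, ...] = ("FDS", "ED", "FPB_APB")

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SimulationError("sampling_rate must be positive")
        if len(self.channel_names) == 0:
            raise SimulationError("at least one channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SimulationError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


# Default per-class mean activation (fraction of MVIC), rows in the fixed
# class order R, TVG, LP, EG, E for channels (FDS, ED, FPB_APB): a
# flexor-dominant volar grip, thumb-dominant pinch, mixed extension grip,
# extensor-dominant open hand, and a near-silent rest state.
DEFAULT_MU = np.array(
    [
        [0.02, 0.02, 0.02],  # R
        [0.60, 0.10, 0.30],  # TVG
        [0.30, 0.10, 0.70],  # LP
        [0.20, 0.40, 0.40],  # EG
        [0.05, 0.70, 0.10],  # E
    ]
)


@dataclass(frozen=True)
class ActivationProfile:
    """Statistical shape of a subject's muscle activations.

    mu[c, k] is the mean activation of channel k during class c as a
    fraction of that channel's MVIC.  jitter_sd is the standard deviation
    of the slow (<= 1 Hz) multiplicative envelope perturbation.  crosstalk
    is a row-stochastic mixing matrix applied to the mu rows (identity =
    perfectly selective electrodes).  baseline_offset and sensor_noise_sd
    are in raw signal units.
    """

    mu: np.ndarray = field(default_factory=lambda: DEFAULT_MU.copy())
    jitter_sd: float = 0.1
    baseline_offset: np.ndarray = field(default_factory=lambda: np.full(3, 0.02))
    sensor_noise_sd: float = 0.01
    crosstalk: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(
            self, "baseline_offset", np.asarray(self.baseline_offset, dtype=float)
        )
        ct = np.asarray(self.crosstalk, dtype=float)
        object.__setattr__(self, "crosstalk", ct)
        if mu.shape[0] != N_CLASSES:
            raise SimulationError(f"mu must have {N_CLASSES} class rows")
        if np.any(mu < 0) or np.any(mu > 1):
            raise SimulationError("all mu must lie in [0, 1]")
        if np.any(mu[PoseClass.R] > 0.05):
            raise SimulationError("relaxation mu must be <= 0.05 on every channel")
        if self.jitter_sd < 0 or self.sensor_noise_sd < 0:
            raise SimulationError("noise standard deviations must be >= 0")
        if ct.shape != (mu.shape[1], mu.shape[1]):
            raise SimulationError("crosstalk must be square [channel x channel]")
        if not np.allclose(ct.sum(axis=1), 1.0, atol=1e-9):
            raise SimulationError("crosstalk rows must sum to 1")

    @property
    def n_channels(self) -> int:
        return self.mu.shape[1]

    @property
    def mixed_mu(self) -> np.ndarray:
        """Activation table after electrode crosstalk: row c gives the
        per-channel level observed while the subject holds class c."""
        return self.mu @ self.crosstalk.T


@dataclass(frozen=True)
class ProtocolSpec:
    """Cued training protocol: each class in ``class_sequence`` is held for
    task_duration seconds and followed by rest_duration seconds of
    relaxation; trim seconds at each block edge are discarded when building
    classifier datasets."""

    task_duration: float = 10.0
    rest_duration: float = 10.0
    trim: float = 2.0
    n_trials: int = 3
    class_sequence: tuple[PoseClass, ...] = (
        PoseClass.TVG,
        PoseClass.LP,
        PoseClass.EG,
        PoseClass.R,
        PoseClass.E,
    )

    def __post_init__(self) -> None:
        if self.task_duration <= 0 or self.rest_duration < 0:
            raise SimulationError("durations must be positive (rest may be 0)")
        if self.task_duration <= 2 * self.trim:
            raise SimulationError("task_duration must exceed 2*trim")
        if self.n_trials < 1:
            raise SimulationError("n_trials must be >= 1")


@dataclass
class EmgRecording:
    """Raw multichannel sEMG with per-sample ground-truth pose labels."""

    acquisition: AcquisitionConfig
    samples: np.ndarray        # [time x channel], raw signal units
    labels: np.ndarray         # [time], int codes per CLASS_ORDER
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.samples.ndim != 2:
            raise SimulationError("samples must be 2-D [time x channel]")
        if len(self.samples) != len(self.labels):
            raise SimulationError("samples and labels must have equal length")
        if self.samples.shape[1] != self.acquisition.n_channels:
            raise SimulationError("channel count mismatch with acquisition config")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.acquisition.sampling_rate

    def label_codes(self) -> list[str]:
        return [CLASS_ORDER[i].code for i in self.labels]


# ---------------------------------------------------------------------------
# label stream construction
# ---------------------------------------------------------------------------

def build_label_stream(
    protocol: ProtocolSpec, acquisition: AcquisitionConfig
) -> np.ndarray:
    """Per-sample ground-truth labels for ONE pass through the protocol.

    Each entry of ``class_sequence`` yields a task block of
    ``task_duration`` followed by a rest block (label R) of
    ``rest_duration``.  Trial repetition is handled by
    :func:`simulate_session`.
    """
    fs = acquisition.sampling_rate
    task_n = int(round(protocol.task_duration * fs))
    rest_n = int(round(protocol.rest_duration * fs))
    parts = []
    for cls in protocol.class_sequence:
        parts.append(np.full(task_n, int(PoseClass(cls)), dtype=np.int8))
        if rest_n:
            parts.append(np.full(rest_n, int(PoseClass.R), dtype=np.int8))
    if not parts:
        return np.zeros(0, dtype=np.int8)
    return np.concatenate(parts)


def label_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous equal-label runs as (start, end, class_index), end exclusive."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# raw signal synthesis
# ---------------------------------------------------------------------------

def _band_limits(fs: float) -> tuple[float, float]:
    """Carrier band, clipped below Nyquist for low sampling rates."""
    high = min(450.0, 0.45 * fs)
    low = min(20.0, 0.5 * high)
    return low, high

def _unit_carrier(rng: np.random.Generator, n: int, n_ch: int, fs: float) -> np.ndarray:
    """Zero-mean, empirically unit-variance noise band-limited to the sEMG band."""
    white = rng.standard_normal((n, n_ch))
    low, high = _band_limits(fs)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfilt(sos, white, axis=0)
    std = carrier.std(axis=0)
    std[std == 0] = 1.0
    return carrier / std


def _slow_jitter(
    rng: np.random.Generator, n: int, n_ch: int, fs: float, sd: float
) -> np.ndarray:
    """Smooth (<=1 Hz) multiplicative perturbation with standard deviation sd."""
    if sd == 0 or n < 16:
        return np.zeros((n, n_ch))
    white = rng.standard_normal((n, n_ch))
    sos = signal.butter(2, min(1.0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    slow = signal.sosfilt(sos, white, axis=0)
    std = slow.std(axis=0)
    std[std == 0] = 1.0
    return sd * slow / std


def _activation_levels(
    labels: np.ndarray,
    profile: ActivationProfile,
    mvic: np.ndarray,
    fs: float,
    ramp_s: float,
) -> np.ndarray:
    """Target carrier amplitude [time x channel], with linear ramps of
    ramp_s seconds at block boundaries (ground-truth labels keep the
    upcoming block's label during the ramp)."""
    table = profile.mixed_mu * mvic[np.newaxis, :]  # [class x channel]
    level = table[labels]
    ramp_n = int(round(ramp_s * fs))
    if ramp_n > 1:
        for start, end, _cls in label_runs(labels):
            if start == 0:
                continue
            m = min(ramp_n, end - start)
            frac = (np.arange(1, m + 1) / ramp_n).clip(max=1.0)[:, None]
            prev = level[start - 1]
            level[start:start + m] = prev + frac * (level[start] - prev)
    return level


def synthesize_raw(
    labels: np.ndarray,
    profile: ActivationProfile,
    mvic: np.ndarray | float,
    acquisition: AcquisitionConfig,
    seed: int,
    ramp_s: float = 0.3,
) -> EmgRecording:
    """Synthesize a raw recording for a given ground-truth label stream.

    raw(t, k) = baseline(k) + A(t, k) * carrier(t, k) + sensor noise, with
    A(t, k) = mvic(k) * crosstalk-mixed mu(class(t), k) * (1 + jitter(t, k)),
    ramped linearly over ``ramp_s`` at class-block boundaries.  Identical
    (labels, profile, mvic, seed) give a bit-identical recording.
    """
    labels = np.asarray(labels, dtype=np.int8)
    if len(labels) == 0:
        raise SimulationError("labels must be non-empty")
    if labels.min() < 0 or labels.max() >= N_CLASSES:
        raise SimulationError("labels contain values outside the pose classes")
    n_ch = acquisition.n_channels
    if profile.n_channels != n_ch:
        raise SimulationError("profile channel count mismatch")
    mvic = np.broadcast_to(np.asarray(mvic, dtype=float), (n_ch,)).copy()
    if np.any(mvic < 0):
        raise SimulationError("mvic amplitudes must be non-negative")

    fs = acquisition.sampling_rate
    n = len(labels)
    rng = np.random.default_rng(seed)
    carrier = _unit_carrier(rng, n, n_ch, fs)
    jitter = _slow_jitter(rng, n, n_ch, fs, profile.jitter_sd)
    level = _activation_levels(labels, profile, mvic, fs, ramp_s)
    amplitude = np.clip(level * (1.0 + jitter), 0.0, None)
    raw = profile.baseline_offset[np.newaxis, :] + amplitude * carrier
    if profile.sensor_noise_sd > 0:
        raw = raw + profile.sensor_noise_sd * rng.standard_normal((n, n_ch))
    return EmgRecording(acquisition=acquisition, samples=raw, labels=labels, seed=seed)


def simulate_session(
    protocol: ProtocolSpec,
    profile: ActivationProfile,
    acquisition: AcquisitionConfig,
    mvic: np.ndarray | float,
    seed: int,
    ramp_s: float = 0.3,
) -> EmgRecording:
    """Full training session: ``n_trials`` consecutive passes through the
    cued protocol, one continuous recording."""
    single = build_label_stream(protocol, acquisition)
    labels = np.tile(single, protocol.n_trials)
    return synthesize_raw(labels, profile, mvic, acquisition, seed, ramp_s=ramp_s)


def simulate_mvic_calibration(
    profile: ActivationProfile,
    acquisition: AcquisitionConfig,
    mvic: np.ndarray | float,
    seed: int,
    effort_duration: float = 3.0,
    rest_duration: float = 2.0,
) -> tuple[EmgRecording, dict[str, list[tuple[float, float]]]]:
    """Maximum-voluntary-contraction calibration recording.

    One maximal-effort burst per channel (carrier amplitude = that
    channel's MVIC; other channels at rest level), separated by rest.
    Returns the recording and the per-channel effort intervals in seconds.
    Rest periods are labeled R (usable for baseline estimation); effort
    periods carry the E label as a placeholder, since maximal isometric
    effort is not one of the cued pose classes.
    """
    fs = acquisition.sampling_rate
    n_ch = acquisition.n_channels
    mvic = np.broadcast_to(np.asarray(mvic, dtype=float), (n_ch,)).copy()
    effort_n = int(round(effort_duration * fs))
    rest_n = int(round(rest_duration * fs))
    rest_level = profile.mixed_mu[PoseClass.R] * mvic

    blocks, labels, segments = [], [], {name: [] for name in acquisition.channel_names}
    t = 0
    for k, name in enumerate(acquisition.channel_names):
        blocks.append(np.tile(rest_level, (rest_n, 1)))
        labels.append(np.full(rest_n, int(PoseClass.R), dtype=np.int8))
        t += rest_n
        burst = np.tile(rest_level, (effort_n, 1))
        burst[:, k] = mvic[k]
        blocks.append(burst)
        labels.append(np.full(effort_n, int(PoseClass.E), dtype=np.int8))
        segments[name].append((t / fs, (t + effort_n) / fs))
        t += effort_n
    blocks.append(np.tile(rest_level, (rest_n, 1)))
    labels.append(np.full(rest_n, int(PoseClass.R), dtype=np.int8))

    level = np.concatenate(blocks)
    lab = np.concatenate(labels)
    n = len(lab)
    rng = np.random.default_rng(seed)
    carrier = _unit_carrier(rng, n, n_ch, fs)
    jitter = _slow_jitter(rng, n, n_ch, fs, profile.jitter_sd)
    amplitude = np.clip(level * (1.0 + jitter), 0.0, None)
    raw = profile.baseline_offset[np.newaxis, :] + amplitude * carrier
    if profile.sensor_noise_sd > 0:
        raw = raw + profile.sensor_noise_sd * rng.standard_normal((n, n_ch))
    rec = EmgRecording(acquisition=acquisition, samples=raw, labels=lab, seed=seed)
    return rec, segments


# ---------------------------------------------------------------------------
# SCI severity model
# ---------------------------------------------------------------------------

def degrade_for_sci(
    profile: ActivationProfile,
    severity: float,
    attenuation_max: float = 0.8,
    crosstalk_gain: float = 1.0,
) -> ActivationProfile:
    """Weaken and de-select the activation profile to emulate cervical SCI.

    Non-rest activation means are scaled by (1 - severity*attenuation_max)
    and the crosstalk matrix is blended toward uniform mixing by
    severity*crosstalk_gain, so off-diagonal (cross-channel) mass grows
    proportionally with severity.  With the default gain, severity 1 means
    complete loss of electrode selectivity (all channels see the same
    mixture) on top of 5x-attenuated activation.  Sensor noise is
    unchanged; severity 0 is the identity.
    """
    if not 0.0 <= severity <= 1.0:
        raise SimulationError("severity must lie in [0, 1]")
    if severity == 0.0:
        return profile
    mu = profile.mu.copy()
    non_rest = [int(c) for c in CLASS_ORDER if c != PoseClass.R]
    mu[non_rest] *= 1.0 - severity * attenuation_max
    n_ch = profile.n_channels
    mix = severity * crosstalk_gain
    uniform = np.full((n_ch, n_ch), 1.0 / n_ch)
    crosstalk = (1.0 - mix) * profile.crosstalk + mix * uniform
    return replace(profile, mu=mu, crosstalk=crosstalk)
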