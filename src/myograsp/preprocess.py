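"""Linear-envelope extraction and MVIC normalization.

The classifier consumes, at every sample, the three-channel linear
envelope: raw sEMG with the resting offset removed, full-wave rectified,
low-passed with a causal 3rd-order 4 Hz Butterworth filter, floored at
zero, and divided by each channel's maximum-voluntary-isometric-
contraction (MVIC) envelope level.  The causal filter introduces a step
delay of roughly 100 ms at 2 kHz, which is part of the controller's
overall reaction latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .poses import CLASS_ORDER, PoseClass
from .simulate import AcquisitionConfig, EmgRecording


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Envelope low-pass: 3rd-order Butterworth, 4 Hz cutoff, causal
    single-pass by default (real-time semantics).  ``causal=False``
    selects zero-phase filtfilt for offline inspection only; anything
    feeding the controller must stay causal."""

    order: int = 3
    cutoff: float = 4.0
    family: str = "butterworth-lowpass"
    causal: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise PreprocessingError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise PreprocessingError("cutoff must be positive")

    def design(self, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
        if self.cutoff >= sampling_rate / 2:
            raise PreprocessingError(
                f"cutoff {self.cutoff} Hz must be below Nyquist "
                f"({sampling_rate / 2} Hz)"
            )
        b, a = signal.butter(self.order, self.cutoff, btype="lowpass",
                             fs=sampling_rate)
        return b, a


@dataclass(frozen=True)
class MvicProfile:
    """Per-channel MVIC envelope amplitudes used for normalization."""

    values: np.ndarray                  # one positive value per channel
    method: str = "p95-envelope"

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if np.any(v <= 0):
            raise PreprocessingError("all MVIC values must be > 0")


@dataclass
class EnvelopeStream:
    """Normalized linear-envelope stream: values[t, k] is channel k's
    activation at sample t as a (non-negative, unclipped) fraction of
    MVIC.  Carries the source labels when available."""

    values: np.ndarray
    sampling_rate: float
    labels: np.ndarray | None = None
    channel_names: tuple[str, ...] = ("FDS", "ED", "FPB_APB")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessingError("envelope values must be [time x channel]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if len(self.labels) != len(self.values):
                raise PreprocessingError("labels/values length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def estimate_baseline(recording: EmgRecording) -> np.ndarray:
    """Per-channel resting offset: mean of the raw signal over all samples
    labeled R (relaxation)."""
    mask = recording.labels == int(PoseClass.R)
    if not mask.any():
        raise PreprocessingError(
            "no relaxation-labeled samples to estimate the baseline from; "
            "pass an explicit per-channel baseline instead"
        )
    return recording.samples[mask].mean(axis=0)


def remove_offset(samples: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Subtract the per-channel resting offset."""
    samples = np.asarray(samples, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (samples.shape[1],):
        raise PreprocessingError("baseline must have one value per channel")
    return samples - baseline[np.newaxis, :]


def rectify(samples: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise magnitude."""
    return np.abs(np.asarray(samples, dtype=float))


def lowpass_envelope(
    samples: np.ndarray,
    sampling_rate: float,
    spec: FilterSpec = FilterSpec(),
    zi: np.ndarray | None = None,
    return_state: bool = False,
):
    """Apply the envelope low-pass (unit DC gain, zero-state start).

    When ``spec.causal``, filtering is a single forward IIR pass;
    ``zi``/``return_state`` carry filter state across chunk boundaries so
    streamed and batch processing agree bit-for-bit.  Zero-phase mode
    (filtfilt) ignores chunk state and is for offline use only.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    b, a = spec.design(sampling_rate)
    if not spec.causal:
        out = signal.filtfilt(b, a, samples, axis=0)
        return (out, None) if return_state else out
    if zi is None:
        zi = np.zeros((max(len(a), len(b)) - 1, samples.shape[1]))
    out, zf = signal.lfilter(b, a, samples, axis=0, zi=zi)
    return (out, zf) if return_state else out


def normalize(envelope: np.ndarray, mvic: MvicProfile) -> np.ndarray:
    """Divide each channel by its MVIC level.  Values above 1 are kept:
    effort can exceed the calibration percentile and the classifier should
    see it."""
    envelope = np.asarray(envelope, dtype=float)
    if mvic.values.shape != (envelope.shape[1],):
        raise PreprocessingError("MVIC profile channel count mismatch")
    return envelope / mvic.values[np.newaxis, :]


def linear_envelope(
    recording: EmgRecording,
    baseline: np.ndarray | None = None,
    spec: FilterSpec = FilterSpec(),
) -> np.ndarray:
    """Unnormalized envelope chain: offset removal, rectification, low-pass,
    and flooring of transient filter undershoot at zero."""
    if baseline is None:
        baseline = estimate_baseline(recording)
    x = remove_offset(recording.samples, baseline)
    x = rectify(x)
    env = lowpass_envelope(x, recording.acquisition.sampling_rate, spec)
    return np.clip(env, 0.0, None)


def preprocess_recording(
    recording: EmgRecording,
    mvic: MvicProfile,
    baseline: np.ndarray | None = None,
    spec: FilterSpec = FilterSpec(),
) -> EnvelopeStream:
    """Full preprocessing chain ending in the MVIC-normalized stream the
    classifier consumes."""
    env = linear_envelope(recording, baseline=baseline, spec=spec)
    return EnvelopeStream(
        values=normalize(env, mvic),
        sampling_rate=recording.acquisition.sampling_rate,
        labels=recording.labels.copy(),
        channel_names=recording.acquisition.channel_names,
    )


def measure_mvic(
    calibration: EmgRecording,
    effort_segments: dict[str, list[tuple[float, float]]],
    spec: FilterSpec = FilterSpec(),
    percentile: float = 95.0,
    noise_floor: float = 0.0,
    baseline: np.ndarray | None = None,
) -> MvicProfile:
    """MVIC per channel: the 95th percentile of the (offset-removed,
    rectified, low-passed) envelope pooled over that channel's maximal-
    effort segments.  The percentile, rather than the absolute maximum,
    is robust to single-sample spikes.

    Each channel needs at least one effort segment of >= 1 s; an MVIC at
    or below ``noise_floor`` raises, since it cannot normalize anything.
    """
    fs = calibration.acquisition.sampling_rate
    if baseline is None:
        try:
            baseline = estimate_baseline(calibration)
        except PreprocessingError:
            baseline = np.zeros(calibration.acquisition.n_channels)
    env = linear_envelope(calibration, baseline=baseline, spec=spec)

    values = np.empty(calibration.acquisition.n_channels)
    for k, name in enumerate(calibration.acquisition.channel_names):
        segments = effort_segments.get(name, [])
        if not segments:
            raise PreprocessingError(f"channel {name!r} has no effort segment")
        pooled = []
        for t0, t1 in segments:
            if t1 - t0 < 1.0:
                raise PreprocessingError(
                    f"effort segment ({t0}, {t1}) on {name!r} is shorter than 1 s"
                )
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            if i1 <= i0 or i1 > len(env):
                raise PreprocessingError(
                    f"effort segment ({t0}, {t1}) outside the recording"
                )
            pooled.append(env[i0:i1, k])
        values[k] = np.percentile(np.concatenate(pooled), percentile)
        if values[k] <= noise_floor:
            raise PreprocessingError(
                f"MVIC for channel {name!r} ({values[k]:.4g}) does not exceed "
                f"the noise floor ({noise_floor:.4g}); check sensor contact"
            )
    return MvicProfile(values=values, method=f"p{percentile:g}-envelope")


def step_delay(
    spec: FilterSpec = FilterSpec(),
    sampling_rate: float = 2000.0,
    fraction: float = 0.5,
    duration: float = 2.0,
) -> float:
    """Delay (s) at which the causal filter's unit-step response first
    reaches ``fraction`` of its final value — the operational reading of
    the envelope filter's ~100 ms lag."""
    n = int(round(duration * sampling_rate))
    step = np.ones((n, 1))
    out = lowpass_envelope(step, sampling_rate, FilterSpec(spec.order, spec.cutoff))
    final = out[-1, 0]
    idx = np.flatnonzero(out[:, 0] >= fraction * final)
    if len(idx) == 0:
        raise PreprocessingError("step response never reached the target fraction")
    return idx[0] / sampling_rate
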