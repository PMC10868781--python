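"""Core in-memory containers shared across the pipeline.

All time series carry their own sampling rate so that stimulus, envelope and
neural-response objects can be aligned without external metadata.  Envelopes
are kept at the 100 Hz analysis rate used throughout the response analyses;
auditory spectrograms run at 200 Hz frames (the rate of the adaptation model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AudioTrack",
    "EnvelopeTrack",
    "EchoSpec",
    "Recording",
    "AuditorySpectrogram",
]

#: sampling rate (Hz) of envelopes and preprocessed responses
ANALYSIS_RATE = 100.0
#: frame rate (Hz) of auditory spectrograms
SPECTROGRAM_RATE = 200.0


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AudioTrack:
    """A mono waveform ``s(t)`` with its sampling rate (Hz)."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_float_array(self.samples, "samples", 1))
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class EnvelopeTrack:
    """A nonnegative slow-modulation time series (sound envelope)."""

    values: np.ndarray
    rate: float = ANALYSIS_RATE

    def __post_init__(self):
        object.__setattr__(self, "values", _as_float_array(self.values, "values", 1))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EchoSpec:
    """Echo construction rule for the mixture ``A s(t) + s(t - tau(t))``.

    Parameters
    ----------
    amplitude : float
        Gain ``A`` applied to the direct (leading) copy.  ``A = 1`` gives the
        0-dB echo convention (echo as strong as the direct sound); ``A = 0.5``
        gives the 6-dB echo convention (echo twice the direct sound).
    schedule : sequence of (start_time_s, delay_s)
        Piecewise-constant delay schedule.  A single entry means a fixed
        delay for the whole track.  Start times must be strictly increasing
        and the first entry must start at 0.
    """

    amplitude: float
    schedule: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("echo amplitude A must be positive")
        sched = tuple((float(t0), float(d)) for t0, d in self.schedule)
        if not sched:
            raise ValueError("schedule must contain at least one (start, delay) entry")
        starts = [t0 for t0, _ in sched]
        if starts[0] != 0.0:
            raise ValueError("first schedule entry must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule start times must be strictly increasing")
        if any(d <= 0 for _, d in sched):
            raise ValueError("delays must be positive")
        object.__setattr__(self, "schedule", sched)

    @classmethod
    def fixed(cls, delay_s: float, amplitude: float = 1.0) -> "EchoSpec":
        """Fixed-delay echo (Experiments with a constant 0.125 s or 0.25 s delay)."""
        return cls(amplitude=amplitude, schedule=((0.0, delay_s),))

    @property
    def is_fixed(self) -> bool:
        return len(self.schedule) == 1

    @property
    def max_delay(self) -> float:
        return max(d for _, d in self.schedule)

    def delay_at(self, times: np.ndarray) -> np.ndarray:
        """Delay tau(t) for an array of times (piecewise constant)."""
        times = np.asarray(times, dtype=float)
        starts = np.array([t0 for t0, _ in self.schedule])
        delays = np.array([d for _, d in self.schedule])
        idx = np.searchsorted(starts, times, side="right") - 1
        idx = np.clip(idx, 0, len(delays) - 1)
        return delays[idx]


@dataclass(frozen=True)
class Recording:
    """Multichannel neural recording: channels x time, with sampling rate."""

    data: np.ndarray
    rate: float
    labels: tuple = ()
    provenance: str = "unknown"

    def __post_init__(self):
        object.__setattr__(self, "data", _as_float_array(self.data, "data", 2))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.labels:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != self.data.shape[0]:
                raise ValueError("labels length must match channel count")
            object.__setattr__(self, "labels", labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class AuditorySpectrogram:
    """128-channel auditory spectrogram at 200 Hz frames.

    ``values`` is channels x frames, nonnegative; ``center_frequencies`` are
    the band centers (Hz), ascending.
    """

    values: np.ndarray
    center_frequencies: np.ndarray
    frame_rate: float = SPECTROGRAM_RATE

    def __post_init__(self):
        object.__setattr__(self, "values", _as_float_array(self.values, "values", 2))
        cf = _as_float_array(self.center_frequencies, "center_frequencies", 1)
        object.__setattr__(self, "center_frequencies", cf)
        if np.any(self.values < 0):
            raise ValueError("spectrogram values must be nonnegative")
        if cf.size != self.values.shape[0]:
            raise ValueError("center_frequencies must match channel count")
        if np.any(np.diff(cf) <= 0):
            raise ValueError("center frequencies must be ascending")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]
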