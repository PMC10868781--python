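"""Synthetic speech-like stimuli and MEG-like responses with known ground truth.

The generator emulates only the statistics the downstream analyses rely on:

* a nonnegative, pause-bearing envelope whose modulation spectrum peaks in
  the 2-8 Hz syllabic range, whose autocorrelation is negligible beyond
  100 ms within voiced stretches, and whose pauses longer than 500 ms recur
  every ~3.4 s on average (0.4-11.2 s range);
* audio built from that envelope by modulating band-limited Gaussian noise
  (so the waveform is exactly decorrelated at the echo lags);
* multichannel responses generated under one of three encoding regimes --
  ``mixture`` (the brain encodes the echoic mixture envelope), ``streaming``
  (direct sound and echo encoded as separate streams with distinct kernels),
  or ``idealized`` (only the direct sound is encoded) -- plus 1/f background
  and white sensor noise at a configurable per-channel SNR.

Envelope-domain echo synthesis runs at a 200 Hz native rate, where both
0.125 s and 0.25 s delays are integer sample shifts; streams are decimated
to the 100 Hz analysis rate afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import (
    ANALYSIS_RATE,
    AudioTrack,
    EchoSpec,
    EnvelopeTrack,
    Recording,
)

__all__ = [
    "SynthConfig",
    "SynthSession",
    "NATIVE_ENV_RATE",
    "speech_like_envelope",
    "speech_like_audio",
    "echoic_envelope_streams",
    "default_kernels",
    "synth_recording",
]

#: native rate for envelope synthesis; 0.125 s and 0.25 s are integer shifts
NATIVE_ENV_RATE = 200.0

REGIMES = ("mixture", "streaming", "idealized")


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for synthetic sessions.

    Defaults mirror the study conditions: 204 gradiometer-like channels,
    voiced stretches averaging 3.4 s separated by >0.5 s pauses, a ~5 Hz
    syllabic envelope, and responses driven through 1-s biphasic kernels.
    """

    duration_s: float = 60.0
    audio_rate: float = 16000.0
    env_rate: float = ANALYSIS_RATE
    n_channels: int = 204
    regime: str = "streaming"
    snr_db: float = -10.0
    #: voiced-interval distribution (gamma), truncated to the observed range
    voiced_mean_s: float = 3.4
    voiced_shape: float = 2.0
    voiced_range_s: tuple = (0.4, 11.2)
    #: pause-duration distribution (uniform), all pauses exceed 0.5 s
    pause_range_s: tuple = (0.65, 1.2)
    #: syllable statistics within voiced stretches
    syllable_period_s: float = 0.2
    syllable_jitter_cv: float = 0.55
    syllable_gap_max_s: float = 0.45
    syllable_width_s: float = 0.12
    syllable_amp_sigma: float = 0.6
    #: fraction of noise variance given to the 1/f component (rest is white)
    pink_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.duration_s < 1.0:
            raise ValueError("duration must be at least 1 s")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")


@dataclass(frozen=True)
class SynthSession:
    """A generated stimulus/response pair with its ground truth."""

    direct: EnvelopeTrack
    echo: EnvelopeTrack
    mixture: EnvelopeTrack
    recording: Recording
    regime: str
    kernels: dict
    gains: np.ndarray
    echo_spec: EchoSpec
    config: SynthConfig


def _segment_plan(rng: np.random.Generator, cfg: SynthConfig, duration_s: float):
    """Alternating (is_voiced, duration) pairs covering duration_s."""
    lo, hi = cfg.voiced_range_s
    scale = cfg.voiced_mean_s / cfg.voiced_shape
    plan, t = [], 0.0
    voiced = True
    while t < duration_s:
        if voiced:
            d = 0.0
            while not (lo <= d <= hi):
                d = rng.gamma(cfg.voiced_shape, scale)
        else:
            d = rng.uniform(*cfg.pause_range_s)
        plan.append((voiced, d))
        t += d
        voiced = not voiced
    return plan


def speech_like_envelope(cfg: SynthConfig) -> EnvelopeTrack:
    """Generate a pause-bearing syllabic envelope at ``cfg.env_rate``.

    Voiced stretches are sums of Hann-shaped syllable pulses with jittered
    onsets and lognormal amplitudes; the jitter decorrelates the envelope
    beyond ~100 ms while keeping the modulation spectrum peaked near the
    syllabic rate.  The same seed always yields the same envelope.
    """
    env = _native_envelope(np.random.default_rng(cfg.seed), cfg)
    return _decimate_env(env, cfg.env_rate)


def _native_envelope(rng: np.random.Generator, cfg: SynthConfig) -> EnvelopeTrack:
    rate = NATIVE_ENV_RATE
    n = int(round(cfg.duration_s * rate))
    env = np.zeros(n)
    width = int(round(cfg.syllable_width_s * rate))
    pulse = np.hanning(width)
    shape = 1.0 / cfg.syllable_jitter_cv**2
    scale = cfg.syllable_period_s / shape

    t = 0.0
    for voiced, seg_dur in _segment_plan(rng, cfg, cfg.duration_s):
        if voiced:
            onset = t + rng.uniform(0, cfg.syllable_period_s / 2)
            while onset < t + seg_dur - cfg.syllable_width_s / 2:
                amp = rng.lognormal(0.0, cfg.syllable_amp_sigma)
                i0 = int(round(onset * rate))
                i1 = min(i0 + width, n)
                if i0 >= n:
                    break
                env[i0:i1] += amp * pulse[: i1 - i0]
                # cap the gap so within-voiced silences never register as pauses
                onset += min(rng.gamma(shape, scale), cfg.syllable_gap_max_s)
        t += seg_dur
    return EnvelopeTrack(env, rate)


def _decimate_env(env: EnvelopeTrack, out_rate: float) -> EnvelopeTrack:
    if env.rate == out_rate:
        return env
    g = np.gcd(int(round(env.rate)), int(round(out_rate)))
    up, down = int(round(out_rate)) // g, int(round(env.rate)) // g
    vals = signal.resample_poly(env.values, up, down)
    return EnvelopeTrack(np.clip(vals, 0.0, None), out_rate)


def speech_like_audio(cfg: SynthConfig) -> AudioTrack:
    """Speech-like audio: the syllabic envelope modulating band-limited noise.

    The carrier is Gaussian noise low-passed below 4 kHz, so the waveform is
    decorrelated at any lag much longer than 0.25 ms -- in particular at the
    0.125 s and 0.25 s echo lags, the condition under which a unit-gain echo
    raises RMS level by exactly 10*log10(2) = 3.01 dB.
    """
    rng = np.random.default_rng(cfg.seed)
    env = _native_envelope(rng, cfg)
    n_audio = int(round(cfg.duration_s * cfg.audio_rate))
    # zero-order-hold then smooth: keeps the envelope nonnegative
    idx = np.minimum(
        (np.arange(n_audio) * (env.rate / cfg.audio_rate)).astype(int), len(env) - 1
    )
    env_audio = env.values[idx]
    sos = signal.butter(4, 50.0, btype="low", fs=cfg.audio_rate, output="sos")
    env_audio = np.clip(signal.sosfiltfilt(sos, env_audio), 0.0, None)
    carrier = rng.standard_normal(n_audio)
    sos_c = signal.butter(8, 4000.0, btype="low", fs=cfg.audio_rate, output="sos")
    carrier = signal.sosfiltfilt(sos_c, carrier)
    return AudioTrack(env_audio * carrier, cfg.audio_rate)


def echoic_envelope_streams(
    direct: EnvelopeTrack, spec: EchoSpec, out_rate: float = ANALYSIS_RATE
):
    """Direct, echo and mixture envelope streams on a common timeline.

    ``direct`` must be sampled at a rate where every scheduled delay is an
    integer sample shift (the 200 Hz native rate works for 0.125 s and
    0.25 s).  The echo stream is the delayed copy truncated to the direct
    sound's support; the mixture is ``A*direct + echo``.  All three streams
    are returned at ``out_rate``.
    """
    rate = direct.rate
    n = len(direct)
    times = np.arange(n) / rate
    delays = spec.delay_at(times)
    shift_f = delays * rate
    shift = np.round(shift_f).astype(int)
    if np.any(np.abs(shift_f - shift) > 1e-9):
        bad = delays[np.argmax(np.abs(shift_f - shift))]
        raise ValueError(f"delay {bad} s is not an integer sample shift at {rate} Hz")
    src = np.arange(n) - shift
    echo_vals = np.where((src >= 0) & (src < n), direct.values[np.clip(src, 0, n - 1)], 0.0)
    echo = EnvelopeTrack(echo_vals, rate)
    mixture = EnvelopeTrack(spec.amplitude * direct.values + echo_vals, rate)
    return (
        _decimate_env(EnvelopeTrack(spec.amplitude * direct.values, rate), out_rate),
        _decimate_env(echo, out_rate),
        _decimate_env(mixture, out_rate),
    )


def _biphasic_kernel(
    n_lags: int, rate: float, peak_pos_s: float, peak_neg_s: float, amp: float = 1.0
) -> np.ndarray:
    """Gamma-shaped biphasic kernel over lags 1..n_lags (positive lobe first)."""
    t = np.arange(1, n_lags + 1) / rate
    def lobe(peak):
        k = 3.0
        theta = peak / (k - 1)
        x = t ** (k - 1) * np.exp(-t / theta)
        return x / x.max()
    k = lobe(peak_pos_s) - 0.6 * lobe(peak_neg_s)
    return amp * k


def default_kernels(regime: str, n_lags: int = 100, rate: float = ANALYSIS_RATE) -> dict:
    """Ground-truth response kernels per stream for each encoding regime.

    Biphasic, with positive peaks near 50 ms and troughs near 100-150 ms,
    within a 1-s integration window.  The streaming regime uses distinct
    kernels for the direct and echo streams so the two are identifiable.
    """
    k_direct = _biphasic_kernel(n_lags, rate, 0.05, 0.10)
    if regime == "mixture":
        return {"mixture": k_direct}
    if regime == "idealized":
        return {"direct": k_direct}
    if regime == "streaming":
        k_echo = 0.6 * _biphasic_kernel(n_lags, rate, 0.09, 0.16)
        return {"direct": k_direct, "echo": k_echo}
    raise ValueError(f"unknown regime {regime!r}")


def _lagged_drive(env: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """sum_tau k(tau) env(t - tau) with lags 1..len(kernel)."""
    full = np.convolve(env, kernel)
    return np.concatenate([[0.0], full])[: env.size]


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, rate: float) -> np.ndarray:
    """1/f-power noise per channel, unit variance, flat below 0.1 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 0.1))
    shaping[0] = 0.0
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def synth_recording(
    direct: EnvelopeTrack, spec: EchoSpec, cfg: SynthConfig, kernels: dict | None = None
) -> SynthSession:
    """Simulate a multichannel response to an echoic stimulus.

    Per channel ``c``: ``response_c = g_c * sum_streams (kernel * stream
    envelope) + noise_c``, where the noise is a 1/f ("spontaneous activity")
    plus white sensor mixture scaled so that the per-channel ratio of driven
    to noise variance equals ``cfg.snr_db``.  The per-channel gains ``g_c``
    play the role of a sensor topography (random sign, lognormal magnitude).

    ``direct`` must be at a rate where the scheduled delays are integer
    shifts (use the 200 Hz native rate); all outputs are at 100 Hz.
    """
    if cfg.regime not in REGIMES:
        raise ValueError(f"unknown regime {cfg.regime!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E55]))
    d100, e100, m100 = echoic_envelope_streams(direct, spec, ANALYSIS_RATE)

    if kernels is None:
        kernels = default_kernels(cfg.regime)
    if cfg.regime == "mixture":
        streams = {"mixture": m100.values}
    elif cfg.regime == "idealized":
        streams = {"direct": d100.values}
    else:
        streams = {"direct": d100.values, "echo": e100.values}

    drive = np.zeros(len(d100))
    for name, kern in kernels.items():
        drive += _lagged_drive(streams[name], kern)
    drive = drive - drive.mean()

    gains = rng.choice([-1.0, 1.0], cfg.n_channels) * rng.lognormal(
        0.0, 0.3, cfg.n_channels
    )
    driven = gains[:, None] * drive[None, :]

    if np.isfinite(cfg.snr_db):
        n = drive.size
        pink = _pink_noise(rng, cfg.n_channels, n, ANALYSIS_RATE)
        white = rng.standard_normal((cfg.n_channels, n))
        noise = np.sqrt(cfg.pink_fraction) * pink + np.sqrt(1 - cfg.pink_fraction) * white
        noise /= noise.std(axis=1, keepdims=True)
        target_noise_sd = driven.std(axis=1) / 10 ** (cfg.snr_db / 20.0)
        data = driven + target_noise_sd[:, None] * noise
    else:
        data = driven

    rec = Recording(
        data,
        ANALYSIS_RATE,
        labels=tuple(f"MEG{i:04d}" for i in range(cfg.n_channels)),
        provenance=f"synthetic:{cfg.regime}",
    )
    return SynthSession(
        direct=d100,
        echo=e100,
        mixture=m100,
        recording=rec,
        regime=cfg.regime,
        kernels=kernels,
        gains=gains,
        echo_spec=spec,
        config=cfg,
    )
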