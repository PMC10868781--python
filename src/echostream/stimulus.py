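"""Echoic stimulus construction and envelope extraction.

An echoic mixture is ``A s(t) + s(t - tau)``: the direct (leading) sound with
gain ``A`` plus a unit-gain delayed copy, the echo.  A unit-gain echo with
delay ``tau`` cancels the envelope Fourier components at the echo-related
frequencies ``(2k - 1) / (2 tau)``, because those components are shifted by
half a period and arrive in antiphase.  With ``A = 1`` the mixture is
``10 log10(2) = 3.01`` dB stronger (RMS) than the direct sound whenever the
signal is decorrelated at the echo lag; with ``A = 0.5`` (echo twice the
direct sound) the gain is ``10 log10(1.25) = 0.97`` dB.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import ANALYSIS_RATE, AudioTrack, EchoSpec, EnvelopeTrack

__all__ = [
    "make_echoic",
    "rms_gain_db",
    "echo_related_frequencies",
    "segment_pauses",
    "vocode_one_channel",
    "extract_envelope_broadband",
    "read_wav",
    "write_wav",
]


def read_wav(path) -> AudioTrack:
    """Read a mono WAV file (PCM 16/24/32-bit or float) as an AudioTrack.

    Integer formats are rescaled to [-1, 1); multichannel files are averaged
    to mono.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioTrack(data, float(rate))


def write_wav(path, audio: AudioTrack) -> None:
    """Write an AudioTrack as a float32 WAV file."""
    from scipy.io import wavfile

    wavfile.write(path, int(round(audio.rate)), audio.samples.astype(np.float32))


def _delay_to_samples(delay_s: float, rate: float) -> int:
    n = delay_s * rate
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 * max(1.0, abs(n)):
        raise ValueError(
            f"delay {delay_s} s is not an integer number of samples at {rate} Hz"
        )
    return n_int


def make_echoic(direct: AudioTrack, spec: EchoSpec) -> AudioTrack:
    """Mix a direct sound with its delayed copy: ``A s(t) + s(t - tau(t))``.

    The output is longer than the input by the maximum delay (the echo tail
    is kept).  Delays must land on integer sample counts so the shift, and
    hence the antiphase cancellation at echo-related frequencies, is exact.
    For a variable-delay schedule the delay is piecewise constant; switch
    points are meant to fall inside pauses of the direct sound (see
    :func:`segment_pauses`), where the splice is inaudible by construction.
    """
    s = direct.samples
    if s.size == 0:
        raise ValueError("cannot add an echo to an empty track")
    rate = direct.rate
    shifts = [_delay_to_samples(d, rate) for _, d in spec.schedule]
    max_shift = max(shifts)
    if spec.max_delay >= direct.duration:
        raise ValueError("echo delay must be shorter than the track duration")
    n_out = s.size + max_shift
    out = np.zeros(n_out)
    out[: s.size] += spec.amplitude * s

    if spec.is_fixed:
        out[shifts[0] : shifts[0] + s.size] += s
    else:
        # piecewise-constant delay on the output timeline; the delay active at
        # output sample i selects which direct sample echoes there
        t_out = np.arange(n_out) / rate
        delays = spec.delay_at(t_out)
        n_shift = np.array([_delay_to_samples(d, rate) for d in delays])
        src = np.arange(n_out) - n_shift
        valid = (src >= 0) & (src < s.size)
        out[valid] += s[src[valid]]
    return AudioTrack(out, rate)


def rms_gain_db(mixture: AudioTrack, direct: AudioTrack) -> float:
    """RMS level of the mixture relative to the direct sound, in dB.

    Both tracks are compared on their overlapping region (the echo tail of
    the mixture and the echo-free head are excluded), so the number reflects
    steady-state superposition rather than edge effects.
    """
    if mixture.rate != direct.rate:
        raise ValueError("tracks must share a sampling rate")
    n = min(len(mixture), len(direct))
    head = len(mixture) - len(direct) if len(mixture) > len(direct) else 0
    m = mixture.samples[head:n]
    d = direct.samples[head:n]
    rms_m = np.sqrt(np.mean(m**2))
    rms_d = np.sqrt(np.mean(d**2))
    if rms_m == 0 or rms_d == 0:
        raise ValueError("cannot compute RMS gain of a silent track")
    return 20.0 * np.log10(rms_m / rms_d)


def echo_related_frequencies(delay_s: float, f_max: float) -> list[float]:
    """Frequencies ``(2k - 1) / (2 tau)`` strictly below ``f_max``, ascending.

    These are the modulation frequencies at which a unit-gain echo with delay
    ``tau`` fully cancels the stimulus envelope (zeros of ``|1 + e^{-i 2 pi
    f tau}|``).
    """
    if delay_s <= 0:
        raise ValueError("delay must be positive")
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    freqs = []
    k = 1
    while True:
        f = (2 * k - 1) / (2.0 * delay_s)
        if f >= f_max:
            break
        freqs.append(f)
        k += 1
    return freqs


def segment_pauses(env: EnvelopeTrack, min_pause_s: float = 0.5) -> list[tuple[float, float]]:
    """Maximal silent intervals of at least ``min_pause_s`` seconds.

    A frame is silent when the envelope falls below 5% of its median over
    voiced frames; the median-based threshold makes the segmentation
    invariant to overall gain.  Returns (start_s, end_s) pairs; an all-silent
    envelope yields one pause spanning the whole track.
    """
    if min_pause_s < 0:
        raise ValueError("min_pause_s must be nonnegative")
    v = env.values
    if v.size == 0:
        return []
    peak = v.max()
    if peak == 0:
        return [(0.0, v.size / env.rate)]
    voiced_guess = v > 0.05 * peak
    ref = np.median(v[voiced_guess]) if voiced_guess.any() else peak
    silent = v < 0.05 * ref

    pauses = []
    min_len = int(np.ceil(min_pause_s * env.rate))
    i = 0
    n = v.size
    while i < n:
        if silent[i]:
            j = i
            while j < n and silent[j]:
                j += 1
            if j - i >= max(min_len, 1):
                pauses.append((i / env.rate, j / env.rate))
            i = j
        else:
            i += 1
    return pauses


def _lowpass(x: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def vocode_one_channel(direct: AudioTrack, spec: EchoSpec, seed: int) -> AudioTrack:
    """One-channel noise vocoding of an echoic mixture.

    The direct stream (``A s(t)``) and the echo stream (``s(t - tau)``) are
    vocoded separately and then mixed: each stream's Hilbert envelope
    (low-passed below 160 Hz, 4th-order Butterworth) modulates Gaussian white
    noise low-passed below 4 kHz, which removes the spectro-temporal fine
    structure that serves as the segregation cue while preserving each
    stream's envelope.  The output RMS is rescaled to match the non-vocoded
    echoic mixture.
    """
    rate = direct.rate
    if rate <= 8000:
        raise ValueError("audio rate must exceed 8 kHz to represent the 4 kHz carrier band")
    if direct.samples.size == 0:
        raise ValueError("empty input")

    mixture = make_echoic(direct, spec)
    n_out = len(mixture)

    # the two streams on the mixture timeline
    direct_stream = np.zeros(n_out)
    direct_stream[: len(direct)] = spec.amplitude * direct.samples
    echo_stream = mixture.samples - direct_stream

    rng = np.random.default_rng(seed)
    voc = np.zeros(n_out)
    for stream in (direct_stream, echo_stream):
        envelope = np.abs(signal.hilbert(stream))
        envelope = np.clip(_lowpass(envelope, 160.0, rate), 0.0, None)
        carrier = _lowpass(rng.standard_normal(n_out), 4000.0, rate)
        voc += envelope * carrier

    rms_target = np.sqrt(np.mean(mixture.samples**2))
    rms_voc = np.sqrt(np.mean(voc**2))
    if rms_voc > 0:
        voc *= rms_target / rms_voc
    return AudioTrack(voc, rate)


def extract_envelope_broadband(
    audio: AudioTrack, out_rate: float = ANALYSIS_RATE
) -> EnvelopeTrack:
    """Broadband envelope: full-wave rectification, low-pass below 50 Hz,
    resampled to the analysis rate (100 Hz), clipped at zero.
    """
    x = audio.samples
    if x.size == 0:
        raise ValueError("empty input")
    rect = np.abs(x)
    if audio.rate > 2 * 50.0:
        rect = _lowpass(rect, 50.0, audio.rate)
    if audio.rate != out_rate:
        up, down = (np.array([out_rate, audio.rate]) /
                    np.gcd(int(round(out_rate)), int(round(audio.rate)))).astype(int)
        rect = signal.resample_poly(rect, up, down)
    return EnvelopeTrack(np.clip(rect, 0.0, None), out_rate)
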