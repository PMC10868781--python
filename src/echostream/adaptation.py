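"""Synaptic depression and divisive gain control on auditory spectrograms.

Each of the 128 spectrogram channels ``s(t, c)`` (200 Hz frames) is passed
through a threshold-depression-gain cascade:

    r(t, c) = max(s(t, c) - D(t, c), 0) * G(t, c)
    D(t, c) = V * (1 + sum_n s(t - n, c) W_sd(n))        n = 0 .. N_sd - 1
    G(t, c) = 1 / (1 + sum_n r(t - n, c) W_gc(n))        n = 1 .. N_gc

``V`` is the firing threshold (0 < V < 1 on spectrograms normalized so their
95th percentile is 1), and ``W_sd``/``W_gc`` are raw (unnormalized) Hann
weights over windows of width ``tau_sd``/``tau_gc`` milliseconds.  The gain
sum runs over strictly past outputs so the recursion is well defined; the
depression sum keeps the current input sample.  The simulated
envelope-tracking response is the channel sum of ``r``.

Because the echo of every syllable arrives while depression from the direct
sound is still elevated, the cascade attenuates the lagging copy: it
partially restores the direct-sound envelope for a 0-dB echo, but degrades
it further when the echo is stronger than the direct sound.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import signal as _sig

from .containers import ANALYSIS_RATE, AuditorySpectrogram, EnvelopeTrack

__all__ = [
    "AdaptationParams",
    "AdaptedResponse",
    "normalize_spectrogram",
    "adapt",
    "adapt_reference",
    "fit_params",
    "adapted_coherence_spectrum",
]


@dataclass(frozen=True)
class AdaptationParams:
    """Firing threshold and time constants (ms) of the adaptation cascade."""

    v: float
    tau_sd_ms: float
    tau_gc_ms: float

    def __post_init__(self):
        if not 0 <= self.v < 1:
            raise ValueError("firing threshold V must be in [0, 1)")
        if self.tau_sd_ms < 0 or self.tau_gc_ms < 0:
            raise ValueError("window widths must be nonnegative")


@dataclass(frozen=True)
class AdaptedResponse:
    """Adapted spectrogram r(t,c) with its intermediates and channel sum."""

    r: np.ndarray  # channels x frames
    depression: np.ndarray  # D(t,c)
    gain: np.ndarray  # G(t,c)
    frame_rate: float

    @property
    def summed(self) -> EnvelopeTrack:
        """Simulated envelope-tracking response: sum of r over channels."""
        return EnvelopeTrack(self.r.sum(axis=0), self.frame_rate)


def _hann_weights(n_taps: int) -> np.ndarray:
    """Nonzero raw Hann weights over a window of ``n_taps`` frames."""
    if n_taps <= 0:
        return np.zeros(0)
    return np.hanning(n_taps + 2)[1:-1]


def _frames(tau_ms: float, rate: float) -> int:
    n = tau_ms / 1000.0 * rate
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"window of {tau_ms} ms is not a whole number of frames")
    return int(round(n))


def normalize_spectrogram(spec: AuditorySpectrogram) -> AuditorySpectrogram:
    """Scale so the 95th percentile equals 1, making the threshold V portable."""
    ref = np.percentile(spec.values, 95)
    if ref == 0:
        return spec
    return AuditorySpectrogram(
        spec.values / ref, spec.center_frequencies, spec.frame_rate
    )


def adapt(spec: AuditorySpectrogram, p: AdaptationParams) -> AdaptedResponse:
    """Run the depression + gain-control cascade on a spectrogram.

    The depression term is a causal convolution of the input and can be
    precomputed; the gain term feeds back on the output and is evaluated
    frame by frame.
    """
    s = spec.values
    if np.any(s < 0):
        raise ValueError("spectrogram input must be nonnegative")
    rate = spec.frame_rate
    n_sd = _frames(p.tau_sd_ms, rate)
    n_gc = _frames(p.tau_gc_ms, rate)
    w_sd = _hann_weights(n_sd)  # taps at lags 0 .. n_sd-1
    w_gc = _hann_weights(n_gc)  # taps at lags 1 .. n_gc

    n_ch, n_t = s.shape
    # causal input convolution, taps accumulated in ascending-lag order so the
    # float rounding matches the direct-summation reference exactly
    dsum = np.zeros_like(s)
    for n in range(n_sd):
        dsum[:, n:] += s[:, : n_t - n] * w_sd[n]
    D = p.v * (1.0 + dsum)

    excess = np.maximum(s - D, 0.0)
    r = np.empty_like(s)
    G = np.empty_like(s)
    if n_gc == 0:
        G[:] = 1.0
        r[:] = excess
    else:
        acc = np.empty(n_ch)
        for t in range(n_t):
            acc[:] = 0.0
            for n in range(1, min(n_gc, t) + 1):
                acc += r[:, t - n] * w_gc[n - 1]
            g = 1.0 / (1.0 + acc)
            G[:, t] = g
            r[:, t] = excess[:, t] * g
    return AdaptedResponse(r=r, depression=D, gain=G, frame_rate=rate)


def adapt_reference(spec: AuditorySpectrogram, p: AdaptationParams) -> AdaptedResponse:
    """Naive direct-summation implementation of :func:`adapt` (oracle).

    Evaluates the defining sums term by term in pure Python loops; intended
    for cross-checking the vectorized implementation on short fixtures.
    """
    s = spec.values
    rate = spec.frame_rate
    n_sd = _frames(p.tau_sd_ms, rate)
    n_gc = _frames(p.tau_gc_ms, rate)
    w_sd = _hann_weights(n_sd)
    w_gc = _hann_weights(n_gc)
    n_ch, n_t = s.shape
    r = np.zeros_like(s)
    D = np.zeros_like(s)
    G = np.zeros_like(s)
    for c in range(n_ch):
        for t in range(n_t):
            acc = 0.0
            for n in range(n_sd):
                if t - n >= 0:
                    acc += s[c, t - n] * w_sd[n]
            D[c, t] = p.v * (1.0 + acc)
            acc = 0.0
            for n in range(1, n_gc + 1):
                if t - n >= 0:
                    acc += r[c, t - n] * w_gc[n - 1]
            G[c, t] = 1.0 / (1.0 + acc)
            r[c, t] = max(s[c, t] - D[c, t], 0.0) * G[c, t]
    return AdaptedResponse(r=r, depression=D, gain=G, frame_rate=rate)


def adapted_envelope(
    spec: AuditorySpectrogram, p: AdaptationParams, out_rate: float = ANALYSIS_RATE
) -> EnvelopeTrack:
    """Channel-summed adapted response resampled to the analysis rate."""
    summed = adapt(normalize_spectrogram(spec), p).summed
    if summed.rate == out_rate:
        return summed
    g = np.gcd(int(round(summed.rate)), int(round(out_rate)))
    up, down = int(round(out_rate)) // g, int(round(summed.rate)) // g
    vals = _sig.resample_poly(summed.values, up, down)
    return EnvelopeTrack(np.clip(vals, 0.0, None), out_rate)


def default_grid(
    v_step: float = 0.05,
    tau_sd_step_ms: float = 50.0,
    tau_gc_step_ms: float = 50.0,
    tau_sd_max_ms: float = 500.0,
    tau_gc_max_ms: float = 500.0,
) -> list[AdaptationParams]:
    """Exhaustive parameter grid: 0 < V < 1 and 0 < tau < max, open bounds."""
    vs = np.arange(v_step, 1.0 - 1e-9, v_step)
    sds = np.arange(tau_sd_step_ms, tau_sd_max_ms - 1e-9, tau_sd_step_ms)
    gcs = np.arange(tau_gc_step_ms, tau_gc_max_ms - 1e-9, tau_gc_step_ms)
    if vs.size == 0 or sds.size == 0 or gcs.size == 0:
        raise ValueError("empty parameter grid")
    return [
        AdaptationParams(round(v, 10), sd, gc)
        for v, sd, gc in product(vs, sds, gcs)
    ]


def fit_params(sessions, grid=None) -> AdaptationParams:
    """Grid-search adaptation parameters on echoic sessions.

    ``sessions`` is a list of ``(echoic_spectrogram, direct_envelope)`` pairs
    (one per echoic condition).  For each grid point the adapted
    channel-summed response is correlated with the direct-sound envelope and
    the correlation is averaged over sessions; the argmax is returned, ties
    broken by the smallest (V, tau_sd, tau_gc) lexicographically.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("empty parameter grid")
    specs = [normalize_spectrogram(spec) for spec, _ in sessions]
    envs = [env for _, env in sessions]

    best = None
    for p in sorted(grid, key=lambda q: (q.v, q.tau_sd_ms, q.tau_gc_ms)):
        rs = []
        for spec, env in zip(specs, envs):
            summed = adapt(spec, p).summed
            pred = _sig.resample_poly(summed.values, 1, 2) if env.rate * 2 == summed.rate \
                else summed.values
            n = min(pred.size, len(env))
            rs.append(np.corrcoef(pred[:n], env.values[:n])[0, 1])
        score = float(np.mean(rs))
        if best is None or score > best[0]:
            best = (score, p)
    return best[1]


def adapted_coherence_spectrum(
    spec: AuditorySpectrogram,
    direct: EnvelopeTrack,
    p: AdaptationParams,
    epoch_len_s: float = 2.0,
):
    """(frequencies, C) between the adapted response and the direct envelope."""
    from .coherence import coherence_spectrum

    pred = adapted_envelope(spec, p, out_rate=direct.rate)
    return coherence_spectrum(direct, pred, epoch_len_s)
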