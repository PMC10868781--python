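"""Auditory-spectrogram front end and modulation spectrum.

The spectrogram approximates subcortical auditory processing as 128
log-spaced narrowband envelopes between 180 Hz and 4 kHz, framed at 200 Hz.
It is implemented as an STFT magnitude re-binned through triangular filters
on the log-frequency axis; the downstream analyses (adaptation simulation,
modulation spectrum) depend only on having 128 narrowband envelopes at
200 Hz, not on the detailed cochlear nonlinearity.

The modulation spectrum is the DFT amplitude of each narrowband envelope,
summed over channels and normalized by the maximum of a reference (anechoic)
stimulus; a unit-gain echo notches it at the echo-related frequencies.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import SPECTROGRAM_RATE, AudioTrack, AuditorySpectrogram

__all__ = ["auditory_spectrogram", "modulation_spectrum", "ModulationSpectrum"]

N_BANDS = 128
F_LO = 180.0
F_HI = 4000.0


def _band_matrix(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangular weights mapping FFT bins to 128 log-spaced bands.

    Triangles narrower than the FFT bin spacing are widened to one bin so
    every band sees at least one bin; rows are normalized to unit sum, making
    each band an average (not an integral) over its bins.
    """
    df = freqs[1] - freqs[0]
    edges = np.geomspace(F_LO, F_HI, N_BANDS + 2)
    centers = edges[1:-1]
    W = np.zeros((N_BANDS, freqs.size))
    for b in range(N_BANDS):
        lo, mid, hi = edges[b], edges[b + 1], edges[b + 2]
        lo = min(lo, mid - df)
        hi = max(hi, mid + df)
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        W[b] = np.clip(np.minimum(up, down), 0.0, None)
        W[b] /= W[b].sum()
    return W, centers


def auditory_spectrogram(audio: AudioTrack) -> AuditorySpectrogram:
    """128-band auditory spectrogram at 200 Hz frames.

    Raises if the sampling rate cannot represent the 4 kHz upper band edge.
    """
    if audio.rate < 8000.0:
        raise ValueError("audio rate must be at least 8 kHz for the 4 kHz band edge")
    hop = audio.rate / SPECTROGRAM_RATE
    if abs(hop - round(hop)) > 1e-9:
        raise ValueError("audio rate must be an integer multiple of 200 Hz")
    hop = int(round(hop))
    nperseg = 8 * hop  # 40 ms analysis window (25 Hz bin spacing at 16 kHz)
    freqs, _, Z = signal.stft(
        audio.samples,
        fs=audio.rate,
        nperseg=nperseg,
        noverlap=nperseg - hop,
        window="hann",
        boundary="zeros",
        padded=True,
    )
    mag = np.abs(Z)
    W, centers = _band_matrix(freqs)
    values = W @ mag
    return AuditorySpectrogram(values=values, center_frequencies=centers)


class ModulationSpectrum:
    """Summed narrowband-envelope DFT amplitude, reference-normalized."""

    def __init__(self, frequencies: np.ndarray, amplitude: np.ndarray):
        self.frequencies = np.asarray(frequencies, dtype=float)
        self.amplitude = np.asarray(amplitude, dtype=float)

    def at(self, f: float) -> float:
        """Amplitude at the bin nearest to ``f`` Hz."""
        return float(self.amplitude[np.argmin(np.abs(self.frequencies - f))])


def _summed_dft(spec: AuditorySpectrogram) -> np.ndarray:
    # remove each band's mean so the DC peak does not swamp the modulations
    v = spec.values - spec.values.mean(axis=1, keepdims=True)
    return np.abs(np.fft.rfft(v, axis=1)).sum(axis=0)


def modulation_spectrum(audio: AudioTrack, reference: AudioTrack) -> ModulationSpectrum:
    """Modulation spectrum of ``audio`` normalized by the reference's maximum.

    Both tracks go through the auditory front end; each of the 128 narrowband
    envelopes is DFT-transformed over the full track (single window), the
    amplitude spectra are summed over bands, and the result is divided by the
    maximal amplitude of the reference (anechoic) stimulus so the reference
    peaks at 1.
    """
    if audio.rate != reference.rate:
        raise ValueError("audio and reference must share a sampling rate")
    spec = auditory_spectrogram(audio)
    ref = auditory_spectrogram(reference)
    n = min(spec.n_frames, ref.n_frames)
    amp = _summed_dft(
        AuditorySpectrogram(spec.values[:, :n], spec.center_frequencies)
    )
    ref_amp = _summed_dft(
        AuditorySpectrogram(ref.values[:, :n], ref.center_frequencies)
    )
    peak = ref_amp.max()
    if peak == 0:
        raise ValueError("silent reference")
    freqs = np.fft.rfftfreq(n, 1.0 / SPECTROGRAM_RATE)
    return ModulationSpectrum(freqs, amp / peak)
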