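"""Stimulus-response phase coherence spectrum and its shuffle null.

Both signals are cut into non-overlapping epochs (2 s by default, giving a
0.5 Hz bin grid), each epoch is DFT-transformed with a rectangular window,
and the per-epoch phase difference ``theta_ft = alpha_ft - beta_ft`` between
stimulus and response is summarized by its mean resultant length

    C(f) = | (1/T) sum_t exp(i theta_ft) |,

which is 1 for perfectly phase-locked signals and ~0.886/sqrt(T) on average
for independent ones.  Chance level is estimated by shuffling the stimulus
epochs so envelope and response are randomly paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EnvelopeTrack, Recording

__all__ = [
    "EpochPhases",
    "CoherenceResult",
    "epoch_phases",
    "coherence",
    "coherence_spectrum",
    "chance_null",
]


@dataclass(frozen=True)
class EpochPhases:
    """Per-epoch DFT phases of a stimulus/response pair on a common bin grid."""

    frequencies: np.ndarray  # Hz, one per DFT bin
    alpha: np.ndarray  # stimulus phase, bins x epochs
    beta: np.ndarray  # response phase, bins x epochs

    @property
    def theta(self) -> np.ndarray:
        """Phase difference alpha - beta, wrapped to (-pi, pi]."""
        d = self.alpha - self.beta
        return np.angle(np.exp(1j * d))

    @property
    def n_epochs(self) -> int:
        return self.alpha.shape[1]


@dataclass(frozen=True)
class CoherenceResult:
    """Observed coherence with its shuffle-null distribution and p-values."""

    frequencies: np.ndarray
    observed: np.ndarray  # channel-averaged C(f)
    per_channel: np.ndarray  # channels x bins
    null: np.ndarray  # shuffles x bins (channel-averaged)
    p_values: np.ndarray  # one-sided (M+1)/(n_shuffles+1)

    @property
    def chance_level(self) -> np.ndarray:
        return self.null.mean(axis=0)


def _epoch_fft(x: np.ndarray, n_per_epoch: int) -> np.ndarray:
    """Complex epoch spectra (bins x epochs); trailing partial epoch dropped."""
    n_epochs = x.size // n_per_epoch
    if n_epochs < 1:
        raise ValueError("signal shorter than one epoch")
    segs = x[: n_epochs * n_per_epoch].reshape(n_epochs, n_per_epoch)
    return np.fft.rfft(segs, axis=1).T


def epoch_phases(
    stim: EnvelopeTrack, resp: np.ndarray, epoch_len_s: float = 2.0
) -> EpochPhases:
    """DFT phases of stimulus and one response channel in fixed epochs."""
    resp = np.asarray(resp, dtype=float)
    if resp.ndim != 1:
        raise ValueError("resp must be a 1-D channel time series")
    n = min(len(stim), resp.size)
    n_per = epoch_len_s * stim.rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch length must be an integer number of samples")
    n_per = int(round(n_per))
    if n < n_per:
        raise ValueError("signal shorter than one epoch")
    S = _epoch_fft(stim.values[:n], n_per)
    R = _epoch_fft(resp[:n], n_per)
    freqs = np.fft.rfftfreq(n_per, 1.0 / stim.rate)
    return EpochPhases(frequencies=freqs, alpha=np.angle(S), beta=np.angle(R))


def coherence(phases: EpochPhases) -> np.ndarray:
    """Mean resultant length of the phase difference, per frequency bin."""
    if phases.n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    return np.abs(np.exp(1j * phases.theta).mean(axis=1))


def coherence_spectrum(
    stim: EnvelopeTrack, resp, epoch_len_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """(frequencies, C) between a stimulus envelope and a response.

    ``resp`` may be a 1-D array, an :class:`EnvelopeTrack` or a
    :class:`Recording`; for a recording C(f) is computed per channel
    (channels x bins).
    """
    if isinstance(resp, Recording):
        rows = [coherence(epoch_phases(stim, ch, epoch_len_s)) for ch in resp.data]
        ph = epoch_phases(stim, resp.data[0], epoch_len_s)
        return ph.frequencies, np.array(rows)
    if isinstance(resp, EnvelopeTrack):
        resp = resp.values
    ph = epoch_phases(stim, resp, epoch_len_s)
    return ph.frequencies, coherence(ph)


def _phasors(stim: EnvelopeTrack, rec: Recording, epoch_len_s: float, f_max: float):
    n_per = int(round(epoch_len_s * stim.rate))
    n = min(len(stim), rec.n_samples)
    freqs = np.fft.rfftfreq(n_per, 1.0 / stim.rate)
    keep = freqs <= f_max
    S = _epoch_fft(stim.values[:n], n_per)[keep]
    U = np.exp(1j * np.angle(S))  # bins x epochs
    V = np.empty((rec.n_channels,) + U.shape, dtype=complex)
    for c, ch in enumerate(rec.data):
        R = _epoch_fft(ch[:n], n_per)[keep]
        V[c] = np.exp(1j * np.angle(R))
    return freqs[keep], U, V


def chance_null(
    stim,
    resp,
    n_shuffles: int = 5000,
    seed: int = 0,
    epoch_len_s: float = 2.0,
    f_max: float = 20.0,
) -> CoherenceResult:
    """Observed coherence vs the epoch-shuffle null, with one-sided p-values.

    Stimulus epochs are permuted (uniformly, identity included) while the
    response epoch order stays fixed; the coherence of each random pairing is
    averaged across channels -- and across participants when ``stim``/``resp``
    are matching lists -- before comparison.  The p-value at each frequency is
    ``(M + 1) / (n_shuffles + 1)`` where ``M`` counts null values strictly
    exceeding the observed value.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    stims = stim if isinstance(stim, (list, tuple)) else [stim]
    recs = resp if isinstance(resp, (list, tuple)) else [resp]
    if len(stims) != len(recs):
        raise ValueError("stim and resp lists must have equal length")
    recs = [r if isinstance(r, Recording) else Recording(np.atleast_2d(
        r.values if isinstance(r, EnvelopeTrack) else np.asarray(r, float)), stims[i].rate)
        for i, r in enumerate(recs)]

    pairs = [_phasors(s, r, epoch_len_s, f_max) for s, r in zip(stims, recs)]
    freqs = pairs[0][0]
    n_epochs = min(p[1].shape[1] for p in pairs)
    pairs = [(f, U[:, :n_epochs], V[:, :, :n_epochs]) for f, U, V in pairs]

    # observed: channel- (and participant-) averaged C(f)
    per_channel = []
    for _, U, V in pairs:
        per_channel.append(np.abs((U[None] * np.conj(V)).mean(axis=2)))
    per_channel = np.vstack(per_channel)
    observed = per_channel.mean(axis=0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, freqs.size))
    for k in range(n_shuffles):
        perm = rng.permutation(n_epochs)
        acc = np.zeros(freqs.size)
        n_ch = 0
        for _, U, V in pairs:
            Up = U[:, perm]
            acc += np.abs((Up[None, :, :] * np.conj(V)).mean(axis=2)).sum(axis=0)
            n_ch += V.shape[0]
        null[k] = acc / n_ch

    M = (null > observed[None, :]).sum(axis=0)
    p = (M + 1) / (n_shuffles + 1)
    return CoherenceResult(
        frequencies=freqs,
        observed=observed,
        per_channel=per_channel,
        null=null,
        p_values=p,
    )
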