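"""Echoic mixture construction, RMS gain, pauses, vocoding, envelopes."""

import numpy as np
import pytest

from echostream.containers import AudioTrack, EchoSpec, EnvelopeTrack
from echostream.stimulus import (
    echo_related_frequencies,
    extract_envelope_broadband,
    make_echoic,
    rms_gain_db,
    segment_pauses,
    vocode_one_channel,
)
from echostream.synth import SynthConfig, speech_like_audio

RATE = 16000.0


def test_impulse_superposition():
    x = np.zeros(int(0.5 * RATE))
    x[1000] = 1.0
    out = make_echoic(AudioTrack(x, RATE), EchoSpec.fixed(0.125, 1.0))
    shift = int(0.125 * RATE)
    assert out.samples[1000] == 1.0
    assert out.samples[1000 + shift] == 1.0
    assert np.count_nonzero(out.samples) == 2
    assert len(out) == len(x) + shift


def test_antiphase_sinusoid_cancels_in_overlap():
    t = np.arange(int(2 * RATE)) / RATE
    x = np.sin(2 * np.pi * 4.0 * t)  # period 0.25 s = 2 * tau
    out = make_echoic(AudioTrack(x, RATE), EchoSpec.fixed(0.125, 1.0))
    shift = int(0.125 * RATE)
    overlap = out.samples[shift : len(x)]
    assert np.max(np.abs(overlap)) < 1e-9


def test_linearity_of_echo_mixing():
    rng = np.random.default_rng(0)
    a = rng.standard_normal(4000)
    b = rng.standard_normal(4000)
    spec = EchoSpec.fixed(0.125, 0.7)
    mixed = make_echoic(AudioTrack(a + b, RATE), spec)
    parts = (
        make_echoic(AudioTrack(a, RATE), spec).samples
        + make_echoic(AudioTrack(b, RATE), spec).samples
    )
    np.testing.assert_allclose(mixed.samples, parts, atol=1e-12)


def test_non_integer_delay_rejected():
    x = np.ones(1000)
    with pytest.raises(ValueError, match="0.1003"):
        make_echoic(AudioTrack(x, 997.0), EchoSpec.fixed(0.1003, 1.0))
    with pytest.raises(ValueError, match="empty"):
        make_echoic(AudioTrack(np.array([]), RATE), EchoSpec.fixed(0.125, 1.0))


def test_rms_gain_identity_and_silence():
    x = AudioTrack(np.sin(np.arange(8000) / 5.0), RATE)
    assert rms_gain_db(x, x) == pytest.approx(0.0)
    silent = AudioTrack(np.zeros(8000), RATE)
    with pytest.raises(ValueError):
        rms_gain_db(silent, x)


@pytest.mark.parametrize(
    "amplitude, expected_db",
    [(1.0, 10 * np.log10(2.0)), (0.5, 10 * np.log10(1.25))],
    ids=["0dB-echo", "6dB-echo"],
)
def test_rms_gain_on_decorrelated_speech(speech_audio_60s, amplitude, expected_db):
    """A unit-gain echo adds 3.01 dB; the A=0.5 convention adds 0.97 dB."""
    mix = make_echoic(speech_audio_60s, EchoSpec.fixed(0.125, amplitude))
    assert rms_gain_db(mix, speech_audio_60s) == pytest.approx(expected_db, abs=0.05)


def test_mixture_power_approaches_sum_of_powers():
    """For decorrelated signals, power(mixture) -> (A^2 + 1) power(s)."""
    for dur, tol in ((20.0, 0.06), (80.0, 0.03)):
        audio = speech_like_audio(SynthConfig(duration_s=dur, seed=21))
        mix = make_echoic(audio, EchoSpec.fixed(0.25, 1.0))
        n0 = int(0.25 * RATE)
        ratio = np.mean(mix.samples[n0 : len(audio)] ** 2) / np.mean(
            audio.samples[n0:] ** 2
        )
        assert ratio == pytest.approx(2.0, rel=tol)


@pytest.mark.parametrize(
    "delay, f_max, expected",
    [
        (0.125, 10.0, [4.0]),
        (0.25, 10.0, [2.0, 6.0]),
        (0.25, 15.0, [2.0, 6.0, 10.0, 14.0]),
    ],
)
def test_echo_related_frequencies(delay, f_max, expected):
    assert echo_related_frequencies(delay, f_max) == pytest.approx(expected)


def test_comb_transfer_zeros_only_at_echo_frequencies():
    """|A + e^{-i 2 pi f tau}| vanishes iff A = 1 and f = (2k-1)/(2 tau)."""
    tau = 0.125
    f = np.linspace(0.01, 15.0, 40001)
    mag_unit = np.abs(1.0 + np.exp(-2j * np.pi * f * tau))
    zeros = f[mag_unit < 1e-3]
    expected = echo_related_frequencies(tau, 15.0)
    for z in expected:
        assert np.min(np.abs(zeros - z)) < 1e-2
    assert np.all(np.min(np.abs(zeros[:, None] - np.array(expected)), axis=1) < 0.01)
    mag_half = np.abs(0.5 + np.exp(-2j * np.pi * f * tau))
    assert mag_half.min() > 0.4


def test_segment_pauses_degenerate_and_constructed():
    silent = EnvelopeTrack(np.zeros(500), 100.0)
    assert segment_pauses(silent, 0.5) == [(0.0, 5.0)]

    env = np.ones(1000)
    env[300:360] = 0.0  # 0.6-s gap
    pauses = segment_pauses(EnvelopeTrack(env, 100.0), 0.5)
    assert len(pauses) == 1
    start, end = pauses[0]
    assert start == pytest.approx(3.0, abs=0.02)
    assert end == pytest.approx(3.6, abs=0.02)


def test_inter_pause_intervals_match_narration_statistics(speech_env_600s):
    """Pauses >500 ms recur every ~3.4 s on average in the generated speech."""
    pauses = segment_pauses(speech_env_600s, 0.5)
    assert len(pauses) > 50
    starts = np.array([p[0] for p in pauses])
    ends = np.array([p[1] for p in pauses])
    intervals = starts[1:] - ends[:-1]
    assert np.mean(intervals) == pytest.approx(3.4, abs=0.8)


def test_vocoder_preserves_level_and_envelope(speech_audio_60s):
    spec = EchoSpec.fixed(0.125, 1.0)
    voc = vocode_one_channel(speech_audio_60s, spec, seed=3)
    mix = make_echoic(speech_audio_60s, spec)
    rms_ratio = np.sqrt(np.mean(voc.samples**2) / np.mean(mix.samples**2))
    assert rms_ratio == pytest.approx(1.0, abs=1e-6)
    env_v = extract_envelope_broadband(voc).values
    env_m = extract_envelope_broadband(mix).values
    n = min(env_v.size, env_m.size)
    assert np.corrcoef(env_v[:n], env_m[:n])[0, 1] > 0.9


def test_vocoder_silent_input_and_rate_guard():
    silent = AudioTrack(np.zeros(int(2 * RATE)), RATE)
    out = vocode_one_channel(silent, EchoSpec.fixed(0.125, 1.0), seed=0)
    assert np.allclose(out.samples, 0.0)
    low = AudioTrack(np.zeros(8000), 8000.0)
    with pytest.raises(ValueError, match="8 kHz"):
        vocode_one_channel(low, EchoSpec.fixed(0.125, 1.0), seed=0)


def test_vocoder_removes_fine_structure(speech_audio_60s):
    """Spectral flatness of the carrier band rises after vocoding."""
    from scipy.signal import welch

    t = np.arange(int(10 * RATE)) / RATE
    harm = sum(np.sin(2 * np.pi * f0 * t) for f0 in (220, 440, 660, 880, 1320))
    harm = AudioTrack(harm * (1 + 0.5 * np.sin(2 * np.pi * 3 * t)), RATE)
    voc = vocode_one_channel(harm, EchoSpec.fixed(0.125, 1.0), seed=1)

    def flatness(x):
        f, p = welch(x, fs=RATE, nperseg=4096)
        band = p[(f > 150) & (f < 2000)]
        return np.exp(np.mean(np.log(band + 1e-20))) / band.mean()

    assert flatness(voc.samples) > 10 * flatness(harm.samples)


def test_envelope_of_constant_and_tone():
    const = AudioTrack(np.full(int(2 * RATE), 0.5), RATE)
    env = extract_envelope_broadband(const)
    mid = env.values[50:-50]
    assert np.allclose(mid, 0.5, atol=0.01)

    a = 0.8
    t = np.arange(int(4 * RATE)) / RATE
    tone = AudioTrack(a * np.sin(2 * np.pi * 1000.0 * t), RATE)
    env = extract_envelope_broadband(tone)
    assert np.median(env.values[100:-100]) == pytest.approx(2 * a / np.pi, rel=0.02)


def test_envelope_tracks_amplitude_modulation():
    t = np.arange(int(8 * RATE)) / RATE
    am = (1 + 0.9 * np.sin(2 * np.pi * 4.0 * t)) * np.sin(2 * np.pi * 1000.0 * t)
    env = extract_envelope_broadband(AudioTrack(am, RATE))
    spec = np.abs(np.fft.rfft(env.values - env.values.mean()))
    freqs = np.fft.rfftfreq(env.values.size, 1 / 100.0)
    assert freqs[np.argmax(spec)] == pytest.approx(4.0, abs=0.2)


def test_wav_roundtrip(tmp_path):
    from echostream.stimulus import read_wav, write_wav

    rng = np.random.default_rng(3)
    audio = AudioTrack(rng.uniform(-0.5, 0.5, 16000), RATE)
    path = tmp_path / "clip.wav"
    write_wav(path, audio)
    back = read_wav(path)
    assert back.rate == RATE
    np.testing.assert_allclose(back.samples, audio.samples, atol=1e-6)
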