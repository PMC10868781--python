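"""TRF designs, ridge estimation, cross-validated predictive power."""

import numpy as np
import pytest

from echostream.containers import EchoSpec
from echostream.synth import SynthConfig, _native_envelope, synth_recording
from echostream.trf import (
    bandlimited_trf,
    build_design,
    cross_validate,
    default_lambda_grid,
    fit_ridge,
    gather_response,
    model_streams,
    predict,
    trf_predictive_power,
)


def test_design_shape_and_boundary_handling():
    rng = np.random.default_rng(0)
    x = rng.random(1000)
    design = build_design([[x]], n_lags=100)
    assert design.matrix.shape == (900, 100)
    # row t holds x(t-1) .. x(t-100)
    np.testing.assert_array_equal(design.matrix[0], x[99::-1])
    two = build_design([[x], [x[:500]]], n_lags=100)
    assert two.matrix.shape == (900 + 400, 100)
    with pytest.raises(ValueError, match="shorter"):
        build_design([[x[:50]]], n_lags=100)


def test_streaming_design_rank_deficient_for_single_delay():
    """With s_e(t) = s_d(t - d) in one condition the two-stream design is
    singular up to the shift; pooling two delays restores identifiability."""
    rng = np.random.default_rng(1)
    x = rng.random(4000)

    def shifted(x, d):
        return np.concatenate([np.zeros(d), x[:-d]])

    single = build_design([[x, shifted(x, 12)]], n_lags=60)
    s = np.linalg.svd(single.matrix - single.matrix.mean(0), compute_uv=False)
    assert s[-1] / s[0] < 1e-6

    y = rng.random(4000)
    pooled = build_design(
        [[x, shifted(x, 12)], [y, shifted(y, 25)]], n_lags=60
    )
    assert pooled.condition_number() < single.condition_number() / 10


def test_ridge_limits():
    rng = np.random.default_rng(2)
    n = 400
    X = np.linalg.qr(rng.standard_normal((n, 20)))[0]  # orthonormal columns
    w_true = rng.standard_normal(20)
    y = X @ w_true
    ols = fit_ridge(X, y, 0.0)
    Xc = X - X.mean(0)
    w_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    np.testing.assert_allclose(ols.weights[:, 0], w_ols, atol=1e-8)

    shrunk = fit_ridge(X, y, 1e9)
    assert np.max(np.abs(shrunk.weights)) < 1e-6
    with pytest.raises(ValueError):
        fit_ridge(X, y, -1.0)


def test_closed_form_matches_augmented_least_squares():
    """Ridge oracle: solving [X; sqrt(lam) I] by lstsq gives the same kernels."""
    rng = np.random.default_rng(3)
    X = rng.standard_normal((300, 15))
    y = rng.standard_normal(300)
    lam = 3.7
    model = fit_ridge(X, y, lam)
    Xc = X - X.mean(0)
    aug = np.vstack([Xc, np.sqrt(lam) * np.eye(15)])
    target = np.concatenate([y - y.mean(), np.zeros(15)])
    w_ref = np.linalg.lstsq(aug, target, rcond=None)[0]
    np.testing.assert_allclose(model.weights[:, 0], w_ref, atol=1e-6)


def test_noiseless_kernel_recovery():
    """lambda -> 0 on noiseless streaming data recovers the ground truth."""
    from echostream.synth import default_kernels

    cfg = SynthConfig(duration_s=90.0, n_channels=3, regime="streaming",
                      snr_db=np.inf, seed=4)
    sessions, resps = [], []
    for delay in (0.125, 0.25):
        env = _native_envelope(np.random.default_rng(int(delay * 1e4)), cfg)
        ses = synth_recording(env, EchoSpec.fixed(delay, 1.0), cfg)
        sessions.append(model_streams(ses, "streaming"))
        resps.append(ses.recording.data)
    design = build_design(sessions, 100)
    Y = gather_response(design, resps)
    model = fit_ridge(design.matrix, Y, 1e-8 * np.var(design.matrix), n_lags=100)
    truth = default_kernels("streaming")
    for si, name in enumerate(("direct", "echo")):
        for c in range(3):
            r = np.corrcoef(model.kernels[si, :, c], truth[name])[0, 1]
            assert abs(r) >= 0.99


def test_prediction_roundtrip():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((500, 10))
    y = X @ rng.standard_normal(10) + 3.0
    model = fit_ridge(X, y, 1e-6)
    pred = predict(model, X)
    assert np.corrcoef(pred[:, 0], y)[0, 1] > 0.999


def test_cv_on_pure_noise_gives_null_power():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((4000, 30))
    y = rng.standard_normal(4000)
    pp = cross_validate(X, y, n_folds=10)
    assert pp.fold_powers.shape == (10, 1)
    assert abs(pp.mean) < 2 / np.sqrt(4000 / 10)
    assert np.all(np.isfinite(pp.fold_powers))


def test_cv_selects_lambda_on_training_folds_only():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((2000, 20))
    y = X @ rng.standard_normal(20) + 0.5 * rng.standard_normal(2000)
    pp = cross_validate(X, y, n_folds=10)
    grid = default_lambda_grid(X)
    assert np.all(np.isin(pp.selected_lambdas, grid))
    assert pp.mean > 0.8


@pytest.fixture(scope="module")
def regime_participants():
    """Pooled-delay sessions for 6 participants under two regimes."""
    out = {}
    for regime in ("streaming", "mixture"):
        participants = []
        for p in range(6):
            cfg = SynthConfig(duration_s=60.0, n_channels=16, regime=regime,
                              snr_db=-10.0, seed=900 + p)
            rng = np.random.default_rng(900 + p)
            sessions = [
                synth_recording(
                    _native_envelope(np.random.default_rng(rng.integers(2**31)), cfg),
                    EchoSpec.fixed(delay, 1.0), cfg,
                )
                for delay in (0.125, 0.25)
            ]
            participants.append(sessions)
        out[regime] = participants
    return out


def _power(sessions, kind):
    streams = [model_streams(s, kind) for s in sessions]
    resps = [s.recording.data for s in sessions]
    return trf_predictive_power(streams, resps, 100).mean


def test_streaming_model_wins_on_streaming_regime(regime_participants):
    """Paired across participants, the generating (streaming) model beats the
    mixture model on held-out data."""
    from echostream.stats import exact_permutation_p

    diffs = [
        _power(sess, "streaming") - _power(sess, "mixture")
        for sess in regime_participants["streaming"]
    ]
    assert exact_permutation_p(diffs) < 0.05


def test_mixture_model_wins_on_mixture_regime(regime_participants):
    """When the response encodes the mixture as a whole (the vocoded analog),
    the mixture model explains held-out data at least as well as streaming."""
    diffs = [
        _power(sess, "mixture") - _power(sess, "streaming")
        for sess in regime_participants["mixture"]
    ]
    assert np.mean(diffs) > 0


def test_adapted_trf_identity_corner_reduces_to_plain_trf():
    from echostream.adaptation import AdaptationParams, adapted_envelope
    from echostream.containers import AuditorySpectrogram
    from echostream.trf import fit_adapted_trf

    rng = np.random.default_rng(8)
    vals = rng.random((8, 4000))
    spec = AuditorySpectrogram(vals, np.geomspace(200, 4000, 8), 200.0)
    identity = AdaptationParams(0.0, 0.0, 0.0)
    env = adapted_envelope(spec, identity).values
    resp = np.convolve(env, rng.standard_normal(30))[: env.size][None, :]

    power_plain = trf_predictive_power([[env]], [resp], n_lags=40).mean
    (power_adapted, chosen) = fit_adapted_trf([[spec]], [resp], [identity], n_lags=40)
    assert chosen == identity
    assert power_adapted.mean == pytest.approx(power_plain, abs=1e-10)


def test_bandlimited_equals_manual_filtering_and_validates():
    from echostream.pipeline import bandpass_fir

    rng = np.random.default_rng(9)
    x = rng.random(3000)
    resp = rng.standard_normal((2, 3000))
    got = bandlimited_trf([[x]], [resp], band=(0.8, 5.0), n_lags=50, n_folds=5)
    xf = bandpass_fir(x, 100.0, 0.8, 5.0)
    rf = np.vstack([bandpass_fir(ch, 100.0, 0.8, 5.0) for ch in resp])
    ref = trf_predictive_power([[xf]], [rf], n_lags=50, n_folds=5)
    np.testing.assert_allclose(got.fold_powers, ref.fold_powers, atol=1e-12)
    with pytest.raises(ValueError, match="low < high"):
        bandlimited_trf([[x]], [resp], band=(5.0, 0.8))


def test_band_split_dissociates_regimes(regime_participants):
    """Streaming evidence concentrates in the low band on streaming-regime
    data; mixture encoding survives in the high band on mixture-regime data."""
    def band_diff(participants, a, b, band):
        vals = []
        for sessions in participants:
            powers = {}
            for kind in (a, b):
                streams = [model_streams(s, kind) for s in sessions]
                resps = [s.recording.data for s in sessions]
                powers[kind] = bandlimited_trf(streams, resps, band, n_lags=100).mean
            vals.append(powers[a] - powers[b])
        return np.mean(vals)

    low = band_diff(regime_participants["streaming"], "streaming", "mixture", (0.8, 5.0))
    assert low > 0
    high = band_diff(regime_participants["mixture"], "mixture", "idealized", (5.0, 10.0))
    assert high > 0
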