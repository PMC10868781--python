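"""Temporal response function (TRF) encoding models.

A TRF is a linear kernel mapping lagged stimulus envelopes to the neural
response.  Three model kinds differ only in their predictor streams:

* ``mixture``   -- the envelope of the echoic mixture (one stream);
* ``streaming`` -- the direct-sound and echo envelopes as two streams with
  separate kernels (the stream-segregation hypothesis);
* ``idealized`` -- the direct-sound envelope alone.

Kernels span lags 1..D samples (10 ms .. 1 s at 100 Hz, D = 100) and are
estimated per channel by ridge regression.  Predictive power is the Pearson
correlation between held-out response and prediction under 10-fold
cross-validation with contiguous folds; the ridge strength is selected by
nested cross-validation on the training folds only.  With a single fixed
echo delay the direct and echo streams are identical up to a shift and the
streaming design is rank-deficient; pooling sessions with different delays
restores identifiability, so multi-delay sessions are concatenated with lag
windows never crossing a session boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ANALYSIS_RATE

__all__ = [
    "LaggedDesign",
    "TRFModel",
    "PredictivePower",
    "MODEL_KINDS",
    "model_streams",
    "build_design",
    "fit_ridge",
    "predict",
    "cross_validate",
    "fit_adapted_trf",
    "bandlimited_trf",
]

MODEL_KINDS = ("mixture", "streaming", "idealized")
DEFAULT_N_LAGS = 100  # 1 s at 100 Hz


def model_streams(session, kind: str) -> list[np.ndarray]:
    """Predictor streams of a synthetic session for a given model kind."""
    if kind == "mixture":
        return [session.mixture.values]
    if kind == "streaming":
        return [session.direct.values, session.echo.values]
    if kind == "idealized":
        return [session.direct.values]
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


@dataclass(frozen=True)
class LaggedDesign:
    """Lag-expanded predictors pooled over sessions.

    ``matrix`` has one row per usable response sample and ``n_streams *
    n_lags`` columns ordered stream-major; ``row_slices`` give each pooled
    session's rows; ``response_rows`` are the per-session sample indices the
    rows align to (the first ``n_lags`` samples of every session are dropped
    so no lag window crosses a boundary).
    """

    matrix: np.ndarray
    n_streams: int
    n_lags: int
    row_slices: tuple
    response_rows: tuple

    def condition_number(self) -> float:
        """Ratio of largest to smallest singular value (collinearity check)."""
        s = np.linalg.svd(self.matrix - self.matrix.mean(0), compute_uv=False)
        return float(s[0] / max(s[-1], np.finfo(float).tiny))


def _lag_block(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Rows t = n_lags..n-1 of [x(t-1), ..., x(t-n_lags)]."""
    windows = np.lib.stride_tricks.sliding_window_view(x, n_lags)
    return windows[: x.size - n_lags, ::-1]


def build_design(sessions, n_lags: int = DEFAULT_N_LAGS) -> LaggedDesign:
    """Assemble the lag design from pooled sessions.

    ``sessions`` is a list of stream lists: each session contributes the same
    number of streams (1 or 2), all of equal length within the session.
    """
    if not sessions:
        raise ValueError("need at least one session")
    n_streams = len(sessions[0])
    blocks, slices, resp_rows = [], [], []
    row0 = 0
    for streams in sessions:
        if len(streams) != n_streams:
            raise ValueError("all sessions must have the same number of streams")
        n = min(s.size for s in streams)
        if n <= n_lags:
            raise ValueError("session shorter than the lag window")
        block = np.hstack([_lag_block(np.asarray(s, float)[:n], n_lags) for s in streams])
        blocks.append(block)
        slices.append(slice(row0, row0 + block.shape[0]))
        resp_rows.append(np.arange(n_lags, n))
        row0 += block.shape[0]
    return LaggedDesign(
        matrix=np.vstack(blocks),
        n_streams=n_streams,
        n_lags=n_lags,
        row_slices=tuple(slices),
        response_rows=tuple(resp_rows),
    )


def gather_response(design: LaggedDesign, responses) -> np.ndarray:
    """Stack per-session responses (channels x time) into design-aligned rows."""
    rows = []
    for resp, idx in zip(responses, design.response_rows):
        arr = np.atleast_2d(np.asarray(resp, float))
        rows.append(arr[:, idx].T)
    return np.vstack(rows)


@dataclass(frozen=True)
class TRFModel:
    """Fitted kernels (streams x lags x channels) with their ridge strength."""

    kind: str
    kernels: np.ndarray
    ridge_lambda: float
    n_lags: int
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        """Flat (columns x channels) weight matrix."""
        s, d, c = self.kernels.shape
        return self.kernels.reshape(s * d, c)


@dataclass(frozen=True)
class PredictivePower:
    """Per-fold, per-channel held-out correlations from cross-validation."""

    fold_powers: np.ndarray  # n_folds x channels
    selected_lambdas: np.ndarray  # per fold

    @property
    def per_channel(self) -> np.ndarray:
        return self.fold_powers.mean(axis=0)

    @property
    def mean(self) -> float:
        return float(self.fold_powers.mean())


def fit_ridge(X: np.ndarray, Y: np.ndarray, lam: float, kind: str = "mixture",
              n_lags: int | None = None) -> TRFModel:
    """Closed-form ridge fit, intercept handled by mean-centering."""
    if lam < 0:
        raise ValueError("ridge strength must be nonnegative")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and response row counts differ")
    n_lags = n_lags or X.shape[1]
    mx = X.mean(axis=0)
    my = Y.mean(axis=0)
    Xc = X - mx
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    W = np.linalg.solve(A, Xc.T @ (Y - my))
    n_streams = X.shape[1] // n_lags
    return TRFModel(
        kind=kind,
        kernels=W.reshape(n_streams, n_lags, -1),
        ridge_lambda=float(lam),
        n_lags=n_lags,
        x_mean=mx,
        y_mean=my,
    )


def predict(model: TRFModel, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, float) - model.x_mean) @ model.weights + model.y_mean


def default_lambda_grid(X: np.ndarray) -> np.ndarray:
    """10^0 .. 10^6 times the mean design-column variance."""
    base = float(np.var(X, axis=0).mean())
    base = base if base > 0 else 1.0
    return base * 10.0 ** np.arange(0, 7)


class _FoldStats:
    """Sufficient statistics per contiguous fold for fast nested ridge CV."""

    def __init__(self, X, Y, n_folds):
        n = X.shape[0]
        edges = np.linspace(0, n, n_folds + 1).astype(int)
        self.slices = [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
        self.xtx = np.stack([X[s].T @ X[s] for s in self.slices])
        self.xty = np.stack([X[s].T @ Y[s] for s in self.slices])
        self.ytyd = np.stack([(Y[s] ** 2).sum(axis=0) for s in self.slices])
        self.xsum = np.stack([X[s].sum(axis=0) for s in self.slices])
        self.ysum = np.stack([Y[s].sum(axis=0) for s in self.slices])
        self.counts = np.array([s.stop - s.start for s in self.slices])

    def fit(self, train_mask, lam):
        from scipy.linalg import cho_factor, cho_solve

        xtx = self.xtx[train_mask].sum(0)
        xty = self.xty[train_mask].sum(0)
        xs = self.xsum[train_mask].sum(0)
        ys = self.ysum[train_mask].sum(0)
        n = self.counts[train_mask].sum()
        cxx = xtx - np.outer(xs, xs) / n
        cxy = xty - np.outer(xs, ys) / n
        cxx.flat[:: cxx.shape[0] + 1] += lam
        return cho_solve(cho_factor(cxx, lower=True, check_finite=False), cxy,
                         check_finite=False)

    def test_corr(self, W, j):
        """Per-channel Pearson r of X_j @ W against Y_j (shift-invariant)."""
        n = self.counts[j]
        pred_sum = self.xsum[j] @ W
        pred_sq = ((self.xtx[j] @ W) * W).sum(axis=0)
        cov = (self.xty[j] * W).sum(axis=0) / n - pred_sum * self.ysum[j] / n**2
        var_p = pred_sq / n - (pred_sum / n) ** 2
        var_y = self.ytyd[j] / n - (self.ysum[j] / n) ** 2
        denom = np.sqrt(np.maximum(var_p * var_y, 0.0))
        out = np.zeros_like(cov)
        ok = denom > 0
        out[ok] = cov[ok] / denom[ok]
        return out


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    lam_grid=None,
    n_folds: int = 10,
) -> PredictivePower:
    """10-fold CV predictive power with nested ridge-strength selection.

    Folds are contiguous time blocks.  For each held-out fold the ridge
    strength is chosen to maximize the mean correlation over the remaining
    folds in an inner leave-one-fold-out loop (the held-out fold never
    influences the choice); the selected model is then scored on the
    held-out fold, per channel.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] < n_folds:
        raise ValueError("fewer rows than folds")
    if lam_grid is None:
        lam_grid = default_lambda_grid(X)
    lam_grid = np.asarray(lam_grid, float)

    stats = _FoldStats(X, Y, n_folds)
    fold_powers = np.empty((n_folds, Y.shape[1]))
    chosen = np.empty(n_folds)
    for k in range(n_folds):
        outer_mask = np.ones(n_folds, bool)
        outer_mask[k] = False
        inner_scores = np.zeros(lam_grid.size)
        for li, lam in enumerate(lam_grid):
            vals = []
            for j in range(n_folds):
                if j == k:
                    continue
                m = outer_mask.copy()
                m[j] = False
                W = stats.fit(m, lam)
                vals.append(stats.test_corr(W, j).mean())
            inner_scores[li] = np.mean(vals)
        li = int(np.argmax(inner_scores))
        chosen[k] = lam_grid[li]
        W = stats.fit(outer_mask, lam_grid[li])
        fold_powers[k] = stats.test_corr(W, k)
    return PredictivePower(fold_powers=fold_powers, selected_lambdas=chosen)


def trf_predictive_power(
    sessions, responses, n_lags: int = DEFAULT_N_LAGS, lam_grid=None, n_folds: int = 10
) -> PredictivePower:
    """Design assembly + cross-validation in one call."""
    design = build_design(sessions, n_lags)
    Y = gather_response(design, responses)
    return cross_validate(design.matrix, Y, lam_grid, n_folds)


def fit_adapted_trf(
    stream_spectrograms,
    responses,
    param_grid,
    n_lags: int = DEFAULT_N_LAGS,
    lam_grid=None,
    n_folds: int = 10,
    out_rate: float = ANALYSIS_RATE,
):
    """TRF on adaptation-transformed inputs, adaptation parameters gridded.

    ``stream_spectrograms`` is a list of sessions, each a list of per-stream
    :class:`AuditorySpectrogram` objects.  Every stream is passed through the
    adaptation cascade (its channel-summed output resampled to the analysis
    rate) before lag expansion; the grid point maximizing the mean CV
    predictive power is returned as ``(power, params)``.
    """
    from .adaptation import adapted_envelope

    best = None
    for p in param_grid:
        sessions = [
            [adapted_envelope(spec, p, out_rate).values for spec in streams]
            for streams in stream_spectrograms
        ]
        power = trf_predictive_power(sessions, responses, n_lags, lam_grid, n_folds)
        if best is None or power.mean > best[0].mean:
            best = (power, p)
    return best


def bandlimited_trf(
    sessions,
    responses,
    band: tuple[float, float],
    rate: float = ANALYSIS_RATE,
    n_lags: int = DEFAULT_N_LAGS,
    lam_grid=None,
    n_folds: int = 10,
) -> PredictivePower:
    """Cross-validated TRF after band-passing predictors and responses.

    ``band`` must lie within the 0.8-10 Hz analysis band; both the stimulus
    streams and the response channels are filtered with the same linear-phase
    FIR (delay-compensated), so their alignment is preserved.
    """
    from .pipeline import bandpass_fir

    lo, hi = band
    if not lo < hi:
        raise ValueError("band must be (low, high) with low < high")
    filt_sessions, filt_responses = [], []
    for streams, resp in zip(sessions, responses):
        filt_sessions.append([bandpass_fir(np.asarray(s, float), rate, lo, hi) for s in streams])
        arr = np.atleast_2d(np.asarray(resp, float))
        filt_responses.append(np.vstack([bandpass_fir(ch, rate, lo, hi) for ch in arr]))
    return trf_predictive_power(filt_sessions, filt_responses, n_lags, lam_grid, n_folds)
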