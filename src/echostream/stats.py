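"""Inferential machinery: exact sign-flip permutation test, unpaired
bootstrap, and Benjamini-Hochberg FDR correction.

The paired permutation test enumerates all ``2^N`` sign flips of the
per-participant condition differences; with ``M`` permuted means strictly
exceeding the observed mean, the one-sided significance level is
``(M + 1) / (2^N + 1)``.  The unpaired bootstrap resamples one group's
participants with replacement and counts resampled means strictly below the
other group's mean, giving ``(M + 1) / (n_boot + 1)``.  Ties count as not
exceeding in both tests (this is anti-conservative exactly at the tie margin
and follows the strict-inequality definition).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "exact_permutation_p",
    "sign_flip_p_montecarlo",
    "bootstrap_unpaired_p",
    "bca_interval",
    "fdr_adjust",
]

MAX_EXACT_N = 22  # 2^22 sign patterns; beyond this use the Monte-Carlo variant


def _perm_means(diffs: np.ndarray) -> np.ndarray:
    """Means of all 2^N sign-flip patterns (meet-in-the-middle enumeration)."""
    n = diffs.size
    half = n // 2
    def sums(d):
        out = np.zeros(1)
        for x in d:
            out = np.concatenate([out - x, out + x])
        return out
    return np.add.outer(sums(diffs[:half]), sums(diffs[half:])).ravel() / n


def exact_permutation_p(diffs) -> float:
    """One-sided exact sign-flip test that the mean difference is positive.

    Enumerates the full set of ``2^N`` sign flips.  Raises for ``N`` above
    22; use :func:`sign_flip_p_montecarlo` for larger samples.
    """
    diffs = np.asarray(diffs, float)
    if diffs.ndim != 1 or diffs.size < 1:
        raise ValueError("diffs must be a non-empty 1-D array")
    n = diffs.size
    if n > MAX_EXACT_N:
        raise ValueError(
            f"N = {n} exceeds the exact-enumeration limit ({MAX_EXACT_N}); "
            "use sign_flip_p_montecarlo instead"
        )
    observed = diffs.mean()
    perm = _perm_means(diffs)
    # values within float rounding of the observed mean are ties, not exceedances
    tol = 1e-9 * max(1.0, np.abs(diffs).max())
    m = int((perm > observed + tol).sum())
    return (m + 1) / (perm.size + 1)


def sign_flip_p_montecarlo(diffs, n_perm: int = 10000, seed: int = 0) -> float:
    """Monte-Carlo sign-flip test for samples too large to enumerate."""
    diffs = np.asarray(diffs, float)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    perm = (signs * diffs).mean(axis=1)
    m = int((perm > diffs.mean()).sum())
    return (m + 1) / (n_perm + 1)


def bootstrap_unpaired_p(group_a, group_b, n_boot: int = 10000, seed: int = 0) -> float:
    """One-sided unpaired bootstrap that group A's mean exceeds group B's.

    Group A is resampled with replacement ``n_boot`` times; ``M`` counts the
    resampled means strictly below ``mean(group_b)``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    means = a[idx].mean(axis=1)
    m = int((means < b.mean()).sum())
    return (m + 1) / (n_boot + 1)


def bca_interval(sample, alpha: float = 0.05, n_boot: int = 10000, seed: int = 0):
    """Bias-corrected and accelerated bootstrap interval for the mean."""
    from scipy.stats import norm

    x = np.asarray(sample, float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)
    boots = x[rng.integers(0, x.size, size=(n_boot, x.size))].mean(axis=1)
    theta = x.mean()
    z0 = norm.ppf(((boots < theta).sum() + 0.5) / (n_boot + 1))
    jack = (x.sum() - x) / (x.size - 1)
    d = jack.mean() - jack
    denom = 6.0 * (d**2).sum() ** 1.5
    a = (d**3).sum() / denom if denom > 0 else 0.0
    lo, hi = [
        norm.cdf(z0 + (z0 + norm.ppf(q)) / (1 - a * (z0 + norm.ppf(q))))
        for q in (alpha / 2, 1 - alpha / 2)
    ]
    return tuple(np.quantile(boots, [lo, hi]))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
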