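"""Shared low-level statistical helpers.

Every percentile in the package goes through :func:`percentile` so that the
convention (linear interpolation between closest ranks, the classic "type 7"
rule) is fixed in exactly one place — percentile-based thresholds are
convention-sensitive, so the normalizer and the histogram features must
agree by construction.
"""

from __future__ import annotations

import numpy as np


def percentile(values: np.ndarray, q) -> np.ndarray | float:
    """Type-7 (linear interpolation) percentile of a flat sample."""
    return np.percentile(np.asarray(values, dtype=float), q, method="linear")


def standardized_moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness and (non-excess) kurtosis.

    Skewness is the third standardized moment, kurtosis the fourth (a normal
    sample gives kurtosis ≈ 3). On a constant sample the variance is 0 and
    skewness/kurtosis are undefined; NaN is returned for the caller to flag.
    """
    v = np.asarray(values, dtype=float).ravel()
    mean = float(v.mean())
    centered = v - mean
    var = float(np.mean(centered**2))
    if var == 0.0:
        return mean, 0.0, float("nan"), float("nan")
    sd = np.sqrt(var)
    skew = float(np.mean(centered**3) / sd**3)
    kurt = float(np.mean(centered**4) / var**2)
    return mean, var, skew, kurt


def xlog2x_sum(p: np.ndarray) -> float:
    """Shannon entropy −Σ p·log2(p) in bits with the 0·log0 := 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())
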