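"""Mask-aware gray-level co-occurrence matrices and Haralick-style features.

The co-occurrence matrix P(i, j | d, θ) gives the probability that two
in-mask pixels separated by the displacement (d, θ) carry quantized gray
levels i and j. Because the ROIs are irregular contoured regions, a pixel
pair contributes only when *both* endpoints lie inside the mask. The
regular matrix and its transpose are summed, so P is symmetric and the
four angles 0°, 45°, 90°, 135° cover all eight compass directions.

Angle-to-offset convention (rows increase downward):
    0° → (0, +d)   45° → (−d, +d)   90° → (−d, 0)   135° → (−d, −d)

From each symmetric P the 22 classical second-order statistics are derived
(energy/ASM, entropy, contrast, correlation, the cluster moments, the sum
and difference statistics, the two information measures of correlation,
and the normalized inverse-difference pair). Logs are base 2 and
0·log 0 := 0; features whose denominators vanish (e.g. correlation on a
constant ROI) are flagged undefined rather than emitted as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import xlog2x_sum
from .preprocess import QuantizedROI
from .vector import FeatureVector

DEFAULT_DISTANCES = (1, 2, 3, 4, 5)
ANGLES = (0, 45, 90, 135)

#: (row, col) unit offsets per angle; rows increase downward
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "GLCM_Autocorrelation",
    "GLCM_Contrast",
    "GLCM_Correlation",
    "GLCM_ClusterProminence",
    "GLCM_ClusterShade",
    "GLCM_ClusterTendency",
    "GLCM_Dissimilarity",
    "GLCM_Energy",
    "GLCM_Entropy",
    "GLCM_Homogeneity",
    "GLCM_InverseVariance",
    "GLCM_MaximumProbability",
    "GLCM_SumOfSquares",
    "GLCM_SumAverage",
    "GLCM_SumVariance",
    "GLCM_SumEntropy",
    "GLCM_DifferenceVariance",
    "GLCM_DifferenceEntropy",
    "GLCM_IMC1",
    "GLCM_IMC2",
    "GLCM_IDN",
    "GLCM_IDMN",
)


@dataclass
class GLCMatrix:
    """Symmetric normalized co-occurrence probabilities for one (d, θ)."""

    p: np.ndarray  # n_levels x n_levels, rows/cols indexed by level 1..n
    d: int
    theta: int
    n_pairs: int  # ordered in-mask pairs counted (before symmetrization)

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def compute_glcm(qroi: QuantizedROI, d: int, theta: int) -> GLCMatrix:
    """Count in-mask co-occurrences at displacement (d, θ) and symmetrize.

    Every ordered pixel pair (a, a + offset) with both endpoints inside the
    mask contributes one count; the transpose is added and the result
    normalized to probabilities. A mask too small to contain any pair at
    this displacement yields an empty-flagged matrix.
    """
    if theta not in OFFSETS:
        raise ValueError(f"theta must be one of {ANGLES}")
    if d < 1:
        raise ValueError("d must be a positive integer")
    n = qroi.n_levels
    dr, dc = OFFSETS[theta][0] * d, OFFSETS[theta][1] * d
    lv = qroi.levels
    h, w = lv.shape

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return GLCMatrix(p=np.zeros((n, n)), d=d, theta=theta, n_pairs=0)

    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a > 0) & (b > 0)
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        return GLCMatrix(p=np.zeros((n, n)), d=d, theta=theta, n_pairs=0)

    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T
    return GLCMatrix(p=counts / counts.sum(), d=d, theta=theta, n_pairs=n_pairs)


def glcm_features(g: GLCMatrix) -> FeatureVector:
    """The 22 second-order statistics of one symmetric co-occurrence matrix."""
    fv = FeatureVector()
    if g.empty:
        for name in GLCM_FEATURE_NAMES:
            fv.add_undefined(name)
        return fv

    p = g.p
    n = p.shape[0]
    levels = np.arange(1, n + 1, dtype=float)
    i = levels[:, None]
    j = levels[None, :]

    px = p.sum(axis=1)  # == py by symmetry
    mu = float((levels * px).sum())
    var_x = float(((levels - mu) ** 2 * px).sum())
    sigma = np.sqrt(var_x)

    # sum and difference marginals p_{x+y}(k), k = 2..2n and p_{x-y}(k), k = 0..n-1
    ksum = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (np.add.outer(np.arange(n), np.arange(n))).ravel(), p.ravel())
    kdiff = np.arange(0, n, dtype=float)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(np.subtract.outer(np.arange(n), np.arange(n))).ravel(),
              p.ravel())

    diff2 = (i - j) ** 2
    absdiff = np.abs(i - j)

    fv.add("GLCM_Autocorrelation", float((i * j * p).sum()))
    fv.add("GLCM_Contrast", float((diff2 * p).sum()))
    if sigma > 0:
        fv.add("GLCM_Correlation",
               float(((i * j * p).sum() - mu * mu) / (sigma * sigma)))
    else:
        fv.add_undefined("GLCM_Correlation")
    dev = i + j - 2 * mu
    fv.add("GLCM_ClusterProminence", float((dev**4 * p).sum()))
    fv.add("GLCM_ClusterShade", float((dev**3 * p).sum()))
    fv.add("GLCM_ClusterTendency", float((dev**2 * p).sum()))
    fv.add("GLCM_Dissimilarity", float((absdiff * p).sum()))
    fv.add("GLCM_Energy", float((p**2).sum()))
    fv.add("GLCM_Entropy", xlog2x_sum(p))
    fv.add("GLCM_Homogeneity", float((p / (1.0 + diff2)).sum()))
    off = absdiff > 0
    fv.add("GLCM_InverseVariance", float((p[off] / diff2[off]).sum()))
    fv.add("GLCM_MaximumProbability", float(p.max()))
    fv.add("GLCM_SumOfSquares", float((((i - mu) ** 2) * p).sum()))
    sum_avg = float((ksum * p_sum).sum())
    fv.add("GLCM_SumAverage", sum_avg)
    fv.add("GLCM_SumVariance", float(((ksum - sum_avg) ** 2 * p_sum).sum()))
    fv.add("GLCM_SumEntropy", xlog2x_sum(p_sum))
    diff_avg = float((kdiff * p_diff).sum())
    fv.add("GLCM_DifferenceVariance", float(((kdiff - diff_avg) ** 2 * p_diff).sum()))
    fv.add("GLCM_DifferenceEntropy", xlog2x_sum(p_diff))

    # information measures of correlation
    hxy = xlog2x_sum(p)
    hx = xlog2x_sum(px)
    outer = np.outer(px, px)
    support = (p > 0) | (outer > 0)
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p[support] * log_outer[support]).sum())
    hxy2 = float(-(outer[outer > 0] * log_outer[outer > 0]).sum())
    if hx > 0:
        fv.add("GLCM_IMC1", (hxy - hxy1) / hx)
    else:
        fv.add_undefined("GLCM_IMC1")
    fv.add("GLCM_IMC2", float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))))

    fv.add("GLCM_IDN", float((p / (1.0 + absdiff / n)).sum()))
    fv.add("GLCM_IDMN", float((p / (1.0 + diff2 / (n * n))).sum()))
    return fv


def glcm_feature_block(qroi: QuantizedROI,
                       distances=DEFAULT_DISTANCES,
                       angles=ANGLES) -> FeatureVector:
    """All 22 features over the (d, θ) grid, suffixed ``_dK_aAAA``."""
    block = FeatureVector()
    for d in distances:
        for theta in angles:
            g = compute_glcm(qroi, d, theta)
            block.extend(glcm_features(g), suffix=f"_d{d}_a{theta:03d}")
    return block
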