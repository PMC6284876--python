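"""First-order (intensity-histogram and gradient) features of a masked ROI.

These features describe the marginal distribution of intensities inside the
contour — moments, percentiles and histogram information measures — plus a
small set of texture descriptors that look at local structure without a
co-occurrence matrix: the Tamura-style coarseness / directionality /
contrast triple and the moments of the absolute intensity gradient.

All statistics are computed strictly over masked pixels. Histogram-based
quantities (energy, entropy, uniformity) use ``n_bins`` equal-width bins
spanning the masked min–max range, which makes them invariant to positive
affine intensity transforms; moments use population (1/N) normalization;
percentiles use the package-wide linear-interpolation rule.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._stats import percentile, standardized_moments, xlog2x_sum
from .io import ROIImage
from .vector import FeatureVector

DEFAULT_N_BINS = 256

#: Tamura coarseness window exponents: window sizes 2**k, largest that fits
_COARSENESS_MAX_K = 5


def _histogram_probabilities(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:  # constant ROI: all mass in one bin
        return np.array([1.0])
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    return counts / counts.sum()


def _gradient_magnitude(roi: ROIImage) -> np.ndarray:
    """Finite-difference gradient magnitude at mask pixels.

    Central differences where both axis neighbours are inside the mask,
    one-sided at the mask boundary; pixels with no in-mask neighbour along
    either axis are excluded. Returns the flat array of magnitudes.
    """
    px, mask = roi.pixels, roi.mask
    grads = []
    ok_any = np.zeros(mask.shape, dtype=bool)
    for axis in (0, 1):
        fwd_ok = np.zeros_like(mask)
        bwd_ok = np.zeros_like(mask)
        fwd = np.zeros_like(px)
        bwd = np.zeros_like(px)
        sl_all = [slice(None), slice(None)]
        sl_lo = sl_all.copy(); sl_lo[axis] = slice(None, -1)
        sl_hi = sl_all.copy(); sl_hi[axis] = slice(1, None)
        lo, hi = tuple(sl_lo), tuple(sl_hi)
        fwd_ok[lo] = mask[lo] & mask[hi]
        bwd_ok[hi] = mask[lo] & mask[hi]
        fwd[lo] = px[hi] - px[lo]
        bwd[hi] = px[hi] - px[lo]
        d = np.zeros_like(px)
        central = fwd_ok & bwd_ok
        d[central] = 0.5 * (fwd[central] + bwd[central])
        only_f = fwd_ok & ~bwd_ok
        only_b = bwd_ok & ~fwd_ok
        d[only_f] = fwd[only_f]
        d[only_b] = bwd[only_b]
        grads.append(d)
        ok_any |= fwd_ok | bwd_ok
    mag = np.hypot(grads[0], grads[1])
    return mag[mask & ok_any]


def _fill_outside(roi: ROIImage) -> np.ndarray:
    """Image with out-of-mask pixels replaced by the masked mean (for filters)."""
    filled = np.where(roi.mask, roi.pixels, roi.masked_values.mean())
    return filled


def _tamura_coarseness(roi: ROIImage) -> float:
    """Mean best scale 2**k at which local average contrast peaks.

    The classic construction: for window sizes 2**k compute neighbourhood
    averages, take horizontal/vertical differences of averages separated by
    the window size, and per pixel keep the size maximizing the difference;
    coarseness is the mean winning size over masked pixels.
    """
    img = _fill_outside(roi)
    h, w = img.shape
    max_k = min(_COARSENESS_MAX_K, int(np.floor(np.log2(max(min(h, w) // 2, 1)))))
    if max_k < 1:
        return 1.0
    best_e = np.full(img.shape, -np.inf)
    best_size = np.ones(img.shape)
    for k in range(1, max_k + 1):
        size = 2**k
        avg = ndimage.uniform_filter(img, size=size, mode="nearest")
        for axis in (0, 1):
            e = np.abs(np.roll(avg, -size // 2, axis=axis)
                       - np.roll(avg, size // 2, axis=axis))
            win = e > best_e
            best_e[win] = e[win]
            best_size[win] = size
    return float(best_size[roi.mask].mean())


def _tamura_directionality(roi: ROIImage) -> float:
    """Anisotropy of the gradient-orientation distribution, in [0, 1].

    Gradient orientations (mod π) of masked pixels are summarized by the
    magnitude-weighted circular resultant on the doubled angle; 0 means
    orientations are spread uniformly (isotropic texture), 1 means a single
    dominant direction. A ROI with vanishing gradients is isotropic (0).
    """
    img = _fill_outside(roi)
    gy, gx = np.gradient(img)
    weight = np.hypot(gx, gy)[roi.mask]
    theta = np.arctan2(gy, gx)[roi.mask]
    total = weight.sum()
    if total <= 0:
        return 0.0
    resultant = np.abs(np.sum(weight * np.exp(2j * theta))) / total
    return float(resultant)


def histogram_features(roi: ROIImage, n_bins: int = DEFAULT_N_BINS) -> FeatureVector:
    """First-order feature vector of a masked ROI.

    Emits mean, variance (population), standard deviation, skewness,
    kurtosis (non-excess: a normal sample gives ≈3), histogram energy /
    uniformity (both Σp², distinct names as both are conventionally
    reported), histogram entropy in bits, percentiles 1/10/50/90/99,
    Tamura-style coarseness / directionality / contrast
    (contrast = σ / kurtosis**0.25), and four absolute-gradient moments.
    On a constant ROI the standardized moments and gradient shape moments
    are undefined and flagged; entropy is 0 and energy/uniformity are 1.
    """
    fv = FeatureVector()
    values = roi.masked_values

    mean, var, skew, kurt = standardized_moments(values)
    fv.add("HIST_Mean", mean)
    fv.add("HIST_Variance", var)
    fv.add("HIST_StdDev", float(np.sqrt(var)))
    fv.add("HIST_Skewness", skew)
    fv.add("HIST_Kurtosis", kurt)

    p = _histogram_probabilities(values, n_bins)
    fv.add("HIST_Energy", float((p**2).sum()))
    fv.add("HIST_Entropy", xlog2x_sum(p))
    fv.add("HIST_Uniformity", float((p**2).sum()))

    for q, label in ((1, "01"), (10, "10"), (50, "50"), (90, "90"), (99, "99")):
        fv.add(f"HIST_Percentile{label}", float(percentile(values, q)))

    fv.add("HIST_Coarseness", _tamura_coarseness(roi))
    fv.add("HIST_Directionality", _tamura_directionality(roi))
    # Tamura contrast: sigma / alpha4^(1/4), alpha4 the non-excess kurtosis
    if var > 0 and np.isfinite(kurt) and kurt > 0:
        fv.add("HIST_Contrast", float(np.sqrt(var) / kurt**0.25))
    else:
        fv.add_undefined("HIST_Contrast")

    grad = _gradient_magnitude(roi)
    if grad.size == 0:
        for stat in ("Mean", "Variance", "Skewness", "Kurtosis"):
            fv.add_undefined(f"HIST_AbsGrad{stat}")
    else:
        gmean, gvar, gskew, gkurt = standardized_moments(grad)
        fv.add("HIST_AbsGradMean", gmean)
        fv.add("HIST_AbsGradVariance", gvar)
        fv.add("HIST_AbsGradSkewness", gskew)
        fv.add("HIST_AbsGradKurtosis", gkurt)
    return fv
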