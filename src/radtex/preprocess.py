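"""Intensity normalization and gray-level quantization.

Two independent preprocessing concerns feed the texture matrices:

* **1%–99% normalization** compresses each ROI's intensity range to the span
  between the 1st and 99th percentile of its own cumulated histogram,
  clipping the tails and mapping linearly onto [0, 1]. Each ROI is
  normalized against itself, so the operation removes between-ROI location
  and scale while preserving within-ROI rank order.
* **Quantization** discretizes the masked intensities into ``n_levels``
  equal-width bins (levels 1..N_g, 0 outside the mask), which is what the
  co-occurrence and run-length matrices operate on. Equal-width binning over
  the masked min–max range makes the level raster invariant to positive
  affine rescalings of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._stats import percentile
from .io import ROIImage

DEFAULT_N_LEVELS = 64


@dataclass(frozen=True)
class QuantizationRule:
    mode: str  # "raw_range" or "normalized"
    lower_bound: float
    upper_bound: float
    degenerate: bool = False


@dataclass
class QuantizedROI:
    """Integer gray-level raster (1..n_levels inside the mask, 0 outside)."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    rule: QuantizationRule

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("quantized ROI has an empty mask")
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValueError("masked levels outside 1..n_levels")
        if (self.levels[~self.mask] != 0).any():
            raise ValueError("nonzero levels outside the mask")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def normalize_1_99(roi: ROIImage) -> ROIImage:
    """Clip a ROI to its own [P1, P99] intensity band and map it onto [0, 1].

    P1 and P99 are the 1st and 99th percentiles of the masked intensities
    under the package-wide linear-interpolation convention. Pixels outside
    the mask are left untouched. A constant ROI (or one whose P1 equals its
    P99) has no range to map; it comes back all-zero inside the mask with
    ``degenerate_normalization=True`` recorded on the result, never as an
    exception.
    """
    values = roi.masked_values
    p1, p99 = percentile(values, [1, 99])
    out = roi.pixels.copy()
    degenerate = not p99 > p1
    if degenerate:
        out[roi.mask] = 0.0
    else:
        out[roi.mask] = (np.clip(values, p1, p99) - p1) / (p99 - p1)
    result = roi.with_pixels(out)
    result.degenerate_normalization = degenerate
    return result


def quantize(roi: ROIImage, n_levels: int = DEFAULT_N_LEVELS,
             mode: str = "raw_range") -> QuantizedROI:
    """Discretize masked intensities into ``n_levels`` equal-width gray levels.

    level = 1 + floor(n_levels * (v − min) / (max − min)), with the maximum
    value assigned level ``n_levels``. A constant ROI maps to level 1
    everywhere inside the mask, with the rule's degenerate flag set.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    values = roi.masked_values
    lo, hi = float(values.min()), float(values.max())
    levels = np.zeros(roi.pixels.shape, dtype=np.int64)
    if hi > lo:
        scaled = 1 + np.floor(n_levels * (values - lo) / (hi - lo)).astype(np.int64)
        levels[roi.mask] = np.minimum(scaled, n_levels)
        rule = QuantizationRule(mode=mode, lower_bound=lo, upper_bound=hi)
    else:
        levels[roi.mask] = 1
        rule = QuantizationRule(mode=mode, lower_bound=lo, upper_bound=hi,
                                degenerate=True)
    return QuantizedROI(levels=levels, n_levels=n_levels, mask=roi.mask.copy(),
                        rule=rule)
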