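"""Gray-level run-length matrices and the run-based higher-order features.

A *run* is a maximal collinear segment of in-mask pixels sharing one
quantized gray level along a direction θ ∈ {0°, 45°, 90°, 135°}. The
run-length matrix r(i, ℓ) counts the maximal runs of level i and length ℓ;
a mask gap terminates a run, so the conservation law

    Σ_i Σ_ℓ ℓ · r(i, ℓ) = number of masked pixels

holds along every direction. The 13 classical run statistics (short/long
run emphasis, gray-level and run-length non-uniformity, run percentage, the
four joint low/high emphases, and the two run-distribution variances) are
computed from r; the variances use the run probability distribution
p(i, ℓ) = r(i, ℓ) / n_runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import QuantizedROI
from .vector import FeatureVector

ANGLES = (0, 45, 90, 135)

GLRLM_FEATURE_NAMES = (
    "GLRLM_SRE",      # short-run emphasis
    "GLRLM_LRE",      # long-run emphasis
    "GLRLM_GLN",      # gray-level non-uniformity
    "GLRLM_RLN",      # run-length non-uniformity
    "GLRLM_RP",       # run percentage
    "GLRLM_LGLRE",    # low gray-level run emphasis
    "GLRLM_HGLRE",    # high gray-level run emphasis
    "GLRLM_SRLGLE",   # short-run low gray-level emphasis
    "GLRLM_SRHGLE",   # short-run high gray-level emphasis
    "GLRLM_LRLGLE",   # long-run low gray-level emphasis
    "GLRLM_LRHGLE",   # long-run high gray-level emphasis
    "GLRLM_GLV",      # gray-level variance (over run distribution)
    "GLRLM_RLV",      # run-length variance (over run distribution)
)


@dataclass
class RunLengthMatrix:
    """Counts r(i, ℓ) of maximal runs of level i (rows) and length ℓ (cols)."""

    r: np.ndarray  # n_levels x L_max integer counts
    theta: int
    n_runs: int
    n_pixels: int  # masked pixels, for run percentage

    @property
    def empty(self) -> bool:
        return self.n_runs == 0


def _lines(levels: np.ndarray, theta: int) -> list[np.ndarray]:
    """Level sequences of all image lines along θ (0 outside the mask)."""
    h, w = levels.shape
    if theta == 0:
        return [levels[r, :] for r in range(h)]
    if theta == 90:
        return [levels[:, c] for c in range(w)]
    if theta == 135:  # down-right diagonals: constant (row - col)
        return [np.diagonal(levels, offset=k) for k in range(-(h - 1), w)]
    if theta == 45:  # up-right anti-diagonals: constant (row + col)
        flipped = levels[::-1, :]
        return [np.diagonal(flipped, offset=k) for k in range(-(h - 1), w)]
    raise ValueError(f"theta must be one of {ANGLES}")


def compute_glrlm(qroi: QuantizedROI, theta: int) -> RunLengthMatrix:
    """Enumerate maximal in-mask runs along θ and tally them by level and length.

    All lines of the raster along the direction are concatenated with a
    zero separator; run boundaries are the points where the level sequence
    changes, and zero-level (out-of-mask) runs are discarded. The matrix is
    trimmed to its occupied run-length columns (the features are sums, so
    trimming is value-neutral).
    """
    lines = _lines(qroi.levels, theta)
    n_pixels = qroi.n_masked
    sep = np.array([0], dtype=np.int64)
    seq = np.concatenate([part for line in lines for part in (line, sep)])
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(seq) - 1]))
    run_values = seq[starts]
    run_lengths = ends - starts + 1
    keep = run_values > 0
    run_values = run_values[keep]
    run_lengths = run_lengths[keep]

    n_runs = int(keep.sum())
    if n_runs == 0:
        return RunLengthMatrix(r=np.zeros((qroi.n_levels, 1), dtype=np.int64),
                               theta=theta, n_runs=0, n_pixels=n_pixels)
    l_max = int(run_lengths.max())
    flat = (run_values - 1) * l_max + (run_lengths - 1)
    r = np.bincount(flat, minlength=qroi.n_levels * l_max)
    r = r.reshape(qroi.n_levels, l_max).astype(np.int64)
    return RunLengthMatrix(r=r, theta=theta, n_runs=n_runs, n_pixels=n_pixels)


def glrlm_features(rlm: RunLengthMatrix) -> FeatureVector:
    """The 13 run-length statistics of one direction's matrix."""
    fv = FeatureVector()
    if rlm.empty:
        for name in GLRLM_FEATURE_NAMES:
            fv.add_undefined(name)
        return fv

    r = rlm.r.astype(float)
    n_runs = float(rlm.n_runs)
    n_levels, l_max = r.shape
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]
    ell = np.arange(1, l_max + 1, dtype=float)[None, :]

    level_sums = r.sum(axis=1)   # Σ_ℓ r(i, ℓ)
    length_sums = r.sum(axis=0)  # Σ_i r(i, ℓ)

    fv.add("GLRLM_SRE", float((r / ell**2).sum() / n_runs))
    fv.add("GLRLM_LRE", float((r * ell**2).sum() / n_runs))
    fv.add("GLRLM_GLN", float((level_sums**2).sum() / n_runs))
    fv.add("GLRLM_RLN", float((length_sums**2).sum() / n_runs))
    fv.add("GLRLM_RP", n_runs / float(rlm.n_pixels))
    fv.add("GLRLM_LGLRE", float((r / i**2).sum() / n_runs))
    fv.add("GLRLM_HGLRE", float((r * i**2).sum() / n_runs))
    fv.add("GLRLM_SRLGLE", float((r / (i**2 * ell**2)).sum() / n_runs))
    fv.add("GLRLM_SRHGLE", float((r * i**2 / ell**2).sum() / n_runs))
    fv.add("GLRLM_LRLGLE", float((r * ell**2 / i**2).sum() / n_runs))
    fv.add("GLRLM_LRHGLE", float((r * i**2 * ell**2).sum() / n_runs))

    p = r / n_runs
    mu_i = float((i * p).sum())
    mu_l = float((ell * p).sum())
    fv.add("GLRLM_GLV", float(((i - mu_i) ** 2 * p).sum()))
    fv.add("GLRLM_RLV", float(((ell - mu_l) ** 2 * p).sum()))
    return fv


def glrlm_feature_block(qroi: QuantizedROI, angles=ANGLES) -> FeatureVector:
    """The 13 features at each angle, suffixed ``_aAAA`` (52 values)."""
    block = FeatureVector()
    for theta in angles:
        block.extend(glrlm_features(compute_glrlm(qroi, theta)),
                     suffix=f"_a{theta:03d}")
    return block
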