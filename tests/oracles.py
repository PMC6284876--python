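"""Independent brute-force oracles the implementation is checked against.

Everything here is written for clarity, not speed: explicit Python loops,
explicit pair/run enumeration, exact integer or rational arithmetic where
possible. None of it shares code with the package internals.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

# (row, col) steps per angle, matching the documented package convention
STEP = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                           d: int, theta: int) -> np.ndarray:
    """Symmetrized co-occurrence counts by enumerating every ordered pair."""
    h, w = levels.shape
    dr, dc = STEP[theta][0] * d, STEP[theta][1] * d
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    return counts + counts.T


def glrlm_counts_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                            theta: int) -> dict[tuple[int, int], int]:
    """Run counts {(level, length): n} by explicit line tracing.

    Walks every line of the raster along the direction pixel by pixel,
    starting a new run whenever the level changes or the mask breaks.
    """
    h, w = levels.shape
    dr, dc = STEP[theta]
    # line starts: pixels with no in-grid predecessor along (dr, dc)
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs: dict[tuple[int, int], int] = {}
    for r0, c0 in starts:
        r, c = r0, c0
        current, length = 0, 0
        while 0 <= r < h and 0 <= c < w:
            level = levels[r, c] if mask[r, c] else 0
            if level == current:
                length += 1
            else:
                if current > 0:
                    runs[(current, length)] = runs.get((current, length), 0) + 1
                current, length = level, 1
            r, c = r + dr, c + dc
        if current > 0:
            runs[(current, length)] = runs.get((current, length), 0) + 1
    return runs


def auc_pair_counting(scores, labels) -> Fraction:
    """Exact Mann–Whitney AUC by O(n^2) pair enumeration."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1 for p in pos for q in neg if p > q)
    ties = sum(1 for p in pos for q in neg if p == q)
    return Fraction(2 * wins + ties, 2 * len(pos) * len(neg))


def best_threshold_scan(values, labels):
    """Exhaustive accuracy scan over all midpoints and both directions.

    Returns (direction, cut, accuracy, perfect) with ties broken toward the
    smaller cut; mirrors the contract of the package's threshold finder.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    uniq = np.unique(values)
    best = None
    for cut in (uniq[:-1] + uniq[1:]) / 2.0:
        for direction in ("<", ">"):
            pred = values < cut if direction == "<" else values > cut
            acc = float((pred == labels).mean())
            if best is None or acc > best[2] + 1e-12:
                best = (direction, float(cut), acc, acc == 1.0)
    return best


def percentile_sort_interp(values, q: float) -> float:
    """Type-7 percentile by explicit sorting and linear interpolation."""
    v = sorted(float(x) for x in values)
    n = len(v)
    pos = (q / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def two_pass_moments(values):
    """Textbook two-pass population moments: mean, var, skew, kurtosis."""
    v = [float(x) for x in values]
    n = len(v)
    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    if m2 == 0:
        return mean, 0.0, None, None
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def random_masked_image(rng: np.random.Generator, max_side: int = 12,
                        n_levels: int = 8, p_mask: float = 0.7):
    """A random quantized raster with a random (nonempty) mask."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = rng.integers(1, n_levels + 1, size=(h, w))
    mask = rng.random((h, w)) < p_mask
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), mask, n_levels
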