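"""Gray-level histograms, Otsu thresholding and inter-class statistics.

This is the numerical kernel of the detector.  For a window's gray-level
histogram it computes

* the Otsu threshold ``T`` — the level ``k`` maximizing the between-class
  variance ``w1(k) * w2(k) * (m1(k) - m2(k))**2``;
* the conditional class means ``m1`` (levels <= k) and ``m2`` (levels
  k+1 .. L, with L the highest occupied level);
* the inter-class average grayscale difference ``delta_d = |m1 - m2|``,
  which gates whether a window is really thresholded.

Gray level 0 is reserved for removed background, so histograms can be built
with that bin excluded; this is what lets windows straddling the fruit rim
produce a defect-separating threshold instead of the degenerate ``T = 0``
split between background and fruit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._counters import counters
from .errors import DegenerateHistogramError

N_LEVELS = 256


@dataclass(frozen=True)
class Histogram:
    """A 256-bin gray-level histogram.

    Attributes
    ----------
    counts : (256,) int64 array of per-level pixel counts.
    zero_excluded : whether bin 0 was forced to zero (reserved background).
    """

    counts: np.ndarray
    zero_excluded: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def max_level(self) -> int:
        """L, the highest occupied gray level (-1 if empty)."""
        occ = np.nonzero(self.counts)[0]
        return int(occ[-1]) if occ.size else -1

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class ThresholdStats:
    """Otsu threshold plus conditional class means and their difference.

    ``degenerate`` is set when one of the two classes is empty (then that
    class's mean is defined as 0); a degenerate split carries no evidence of
    a defect and must not pass the delta_d gate.
    """

    T: int
    m1: float
    m2: float
    delta_d: float
    degenerate: bool = False


def build_histogram(gray_window: np.ndarray, exclude_zero: bool = False) -> Histogram:
    """Histogram an 8-bit gray window, optionally dropping the reserved 0 bin."""
    arr = np.asarray(gray_window)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty window")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("expected 8-bit gray values in [0, 255]")
    counts = np.bincount(arr.ravel(), minlength=N_LEVELS).astype(np.int64)
    if exclude_zero:
        counts[0] = 0
    return Histogram(counts=counts, zero_excluded=exclude_zero)


def otsu_threshold(hist: Histogram) -> int:
    """Threshold maximizing between-class variance; smallest maximizer on ties.

    A single-occupied-bin histogram returns that bin's level (the variance is
    identically zero; downstream :func:`class_stats` flags the degeneracy).
    """
    counts = hist.counts
    total = hist.total
    if total == 0:
        raise DegenerateHistogramError("empty histogram")
    counters["otsu_calls"] += 1
    if hist.n_occupied == 1:
        return hist.max_level

    levels = np.arange(N_LEVELS, dtype=np.float64)
    p = counts / total
    w1 = np.cumsum(p)
    mu = np.cumsum(levels * p)
    mu_total = mu[-1]
    w2 = 1.0 - w1
    valid = (w1 > 0) & (w2 > 0)
    sigma_b = np.zeros(N_LEVELS)
    # w1*w2*(m1-m2)^2 written in the cancellation-free cumulative form
    sigma_b[valid] = (mu_total * w1[valid] - mu[valid]) ** 2 / (w1[valid] * w2[valid])
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def class_stats(hist: Histogram, k: int) -> ThresholdStats:
    """Conditional class means m1, m2 about threshold ``k`` and their gap.

    m1 averages the occupied levels <= k, m2 the occupied levels k+1..L.  An
    empty class has mean 0 and marks the result degenerate.
    """
    total = hist.total
    if total == 0:
        raise DegenerateHistogramError("empty histogram")
    L = hist.max_level
    if not (0 <= k < N_LEVELS):
        raise ValueError(f"threshold {k} outside [0, 255]")
    levels = np.arange(N_LEVELS, dtype=np.float64)
    c = hist.counts.astype(np.float64)
    n1 = c[: k + 1].sum()
    n2 = c[k + 1 :].sum()
    m1 = float((levels[: k + 1] * c[: k + 1]).sum() / n1) if n1 > 0 else 0.0
    m2 = float((levels[k + 1 :] * c[k + 1 :]).sum() / n2) if n2 > 0 else 0.0
    degenerate = n1 == 0 or n2 == 0
    return ThresholdStats(T=int(k), m1=m1, m2=m2, delta_d=abs(m1 - m2), degenerate=degenerate)


def threshold_stats(gray_window: np.ndarray, exclude_zero: bool = True) -> ThresholdStats:
    """Convenience: histogram + Otsu + class statistics in one call."""
    hist = build_histogram(gray_window, exclude_zero=exclude_zero)
    k = otsu_threshold(hist)
    return class_stats(hist, k)
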