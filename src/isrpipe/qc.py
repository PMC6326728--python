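"""Cell-containing barcode identification by the log10(UMI) knee rule.

Droplet experiments produce a bimodal distribution of per-barcode total UMI
counts: a high mode of real cells and a low mode of empty droplets carrying
ambient RNA. The filter histograms log10(UMI totals), smooths with a short
centered moving average, and places the threshold at the first local minimum
whose bin center lies at or above a floor (default 2.0, i.e. 100 UMIs).
Barcodes at or above the threshold are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import CountMatrix

__all__ = [
    "UmiHistogram",
    "NoThresholdFound",
    "build_umi_histogram",
    "find_umi_threshold",
    "filter_barcodes",
    "BarcodeFilter",
]


class NoThresholdFound(RuntimeError):
    """No qualifying local minimum exists at or above the floor."""


@dataclass
class UmiHistogram:
    """Histogram of log10 per-barcode UMI totals with a smoothed copy."""

    bin_edges: np.ndarray  # len = n_bins + 1, uniform width
    raw_counts: np.ndarray
    smoothed_counts: np.ndarray
    floor: float = 2.0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return x.astype(float)
    # full convolution with boundary mass folded back into the first/last
    # bins, so the smoothed histogram conserves the total count exactly
    pad = window // 2
    kernel = np.ones(window) / window
    full = np.convolve(x.astype(float), kernel, mode="full")
    out = full[pad:-pad].copy()
    out[0] += full[:pad].sum()
    out[-1] += full[-pad:].sum()
    return out


def build_umi_histogram(
    counts: CountMatrix | np.ndarray,
    bin_width: float = 0.05,
    smooth_window: int = 7,
    floor: float = 2.0,
) -> UmiHistogram:
    """Histogram log10 barcode totals on a uniform grid and smooth.

    ``counts`` may be a :class:`CountMatrix` or a vector of per-barcode
    totals. Barcodes with zero total are excluded (log10 undefined); an
    all-zero matrix is an error.
    """
    if isinstance(counts, CountMatrix):
        totals = counts.barcode_totals()
    else:
        totals = np.asarray(counts, dtype=float)
    totals = totals[totals >= 1]
    if totals.size == 0:
        raise ValueError("no nonempty barcodes")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    log_totals = np.log10(totals)
    lo = np.floor(log_totals.min() / bin_width) * bin_width
    hi = np.ceil(log_totals.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    raw, _ = np.histogram(log_totals, bins=edges)
    smoothed = _moving_average(raw, smooth_window)
    return UmiHistogram(
        bin_edges=edges,
        raw_counts=raw,
        smoothed_counts=smoothed,
        floor=floor,
    )


def find_umi_threshold(hist: UmiHistogram) -> float:
    """First local minimum of the smoothed histogram at/above the floor.

    Returns the center of the lowest-index bin whose smoothed count is
    strictly less than both flanking non-equal values; plateaus resolve to
    their left-most bin. Raises :class:`NoThresholdFound` if no such bin
    with center >= floor exists.
    """
    y = hist.smoothed_counts
    centers = hist.bin_centers
    n = y.size
    i = 1
    while i < n - 1:
        if y[i] < y[i - 1]:
            # scan over any plateau starting at i
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j + 1 < n and y[j + 1] > y[i] and centers[i] >= hist.floor:
                return float(centers[i])
            i = j + 1
        else:
            i += 1
    raise NoThresholdFound(
        f"no local minimum with bin center >= {hist.floor}"
    )


def filter_barcodes(counts: CountMatrix, threshold: float) -> CountMatrix:
    """Retain barcodes with log10(total UMI) >= ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    totals = counts.barcode_totals()
    with np.errstate(divide="ignore"):
        keep = np.log10(np.maximum(totals, 0)) >= threshold
    if not keep.any():
        raise ValueError("threshold retains zero barcodes")
    return counts.subset_barcodes(keep)


class BarcodeFilter(BaseEstimator):
    """Estimator wrapper around the knee-point barcode filter.

    Parameters
    ----------
    bin_width : float, default 0.05
        Histogram bin width in log10(UMI) units.
    smooth_window : int, default 7
        Odd length of the centered moving-average smoother.
    floor : float, default 2.0
        Minimum log10(UMI) bin center considered for the local minimum.

    Attributes
    ----------
    histogram_ : UmiHistogram
    threshold_ : float
        Selected log10(UMI) threshold.
    """

    def __init__(self, bin_width: float = 0.05, smooth_window: int = 7,
                 floor: float = 2.0):
        self.bin_width = bin_width
        self.smooth_window = smooth_window
        self.floor = floor

    def fit(self, X: CountMatrix, y=None) -> "BarcodeFilter":
        self.histogram_ = build_umi_histogram(
            X, bin_width=self.bin_width, smooth_window=self.smooth_window,
            floor=self.floor,
        )
        self.threshold_ = find_umi_threshold(self.histogram_)
        return self

    def transform(self, X: CountMatrix) -> CountMatrix:
        return filter_barcodes(X, self.threshold_)

    def fit_transform(self, X: CountMatrix, y=None) -> CountMatrix:
        return self.fit(X).transform(X)
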