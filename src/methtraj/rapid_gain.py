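"""Rapid-gain CpG detection by histogram local-minimum thresholding.

The distribution of significant mean slopes is skewed towards methylation
gain and shows a distinct shoulder of rapidly gaining CpGs. The class
boundary is found on a fixed-bin-width histogram (default 0.0005
beta/year): starting from the global mode, the first local minimum to the
right in the positive-slope region marks the valley between the bulk and
the gain shoulder, and its left bin edge is the reported threshold.
Counts are smoothed with a short moving average before valley detection
(the raw counts are what gets reported) because at this bin width the
valley region is noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ThresholdResult",
    "NoValleyError",
    "find_rapid_gain_threshold",
    "classify_rapid_gain",
    "RapidGainDetector",
]


class NoValleyError(RuntimeError):
    """No local minimum right of the mode; supply a manual threshold."""


@dataclass
class ThresholdResult:
    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    threshold: float
    n_rapid_gain: int

    def histogram(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:], "count": self.counts}
        )


def find_rapid_gain_threshold(
    mean_slopes: np.ndarray,
    bin_width: float = 0.0005,
    smooth_window: int = 3,
    min_cpgs: int = 100,
) -> ThresholdResult:
    """Locate the valley between the slope bulk and the rapid-gain shoulder.

    Bins are anchored at integer multiples of ``bin_width``. A bin is a
    local minimum if its (smoothed) count is strictly less than both
    neighbours; the first such bin right of the global mode with a
    positive left edge gives the threshold. Adding CpGs with negative
    slopes cannot move the detected threshold.
    """
    s = np.asarray(mean_slopes, float)
    s = s[np.isfinite(s)]
    if s.size < min_cpgs:
        raise ValueError(f"need >= {min_cpgs} significant CpGs, got {s.size}")
    # edges are exact integer multiples of the bin width so that detection
    # is invariant to how far the distribution extends on either side
    k_lo = int(np.floor(s.min() / bin_width))
    k_hi = int(np.ceil(s.max() / bin_width))
    edges = np.arange(k_lo, k_hi + 1) * bin_width
    if len(edges) < 4:
        raise NoValleyError("slope range spans too few bins for valley detection")
    counts, edges = np.histogram(s, bins=edges)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        work = np.convolve(counts, kernel, mode="same")
    else:
        work = counts.astype(float)
    mode = int(np.argmax(work))
    threshold = None
    for b in range(mode + 1, len(work) - 1):
        if edges[b] <= 0:
            continue
        if work[b] < work[b - 1] and work[b] < work[b + 1]:
            threshold = float(edges[b])
            break
    if threshold is None:
        raise NoValleyError(
            "no local minimum found right of the mode; the slope distribution "
            "looks unimodal — pass an explicit threshold instead"
        )
    n_rapid = int((s > threshold).sum())
    return ThresholdResult(
        bin_width=bin_width,
        bin_edges=edges,
        counts=counts,
        threshold=threshold,
        n_rapid_gain=n_rapid,
    )


def classify_rapid_gain(
    summaries: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Significant CpGs with mean slope strictly above the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sig = summaries[summaries["significant"]] if "significant" in summaries.columns else summaries
    hits = sig[sig["mean_slope"] > threshold]
    return hits[["mean_slope"]].copy()


class RapidGainDetector(BaseEstimator):
    """Histogram-valley rapid-gain classifier.

    ``threshold`` overrides valley detection when given (the documented
    escape hatch for unimodal slope distributions).
    """

    def __init__(
        self,
        bin_width: float = 0.0005,
        smooth_window: int = 3,
        threshold: float | None = None,
    ):
        self.bin_width = bin_width
        self.smooth_window = smooth_window
        self.threshold = threshold

    def fit(self, summaries: pd.DataFrame, y=None):
        sig = (
            summaries[summaries["significant"]]
            if "significant" in summaries.columns
            else summaries
        )
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.result_ = None
        else:
            self.result_ = find_rapid_gain_threshold(
                sig["mean_slope"].to_numpy(),
                bin_width=self.bin_width,
                smooth_window=self.smooth_window,
            )
            self.threshold_ = self.result_.threshold
        self.rapid_gain_ = classify_rapid_gain(summaries, self.threshold_)
        return self

    def predict(self, summaries: pd.DataFrame) -> pd.Series:
        hits = classify_rapid_gain(summaries, self.threshold_)
        return pd.Series(summaries.index.isin(hits.index), index=summaries.index)
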