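"""Up-state detection on multiunit activity via a median-filtered spike count.

Anesthesia-induced up states are epochs of elevated network excitability that
can inflate spike correlations. The detector bins pooled multiunit spike
times in 10-ms intervals and replaces each interior bin with the median of
its 10 neighboring bins (5 each side, the center excluded; the even-count
median is the mean of the two middle values). A bin belongs to an up state
when its filtered value exceeds 0, which requires firing in six or more of
the 10 neighboring bins. Edge bins carry no filtered value and can neither
open nor close a state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BIN = 0.010  # s
FILTER_BINS = 10


@dataclass
class MUATrace:
    """Pooled spike times (s) of all units of one site during baseline."""

    times: np.ndarray
    total_duration: float

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, float))
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.total_duration):
            raise ValueError("spike times outside [0, total_duration]")


@dataclass
class UpStateResult:
    intervals: list[tuple[float, float]]
    fraction_time: float  # percent of evaluated (interior) time in up-state


def _neighbor_median(counts: np.ndarray, half: int) -> np.ndarray:
    """Median of the 2*half neighbors (center excluded) for interior bins.

    The even-count median is the lower middle order statistic: exactly half
    the neighbors firing does not open an up state, six or more in ten do.
    """
    n = counts.size
    interior = np.arange(half, n - half)
    neigh = np.empty((interior.size, 2 * half))
    for k, i in enumerate(interior):
        neigh[k, :half] = counts[i - half : i]
        neigh[k, half:] = counts[i + 1 : i + 1 + half]
    neigh.sort(axis=1)
    return neigh[:, half - 1]


def detect_upstates(
    mua: MUATrace, bin_size: float = BIN, filter_bins: int = FILTER_BINS
) -> UpStateResult:
    """Detect up states; returns intervals (s) and percent time in up state."""
    if mua.total_duration < filter_bins * bin_size:
        raise ValueError("trace shorter than the filter window")
    n_bins = int(np.floor(mua.total_duration / bin_size + 1e-9))
    edges = np.arange(n_bins + 1) * bin_size
    counts = np.histogram(mua.times, bins=edges)[0]
    half = filter_bins // 2
    if n_bins <= 2 * half:
        return UpStateResult([], 0.0)
    med = _neighbor_median(counts, half)
    up = med > 0
    intervals: list[tuple[float, float]] = []
    start = None
    for k, flag in enumerate(up):
        i = k + half  # absolute bin index
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start * bin_size, i * bin_size))
            start = None
    if start is not None:
        intervals.append((start * bin_size, (up.size + half) * bin_size))
    frac = 100.0 * up.mean() if up.size else 0.0
    return UpStateResult(intervals=intervals, fraction_time=float(frac))
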