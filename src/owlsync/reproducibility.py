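"""Shuffled autocorrelogram (SAC) reproducibility.

The SAC is the histogram of time intervals between each spike of one trial
and every spike of the *other* trials (within-trial intervals are excluded,
which removes refractoriness and ISI structure and isolates across-trial
patterning). With the density normalization used here the SAC of independent
Poisson trains converges to the squared mean rate m^2, so the reproducibility
integral

    R = integral_{-w}^{+w} (SAC(tau) - m^2) dtau / m

is ~0 for unpatterned spiking and ~1 for perfectly repeated spike patterns
(narrow integration window), independent of firing rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trials import TrialSet, analysis_window, firing_rate

#: Bin sizes used to resolve the center-peak half-width (s): 100 us for ICcl-like
#: precision, 2 ms for space-map (OT-like) precision.
ICCL_BIN = 100e-6
OT_BIN = 2e-3

#: Integration windows (s) matching the reported median center-peak half-widths.
ICCL_WINDOW = 1e-3
OT_WINDOW = 10e-3

_FLANK = (0.020, 0.050)  # |lag| range (s) defining the flanks


@dataclass
class Correlogram:
    """Lag grid plus normalized values of a SAC or CCG.

    ``lags`` are uniform bin centers symmetric about zero; ``values`` are in
    the units given by ``normalization``: ``sac_density`` is coincidence
    density in (spikes/s)^2, ``ccg_per_spike`` is coincidences per GM spike
    per second of lag (see :mod:`owlsync.synchrony`).
    """

    lags: np.ndarray
    values: np.ndarray
    bin_size: float
    normalization: str
    n_trials: int
    raw_counts: np.ndarray | None = None

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags/values shape mismatch")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlogram values must be finite")
        if not np.allclose(self.lags, -self.lags[::-1], atol=1e-12):
            raise ValueError("lag grid must be symmetric about zero")

    @property
    def max_lag(self) -> float:
        return float(self.lags[-1] + self.bin_size / 2)


@dataclass
class ReproducibilityResult:
    value: float
    window: float
    m: float
    bin_size: float


def lag_grid(bin_size: float, max_lag: float) -> np.ndarray:
    """Centers of an odd number of uniform bins covering ±max_lag."""
    k = int(np.ceil(max_lag / bin_size - 0.5))
    return np.arange(-k, k + 1) * bin_size


def _cross_trial_intervals(spikes: list[np.ndarray], max_abs: float) -> np.ndarray:
    """All t_a - t_b for spikes in distinct trials, |interval| <= max_abs.

    Counts both directions, so the SAC is exactly symmetric. Uses a
    sort+searchsorted sweep to avoid the full quadratic outer product.
    """
    counts = np.array([s.size for s in spikes])
    if counts.sum() == 0:
        return np.empty(0)
    allt = np.concatenate([s for s in spikes])
    trial = np.repeat(np.arange(len(spikes)), counts)
    order = np.argsort(allt, kind="stable")
    allt, trial = allt[order], trial[order]
    lo = np.searchsorted(allt, allt - max_abs, side="left")
    hi = np.searchsorted(allt, allt + max_abs, side="right")
    span = hi - lo
    tot = int(span.sum())
    if tot == 0:
        return np.empty(0)
    # flatten all per-spike neighbor ranges into one index vector
    offs = np.cumsum(span) - span
    idx = np.arange(tot) - np.repeat(offs, span) + np.repeat(lo, span)
    src = np.repeat(np.arange(allt.size), span)
    keep = trial[src] != trial[idx]
    return (allt[src] - allt[idx])[keep]


def compute_sac(ts: TrialSet, bin_size: float = ICCL_BIN, max_lag: float = 0.050) -> Correlogram:
    """Shuffled autocorrelogram of a TrialSet as a coincidence density.

    Counts in each lag bin are divided by ``N(N-1) * bin_size * D`` (N trials,
    D analysis duration), giving density in (spikes/s)^2 whose expectation for
    independent Poisson trains is m^2. The onset-exclusion window of the
    TrialSet is applied first.
    """
    if not 50e-6 - 1e-12 <= bin_size <= 20e-3 + 1e-12:
        raise ValueError("bin_size outside the supported 0.05-20 ms range")
    w = analysis_window(ts)
    n = w.n_trials
    if n < 2:
        raise ValueError("SAC needs at least 2 trials")
    if all(t.size == 0 for t in w.spikes):
        raise ValueError("all trials are empty")
    lags = lag_grid(bin_size, max_lag)
    edges = np.concatenate([lags - bin_size / 2, [lags[-1] + bin_size / 2]])
    iv = _cross_trial_intervals(w.spikes, edges[-1])
    counts, _ = np.histogram(iv, bins=edges)
    dens = counts / (n * (n - 1) * bin_size * w.stim_duration)
    return Correlogram(
        lags=lags,
        values=dens,
        bin_size=bin_size,
        normalization="sac_density",
        n_trials=n,
        raw_counts=counts.astype(float),
    )


def _flank_stats(sac: Correlogram) -> tuple[float, float]:
    sel = (np.abs(sac.lags) >= _FLANK[0]) & (np.abs(sac.lags) <= _FLANK[1])
    if not np.any(sel):
        raise ValueError("SAC max_lag must reach 50 ms to evaluate flanks")
    f = sac.values[sel]
    return float(f.mean()), float(f.std(ddof=0))


def check_peak(sac: Correlogram) -> bool:
    """True iff the 0-lag SAC value exceeds the flank mean by > 2 flank SD."""
    mean, sd = _flank_stats(sac)
    center = sac.values[np.argmin(np.abs(sac.lags))]
    return bool(center > mean + 2 * sd)


def sac_half_width(sac: Correlogram) -> float:
    """Half of the full width at half height of the center peak (s).

    Height is measured above the flank mean; crossings are linearly
    interpolated between bin centers, taking the outermost crossing below the
    half level on each side. Raises if the SAC has no significant center peak.
    """
    if not check_peak(sac):
        raise ValueError("no significant center peak; half-width undefined")
    flank_mean, _ = _flank_stats(sac)
    h = sac.values - flank_mean
    c = int(np.argmin(np.abs(sac.lags)))
    half = h[c] / 2.0

    def crossing(direction: int) -> float:
        i = c
        while True:
            j = i + direction
            if j < 0 or j >= h.size:
                return float(sac.lags[i])  # peak wider than the correlogram
            if h[j] < half:  # outermost crossing: keep going past ties at half
                frac = (h[i] - half) / (h[i] - h[j])
                return float(sac.lags[i] + frac * (sac.lags[j] - sac.lags[i]))
            i = j

    left = crossing(-1)
    right = crossing(+1)
    return (right - left) / 2.0


def reproducibility(
    sac: Correlogram, window: float, m: float
) -> ReproducibilityResult:
    """Normalized integral of the center SAC peak.

    ``window`` is the integration half-width (s); bins whose centers satisfy
    ``|lag| <= window`` are included. ``m`` is the mean firing rate over the
    same analysis window as the SAC. Negative values indicate anti-patterned
    spiking (less coincident than chance).
    """
    if sac.normalization != "sac_density":
        raise ValueError("reproducibility requires a SAC density correlogram")
    if window > sac.max_lag:
        raise ValueError("integration window exceeds correlogram range")
    if m <= 0:
        raise ValueError("reproducibility undefined for zero firing rate")
    sel = np.abs(sac.lags) <= window + 1e-12
    val = float(((sac.values[sel] - m * m) * sac.bin_size).sum() / m)
    return ReproducibilityResult(value=val, window=window, m=m, bin_size=sac.bin_size)


def reproducibility_of(ts: TrialSet, window: float = ICCL_WINDOW,
                       bin_size: float = ICCL_BIN) -> ReproducibilityResult:
    """SAC + rate + integral in one call, using the TrialSet's onset exclusion."""
    max_lag = max(5 * window, 10 * bin_size)
    sac = compute_sac(ts, bin_size=bin_size, max_lag=max_lag)
    m = firing_rate(ts)
    return reproducibility(sac, window, m)


def population_window(sacs: list[Correlogram]) -> float:
    """Median center-peak half-width across SACs with a significant peak."""
    widths = []
    for sac in sacs:
        try:
            widths.append(sac_half_width(sac))
        except ValueError:
            continue
    if not widths:
        raise ValueError("no SAC in the population has a significant center peak")
    if len(widths) < len(sacs):
        warnings.warn(
            f"{len(sacs) - len(widths)} SAC(s) without significant peak excluded "
            "from the population window", stacklevel=2,
        )
    return float(np.median(widths))
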