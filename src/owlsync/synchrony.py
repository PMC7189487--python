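"""Pairwise cross-correlograms and the shift-predictor synchrony correction.

Coincidences between two units are counted on a 1-ms lag grid (spikes within
1 ms are coincident), smoothed with a 5-ms sliding window, and normalized by
bin size times the geometric-mean (GM) firing rate. Three correlogram kinds:

* ``standard`` - simultaneous trials (trial i of A vs trial i of B);
* ``shifted``  - trial i of A vs trial i+1 of B (cyclic), which retains only
  coincidences reproduced across trials, i.e. stimulus-locked patterning;
* ``corrected`` - standard minus shifted, bin-wise on raw counts, leaving
  coincidences not explained by shared patterning.

Synchrony is the integral of the normalized CCG over a +/-10 ms center
window and is dimensionless (coincidences per GM spike). For two independent
Poisson trains its expectation is ``0.021 * gm`` (21 one-ms bins at chance
level), so corrected synchrony is ~0 for independent pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reproducibility import Correlogram
from .trials import Condition, TrialSet, analysis_window, firing_rate, gm_rate

COINCIDENCE_BIN = 0.001  # s
SMOOTH_WINDOW = 0.005  # s, boxcar
INTEGRATION_HALFWIDTH = 0.010  # s

CCG_KINDS = ("standard", "shifted", "corrected")


@dataclass
class PairResponse:
    """Simultaneously recorded responses of two units across conditions."""

    unit_a: dict[Condition, TrialSet]
    unit_b: dict[Condition, TrialSet]
    baseline_mean: tuple[float, float] = (0.0, 0.0)
    baseline_sd: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if set(self.unit_a) != set(self.unit_b):
            raise ValueError("both units must share the same condition set")
        for c in self.unit_a:
            if self.unit_a[c].n_trials != self.unit_b[c].n_trials:
                raise ValueError(f"unequal trial counts for condition {c}")

    @property
    def conditions(self) -> list[Condition]:
        return list(self.unit_a)


@dataclass
class SynchronyResult:
    value: float
    ccg_kind: str
    integration_halfwidth: float
    gm: float


def binned_counts(ts: TrialSet, bin_size: float = COINCIDENCE_BIN,
                  drop_first_spike: bool = False) -> np.ndarray:
    """(n_trials, n_bins) spike-count raster over the analysis window."""
    w = analysis_window(ts)
    n_bins = int(np.floor(w.stim_duration / bin_size + 1e-9))
    edges = np.arange(n_bins + 1) * bin_size
    rows = []
    for tr in w.spikes:
        if drop_first_spike and tr.size:
            tr = tr[1:]
        rows.append(np.histogram(tr, bins=edges)[0])
    return np.asarray(rows, dtype=float)


def _smooth_mass_conserving(counts: np.ndarray, width_bins: int) -> np.ndarray:
    """Boxcar smoothing that distributes each bin's mass over its neighbors.

    Interior bins see the ordinary centered boxcar; at the edges each input
    bin's mass is renormalized over the neighbors that exist, so the total
    count is conserved exactly.
    """
    if width_bins <= 1:
        return counts.astype(float)
    half = width_bins // 2
    L = counts.size
    idx = np.arange(L)
    n_avail = np.minimum(idx + half, L - 1) - np.maximum(idx - half, 0) + 1
    weighted = counts / n_avail
    kernel = np.ones(2 * half + 1)
    return np.convolve(weighted, kernel, mode="same")


def _raw_ccg_counts(na: np.ndarray, nb: np.ndarray, pairing: str,
                    max_lag_bins: int) -> np.ndarray:
    """Total coincidence counts per lag bin over all trial pairings.

    ``na``, ``nb`` are (n_trials, n_bins) rasters. Lag is t_a - t_b; the
    shifted pairing matches trial i of A with trial i+1 of B, wrapping the
    last trial to the first so all trials contribute.
    """
    n_trials, n_bins = na.shape
    if pairing == "shifted":
        nb = np.roll(nb, -1, axis=0)
    out = np.zeros(2 * max_lag_bins + 1)
    for l in range(-max_lag_bins, max_lag_bins + 1):
        if l >= 0:
            out[l + max_lag_bins] = np.sum(na[:, l:] * nb[:, : n_bins - l])
        else:
            out[l + max_lag_bins] = np.sum(na[:, :l] * nb[:, -l:])
    return out


def ccg(
    a: TrialSet,
    b: TrialSet,
    kind: str = "standard",
    coincidence_bin: float = COINCIDENCE_BIN,
    smooth: float = SMOOTH_WINDOW,
    max_lag: float = 0.050,
    drop_first_spike: bool = False,
) -> Correlogram:
    """Cross-correlogram between two simultaneously recorded TrialSets.

    Returns a normalized correlogram (``ccg_per_spike``): smoothed
    coincidence counts per trial pairing per second of record, divided by
    ``coincidence_bin * gm``. The integral over lag (see :func:`synchrony`)
    is then coincidences per GM spike. ``corrected`` subtracts shifted from
    standard on matched raw-count bins before smoothing and normalization.
    """
    if kind not in CCG_KINDS:
        raise ValueError(f"kind must be one of {CCG_KINDS}")
    if a.n_trials != b.n_trials:
        raise ValueError("paired units must have equal trial counts")
    if kind in ("shifted", "corrected") and a.n_trials < 2:
        raise ValueError("shifted CCG needs at least 2 trials")
    ra, rb = firing_rate(a), firing_rate(b)
    gm = gm_rate(ra, rb)
    if gm == 0:
        raise ValueError("CCG normalization undefined for zero GM rate")

    na = binned_counts(a, coincidence_bin, drop_first_spike)
    nb = binned_counts(b, coincidence_bin, drop_first_spike)
    max_lag_bins = int(round(max_lag / coincidence_bin))
    if kind == "corrected":
        counts = _raw_ccg_counts(na, nb, "standard", max_lag_bins) - _raw_ccg_counts(
            na, nb, "shifted", max_lag_bins
        )
    else:
        counts = _raw_ccg_counts(na, nb, kind, max_lag_bins)

    width_bins = max(1, int(round(smooth / coincidence_bin)))
    smoothed = _smooth_mass_conserving(counts, width_bins)

    n_pairings = a.n_trials
    duration = na.shape[1] * coincidence_bin
    values = smoothed / (n_pairings * duration * coincidence_bin * gm)
    lags = np.arange(-max_lag_bins, max_lag_bins + 1) * coincidence_bin
    return Correlogram(
        lags=lags,
        values=values,
        bin_size=coincidence_bin,
        normalization="ccg_per_spike",
        n_trials=a.n_trials,
        raw_counts=counts,
    )


def synchrony(cg: Correlogram, halfwidth: float = INTEGRATION_HALFWIDTH,
              kind: str = "standard", gm: float = float("nan")) -> SynchronyResult:
    """Integral of the normalized CCG over ``|lag| <= halfwidth``."""
    if cg.normalization != "ccg_per_spike":
        raise ValueError("synchrony requires a ccg_per_spike correlogram")
    if halfwidth > cg.max_lag:
        raise ValueError("integration halfwidth exceeds correlogram range")
    sel = np.abs(cg.lags) <= halfwidth + 1e-12
    val = float((cg.values[sel] * cg.bin_size).sum())
    return SynchronyResult(value=val, ccg_kind=kind,
                           integration_halfwidth=halfwidth, gm=gm)


def pair_synchrony(a: TrialSet, b: TrialSet, kind: str = "standard",
                   halfwidth: float = INTEGRATION_HALFWIDTH,
                   **ccg_kwargs) -> SynchronyResult:
    """CCG + integral in one call; records the pair's GM rate."""
    cg = ccg(a, b, kind=kind, max_lag=max(2 * halfwidth, 0.015), **ccg_kwargs)
    gm = gm_rate(firing_rate(a), firing_rate(b))
    res = synchrony(cg, halfwidth, kind=kind)
    res.gm = gm
    return res


def bulk_pair_synchrony(
    rasters: np.ndarray,
    pairs: np.ndarray,
    kind: str = "standard",
    bin_size: float = COINCIDENCE_BIN,
    halfwidth: float = INTEGRATION_HALFWIDTH,
    smooth: float = SMOOTH_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """CCG-integral synchrony for many unit pairs at once.

    ``rasters`` is (n_units, n_trials, n_bins) binned spike counts (onset
    already excluded); ``pairs`` an (n_pairs, 2) index array. Equivalent to
    :func:`ccg` + :func:`synchrony` for each pair - the smoothing+integration
    reduces to a fixed per-lag weight (the fraction of each lag's smoothed
    mass landing inside the integration window), so only raw coincidence
    counts for |lag| <= halfwidth + smoothing reach are needed, computed as
    one matrix product per lag. Returns (synchrony values, GM rates); pairs
    whose GM rate is zero get NaN.
    """
    if kind not in ("standard", "shifted"):
        raise ValueError("bulk synchrony supports 'standard' and 'shifted'")
    U, n_trials, n_bins = rasters.shape
    hw = int(round(halfwidth / bin_size))
    sm_half = max(1, int(round(smooth / bin_size))) // 2
    max_l = hw + sm_half
    pad = np.zeros((U, n_trials, max_l), rasters.dtype)
    A = np.concatenate([rasters, pad], axis=2).reshape(U, -1)
    rolled = np.roll(rasters, -1, axis=1) if kind == "shifted" else rasters
    B = np.concatenate([rolled, pad], axis=2).reshape(U, -1)
    K = A.shape[1]
    i_idx = np.asarray(pairs)[:, 0]
    j_idx = np.asarray(pairs)[:, 1]
    vals = np.zeros(len(pairs))
    denom_bins = 2 * sm_half + 1
    for l in range(-max_l, max_l + 1):
        in_win = np.sum(np.abs(np.arange(l - sm_half, l + sm_half + 1)) <= hw)
        if in_win == 0:
            continue
        w = in_win / denom_bins
        if l >= 0:
            C = A[:, l:] @ B[:, : K - l].T
        else:
            C = A[:, :l] @ B[:, -l:].T
        vals += w * C[i_idx, j_idx]
    duration = n_bins * bin_size
    unit_rates = rasters.sum(axis=2).mean(axis=1) / duration
    gm = np.sqrt(unit_rates[i_idx] * unit_rates[j_idx])
    out = np.full(len(pairs), np.nan)
    ok = gm > 0
    out[ok] = vals[ok] / (n_trials * duration * gm[ok])
    return out, gm


def include_pair(pair: PairResponse) -> tuple[bool, list[Condition]]:
    """Inclusion filter: a condition is retained when both units respond at
    least 2 SD above their baseline mean; the pair is retained when at least
    two conditions survive."""
    kept = []
    for cond in pair.conditions:
        ra = firing_rate(pair.unit_a[cond])
        rb = firing_rate(pair.unit_b[cond])
        ok_a = ra >= pair.baseline_mean[0] + 2 * pair.baseline_sd[0]
        ok_b = rb >= pair.baseline_mean[1] + 2 * pair.baseline_sd[1]
        if ok_a and ok_b:
            kept.append(cond)
    return len(kept) >= 2, kept
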