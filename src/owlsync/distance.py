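"""Victor-Purpura spike-train distance with Monte-Carlo chance correction.

The VP distance is the minimal total cost of transforming one spike train
into another using three elementary operations: insert a spike (cost 1),
delete a spike (cost 1), shift a spike by dt (cost q*|dt|). ``q`` (1/s) sets
the temporal precision of the metric: spikes further apart than 2/q are
cheaper to delete+insert than to shift.

Because the distance grows with spike count, raw distances are corrected by
subtracting the distance expected by chance between random (uniform) spike
trains of matched count, estimated by Monte-Carlo simulation and summarized
as a fourth-order zero-intercept polynomial in the geometric-mean spike
count. Negative corrected distances mean the trains are more similar than
chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numba import njit

DEFAULT_Q = 100.0  # 1/s
ALTERNATE_Q = (33.0, 64.0, 250.0)


@dataclass(frozen=True)
class VPConfig:
    q: float = DEFAULT_Q

    def __post_init__(self):
        if not self.q > 0:
            raise ValueError("q must be positive")


@njit(cache=True)
def _vp_dp(a, b, q):  # pragma: no cover - exercised via vp_distance
    na, nb = a.size, b.size
    prev = np.empty(nb + 1)
    cur = np.empty(nb + 1)
    for j in range(nb + 1):
        prev[j] = j
    for i in range(1, na + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, nb + 1):
            shift = prev[j - 1] + q * abs(ai - b[j - 1])
            dele = prev[j] + 1.0
            ins = cur[j - 1] + 1.0
            m = shift
            if dele < m:
                m = dele
            if ins < m:
                m = ins
            cur[j] = m
        prev, cur = cur, prev
    return prev[nb]


def vp_distance(a, b, q: float = DEFAULT_Q) -> float:
    """VP distance between two sorted spike-time sequences (times in s)."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0:
        return float(b.size)
    if b.size == 0:
        return float(a.size)
    return float(_vp_dp(a, b, q))


def mean_pairwise_distance(ts, cfg: VPConfig = VPConfig()) -> float:
    """Mean VP distance over all unordered pairs of non-empty trials.

    Empty trials are omitted (they would bias the average toward zero since
    the metric is |b| against an empty train). Raises if fewer than two
    non-empty trials remain.
    """
    from .trials import analysis_window

    w = analysis_window(ts)
    trains = [t for t in w.spikes if t.size]
    if len(trains) < 2:
        raise ValueError("need >=2 non-empty trials for a pairwise distance")
    tot = 0.0
    npairs = 0
    for x, y in combinations(trains, 2):
        tot += vp_distance(x, y, cfg.q)
        npairs += 1
    return tot / npairs


@dataclass(frozen=True)
class ChanceDistanceModel:
    """Zero-intercept quartic mapping GM spike count -> expected VP distance.

    ``coeffs`` are (c4, c3, c2, c1) of c4*x^4 + c3*x^3 + c2*x^2 + c1*x where
    x is the geometric mean of the two trains' spike counts within the
    analysis window (x = GM rate in spikes/s times the duration).
    """

    duration: float
    coeffs: tuple[float, float, float, float]
    fit_range: tuple[float, float] = (0.0, 51.5)

    def __post_init__(self):
        if not all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")

    def expected_distance(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        c4, c3, c2, c1 = self.coeffs
        val = ((c4 * x + c3) * x + c2) * x * x + c1 * x
        return float(val) if val.ndim == 0 else val

    def expected_distance_from_rate(self, gm_rate: float) -> float:
        """Expected distance for a GM firing rate in spikes/s."""
        return float(self.expected_distance(gm_rate * self.duration))


#: Chance models for the three analysis durations used with recorded data,
#: with the published coefficients for each.
PUBLISHED_MODELS = {
    0.100: ChanceDistanceModel(0.100, (-1.19e-5, 1.30e-3, -0.05, 1.38)),
    0.200: ChanceDistanceModel(0.200, (-1.03e-5, 1.30e-3, -0.06, 1.70)),
    0.400: ChanceDistanceModel(0.400, (-5.62e-6, 7.74e-4, -0.04, 1.82)),
}


def chance_model(duration: float) -> ChanceDistanceModel:
    """Published chance model for a supported duration (0.1/0.2/0.4 s)."""
    for d, m in PUBLISHED_MODELS.items():
        if abs(duration - d) < 1e-9:
            return m
    raise KeyError(
        f"no published chance model for duration {duration}; use fit_chance_model"
    )


def fit_chance_model(
    duration: float,
    max_count: float = 51.5,
    n_sims: int = 20000,
    seed: int | np.random.Generator = 0,
    q: float = DEFAULT_Q,
    max_ratio: float = 3.0,
) -> ChanceDistanceModel:
    """Monte-Carlo fit of the chance-distance polynomial.

    For each simulation a base count ``n1`` is drawn uniformly from
    ``0..max_count`` and a partner count ``n2 = round(n1 * U(1/max_ratio,
    max_ratio))`` models across-trial rate disparity: with the default
    ``max_ratio`` of 3 the count *difference* can reach twice the base
    train's count. Both trains are uniform over ``[0, duration]``; the VP
    distance is regressed on the GM spike count with a fourth-order
    zero-intercept polynomial.
    """
    if n_sims < 1000:
        raise ValueError("n_sims >= 1000 required for a stable fit")
    if max_count <= 0:
        raise ValueError("degenerate rate grid: max_count must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nmax = int(np.floor(max_count))
    x = np.empty(n_sims)
    d = np.empty(n_sims)
    for k in range(n_sims):
        n1 = rng.integers(0, nmax + 1)
        ratio = rng.uniform(1.0 / max_ratio, max_ratio)
        n2 = int(round(n1 * ratio))
        a = np.sort(rng.uniform(0, duration, n1))
        b = np.sort(rng.uniform(0, duration, n2))
        x[k] = np.sqrt(n1 * n2)
        d[k] = vp_distance(a, b, q)
    # zero-intercept quartic least squares
    basis = np.vstack([x**4, x**3, x**2, x]).T
    coeffs, *_ = np.linalg.lstsq(basis, d, rcond=None)
    return ChanceDistanceModel(
        duration=duration,
        coeffs=tuple(float(c) for c in coeffs),
        fit_range=(0.0, max_count),
    )


def corrected_distance(raw: float, gm_count: float, model: ChanceDistanceModel) -> float:
    """Raw distance minus the chance expectation at GM spike count ``gm_count``."""
    lo, hi = model.fit_range
    if gm_count > hi * 1.2:
        warnings.warn(
            f"GM count {gm_count:.1f} well outside the fit range {model.fit_range}",
            stacklevel=2,
        )
    return float(raw - model.expected_distance(gm_count))
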