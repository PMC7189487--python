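"""Correlation machinery for rate-vs-metric analyses.

Per-unit correlations are Fisher z-transformed for group statistics and
converted back to r for reporting. Pooled analyses first normalize each
unit's rates and metric values (max or min-max) so that units with different
dynamic ranges contribute comparably. Distance-vs-rate analyses use Spearman
rank correlation because corrected distances are heteroscedastic with
outliers (flagged by the MAD rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-12


def fisher_z(r) -> np.ndarray | float:
    """atanh(r) with |r| clipped just below 1 so perfect units stay finite."""
    r = np.clip(np.asarray(r, float), -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def inverse_fisher_z(z) -> np.ndarray | float:
    z = np.asarray(z, float)
    r = np.tanh(z)
    return float(r) if r.ndim == 0 else r


def _corr(x, y, method: str):
    if method == "pearson":
        return sps.pearsonr(x, y)
    if method == "spearman":
        return sps.spearmanr(x, y)
    raise ValueError("method must be 'pearson' or 'spearman'")


@dataclass
class PerUnitCorrelation:
    per_unit: pd.DataFrame  # unit, r, z, n
    mean_r: float  # tanh of mean z (reported back on the r scale)
    mean_r_arithmetic: float
    sd_r: float
    t_stat: float
    p_value: float
    excluded: list


def per_unit_correlation(
    table: pd.DataFrame,
    method: str = "pearson",
    unit_col: str = "unit_id",
    x_col: str = "rate",
    y_col: str = "metric",
    min_points: int = 3,
) -> PerUnitCorrelation:
    """Correlation of metric vs rate within each unit, aggregated via Fisher z.

    Units with a constant metric or rate (r undefined) or fewer than
    ``min_points`` conditions are excluded and logged. The group test is a
    two-tailed one-sample t test on the z values.
    """
    rows, excluded = [], []
    for unit, g in table.groupby(unit_col, sort=False):
        x, y = g[x_col].to_numpy(float), g[y_col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < min_points or np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded.append(unit)
            logger.info("unit %s excluded from correlation (constant or <%d points)",
                        unit, min_points)
            continue
        r = float(_corr(x, y, method)[0])
        rows.append({unit_col: unit, "r": r, "z": fisher_z(r), "n": x.size})
    per_unit = pd.DataFrame(rows, columns=[unit_col, "r", "z", "n"])
    if per_unit.empty:
        raise ValueError("no unit had enough usable points")
    z = per_unit["z"].to_numpy()
    if z.size > 1 and np.ptp(z) > 0:
        t_stat, p = sps.ttest_1samp(z, 0.0)
    else:
        t_stat, p = np.nan, np.nan
    return PerUnitCorrelation(
        per_unit=per_unit,
        mean_r=float(inverse_fisher_z(z.mean())),
        mean_r_arithmetic=float(per_unit["r"].mean()),
        sd_r=float(per_unit["r"].std(ddof=1)) if len(per_unit) > 1 else 0.0,
        t_stat=float(t_stat),
        p_value=float(p),
        excluded=excluded,
    )


def pooled_correlation(
    table: pd.DataFrame,
    method: str = "pearson",
    normalize: str = "max",
    unit_col: str = "unit_id",
    x_col: str = "rate",
    y_col: str = "metric",
) -> tuple[float, float]:
    """Correlation after pooling per-unit normalized points across units.

    ``normalize``: 'max' divides each unit's x and y by the unit maximum,
    'minmax' maps them onto [0, 1], 'none' pools raw values. Units whose
    normalizer is degenerate (max or range equal to zero) are excluded.
    """
    xs, ys = [], []
    for unit, g in table.groupby(unit_col, sort=False):
        x, y = g[x_col].to_numpy(float), g[y_col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size == 0:
            continue
        if normalize == "max":
            if x.max() <= 0 or np.abs(y).max() == 0:
                continue
            x, y = x / x.max(), y / np.abs(y).max()
        elif normalize == "minmax":
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            x = (x - x.min()) / np.ptp(x)
            y = (y - y.min()) / np.ptp(y)
        elif normalize != "none":
            raise ValueError("normalize must be 'max', 'minmax' or 'none'")
        xs.append(x)
        ys.append(y)
    if not xs:
        raise ValueError("no unit survived normalization")
    x, y = np.concatenate(xs), np.concatenate(ys)
    r, p = _corr(x, y, method)
    return float(r), float(p)


@dataclass
class SlopeRangeComparison:
    slopes_a: pd.Series
    slopes_b: pd.Series
    slope_stat: float
    slope_p: float
    ranges_a: pd.Series
    ranges_b: pd.Series
    range_stat: float
    range_p: float


def slope_and_range_compare(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    unit_col: str = "unit_id",
    x_col: str = "rate",
    y_col: str = "metric",
    min_points: int = 3,
) -> SlopeRangeComparison:
    """Per-unit OLS slopes of metric-vs-rate for two cue types, compared with
    a paired two-tailed Wilcoxon signed-rank test; per-unit rate dynamic
    ranges (max - min) compared with a paired t test."""

    def per_unit(table):
        slopes, ranges = {}, {}
        for unit, g in table.groupby(unit_col, sort=False):
            x, y = g[x_col].to_numpy(float), g[y_col].to_numpy(float)
            if x.size < min_points or np.ptp(x) == 0:
                continue
            slopes[unit] = float(np.polyfit(x, y, 1)[0])
            ranges[unit] = float(np.ptp(x))
        return pd.Series(slopes), pd.Series(ranges)

    sa, ra = per_unit(table_a)
    sb, rb = per_unit(table_b)
    common = sa.index.intersection(sb.index)
    if len(common) < 2:
        raise ValueError("need >=2 units measured under both cue types")
    sa, sb, ra, rb = sa[common], sb[common], ra[common], rb[common]
    diffs = (sa - sb).to_numpy()
    if np.allclose(diffs, 0):
        slope_stat, slope_p = 0.0, 1.0
    else:
        slope_stat, slope_p = sps.wilcoxon(sa, sb)
    rdiffs = (ra - rb).to_numpy()
    if np.allclose(rdiffs, 0):
        range_stat, range_p = 0.0, 1.0
    else:
        range_stat, range_p = sps.ttest_rel(ra, rb)
    return SlopeRangeComparison(sa, sb, float(slope_stat), float(slope_p),
                                ra, rb, float(range_stat), float(range_p))


def mad_outliers(values, threshold: float = 3.0) -> np.ndarray:
    """Boolean flags for |x - median| / (1.4826 * MAD) > threshold.

    The 1.4826 factor scales the MAD to the SD of a normal distribution, so
    threshold 3 flags ~0.3% of clean Gaussian data. When the MAD collapses to
    zero (a majority of identical values) the scaled threshold is zero and
    every value off the median is flagged, with a warning that the rule has
    degenerated; a fully constant vector flags nothing.
    """
    x = np.asarray(values, float)
    if x.size < 5:
        raise ValueError("MAD outlier detection needs >=5 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; flagging any deviation from the median",
                      stacklevel=2)
        return x != med
    return np.abs(x - med) / (1.4826 * mad) > threshold


def is_normal(values, alpha: float = 0.05) -> bool:
    """D'Agostino-Pearson normality gate used to pick t vs rank tests."""
    stat, p = sps.normaltest(np.asarray(values, float))
    logger.info("normality test p=%.4g -> %s", p, "parametric" if p >= alpha else "non-parametric")
    return bool(p >= alpha)
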