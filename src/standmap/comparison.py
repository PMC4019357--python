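"""Plot-versus-map agreement: extraction, regression, distributional tests.

Field plots and map pixels are compared by (1) extracting, for each plot
cluster, the mean of the pixel values containing its four subplot centers
(one pixel for single-plot designs), (2) regressing mapped on field values
(OLS slope and R²; RMSE from raw pair differences), (3) the two-sample
Kolmogorov–Smirnov sup-distance between the field and mapped empirical
CDFs, and (4) the fraction of plots whose field 95% CI overlaps the pixel
95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster import Raster
from .synthetic import MODE_NFI, PlotCluster
from .uncertainty import PlotCI

__all__ = [
    "ComparisonStats",
    "extract_plot_prediction",
    "agreement_regression",
    "ks_statistic",
    "ci_overlap_fraction",
    "cdf_table",
]

log = logging.getLogger(__name__)


@dataclass
class ComparisonStats:
    r_squared: float
    slope: float
    intercept: float
    rmse: float  # Mg/ha
    ks: float | None = None
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared out of [0, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.ks is not None and not 0.0 <= self.ks <= 1.0:
            raise ValueError("KS statistic out of [0, 1]")


def extract_plot_prediction(raster: Raster, cluster: PlotCluster) -> float:
    """Mean of the pixel values containing the cluster's subplot centers.

    Pixel membership uses the raster's half-open convention
    ``[x, x+s) x (y-s, y]``.  A subplot outside the extent raises; a
    no-data pixel raises ValueError (callers exclude the pair and log).
    """
    vals = []
    for x, y in cluster.subplot_centers:
        v = raster.value_at(x, y)
        if raster.is_nodata(v):
            raise ValueError(
                f"no-data pixel at subplot ({x:.1f}, {y:.1f}) of plot "
                f"{cluster.plot_id}"
            )
        vals.append(v)
    if cluster.inventory_mode == MODE_NFI:
        return vals[0]
    return float(np.mean(vals))


def extract_paired_values(
    raster: Raster, clusters: list[PlotCluster], field_values: list[float]
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pair field values with extracted pixel means, excluding no-data plots.

    Returns (field, mapped, excluded_plot_ids); exclusions are logged.
    """
    if len(clusters) != len(field_values):
        raise ValueError("clusters and field_values must be paired")
    f, m, excluded = [], [], []
    for cl, fv in zip(clusters, field_values):
        try:
            mv = extract_plot_prediction(raster, cl)
        except ValueError as err:
            log.warning("excluding plot %s: %s", cl.plot_id, err)
            excluded.append(cl.plot_id)
            continue
        f.append(fv)
        m.append(mv)
    return np.asarray(f), np.asarray(m), excluded


def agreement_regression(field: np.ndarray, mapped: np.ndarray) -> ComparisonStats:
    """OLS of mapped (y) on field (x) plus raw-difference RMSE.

    The regression direction is fixed (mapped on field) so a slope above 1
    means the map over-predicts.  RMSE is computed from the raw pair
    differences ``mapped - field`` by default — it measures map error
    directly rather than scatter about the fitted line.
    """
    field = np.asarray(field, dtype=float)
    mapped = np.asarray(mapped, dtype=float)
    if len(field) != len(mapped):
        raise ValueError("field and mapped must be paired")
    if len(field) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(field) == 0:
        raise ValueError("zero variance in field values: regression undefined")
    res = stats.linregress(field, mapped)
    rmse = float(np.sqrt(np.mean((mapped - field) ** 2)))
    return ComparisonStats(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=rmse,
        ks=float(ks_statistic(field, mapped)),
        n_pairs=len(field),
    )


def residual_rmse(field: np.ndarray, mapped: np.ndarray) -> float:
    """RMSE about the fitted OLS line (the alternative RMSE convention)."""
    res = stats.linregress(field, mapped)
    fitted = res.intercept + res.slope * np.asarray(field, dtype=float)
    return float(np.sqrt(np.mean((np.asarray(mapped) - fitted) ** 2)))


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov sup-distance between empirical CDFs.

    0 for identical distributions, 1 for fully separated supports; higher
    values reflect poorer agreement.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS statistic needs two non-empty samples")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def ci_overlap_fraction(
    field_cis: list[PlotCI] | list[tuple[float, float]],
    pixel_cis: list[tuple[float, float]],
) -> float:
    """Fraction of paired closed intervals that intersect.

    Touching endpoints count as overlap.
    """
    if len(field_cis) != len(pixel_cis):
        raise ValueError("interval lists must be paired")
    if not field_cis:
        raise ValueError("empty interval lists")
    n_overlap = 0
    for f, p in zip(field_cis, pixel_cis):
        flo, fhi = (f.lower, f.upper) if isinstance(f, PlotCI) else f
        plo, phi = p
        if flo > fhi or plo > phi:
            raise ValueError("malformed interval (lower > upper)")
        if flo <= phi and plo <= fhi:
            n_overlap += 1
    return n_overlap / len(field_cis)


def cdf_table(sample: np.ndarray) -> np.ndarray:
    """Empirical CDF as a (k, 2) array of (sorted unique value, F(value))."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) == 0:
        raise ValueError("empty sample")
    values = np.sort(sample)
    uniq = np.unique(values)
    F = np.searchsorted(values, uniq, side="right") / len(values)
    return np.column_stack([uniq, F])
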