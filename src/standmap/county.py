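"""County-scale biomass estimation by three routes.

* DESIGN — the sample mean of plot densities (Mg/ha) with a t-interval,
  expanded to a county total by ``mean x area_ha x 1e-6`` Tg.
* PIXEL_SAMPLE — the same design estimator applied to map values extracted
  at the plot locations, mimicking the inventory sample design on the map.
* PIXEL_SUM — the full-map total: sum of 30-m pixel Mg/ha values times
  0.09 ha/pixel (recomputed from the actual pixel area when it differs),
  times 1e-6 for Tg; uncertainty bands only when the map carries per-pixel
  intervals, summed the same way.

Plus the nonforest decomposition (all-tree total minus forest-only total)
and pairwise estimate gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .comparison import extract_paired_values, extract_plot_prediction
from .raster import Raster
from .synthetic import PlotCluster

__all__ = [
    "CountyEstimate",
    "design_estimate",
    "pixel_sample_estimate",
    "pixel_sum_estimate",
    "nonforest_share",
    "estimate_gap",
]

log = logging.getLogger(__name__)

METHOD_DESIGN = "DESIGN"
METHOD_PIXEL_SAMPLE = "PIXEL_SAMPLE"
METHOD_PIXEL_SUM = "PIXEL_SUM"

MG_PER_TG = 1e6


@dataclass
class CountyEstimate:
    """Mean (Mg/ha) and total (Tg) biomass with 95% CIs for one area."""

    method: str
    mean: float | None  # Mg/ha
    mean_ci: tuple[float, float] | None
    total: float  # Tg
    total_ci: tuple[float, float] | None
    n: int  # plots or pixels
    area_ha: float | None = None

    def __post_init__(self) -> None:
        for ci in (self.mean_ci, self.total_ci):
            if ci is not None and ci[0] > ci[1]:
                raise ValueError("CI bounds out of order")


def _t_interval(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Textbook t-interval for the mean (n-1 degrees of freedom)."""
    n = len(values)
    m = float(np.mean(values))
    se = float(np.std(values, ddof=1)) / np.sqrt(n)
    if se == 0:
        return (m, m)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return (m - tcrit * se, m + tcrit * se)


def _bootstrap_interval(
    values: np.ndarray, level: float = 0.95, n_boot: int = 5000, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = np.asarray(values)[idx].mean(axis=1)
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    lo, hi = np.percentile(means, q)
    return float(lo), float(hi)


def design_estimate(
    plot_values: np.ndarray,
    county_area: float,
    ci_method: str = "t",
    seed: int = 0,
) -> CountyEstimate:
    """Design-based expansion of plot densities to a county mean and total.

    ``total_Tg = mean_Mgha x area_ha x 1e-6``; the CI is a t-interval on
    the plot sample by default (``ci_method="bootstrap"`` for a percentile
    bootstrap alternative).
    """
    plot_values = np.asarray(plot_values, dtype=float)
    if county_area <= 0:
        raise ValueError("county_area must be positive")
    if len(plot_values) < 2:
        raise ValueError("need at least 2 plots for a design estimate with a CI")
    mean = float(np.mean(plot_values))
    if ci_method == "t":
        ci = _t_interval(plot_values)
    elif ci_method == "bootstrap":
        ci = _bootstrap_interval(plot_values, seed=seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    to_tg = county_area / MG_PER_TG
    return CountyEstimate(
        method=METHOD_DESIGN,
        mean=mean,
        mean_ci=ci,
        total=mean * to_tg,
        total_ci=(ci[0] * to_tg, ci[1] * to_tg),
        n=len(plot_values),
        area_ha=county_area,
    )


def pixel_sample_estimate(
    raster: Raster,
    clusters: list[PlotCluster],
    county_area: float,
    ci_method: str = "t",
) -> CountyEstimate:
    """Design estimator applied to map values sampled at the plot locations."""
    if len(clusters) < 2:
        raise ValueError("need at least 2 plots for a design estimate with a CI")
    vals, mapped, _excluded = extract_paired_values(
        raster, clusters, [0.0] * len(clusters)
    )
    est = design_estimate(mapped, county_area, ci_method=ci_method)
    return CountyEstimate(
        method=METHOD_PIXEL_SAMPLE,
        mean=est.mean,
        mean_ci=est.mean_ci,
        total=est.total,
        total_ci=est.total_ci,
        n=est.n,
        area_ha=county_area,
    )


def pixel_sum_estimate(
    raster: Raster,
    lower: Raster | None = None,
    upper: Raster | None = None,
    county_area: float | None = None,
) -> CountyEstimate:
    """Full-map total: sum pixels (Mg/ha) x ha-per-pixel x 1e-6 Tg.

    The 0.09 factor applies to 30-m pixels; any other pixel size recomputes
    the factor from the actual pixel area (logged).  Bounds rasters, when
    provided, are summed identically to give a total CI.
    """
    factor = raster.pixel_area_ha
    if not np.isclose(raster.pixel_size, 30.0):
        log.info(
            "pixel size %.3f m != 30 m: using %.6f ha/pixel instead of 0.09",
            raster.pixel_size,
            factor,
        )
    valid = ~np.isclose(raster.values, raster.nodata) & ~np.isnan(raster.values)
    total = float(raster.values[valid].sum()) * factor / MG_PER_TG
    total_ci = None
    if lower is not None and upper is not None:
        lo = float(lower.values[valid].sum()) * factor / MG_PER_TG
        hi = float(upper.values[valid].sum()) * factor / MG_PER_TG
        total_ci = (lo, hi)
    mean = None
    if county_area:
        mean = total * MG_PER_TG / county_area
    return CountyEstimate(
        method=METHOD_PIXEL_SUM,
        mean=mean,
        mean_ci=None,
        total=total,
        total_ci=total_ci,
        n=int(valid.sum()),
        area_ha=county_area,
    )


def nonforest_share(total_all_trees: float, total_forest_only: float) -> dict:
    """Biomass on nonforest land: Tg difference and percent of the all-tree total."""
    if not total_all_trees >= total_forest_only >= 0:
        raise ValueError(
            "totals out of order: need total_all_trees >= total_forest_only >= 0"
        )
    diff = total_all_trees - total_forest_only
    pct = 100.0 * diff / total_all_trees if total_all_trees > 0 else 0.0
    return {"nonforest_tg": diff, "nonforest_pct": pct}


def estimate_gap(estimate_a: CountyEstimate, estimate_b: CountyEstimate) -> dict:
    """Signed gap between two county estimates of the same area.

    Returns the total difference (a - b, Tg), the percent difference
    relative to b, and whether a's total lies inside b's 95% total CI.
    """
    diff = estimate_a.total - estimate_b.total
    pct = 100.0 * diff / estimate_b.total if estimate_b.total != 0 else float("nan")
    within = None
    if estimate_b.total_ci is not None:
        lo, hi = estimate_b.total_ci
        within = bool(lo <= estimate_a.total <= hi)
    return {"difference_tg": diff, "pct_difference": pct, "within_ci": within}
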