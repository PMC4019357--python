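"""Synthetic landscapes, plot networks, tree lists and LIDAR-style metrics.

Everything downstream of real inventory + LIDAR data assumes a particular
statistical structure: biomass varies smoothly in space (an exponential-
covariance Gaussian process), inventory plots are clustered subplots placed
systematically, stem diameters follow a Weibull distribution, trees on
"nonforest" land are censored by the standard inventory protocol, and LIDAR
metrics are noisy monotone transforms of biomass.  This module generates
data with exactly that structure so the full pipeline is testable without
any external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raster import Raster

__all__ = [
    "FOREST",
    "NONFOREST",
    "GridSpec",
    "TrueSurface",
    "PlotCluster",
    "StandParams",
    "generate_biomass_surface",
    "generate_plot_network",
    "generate_tree_list",
    "generate_lidar_metrics",
    "calibrate_lidar_noise",
    "apply_inventory_protocol",
    "TreeRecord",
]

FOREST = "forest"
NONFOREST = "nonforest"

#: plot geometry defaults: 4 clustered subplots of 168 m2 spaced 7 m apart
#: (center + 3 satellites); the single-plot nonforest-inventory design uses
#: one 400 m2 center plot.
SUBPLOT_AREA_M2 = 168.0
SUBPLOT_SPACING_M = 7.0
NFI_PLOT_AREA_M2 = 400.0

MODE_FIA = "FIA"
MODE_NFI = "NFI"
MODE_FIA_LIKE = "FIA_LIKE"
_MODES = (MODE_FIA, MODE_NFI, MODE_FIA_LIKE)


@dataclass(frozen=True)
class GridSpec:
    """A north-up raster grid in a projected CRS (meters)."""

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x of west edge, y of south edge)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def width_m(self) -> float:
        return self.n_cols * self.pixel_size

    @property
    def height_m(self) -> float:
        return self.n_rows * self.pixel_size

    @property
    def y_top(self) -> float:
        return self.origin[1] + self.height_m

    @property
    def area_ha(self) -> float:
        return self.width_m * self.height_m / 1e4

    def empty_raster(self, fill: float = 0.0) -> Raster:
        return Raster(
            np.full((self.n_rows, self.n_cols), fill, dtype=float),
            x0=self.origin[0],
            y_top=self.y_top,
            pixel_size=self.pixel_size,
        )


@dataclass
class TrueSurface:
    """Ground-truth biomass (Mg/ha) and forest/nonforest condition per pixel."""

    grid: GridSpec
    biomass: np.ndarray  # (n_rows, n_cols), Mg/ha, >= 0
    condition: np.ndarray  # (n_rows, n_cols), {"forest", "nonforest"}

    def __post_init__(self) -> None:
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.biomass.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("biomass shape does not match grid")
        if self.condition.shape != self.biomass.shape:
            raise ValueError("condition shape does not match grid")
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be non-negative")

    def to_raster(self) -> Raster:
        return Raster(
            self.biomass.copy(),
            x0=self.grid.origin[0],
            y_top=self.grid.y_top,
            pixel_size=self.grid.pixel_size,
        )

    @property
    def nonforest_mask(self) -> np.ndarray:
        return self.condition == NONFOREST

    def nonforest_biomass_share(self) -> float:
        """Share of total landscape biomass on nonforest-labeled pixels."""
        total = float(self.biomass.sum())
        if total == 0:
            return 0.0
        return float(self.biomass[self.nonforest_mask].sum()) / total

    def condition_at(self, x: float, y: float) -> str:
        r = self.to_raster()
        i, j = r.index_of(x, y)
        return str(self.condition[i, j])

    def biomass_at(self, x: float, y: float) -> float:
        r = self.to_raster()
        i, j = r.index_of(x, y)
        return float(self.biomass[i, j])


@dataclass
class PlotCluster:
    """One inventory plot: a cluster of subplot centers.

    The standard design is 4 subplots of 168 m2 (center + 3 satellites
    spaced ``spacing`` m from it); the nonforest-inventory (NFI) design is a
    single 400 m2 center plot.
    """

    plot_id: int
    subplot_centers: list[tuple[float, float]]
    subplot_area: float = SUBPLOT_AREA_M2
    inventory_mode: str = MODE_FIA

    def __post_init__(self) -> None:
        if self.inventory_mode not in _MODES:
            raise ValueError(f"unknown inventory mode {self.inventory_mode!r}")
        n_expected = 1 if self.inventory_mode == MODE_NFI else 4
        if len(self.subplot_centers) != n_expected:
            raise ValueError(
                f"{self.inventory_mode} cluster needs {n_expected} subplots, "
                f"got {len(self.subplot_centers)}"
            )

    @property
    def center(self) -> tuple[float, float]:
        return self.subplot_centers[0]

    @property
    def sampled_area_m2(self) -> float:
        return self.subplot_area * len(self.subplot_centers)


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem."""

    plot_id: int
    subplot_id: int
    condition: str
    species_group: str
    dbh_cm: float
    bole_height_m: float


@dataclass
class StandParams:
    """Stand-structure parameters controlling synthetic tree lists.

    Stem diameters are Weibull(shape, scale) in cm.  The expected stem count
    on a subplot is biomass-proportional: local Mg/ha divided by the mean
    single-tree biomass implied by the Weibull under a nominal ln-ln
    allometry, so that plot-summed biomass tracks the surface.
    ``stems_per_ha`` optionally caps the density per broad class.
    """

    weibull_shape: float = 2.0
    weibull_scale: float = 22.0
    species_mix: dict[str, float] = field(
        default_factory=lambda: {
            "red_maple": 0.25,
            "white_oak": 0.20,
            "yellow_poplar": 0.20,
            "sweetgum": 0.15,
            "loblolly_pine": 0.20,
        }
    )
    stems_per_ha: dict[str, float] | None = None  # per density class cap
    # nominal ln-ln coefficients used only to scale stem counts
    nominal_b0: float = -2.48
    nominal_b1: float = 2.4835

    def __post_init__(self) -> None:
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        total = sum(self.species_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("species_mix proportions must sum to 1")

    def mean_tree_biomass_mg(self) -> float:
        """E[biomass] of one stem in Mg, closed form for Weibull DBH.

        E[D^b1] = scale^b1 * Gamma(1 + b1/shape).
        """
        k = self.nominal_b1 / self.weibull_shape
        e_dbh_pow = self.weibull_scale**self.nominal_b1 * math.gamma(1.0 + k)
        return math.exp(self.nominal_b0) * e_dbh_pow / 1000.0


# ---------------------------------------------------------------------------
# biomass surface
# ---------------------------------------------------------------------------


def generate_biomass_surface(
    grid: GridSpec,
    spatial_params: dict,
    nonforest_fraction: float,
    seed: int,
    *,
    scattered_trees: bool = True,
    nonforest_biomass_share: float | None = None,
) -> TrueSurface:
    """Simulate a true biomass surface with exponential spatial covariance.

    The field is a Gaussian random field with covariance
    ``sill * exp(-decay * d)`` (d in meters) around ``mean``, clipped at
    zero.  Contiguous rectangular blocks covering ``nonforest_fraction`` of
    the pixels are labeled nonforest; with ``scattered_trees`` those pixels
    keep (possibly rescaled) biomass — isolated trees in yards and
    rights-of-way — otherwise they are zeroed.

    Parameters
    ----------
    spatial_params : dict with keys ``sill`` (Mg/ha)^2, ``decay`` (1/m),
        ``mean`` (Mg/ha).
    nonforest_biomass_share : if given (and ``scattered_trees``), rescale
        nonforest-pixel biomass so that exactly this share of total
        landscape biomass sits on nonforest pixels.
    """
    sill = float(spatial_params["sill"])
    decay = float(spatial_params["decay"])
    mean = float(spatial_params.get("mean", 0.0))
    if sill <= 0 or decay <= 0:
        raise ValueError("sill and decay must be positive")
    if not 0.0 <= nonforest_fraction <= 1.0:
        raise ValueError("nonforest_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n = grid.n_rows * grid.n_cols
    s = grid.pixel_size
    xs = (np.arange(grid.n_cols) + 0.5) * s
    ys = (np.arange(grid.n_rows) + 0.5) * s
    xx, yy = np.meshgrid(xs, ys)
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    d = np.hypot(
        coords[:, None, 0] - coords[None, :, 0],
        coords[:, None, 1] - coords[None, :, 1],
    )
    cov = sill * np.exp(-decay * d)
    cov[np.diag_indices(n)] += 1e-8 * sill
    chol = np.linalg.cholesky(cov)
    z = mean + chol @ rng.standard_normal(n)
    biomass = np.clip(z, 0.0, None).reshape(grid.n_rows, grid.n_cols)

    condition = np.full(biomass.shape, FOREST, dtype=object)
    target = int(round(nonforest_fraction * n))
    if target > 0:
        _carve_nonforest_blocks(condition, target, rng)
    nf = condition == NONFOREST

    if not scattered_trees:
        biomass[nf] = 0.0
    elif nonforest_biomass_share is not None:
        if not 0.0 <= nonforest_biomass_share < 1.0:
            raise ValueError("nonforest_biomass_share must be in [0, 1)")
        forest_total = biomass[~nf].sum()
        nf_total = biomass[nf].sum()
        if nf_total > 0 and forest_total > 0:
            s_target = nonforest_biomass_share
            factor = (s_target / (1.0 - s_target)) * forest_total / nf_total
            biomass[nf] *= factor

    condition = condition.astype(str)
    return TrueSurface(grid=grid, biomass=biomass, condition=condition)


def _carve_nonforest_blocks(condition: np.ndarray, target: int, rng) -> None:
    """Label ~target pixels nonforest as random rectangles, trimmed to exact."""
    n_rows, n_cols = condition.shape
    max_side = max(2, min(n_rows, n_cols) // 4)
    guard = 0
    while (condition == NONFOREST).sum() < target and guard < 10_000:
        guard += 1
        h = int(rng.integers(1, max_side + 1))
        w = int(rng.integers(1, max_side + 1))
        i = int(rng.integers(0, max(1, n_rows - h + 1)))
        j = int(rng.integers(0, max(1, n_cols - w + 1)))
        condition[i : i + h, j : j + w] = NONFOREST
    # trim overshoot back to the exact pixel count
    nf_idx = np.flatnonzero((condition == NONFOREST).ravel())
    excess = len(nf_idx) - target
    if excess > 0:
        drop = rng.choice(nf_idx, size=excess, replace=False)
        condition.ravel()[drop] = FOREST


# ---------------------------------------------------------------------------
# plot network
# ---------------------------------------------------------------------------


def _cluster_offsets(mode: str, spacing: float) -> list[tuple[float, float]]:
    if mode == MODE_NFI:
        return [(0.0, 0.0)]
    # center + 3 satellites at azimuths 0, 120, 240 degrees
    offs = [(0.0, 0.0)]
    for az_deg in (0.0, 120.0, 240.0):
        az = math.radians(az_deg)
        offs.append((spacing * math.sin(az), spacing * math.cos(az)))
    return offs


def generate_plot_network(
    grid: GridSpec,
    n_plots: int,
    mode: str = MODE_FIA,
    seed: int = 0,
    *,
    spacing: float = SUBPLOT_SPACING_M,
    surface: TrueSurface | None = None,
) -> list[PlotCluster]:
    """Place plot clusters on a systematic lattice with a random start.

    FIA/FIA_LIKE clusters have 4 subplots of 168 m2 (satellites ``spacing``
    m from the center); NFI plots are single 400 m2 circles.  FIA_LIKE
    placement is restricted to forest-labeled pixels of ``surface``.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown inventory mode {mode!r}")
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if mode == MODE_FIA_LIKE and surface is None:
        raise ValueError("FIA_LIKE placement needs the true surface")

    rng = np.random.default_rng(seed)
    margin = spacing + 1.0  # keep satellites inside the grid
    x_lo = grid.origin[0] + margin
    y_lo = grid.origin[1] + margin
    w_eff = grid.width_m - 2 * margin
    h_eff = grid.height_m - 2 * margin
    if w_eff <= 0 or h_eff <= 0:
        raise ValueError("grid too small for the requested plot geometry")

    # oversample candidates for FIA_LIKE so forest-only filtering can succeed
    n_candidates = n_plots if mode != MODE_FIA_LIKE else max(4 * n_plots, n_plots + 8)
    k_x = max(1, int(round(math.sqrt(n_candidates * w_eff / h_eff))))
    k_y = int(math.ceil(n_candidates / k_x))
    sx = w_eff / k_x
    sy = h_eff / k_y
    if min(sx, sy) < 2 * spacing:
        raise ValueError(
            f"grid capacity exceeded: lattice spacing {min(sx, sy):.1f} m "
            f"would overlap cluster footprints (need >= {2 * spacing:.1f} m)"
        )
    u, v = rng.uniform(0, 1, size=2)
    centers = [
        (x_lo + (i + u) * sx, y_lo + (j + v) * sy)
        for j in range(k_y)
        for i in range(k_x)
    ]

    if mode == MODE_FIA_LIKE:
        centers = [
            c for c in centers if surface.condition_at(c[0], c[1]) == FOREST
        ]
    if len(centers) < n_plots:
        raise ValueError(
            f"grid capacity exceeded: {len(centers)} candidate positions "
            f"for {n_plots} requested plots"
        )
    centers = centers[:n_plots]

    offsets = _cluster_offsets(mode, spacing)
    area = NFI_PLOT_AREA_M2 if mode == MODE_NFI else SUBPLOT_AREA_M2
    clusters = []
    for pid, (cx, cy) in enumerate(centers):
        subs = [(cx + dx, cy + dy) for dx, dy in offsets]
        clusters.append(
            PlotCluster(
                plot_id=pid,
                subplot_centers=subs,
                subplot_area=area,
                inventory_mode=mode,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# tree lists
# ---------------------------------------------------------------------------


def generate_tree_list(
    cluster: PlotCluster,
    surface: TrueSurface,
    stand: StandParams,
    seed: int,
) -> list[TreeRecord]:
    """Draw a synthetic tree list for one plot cluster.

    Per subplot, the expected stem count is the local surface biomass times
    the subplot area divided by the mean single-tree biomass implied by the
    stand's Weibull DBH distribution (Poisson-distributed), so plot-summed
    biomass tracks the surface.  Each tree inherits the condition label of
    its subplot's pixel.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = surface.to_raster().bounds
    for x, y in cluster.subplot_centers:
        if not (xmin <= x < xmax and ymin < y <= ymax):
            raise ValueError(f"subplot center ({x}, {y}) outside surface extent")

    mean_tree_mg = stand.mean_tree_biomass_mg()
    area_ha = cluster.subplot_area / 1e4
    species = list(stand.species_mix)
    probs = np.array([stand.species_mix[s] for s in species])

    trees: list[TreeRecord] = []
    for sub_id, (x, y) in enumerate(cluster.subplot_centers):
        b_local = surface.biomass_at(x, y)  # Mg/ha
        cond = surface.condition_at(x, y)
        lam = b_local * area_ha / mean_tree_mg
        if stand.stems_per_ha:
            cap = max(stand.stems_per_ha.values()) * area_ha
            lam = min(lam, cap)
        n_trees = int(rng.poisson(lam))
        if n_trees == 0:
            continue
        dbhs = stand.weibull_scale * rng.weibull(stand.weibull_shape, size=n_trees)
        dbhs = np.clip(dbhs, 2.5, None)  # below-breast-height stems not tallied
        sp = rng.choice(species, size=n_trees, p=probs)
        # bole height: monotone power law in DBH with 10% multiplicative noise
        heights = 1.3 * dbhs**0.72 * np.exp(rng.normal(0.0, 0.1, size=n_trees))
        for d, h, spg in zip(dbhs, heights, sp):
            trees.append(
                TreeRecord(
                    plot_id=cluster.plot_id,
                    subplot_id=sub_id,
                    condition=cond,
                    species_group=str(spg),
                    dbh_cm=float(d),
                    bole_height_m=float(h),
                )
            )
    return trees


# ---------------------------------------------------------------------------
# LIDAR-style metrics
# ---------------------------------------------------------------------------


def generate_lidar_metrics(
    surface: TrueSurface,
    link_params: dict,
    n_metrics: int = 3,
    seed: int = 0,
) -> list[Raster]:
    """Emulate LIDAR canopy metrics: noisy monotone power links of biomass.

    Metric k = scale_k * biomass^exponent + N(0, noise_sd).  All metrics
    share the biomass signal, hence are mutually correlated, mimicking
    height percentiles / density / cover metrics.
    """
    if n_metrics < 1:
        raise ValueError("n_metrics must be >= 1")
    exponent = float(link_params.get("exponent", 0.7))
    noise_sd = float(link_params.get("noise_sd", 1.0))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    base = surface.biomass**exponent
    template = surface.to_raster()
    rasters = []
    for k in range(n_metrics):
        scale = 1.0 + 0.25 * k
        vals = scale * base + rng.normal(0.0, noise_sd, size=base.shape)
        rasters.append(template.copy_with(vals))
    return rasters


def calibrate_lidar_noise(
    surface: TrueSurface,
    target_r2: float,
    *,
    exponent: float = 0.7,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 60,
) -> float:
    """Find the metric noise SD giving a target R2 for metric -> biomass OLS.

    Bisection on noise_sd; the fit is a simple linear regression of biomass
    on the first metric over all pixels, refit after each generation.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")

    def achieved(sd: float) -> float:
        m = generate_lidar_metrics(
            surface, {"exponent": exponent, "noise_sd": sd}, 1, seed
        )[0]
        x = m.values.ravel()
        y = surface.biomass.ravel()
        r = np.corrcoef(x, y)[0, 1]
        return float(r**2)

    lo, hi = 0.0, 1.0
    while achieved(hi) > target_r2 and hi < 1e6:
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r2 = achieved(mid)
        if abs(r2 - target_r2) < tol:
            return mid
        if r2 > target_r2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# inventory protocol (forest/nonforest censoring)
# ---------------------------------------------------------------------------


def apply_inventory_protocol(trees: list[TreeRecord], mode: str) -> list[TreeRecord]:
    """Censor a tree list the way each inventory protocol would.

    FIA drops every tree whose condition is nonforest (the plot stays in
    the sample, possibly with zero trees); NFI keeps all trees on the
    single 400 m2 center plot; FIA_LIKE keeps everything (placement was
    already restricted to forest).
    """
    if mode == MODE_FIA:
        return [t for t in trees if t.condition != NONFOREST]
    if mode == MODE_NFI:
        return [t for t in trees if t.subplot_id == 0]
    if mode == MODE_FIA_LIKE:
        return list(trees)
    raise ValueError(f"unknown inventory mode {mode!r}")
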