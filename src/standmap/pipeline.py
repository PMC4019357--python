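"""Configuration, table I/O and the end-to-end synthetic experiment.

``run_pipeline`` reproduces the full analysis chain on a synthetic
landscape: generate truth and plots -> tree lists -> inventory censoring ->
allometric densities (three families) -> allometric-error propagation to
plot CIs -> LIDAR-metric generation -> spatial-Bayesian and random-forest
maps -> plot/pixel agreement statistics -> county-level estimates by all
three routes.  Every stage draws its seed deterministically from the master
seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry, comparison, county, mapping, synthetic, uncertainty
from .raster import Raster, read_ascii_grid, write_ascii_grid

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
    "write_tree_table",
    "read_tree_table",
    "write_plot_table",
    "read_plot_table",
]

log = logging.getLogger("standmap.pipeline")

TREE_COLUMNS = [
    "plot_id",
    "subplot_id",
    "condition",
    "species_group",
    "dbh_cm",
    "bole_height_m",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of master seed + stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs for one synthetic end-to-end experiment."""

    seed: int = 20140508
    # landscape
    n_rows: int = 40
    n_cols: int = 40
    pixel_size: float = 30.0
    spatial_sill: float = 2500.0
    spatial_decay: float = 0.01  # 1/m -> effective range 300 m
    spatial_mean: float = 60.0
    nonforest_fraction: float = 0.30
    nonforest_biomass_share: float = 0.25
    scattered_trees: bool = True
    # plots
    n_plots: int = 60
    subplot_spacing: float = synthetic.SUBPLOT_SPACING_M
    # stand structure
    weibull_shape: float = 2.0
    weibull_scale: float = 22.0
    # allometric error engine
    n_subsets: int = 100
    n_reps: int = 10_000
    # LIDAR metrics
    n_metrics: int = 3
    metric_exponent: float = 0.7
    metric_target_r2: float = 0.67
    # mapping
    mcmc_iters: int = 4000
    mcmc_burn_in: int = 2000
    mcmc_thin: int = 5
    predict_draws: int = 250
    rf_trees: int = 500
    # registry
    registry_path: str | None = None  # None -> packaged defaults

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def grid(self) -> synthetic.GridSpec:
        return synthetic.GridSpec(self.n_rows, self.n_cols, self.pixel_size)

    def stand(self) -> synthetic.StandParams:
        return synthetic.StandParams(
            weibull_shape=self.weibull_shape, weibull_scale=self.weibull_scale
        )

    def registry(self) -> allometry.EquationRegistry:
        if self.registry_path:
            return allometry.EquationRegistry.from_yaml(self.registry_path)
        return allometry.load_default_registry()


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def trees_to_dataframe(trees: list[synthetic.TreeRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in trees], columns=TREE_COLUMNS)


def trees_from_dataframe(df: pd.DataFrame) -> list[synthetic.TreeRecord]:
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tree table missing required columns: {missing}")
    return [
        synthetic.TreeRecord(
            plot_id=int(r.plot_id),
            subplot_id=int(r.subplot_id),
            condition=str(r.condition),
            species_group=str(r.species_group),
            dbh_cm=float(r.dbh_cm),
            bole_height_m=float(r.bole_height_m),
        )
        for r in df.itertuples()
    ]


def write_tree_table(trees: list[synthetic.TreeRecord], path: str | Path) -> None:
    trees_to_dataframe(trees).to_csv(path, index=False)


def read_tree_table(path: str | Path) -> list[synthetic.TreeRecord]:
    return trees_from_dataframe(pd.read_csv(path))


def write_plot_table(clusters: list[synthetic.PlotCluster], path: str | Path) -> None:
    rows = []
    for cl in clusters:
        for k, (x, y) in enumerate(cl.subplot_centers):
            rows.append(
                {
                    "plot_id": cl.plot_id,
                    "subplot_id": k,
                    "x": x,
                    "y": y,
                    "subplot_area_m2": cl.subplot_area,
                    "inventory_mode": cl.inventory_mode,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plot_table(path: str | Path) -> list[synthetic.PlotCluster]:
    df = pd.read_csv(path)
    required = {"plot_id", "subplot_id", "x", "y", "subplot_area_m2", "inventory_mode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plot table missing required columns: {sorted(missing)}")
    clusters = []
    for pid, grp in df.groupby("plot_id", sort=True):
        grp = grp.sort_values("subplot_id")
        clusters.append(
            synthetic.PlotCluster(
                plot_id=int(pid),
                subplot_centers=[(float(r.x), float(r.y)) for r in grp.itertuples()],
                subplot_area=float(grp.subplot_area_m2.iloc[0]),
                inventory_mode=str(grp.inventory_mode.iloc[0]),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic experiment; write artifacts; return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    registry = cfg.registry()
    grid = cfg.grid()
    stand = cfg.stand()
    area_ha = grid.area_ha

    # -- stage 1: true landscape -------------------------------------------
    log.info("stage=surface seed=%d", stage_seed(cfg.seed, "surface"))
    surface = synthetic.generate_biomass_surface(
        grid,
        {"sill": cfg.spatial_sill, "decay": cfg.spatial_decay, "mean": cfg.spatial_mean},
        cfg.nonforest_fraction,
        stage_seed(cfg.seed, "surface"),
        scattered_trees=cfg.scattered_trees,
        nonforest_biomass_share=cfg.nonforest_biomass_share,
    )
    write_ascii_grid(surface.to_raster(), out / "true_biomass.asc")

    # -- stage 2: plot network + tree lists --------------------------------
    clusters = synthetic.generate_plot_network(
        grid,
        cfg.n_plots,
        synthetic.MODE_FIA,
        stage_seed(cfg.seed, "plots"),
        spacing=cfg.subplot_spacing,
    )
    write_plot_table(clusters, out / "plots.csv")
    all_trees: list[synthetic.TreeRecord] = []
    per_plot_trees: dict[int, list[synthetic.TreeRecord]] = {}
    for cl in clusters:
        t = synthetic.generate_tree_list(
            cl, surface, stand, stage_seed(cfg.seed, f"trees:{cl.plot_id}")
        )
        per_plot_trees[cl.plot_id] = t
        all_trees.extend(t)
    write_tree_table(all_trees, out / "trees.csv")

    # -- stage 3: inventory censoring + allometric densities ---------------
    sampled_area = clusters[0].sampled_area_m2
    dens_all, dens_fia = [], []
    for cl in clusters:
        trees = per_plot_trees[cl.plot_id]
        trees_fia = synthetic.apply_inventory_protocol(trees, synthetic.MODE_FIA)
        dens_all.append(
            allometry.plot_biomass_density(
                trees, sampled_area, allometry.FAMILY_LNLN, registry
            )
        )
        dens_fia.append(
            allometry.plot_biomass_density(
                trees_fia, sampled_area, allometry.FAMILY_LNLN, registry
            )
        )
    dens_all = np.asarray(dens_all)
    dens_fia = np.asarray(dens_fia)

    choice = allometry.compare_allometry_choices(
        list(per_plot_trees.values()), registry, sampled_area
    )

    # -- stage 4: allometric error propagation -----------------------------
    groups = sorted({t.species_group for t in all_trees})
    se_functions = {}
    for g in groups:
        eq = allometry.resolve_group_equation(registry, allometry.FAMILY_LNLN, g)
        se_functions[g] = uncertainty.derive_mean_se_function(
            eq,
            {"shape": cfg.weibull_shape, "scale": cfg.weibull_scale},
            n_subsets=cfg.n_subsets,
            seed=stage_seed(cfg.seed, f"sefun:{g}"),
        )
    plot_cis = [
        uncertainty.propagate_plot_ci(
            per_plot_trees[cl.plot_id],
            se_functions,
            registry,
            sampled_area,
            n_reps=cfg.n_reps,
            seed=stage_seed(cfg.seed, f"plotci:{cl.plot_id}"),
            plot_id=cl.plot_id,
        )
        for cl in clusters
    ]
    pd.DataFrame(
        {
            "plot_id": [c.plot_id for c in plot_cis],
            "mean_mgha": [c.mean for c in plot_cis],
            "lo95": [c.lower for c in plot_cis],
            "hi95": [c.upper for c in plot_cis],
        }
    ).to_csv(out / "plot_ci.csv", index=False)
    widths = np.array([c.width for c in plot_cis])
    nonzero = np.array([c.mean for c in plot_cis]) > 0
    mean_width = float(widths[nonzero].mean()) if nonzero.any() else 0.0
    width_pct = (
        float(
            np.mean(
                [c.width_pct_of_mean for c in plot_cis if c.mean > 0]
            )
        )
        if nonzero.any()
        else float("nan")
    )

    # -- stage 5: LIDAR metrics --------------------------------------------
    noise_sd = synthetic.calibrate_lidar_noise(
        surface,
        cfg.metric_target_r2,
        exponent=cfg.metric_exponent,
        seed=stage_seed(cfg.seed, "lidar"),
    )
    metrics = synthetic.generate_lidar_metrics(
        surface,
        {"exponent": cfg.metric_exponent, "noise_sd": noise_sd},
        cfg.n_metrics,
        stage_seed(cfg.seed, "lidar"),
    )

    # -- stage 6: map fitting ----------------------------------------------
    coords = np.array([cl.center for cl in clusters])
    X_train = np.column_stack(
        [np.ones(len(clusters))]
        + [
            np.array([comparison.extract_plot_prediction(m, cl) for cl in clusters])
            for m in metrics
        ]
    )
    y_train = dens_all  # all-tree densities: the training inventory measures
    # every tree, like the variable-radius training data of a real campaign
    fit = mapping.fit_spatial_regression(
        y_train,
        X_train,
        coords,
        mcmc={
            "n_iter": cfg.mcmc_iters,
            "burn_in": cfg.mcmc_burn_in,
            "thin": cfg.mcmc_thin,
            "seed": stage_seed(cfg.seed, "mcmc"),
        },
    )
    px, py = surface.to_raster().pixel_centers()
    X_pix = np.column_stack(
        [np.ones(len(px))] + [m.values.ravel() for m in metrics]
    )
    pred = mapping.predict_posterior(
        fit,
        X_pix,
        np.column_stack([px, py]),
        n_draws=cfg.predict_draws,
        seed=stage_seed(cfg.seed, "predict"),
    )
    shape = (grid.n_rows, grid.n_cols)
    template = surface.to_raster()
    bay_mean = template.copy_with(pred.mean.reshape(shape))
    bay_lo = template.copy_with(pred.lower.reshape(shape))
    bay_hi = template.copy_with(pred.upper.reshape(shape))
    write_ascii_grid(bay_mean, out / "map_bay_mean.asc")
    write_ascii_grid(bay_lo, out / "map_bay_lo95.asc")
    write_ascii_grid(bay_hi, out / "map_bay_hi95.asc")

    rf = mapping.fit_ensemble_baseline(
        y_train,
        X_train[:, 1:],
        X_predict=X_pix[:, 1:],
        n_trees=cfg.rf_trees,
        seed=stage_seed(cfg.seed, "rf") % (2**31),
    )
    rf_map = template.copy_with(rf["predictions"].reshape(shape))
    write_ascii_grid(rf_map, out / "map_rf.asc")

    # -- stage 7: plot/pixel comparison ------------------------------------
    comp = {}
    for name, raster in (("bay", bay_mean), ("rf", rf_map)):
        f, m, excluded = comparison.extract_paired_values(
            raster, clusters, list(dens_all)
        )
        stats_all = comparison.agreement_regression(f, m)
        forest_sel = f > 0
        stats_forest = (
            comparison.agreement_regression(f[forest_sel], m[forest_sel])
            if forest_sel.sum() >= 3 and np.var(f[forest_sel]) > 0
            else None
        )
        comp[name] = {
            "all_pairs": stats_all.__dict__,
            "forest_only": stats_forest.__dict__ if stats_forest else None,
            "excluded_plots": excluded,
        }
    pixel_cis = [
        (
            comparison.extract_plot_prediction(bay_lo, cl),
            comparison.extract_plot_prediction(bay_hi, cl),
        )
        for cl in clusters
    ]
    overlap = comparison.ci_overlap_fraction(plot_cis, pixel_cis)

    # -- stage 8: county-level estimates -----------------------------------
    est_all = county.design_estimate(dens_all, area_ha)
    est_fia = county.design_estimate(dens_fia, area_ha)
    share = county.nonforest_share(est_all.total, est_fia.total)
    est_bay_sample = county.pixel_sample_estimate(bay_mean, clusters, area_ha)
    est_rf_sample = county.pixel_sample_estimate(rf_map, clusters, area_ha)
    est_bay_sum = county.pixel_sum_estimate(
        bay_mean, lower=bay_lo, upper=bay_hi, county_area=area_ha
    )
    est_rf_sum = county.pixel_sum_estimate(rf_map, county_area=area_ha)
    est_truth_sum = county.pixel_sum_estimate(template, county_area=area_ha)

    def _est(e: county.CountyEstimate) -> dict:
        return {
            "method": e.method,
            "mean_mgha": e.mean,
            "mean_ci": list(e.mean_ci) if e.mean_ci else None,
            "total_tg": e.total,
            "total_ci": list(e.total_ci) if e.total_ci else None,
            "n": e.n,
        }

    report = {
        "config": asdict(cfg),
        "landscape": {
            "area_ha": area_ha,
            "true_total_tg": est_truth_sum.total,
            "true_nonforest_biomass_share": surface.nonforest_biomass_share(),
        },
        "allometry_choice": {
            "per_family": choice["per_family"],
            "pct_difference": {
                f"{a}_vs_{b}": v for (a, b), v in choice["pct_difference"].items()
            },
        },
        "plot_ci": {
            "mean_width_mgha": mean_width,
            "mean_width_pct_of_mean": width_pct,
            "lidar_noise_sd": noise_sd,
        },
        "mapping": {
            "bay_diagnostics": fit.diagnostics,
            "rf_oob_r2": rf["oob_r2"],
            "rf_oob_rmse": rf["oob_rmse"],
        },
        "comparison": comp,
        "ci_overlap_fraction": overlap,
        "county": {
            "design_all_trees": _est(est_all),
            "design_fia_only": _est(est_fia),
            "nonforest_share": share,
            "pixel_sample_bay": _est(est_bay_sample),
            "pixel_sample_rf": _est(est_rf_sample),
            "pixel_sum_bay": _est(est_bay_sum),
            "pixel_sum_rf": _est(est_rf_sum),
            "gap_bay_sum_vs_design_all": county.estimate_gap(est_bay_sum, est_all),
            "gap_rf_sum_vs_design_all": county.estimate_gap(est_rf_sum, est_all),
        },
    }
    with (out / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, default=float)
    cfg.to_yaml(out / "config_resolved.yaml")
    _write_text_report(report, out / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["Synthetic plot/map integration experiment", "=" * 42, ""]
    ch = report["allometry_choice"]
    lines.append("Allometric family comparison (plot mean +/- sd, Mg/ha):")
    for fam, st in ch["per_family"].items():
        lines.append(f"  {fam:18s} {st['mean_mgha']:8.1f} +/- {st['sd_mgha']:.1f}")
    for k, v in ch["pct_difference"].items():
        lines.append(f"  {k}: {v:+.0f}%")
    pc = report["plot_ci"]
    lines.append("")
    lines.append(
        f"Propagated allometric error: mean plot 95% CI width "
        f"{pc['mean_width_mgha']:.1f} Mg/ha "
        f"({pc['mean_width_pct_of_mean']:.0f}% of plot biomass)"
    )
    lines.append("")
    lines.append("Plot vs map agreement (all pairs):")
    for name, c in report["comparison"].items():
        s = c["all_pairs"]
        lines.append(
            f"  {name.upper():4s} R2={s['r_squared']:.2f} slope={s['slope']:.2f} "
            f"RMSE={s['rmse']:.1f} Mg/ha KS={s['ks']:.2f} (n={s['n_pairs']})"
        )
    lines.append(
        f"  field/pixel 95% CI overlap: "
        f"{100 * report['ci_overlap_fraction']:.0f}% of plots"
    )
    lines.append("")
    lines.append("County estimates (total Tg [95% CI]):")
    for key, e in report["county"].items():
        if not isinstance(e, dict) or "total_tg" not in e:
            continue
        ci = e["total_ci"]
        ci_s = f" [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
        lines.append(f"  {key:22s} {e['total_tg']:.3f}{ci_s}")
    sh = report["county"]["nonforest_share"]
    lines.append(
        f"  nonforest biomass: {sh['nonforest_tg']:.3f} Tg "
        f"({sh['nonforest_pct']:.0f}% of all-tree total; "
        f"true share {100 * report['landscape']['true_nonforest_biomass_share']:.0f}%)"
    )
    path.write_text("\n".join(lines) + "\n")
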