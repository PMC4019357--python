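"""Tree- and plot-level aboveground biomass under three allometric families.

Three ways to turn stem measurements into biomass are supported, mirroring
the families commonly compared in US forest-carbon work:

* ``LN_LN`` — generalized national ln-ln equations by species group,
  ``biomass_kg = exp(b0 + b1 * ln(dbh_cm))``, DBH-only.
* ``VOLUME_CRM`` — a component-ratio-method chain: bole volume from a
  combined-variable equation ``v = a + b * dbh^2 * bole_height``, times
  wood density (kg/m3), expanded to whole-tree by a bole-to-total ratio.
* ``SPECIES_SPECIFIC`` — local per-species equations (ln-ln form), with the
  general ln-ln group equation substituted when a species has no entry.

Units are fixed throughout: DBH cm, height m, tree biomass kg, plot-level
density Mg/ha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .synthetic import TreeRecord

__all__ = [
    "AllometricEquation",
    "EquationRegistry",
    "OutOfRangeWarning",
    "predict_biomass_lnln",
    "predict_biomass_crm",
    "predict_biomass_species",
    "plot_biomass_density",
    "compare_allometry_choices",
    "load_default_registry",
]

FAMILY_LNLN = "LN_LN"
FAMILY_CRM = "VOLUME_CRM"
FAMILY_SPECIES = "SPECIES_SPECIFIC"
_FAMILIES = (FAMILY_LNLN, FAMILY_CRM, FAMILY_SPECIES)

KG_PER_MG = 1000.0
M2_PER_HA = 1e4


class OutOfRangeWarning(UserWarning):
    """DBH outside the source equation's fitted range (value still returned)."""


@dataclass
class AllometricEquation:
    """One coefficient set plus fit metadata from its source regression."""

    family: str
    group: str  # species group, or species name for SPECIES_SPECIFIC
    coefficients: dict[str, float]
    r_squared: float = 0.99
    n_obs: int = 100
    dbh_range: tuple[float, float] = (2.5, 100.0)
    source: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown allometric family {self.family!r}")
        if not 0.0 < self.r_squared <= 1.0:
            raise ValueError("r_squared must be in (0, 1]")
        if self.n_obs < 2:
            raise ValueError("n_obs must be >= 2")
        if self.family == FAMILY_CRM and self.coefficients.get("density", 1.0) <= 0:
            raise ValueError("wood density must be positive")


class EquationRegistry:
    """Keyed collection of equations with the group-fallback rule.

    Keys are (family, group).  A ``SPECIES_SPECIFIC`` lookup that misses
    falls back to the ``LN_LN`` equation of the species' group via
    ``species_to_group``.
    """

    def __init__(
        self,
        equations: list[AllometricEquation],
        species_to_group: dict[str, str] | None = None,
    ) -> None:
        self._eq: dict[tuple[str, str], AllometricEquation] = {}
        for eq in equations:
            self._eq[(eq.family, eq.group)] = eq
        self.species_to_group = dict(species_to_group or {})

    def get(self, family: str, group: str) -> AllometricEquation:
        try:
            return self._eq[(family, group)]
        except KeyError:
            raise KeyError(f"no {family} equation for group {group!r}") from None

    def has(self, family: str, group: str) -> bool:
        return (family, group) in self._eq

    def groups(self, family: str) -> list[str]:
        return sorted(g for f, g in self._eq if f == family)

    def group_of(self, species: str) -> str:
        if species in self.species_to_group:
            return self.species_to_group[species]
        if self.has(FAMILY_LNLN, species):  # species label already a group
            return species
        raise KeyError(f"species {species!r} has no group mapping")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EquationRegistry":
        with Path(path).open() as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "EquationRegistry":
        eqs = []
        for entry in doc.get("equations", []):
            eqs.append(
                AllometricEquation(
                    family=entry["family"],
                    group=entry["group"],
                    coefficients={k: float(v) for k, v in entry["coefficients"].items()},
                    r_squared=float(entry.get("r_squared", 0.99)),
                    n_obs=int(entry.get("n_obs", 100)),
                    dbh_range=tuple(entry.get("dbh_range", (2.5, 100.0))),
                    source=str(entry.get("source", "")),
                )
            )
        return cls(eqs, doc.get("species_to_group"))


def load_default_registry() -> EquationRegistry:
    """Load the packaged default coefficient tables."""
    ref = resources.files("standmap.data") / "equations.yaml"
    with resources.as_file(ref) as path:
        return EquationRegistry.from_yaml(path)


# ---------------------------------------------------------------------------
# per-tree predictions
# ---------------------------------------------------------------------------


def _check_range(dbh: float, eq: AllometricEquation) -> None:
    lo, hi = eq.dbh_range
    if not lo <= dbh <= hi:
        warnings.warn(
            f"dbh {dbh:.1f} cm outside fitted range [{lo}, {hi}] "
            f"for {eq.family}/{eq.group}",
            OutOfRangeWarning,
            stacklevel=3,
        )


def predict_biomass_lnln(dbh: float, eq: AllometricEquation) -> float:
    """Aboveground biomass (kg) from the ln-ln form exp(b0 + b1 ln dbh)."""
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    if eq.family != FAMILY_LNLN:
        raise ValueError(f"expected a {FAMILY_LNLN} equation, got {eq.family}")
    _check_range(dbh, eq)
    b0 = eq.coefficients["b0"]
    b1 = eq.coefficients["b1"]
    return float(np.exp(b0 + b1 * np.log(dbh)))


def predict_biomass_crm(
    dbh: float, bole_height: float | None, eq: AllometricEquation
) -> float:
    """Aboveground biomass (kg) via the volume -> density -> ratio chain.

    volume (m3) = a + b * dbh^2 * bole_height  (combined-variable form);
    bole biomass = volume * wood density (kg/m3);
    total = bole biomass / bole_to_total_ratio.
    """
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    if eq.family != FAMILY_CRM:
        raise ValueError(f"expected a {FAMILY_CRM} equation, got {eq.family}")
    if bole_height is None or (isinstance(bole_height, float) and np.isnan(bole_height)):
        raise ValueError(
            "bole_height measurement missing: the volume-based family "
            "requires it and does not impute"
        )
    if bole_height < 0:
        raise ValueError("bole_height must be non-negative")
    _check_range(dbh, eq)
    c = eq.coefficients
    volume = c.get("a", 0.0) + c["b"] * dbh**2 * bole_height
    bole_kg = volume * c["density"]
    ratio = c.get("bole_to_total_ratio", 1.0)
    return float(bole_kg / ratio)


def predict_biomass_species(
    dbh: float, species: str, registry: EquationRegistry
) -> tuple[float, str]:
    """Species-specific biomass (kg) with the group-equation substitution rule.

    Returns (biomass_kg, path) where path is ``"species"`` when a
    species-level equation was used and ``"group_fallback"`` when the
    general ln-ln equation of the species' group was substituted.
    """
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    if registry.has(FAMILY_SPECIES, species):
        eq = registry.get(FAMILY_SPECIES, species)
        _check_range(dbh, eq)
        b0 = eq.coefficients["b0"]
        b1 = eq.coefficients["b1"]
        return float(np.exp(b0 + b1 * np.log(dbh))), "species"
    group = registry.group_of(species)
    eq = registry.get(FAMILY_LNLN, group)
    return predict_biomass_lnln(dbh, eq), "group_fallback"


def resolve_group_equation(
    registry: EquationRegistry, family: str, name: str
) -> AllometricEquation:
    """Equation for a species-or-group label: direct hit, else via its group."""
    if registry.has(family, name):
        return registry.get(family, name)
    return registry.get(family, registry.group_of(name))


def predict_tree_biomass(
    tree: TreeRecord, family: str, registry: EquationRegistry
) -> float:
    """Dispatch one tree to the requested family; kg."""
    if family == FAMILY_LNLN:
        eq = resolve_group_equation(registry, FAMILY_LNLN, tree.species_group)
        return predict_biomass_lnln(tree.dbh_cm, eq)
    if family == FAMILY_CRM:
        eq = resolve_group_equation(registry, FAMILY_CRM, tree.species_group)
        return predict_biomass_crm(tree.dbh_cm, tree.bole_height_m, eq)
    if family == FAMILY_SPECIES:
        value, _ = predict_biomass_species(tree.dbh_cm, tree.species_group, registry)
        return value
    raise ValueError(f"unknown allometric family {family!r}")


# ---------------------------------------------------------------------------
# plot aggregation and family comparison
# ---------------------------------------------------------------------------


def plot_biomass_density(
    trees: list[TreeRecord],
    sampled_area: float,
    family: str,
    registry: EquationRegistry,
) -> float:
    """Plot biomass density in Mg/ha: sum of tree kg over the sampled m2.

    ``sum(kg) / 1000 / (area_m2 / 10000)``; an empty tree list is a valid
    zero-biomass plot.
    """
    if sampled_area <= 0:
        raise ValueError("sampled_area must be positive")
    total_kg = sum(predict_tree_biomass(t, family, registry) for t in trees)
    return total_kg / KG_PER_MG / (sampled_area / M2_PER_HA)


def percent_difference(a: float, b: float) -> float:
    """100 * (a - b) / b."""
    return 100.0 * (a - b) / b


def compare_allometry_choices(
    plots: list[list[TreeRecord]],
    registry: EquationRegistry,
    sampled_area: float,
    families: tuple[str, ...] = (FAMILY_LNLN, FAMILY_CRM, FAMILY_SPECIES),
) -> dict:
    """Mean/SD of plot densities per family plus pairwise percent differences.

    Returns ``{"per_family": {family: {"mean_mgha", "sd_mgha"}},
    "pct_difference": {(A, B): 100*(mean_A-mean_B)/mean_B}}``.
    """
    if not plots:
        raise ValueError("need at least one plot")
    per_family: dict[str, dict[str, float]] = {}
    for fam in families:
        dens = np.array(
            [plot_biomass_density(p, sampled_area, fam, registry) for p in plots]
        )
        per_family[fam] = {
            "mean_mgha": float(dens.mean()),
            "sd_mgha": float(dens.std(ddof=1)) if len(dens) > 1 else 0.0,
        }
    pct = {}
    for fa in families:
        for fb in families:
            if fa == fb:
                continue
            pct[(fa, fb)] = percent_difference(
                per_family[fa]["mean_mgha"], per_family[fb]["mean_mgha"]
            )
    return {"per_family": per_family, "pct_difference": pct}
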