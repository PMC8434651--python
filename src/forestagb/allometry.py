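"""Species-specific allometric biomass equations for northeastern-China forests.

Individual-tree aboveground biomass (AGB) follows the power law

    W = a * D**b

with ``W`` in kg, ``D`` the diameter at breast height (DBH, cm), and ``(a, b)``
species-specific coefficients fitted for the major tree and understory species
of natural secondary forests and plantations in northeastern China.  Plot-level
AGB density (Mg/ha) is the cumulative sum of tree AGB divided by plot area.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AllometricParams",
    "TreeRecord",
    "PlotAgb",
    "ALLOMETRY_TABLE",
    "species_params",
    "tree_agb",
    "plot_agb_density",
    "plots_agb_from_trees",
]

# Census threshold: trees below this DBH (cm) are not inventoried.
MIN_DBH_CM = 5.0

# Default plot: 20 m x 30 m = 600 m2 = 0.06 ha.
DEFAULT_PLOT_AREA_HA = 0.06


@dataclass(frozen=True)
class AllometricParams:
    """One row of the coefficient table: W = a * D**b for one species."""

    species: str
    a: float  # kg * cm^(-b)
    b: float  # dimensionless
    origin: str  # "natural" | "plantation" | "understory"

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"allometric coefficients must be positive: {self}")


@dataclass(frozen=True)
class TreeRecord:
    plot_id: str
    species: str
    dbh_cm: float


@dataclass(frozen=True)
class PlotAgb:
    plot_id: str
    w_total_kg: float
    agb_density_mg_ha: float
    plot_area_ha: float


# The 18 coefficient rows.  Plantation variants carry the "_plantation" suffix;
# the shared deciduous row is registered under all three of its species names.
_ROWS: tuple[tuple[str, float, float, str], ...] = (
    ("Acer mono", 0.318, 2.081, "natural"),
    ("Ulmus pumila", 0.350, 1.995, "natural"),
    ("Populus davidiana", 0.078, 2.512, "natural"),
    ("Betula platyphylla", 0.313, 2.114, "natural"),
    ("Quercus mongolica", 0.097, 2.501, "natural"),
    ("Tilia mongolica", 0.083, 2.422, "natural"),
    ("Fraxinus mandshurica", 0.268, 2.118, "natural"),
    ("Larix olgensis", 0.168, 2.248, "natural"),
    ("Pinus koraiensis", 0.082, 2.426, "natural"),
    ("Picea asperata", 0.067, 2.517, "natural"),
    ("Larix olgensis_plantation", 0.222, 2.174, "plantation"),
    ("Pinus koraiensis_plantation", 0.206, 2.117, "plantation"),
    ("Pinus sylvestris_plantation", 0.080, 2.440, "plantation"),
    ("Acer ginnala", 0.527, 2.217, "understory"),
    ("Syringa reticulata", 0.395, 2.300, "understory"),
    ("Padus asiatica", 0.090, 2.696, "understory"),
    ("Rhamnus yoshinoi", 0.169, 2.555, "understory"),
    ("Arbor-like mixed species", 0.182, 2.487, "understory"),
)

ALLOMETRY_TABLE: tuple[AllometricParams, ...] = tuple(
    AllometricParams(*row) for row in _ROWS
)

# Species-name lookup.  "Fraxinus mandshurica / Juglans mandshurica /
# Phellodendron amurense" share one coefficient pair.
_ALIASES: Mapping[str, str] = {
    "Juglans mandshurica": "Fraxinus mandshurica",
    "Phellodendron amurense": "Fraxinus mandshurica",
}

_LOOKUP: dict[str, AllometricParams] = {p.species: p for p in ALLOMETRY_TABLE}
for _alias, _target in _ALIASES.items():
    _LOOKUP[_alias] = _LOOKUP[_target]

# The understory catch-all; usable as a fallback only when asked for.
_CATCH_ALL = "Arbor-like mixed species"


class UnknownSpeciesError(KeyError):
    """Raised when a species has no registered allometric coefficients."""


def species_params(
    species: str, *, fallback_mixed: bool = False
) -> AllometricParams:
    """Return the coefficient row for ``species``.

    With ``fallback_mixed=True`` an unknown species resolves to the understory
    "arbor-like mixed species" catch-all instead of raising.
    """
    try:
        return _LOOKUP[species]
    except KeyError:
        if fallback_mixed:
            return _LOOKUP[_CATCH_ALL]
        near = difflib.get_close_matches(species, _LOOKUP.keys(), n=3)
        raise UnknownSpeciesError(
            f"no allometric coefficients for species {species!r};"
            f" nearest registered names: {near}"
        ) from None


def tree_agb(
    tree: TreeRecord | tuple[str, float],
    *,
    fallback_mixed: bool = False,
    allow_small: bool = False,
) -> float:
    """Aboveground biomass (kg) of one tree: W = a * D**b.

    ``tree`` is a :class:`TreeRecord` or a ``(species, dbh_cm)`` pair.  DBH
    below the 5 cm census threshold raises unless ``allow_small`` is set
    (DBH = 0 is always permitted and yields 0 kg).
    """
    if isinstance(tree, TreeRecord):
        species, dbh = tree.species, tree.dbh_cm
    else:
        species, dbh = tree
    if dbh < 0:
        raise ValueError(f"negative DBH: {dbh}")
    if 0 < dbh < MIN_DBH_CM and not allow_small:
        raise ValueError(
            f"DBH {dbh} cm below the {MIN_DBH_CM} cm census threshold"
            " (pass allow_small=True to override)"
        )
    p = species_params(species, fallback_mixed=fallback_mixed)
    return p.a * dbh**p.b


def plot_agb_density(
    trees: Iterable[TreeRecord | tuple[str, float]],
    plot_area_ha: float = DEFAULT_PLOT_AREA_HA,
    *,
    plot_id: str = "",
    fallback_mixed: bool = False,
    allow_small: bool = False,
) -> PlotAgb:
    """Plot AGB density (Mg/ha) as the cumulative sum of tree AGB.

    An empty tree list yields density 0 (a treeless plot is not an error).
    """
    if plot_area_ha <= 0:
        raise ValueError(f"plot area must be positive, got {plot_area_ha}")
    w_total = float(
        sum(
            tree_agb(t, fallback_mixed=fallback_mixed, allow_small=allow_small)
            for t in trees
        )
    )
    density = (w_total / 1000.0) / plot_area_ha
    return PlotAgb(plot_id, w_total, density, plot_area_ha)


def plots_agb_from_trees(
    trees: pd.DataFrame,
    plot_area_ha: float = DEFAULT_PLOT_AREA_HA,
    *,
    fallback_mixed: bool = False,
    allow_small: bool = False,
) -> pd.DataFrame:
    """Vectorized plot aggregation over a trees table.

    ``trees`` needs columns ``plot_id``, ``species``, ``dbh_cm``.  Returns a
    DataFrame with columns ``plot_id``, ``w_total_kg``, ``agb_mg_ha`` sorted by
    plot id; plots present in the input with zero trees are absent (callers
    merging against a plot list should fill 0).
    """
    required = {"plot_id", "species", "dbh_cm"}
    missing = required - set(trees.columns)
    if missing:
        raise ValueError(f"trees table missing columns: {sorted(missing)}")
    rows = []
    for pid, grp in trees.groupby("plot_id", sort=True):
        rec = plot_agb_density(
            [(s, d) for s, d in zip(grp["species"], grp["dbh_cm"])],
            plot_area_ha,
            plot_id=str(pid),
            fallback_mixed=fallback_mixed,
            allow_small=allow_small,
        )
        rows.append((rec.plot_id, rec.w_total_kg, rec.agb_density_mg_ha))
    return pd.DataFrame(rows, columns=["plot_id", "w_total_kg", "agb_mg_ha"])
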