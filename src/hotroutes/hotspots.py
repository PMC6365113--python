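"""Grid-based endemism summaries and hotspot delineation.

A biodiversity hotspot here is a set of grid cells selected from a
species x cell occurrence table by one of three conventions:

* ``delineate_top_quantile`` — the top 20% of occupied cells by weighted
  endemicity (WE) or species richness (SR);
* ``delineate_nrs`` — every cell occupied by at least one narrow-ranged
  species (range <= 10 cells of 100 km for the canonical 100,000 km2
  threshold).

WE weights each occurrence by the inverse of the species' range size in
cells, so each species contributes exactly 1 summed over the whole grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceGrid",
    "RegionPartition",
    "weighted_endemicity",
    "species_richness",
    "delineate_top_quantile",
    "delineate_nrs",
    "nrs_cell_threshold",
    "partition_overlap",
]


@dataclass
class OccurrenceGrid:
    """Deduplicated species x grid-cell presence table.

    ``occurrences`` has columns (species, cell_id); ``cells`` has columns
    (cell_id, x, y, realm) with x/y integer grid indices.  ``cell_km`` is
    the cell side length in km.
    """

    occurrences: pd.DataFrame
    cells: pd.DataFrame
    cell_km: float = 100.0

    def __post_init__(self) -> None:
        occ = self.occurrences[["species", "cell_id"]].drop_duplicates().reset_index(drop=True)
        self.occurrences = occ
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids in cell table")
        if "realm" not in self.cells.columns:
            self.cells = self.cells.assign(realm="all")
        unknown = set(occ["cell_id"]) - set(self.cells["cell_id"])
        if unknown:
            raise ValueError(f"occurrences reference unknown cells: {sorted(unknown)[:5]}")

    @property
    def species(self) -> list[str]:
        return sorted(self.occurrences["species"].unique())

    @property
    def occupied_cells(self) -> list:
        return sorted(self.occurrences["cell_id"].unique())

    def range_sizes(self) -> pd.Series:
        """Occupied-cell count per species."""
        return self.occurrences.groupby("species")["cell_id"].nunique()

    def cell_coords(self) -> pd.DataFrame:
        return self.cells.set_index("cell_id")[["x", "y"]]

    def cell_realms(self) -> pd.Series:
        return self.cells.set_index("cell_id")["realm"]

    def subset_species(self, keep: set) -> "OccurrenceGrid":
        occ = self.occurrences[self.occurrences["species"].isin(keep)]
        if occ.empty:
            raise ValueError("no species left after subsetting")
        return OccurrenceGrid(occ.reset_index(drop=True), self.cells, self.cell_km)

    # ------------------------------------------------------------------
    @classmethod
    def read_csv(cls, occurrence_path: str, cell_path: str, cell_km: float = 100.0) -> "OccurrenceGrid":
        return cls(pd.read_csv(occurrence_path), pd.read_csv(cell_path), cell_km)

    def write_csv(self, occurrence_path: str, cell_path: str) -> None:
        self.occurrences.to_csv(occurrence_path, index=False)
        self.cells.to_csv(cell_path, index=False)


@dataclass
class RegionPartition:
    """Hotspot / non-hotspot classification of occupied cells.

    ``table`` has columns (cell_id, klass, realm) with klass in
    {"hotspot", "non-hotspot"}; only occupied cells appear.
    """

    table: pd.DataFrame
    clade: str = "all"
    metric: str = ""
    n_hotspot: int = field(init=False)

    def __post_init__(self) -> None:
        bad = set(self.table["klass"]) - {"hotspot", "non-hotspot"}
        if bad:
            raise ValueError(f"unknown classes {bad}")
        self.n_hotspot = int((self.table["klass"] == "hotspot").sum())

    @property
    def hotspot_cells(self) -> set:
        return set(self.table.loc[self.table["klass"] == "hotspot", "cell_id"])

    @property
    def non_hotspot_cells(self) -> set:
        return set(self.table.loc[self.table["klass"] == "non-hotspot", "cell_id"])

    def klass_of(self) -> pd.Series:
        return self.table.set_index("cell_id")["klass"]

    def realm_of(self) -> pd.Series:
        return self.table.set_index("cell_id")["realm"]

    def write_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str, clade: str = "all", metric: str = "") -> "RegionPartition":
        return cls(pd.read_csv(path), clade=clade, metric=metric)


# ----------------------------------------------------------------------
# per-cell metrics
# ----------------------------------------------------------------------

def weighted_endemicity(occ: OccurrenceGrid) -> pd.Series:
    """Per-cell WE: sum over resident species of 1 / range size (in cells).

    Cells with no species are omitted (their WE is 0 by definition).
    Summed over all cells WE equals the number of species exactly.
    """
    rng = occ.range_sizes()
    weights = occ.occurrences["species"].map(1.0 / rng)
    we = weights.groupby(occ.occurrences["cell_id"]).sum()
    return we.rename("WE").sort_index()


def species_richness(occ: OccurrenceGrid) -> pd.Series:
    """Per-cell SR: count of species present."""
    sr = occ.occurrences.groupby("cell_id")["species"].nunique()
    return sr.rename("SR").sort_index()


# ----------------------------------------------------------------------
# delineation
# ----------------------------------------------------------------------

def delineate_top_quantile(
    values: pd.Series,
    realms: pd.Series,
    fraction: float = 0.20,
    clade: str = "all",
    metric: str = "WE",
) -> RegionPartition:
    """Label the top ``fraction`` of cells (by ``values``) as hotspot.

    The quantile universe is the cells carried by ``values`` (occupied
    cells); exactly ceil(fraction * n) cells become hotspot, with ties at
    the threshold broken by cell id so the partition is deterministic.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if values.nunique() == 1:
        raise ValueError("metric is degenerate: all cell values equal; "
                         "a quantile hotspot is undefined")
    n_hot = math.ceil(fraction * len(values))
    order = values.to_frame("v").reset_index()
    order.columns = ["cell_id", "v"]
    order = order.sort_values(["v", "cell_id"], ascending=[False, True], kind="mergesort")
    hot = set(order["cell_id"].head(n_hot))
    table = pd.DataFrame({
        "cell_id": values.index,
        "klass": ["hotspot" if c in hot else "non-hotspot" for c in values.index],
        "realm": realms.reindex(values.index).values,
    })
    return RegionPartition(table.reset_index(drop=True), clade=clade, metric=metric)


def nrs_cell_threshold(area_km2: float = 100_000.0, cell_km: float = 100.0) -> int:
    """Cell-count equivalent of a range-area threshold (km2)."""
    return int(math.floor(area_km2 / cell_km ** 2))


def delineate_nrs(occ: OccurrenceGrid, max_cells: int = 10, clade: str = "all") -> RegionPartition:
    """Hotspot = any cell holding >= 1 species with range <= ``max_cells``."""
    if max_cells < 1:
        raise ValueError("max_cells must be >= 1")
    rng = occ.range_sizes()
    narrow = set(rng.index[rng <= max_cells])
    hot = set(occ.occurrences.loc[occ.occurrences["species"].isin(narrow), "cell_id"])
    realms = occ.cell_realms()
    cells = occ.occupied_cells
    table = pd.DataFrame({
        "cell_id": cells,
        "klass": ["hotspot" if c in hot else "non-hotspot" for c in cells],
        "realm": realms.reindex(cells).values,
    })
    return RegionPartition(table, clade=clade, metric=f"NRS<= {max_cells}")


def partition_overlap(a: RegionPartition, b: RegionPartition, method: str = "min") -> float:
    """Percent overlap of two hotspot cell sets.

    ``method='min'`` (default): |A & B| / min(|A|, |B|) x 100 — symmetric
    and robust to unequal hotspot sizes.  ``method='jaccard'``:
    |A & B| / |A | B| x 100.
    """
    ha, hb = a.hotspot_cells, b.hotspot_cells
    if not ha or not hb:
        raise ValueError("cannot compute overlap with an empty hotspot set")
    inter = len(ha & hb)
    if method == "min":
        return 100.0 * inter / min(len(ha), len(hb))
    if method == "jaccard":
        return 100.0 * inter / len(ha | hb)
    raise ValueError(f"unknown overlap method {method!r}")
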