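"""Gridded presence-absence matrices and matrix-level diversity descriptors.

The central container is :class:`CommunityMatrix`: a binary cells x species
occupancy matrix on a :class:`~phylogrid.grid.GridSpec`.  Matrices are built
either from species range polygons (any cell overlapped with nonzero area is
occupied) or from point occurrence records (any cell holding at least one
record is occupied), and feed every downstream metric: species richness (SR),
weighted endemism (WE = sum over resident species of the inverse of their
occupied-cell count), and NODF nestedness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .errors import InvalidInputError, UndefinedMetricError
from .grid import GridSpec

logger = logging.getLogger(__name__)


@dataclass
class CommunityMatrix:
    """Binary occupancy of species across grid cells.

    Attributes
    ----------
    grid
        The grid the cells live on; cell ids are row-major.
    species
        Ordered, unique species labels (matrix columns).
    presence
        ``(n_cells, n_species)`` array with entries in {0, 1}.
    """

    grid: GridSpec
    species: list[str]
    presence: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (self.grid.n_cells, len(self.species)):
            raise InvalidInputError(
                f"presence shape {self.presence.shape} does not match "
                f"{self.grid.n_cells} cells x {len(self.species)} species"
            )
        if len(set(self.species)) != len(self.species):
            raise InvalidInputError("species labels must be unique")
        vals = np.unique(self.presence)
        if not np.isin(vals, [0, 1]).all():
            raise InvalidInputError("presence entries must be 0 or 1")
        self.presence = self.presence.astype(np.uint8)

    @property
    def n_cells(self) -> int:
        return self.presence.shape[0]

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    def richness(self) -> np.ndarray:
        """Per-cell species count s (row sums)."""
        return self.presence.sum(axis=1).astype(int)

    def range_sizes(self) -> np.ndarray:
        """Per-species occupied-cell count r_i (column sums)."""
        return self.presence.sum(axis=0).astype(int)

    def drop_empty_species(self) -> "CommunityMatrix":
        """Remove all-zero species columns (r_i = 0), logging what was dropped.

        WE and the fixed-fixed null models are undefined for species that
        occupy no cell, so those columns are excluded before analysis.
        """
        r = self.range_sizes()
        keep = r > 0
        dropped = [s for s, k in zip(self.species, keep) if not k]
        if dropped:
            logger.info("dropping %d all-zero species columns: %s", len(dropped), dropped)
        meta = dict(self.meta)
        meta["dropped_species"] = meta.get("dropped_species", []) + dropped
        return CommunityMatrix(
            self.grid,
            [s for s, k in zip(self.species, keep) if k],
            self.presence[:, keep],
            meta,
        )

    # ---- I/O ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        centers = self.grid.cell_centers()
        df = pd.DataFrame(self.presence, columns=self.species)
        df.insert(0, "cell_id", np.arange(self.n_cells))
        df.insert(1, "x", centers[:, 0])
        df.insert(2, "y", centers[:, 1])
        return df

    def to_csv(self, path: str | Path, metadata: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata:
            meta = {
                "n_rows": self.grid.n_rows,
                "n_cols": self.grid.n_cols,
                "cell_size": self.grid.cell_size,
                "x0": self.grid.x0,
                "y0": self.grid.y0,
                **self.meta,
            }
            path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CommunityMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            grid = GridSpec(
                meta["n_rows"], meta["n_cols"], meta["cell_size"],
                meta.get("x0", 0.0), meta.get("y0", 0.0),
            )
        else:  # infer a square-ish grid purely from cell coordinates
            xs, ys = np.unique(df["x"]), np.unique(df["y"])
            cs = float(np.min(np.diff(xs))) if len(xs) > 1 else float(np.min(np.diff(ys)))
            grid = GridSpec(len(ys), len(xs), cs, float(xs[0]) - cs / 2, float(ys[0]) - cs / 2)
            meta = {}
        species = [c for c in df.columns if c not in ("cell_id", "x", "y")]
        presence = df[species].to_numpy()
        extra = {k: v for k, v in meta.items()
                 if k not in ("n_rows", "n_cols", "cell_size", "x0", "y0")}
        return cls(grid, species, presence, extra)


# ---- matrix construction ----------------------------------------------


def rasterize_ranges(
    polygons: Mapping[str, Sequence[tuple[float, float]]] | Mapping[str, shapely.Polygon],
    grid: GridSpec,
) -> CommunityMatrix:
    """Convert species range polygons to a presence-absence matrix.

    A species is present in a cell iff its range polygon intersects the
    cell rectangle with **nonzero area** (cell-center containment is not
    required).  Species whose polygon misses the grid entirely are kept as
    all-zero columns and listed in ``meta['empty_species']``.

    Parameters
    ----------
    polygons
        Mapping from species label to either a shapely Polygon or a vertex
        list ``[(x, y), ...]`` in km.
    """
    species = list(polygons)
    geoms = []
    for name in species:
        poly = polygons[name]
        if not isinstance(poly, shapely.Geometry):
            verts = list(poly)
            if len(verts) < 3:
                raise InvalidInputError(f"polygon for {name!r} has fewer than 3 vertices")
            poly = shapely.Polygon(verts)
        if not poly.is_valid:
            raise InvalidInputError(f"polygon for {name!r} is not simple/valid")
        geoms.append(poly)

    cells = [shapely.box(*grid.cell_bounds(i)) for i in range(grid.n_cells)]
    presence = np.zeros((grid.n_cells, len(species)), dtype=np.uint8)
    for j, poly in enumerate(geoms):
        inter = shapely.area(shapely.intersection(np.array(cells, dtype=object), poly))
        presence[:, j] = inter > 0
    empty = [s for s, occ in zip(species, presence.sum(axis=0)) if occ == 0]
    if empty:
        logger.info("%d species intersect no grid cell: %s", len(empty), empty)
    return CommunityMatrix(grid, species, presence, {"empty_species": empty})


def points_to_matrix(
    occurrences: pd.DataFrame | Iterable[tuple[str, float, float]],
    grid: GridSpec,
) -> CommunityMatrix:
    """Bin point occurrence records (species, x, y) into a presence matrix.

    A species is present in a cell iff at least one record falls inside it;
    cells use half-open ``[left, right) x [bottom, top)`` intervals, so the
    grid's outer right/top edges belong to no cell.  Out-of-grid records are
    dropped and counted in ``meta['n_out_of_grid']`` rather than raising.
    """
    if not isinstance(occurrences, pd.DataFrame):
        occurrences = pd.DataFrame(list(occurrences), columns=["species", "x", "y"])
    if occurrences.empty:
        raise InvalidInputError("no occurrence records supplied")
    if not np.isfinite(occurrences[["x", "y"]].to_numpy()).all():
        raise InvalidInputError("occurrence coordinates must be finite")

    ids, inside = grid.locate(occurrences["x"].to_numpy(), occurrences["y"].to_numpy())
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d occurrence records fall outside the grid", n_out)
    species = sorted(occurrences["species"].unique())
    sp_index = {s: j for j, s in enumerate(species)}
    presence = np.zeros((grid.n_cells, len(species)), dtype=np.uint8)
    for sp, cid in zip(occurrences["species"][inside], ids[inside]):
        presence[cid, sp_index[sp]] = 1
    return CommunityMatrix(grid, species, presence, {"n_out_of_grid": n_out})


# ---- matrix-level metrics ---------------------------------------------


def species_richness(cm: CommunityMatrix) -> np.ndarray:
    """SR per cell: the number of species present."""
    return cm.richness()


def weighted_endemism(cm: CommunityMatrix) -> np.ndarray:
    """WE per cell: sum over resident species of 1 / r_i.

    r_i is the number of grid cells species i occupies, so a single-cell
    endemic contributes exactly 1 to its cell.  All-zero species columns
    are excluded (their inverse range is undefined).
    """
    r = cm.range_sizes().astype(float)
    occupied = r > 0
    inv_r = np.zeros_like(r)
    inv_r[occupied] = 1.0 / r[occupied]
    return cm.presence @ inv_r


def nodf(cm_or_matrix: CommunityMatrix | np.ndarray) -> float:
    """NODF nestedness (0-100) of a binary matrix.

    For every unordered pair of rows (and of columns) with *strictly*
    decreasing marginal totals, the paired overlap is the percentage of the
    poorer line's presences shared with the richer line; pairs with equal
    totals contribute 0.  NODF is the mean paired overlap over all row and
    column pairs.
    """
    m = cm_or_matrix.presence if isinstance(cm_or_matrix, CommunityMatrix) else np.asarray(cm_or_matrix)
    m = m.astype(np.int64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InvalidInputError("NODF needs a matrix with >=2 rows and >=2 columns")
    if m.sum() == 0:
        raise UndefinedMetricError("NODF undefined for an all-zero matrix")

    def _axis_sum(a: np.ndarray) -> tuple[float, int]:
        fills = a.sum(axis=1)
        shared = a @ a.T
        total = 0.0
        n = a.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
                if fills[hi] > fills[lo] and fills[lo] > 0:
                    total += 100.0 * shared[hi, lo] / fills[lo]
        return total, n * (n - 1) // 2

    row_sum, row_pairs = _axis_sum(m)
    col_sum, col_pairs = _axis_sum(m.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)
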