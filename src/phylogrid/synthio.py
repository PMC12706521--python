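"""Synthetic phylogenies, communities, climate series and regression data.

Every downstream stage of the pipeline is testable without any external
download because this module generates inputs with known ground truth:

* pure-birth (Yule) ultrametric phylogenies;
* spatially contiguous species ranges on a planar grid, with an optional
  endemism *hotspot* where the shortest-branch (neo), longest-branch
  (paleo) or both (mixed) quantiles of species are confined with small
  ranges — the occupancy structure the CANAPE classification is designed
  to detect;
* gridded climate time series with known spatial gradients, temporal
  trends and Gaussian noise;
* responses from a simultaneous-autoregressive (SAR) error process with
  known coefficients and autocorrelation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .community import CommunityMatrix
from .errors import InvalidParameterError, NumericalFailureError
from .grid import GridSpec
from .phylometrics import Phylogeny

__all__ = [
    "ScenarioSpec",
    "simulate_phylogeny",
    "simulate_ranges",
    "simulate_scenario",
    "simulate_climate_series",
    "simulate_sar_response",
    "ClimateSeries",
]


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic community scenario.

    Defaults describe a mid-sized study system: a 12 x 12 grid of 25-km
    cells holding 80 species from a unit-rate pure-birth tree, with mean
    range size of 18 cells and, when a hotspot is requested, a 3 x 3 cell
    block in the grid interior where the flagged quantile (q = 0.2) of
    species is confined with small ranges (mean 6 cells) — a dense
    concentration of range-restricted branches, the occupancy structure an
    endemism hotspot presents.
    """

    n_rows: int = 12
    n_cols: int = 12
    cell_size: float = 25.0
    n_species: int = 80
    birth_rate: float = 1.0
    mean_range_cells: float = 18.0
    range_dispersion: float = 2.0  # gamma shape of the Poisson mixing rate
    hotspot: str = "none"  # none | neo | paleo | mixed
    hotspot_block: tuple[int, int, int, int] = (4, 4, 3, 3)  # row0, col0, n_rows, n_cols
    hotspot_quantile: float = 0.2
    hotspot_mean_range_cells: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise InvalidParameterError("need at least 2 species")
        if self.cell_size <= 0:
            raise InvalidParameterError("cell size must be positive")
        if self.hotspot not in ("none", "neo", "paleo", "mixed"):
            raise InvalidParameterError(f"unknown hotspot type {self.hotspot!r}")
        if self.hotspot != "none":
            r0, c0, nr, nc = self.hotspot_block
            if not (0 <= r0 and 0 <= c0 and nr >= 1 and nc >= 1
                    and r0 + nr <= self.n_rows and c0 + nc <= self.n_cols):
                raise InvalidParameterError("hotspot block must lie inside the grid")
        if not 0 < self.hotspot_quantile < 1:
            raise InvalidParameterError("hotspot quantile must be in (0, 1)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size)

    def hotspot_cells(self) -> np.ndarray:
        r0, c0, nr, nc = self.hotspot_block
        rows, cols = np.meshgrid(np.arange(r0, r0 + nr), np.arange(c0, c0 + nc), indexing="ij")
        return (rows * self.n_cols + cols).ravel()


# ---- phylogeny --------------------------------------------------------


def simulate_phylogeny(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_species`` tips.

    Starting from the root's two daughter lineages, each extant lineage
    splits at rate ``birth_rate``; the waiting time with k lineages is
    exponential with rate k * birth_rate, and the process is stopped after
    the interval spent with n lineages.  The expected root age is therefore
    sum_{k=2..n} 1 / (k * birth_rate).
    """
    if n_species < 2:
        raise InvalidParameterError("n_species must be >= 2")
    if not birth_rate > 0:
        raise InvalidParameterError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    # node bookkeeping: root=0 with children 1, 2 born at time 0
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while True:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_species:
            break
        idx = rng.integers(k)
        node = active.pop(idx)
        for _ in range(2):
            parent.append(node)
            birth.append(t)
            active.append(len(parent) - 1)
    present = t

    n_nodes = len(parent)
    is_tip = np.ones(n_nodes, dtype=bool)
    for p in parent:
        if p >= 0:
            is_tip[p] = False
    tips = np.flatnonzero(is_tip)
    internals = np.flatnonzero(~is_tip)
    order = np.concatenate([tips, internals])
    remap = np.empty(n_nodes, dtype=int)
    remap[order] = np.arange(n_nodes)

    new_parent = np.full(n_nodes, -1, dtype=int)
    new_len = np.full(n_nodes, np.nan)
    birth = np.asarray(birth)
    for old in range(n_nodes):
        new = remap[old]
        if parent[old] >= 0:
            new_parent[new] = remap[parent[old]]
        end = present if is_tip[old] else birth[[o for o, p in enumerate(parent) if p == old][0]]
        new_len[new] = (end - birth[old]) if parent[old] >= 0 else 0.0
    width = len(str(n_species))
    labels = [f"sp{i + 1:0{width}d}" for i in range(len(tips))]
    return Phylogeny(new_parent, new_len, labels)


# ---- ranges -----------------------------------------------------------


def _grow_block(grid: GridSpec, center: int, size: int, allowed: np.ndarray | None = None) -> np.ndarray:
    """Contiguous block of ``size`` cells grown from ``center`` in square rings.

    Cells are taken ring by ring (Chebyshev distance), breaking ties within
    a ring by cell index; growth is clipped to ``allowed`` cells (used to
    confine hotspot species) and to the grid.
    """
    crow, ccol = grid.rowcol(center)
    mask = np.zeros(grid.n_cells, dtype=bool)
    if allowed is not None:
        ok = np.zeros(grid.n_cells, dtype=bool)
        ok[allowed] = True
    else:
        ok = np.ones(grid.n_cells, dtype=bool)
    chosen: list[int] = []
    ring = 0
    while len(chosen) < size:
        rows = np.arange(max(0, crow - ring), min(grid.n_rows, crow + ring + 1))
        cols = np.arange(max(0, ccol - ring), min(grid.n_cols, ccol + ring + 1))
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        cheb = np.maximum(np.abs(rr - crow), np.abs(cc - ccol))
        ids = np.sort((rr * grid.n_cols + cc)[cheb == ring].ravel())
        added = False
        for cid in ids:
            if ok[cid] and not mask[cid]:
                mask[cid] = True
                chosen.append(int(cid))
                added = True
                if len(chosen) == size:
                    break
        ring += 1
        if not added and ring > grid.n_rows + grid.n_cols:
            break  # allowed region exhausted; range capped
    return np.array(chosen, dtype=int)


def _range_sizes(rng, n: int, mean: float, dispersion: float, max_cells: int) -> np.ndarray:
    """Gamma-Poisson (negative binomial) range sizes, clipped to [1, max]."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n)
    return np.clip(rng.poisson(lam), 1, max_cells)


def _paleo_flags(tree: Phylogeny, n_flag: int) -> np.ndarray:
    """Species to confine for a paleo hotspot: subtenders of the longest branches.

    Branches (terminal and internal) are visited in decreasing length order
    and a branch's full descendant tip set is confined whenever it fits in
    the remaining budget, so that the long branch itself — not just
    terminal twigs — becomes range-restricted, the structure paleo
    endemism consists of.  Remaining budget is filled with the species on
    the longest terminal branches.
    """
    desc = tree.descendant_tips()[tree.branch_nodes]
    order = np.argsort(tree.branch_lengths)[::-1]
    confined = np.zeros(tree.n_tips, dtype=bool)
    for b in order:
        tips = desc[b]
        new = tips & ~confined
        if new.any() and confined.sum() + new.sum() <= n_flag:
            confined |= tips
        if confined.sum() == n_flag:
            break
    if confined.sum() < n_flag:  # pad with longest remaining terminal branches
        term = tree.lengths[: tree.n_tips].copy()
        term[confined] = -np.inf
        extra = np.argsort(term)[::-1][: n_flag - confined.sum()]
        confined[extra] = True
    return confined


def simulate_ranges(tree: Phylogeny, spec: ScenarioSpec) -> CommunityMatrix:
    """Place contiguous species ranges on the grid, optionally with a hotspot.

    Ordinary species get a block range around a uniform random centre with
    a negative-binomial size.  Under a *neo* hotspot, species on the
    shortest ``hotspot_quantile`` of terminal branches are confined to the
    hotspot block with small ranges; under *paleo*, species on the longest
    quantile; under *mixed*, both.  Every species occupies at least one
    cell.
    """
    if len(tree.tip_labels) != spec.n_species:
        raise InvalidParameterError("tree tip count does not match spec.n_species")
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    # terminal branch length per tip (tips are nodes 0..n_tips-1)
    term = tree.lengths[: tree.n_tips].copy()

    n_flag = int(round(spec.hotspot_quantile * spec.n_species))
    confined = np.zeros(spec.n_species, dtype=bool)
    if spec.hotspot in ("neo", "mixed"):
        confined[np.argsort(term)[:n_flag]] = True
    if spec.hotspot in ("paleo", "mixed"):
        confined |= _paleo_flags(tree, n_flag)
    if spec.hotspot != "none":
        n_demanded = 2 * n_flag if spec.hotspot == "mixed" else n_flag
        if n_flag < 1 or n_demanded >= spec.n_species or confined.sum() >= spec.n_species:
            raise InvalidParameterError(
                "hotspot demands more species than available at this quantile"
            )

    hotspot = spec.hotspot_cells()
    sizes = _range_sizes(rng, spec.n_species, spec.mean_range_cells,
                         spec.range_dispersion, grid.n_cells)
    small = _range_sizes(rng, spec.n_species, spec.hotspot_mean_range_cells,
                         spec.range_dispersion, len(hotspot))
    presence = np.zeros((grid.n_cells, spec.n_species), dtype=np.uint8)
    for j in range(spec.n_species):
        if confined[j]:
            center = int(rng.choice(hotspot))
            cells = _grow_block(grid, center, int(small[j]), allowed=hotspot)
        else:
            center = int(rng.integers(grid.n_cells))
            cells = _grow_block(grid, center, int(sizes[j]))
        presence[cells, j] = 1
    meta = {"hotspot": spec.hotspot,
            "hotspot_cells": spec.hotspot_cells().tolist() if spec.hotspot != "none" else [],
            "confined_species": [tree.tip_labels[j] for j in np.flatnonzero(confined)]}
    return CommunityMatrix(grid, list(tree.tip_labels), presence, meta)


def simulate_scenario(spec: ScenarioSpec) -> tuple[Phylogeny, CommunityMatrix]:
    """Convenience wrapper: tree plus ranges from one ScenarioSpec."""
    tree = simulate_phylogeny(spec.n_species, spec.birth_rate, spec.seed)
    return tree, simulate_ranges(tree, spec)


# ---- climate ----------------------------------------------------------


@dataclass
class ClimateSeries:
    """A gridded climate variable through time.

    ``values`` has shape (n_steps, n_rows, n_cols); ``times`` are
    timestamps in years, strictly increasing.
    """

    grid: GridSpec
    times: np.ndarray
    values: np.ndarray
    variable: str = "var"
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("need >= 2 strictly increasing timestamps")
        if self.values.shape != (len(self.times), self.grid.n_rows, self.grid.n_cols):
            raise InvalidParameterError("values shape must be (n_steps, n_rows, n_cols)")


def simulate_climate_series(
    grid: GridSpec,
    base: float = 20.0,
    spatial_slope: float = 0.01,
    temporal_slope: float = 0.05,
    noise_sd: float = 0.0,
    n_steps: int = 220,
    step_years: float = 100.0,
    seed: int = 0,
    variable: str = "var",
) -> ClimateSeries:
    """Linear-trend climate series: base + spatial_slope*x + temporal_slope*t + noise.

    ``x`` is the cell-centre x coordinate in km and ``t`` the step index, so
    ``temporal_slope`` is per time step (``step_years`` years, default one
    century, emulating LGM-to-present paleoclimate series).
    """
    if n_steps < 2:
        raise InvalidParameterError("n_steps must be >= 2")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = grid.cell_centers()[:, 0].reshape(grid.n_rows, grid.n_cols)
    t = np.arange(n_steps)
    vals = base + spatial_slope * x[None, :, :] + temporal_slope * t[:, None, None]
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    times = t * step_years
    return ClimateSeries(grid, times, vals, variable=variable)


# ---- SAR response -----------------------------------------------------


def simulate_sar_response(
    X: np.ndarray,
    W,
    beta: np.ndarray,
    lam: float = 0.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw y = X beta + u with SAR(1) errors u = lam * W u + eps.

    ``W`` must be row-standardized and ``|lam| < 1``; the realization solves
    (I - lam W) u = eps with iid Gaussian eps.
    """
    from .spatialstats import SpatialWeights  # local import to avoid cycle

    if isinstance(W, SpatialWeights):
        W = W.matrix()
    W = sp.csr_matrix(W)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if abs(lam) >= 1:
        raise InvalidParameterError("|lambda| must be < 1")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    A = sp.eye(n, format="csc") - lam * W
    try:
        u = sp.linalg.spsolve(A, eps)
    except Exception as exc:
        raise NumericalFailureError(f"(I - lambda W) solve failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise NumericalFailureError("(I - lambda W) is singular or ill-conditioned")
    return X @ beta + u
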