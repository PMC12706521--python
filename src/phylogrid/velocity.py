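"""Gradient-based climate-change velocity from gridded time series.

Velocity at a cell is the absolute temporal trend of the climate variable
(units per year, OLS over the full series) divided by the local spatial
gradient of its time mean (units per km, central differences), giving km
per year — the speed at which an organism would have to move to keep its
climate constant.  Low velocity marks climatically stable areas.  A small
gradient floor prevents division blow-up over flat terrain; where it was
applied is reported in an audit mask.  Per-variable velocities are min-max
rescaled to [0, 1] and summed to combine variables (e.g. temperature and
precipitation) into one stability layer in [0, 2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .grid import GridSpec
from .synthio import ClimateSeries

__all__ = [
    "VelocityRaster",
    "temporal_trend",
    "spatial_gradient",
    "climate_velocity",
    "normalize_and_combine",
]


@dataclass
class VelocityRaster:
    """Per-cell climate-change velocity plus its ingredients for audit."""

    grid: GridSpec
    velocity: np.ndarray  # km / year, (n_rows, n_cols)
    temporal_slope: np.ndarray  # units / year
    gradient: np.ndarray  # units / km
    floor_applied: np.ndarray  # bool mask where the gradient floor kicked in
    variable: str = "var"


def temporal_trend(cs: ClimateSeries) -> np.ndarray:
    """Per-cell OLS slope of value against time, in units per year.

    Cells with fewer than 2 finite values are NaN.
    """
    t = cs.times
    vals = cs.values.reshape(len(t), -1)
    finite = np.isfinite(vals)
    slopes = np.full(vals.shape[1], np.nan)
    complete = finite.all(axis=0)
    if complete.any():  # vectorized closed-form OLS for fully observed cells
        tc = t - t.mean()
        denom = (tc ** 2).sum()
        slopes[complete] = tc @ vals[:, complete] / denom
    for j in np.flatnonzero(~complete):
        ok = finite[:, j]
        if ok.sum() >= 2:
            tc = t[ok] - t[ok].mean()
            slopes[j] = tc @ vals[ok, j] / (tc ** 2).sum()
    return slopes.reshape(cs.grid.n_rows, cs.grid.n_cols)


def spatial_gradient(raster: np.ndarray, cell_size: float) -> np.ndarray:
    """Gradient magnitude of a raster in units per km.

    Central differences in the interior (mean of forward and backward
    differences over one cell size), one-sided at edges; this is exactly
    ``numpy.gradient`` with the cell size as spacing.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.shape[0] < 3 or raster.shape[1] < 3:
        raise InvalidInputError("spatial gradient needs a grid of at least 3x3")
    dy, dx = np.gradient(raster, cell_size)
    return np.hypot(dx, dy)


def climate_velocity(cs: ClimateSeries, gradient_floor: float = 1e-6) -> VelocityRaster:
    """Velocity = |temporal trend| / max(spatial gradient, floor), km/yr.

    The spatial gradient is taken on the time-mean raster.  Cells where the
    floor replaced a smaller gradient are flagged in ``floor_applied``.
    """
    slope = temporal_trend(cs)
    mean_raster = np.nanmean(cs.values, axis=0)
    grad = spatial_gradient(mean_raster, cs.grid.cell_size)
    floored = grad < gradient_floor
    vel = np.abs(slope) / np.maximum(grad, gradient_floor)
    return VelocityRaster(
        grid=cs.grid,
        velocity=vel,
        temporal_slope=slope,
        gradient=grad,
        floor_applied=floored & np.isfinite(slope),
        variable=cs.variable,
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    finite = np.isfinite(values)
    if not finite.any():
        raise InvalidInputError("raster has no finite cells")
    lo, hi = values[finite].min(), values[finite].max()
    if hi == lo:
        warnings.warn("constant raster: normalized layer is all zero")
        out = np.where(finite, 0.0, np.nan)
        return out
    return (values - lo) / (hi - lo)


def normalize_and_combine(v1: VelocityRaster, v2: VelocityRaster) -> np.ndarray:
    """Min-max rescale each velocity raster to [0, 1] and add them.

    0 in a layer marks the most climatically stable cell for that
    variable, 1 the least; the combined layer lies in [0, 2].
    """
    if v1.grid != v2.grid:
        raise InvalidInputError("velocity rasters live on different grids")
    return _minmax(v1.velocity) + _minmax(v2.velocity)
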