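"""Inverse-distance-weighted (IDW) interpolation.

IDW predicts the value at a target location as a positively weighted
average of sample values, with weights proportional to
``distance^(-power)``.  It is the interpolator of choice for very small
sample sizes, where variogram-based methods cannot be fit.  Predictions
are convex combinations of the sample values, so they always lie within
the sample min/max; a target coinciding with a sample point returns
that sample's value exactly (coincident duplicates: their mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .sampling import SampleValues
from .terrain import Raster

__all__ = ["IdwConfig", "idw_predict", "idw_grid"]

# Distance below which a target is treated as coincident with a sample (m).
_COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class IdwConfig:
    """IDW settings.

    power
        Exponent on inverse distance; larger values localize the
        prediction.  Default 2, the dominant convention.
    max_neighbors
        Number of nearest samples used per target; ``None`` means all
        samples (global neighborhood, the default).
    """

    power: float = 2.0
    max_neighbors: int | None = None

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValueError("power must be positive")
        if self.max_neighbors is not None and self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1 (or None for all)")


def idw_predict(
    samples: SampleValues, target_xy, config: IdwConfig = IdwConfig()
) -> np.ndarray:
    """IDW prediction at one or more target coordinates.

    Returns a 1-D array of predictions (length = number of targets).
    Extrapolation outside the sample hull is permitted; the convex
    weighting still bounds predictions by the sample min/max.
    """
    pts = samples.design.points
    z = samples.values
    if len(pts) == 0:
        raise ValueError("empty sample set")
    targets = np.atleast_2d(np.asarray(target_xy, dtype=float))
    if targets.shape[1] != 2:
        raise ValueError("targets must be (m, 2) x, y coordinates")

    k = len(pts) if config.max_neighbors is None else min(config.max_neighbors, len(pts))
    if k < len(pts):
        tree = cKDTree(pts)
        d, idx = tree.query(targets, k=k)
        d = d.reshape(len(targets), k)
        zn = z[idx.reshape(len(targets), k)]
    else:
        d = cdist(targets, pts)
        zn = np.broadcast_to(z, d.shape)

    out = np.empty(len(targets))
    coincident = d <= _COINCIDENT_TOL
    hit = coincident.any(axis=1)
    if hit.any():
        # exact passthrough; mean over coincident duplicates
        masked = np.where(coincident, zn, np.nan)
        out[hit] = np.nanmean(masked[hit], axis=1)
    free = ~hit
    if free.any():
        w = d[free] ** (-config.power)
        # weighted mean as a shift from the sample mean: exact on constant
        # samples (no catastrophic residue from w*z summation)
        zm = z.mean()
        out[free] = zm + (w * (zn[free] - zm)).sum(axis=1) / w.sum(axis=1)
    return out


def idw_grid(
    samples: SampleValues, template: Raster, config: IdwConfig = IdwConfig()
) -> Raster:
    """IDW prediction at every cell center of ``template``.

    The output raster shares the template's geometry (the evaluation
    convention: interpolations are produced on the same grid as the
    population raster so they can be compared cell-wise).
    """
    preds = idw_predict(samples, template.center_grid(), config)
    return Raster(
        preds.reshape(template.shape),
        template.cell_size,
        template.origin,
        template.nodata_marker,
    )
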