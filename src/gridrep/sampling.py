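"""Regular sample designs and raster value extraction.

Two layouts are built in:

* ``lattice`` — a most-nearly-square r x c lattice of a requested size n
  with a uniform random anchoring offset, wrapped torus-fashion so each
  draw keeps the regular spacing but shifts where it starts.  This is
  the generic "regularly arranged sample" evaluated at
  n = 4, 8, 16, 30, 60, 120.
* ``rapeld`` — the RAPELD biodiversity-survey grid: 30 plots on six
  parallel 5 km trails at 1 km spacing inside a 5x5 km area.

Custom designs can be imported from CSV (columns ``x_m``, ``y_m``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .terrain import Raster

__all__ = [
    "SampleDesign",
    "SampleValues",
    "lattice_dims",
    "regular_lattice",
    "rapeld_design",
    "extract_values",
    "design_from_csv",
    "design_to_csv",
]


@dataclass
class SampleDesign:
    """An ordered set of planar sample coordinates with provenance."""

    points: np.ndarray  # (n, 2) x, y in meters
    layout: str = "lattice"  # lattice | rapeld | custom
    dims: tuple[int, int] | None = None  # (rows_of_points, cols_of_points)
    offset: tuple[float, float] = (0.0, 0.0)
    requested_n: int | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of x, y")
        if self.requested_n is None:
            self.requested_n = len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class SampleValues:
    """Raster values extracted at a design's points, one value per point."""

    design: SampleDesign
    values: np.ndarray
    source_area_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.design.points):
            raise ValueError("one value per design point required")


def lattice_dims(n: int) -> tuple[int, int]:
    """Most-nearly-square factor pair (r, c), r <= c, r*c = n.

    For prime n > 3 (no usable factor pair) the pair for the largest
    composite below n is returned and the caller places fewer points.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = n
    while True:
        best = None
        for r in range(int(np.sqrt(m)), 0, -1):
            if m % r == 0:
                best = (r, m // r)
                break
        if best is not None and not (best[0] == 1 and m > 3):
            return best
        m -= 1


def _extent_of(raster_or_extent) -> tuple[float, float]:
    if isinstance(raster_or_extent, Raster):
        return raster_or_extent.width, raster_or_extent.height
    w, h = raster_or_extent
    return float(w), float(h)


def regular_lattice(raster_extent, n: int, rng: np.random.Generator) -> SampleDesign:
    """Regular r x c lattice of n points with a random torus-wrapped offset.

    Base points sit at cell centers of the lattice (spacing
    ``sx = width / c``, ``sy = height / r``); a uniform offset
    ``dx ~ U[-sx/2, sx/2)``, ``dy ~ U[-sy/2, sy/2)`` shifts the anchor
    and points wrap back into the extent, so every draw preserves the
    spacing and the point count.
    """
    width, height = _extent_of(raster_extent)
    r, c = lattice_dims(n)
    sx, sy = width / c, height / r
    if sx <= 0 or sy <= 0:
        raise ValueError("extent smaller than one lattice spacing")
    dx = rng.uniform(-sx / 2, sx / 2)
    dy = rng.uniform(-sy / 2, sy / 2)
    j, i = np.meshgrid(np.arange(c), np.arange(r))
    x = (sx / 2 + j.ravel() * sx + dx) % width
    y = (sy / 2 + i.ravel() * sy + dy) % height
    return SampleDesign(
        np.column_stack([x, y]),
        layout="lattice",
        dims=(r, c),
        offset=(dx, dy),
        requested_n=n,
    )


def rapeld_design(raster: Raster) -> SampleDesign:
    """The standard RAPELD 25 km^2 grid: 30 plots at 1 km intervals.

    Six parallel north-south trails at x = 0, 1, ..., 5 km (clamped half
    a cell inside the extent) each carry five plots at
    y = 0.5, 1.5, ..., 4.5 km.
    """
    width, height = raster.width, raster.height
    cell = raster.cell_size
    if abs(width - 5000.0) > cell or abs(height - 5000.0) > cell:
        raise ValueError("RAPELD layout requires a 5x5 km extent (within one cell)")
    trail_x = np.clip(np.arange(6) * 1000.0, cell / 2, width - cell / 2)
    plot_y = np.arange(5) * 1000.0 + 500.0
    xx, yy = np.meshgrid(trail_x, plot_y, indexing="ij")
    return SampleDesign(
        np.column_stack([xx.ravel(), yy.ravel()]),
        layout="rapeld",
        dims=(5, 6),
        requested_n=30,
    )


def extract_values(
    raster: Raster, design: SampleDesign, area_id: str = ""
) -> SampleValues:
    """Value of the raster cell whose center is nearest each design point.

    Ties (a point exactly on a cell edge) break toward the lower row /
    lower column, so sample values are always actual population values.
    Points outside the extent or landing on a nodata cell raise.
    """
    ox, oy = raster.origin
    rows, cols = raster.shape
    pts = design.points
    fx = (pts[:, 0] - ox) / raster.cell_size
    fy = (pts[:, 1] - oy) / raster.cell_size
    eps = 1e-9
    if (fx < -eps).any() or (fx > cols + eps).any() or (fy < -eps).any() or (
        fy > rows + eps
    ).any():
        raise ValueError("design point outside raster extent")

    def _index(f: np.ndarray, nmax: int) -> np.ndarray:
        idx = np.floor(f).astype(int)
        on_edge = np.isclose(f, np.round(f), rtol=0, atol=1e-6) & (np.round(f) > 0)
        idx = np.where(on_edge, np.round(f).astype(int) - 1, idx)
        return np.clip(idx, 0, nmax - 1)

    jj = _index(fx, cols)
    ii = _index(fy, rows)
    vals = raster.values[ii, jj]
    if np.isnan(vals).any():
        raise ValueError("design point landed on a nodata cell")
    return SampleValues(design, vals, source_area_id=area_id)


def design_to_csv(design: SampleDesign, path) -> None:
    """Export points as CSV with header columns x_m, y_m."""
    pd.DataFrame(design.points, columns=["x_m", "y_m"]).to_csv(path, index=False)


def design_from_csv(path) -> SampleDesign:
    """Import a custom design from CSV (required columns x_m, y_m)."""
    df = pd.read_csv(path)
    if not {"x_m", "y_m"}.issubset(df.columns):
        raise ValueError("design CSV requires columns x_m, y_m")
    return SampleDesign(df[["x_m", "y_m"]].to_numpy(), layout="custom")
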