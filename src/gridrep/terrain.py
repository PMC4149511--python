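"""Synthetic elevation rasters and raster I/O.

A :class:`Raster` is a regular grid of elevation values treated as the
*population* surface that sampling designs are judged against.  Synthetic
surfaces emulate 5x5 km digital-elevation tiles at ~90 m resolution:
stationary Gaussian random fields with a controllable mean, standard
deviation and spatial correlation length, optionally pushed through a
monotone convex transform to produce the long right tails seen in some
real elevation tiles.

Conventions (used everywhere in the package):

* coordinates are planar meters; no geodetic projection handling;
* the raster origin is the lower-left corner of the lower-left cell;
* cell values are attached to cell centers;
* row 0 of ``values`` is the *southernmost* row (y increases with row
  index); file formats that store rows north-to-south are flipped on
  read/write;
* missing cells are NaN in memory and ``nodata_marker`` on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Raster",
    "TerrainSpec",
    "make_constant",
    "make_ramp",
    "make_gaussian_field",
    "read_raster",
    "write_raster",
]


@dataclass
class Raster:
    """A regular grid of elevation values.

    Parameters
    ----------
    values
        2-D float array, shape ``(rows, cols)``; row 0 is the southern
        edge.  Missing cells are NaN.
    cell_size
        Edge length of one (square) cell, in meters.
    origin
        ``(x, y)`` of the lower-left corner of the lower-left cell (m).
    nodata_marker
        Sentinel written to disk for missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_marker: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("raster must be at least 2x2 cells")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("raster values must be finite or NaN")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def width(self) -> float:
        """Extent along x, in meters."""
        return self.values.shape[1] * self.cell_size

    @property
    def height(self) -> float:
        """Extent along y, in meters."""
        return self.values.shape[0] * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates: ``(x, y)`` 1-D arrays of length cols, rows."""
        ox, oy = self.origin
        rows, cols = self.values.shape
        x = ox + (np.arange(cols) + 0.5) * self.cell_size
        y = oy + (np.arange(rows) + 0.5) * self.cell_size
        return x, y

    def center_grid(self) -> np.ndarray:
        """All cell-center coordinates as an ``(rows*cols, 2)`` array.

        Row-major over (row, col), matching ``values.ravel()``.
        """
        x, y = self.cell_centers()
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    # -- statistics ---------------------------------------------------
    def valid_values(self) -> np.ndarray:
        """All non-missing cell values as a flat array."""
        v = self.values.ravel()
        return v[~np.isnan(v)]

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def sd(self) -> float:
        """Population standard deviation (ddof=0) of non-missing cells."""
        return float(np.nanstd(self.values))


@dataclass(frozen=True)
class TerrainSpec:
    """Recipe for one synthetic terrain tile.

    ``correlation_length`` is the e-folding scale (m) of the Gaussian
    autocorrelation of the underlying random field; ``tail`` selects a
    symmetric ("gaussian") or right-skewed ("long_tailed") marginal.
    Identical spec + seed always yields an identical raster.
    """

    rows: int = 56
    cols: int = 56
    cell_size: float = 90.0
    target_mean: float = 159.5
    target_sd: float = 40.0
    correlation_length: float = 1000.0
    tail: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("rows and cols must be >= 2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.target_sd < 0:
            raise ValueError("target_sd must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.tail not in ("gaussian", "long_tailed"):
            raise ValueError("tail must be 'gaussian' or 'long_tailed'")


def make_constant(rows: int, cols: int, cell_size: float, value: float) -> Raster:
    """Flat surface: every cell equals ``value`` (SD = 0)."""
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    return Raster(np.full((rows, cols), float(value)), cell_size)


def make_ramp(
    rows: int,
    cols: int,
    cell_size: float,
    slope_x: float,
    slope_y: float,
    intercept: float = 0.0,
) -> Raster:
    """Planar gradient: value at a cell center (x, y) is
    ``intercept + slope_x * x + slope_y * y``.

    An anisotropic fixture: real landscapes carry directional gradients
    that a stationary isotropic field does not.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    x = (np.arange(cols) + 0.5) * cell_size
    y = (np.arange(rows) + 0.5) * cell_size
    vals = intercept + slope_x * x[np.newaxis, :] + slope_y * y[:, np.newaxis]
    return Raster(np.broadcast_to(vals, (rows, cols)).copy(), cell_size)


def make_gaussian_field(spec: TerrainSpec) -> Raster:
    """Stationary correlated Gaussian random field, rescaled to target moments.

    White noise is smoothed with an isotropic Gaussian kernel (periodic
    boundaries) whose width is set so the field autocorrelation is
    approximately ``exp(-r^2 / (2 * correlation_length^2))``, then
    standardized.  For ``tail='long_tailed'`` the standardized field is
    exponentiated (a monotone convex transform forcing right skew)
    before the final affine rescale that pins the realized raster mean
    and SD to ``target_mean`` / ``target_sd`` exactly (to float
    precision).
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.rows, spec.cols))
    if spec.target_sd == 0.0:
        return Raster(
            np.full((spec.rows, spec.cols), spec.target_mean), spec.cell_size
        )

    # Smoothing a white field with a Gaussian kernel of width sigma_f
    # yields autocorrelation Gaussian with scale sigma_f * sqrt(2).
    sigma_cells = spec.correlation_length / spec.cell_size / np.sqrt(2.0)
    f = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="wrap")
    sd = f.std()
    if sd == 0.0:  # pathological: over-smoothed tiny grid
        f = noise
        sd = f.std()
    z = (f - f.mean()) / sd
    if spec.tail == "long_tailed":
        z = np.exp(z)
        z = (z - z.mean()) / z.std()
    vals = spec.target_mean + spec.target_sd * z
    return Raster(vals, spec.cell_size)


# ---------------------------------------------------------------------
# I/O: ESRI ASCII grid and single-band GeoTIFF
# ---------------------------------------------------------------------

_ASCII_EXT = (".asc", ".txt", ".grd")
_TIFF_EXT = (".tif", ".tiff")


def write_raster(raster: Raster, path) -> None:
    """Write a raster as ESRI ASCII grid (.asc/.txt) or GeoTIFF (.tif).

    Format is chosen by extension.  NaN cells are written as the
    raster's ``nodata_marker``.
    """
    p = str(path)
    low = p.lower()
    if low.endswith(_ASCII_EXT):
        _write_ascii(raster, p)
    elif low.endswith(_TIFF_EXT):
        _write_geotiff(raster, p)
    else:
        raise ValueError(f"unrecognized raster extension: {p}")


def read_raster(path) -> Raster:
    """Read a single-band GeoTIFF or ESRI ASCII grid.

    Falls back to origin (0, 0) and cell size 1 with a warning when a
    TIFF carries no georeferencing tags.  Multi-band files are rejected.
    """
    p = str(path)
    low = p.lower()
    if low.endswith(_ASCII_EXT):
        return _read_ascii(p)
    if low.endswith(_TIFF_EXT):
        return _read_geotiff(p)
    raise ValueError(f"unrecognized raster extension: {p}")


def _write_ascii(raster: Raster, path: str) -> None:
    rows, cols = raster.shape
    ox, oy = raster.origin
    out = np.where(np.isnan(raster.values), raster.nodata_marker, raster.values)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {ox!r}\n"
        f"yllcorner {oy!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata_marker!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores rows north-to-south.
        np.savetxt(fh, out[::-1], fmt="%.10g")


def _read_ascii(path: str) -> Raster:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field {req!r}")
    vals = np.loadtxt(data_lines).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return Raster(vals[::-1].copy(), header["cellsize"], origin, nodata)


# GeoTIFF tag codes for a plain axis-aligned raster.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(raster: Raster, path: str) -> None:
    import tifffile

    rows, _ = raster.shape
    ox, oy = raster.origin
    top = oy + raster.height
    out = np.where(
        np.isnan(raster.values), raster.nodata_marker, raster.values
    ).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        # raster (0,0) i.e. top-left pixel corner -> world (ox, top)
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata_marker)),
    ]
    # TIFF rows run north-to-south.
    tifffile.imwrite(path, out[::-1], extratags=extratags)


def _read_geotiff(path: str) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = page.asarray()
        if vals.ndim == 3:
            if vals.shape[-1] == 1:
                vals = vals[..., 0]
            else:
                raise ValueError("multi-band rasters are not supported")
        if vals.ndim != 2:
            raise ValueError("expected a single-band 2-D raster")
        if len(tf.pages) > 1:
            raise ValueError("multi-page rasters are not supported")
        tags = page.tags
        scale_tag = tags.get(_TAG_PIXEL_SCALE)
        tie_tag = tags.get(_TAG_TIEPOINT)
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        scale = scale_tag.value if scale_tag is not None else None
        tie = tie_tag.value if tie_tag is not None else None
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
    vals = np.asarray(vals, dtype=float)
    vals = np.where(vals == nodata, np.nan, vals)
    if scale is None or tie is None:
        warnings.warn(
            "TIFF carries no georeferencing tags; assuming origin (0, 0) "
            "and cell size 1",
            stacklevel=3,
        )
        cell, origin = 1.0, (0.0, 0.0)
    else:
        cell = float(scale[0])
        top_left_x, top_left_y = float(tie[3]), float(tie[4])
        origin = (top_left_x, top_left_y - vals.shape[0] * cell)
    return Raster(vals[::-1].copy(), cell, origin, nodata)
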