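"""Lightweight raster data model and focal (moving-window) statistics.

Grids are plain 2D value arrays with a boolean nodata mask, a square cell
size in metres, and the (x, y) of the lower-left corner.  Row 0 sits at the
south edge; the centre of cell (i, j) is ``origin + ((j + 0.5), (i + 0.5)) *
cell_size``.  No projection or datum handling is attempted: coordinates are
planar metres.

Focal statistics use a circular window whose membership rule is
centre-to-centre distance <= radius (ties included).  For the default 100 m
radius on 25 m cells this is a fixed 49-cell neighbourhood.  Windows are
clipped at grid edges and around masked cells: denominators count only the
cells actually available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "RasterStack",
    "WindowSpec",
    "GeometryError",
    "focal_mean",
    "focal_std",
    "focal_proportion",
    "focal_density",
    "ndvi",
    "pc1",
    "terrain_derivatives",
    "simpson_diversity",
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
]


class GeometryError(ValueError):
    """Raised when grids with incompatible shape/cell size/origin are combined."""


@dataclass
class RasterGrid:
    """A single-band grid with nodata mask.

    Parameters
    ----------
    values : 2D float array.
    mask : 2D bool array, ``True`` where the cell holds no data.  Masked cells
        are excluded from every statistic.
    cell_size : edge length of a (square) cell in metres.
    origin : ``(x0, y0)`` of the lower-left grid corner in metres.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    cell_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise GeometryError("values and mask must have identical shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def geometry(self) -> tuple:
        return (self.shape, float(self.cell_size), self.origin)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """A new grid sharing this grid's geometry."""
        return RasterGrid(values, mask=mask, cell_size=self.cell_size, origin=self.origin)

    def copy(self) -> "RasterGrid":
        return self.like(self.values.copy(), self.mask.copy())

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates."""
        ny, nx = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_at(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        i = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        ny, nx = self.shape
        if np.any((i < 0) | (i >= ny) | (j < 0) | (j >= nx)):
            raise IndexError("point outside grid extent")
        return i, j

    def sample(self, x, y) -> np.ndarray:
        """Values at points; NaN where the containing cell is masked."""
        i, j = self.cell_at(x, y)
        out = self.values[i, j].astype(float)
        out = np.where(self.mask[i, j], np.nan, out)
        return out

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0


class RasterStack:
    """An ordered name -> :class:`RasterGrid` mapping with shared geometry."""

    def __init__(self, layers: dict[str, RasterGrid] | None = None):
        self._layers: dict[str, RasterGrid] = {}
        if layers:
            for name, grid in layers.items():
                self.add(name, grid)

    def add(self, name: str, grid: RasterGrid) -> None:
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self._layers:
            ref = next(iter(self._layers.values()))
            if not ref.same_geometry(grid):
                raise GeometryError(
                    f"layer {name!r} geometry {grid.geometry} does not match stack {ref.geometry}"
                )
        self._layers[name] = grid

    def __getitem__(self, name: str) -> RasterGrid:
        if name not in self._layers:
            raise KeyError(f"missing layer {name!r}; stack has {sorted(self._layers)}")
        return self._layers[name]

    def __setitem__(self, name: str, grid: RasterGrid) -> None:
        if name in self._layers:
            del self._layers[name]
        self.add(name, grid)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def items(self):
        return self._layers.items()

    def copy(self) -> "RasterStack":
        return RasterStack({k: v.copy() for k, v in self.items()})

    @property
    def geometry(self) -> tuple:
        return next(iter(self._layers.values())).geometry

    def table(self, names: list[str] | None = None, where: np.ndarray | None = None):
        """Flatten layers into an (n_cells, n_layers) table (pandas DataFrame).

        ``where`` is a boolean cell selector; defaults to cells valid in every
        requested layer.
        """
        import pandas as pd

        names = list(names) if names is not None else self.names
        if where is None:
            where = np.ones(self[names[0]].shape, dtype=bool)
            for n in names:
                where &= self[n].valid
        data = {n: self[n].values[where] for n in names}
        return pd.DataFrame(data), where


@dataclass(frozen=True)
class WindowSpec:
    """Circular focal window; membership by cell-centre distance <= radius."""

    radius_m: float = 100.0

    def offsets(self, cell_size: float) -> np.ndarray:
        if self.radius_m < cell_size:
            raise ValueError("radius_m must be at least one cell size")
        r = self.radius_m / cell_size
        k = int(np.floor(r + 1e-9))
        di, dj = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1), indexing="ij")
        inside = di**2 + dj**2 <= r**2 * (1 + 1e-12) + 1e-9
        return np.stack([di[inside], dj[inside]], axis=1)

    def footprint(self, cell_size: float) -> np.ndarray:
        """Boolean (2k+1, 2k+1) window membership kernel."""
        off = self.offsets(cell_size)
        k = int(np.max(np.abs(off)))
        fp = np.zeros((2 * k + 1, 2 * k + 1), dtype=bool)
        fp[off[:, 0] + k, off[:, 1] + k] = True
        return fp


def _focal_sum_count(values: np.ndarray, valid: np.ndarray, footprint: np.ndarray):
    fp = footprint.astype(float)
    v = np.where(valid, values, 0.0)
    s = ndimage.correlate(v, fp, mode="constant", cval=0.0)
    c = np.rint(ndimage.correlate(valid.astype(float), fp, mode="constant", cval=0.0))
    return s, c


def focal_mean(grid: RasterGrid, window: WindowSpec = WindowSpec()) -> RasterGrid:
    """Mean over the unmasked cells of the circular window at every cell."""
    fp = window.footprint(grid.cell_size)
    s, c = _focal_sum_count(grid.values, grid.valid, fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return grid.like(np.where(c > 0, out, 0.0), mask=c == 0)

def focal_std(grid: RasterGrid, window: WindowSpec = WindowSpec()) -> RasterGrid:
    """Population standard deviation over the window (roughness index)."""
    fp = window.footprint(grid.cell_size)
    s, c = _focal_sum_count(grid.values, grid.valid, fp)
    s2, _ = _focal_sum_count(grid.values**2, grid.valid, fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = s / np.maximum(c, 1)
        var = s2 / np.maximum(c, 1) - m**2
    out = np.sqrt(np.clip(var, 0.0, None))
    return grid.like(np.where(c > 0, out, 0.0), mask=c == 0)


def focal_proportion(
    class_map: RasterGrid, class_group, window: WindowSpec = WindowSpec()
) -> RasterGrid:
    """Fraction of unmasked window cells whose class value is in ``class_group``.

    ``class_map`` holds integer class codes; ``class_group`` is a non-empty
    collection of codes present in the map's vocabulary.
    """
    group = list(class_group)
    if not group:
        raise ValueError("class_group must be non-empty")
    known = np.unique(class_map.values[class_map.valid])
    unknown = [g for g in group if g not in known]
    if unknown:
        raise ValueError(f"unknown class label(s) in group: {unknown}")
    indicator = np.isin(class_map.values, group).astype(float)
    fp = window.footprint(class_map.cell_size)
    s, c = _focal_sum_count(indicator, class_map.valid, fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c > 0, s / np.maximum(c, 1), 0.0)
    return class_map.like(out, mask=c == 0)


def focal_density(grid: RasterGrid, window: WindowSpec = WindowSpec()) -> RasterGrid:
    """Window sum divided by available window area, in units per hectare.

    Input cells hold per-cell counts (e.g. trees) or lengths (e.g. metres of
    road).  The denominator is the number of available (in-grid, unmasked)
    window cells times the cell area, so edge cells are normalized by their
    clipped window.
    """
    if np.any(grid.values[grid.valid] < 0):
        raise ValueError("focal_density requires non-negative counts")
    fp = window.footprint(grid.cell_size)
    s, c = _focal_sum_count(grid.values, grid.valid, fp)
    area_ha = np.maximum(c, 1) * grid.cell_area_ha
    out = np.where(c > 0, s / area_ha, 0.0)
    return grid.like(out, mask=c == 0)


def ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """Normalized difference vegetation index (NIR - RED) / (NIR + RED).

    Cells where the denominator vanishes (or either band is masked) are
    masked in the output; values are bounded in [-1, 1] for non-negative
    reflectances.
    """
    if not nir.same_geometry(red):
        raise GeometryError("NIR and RED grids must share geometry")
    denom = nir.values + red.values
    bad = nir.mask | red.mask | (np.abs(denom) < 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir.values - red.values) / denom
    return nir.like(np.where(bad, 0.0, out), mask=bad)


def pc1(bands: list[RasterGrid]) -> RasterGrid:
    """Score on the first principal component of standardized bands.

    Bands are centred and scaled to unit variance over jointly-valid cells
    before the eigendecomposition; the component sign is fixed so the loading
    of the first (retained) band is non-negative.  Constant bands are excluded
    with a warning.
    """
    if len(bands) < 2:
        raise ValueError("need at least two bands")
    ref = bands[0]
    for b in bands[1:]:
        if not ref.same_geometry(b):
            raise GeometryError("bands must share geometry")
    valid = np.ones(ref.shape, dtype=bool)
    for b in bands:
        valid &= b.valid
    if valid.sum() < 2:
        raise ValueError("need at least two jointly unmasked cells")
    X = np.column_stack([b.values[valid] for b in bands])
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"{(~keep).sum()} constant band(s) excluded from PC1")
    if keep.sum() < 1:
        raise ValueError("all bands constant")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    corr = np.corrcoef(Xs, rowvar=False)
    corr = np.atleast_2d(corr)
    w, v = np.linalg.eigh(corr)
    lead = v[:, np.argmax(w)]
    if lead[0] < 0:
        lead = -lead
    scores = Xs @ lead
    out = np.zeros(ref.shape)
    out[valid] = scores
    return ref.like(out, mask=~valid)


def terrain_derivatives(
    dem: RasterGrid, roughness_window: WindowSpec = WindowSpec(100.0)
) -> dict[str, RasterGrid]:
    """Slope, northness, eastness and roughness from an elevation grid.

    Slope (degrees) from central-difference gradients.  Aspect is the
    direction of steepest *descent*, measured clockwise from north, so
    NORTH = cos(aspect) = -dz/dy / |grad|, EAST = sin(aspect) = -dz/dx / |grad|.
    Flat cells get NORTH = EAST = 0 by convention.  ROUGH is the focal
    standard deviation of elevation.
    """
    dzdy, dzdx = np.gradient(dem.values, dem.cell_size)
    g = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(g))
    with np.errstate(invalid="ignore", divide="ignore"):
        north = np.where(g > 0, -dzdy / np.where(g > 0, g, 1.0), 0.0)
        east = np.where(g > 0, -dzdx / np.where(g > 0, g, 1.0), 0.0)
    m = dem.mask
    return {
        "SLOPE": dem.like(slope, m.copy()),
        "NORTH": dem.like(north, m.copy()),
        "EAST": dem.like(east, m.copy()),
        "ROUGH": focal_std(dem, roughness_window),
    }


def simpson_diversity(prop_layers: list[RasterGrid]) -> RasterGrid:
    """Simpson's diversity index 1 - sum(p_hat_i^2) over type proportions.

    Proportions are renormalized to sum to one per cell; where all
    proportions are zero the index is 0 (monoculture-equivalent), keeping the
    layer defined on bare ground.  Range [0, 1 - 1/k] for k types.
    """
    ref = prop_layers[0]
    mask = np.zeros(ref.shape, dtype=bool)
    for p in prop_layers:
        if not ref.same_geometry(p):
            raise GeometryError("proportion layers must share geometry")
        if np.any(p.values[p.valid] < 0):
            raise ValueError("negative proportion")
        mask |= p.mask
    P = np.stack([p.values for p in prop_layers])
    total = P.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phat = np.where(total > 0, P / np.where(total > 0, total, 1.0), 0.0)
    sidi = np.where(total > 0, 1.0 - (phat**2).sum(axis=0), 0.0)
    return ref.like(np.where(mask, 0.0, sidi), mask=mask)


# -- I/O -------------------------------------------------------------------

_ASC_NODATA = -9999.0


def write_raster(grid: RasterGrid, path, fmt: str = "%.17g") -> None:
    """Write a grid to ESRI ASCII (.asc) or single-band TIFF (.tif/.tiff).

    The ASCII path is plain text; ``%.17g`` round-trips float64 exactly.
    The TIFF path stores float64 values with NaN at masked cells and carries
    cell size, origin and the mask convention in the ImageDescription tag.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".agr"):
        nodata = _ASC_NODATA
        if np.any(np.isclose(grid.values[grid.valid], nodata)):
            nodata = float(np.nanmin(grid.values) - 1e6)
        vals = np.where(grid.mask, nodata, grid.values)
        ny, nx = grid.shape
        header = (
            f"ncols {nx}\nnrows {ny}\n"
            f"xllcorner {grid.origin[0]!r}\nyllcorner {grid.origin[1]!r}\n"
            f"cellsize {grid.cell_size!r}\nnodata_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, np.flipud(vals), fmt=fmt)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        vals = np.where(grid.mask, np.nan, grid.values)
        meta = {
            "cell_size": grid.cell_size,
            "origin": list(grid.origin),
            "nodata": "nan",
        }
        tifffile.imwrite(path, np.flipud(vals), description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported raster format {suffix!r}")


def read_raster(path) -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".agr"):
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh, ndmin=2)
        vals = np.flipud(vals)
        nodata = header["nodata_value"]
        mask = vals == nodata
        return RasterGrid(
            np.where(mask, 0.0, vals),
            mask=mask,
            cell_size=header["cellsize"],
            origin=(header["xllcorner"], header["yllcorner"]),
        )
    if suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            vals = np.flipud(tf.pages[0].asarray()).astype(float)
            meta = json.loads(tf.pages[0].description)
        mask = np.isnan(vals)
        return RasterGrid(
            np.where(mask, 0.0, vals),
            mask=mask,
            cell_size=float(meta["cell_size"]),
            origin=tuple(meta["origin"]),
        )
    raise ValueError(f"unsupported raster format {suffix!r}")


def write_stack(stack: RasterStack, directory, fmt: str = "%.17g", ext: str = ".asc") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"layers": {}, "format": ext}
    for name, grid in stack.items():
        fname = f"{name}{ext}"
        write_raster(grid, directory / fname, fmt=fmt)
        manifest["layers"][name] = fname
    (directory / "stack.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_stack(directory) -> RasterStack:
    directory = Path(directory)
    manifest = json.loads((directory / "stack.json").read_text())
    stack = RasterStack()
    for name, fname in manifest["layers"].items():
        stack.add(name, read_raster(directory / fname))
    return stack
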