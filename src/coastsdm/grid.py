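"""Raster data model, GeoTIFF I/O, and deterministic predictor derivations.

All spatial layers share a single lightweight currency, :class:`RasterGrid`:
a 2-D value array with an affine geotransform (GDAL order, units of meters),
a CRS tag, and a boolean nodata mask.  Row 0 is the northernmost row and
cell coordinates always refer to cell centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import LineString, MultiPoint, Point, Polygon, shape as shapely_shape
from shapely.geometry import mapping as shapely_mapping

__all__ = [
    "RasterGrid",
    "PredictorStack",
    "FeatureGeometry",
    "derive_slope_aspect",
    "distance_surface",
    "temporal_mean",
    "resample_to",
    "pairwise_correlation",
    "read_geotiff",
    "write_geotiff",
]

# GeoTIFF tag codes used for round-tripping georeferencing through tifffile.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_DEFAULT_NODATA = -9999.0


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


class AlignmentError(InvalidInputError):
    """Raised when grids that must share shape/transform/CRS do not."""


@dataclass
class RasterGrid:
    """A single-band raster layer on a projected (meter) grid.

    Parameters
    ----------
    values
        2-D float array of cell values (layer units).
    transform
        GDAL-style affine 6-tuple ``(x0, dx, rxy, y0, ryx, dy)`` mapping
        (col, row) pixel-corner indices to projected x/y in meters.
        ``dy`` is negative for north-up grids (row 0 northernmost).
    crs_tag
        Free-text identifier of the projected CRS (e.g. ``"EPSG:32633"``).
    nodata_mask
        Boolean array, True where the cell carries no data.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs_tag: str = "EPSG:32633"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("RasterGrid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise InvalidInputError("nodata_mask shape mismatch")
        t = tuple(float(v) for v in self.transform)
        if len(t) != 6:
            raise InvalidInputError("transform must be a 6-tuple")
        if t[1] == 0.0 or t[5] == 0.0:
            raise InvalidInputError("pixel sizes must be nonzero")
        self.transform = t

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def dx(self) -> float:
        return self.transform[1]

    @property
    def dy(self) -> float:
        return self.transform[5]

    @property
    def cell_area(self) -> float:
        return abs(self.dx * self.dy)

    def xy(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Projected coordinates of cell centers for (row, col) indices."""
        x0, dx, rxy, y0, ryx, dy = self.transform
        c = np.asarray(cols, dtype=float) + 0.5
        r = np.asarray(rows, dtype=float) + 0.5
        return x0 + dx * c + rxy * r, y0 + ryx * c + dy * r

    def index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing projected points."""
        x0, dx, rxy, y0, ryx, dy = self.transform
        if rxy or ryx:  # pragma: no cover - rotated grids unused here
            raise InvalidInputError("rotated transforms not supported for index()")
        col = np.floor((np.asarray(x, dtype=float) - x0) / dx).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - y0) / dy).astype(int)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Full grids of x and y center coordinates, shape == values.shape."""
        rows, cols = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return self.xy(rows, cols)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.transform, other.transform)
            and self.crs_tag == other.crs_tag
        )

    def with_values(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """A new grid on the same georeference with different values."""
        mask = self.nodata_mask.copy() if nodata_mask is None else np.asarray(nodata_mask, bool)
        return RasterGrid(np.asarray(values, float), self.transform, self.crs_tag, mask)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell values at projected points; NaN off-grid or on nodata."""
        row, col = self.index(x, y)
        out = np.full(row.shape, np.nan)
        ok = (row >= 0) & (row < self.shape[0]) & (col >= 0) & (col < self.shape[1])
        rr, cc = row[ok], col[ok]
        vals = self.values[rr, cc].astype(float)
        vals[self.nodata_mask[rr, cc]] = np.nan
        out[ok] = vals
        return out


@dataclass
class PredictorStack:
    """Named, grid-aligned raster layers forming the model design space."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise InvalidInputError("layer names must be unique")
        ref = None
        for name, grid in self.layers.items():
            if ref is None:
                ref = grid
            elif not grid.aligned_with(ref):
                raise AlignmentError(f"layer {name!r} is not aligned to the reference grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def reference(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        return PredictorStack({n: self.layers[n] for n in names})

    def joint_valid_mask(self) -> np.ndarray:
        """True where every layer holds data."""
        mask = ~self.reference.nodata_mask
        for grid in self.layers.values():
            mask &= ~grid.nodata_mask
        return mask

    def table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Flatten jointly valid cells (or a supplied cell mask) to a frame."""
        m = self.joint_valid_mask() if mask is None else mask
        return pd.DataFrame({n: g.values[m] for n, g in self.layers.items()})

    def sample(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({n: g.sample(x, y) for n, g in self.layers.items()})


@dataclass
class FeatureGeometry:
    """Points, a polygon, or a polyline in the raster CRS (meters)."""

    kind: str  # {points, polygon, polyline}
    coordinates: list[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"points", "polygon", "polyline"}:
            raise InvalidInputError(f"unknown geometry kind {self.kind!r}")
        self.coordinates = [(float(x), float(y)) for x, y in self.coordinates]
        if not self.coordinates:
            raise InvalidInputError("empty feature geometry")
        if self.kind == "polygon" and self.coordinates[0] != self.coordinates[-1]:
            self.coordinates.append(self.coordinates[0])

    def to_shapely(self):
        if self.kind == "points":
            if len(self.coordinates) == 1:
                return Point(self.coordinates[0])
            return MultiPoint(self.coordinates)
        if self.kind == "polyline":
            return LineString(self.coordinates)
        return Polygon(self.coordinates)

    def boundary(self):
        """The geometry distances are measured to (polygon -> its ring)."""
        geom = self.to_shapely()
        return geom.boundary if self.kind == "polygon" else geom

    # GeoJSON / WKT round-trip -------------------------------------------------
    def to_geojson(self) -> dict:
        return {
            "type": "Feature",
            "properties": {"label": self.label, "kind": self.kind},
            "geometry": shapely_mapping(self.to_shapely()),
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "FeatureGeometry":
        geom = shapely_shape(obj["geometry"])
        props = obj.get("properties") or {}
        label = props.get("label", "")
        if geom.geom_type in ("Point", "MultiPoint"):
            coords = [(g.x, g.y) for g in getattr(geom, "geoms", [geom])]
            return cls("points", coords, label)
        if geom.geom_type == "LineString":
            return cls("polyline", list(geom.coords), label)
        if geom.geom_type == "Polygon":
            return cls("polygon", list(geom.exterior.coords), label)
        raise InvalidInputError(f"unsupported GeoJSON geometry {geom.geom_type}")

    def to_wkt(self) -> str:
        return self.to_shapely().wkt

    @classmethod
    def from_wkt(cls, wkt: str, label: str = "") -> "FeatureGeometry":
        return cls.from_geojson({"geometry": shapely_mapping(shapely.from_wkt(wkt)),
                                 "properties": {"label": label}})


# ---------------------------------------------------------------------------
# Derivations
# ---------------------------------------------------------------------------

def derive_slope_aspect(depth: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope and aspect (degrees) from an elevation/bathymetry grid.

    Uses Horn's 8-neighbor finite differences.  Aspect is measured clockwise
    from north in [0, 360); it is undefined (nodata) on perfectly flat cells.
    Cells whose 3x3 neighborhood touches the grid edge or a nodata cell are
    nodata in both outputs.
    """
    nr, nc = depth.shape
    if nr < 3 or nc < 3:
        raise InvalidInputError("grid must be at least 3x3 for slope/aspect")
    z = depth.values
    dx, dy = abs(depth.dx), abs(depth.dy)

    # Neighborhood views (interior cells only).
    c = np.s_[1:-1, 1:-1]
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]

    # Horn's weighted differences: rate of change eastward and northward.
    dz_dx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * dx)
    dz_dy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * dy)

    grad = np.hypot(dz_dx, dz_dy)
    slope_deg = np.degrees(np.arctan(grad))
    # Aspect: downslope azimuth, clockwise from north in [0, 360).
    aspect_deg = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0

    bad = np.zeros((nr, nc), dtype=bool)
    bad[:] = True
    interior_bad = np.zeros_like(dz_dx, dtype=bool)
    m = depth.nodata_mask
    for view in (m[:-2, :-2], m[:-2, 1:-1], m[:-2, 2:], m[1:-1, :-2], m[1:-1, 1:-1],
                 m[1:-1, 2:], m[2:, :-2], m[2:, 1:-1], m[2:, 2:]):
        interior_bad |= view
    bad[c] = interior_bad

    slope = np.full((nr, nc), np.nan)
    aspect = np.full((nr, nc), np.nan)
    slope[c] = slope_deg
    aspect[c] = aspect_deg
    flat = np.zeros((nr, nc), dtype=bool)
    flat[c] = grad == 0.0
    aspect_mask = bad | flat
    slope[bad] = np.nan
    aspect[aspect_mask] = np.nan
    return (
        depth.with_values(slope, bad),
        depth.with_values(aspect, aspect_mask),
    )


def distance_surface(reference: RasterGrid, features: FeatureGeometry) -> RasterGrid:
    """Per-cell Euclidean distance (m) from cell centers to the feature.

    Point features measure to the nearest point; polylines and polygons
    measure to the nearest location on the line / polygon boundary.
    """
    xs, ys = reference.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    geom = features.boundary()
    dist = shapely.distance(pts, geom).reshape(reference.shape)
    dist[reference.nodata_mask] = np.nan
    return reference.with_values(dist)


def temporal_mean(daily_layers: Sequence[RasterGrid]) -> RasterGrid:
    """Nodata-aware per-cell mean over a stack of aligned daily layers."""
    layers = list(daily_layers)
    if not layers:
        raise InvalidInputError("need at least one layer")
    ref = layers[0]
    for g in layers[1:]:
        if not g.aligned_with(ref):
            raise AlignmentError("temporal_mean layers are not aligned")
    vals = np.stack([np.where(g.nodata_mask, np.nan, g.values) for g in layers])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=0)
    mask = np.all([g.nodata_mask for g in layers], axis=0)
    mean[mask] = np.nan
    return ref.with_values(mean, mask)


def resample_to(source: RasterGrid, target: RasterGrid, method: str = "bilinear") -> RasterGrid:
    """Interpolate ``source`` onto ``target`` cell centers.

    Bilinear for continuous fields (default); ``method="nearest"`` for
    categorical layers.  Target cells falling outside the source extent, or
    whose interpolation support includes nodata, are nodata.
    """
    from scipy.interpolate import RegularGridInterpolator

    sx0, sdx, _, sy0, _, sdy = source.transform
    nr, nc = source.shape
    # Source cell-center axes (row axis may be descending in y; flip to ascend).
    src_y = sy0 + sdy * (np.arange(nr) + 0.5)
    src_x = sx0 + sdx * (np.arange(nc) + 0.5)
    vals = np.where(source.nodata_mask, np.nan, source.values)
    flip_y, flip_x = src_y[0] > src_y[-1], src_x[0] > src_x[-1]
    if flip_y:
        src_y, vals = src_y[::-1], vals[::-1, :]
    if flip_x:
        src_x, vals = src_x[::-1], vals[:, ::-1]

    tx, ty = target.cell_centers()
    if (tx.max() < src_x.min() or tx.min() > src_x.max()
            or ty.max() < src_y.min() or ty.min() > src_y.max()):
        raise InvalidInputError("source and target extents are disjoint")

    interp = RegularGridInterpolator(
        (src_y, src_x), vals,
        method="linear" if method == "bilinear" else "nearest",
        bounds_error=False, fill_value=np.nan,
    )
    out = interp(np.stack([ty.ravel(), tx.ravel()], axis=1)).reshape(target.shape)
    mask = ~np.isfinite(out) | target.nodata_mask
    out[mask] = np.nan
    return target.with_values(out, mask)


def pairwise_correlation(
    stack: PredictorStack, at_cells: np.ndarray | None = None
) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over jointly valid cells.

    Pairs involving a zero-variance layer are NaN (undefined correlation).
    """
    names = stack.names
    if len(names) < 2:
        raise InvalidInputError("need at least two layers")
    table = stack.table(at_cells)
    if len(table) < 3:
        raise InvalidInputError("need at least three jointly valid cells")
    arr = table.to_numpy()
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band, float32, explicit nodata)
# ---------------------------------------------------------------------------

def write_geotiff(grid: RasterGrid, path, nodata: float = _DEFAULT_NODATA) -> None:
    data = np.where(grid.nodata_mask, nodata, grid.values).astype(np.float32)
    x0, dx, _, y0, _, dy = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, description=json.dumps({"crs_tag": grid.crs_tag}),
                     extratags=extratags)


def read_geotiff(path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else _DEFAULT_NODATA
        crs_tag = "unknown"
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                crs_tag = json.loads(desc.value).get("crs_tag", "unknown")
            except (json.JSONDecodeError, AttributeError):
                pass
    dx, dy = float(scale[0]), -abs(float(scale[1]))
    x0, y0 = float(tiepoint[3]), float(tiepoint[4])
    mask = data == nodata
    data = np.where(mask, np.nan, data)
    return RasterGrid(data, (x0, dx, 0.0, y0, 0.0, dy), crs_tag, mask)


def write_stack(stack: PredictorStack, outdir, manifest_name: str = "layers.json") -> None:
    """Write every layer as GeoTIFF plus a name->path manifest."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, grid in stack.layers.items():
        fn = f"{name}.tif"
        write_geotiff(grid, outdir / fn)
        manifest[name] = fn
    (outdir / manifest_name).write_text(json.dumps(manifest, indent=2))


def read_stack(outdir, manifest_name: str = "layers.json") -> PredictorStack:
    import pathlib

    outdir = pathlib.Path(outdir)
    manifest = json.loads((outdir / manifest_name).read_text())
    return PredictorStack({n: read_geotiff(outdir / fn) for n, fn in manifest.items()})
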