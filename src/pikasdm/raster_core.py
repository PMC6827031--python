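"""Raster data model and plumbing for the 1-km modeling grid.

Everything downstream (covariate derivation, maxent fitting, mapping)
operates on a single aligned grid of square cells.  The conventions are:

* cell ``(r, c)`` covers the half-open square
  ``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]`` where ``(x0, y0)``
  is the north-west corner and ``s`` the cell size; row 0 is the north edge;
* points exactly on the east/south grid boundary are clamped inward;
* nodata is held internally as NaN and propagates: a cell is valid for
  modeling only if *no* layer holds nodata there.

Supported on-disk formats are ESRI ASCII grid (text) and single-band
GeoTIFF (via tifffile, using ModelPixelScale/ModelTiepoint tags).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

Kind = Literal["continuous", "categorical"]

__all__ = [
    "GridSpec",
    "Layer",
    "LayerStack",
    "OccurrenceSet",
    "RasterError",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "resample",
    "extract_at_points",
    "sample_background",
]


class RasterError(ValueError):
    """Raised for malformed rasters or contract violations."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid with square cells.

    ``(x_origin, y_origin)`` is the north-west *corner* of the grid (not a
    cell center).  ``crs_tag`` is carried opaquely and ignored by alignment
    checks.
    """

    x_origin: float
    y_origin: float
    cell_size: float
    n_rows: int
    n_cols: int
    nodata: float = -9999.0
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise RasterError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise RasterError("grid must have at least one row and column")

    def aligned_with(self, other: "GridSpec") -> bool:
        return (
            self.x_origin == other.x_origin
            and self.y_origin == other.y_origin
            and self.cell_size == other.cell_size
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.nodata == other.nodata
        )

    # --- coordinate helpers -------------------------------------------------
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, shape (n_rows, n_cols)."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates -> (row, col, inside) arrays.

        Points exactly on the east/south outer boundary are clamped to the
        last column/row; anything else outside gets ``inside=False``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - y) / self.cell_size).astype(int)
        x_max = self.x_origin + self.n_cols * self.cell_size
        y_min = self.y_origin - self.n_rows * self.cell_size
        col = np.where(x == x_max, self.n_cols - 1, col)
        row = np.where(y == y_min, self.n_rows - 1, row)
        inside = (
            (x >= self.x_origin) & (x <= x_max) & (y >= y_min) & (y <= self.y_origin)
        )
        return row, col, inside


@dataclass
class Layer:
    """A named single-band raster. ``values`` uses NaN for nodata."""

    name: str
    kind: Kind
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError(f"layer {self.name!r}: values must be 2-D")
        if self.kind not in ("continuous", "categorical"):
            raise RasterError(f"layer {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and not np.allclose(finite, np.round(finite)):
                raise RasterError(
                    f"categorical layer {self.name!r} holds non-integer codes"
                )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self, name: str | None = None) -> "Layer":
        return Layer(name or self.name, self.kind, self.values.copy())


@dataclass
class LayerStack:
    """Aligned, ordered collection of layers sharing one GridSpec."""

    spec: GridSpec
    layers: list[Layer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise RasterError(f"duplicate layer names: {names}")
        for l in self.layers:
            self._check_shape(l)

    def _check_shape(self, layer: Layer) -> None:
        if layer.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise RasterError(
                f"layer {layer.name!r} shape {layer.values.shape} does not match "
                f"grid ({self.spec.n_rows}, {self.spec.n_cols})"
            )

    def add(self, layer: Layer) -> None:
        if layer.name in self.names:
            raise RasterError(f"duplicate layer name {layer.name!r}")
        self._check_shape(layer)
        self.layers.append(layer)

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: Sequence[str]) -> "LayerStack":
        return LayerStack(self.spec, [self[n] for n in names])

    def valid_mask(self) -> np.ndarray:
        """A cell is valid iff no layer holds nodata there."""
        mask = np.ones((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for l in self.layers:
            mask &= l.valid_mask
        return mask

    def kinds(self) -> dict[str, Kind]:
        return {l.name: l.kind for l in self.layers}

    def table_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Feature table (one column per layer) at the given cell indices."""
        data = {l.name: l.values[rows, cols] for l in self.layers}
        return pd.DataFrame(data)


@dataclass
class OccurrenceSet:
    """Presence coordinates plus the sampled background, with feature tables."""

    presence_xy: np.ndarray  # (n, 2) map coordinates
    background_cells: np.ndarray  # (m, 2) integer (row, col)
    features_presence: pd.DataFrame
    features_background: pd.DataFrame

    @property
    def n_presence(self) -> int:
        return len(self.presence_xy)

    @property
    def n_background(self) -> int:
        return len(self.background_cells)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASC_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_esri_ascii(path: Path) -> tuple[np.ndarray, GridSpec]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
        if m and m.group(1).lower() in _ASC_KEYS + ("dx", "dy"):
            header[m.group(1).lower()] = float(m.group(2))
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize", "xllcorner", "yllcorner"):
        if key not in header:
            raise RasterError(f"{path}: missing ESRI ASCII header key {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    body = "".join(lines[n_header:])
    values = np.array(body.split(), dtype=float)
    if values.size != n_rows * n_cols:
        raise RasterError(
            f"{path}: expected {n_rows * n_cols} values, found {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    values[values == nodata] = np.nan
    spec = GridSpec(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        nodata=nodata,
    )
    return values, spec


def _write_esri_ascii(path: Path, layer: Layer, spec: GridSpec) -> None:
    vals = np.where(np.isfinite(layer.values), layer.values, spec.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_origin!r}\n")
        fh.write(f"yllcorner {spec.y_origin - spec.n_rows * spec.cell_size!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {spec.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path) -> tuple[np.ndarray, GridSpec, dict]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterError(f"{path}: GeoTIFF lacks georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise RasterError(f"{path}: non-square cells ({sx} x {sy}) not supported")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        meta: dict = {}
        if 270 in tags:
            try:
                meta = json.loads(str(tags[270].value))
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if values.ndim != 2:
        raise RasterError(f"{path}: expected single-band raster")
    n_rows, n_cols = values.shape
    if nodata is not None:
        values[values == nodata] = np.nan
    spec = GridSpec(
        x_origin=float(tie[3]),
        y_origin=float(tie[4]),
        cell_size=float(sx),
        n_rows=n_rows,
        n_cols=n_cols,
        nodata=nodata if nodata is not None else -9999.0,
        crs_tag=str(meta.get("crs_tag", "")),
    )
    return values, spec, meta


def _write_geotiff(path: Path, layer: Layer, spec: GridSpec) -> None:
    import tifffile

    vals = np.where(np.isfinite(layer.values), layer.values, spec.nodata)
    desc = json.dumps({"crs_tag": spec.crs_tag, "kind": layer.kind, "name": layer.name})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_origin, spec.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(spec.nodata)),
    ]
    tifffile.imwrite(
        str(path), vals.astype(np.float64), description=desc, extratags=extratags
    )


def read_raster(path: str | Path, kind: Kind = "continuous") -> tuple[Layer, GridSpec]:
    """Read a single-band raster (GeoTIFF or ESRI ASCII grid).

    Nodata cells become NaN; all other values are untouched.  The layer name
    defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise RasterError(f"no such raster: {path}")
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt"):
        values, spec = _read_esri_ascii(path)
        name = path.stem
    elif suffix in (".tif", ".tiff"):
        values, spec, meta = _read_geotiff(path)
        name = str(meta.get("name", path.stem))
    else:
        # sniff: ESRI ASCII starts with 'ncols'
        head = path.read_bytes()[:5].lower()
        if head == b"ncols":
            values, spec = _read_esri_ascii(path)
            name = path.stem
        else:
            raise RasterError(f"unrecognized raster format: {path}")
    return Layer(name=name, kind=kind, values=values), spec


def write_raster(path: str | Path, layer: Layer, spec: GridSpec) -> None:
    """Write a layer as ESRI ASCII (.asc) or GeoTIFF (.tif/.tiff)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt"):
        _write_esri_ascii(path, layer, spec)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(path, layer, spec)
    else:
        raise RasterError(f"unsupported raster extension: {path.suffix!r}")


def read_occurrences(path: str | Path) -> np.ndarray:
    """Read presence coordinates from a CSV with header ``x,y``."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise RasterError(f"{path}: occurrence CSV must have columns x,y")
    return df[[cols["x"], cols["y"]]].to_numpy(dtype=float)


def write_occurrences(path: str | Path, xy: np.ndarray) -> None:
    pd.DataFrame(np.asarray(xy), columns=["x", "y"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample(
    layer: Layer,
    from_spec: GridSpec,
    to_spec: GridSpec,
    method: Literal["bilinear", "nearest"],
) -> Layer:
    """Resample a layer onto a target grid.

    Continuous layers use bilinear interpolation between source cell centers;
    categorical layers must use nearest-neighbor (requesting bilinear for a
    categorical layer is an error).  Target centers outside the source
    center hull are clamped to the nearest source cell.
    """
    if method not in ("bilinear", "nearest"):
        raise RasterError(f"unknown resampling method {method!r}")
    if method == "bilinear" and layer.kind == "categorical":
        raise RasterError(
            f"bilinear resampling is invalid for categorical layer {layer.name!r}"
        )
    tx, ty = to_spec.cell_centers()
    # fractional source index of each target center (index space: centers at i)
    ci = (tx - from_spec.x_origin) / from_spec.cell_size - 0.5
    ri = (from_spec.y_origin - ty) / from_spec.cell_size - 0.5
    order = 1 if method == "bilinear" else 0
    out = ndimage.map_coordinates(
        layer.values, [ri, ci], order=order, mode="nearest"
    )
    return Layer(layer.name, layer.kind, out)


# ---------------------------------------------------------------------------
# Point extraction and background sampling
# ---------------------------------------------------------------------------


def extract_at_points(stack: LayerStack, xy: np.ndarray) -> pd.DataFrame:
    """Feature table at the cells containing the given points.

    Returns one row per point with columns ``x, y, row, col, inside, valid``
    plus one column per layer.  Points outside the grid get
    ``inside=False`` and NaN features (an explicit per-point error record,
    never a silent drop); points on nodata cells get ``valid=False``.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    row, col, inside = stack.spec.point_to_cell(xy[:, 0], xy[:, 1])
    r_safe = np.clip(row, 0, stack.spec.n_rows - 1)
    c_safe = np.clip(col, 0, stack.spec.n_cols - 1)
    table = stack.table_at_cells(r_safe, c_safe)
    for c in table.columns:
        table.loc[~inside, c] = np.nan
    valid = inside & stack.valid_mask()[r_safe, c_safe]
    out = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "row": np.where(inside, row, -1),
            "col": np.where(inside, col, -1),
            "inside": inside,
            "valid": valid,
        }
    )
    return pd.concat([out, table], axis=1)


def sample_background(
    stack: LayerStack,
    n: int,
    bias_mask: Layer | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n`` distinct valid background cells, uniformly without
    replacement; optionally restricted to cells where ``bias_mask`` is 1
    (the sampling-bias correction zone).  Returns an (n, 2) array of
    (row, col), reproducible under ``seed``.
    """
    mask = stack.valid_mask()
    if bias_mask is not None:
        mask &= np.nan_to_num(bias_mask.values, nan=0.0) > 0
    rows, cols = np.nonzero(mask)
    n_valid = rows.size
    if n > n_valid:
        raise RasterError(
            f"requested {n} background cells but only {n_valid} valid cells "
            f"are available (deficit {n - n_valid})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_valid, size=n, replace=False)
    idx.sort()
    return np.column_stack([rows[idx], cols[idx]])


def background_features(stack: LayerStack, cells: np.ndarray) -> pd.DataFrame:
    """Feature table over background cells (one row per cell)."""
    cells = np.asarray(cells)
    return stack.table_at_cells(cells[:, 0], cells[:, 1])


def make_occurrence_set(
    stack: LayerStack,
    presence_xy: np.ndarray,
    n_background: int,
    bias_mask: Layer | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Bundle presences and a fresh background sample with feature tables.

    Presence points falling outside the grid or on invalid cells raise, per
    the OccurrenceSet invariant.
    """
    pres = extract_at_points(stack, presence_xy)
    if not pres["inside"].all():
        bad = pres.index[~pres["inside"]].tolist()
        raise RasterError(f"presence points outside grid: rows {bad}")
    if not pres["valid"].all():
        bad = pres.index[~pres["valid"]].tolist()
        raise RasterError(f"presence points on nodata cells: rows {bad}")
    cells = sample_background(stack, n_background, bias_mask=bias_mask, seed=seed)
    return OccurrenceSet(
        presence_xy=np.asarray(presence_xy, dtype=float),
        background_cells=cells,
        features_presence=pres[stack.names].reset_index(drop=True),
        features_background=background_features(stack, cells),
    )
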