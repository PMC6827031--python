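"""Derived covariate layers: terrain, distance maps, smoothed time series.

These are the predictors the pipeline computes itself from primary data:
slope/aspect and topographic wetness from a DEM, Euclidean distance maps
from vector features (roads, rivers, resident sites), and annual statistics
of Savitzky-Golay-smoothed vegetation-index time series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import shapely
from scipy.signal import savgol_filter

from .raster_core import GridSpec, Layer, RasterError

__all__ = [
    "VectorFeatureSet",
    "TimeSeriesCube",
    "slope_aspect",
    "derive_terrain",
    "twi",
    "euclidean_distance",
    "buffer_mask",
    "savitzky_golay",
    "series_stats",
]

FLAT_ASPECT = -1.0

# D8 neighbor offsets in clockwise order from north; ties in steepest
# descent are broken by the first direction in this order.
_D8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class VectorFeatureSet:
    """Point or polyline features in map coordinates.

    ``coordinates`` is a list of vertex sequences: length-1 sequences for
    points, >=2 for polylines.
    """

    kind: Literal["points", "polylines"]
    coordinates: list[np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = [np.atleast_2d(np.asarray(c, dtype=float)) for c in self.coordinates]
        if not self.coordinates:
            raise ValueError(f"feature set {self.label!r} is empty")
        for c in self.coordinates:
            if not np.all(np.isfinite(c)):
                raise ValueError(f"feature set {self.label!r} has non-finite vertices")
            if self.kind == "polylines" and len(c) < 2:
                raise ValueError("polylines need at least 2 vertices")
            if self.kind == "points" and len(c) != 1:
                raise ValueError("point features hold exactly one vertex each")

    def to_shapely(self):
        if self.kind == "points":
            return shapely.MultiPoint([tuple(c[0]) for c in self.coordinates])
        return shapely.MultiLineString([c.tolist() for c in self.coordinates])

    # --- I/O ---------------------------------------------------------------
    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for c in self.coordinates:
            if self.kind == "points":
                geom = {"type": "Point", "coordinates": list(c[0])}
            else:
                geom = {"type": "LineString", "coordinates": c.tolist()}
            feats.append({"type": "Feature", "properties": {"label": self.label}, "geometry": geom})
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )

    @classmethod
    def from_geojson(cls, path: str | Path, label: str = "") -> "VectorFeatureSet":
        data = json.loads(Path(path).read_text())
        coords: list[np.ndarray] = []
        kind = None
        for feat in data.get("features", []):
            geom = feat["geometry"]
            t = geom["type"]
            if t == "Point":
                kind = kind or "points"
                coords.append(np.array([geom["coordinates"]]))
            elif t == "LineString":
                kind = kind or "polylines"
                coords.append(np.array(geom["coordinates"]))
            elif t == "MultiLineString":
                kind = kind or "polylines"
                coords.extend(np.array(part) for part in geom["coordinates"])
            else:
                raise ValueError(f"unsupported GeoJSON geometry {t!r}")
        if kind is None:
            raise ValueError(f"{path}: no features")
        return cls(kind=kind, coordinates=coords, label=label or Path(path).stem)

    @classmethod
    def from_csv(cls, path: str | Path, kind: Literal["points", "polylines"], label: str = "") -> "VectorFeatureSet":
        """CSV dialect ``feature_id,vertex_index,x,y``."""
        import pandas as pd

        df = pd.read_csv(path)
        coords = [
            g.sort_values("vertex_index")[["x", "y"]].to_numpy()
            for _, g in df.groupby("feature_id", sort=True)
        ]
        return cls(kind=kind, coordinates=coords, label=label or Path(path).stem)


@dataclass
class TimeSeriesCube:
    """Stack of rasters through time: values shape (n_times, n_rows, n_cols)."""

    spec: GridSpec
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.values.shape != (
            len(self.timestamps),
            self.spec.n_rows,
            self.spec.n_cols,
        ):
            raise ValueError("cube values shape must be (time, rows, cols)")


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------


def _horn_gradients(dem: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 finite differences; edges use replicated padding.

    Returns (dz/dx, dz/dy) in map orientation: x east, y north.
    """
    z = np.pad(dem, 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                   f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    # row index grows southward, so north-positive dz/dy flips the sign
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell_size)
    return dzdx, dzdy


def slope_aspect(dem: Layer, spec: GridSpec) -> tuple[Layer, Layer]:
    """Slope (degrees, [0, 90]) and aspect (degrees clockwise from north,
    [0, 360); flat cells get the sentinel -1) from Horn's method."""
    if dem.kind != "continuous":
        raise RasterError("DEM must be continuous")
    if spec.n_rows < 3 or spec.n_cols < 3:
        raise RasterError("slope/aspect require a grid of at least 3x3")
    dzdx, dzdy = _horn_gradients(dem.values, spec.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downhill azimuth: direction of -gradient, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = FLAT_ASPECT
    nodata = ~np.isfinite(dem.values)
    slope[nodata] = np.nan
    aspect[nodata] = np.nan
    return Layer("slope", "continuous", slope), Layer("aspect", "continuous", aspect)


def derive_terrain(
    dem: Layer,
    dem_spec: GridSpec,
    target_spec: GridSpec | None = None,
    order: Literal["derive_then_resample", "resample_then_derive"] = "derive_then_resample",
) -> tuple[Layer, Layer]:
    """Slope/aspect on a target grid from a (possibly finer) DEM.

    Whether terrain derivatives should be computed at native DEM resolution
    and then aggregated, or computed on the already-resampled DEM, is a
    genuine modeling choice with different smoothing behavior; both orders
    are exposed and neither is claimed canonical.  Aspect is resampled by
    nearest neighbor (degrees are circular; averaging them is meaningless).
    """
    from .raster_core import resample

    if target_spec is None or target_spec.aligned_with(dem_spec):
        return slope_aspect(dem, dem_spec)
    if order == "derive_then_resample":
        slope, aspect = slope_aspect(dem, dem_spec)
        return (
            resample(slope, dem_spec, target_spec, "bilinear"),
            resample(aspect, dem_spec, target_spec, "nearest"),
        )
    if order == "resample_then_derive":
        coarse = resample(dem, dem_spec, target_spec, "bilinear")
        return slope_aspect(coarse, target_spec)
    raise ValueError(f"unknown order {order!r}")


def d8_flow_accumulation(dem: Layer, spec: GridSpec) -> np.ndarray:
    """Number of upstream cells draining through each cell (self excluded).

    Single-direction D8 routing: each cell sends its accumulation to the
    neighbor with the steepest positive drop (drop = dz / distance); ties go
    to the first direction clockwise from north.  Pits and flats drain
    nowhere.
    """
    z = dem.values
    nr, nc = z.shape
    target = np.full((nr, nc, 2), -1, dtype=int)
    best = np.full((nr, nc), 0.0)
    for dr, dc in _D8:
        dist = spec.cell_size * (np.hypot(dr, dc))
        zn = np.full_like(z, np.nan)
        r0, r1 = max(dr, 0), nr + min(dr, 0)
        c0, c1 = max(dc, 0), nc + min(dc, 0)
        zn[r0 - dr : r1 - dr, c0 - dc : c1 - dc] = z[r0:r1, c0:c1]
        drop = (z - zn) / dist
        take = np.isfinite(drop) & (drop > best)
        best = np.where(take, drop, best)
        rr, cc = np.nonzero(take)
        target[rr, cc, 0] = rr + dr
        target[rr, cc, 1] = cc + dc
    acc = np.zeros((nr, nc), dtype=float)
    order = np.argsort(z, axis=None)[::-1]  # high to low
    finite = np.isfinite(z.ravel()[order])
    for flat_idx in order[finite]:
        r, c = divmod(int(flat_idx), nc)
        tr, tc = target[r, c]
        if tr >= 0:
            acc[tr, tc] += acc[r, c] + 1
    acc[~np.isfinite(z)] = np.nan
    return acc


def twi(dem: Layer, spec: GridSpec, tan_beta_floor: float = 0.001) -> Layer:
    """Topographic wetness index ln(a / tan(beta)).

    ``a`` is the upslope contributing area per unit contour width,
    (D8 accumulation count + 1) * cell_size; ``beta`` is the Horn slope with
    tan(beta) floored at ``tan_beta_floor`` to keep flats finite.
    """
    slope, _ = slope_aspect(dem, spec)
    acc = d8_flow_accumulation(dem, spec)
    a = (acc + 1.0) * spec.cell_size
    tan_beta = np.maximum(np.tan(np.radians(slope.values)), tan_beta_floor)
    return Layer("twi", "continuous", np.log(a / tan_beta))


# ---------------------------------------------------------------------------
# Distance maps
# ---------------------------------------------------------------------------


def euclidean_distance(features: VectorFeatureSet, spec: GridSpec) -> Layer:
    """Minimum Euclidean distance (map units) from each cell center to the
    feature geometry (true vector geometry, not a rasterization)."""
    geom = features.to_shapely()
    xs, ys = spec.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    d = shapely.distance(pts, geom).reshape(spec.n_rows, spec.n_cols)
    name = f"dis_to_{features.label}" if features.label else "distance"
    return Layer(name, "continuous", d)


def buffer_mask(features: VectorFeatureSet, spec: GridSpec, radius: float) -> Layer:
    """0/1 layer: 1 where the cell center lies within ``radius`` of the
    features — the background sampling-bias correction zone."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    d = euclidean_distance(features, spec)
    return Layer(f"{features.label}_buffer", "continuous", (d.values <= radius).astype(float))


# ---------------------------------------------------------------------------
# Time-series smoothing and statistics
# ---------------------------------------------------------------------------


def savitzky_golay(cube: TimeSeriesCube, window: int, order: int) -> TimeSeriesCube:
    """Per-cell Savitzky-Golay smoothing along time.

    Local least-squares polynomial fit of the given order in a centered odd
    window; the edges are handled by fitting a polynomial to the truncated
    terminal window and evaluating it there.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be < window ({window})")
    if len(cube.timestamps) < window:
        raise ValueError("cube shorter than the smoothing window")
    smoothed = savgol_filter(cube.values, window, order, axis=0, mode="interp")
    return TimeSeriesCube(cube.spec, cube.timestamps.copy(), smoothed)


def series_stats(cube: TimeSeriesCube, basename: str = "series") -> list[Layer]:
    """Per-cell mean / max / min / std (population divisor n) layers,
    named ``{basename}_mean`` etc.  All-nodata cells stay nodata."""
    if len(cube.timestamps) < 2:
        raise ValueError("need at least 2 time steps")
    v = cube.values
    return [
        Layer(f"{basename}_mean", "continuous", v.mean(axis=0)),
        Layer(f"{basename}_max", "continuous", v.max(axis=0)),
        Layer(f"{basename}_min", "continuous", v.min(axis=0)),
        Layer(f"{basename}_std", "continuous", v.std(axis=0, ddof=0)),
    ]
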