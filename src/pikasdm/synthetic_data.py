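"""Synthetic study landscapes with known truth.

The real study's field occurrences and GIS layers are not deposited, so
validation runs on generated landscapes that carry the same statistical
structure: spatially autocorrelated continuous covariates (climate /
vegetation / altitude stand-ins), one spatially coherent categorical layer
(soil type stand-in), distance-to-feature layers derived from generated
roads, rivers and resident sites, a lake-shaped nodata region, and presence
points drawn from a known logistic suitability surface with optional
road-biased detection and minimum-distance thinning.

Everything here is a pure function of (config, seed); the TruthSpec is kept
so recovery tests can compare fitted importance against the generating
coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from . import covariates as cov
from .raster_core import (
    GridSpec,
    Layer,
    LayerStack,
    OccurrenceSet,
    make_occurrence_set,
    write_occurrences,
    write_raster,
)

__all__ = [
    "TruthSpec",
    "SyntheticStudy",
    "StudyConfig",
    "gaussian_random_field",
    "make_categorical",
    "make_features",
    "true_suitability",
    "sample_presences",
    "generate_study",
    "write_study",
]


@dataclass
class TruthSpec:
    """Generating model for suitability: logistic in min-max-scaled
    variables.  Distances and decay lengths are in map units (nominally km)."""

    intercept: float = 0.0
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    categorical_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    bias_decay_length: float = 10.0  # e-folding of road-biased detection
    thin_distance: float = 2.0  # minimum distance between kept presences

    def informative_variables(self) -> list[str]:
        out = [v for v, c in self.linear.items() if c != 0]
        out += [v for v, c in self.quadratic.items() if c != 0 and v not in out]
        out += [v for v in self.categorical_effects if v not in out]
        return out


@dataclass
class SyntheticStudy:
    """One generated study bundle: landscape, truth, and sampled presences."""

    stack: LayerStack
    roads: cov.VectorFeatureSet
    rivers: cov.VectorFeatureSet
    residents: cov.VectorFeatureSet
    truth: TruthSpec
    suitability: Layer
    presences: OccurrenceSet
    seed: int


@dataclass
class StudyConfig:
    """Default profile: 100x100 grid of nominal 1-km cells, 5 continuous
    random-field layers, 1 categorical soil layer, 3 distance layers, an
    elliptical lake of nodata, and 77 presences."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0
    n_continuous: int = 5
    correlation_lengths: tuple[float, ...] = (15.0, 10.0, 20.0, 8.0, 12.0)
    n_soil_codes: int = 4
    n_roads: int = 2
    n_rivers: int = 2
    n_residents: int = 12
    n_presences: int = 77
    n_background: int = 3000
    # Background sampling zone: None draws from the whole valid area (the
    # study drew its background from the entire basin); a radius restricts
    # the draw to the road-buffer bias-correction zone instead.
    background_bias_radius: float | None = None
    lake: tuple[float, float, float, float] | None = (62.0, 55.0, 16.0, 10.0)
    # (center_x, center_y, semi_axis_x, semi_axis_y) in map units
    truth: TruthSpec | None = None


def default_truth() -> TruthSpec:
    """Road-driven truth echoing the study's findings: suitability falls
    steeply with distance to road, soil type matters secondarily, and one
    climate stand-in has a humped response."""
    return TruthSpec(
        intercept=1.0,
        linear={"dis_to_road": -15.0, "clim1": 2.0},
        quadratic={"clim1": -2.5},
        categorical_effects={"soil_type": {1: 0.9, 2: -0.9, 3: 0.45, 4: -0.45}},
        bias_decay_length=10.0,
        thin_distance=2.0,
    )


# ---------------------------------------------------------------------------
# Landscape pieces
# ---------------------------------------------------------------------------


def gaussian_random_field(
    spec: GridSpec, correlation_length: float, seed: int, name: str = "grf"
) -> Layer:
    """Zero-mean unit-variance stationary field with isotropic
    squared-exponential correlation, by Gaussian-kernel smoothing of seeded
    white noise followed by re-standardization."""
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((spec.n_rows, spec.n_cols))
    sigma = correlation_length / spec.cell_size / 2.0
    if sigma > 0.05:
        fld = gaussian_filter(noise, sigma=sigma, mode="reflect")
    else:
        fld = noise
    fld = (fld - fld.mean()) / fld.std()
    return Layer(name, "continuous", fld)


def make_categorical(fld: Layer, n_codes: int, name: str = "soil_type") -> Layer:
    """Quantile-bin a continuous field into spatially coherent integer
    classes coded 1..n_codes."""
    if n_codes < 2:
        raise ValueError("n_codes must be >= 2")
    v = fld.values
    finite = v[np.isfinite(v)]
    edges = np.quantile(finite, np.linspace(0, 1, n_codes + 1)[1:-1])
    codes = np.digitize(v, edges) + 1.0
    codes[~np.isfinite(v)] = np.nan
    return Layer(name, "categorical", codes)


def make_features(
    spec: GridSpec,
    kind: Literal["road", "river", "resident"],
    n: int,
    seed: int,
    near: cov.VectorFeatureSet | None = None,
) -> cov.VectorFeatureSet:
    """Generate roads/rivers as random-walk polylines crossing the grid, or
    resident sites as points (clustered near ``near`` features when given,
    emulating settlement along roads)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    width = spec.n_cols * spec.cell_size
    height = spec.n_rows * spec.cell_size
    x0, y0 = spec.x_origin, spec.y_origin
    if kind in ("road", "river"):
        lines = []
        for _ in range(n):
            y = y0 - rng.uniform(0.15, 0.85) * height
            x = x0
            heading = rng.uniform(-0.35, 0.35)
            pts = [(x, y)]
            step = 4.0 * spec.cell_size
            while x < x0 + width:
                heading = np.clip(heading + rng.normal(0, 0.25), -1.0, 1.0)
                x = x + step * np.cos(heading)
                y = np.clip(y + step * np.sin(heading), y0 - height, y0)
                pts.append((x, y))
            lines.append(np.array(pts))
        return cov.VectorFeatureSet("polylines", lines, label=kind)
    # resident sites
    pts = []
    if near is not None:
        verts = np.vstack(near.coordinates)
        for _ in range(n):
            v = verts[rng.integers(len(verts))]
            p = v + rng.normal(0, 3.0 * spec.cell_size, size=2)
            p[0] = np.clip(p[0], x0, x0 + width)
            p[1] = np.clip(p[1], y0 - height, y0)
            pts.append(np.array([p]))
    else:
        for _ in range(n):
            pts.append(
                np.array(
                    [[x0 + rng.uniform(0, width), y0 - rng.uniform(0, height)]]
                )
            )
    return cov.VectorFeatureSet("points", pts, label=kind)


def true_suitability(stack: LayerStack, truth: TruthSpec) -> Layer:
    """logistic(intercept + Σ linear·x̃ + Σ quadratic·x̃² + categorical
    effects), x̃ the min-max-scaled variable over valid cells; in (0, 1)."""
    for v in truth.informative_variables():
        if v not in stack:
            raise KeyError(f"truth names variable {v!r} absent from stack")
    eta = np.full((stack.spec.n_rows, stack.spec.n_cols), truth.intercept, dtype=float)

    def scaled(name: str) -> np.ndarray:
        vals = stack[name].values
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        return (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)

    for v, c in truth.linear.items():
        eta += c * scaled(v)
    for v, c in truth.quadratic.items():
        eta += c * scaled(v) ** 2
    for v, effects in truth.categorical_effects.items():
        vals = stack[v].values
        for code, eff in effects.items():
            eta += np.where(vals == code, eff, 0.0)
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit[~stack.valid_mask()] = np.nan
    return Layer("true_suitability", "continuous", suit)


def sample_presences(
    suitability: Layer,
    spec: GridSpec,
    n: int,
    seed: int,
    bias_decay_length: float | None = None,
    road_distance: Layer | None = None,
    thin_distance: float = 0.0,
) -> np.ndarray:
    """Draw presence cell centers with probability ∝ suitability (optionally
    times the roadside detection bias e^{-d_road/decay}), sequentially
    without replacement with greedy earlier-point-wins thinning at
    ``thin_distance``.  Returns an (n, 2) array of (x, y); raises if the
    landscape cannot host n thinned points.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = suitability.values
    weight = np.where(np.isfinite(s), s, 0.0).ravel().astype(float)
    if bias_decay_length is not None:
        if road_distance is None:
            raise ValueError("bias requires a distance-to-road layer")
        d = np.nan_to_num(road_distance.values, nan=np.inf).ravel()
        weight = weight * np.exp(-d / bias_decay_length)
    if weight.sum() == 0:
        raise ValueError("suitability has no positive mass")
    rng = np.random.default_rng(seed)
    xs, ys = spec.cell_centers()
    xs, ys = xs.ravel(), ys.ravel()
    accepted: list[int] = []
    w = weight.copy()
    while len(accepted) < n:
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"thinning at {thin_distance} exhausted candidate cells after "
                f"{len(accepted)} of {n} presences"
            )
        idx = int(rng.choice(w.size, p=w / total))
        w[idx] = 0.0
        if thin_distance > 0 and accepted:
            ax = xs[accepted]
            ay = ys[accepted]
            if np.min(np.hypot(ax - xs[idx], ay - ys[idx])) < thin_distance:
                continue
        accepted.append(idx)
    return np.column_stack([xs[accepted], ys[accepted]])


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


def _child_seed(seed: int, *tags: int) -> int:
    """Deterministic sub-seed below 2^31 from a master seed and stage tags."""
    ss = np.random.SeedSequence([int(seed), *map(int, tags)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full synthetic study bundle (pure function of inputs)."""
    config = config or StudyConfig()
    truth = config.truth or default_truth()
    spec = GridSpec(
        x_origin=0.0,
        y_origin=config.n_rows * config.cell_size,
        cell_size=config.cell_size,
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        crs_tag="synthetic",
    )
    lake_mask = None
    if config.lake is not None:
        cx, cy, ax, ay = config.lake
        gx, gy = spec.cell_centers()
        lake_mask = ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 <= 1.0

    layers: list[Layer] = []
    for i in range(config.n_continuous):
        ell = config.correlation_lengths[i % len(config.correlation_lengths)]
        layers.append(
            gaussian_random_field(spec, ell, _child_seed(seed, 1, i), name=f"clim{i + 1}")
        )
    soil_field = gaussian_random_field(spec, 12.0, _child_seed(seed, 2))
    layers.append(make_categorical(soil_field, config.n_soil_codes, name="soil_type"))

    roads = make_features(spec, "road", config.n_roads, _child_seed(seed, 3))
    rivers = make_features(spec, "river", config.n_rivers, _child_seed(seed, 4))
    residents = make_features(
        spec, "resident", config.n_residents, _child_seed(seed, 5), near=roads
    )
    layers.append(cov.euclidean_distance(roads, spec))
    layers.append(cov.euclidean_distance(rivers, spec))
    layers.append(cov.euclidean_distance(residents, spec))

    if lake_mask is not None:
        for l in layers:
            l.values[lake_mask] = np.nan
    stack = LayerStack(spec, layers)

    suit = true_suitability(stack, truth)
    presence_xy = sample_presences(
        suit,
        spec,
        config.n_presences,
        _child_seed(seed, 6),
        bias_decay_length=truth.bias_decay_length,
        road_distance=stack["dis_to_road"],
        thin_distance=truth.thin_distance,
    )
    bias_zone = None
    if config.background_bias_radius is not None:
        bias_zone = cov.buffer_mask(roads, spec, radius=config.background_bias_radius)
    occ = make_occurrence_set(
        stack,
        presence_xy,
        n_background=config.n_background,
        bias_mask=bias_zone,
        seed=_child_seed(seed, 7),
    )
    return SyntheticStudy(
        stack=stack,
        roads=roads,
        rivers=rivers,
        residents=residents,
        truth=truth,
        suitability=suit,
        presences=occ,
        seed=seed,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path, fmt: str = "asc") -> list[str]:
    """Write the bundle in the formats the real pipeline reads: rasters,
    GeoJSON features, presence CSV, truth JSON, config YAML.  Returns the
    manifest of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for layer in study.stack.layers + [study.suitability]:
        p = out / f"{layer.name}.{fmt}"
        write_raster(p, layer, study.stack.spec)
        written.append(p.name)
    for feats in (study.roads, study.rivers, study.residents):
        p = out / f"{feats.label}.geojson"
        feats.to_geojson(p)
        written.append(p.name)
    p = out / "presences.csv"
    write_occurrences(p, study.presences.presence_xy)
    written.append(p.name)
    truth_dict = asdict(study.truth)
    (out / "truth.json").write_text(json.dumps(truth_dict, indent=2))
    written.append("truth.json")
    meta = {
        "seed": study.seed,
        "kinds": study.stack.kinds(),
        "layers": study.stack.names,
        "n_presences": int(study.presences.n_presence),
        "n_background": int(study.presences.n_background),
    }
    (out / "study.yaml").write_text(yaml.safe_dump(meta))
    written.append("study.yaml")
    written.append("manifest.json")
    (out / "manifest.json").write_text(json.dumps(sorted(written), indent=2))
    return sorted(written)
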