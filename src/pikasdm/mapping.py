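"""Suitability maps, binarization, area accounting, scenario comparison.

Turns fitted models (or replicate reports) into probability maps, converts
them to binary presence/absence maps at the max-TSS threshold, summarizes
suitable area, and quantifies the with/without-human-factors contrast as a
paired design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from . import evaluation as ev
from . import maxent_core as mx
from .raster_core import GridSpec, Layer, LayerStack, RasterError

__all__ = [
    "SuitabilityMap",
    "ScenarioComparison",
    "predict_map",
    "binarize",
    "suitable_area",
    "compare_scenarios",
]


@dataclass
class SuitabilityMap:
    """Per-cell logistic suitability in [0, 1] (NaN = nodata) with provenance."""

    spec: GridSpec
    probabilities: np.ndarray
    scenario: str = ""
    n_replicates: int = 1

    def as_layer(self, name: str = "suitability") -> Layer:
        return Layer(name, "continuous", self.probabilities)


@dataclass
class ScenarioComparison:
    """Full vs reduced (e.g. without human factors) paired comparison."""

    threshold_full: float
    threshold_reduced: float
    suitable_area_full: float  # km^2 (map units^2)
    suitable_area_reduced: float
    increase_area: float  # km^2 where the full model raises probability
    extension_percent: float
    wilcoxon: dict[str, dict]  # per metric: {"W": .., "p": .., "direction": ..}
    delta: float = 0.0
    restrict_to_full_suitable: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def predict_map(
    model_or_report: mx.MaxentModel | ev.EvalReport,
    stack: LayerStack,
    scenario: str = "",
) -> SuitabilityMap:
    """Logistic suitability at every valid cell of the stack.

    A fitted model is evaluated directly; an EvalReport contributes its
    replicate-mean map (the consensus of the replicate runs).
    """
    if isinstance(model_or_report, ev.EvalReport):
        if model_or_report.mean_map is None:
            raise ValueError("EvalReport carries no mean map (run with stack=...)")
        return SuitabilityMap(
            spec=stack.spec,
            probabilities=model_or_report.mean_map.values.copy(),
            scenario=scenario,
            n_replicates=len(model_or_report.replicates),
        )
    model = model_or_report
    missing = [v for v in model.expansion.variables if v not in stack]
    if missing:
        raise RasterError(f"stack lacks model variables: {missing}")
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    probs = np.full((stack.spec.n_rows, stack.spec.n_cols), np.nan)
    table = stack.table_at_cells(rows, cols)
    probs[rows, cols] = mx.predict_logistic(model, table)
    return SuitabilityMap(spec=stack.spec, probabilities=probs, scenario=scenario)


def binarize(suit_map: SuitabilityMap, threshold: float) -> Layer:
    """1 where probability >= threshold, 0 otherwise; nodata preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    p = suit_map.probabilities
    out = np.where(np.isfinite(p), (p >= threshold).astype(float), np.nan)
    return Layer("suitable", "categorical", out)


def suitable_area(binary: Layer, spec: GridSpec) -> tuple[float, float]:
    """(area in map-units^2, fraction of valid cells) of the 1-class."""
    v = binary.values
    n_suit = float(np.nansum(v == 1))
    n_valid = float(np.isfinite(v).sum())
    area = n_suit * spec.cell_size**2
    fraction = n_suit / n_valid if n_valid else 0.0
    return area, fraction


def compare_scenarios(
    full_report: ev.EvalReport,
    reduced_report: ev.EvalReport,
    stack_spec: GridSpec,
    delta: float = 0.0,
    restrict_to_full_suitable: bool = True,
) -> ScenarioComparison:
    """Paired comparison of two replicate runs sharing split plans.

    Each scenario gets its own max-TSS threshold and binary map (from its
    replicate-mean map and mean TSS curve).  ``increase_area`` counts valid
    cells where the full model's mean probability exceeds the reduced
    model's by more than ``delta`` (by default restricted to cells suitable
    under the full model).  Per-replicate training AUC, test AUC and max
    TSS are compared by the paired Wilcoxon signed-rank test.
    """
    if full_report.mean_map is None or reduced_report.mean_map is None:
        raise ValueError("both reports must carry mean maps")
    if len(full_report.replicates) != len(reduced_report.replicates):
        raise ValueError("scenario runs have different replicate counts")
    if full_report.seed != reduced_report.seed:
        raise ValueError("scenario runs must share the split-plan seed (paired design)")

    maps = {}
    thresholds = {}
    areas = {}
    for name, rep in (("full", full_report), ("reduced", reduced_report)):
        smap = SuitabilityMap(
            stack_spec, rep.mean_map.values, scenario=name,
            n_replicates=len(rep.replicates),
        )
        t = rep.mean_optimal_threshold
        binary = binarize(smap, t)
        area, _ = suitable_area(binary, stack_spec)
        maps[name], thresholds[name], areas[name] = (smap, binary), t, area

    p_full = maps["full"][0].probabilities
    p_red = maps["reduced"][0].probabilities
    gain_cells = np.isfinite(p_full) & np.isfinite(p_red) & (p_full - p_red > delta)
    if restrict_to_full_suitable:
        gain_cells &= maps["full"][1].values == 1
    increase_area = float(gain_cells.sum()) * stack_spec.cell_size**2

    if areas["reduced"] > 0:
        extension = 100.0 * (areas["full"] - areas["reduced"]) / areas["reduced"]
    else:
        extension = float("inf") if areas["full"] > 0 else 0.0

    wil = {}
    for metric in ("train_auc", "test_auc", "max_tss"):
        try:
            w, p, direction = ev.wilcoxon_signed_rank(
                full_report.replicates[metric].to_numpy(),
                reduced_report.replicates[metric].to_numpy(),
            )
            wil[metric] = {"W": w, "p": p, "direction": direction}
        except ValueError as err:  # too few nonzero differences to test
            wil[metric] = {"W": None, "p": None, "direction": "none", "note": str(err)}

    return ScenarioComparison(
        threshold_full=thresholds["full"],
        threshold_reduced=thresholds["reduced"],
        suitable_area_full=areas["full"],
        suitable_area_reduced=areas["reduced"],
        increase_area=increase_area,
        extension_percent=extension,
        wilcoxon=wil,
        delta=delta,
        restrict_to_full_suitable=restrict_to_full_suitable,
    )
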