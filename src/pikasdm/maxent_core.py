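"""Presence-only maximum-entropy model (Gibbs density over background).

The model fits an exponential-family density q(x) ∝ exp(λ·f(x)) over the
background cells, choosing λ to maximize the L1-penalized log-likelihood of
the presence sample:

    J(λ) = (1/m) Σ_presence λ·f(x_i)  −  ln Σ_background e^{λ·f(x)}
           − Σ_j β_j |λ_j|

which is concave; at the optimum with β = 0 the background-expected
features equal the presence means (exponential-family moment matching).
Feature expansion mirrors the conventional maxent machinery: linear,
quadratic, product, threshold and hinge transforms of continuous variables
(scaled to [0, 1] by their background range) plus one indicator per
categorical code.

Outputs: "raw" is the normalized q over the training background (sums to 1);
"logistic" is the entropy-calibrated suitability index
L(x) = e^H raw(x) / (1 + e^H raw(x)), H the entropy of q.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "FeatureDef",
    "FeatureExpansion",
    "MaxentModel",
    "ConvergenceError",
    "auto_feature_classes",
    "build_expansion",
    "fit",
    "predict_raw",
    "predict_logistic",
    "training_gain",
]

FeatureClass = Literal["linear", "quadratic", "product", "threshold", "hinge", "categorical"]


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the final gradient norm."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm


def auto_feature_classes(n_presence: int) -> tuple[str, ...]:
    """Feature classes activated by presence sample size, mirroring the
    conventional defaults: <10 linear; <15 +quadratic; <80 +hinge; else all."""
    if n_presence < 10:
        return ("linear",)
    if n_presence < 15:
        return ("linear", "quadratic")
    if n_presence < 80:
        return ("linear", "quadratic", "hinge")
    return ("linear", "quadratic", "product", "threshold", "hinge")


@dataclass(frozen=True)
class FeatureDef:
    """One derived feature: a pure transform of a single input variable
    (or a pair, for products)."""

    kind: str  # linear|quadratic|product|threshold|hinge_fwd|hinge_rev|indicator
    var: str
    var2: str | None = None  # product partner
    knot: float = math.nan  # threshold/hinge knot (original units)
    code: float = math.nan  # categorical code

    def describe(self) -> str:
        if self.kind == "product":
            return f"product({self.var}*{self.var2})"
        if self.kind in ("threshold",):
            return f"threshold({self.var}>{self.knot:g})"
        if self.kind == "hinge_fwd":
            return f"hinge({self.var}>={self.knot:g})"
        if self.kind == "hinge_rev":
            return f"hinge({self.var}<={self.knot:g})"
        if self.kind == "indicator":
            return f"indicator({self.var}=={self.code:g})"
        return f"{self.kind}({self.var})"


@dataclass
class FeatureExpansion:
    """Deterministic feature map built from the background sample.

    Continuous variables are min-max scaled using their *background* bounds
    (stored per variable); the expansion is a pure function of the stack
    variables, the background table and the class configuration.
    """

    features: list[FeatureDef]
    bounds: dict[str, tuple[float, float]]  # per continuous variable
    kinds: dict[str, str]  # variable -> continuous|categorical
    classes: tuple[str, ...]
    feature_std: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for v in (f.var, f.var2):
                if v and v not in seen:
                    seen.append(v)
        return seen

    def _scaled(self, table: pd.DataFrame, var: str) -> np.ndarray:
        lo, hi = self.bounds[var]
        return (table[var].to_numpy(dtype=float) - lo) / (hi - lo)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Design matrix (n_rows x n_features) for a feature table."""
        n = len(table)
        X = np.empty((n, self.n_features))
        cache: dict[str, np.ndarray] = {}

        def scaled(var: str) -> np.ndarray:
            if var not in cache:
                cache[var] = self._scaled(table, var)
            return cache[var]

        unseen_codes: set[tuple[str, float]] = set()
        for j, f in enumerate(self.features):
            if f.kind == "linear":
                X[:, j] = scaled(f.var)
            elif f.kind == "quadratic":
                X[:, j] = scaled(f.var) ** 2
            elif f.kind == "product":
                X[:, j] = scaled(f.var) * scaled(f.var2)
            elif f.kind == "threshold":
                X[:, j] = (table[f.var].to_numpy(dtype=float) > f.knot).astype(float)
            elif f.kind == "hinge_fwd":
                lo, hi = self.bounds[f.var]
                x = table[f.var].to_numpy(dtype=float)
                X[:, j] = np.clip((x - f.knot) / (hi - f.knot), 0.0, 1.0)
            elif f.kind == "hinge_rev":
                lo, hi = self.bounds[f.var]
                x = table[f.var].to_numpy(dtype=float)
                X[:, j] = np.clip((f.knot - x) / (f.knot - lo), 0.0, 1.0)
            elif f.kind == "indicator":
                x = table[f.var].to_numpy(dtype=float)
                X[:, j] = (x == f.code).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {f.kind!r}")
        # warn once per table about unseen categorical codes
        for var, kind in self.kinds.items():
            if kind == "categorical" and var in table.columns:
                codes = {f.code for f in self.features if f.kind == "indicator" and f.var == var}
                present = set(np.unique(table[var].to_numpy(dtype=float)))
                extra = present - codes
                if extra:
                    warnings.warn(
                        f"variable {var!r}: codes {sorted(extra)} unseen in the "
                        "background; they contribute 0 to all indicators",
                        stacklevel=2,
                    )
        return X


def build_expansion(
    background: pd.DataFrame,
    kinds: dict[str, str],
    classes: Sequence[str] | None = None,
    n_presence: int | None = None,
    hinge_knots: int = 50,
    threshold_knots: int = 50,
) -> FeatureExpansion:
    """Build the feature expansion from the background feature table.

    ``classes`` defaults to the sample-size auto rule when ``n_presence``
    is given, else to linear+quadratic+hinge.  Hinge/threshold knots sit at
    background quantiles.  Constant variables contribute no features (with
    a warning).
    """
    if background.empty:
        raise ValueError("background table is empty")
    if classes is None:
        classes = (
            auto_feature_classes(n_presence)
            if n_presence is not None
            else ("linear", "quadratic", "hinge")
        )
    classes = tuple(classes)
    feats: list[FeatureDef] = []
    bounds: dict[str, tuple[float, float]] = {}
    cont_vars: list[str] = []
    for var in background.columns:
        kind = kinds.get(var, "continuous")
        x = background[var].to_numpy(dtype=float)
        if kind == "categorical":
            for code in np.unique(x[np.isfinite(x)]):
                feats.append(FeatureDef("indicator", var, code=float(code)))
            continue
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
        if lo == hi:
            warnings.warn(
                f"variable {var!r} is constant over the background; dropped",
                stacklevel=2,
            )
            continue
        bounds[var] = (lo, hi)
        cont_vars.append(var)
        if "linear" in classes:
            feats.append(FeatureDef("linear", var))
        if "quadratic" in classes:
            feats.append(FeatureDef("quadratic", var))
        if "threshold" in classes:
            qs = np.quantile(x, np.linspace(0, 1, threshold_knots + 2)[1:-1])
            for k in np.unique(qs):
                if lo < k < hi:
                    feats.append(FeatureDef("threshold", var, knot=float(k)))
        if "hinge" in classes:
            qs = np.quantile(x, np.linspace(0, 1, hinge_knots + 2)[1:-1])
            for k in np.unique(qs):
                if lo < k < hi:
                    feats.append(FeatureDef("hinge_fwd", var, knot=float(k)))
                    feats.append(FeatureDef("hinge_rev", var, knot=float(k)))
    if "product" in classes:
        for i, v1 in enumerate(cont_vars):
            for v2 in cont_vars[i + 1 :]:
                feats.append(FeatureDef("product", v1, var2=v2))
    exp = FeatureExpansion(features=feats, bounds=bounds, kinds=dict(kinds), classes=classes)
    Xb = exp.transform(background)
    exp.feature_std = Xb.std(axis=0, ddof=0)
    return exp


@dataclass
class MaxentModel:
    """Fitted maxent model: weights, normalizer and entropy over the
    training background."""

    expansion: FeatureExpansion
    lambdas: np.ndarray
    log_partition: float  # ln Z = ln Σ_background e^{λ·f}
    entropy_H: float
    beta: np.ndarray  # per-feature L1 penalty actually used
    n_background: int
    converged: bool = True
    n_iter: int = 0

    # --- serialization -----------------------------------------------------
    def to_lambdas_file(self, path: str | Path) -> None:
        lines = [
            f"# pikasdm maxent lambdas v1",
            f"# n_background, {self.n_background}",
            f"# log_partition, {self.log_partition!r}",
            f"# entropy_H, {self.entropy_H!r}",
        ]
        for f, lam in zip(self.expansion.features, self.lambdas):
            lo, hi = self.expansion.bounds.get(f.var, (0.0, 1.0))
            lines.append(f"{f.describe()}, {lam!r}, {lo!r}, {hi!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def _objective_parts(
    lam: np.ndarray, Xp: np.ndarray, Xb: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """(smooth objective J0, gradient of J0, background log-weights)."""
    eta_b = Xb @ lam
    lse = logsumexp(eta_b)
    q = np.exp(eta_b - lse)
    mean_pres = Xp.mean(axis=0)
    j0 = float(mean_pres @ lam - lse)
    grad = mean_pres - q @ Xb
    return j0, grad, eta_b


def fit(
    presence: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    expansion: FeatureExpansion,
    beta: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> MaxentModel:
    """Maximize the L1-penalized presence log-likelihood over background.

    Deterministic accelerated proximal-gradient (FISTA with restart and
    backtracking line search) from λ = 0; ``beta`` is the global
    regularization multiplier, translated per feature as
    β_j = beta * s_j / sqrt(m) with s_j the background std of feature j.
    The problem is convex; ``seed`` is accepted for interface symmetry but
    the solver has no stochastic component.
    """
    Xp = presence if isinstance(presence, np.ndarray) else expansion.transform(presence)
    Xb = background if isinstance(background, np.ndarray) else expansion.transform(background)
    m = Xp.shape[0]
    if m < 2:
        raise ValueError("need at least 2 presence rows")
    if Xb.shape[0] < m:
        raise ValueError("background must be at least as large as presence")
    p = expansion.n_features
    std = expansion.feature_std if expansion.feature_std.size == p else Xb.std(axis=0, ddof=0)
    beta_j = beta * std / math.sqrt(m)

    lam = np.zeros(p)
    z = lam.copy()
    t_mom = 1.0
    step = 1.0
    f0, _, _ = _objective_parts(lam, Xp, Xb)
    obj_prev = f0  # J(0): no penalty at λ = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_z, grad_z, _ = _objective_parts(z, Xp, Xb)
        # backtracking on the smooth majorizer (ascent form: we maximize)
        while True:
            cand = z + step * grad_z
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * beta_j, 0.0)
            f_cand, _, _ = _objective_parts(cand, Xp, Xb)
            diff = cand - z
            if f_cand >= f_z + grad_z @ diff - (diff @ diff) / (2 * step) - 1e-12:
                break
            if step < 1e-14:
                break
            step *= 0.5
        obj_cand = f_cand - float(beta_j @ np.abs(cand))
        # gradient-scheme adaptive restart (momentum pointing the wrong way)
        if (z - cand) @ (cand - lam) > 0:
            t_mom = 1.0
        t_next = (1.0 + math.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        z = cand + ((t_mom - 1.0) / t_next) * (cand - lam)
        if abs(obj_cand - obj_prev) < tol and np.max(np.abs(cand - lam)) < math.sqrt(tol):
            lam = cand
            converged = True
            break
        lam = cand
        t_mom = t_next
        obj_prev = obj_cand
        step *= 1.1  # let the step grow back between backtracks
    f_lam, grad, eta_b = _objective_parts(lam, Xp, Xb)
    if not converged:
        gnorm = float(np.linalg.norm(grad))
        raise ConvergenceError(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(final gradient norm {gnorm:.3e})",
            gnorm,
        )
    lse = logsumexp(eta_b)
    logq = eta_b - lse
    entropy = float(-np.exp(logq) @ logq)
    return MaxentModel(
        expansion=expansion,
        lambdas=lam,
        log_partition=float(lse),
        entropy_H=entropy,
        beta=beta_j,
        n_background=Xb.shape[0],
        converged=converged,
        n_iter=it,
    )


def _log_raw(model: MaxentModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = features if isinstance(features, np.ndarray) else model.expansion.transform(features)
    return X @ model.lambdas - model.log_partition


def predict_raw(model: MaxentModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Raw output e^{λ·f(x) − ln Z}; sums to 1 over the training background."""
    return np.exp(_log_raw(model, features))


def predict_logistic(model: MaxentModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Entropy-calibrated logistic output in (0, 1):
    L(x) = σ(H + ln raw(x)), i.e. e^H raw / (1 + e^H raw)."""
    logit = model.entropy_H + _log_raw(model, features)
    return 1.0 / (1.0 + np.exp(-logit))


def training_gain(model: MaxentModel, presence: pd.DataFrame | np.ndarray) -> float:
    """Regularized training gain in nats relative to the uniform background
    distribution: (1/m) Σ ln raw(x_i) + ln N − Σ_j β_j |λ_j|.

    Zero for the uniform (all-λ-zero) model by construction.
    """
    log_raw = _log_raw(model, presence)
    return float(
        log_raw.mean()
        + math.log(model.n_background)
        - model.beta @ np.abs(model.lambdas)
    )
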