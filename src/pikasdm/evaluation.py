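"""Model validation and variable-importance machinery.

Replicated subsample validation (train/test splits of the presences),
threshold-independent AUC and threshold-dependent TSS with max-TSS
threshold selection, jackknife variable importance by training gain,
permutation-based percent contribution, correlation-based variable
selection, and the exact paired Wilcoxon signed-rank test used to compare
model scenarios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm, rankdata

from . import maxent_core as mx
from .raster_core import Layer, LayerStack

__all__ = [
    "ModelSettings",
    "SplitPlan",
    "EvalReport",
    "JackknifeReport",
    "auc",
    "tss_curve",
    "optimal_threshold",
    "make_split_plans",
    "run_replicates",
    "jackknife",
    "contribution",
    "select_variables",
    "wilcoxon_signed_rank",
    "grade",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass(frozen=True)
class ModelSettings:
    """Tunable fitting/evaluation settings shared across replicates.

    Defaults mirror the study protocol: 50/50 subsample splits, decile
    threshold grid, automatic feature classes by sample size, global
    regularization multiplier 1.
    """

    beta: float = 1.0
    split_fraction: float = 0.5
    feature_classes: tuple[str, ...] | None = None  # None -> auto rule
    hinge_knots: int = 50
    threshold_knots: int = 50
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_pseudo_absence: int = 10_000
    tol: float = 1e-6
    max_iter: int = 5000
    # Fold the training presences into the fitting background (the
    # conventional maxent default).  Keeps the likelihood bounded when
    # presences fall outside the background sample's environmental hull,
    # e.g. outside the bias-correction zone.
    add_samples_to_background: bool = True


@dataclass(frozen=True)
class SplitPlan:
    replicate_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


@dataclass
class EvalReport:
    """Per-replicate validation metrics plus the replicate-mean map."""

    replicates: pd.DataFrame  # replicate, train_auc, test_auc, max_tss, opt_threshold
    thresholds: np.ndarray
    tss_mean_curve: np.ndarray  # mean TSS per threshold across replicates
    mean_map: Layer | None = None
    seed: int = 0
    settings: ModelSettings = field(default_factory=ModelSettings)

    def summary(self) -> pd.DataFrame:
        cols = ["train_auc", "test_auc", "max_tss", "opt_threshold"]
        return self.replicates[cols].agg(["mean", "std"])

    @property
    def mean_optimal_threshold(self) -> float:
        """Max-TSS threshold of the replicate-mean TSS curve."""
        t, _ = optimal_threshold(
            pd.DataFrame({"threshold": self.thresholds, "tss": self.tss_mean_curve})
        )
        return t


@dataclass
class JackknifeReport:
    """Per-variable with-only / without training gains plus contributions."""

    gains: pd.DataFrame  # variable, gain_with_only, gain_without
    gain_all_variables: float
    contributions: pd.Series | None = None  # percent, sums to 100

    def top_with_only(self) -> str:
        return str(self.gains.loc[self.gains["gain_with_only"].idxmax(), "variable"])


# ---------------------------------------------------------------------------
# Threshold-independent / threshold-dependent metrics
# ---------------------------------------------------------------------------


def auc(presence_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC: P(presence > background) + P(tie)/2."""
    a = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    r1 = ranks[: a.size].sum()
    u = r1 - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def tss_curve(
    presence_scores: Sequence[float],
    pseudoabsence_scores: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Confusion-matrix skill at each threshold (predicted present iff
    score >= t): sensitivity, specificity and TSS = sens + spec - 1."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(pseudoabsence_scores, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    if t.size == 0:
        raise ValueError("threshold grid is empty")
    tp = (p[None, :] >= t[:, None]).sum(axis=1)
    fn = p.size - tp
    fp = (a[None, :] >= t[:, None]).sum(axis=1)
    tn = a.size - fp
    sens = tp / np.maximum(tp + fn, 1)
    spec = tn / np.maximum(tn + fp, 1)
    return pd.DataFrame(
        {
            "threshold": t,
            "sensitivity": sens,
            "specificity": spec,
            "tss": sens + spec - 1.0,
        }
    )


def optimal_threshold(curve: pd.DataFrame) -> tuple[float, float]:
    """Arg-max of TSS over the curve; ties break toward the smaller
    threshold (favoring sensitivity)."""
    curve = curve.sort_values("threshold", kind="stable").reset_index(drop=True)
    i = int(np.argmax(curve["tss"].to_numpy()))  # first max = smallest threshold
    return float(curve.loc[i, "threshold"]), float(curve.loc[i, "tss"])


# ---------------------------------------------------------------------------
# Replicated subsample validation
# ---------------------------------------------------------------------------


def make_split_plans(
    n_presence: int, n_reps: int, seed: int, split_fraction: float = 0.5
) -> list[SplitPlan]:
    """Deterministic train/test splits of the presence set.

    Each replicate's permutation derives from (seed, replicate_id) only, so
    two scenario runs sharing a seed share split plans — a paired design.
    """
    n_train = int(n_presence * split_fraction)
    if n_train < 2 or n_presence - n_train < 1:
        raise ValueError("split leaves too few presences for train or test")
    plans = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(n_presence)
        plans.append(
            SplitPlan(
                replicate_id=rep,
                train_idx=np.sort(perm[:n_train]),
                test_idx=np.sort(perm[n_train:]),
                seed=seed,
            )
        )
    return plans


def run_replicates(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    kinds: dict[str, str],
    n_reps: int,
    seed: int,
    settings: ModelSettings = ModelSettings(),
    stack: LayerStack | None = None,
) -> EvalReport:
    """Repeated subsample validation of the maxent model.

    Per replicate: split presences, fit on the training half against the
    full background, score the held-out presences and a pseudo-absence set
    redrawn from the background, and record training/test AUC plus the
    max-TSS threshold.  When ``stack`` is given the replicate-mean logistic
    map over its valid cells is attached to the report.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    m = len(presence)
    plans = make_split_plans(m, n_reps, seed, settings.split_fraction)
    n_train = len(plans[0].train_idx)
    expansion = mx.build_expansion(
        background,
        kinds,
        classes=settings.feature_classes,
        n_presence=n_train,
        hinge_knots=settings.hinge_knots,
        threshold_knots=settings.threshold_knots,
    )
    Xp = expansion.transform(presence)
    Xb = expansion.transform(background)
    thresholds = np.asarray(settings.thresholds, dtype=float)

    X_map = None
    map_rows = map_cols = None
    if stack is not None:
        mask = stack.valid_mask()
        map_rows, map_cols = np.nonzero(mask)
        X_map = expansion.transform(stack.table_at_cells(map_rows, map_cols))

    rows = []
    tss_sum = np.zeros_like(thresholds)
    map_sum = np.zeros(len(map_rows)) if X_map is not None else None
    for plan in plans:
        Xb_fit = (
            np.vstack([Xb, Xp[plan.train_idx]])
            if settings.add_samples_to_background
            else Xb
        )
        try:
            model = mx.fit(
                Xp[plan.train_idx],
                Xb_fit,
                expansion,
                beta=settings.beta,
                tol=settings.tol,
                max_iter=settings.max_iter,
            )
        except mx.ConvergenceError as err:
            raise RuntimeError(
                f"replicate {plan.replicate_id}: {err}"
            ) from err
        s_bg = mx.predict_logistic(model, Xb)
        s_train = mx.predict_logistic(model, Xp[plan.train_idx])
        s_test = mx.predict_logistic(model, Xp[plan.test_idx])
        rng = np.random.default_rng([plan.seed, plan.replicate_id, 1])
        n_pa = min(settings.n_pseudo_absence, len(background))
        pa_idx = rng.choice(len(background), size=n_pa, replace=False)
        curve = tss_curve(s_test, s_bg[pa_idx], thresholds)
        t_opt, tss_max = optimal_threshold(curve)
        tss_sum += curve["tss"].to_numpy()
        rows.append(
            {
                "replicate": plan.replicate_id,
                "train_auc": auc(s_train, s_bg),
                "test_auc": auc(s_test, s_bg),
                "max_tss": tss_max,
                "opt_threshold": t_opt,
            }
        )
        if X_map is not None:
            map_sum += mx.predict_logistic(model, X_map)

    mean_map = None
    if X_map is not None and stack is not None:
        vals = np.full((stack.spec.n_rows, stack.spec.n_cols), np.nan)
        vals[map_rows, map_cols] = map_sum / n_reps
        mean_map = Layer("suitability", "continuous", vals)
    return EvalReport(
        replicates=pd.DataFrame(rows),
        thresholds=thresholds,
        tss_mean_curve=tss_sum / n_reps,
        mean_map=mean_map,
        seed=seed,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------


def _fit_gain(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    kinds: dict[str, str],
    variables: Sequence[str],
    settings: ModelSettings,
) -> tuple[mx.MaxentModel, float]:
    sub_p = presence[list(variables)]
    sub_b = background[list(variables)]
    expansion = mx.build_expansion(
        sub_b,
        {v: kinds.get(v, "continuous") for v in variables},
        classes=settings.feature_classes,
        n_presence=len(presence),
        hinge_knots=settings.hinge_knots,
        threshold_knots=settings.threshold_knots,
    )
    Xp = expansion.transform(sub_p)
    Xb = expansion.transform(sub_b)
    if settings.add_samples_to_background:
        Xb = np.vstack([Xb, Xp])
    model = mx.fit(
        Xp, Xb, expansion,
        beta=settings.beta, tol=settings.tol, max_iter=settings.max_iter,
    )
    return model, mx.training_gain(model, Xp)


def jackknife(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    kinds: dict[str, str],
    variables: Sequence[str] | None = None,
    settings: ModelSettings = ModelSettings(),
    include_without: bool = True,
) -> JackknifeReport:
    """Jackknife importance: training gain with each variable alone and
    (optionally) with each variable omitted, plus the all-variables gain."""
    variables = list(variables or presence.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    _, gain_all = _fit_gain(presence, background, kinds, variables, settings)
    rows = []
    for v in variables:
        try:
            _, g_only = _fit_gain(presence, background, kinds, [v], settings)
            g_without = math.nan
            if include_without:
                rest = [w for w in variables if w != v]
                _, g_without = _fit_gain(presence, background, kinds, rest, settings)
        except mx.ConvergenceError as err:
            raise RuntimeError(f"jackknife fit failed for variable {v!r}: {err}") from err
        rows.append(
            {"variable": v, "gain_with_only": g_only, "gain_without": g_without}
        )
    return JackknifeReport(gains=pd.DataFrame(rows), gain_all_variables=gain_all)


def contribution(
    model: mx.MaxentModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 10,
) -> pd.Series:
    """Percent contribution per variable by permutation importance.

    Each variable's values are permuted jointly across presence+background;
    the drop in training gain (mean over permutations, floored at 0) is
    normalized to sum to 100.
    """
    variables = model.expansion.variables
    lam = model.lambdas
    ln_n = math.log(model.n_background)
    pen = float(model.beta @ np.abs(lam))

    def gain_of(p_tab: pd.DataFrame, b_tab: pd.DataFrame) -> float:
        Xp = model.expansion.transform(p_tab)
        Xb = model.expansion.transform(b_tab)
        return float((Xp @ lam).mean() - logsumexp(Xb @ lam) + ln_n - pen)

    base = gain_of(presence, background)
    n_p = len(presence)
    drops = {}
    rng = np.random.default_rng(seed)
    for v in variables:
        combined = np.concatenate(
            [presence[v].to_numpy(dtype=float), background[v].to_numpy(dtype=float)]
        )
        acc = 0.0
        for _ in range(n_permutations):
            perm = rng.permutation(combined)
            p_tab = presence.copy()
            b_tab = background.copy()
            p_tab[v] = perm[:n_p]
            b_tab[v] = perm[n_p:]
            acc += base - gain_of(p_tab, b_tab)
        drops[v] = max(acc / n_permutations, 0.0)
    total = sum(drops.values())
    if total == 0:
        return pd.Series({v: 100.0 / len(variables) for v in drops})
    return pd.Series({v: 100.0 * d / total for v, d in drops.items()})


def select_variables(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    kinds: dict[str, str],
    jackknife_report: JackknifeReport,
    r_cut: float = 0.75,
    contribution_cut: float = 0.5,
    settings: ModelSettings = ModelSettings(),
    seed: int = 0,
) -> list[str]:
    """Correlation screening then contribution filtering.

    While any pair of continuous variables has |Pearson r| > ``r_cut`` over
    the background, the member with the lower with-only jackknife gain is
    removed (categorical variables are exempt — r is undefined for codes).
    Variables contributing less than ``contribution_cut`` percent to the
    refitted model are then dropped.
    """
    gains = dict(
        zip(jackknife_report.gains["variable"], jackknife_report.gains["gain_with_only"])
    )
    retained = [v for v in presence.columns if v in gains]
    cont = [v for v in retained if kinds.get(v, "continuous") == "continuous"]
    while len(cont) > 1:
        arr = background[cont].to_numpy(dtype=float)
        r = np.corrcoef(arr, rowvar=False)
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(r)), r.shape)
        if abs(r[i, j]) <= r_cut:
            break
        drop = cont[i] if gains[cont[i]] <= gains[cont[j]] else cont[j]
        cont.remove(drop)
        retained.remove(drop)
    if contribution_cut > 0 and len(retained) > 1:
        model, _ = _fit_gain(presence, background, kinds, retained, settings)
        contrib = contribution(model, presence[retained], background[retained], seed=seed)
        retained = [v for v in retained if contrib[v] >= contribution_cut]
    return retained


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact null counts of W+ (in doubled-rank units) over all 2^n sign
    vectors, by dynamic programming; counts[k] = #assignments with 2*W+ = k."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for dr in doubled_ranks:
        dr = int(dr)
        shifted = np.zeros_like(counts)
        shifted[dr:] = counts[: total + 1 - dr]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped before ranking; |differences| get midranks.
    For n <= 25 the p-value is exact (full enumeration of the null sign
    distribution, ties included); above that a normal approximation with
    tie-aware variance and continuity correction is used.  Returns
    (W = min(W+, W-), two-sided p, direction) where direction says which
    sample tends larger ("a", "b" or "none").
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0, "none"
    if n < 5:
        raise ValueError(
            f"only {n} nonzero differences; need >= 5 for the signed-rank test"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    direction = "a" if w_plus > w_minus else ("b" if w_minus > w_plus else "none")
    if n <= 25:
        doubled = np.round(2 * ranks).astype(np.int64)
        counts = _signed_rank_distribution(doubled)
        total_d = int(doubled.sum())
        wd = int(round(2 * w_plus))
        lo, hi = min(wd, total_d - wd), max(wd, total_d - wd)
        p = (counts[: lo + 1].sum() + counts[hi:].sum()) / counts.sum()
        p = float(min(p, 1.0))
    else:
        mu = ranks.sum() / 2.0
        sigma = math.sqrt(float((ranks**2).sum()) / 4.0)
        z = (abs(w_plus - mu) - 0.5) / sigma
        p = float(2.0 * norm.sf(max(z, 0.0)))
        p = min(p, 1.0)
    return w, p, direction


# ---------------------------------------------------------------------------
# Performance grades
# ---------------------------------------------------------------------------

_AUC_GRADES = [
    (0.5, "worse than random"),
    (0.6, "failed"),
    (0.7, "poor"),
    (0.8, "fair"),
    (0.9, "good"),
    (1.0, "excellent"),
]
_TSS_GRADES = [
    (0.0, "worse than random"),
    (0.2, "bad"),
    (0.4, "poor"),
    (0.6, "fair"),
    (0.8, "good"),
    (1.0, "excellent"),
]


def grade(value: float, scale: Literal["auc", "tss"]) -> str:
    """Categorical performance grade on left-open, right-closed intervals.

    AUC: worse than random (<=0.5), failed, poor, fair, good, excellent.
    TSS: worse than random (<=0), bad, poor, fair, good, excellent.
    """
    if scale == "auc":
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"AUC out of [0, 1]: {value}")
        table = _AUC_GRADES
    elif scale == "tss":
        if not -1.0 <= value <= 1.0:
            raise ValueError(f"TSS out of [-1, 1]: {value}")
        table = _TSS_GRADES
    else:
        raise ValueError(f"unknown scale {scale!r}")
    for bound, label in table:
        if value <= bound:
            return label
    return table[-1][1]  # pragma: no cover
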