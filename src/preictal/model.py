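"""Feature ranking, SOP/feature-count grid search, and the final classifier.

The training set of each patient selects two hyperparameters: the SOP
duration (continuous regime only; segmented data arrive with fixed labels)
and the number of features fed to the classifier. Candidates are scored by
the product ``SS_sample * SP_sample`` on held-out data, the trade-off
objective used to pick a model that neither ignores the rare preictal class
nor floods the interictal majority with false positives.

Cross-validation folds are seizure-wise in the continuous regime: each fold
holds out the timeline block around one training seizure (train on two
seizures, validate on one, for the default three training seizures). In the
segmented regime folds are seeded 70/30 file re-splits.

Features are ranked by the absolute two-sample Welch t statistic between
preictal and interictal training windows — a simple univariate
class-separability score, applied after z-scoring; ties break by column
index so the ordering is deterministic. The classifier is a weighted
logistic regression with no regularization beyond numerical jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .assembly import (
    ClassWeights,
    NormalizationParams,
    compute_class_weights,
    label_windows,
    zscore_apply,
    zscore_fit,
)
from .exceptions import DataError

DEFAULT_SOP_GRID = tuple(range(10, 56, 5))  # minutes
DEFAULT_K_GRID = (5, 10, 20, 40)
#: effectively-unregularized logistic fit: C is the numerical jitter only
_LOGISTIC_C = 1e6


def rank_features(X: np.ndarray, y: np.ndarray, weights: ClassWeights | None = None) -> np.ndarray:
    """Order features by decreasing |Welch t| between the two classes.

    Zero-variance features score minus infinity and land last; ties break by
    column index (stable sort). Input is expected already normalized, so the
    ranking is invariant to affine rescaling of any column.
    """
    y = np.asarray(y)
    g1, g0 = X[y == 1], X[y == 0]
    if g1.shape[0] == 0 or g0.shape[0] == 0:
        raise DataError("both classes must be present to rank features")
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    v1, v0 = g1.var(axis=0, ddof=1), g0.var(axis=0, ddof=1)
    se = np.sqrt(v1 / g1.shape[0] + v0 / g0.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m0) / se
    # constant columns have roundoff-level variance, not exactly zero
    degenerate = se <= 1e-12 * (np.abs(m1) + np.abs(m0) + 1.0)
    # ascending sort of the negated score; degenerate columns land last
    score = np.where(np.isfinite(t) & ~degenerate, -t, np.inf)
    return np.argsort(score, kind="stable")


@dataclass
class ModelSpec:
    """A trained patient-specific model and everything needed to apply it."""

    feature_indices: np.ndarray
    coef: np.ndarray
    intercept: float
    normalization: NormalizationParams
    class_weights: ClassWeights
    sop_min: float | None = None
    k: int = 0
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.feature_indices = np.asarray(self.feature_indices, dtype=int)
        self.coef = np.asarray(self.coef, dtype=float).ravel()
        self.k = len(self.feature_indices)

    def to_dict(self) -> dict:
        return {
            "sop_min": self.sop_min,
            "k": self.k,
            "feature_indices": self.feature_indices.tolist(),
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "normalization": {
                "mean": self.normalization.mean.tolist(),
                "std": self.normalization.std.tolist(),
            },
            "class_weights": {
                "interictal": self.class_weights.weight_interictal,
                "preictal": self.class_weights.weight_preictal,
            },
        }


def train_classifier(
    X_norm: np.ndarray,
    y: np.ndarray,
    feature_indices: np.ndarray,
    normalization: NormalizationParams,
    class_weights: ClassWeights | None = None,
    *,
    sop_min: float | None = None,
    feature_names: list[str] | None = None,
) -> ModelSpec:
    """Fit the weighted logistic regression on the selected feature columns.

    ``X_norm`` must already be z-scored with ``normalization``. Deterministic
    given the data.
    """
    y = np.asarray(y)
    weights = class_weights if class_weights is not None else compute_class_weights(y)
    clf = LogisticRegression(
        C=_LOGISTIC_C, solver="lbfgs", max_iter=2000, tol=1e-6, class_weight=weights.as_dict()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable data legitimately hits max_iter
        clf.fit(X_norm[:, feature_indices], y)
    names = None
    if feature_names is not None:
        names = [feature_names[i] for i in feature_indices]
    return ModelSpec(
        feature_indices=feature_indices,
        coef=clf.coef_,
        intercept=float(clf.intercept_[0]),
        normalization=normalization,
        class_weights=weights,
        sop_min=sop_min,
        feature_names=names,
    )


def predict(model: ModelSpec, X_norm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window probability and binary output at the 0.5 threshold.

    ``X_norm`` is the full normalized feature matrix; the model selects its
    own columns.
    """
    if X_norm.shape[1] <= int(model.feature_indices.max(initial=-1)):
        raise DataError(
            f"feature matrix has {X_norm.shape[1]} columns; model expects index "
            f"{int(model.feature_indices.max())}"
        )
    z = X_norm[:, model.feature_indices] @ model.coef + model.intercept
    proba = 1.0 / (1.0 + np.exp(-z))
    return proba, (proba >= 0.5).astype(int)


def _fold_objective(
    X_tr: np.ndarray, y_tr: np.ndarray, X_va: np.ndarray, y_va: np.ndarray, k_grid: tuple[int, ...]
) -> dict[int, float]:
    """SS*SP on the validation fold for every feature count in the grid."""
    norm = zscore_fit(X_tr)
    Xn_tr = zscore_apply(norm, X_tr)
    Xn_va = zscore_apply(norm, X_va)
    weights = compute_class_weights(y_tr)
    order = rank_features(Xn_tr, y_tr)
    out: dict[int, float] = {}
    for k in k_grid:
        idx = order[: min(k, Xn_tr.shape[1])]
        spec = train_classifier(Xn_tr, y_tr, idx, norm, weights)
        _, binary = predict(spec, Xn_va)
        tp = int(((y_va == 1) & (binary == 1)).sum())
        fn = int(((y_va == 1) & (binary == 0)).sum())
        tn = int(((y_va == 0) & (binary == 0)).sum())
        fp = int(((y_va == 0) & (binary == 1)).sum())
        ss = tp / (tp + fn)
        sp = tn / (tn + fp)
        out[k] = ss * sp
    return out


@dataclass
class CVResult:
    """Grid-search table: mean SS*SP objective per (sop, k) across folds."""

    table: pd.DataFrame  # columns: sop_min, k, objective, n_folds
    sop_star: float | None
    k_star: int


def cv_grid_search(
    X: np.ndarray,
    window_times: np.ndarray,
    onsets: np.ndarray,
    *,
    sop_grid: tuple[float, ...] = DEFAULT_SOP_GRID,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    sph_min: float = 10.0,
    offsets: np.ndarray | None = None,
    ictal_blackout: float = 120.0,
) -> CVResult:
    """Seizure-wise leave-one-out grid search over (SOP, feature count).

    For each SOP the training timeline is relabeled, windows are attributed
    to their nearest training seizure to form folds, and each fold trains on
    the other seizures' blocks and scores ``SS*SP`` on the held-out block.
    The argmax of the fold mean wins; ties prefer the smallest SOP, then the
    smallest k (the less complex model). Folds whose validation block lacks a
    class are skipped with a warning; a grid point with no usable fold scores
    NaN, and an all-NaN grid is an error.
    """
    times = np.asarray(window_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 3:
        raise DataError("seizure-wise LOOCV needs at least 3 training seizures")
    # fold assignment: window belongs to the block of the next seizure ending
    # at that seizure's blackout; trailing windows join the last block
    boundaries = onsets + ictal_blackout
    block = np.searchsorted(boundaries, times, side="right")
    block = np.minimum(block, onsets.size - 1)

    rows = []
    for sop in sop_grid:
        labels = label_windows(times, onsets, sop, sph_min, offsets=offsets, ictal_blackout=ictal_blackout)
        valid = labels >= 0
        per_fold: list[dict[int, float]] = []
        for held in range(onsets.size):
            va = valid & (block == held)
            tr = valid & (block != held)
            y_va, y_tr = labels[va], labels[tr]
            if (y_va == 1).sum() == 0 or (y_va == 0).sum() == 0:
                warnings.warn(f"fold {held} at sop={sop} lacks a class; skipped", stacklevel=2)
                continue
            if (y_tr == 1).sum() == 0 or (y_tr == 0).sum() == 0:
                warnings.warn(f"fold {held} at sop={sop} has single-class training; skipped", stacklevel=2)
                continue
            per_fold.append(_fold_objective(X[tr], y_tr, X[va], y_va, k_grid))
        for k in k_grid:
            vals = [f[k] for f in per_fold]
            rows.append(
                {
                    "sop_min": float(sop),
                    "k": int(k),
                    "objective": float(np.mean(vals)) if vals else np.nan,
                    "n_folds": len(vals),
                }
            )
    table = pd.DataFrame(rows)
    if table["objective"].isna().all():
        raise DataError("grid search failed: every fold was skipped at every grid point")

    best_obj, best = -np.inf, None
    for sop in sop_grid:  # ascending: first strict improvement wins ties
        for k in k_grid:
            row = table[(table.sop_min == float(sop)) & (table.k == int(k))]
            obj = float(row.objective.iloc[0])
            if np.isfinite(obj) and obj > best_obj:
                best_obj, best = obj, (float(sop), int(k))
    return CVResult(table=table, sop_star=best[0], k_star=best[1])


def cv_select_k(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    *,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    n_resplits: int = 3,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> CVResult:
    """Feature-count selection for the segmented regime (labels are fixed).

    Folds are seeded 70/30 re-splits of the training files: preictal seizure
    groups are assigned whole to the sub-train or validation side, interictal
    windows are split by their block group the same way.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    pre_groups = np.unique(groups[y == 1])
    int_groups = np.unique(groups[y == 0])
    if pre_groups.size < 2:
        raise DataError("need at least 2 preictal groups for validation re-splits")
    per_fold: list[dict[int, float]] = []
    for _ in range(n_resplits):
        pre_perm = rng.permutation(pre_groups)
        int_perm = rng.permutation(int_groups)
        n_pre_tr = min(max(int(round(train_fraction * pre_groups.size)), 1), pre_groups.size - 1)
        n_int_tr = min(max(int(round(train_fraction * int_groups.size)), 1), int_groups.size - 1)
        tr_pre, va_pre = set(pre_perm[:n_pre_tr]), set(pre_perm[n_pre_tr:])
        tr_int, va_int = set(int_perm[:n_int_tr]), set(int_perm[n_int_tr:])
        tr = np.array([(g in tr_pre) if lab == 1 else (g in tr_int) for g, lab in zip(groups, y)])
        va = np.array([(g in va_pre) if lab == 1 else (g in va_int) for g, lab in zip(groups, y)])
        if (y[va] == 1).sum() == 0 or (y[va] == 0).sum() == 0:
            warnings.warn("validation re-split lacks a class; skipped", stacklevel=2)
            continue
        per_fold.append(_fold_objective(X[tr], y[tr], X[va], y[va], k_grid))
    if not per_fold:
        raise DataError("all validation re-splits were skipped")
    rows = [
        {"sop_min": np.nan, "k": int(k), "objective": float(np.mean([f[k] for f in per_fold])),
         "n_folds": len(per_fold)}
        for k in k_grid
    ]
    table = pd.DataFrame(rows)
    best_obj, best_k = -np.inf, k_grid[0]
    for k in k_grid:
        obj = float(table[table.k == int(k)].objective.iloc[0])
        if obj > best_obj:
            best_obj, best_k = obj, int(k)
    return CVResult(table=table, sop_star=None, k_star=best_k)
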