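"""Feature reduction, normalization and nested-LOSO support vector regression.

The optimizer holds out each subject once (outer loop); for every grid cell
(kernel, kernel scale, box constraint) it runs a second leave-one-subject-out
loop over the remaining subjects, scores the cell by validation RMSE, refits
the arg-min cell on all training subjects and predicts the held-out one.
In the default leakage-safe mode the feature filter/reduction and all
normalization statistics are recomputed inside every training partition;
``paper_mode`` reproduces the simpler protocol in which the correlation
filter and scaling are computed once on the full cohort before the outer
loop.

Feature ranking uses the absolute Pearson correlation with the target
(features below the 0.4 floor are discarded); scaling is z-score followed by
min-max to [0, 1], with test values soft-clipped to [-0.5, 1.5] so ordering
is preserved.  Reported r/RMSE/MAE are computed over the pooled held-out
predictions on the [0, 1]-normalized target scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVR

from .feature_extraction import FEATURE_NAMES

__all__ = [
    "ReductionSpec",
    "SvrSpec",
    "RegressionResult",
    "default_grid",
    "correlation_filter",
    "pca_reduce",
    "normalize",
    "fit_predict_svr",
    "nested_loso_optimize",
    "metrics",
]

logger = logging.getLogger(__name__)

KERNELS = ("linear", "quadratic", "cubic", "gaussian")


@dataclass(frozen=True)
class ReductionSpec:
    method: str = "correlation_rank"  # or "pca"
    n: int = 15
    r_floor: float = 0.4

    def __post_init__(self) -> None:
        if self.method not in ("correlation_rank", "pca"):
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.r_floor <= 1.0:
            raise ValueError("r_floor must lie in [0, 1]")


@dataclass(frozen=True)
class SvrSpec:
    kernel: str = "linear"
    kernel_scale: float = 1.0
    box_constraint: float = 1.0
    epsilon: float | None = None  # None -> 0.1 * sd of the training target

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if not 0.001 <= self.kernel_scale <= 1000.0:
            raise ValueError("kernel_scale outside the [0.001, 1000] grid bounds")
        if not 0.001 <= self.box_constraint <= 1000.0:
            raise ValueError("box_constraint outside the [0.001, 1000] grid bounds")


@dataclass
class RegressionResult:
    subjects: list[str]
    y_true: np.ndarray  # raw target scale
    y_pred: np.ndarray  # raw target scale
    chosen_specs: list[SvrSpec]
    r: float
    rmse: float
    mae: float
    n_outer_folds: int
    n_inner_fits: int
    target_range: tuple[float, float]  # min/max used for the normalized metrics
    inner_rmse: list[float] = field(default_factory=list)  # winning cell, per fold


def default_grid(
    kernels: tuple[str, ...] = KERNELS,
    log_values: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
) -> list[SvrSpec]:
    """Grid over the [0.001, 1000] ranges; kernel scale only varies for gaussian.

    Ordered for the deterministic tie-break: kernels as listed, then box
    constraint ascending, then kernel scale ascending.
    """
    grid: list[SvrSpec] = []
    for kernel in kernels:
        for box in log_values:
            if kernel == "gaussian":
                for scale in log_values:
                    grid.append(SvrSpec(kernel, scale, box))
            else:
                grid.append(SvrSpec(kernel, 1.0, box))
    return grid


def correlation_filter(
    features: np.ndarray,
    target: np.ndarray,
    r_floor: float = 0.4,
    names: list[str] | None = None,
) -> tuple[list[int], np.ndarray]:
    """Rank features by |Pearson r| with the target, dropping those below the floor.

    Returns ``(kept_indices, r_values)`` with ``kept_indices`` sorted by
    descending |r| (ties broken by canonical column order) and ``r_values``
    the signed correlation of every column.  Zero-variance features get r=0.
    """
    features = np.asarray(features, dtype=float)
    target = np.asarray(target, dtype=float)
    if features.shape[0] < 3:
        raise ValueError("need at least 3 rows to compute correlations")
    if target.std() == 0:
        raise ValueError("target has zero variance")
    yc = target - target.mean()
    xc = features - features.mean(axis=0)
    sx = xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).mean(axis=0) / (sx * yc.std())
    r = np.where(sx == 0, 0.0, r)
    order = np.lexsort((np.arange(len(r)), -np.abs(r)))  # |r| desc, then column order
    kept = [int(i) for i in order if abs(r[i]) >= r_floor]
    return kept, r


def pca_reduce(
    train: np.ndarray, test: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project train/test onto the first ``n`` components fitted on train only."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    max_n = min(train.shape[0] - 1, train.shape[1])
    if n > max_n:
        raise ValueError(f"n={n} exceeds the {max_n} components supported by the data")
    pca = PCA(n_components=n, svd_solver="full")
    train_red = pca.fit_transform(train)
    test_red = pca.transform(test)
    return train_red, test_red, pca.explained_variance_ratio_


@dataclass
class TargetScaler:
    """Invertible min-max map of the target onto [0, 1] (train statistics)."""

    lo: float
    hi: float

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * (self.hi - self.lo) + self.lo


def normalize(
    train: np.ndarray, test: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, TargetScaler]:
    """Z-score then min-max features to [0, 1]; min-max the target.

    All statistics come from the training rows.  Test values falling outside
    [0, 1] are clipped to [-0.5, 1.5] (soft clip: ordering preserved).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    target = np.asarray(target, dtype=float)
    mu, sd = train.mean(axis=0), train.std(axis=0)
    usable = sd > 0
    if not usable.all():
        logger.warning("%d zero-variance features excluded from scaling", int((~usable).sum()))
    train_z = (train[:, usable] - mu[usable]) / sd[usable]
    test_z = (test[:, usable] - mu[usable]) / sd[usable]
    lo, hi = train_z.min(axis=0), train_z.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    train_s = (train_z - lo) / span
    test_s = np.clip((test_z - lo) / span, -0.5, 1.5)
    if target.max() == target.min():
        raise ValueError("target has zero range")
    scaler = TargetScaler(float(target.min()), float(target.max()))
    return train_s, test_s, scaler.transform(target), scaler


def _make_svr(spec: SvrSpec, y_train: np.ndarray) -> SVR:
    eps = spec.epsilon if spec.epsilon is not None else 0.1 * float(np.std(y_train))
    eps = max(eps, 1e-6)
    common = dict(C=spec.box_constraint, epsilon=eps, max_iter=500_000)
    if spec.kernel == "linear":
        return SVR(kernel="linear", **common)
    if spec.kernel == "quadratic":
        return SVR(kernel="poly", degree=2, gamma=1.0, coef0=1.0, **common)
    if spec.kernel == "cubic":
        return SVR(kernel="poly", degree=3, gamma=1.0, coef0=1.0, **common)
    # gaussian: kernel_scale is the width, K(x,z) = exp(-||x-z||^2 / scale^2)
    return SVR(kernel="rbf", gamma=1.0 / spec.kernel_scale**2, **common)


def fit_predict_svr(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, spec: SvrSpec
) -> np.ndarray:
    """Epsilon-insensitive SVR fit on the (already normalized) training data."""
    if len(x_train) == 0:
        raise ValueError("empty training set")
    model = _make_svr(spec, np.asarray(y_train, dtype=float))
    model.fit(np.asarray(x_train, dtype=float), np.asarray(y_train, dtype=float))
    if getattr(model, "fit_status_", 0) != 0:
        raise RuntimeError(f"SVR solver failed to converge for {spec}")
    return model.predict(np.asarray(x_test, dtype=float))


def _prepare_fold(
    train_f: np.ndarray,
    train_y: np.ndarray,
    test_f: np.ndarray,
    reduction: ReductionSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, TargetScaler]:
    """Reduce + normalize one training partition (no test-row statistics)."""
    kept, _ = correlation_filter(train_f, train_y, reduction.r_floor)
    if not kept:
        # degenerate cohort: fall back to the plain |r| ranking
        kept, _ = correlation_filter(train_f, train_y, 0.0)
        logger.warning("no feature passed the %.2f floor; using unfloored ranking", reduction.r_floor)
    if reduction.method == "correlation_rank":
        cols = kept[: reduction.n]
        tr, te = train_f[:, cols], test_f[:, cols]
        tr_s, te_s, y_s, scaler = normalize(tr, te, train_y)
    else:
        cols = kept
        tr_s0, te_s0, y_s, scaler = normalize(train_f[:, cols], test_f[:, cols], train_y)
        n = min(reduction.n, tr_s0.shape[0] - 1, tr_s0.shape[1])
        tr_s, te_s, _ = pca_reduce(tr_s0, te_s0, n)
    return tr_s, te_s, y_s, scaler


def nested_loso_optimize(
    features: np.ndarray,
    target: np.ndarray,
    subjects: list[str],
    reduction: ReductionSpec,
    grid: list[SvrSpec] | None = None,
    paper_mode: bool = False,
) -> RegressionResult:
    """Nested leave-one-subject-out hyperparameter search and evaluation.

    ``features`` is the (n_subjects, n_features) matrix with one row per
    subject(-condition); ``subjects`` the matching row labels.  Returns the
    pooled held-out predictions and r/RMSE/MAE on the [0, 1] scale of the
    full target vector.
    """
    features = np.asarray(features, dtype=float)
    target = np.asarray(target, dtype=float)
    n = features.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects for nested LOSO")
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")

    if paper_mode:
        # global pre-selection: filter/reduce/scale once on the full cohort
        kept, _ = correlation_filter(features, target, reduction.r_floor)
        if not kept:
            kept, _ = correlation_filter(features, target, 0.0)
        if reduction.method == "correlation_rank":
            cols = kept[: reduction.n]
            global_f, _, global_y, global_scaler = normalize(
                features[:, cols], features[:, cols], target
            )
        else:
            f_s, _, global_y, global_scaler = normalize(
                features[:, kept], features[:, kept], target
            )
            m = min(reduction.n, f_s.shape[0] - 1, f_s.shape[1])
            global_f, _, _ = pca_reduce(f_s, f_s, m)

    y_pred = np.empty(n)
    chosen: list[SvrSpec] = []
    winning_rmse: list[float] = []
    n_inner_fits = 0

    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        # inner LOSO: one residual per (inner fold, grid cell)
        cell_sq_err = np.zeros(len(grid))
        cell_failed = np.zeros(len(grid), dtype=bool)
        for j_pos, j in enumerate(train_idx):
            inner_idx = np.delete(train_idx, j_pos)
            if paper_mode:
                tr, te = global_f[inner_idx], global_f[[j]]
                y_tr, y_true_j = global_y[inner_idx], global_y[j]
                inv = global_scaler
            else:
                tr, te, y_tr, inv = _prepare_fold(
                    features[inner_idx], target[inner_idx], features[[j]], reduction
                )
                y_true_j = None  # compare on the raw scale below
            for c, spec in enumerate(grid):
                if cell_failed[c]:
                    continue
                try:
                    pred = fit_predict_svr(tr, y_tr, te, spec)[0]
                    n_inner_fits += 1
                except RuntimeError as exc:
                    logger.warning("grid cell skipped: %s", exc)
                    cell_failed[c] = True
                    continue
                if paper_mode:
                    err = pred - y_true_j
                else:
                    err = inv.inverse(np.array([pred]))[0] - target[j]
                cell_sq_err[c] += err * err
        if cell_failed.all():
            raise RuntimeError("every grid cell failed in the inner validation")
        cell_rmse = np.sqrt(cell_sq_err / len(train_idx))
        cell_rmse[cell_failed] = np.inf
        best_c = int(np.argmin(cell_rmse))  # first minimum: grid order is the tie-break
        chosen.append(grid[best_c])
        winning_rmse.append(float(cell_rmse[best_c]))

        # refit the winning cell on all N-1 training subjects
        if paper_mode:
            pred = fit_predict_svr(
                global_f[train_idx], global_y[train_idx], global_f[[i]], grid[best_c]
            )[0]
            y_pred[i] = global_scaler.inverse(np.array([pred]))[0]
        else:
            tr, te, y_tr, inv = _prepare_fold(
                features[train_idx], target[train_idx], features[[i]], reduction
            )
            pred = fit_predict_svr(tr, y_tr, te, grid[best_c])[0]
            y_pred[i] = inv.inverse(np.array([pred]))[0]

    lo, hi = float(target.min()), float(target.max())
    span = hi - lo if hi > lo else 1.0
    r, rmse, mae = metrics((target - lo) / span, (y_pred - lo) / span)
    return RegressionResult(
        subjects=list(subjects),
        y_true=target,
        y_pred=y_pred,
        chosen_specs=chosen,
        r=r,
        rmse=rmse,
        mae=mae,
        n_outer_folds=n,
        n_inner_fits=n_inner_fits,
        target_range=(lo, hi),
        inner_rmse=winning_rmse,
    )


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """Pearson r, RMSE and MAE of predictions against the target."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    if y_true.std() == 0 or y_pred.std() == 0:
        logger.warning("zero variance in metrics input; reporting r = 0")
        r = 0.0
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    mae = float(np.mean(np.abs(y_pred - y_true)))
    return r, rmse, mae
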