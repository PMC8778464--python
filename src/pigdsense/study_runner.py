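"""Study orchestration: per-group models, transfer tests, group statistics.

Ties the whole pipeline together on any cohort (synthetic or recorded):
simulate/load recordings, estimate orientation, segment strides, extract and
aggregate features, then sweep the regression over feature-set sizes and
reduction methods per subject group, evaluate cross-group transfer, and run
the usual nonparametric group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_extraction import (
    FEATURE_NAMES,
    aggregate_subject,
    extract_all,
    features_table,
)
from .gait_segmentation import segment_recording
from .orientation_estimation import kalman_orientation
from .pigd_regression import (
    RegressionResult,
    ReductionSpec,
    SvrSpec,
    _prepare_fold,
    default_grid,
    fit_predict_svr,
    metrics,
    nested_loso_optimize,
)
from .tug_simulator import SimulationConfig, simulate_cohort

__all__ = [
    "StudyPlan",
    "cohort_feature_table",
    "run_group",
    "transfer_evaluate",
    "compare_groups",
    "feature_target_correlations",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyPlan:
    """Which groups to model, with which reduction settings, and what to transfer."""

    groups: list[tuple[str | None, str | None]] = field(
        default_factory=lambda: [(None, None)]
    )  # (condition filter, fog filter); None = no filter
    sizes: tuple[int, ...] = (5, 10, 15, 20, 25)
    methods: tuple[str, ...] = ("correlation_rank", "pca")
    transfer_pairs: list[tuple[int, int]] = field(default_factory=list)  # group indices

    def reductions(self) -> list[ReductionSpec]:
        return [ReductionSpec(method=m, n=n) for n in self.sizes for m in self.methods]


def cohort_feature_table(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a cohort and push every recording through the full pipeline.

    Returns one row per subject-condition with metadata columns followed by
    the 102 aggregated features.
    """
    recordings, table = simulate_cohort(config)
    rows = []
    for rec, truth in recordings:
        trace = kalman_orientation(rec)
        bouts, strides = segment_recording(trace)
        if not strides:
            logger.warning("%s/%s: no strides detected, subject dropped", rec.subject_id, rec.condition)
            continue
        vectors = extract_all(strides)
        meta = table[
            (table.subject_id == rec.subject_id) & (table.condition == rec.condition)
        ].iloc[0]
        rows.append(
            aggregate_subject(
                vectors,
                subject_id=rec.subject_id,
                condition=rec.condition,
                fog_status=str(meta.fog_status),
                pigd=float(meta.pigd),
            )
        )
    return features_table(rows)


def select_group(
    table: pd.DataFrame, condition: str | None = None, fog: str | None = None
) -> pd.DataFrame:
    out = table
    if condition is not None:
        out = out[out.condition == condition]
    if fog is not None:
        out = out[out.fog_status == fog]
    return out.reset_index(drop=True)


def run_group(
    table: pd.DataFrame,
    plan: StudyPlan | None = None,
    grid: list[SvrSpec] | None = None,
    paper_mode: bool = False,
) -> pd.DataFrame:
    """Sweep the nested-LOSO regression over all (size, method) settings.

    Returns one row per setting with the chosen modal kernel and the pooled
    metrics; the best row (max r, ties by min RMSE then smaller n) is
    flagged in the ``best`` column.
    """
    if plan is None:
        plan = StudyPlan()
    if len(table) < 4:
        raise ValueError(f"group has {len(table)} subjects; need >= 4")
    feats = table[FEATURE_NAMES].to_numpy(dtype=float)
    target = table["pigd"].to_numpy(dtype=float)
    subjects = (table["subject_id"] + "/" + table["condition"]).tolist()
    records = []
    for spec in plan.reductions():
        result = nested_loso_optimize(feats, target, subjects, spec, grid, paper_mode)
        kernels = [s.kernel for s in result.chosen_specs]
        modal_kernel = max(set(kernels), key=kernels.count)
        records.append(
            {
                "n_features": spec.n,
                "method": spec.method,
                "kernel": modal_kernel,
                "kernel_share": kernels.count(modal_kernel) / len(kernels),
                "r": result.r,
                "rmse": result.rmse,
                "mae": result.mae,
            }
        )
    out = pd.DataFrame(records)
    best = out.sort_values(["r", "rmse", "n_features"], ascending=[False, True, True]).index[0]
    out["best"] = False
    out.loc[best, "best"] = True
    return out


def transfer_evaluate(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    reduction: ReductionSpec,
    spec: SvrSpec,
) -> tuple[float, float, float]:
    """Fit once on the full training group, evaluate on a disjoint test group.

    Metrics are computed on the training group's [0, 1] target scale, so a
    shifted test population can legitimately produce RMSE > 1.
    """
    overlap = set(train_table.subject_id) & set(test_table.subject_id)
    if overlap:
        raise ValueError(f"train and test groups share subjects: {sorted(overlap)}")
    train_f = train_table[FEATURE_NAMES].to_numpy(dtype=float)
    test_f = test_table[FEATURE_NAMES].to_numpy(dtype=float)
    train_y = train_table["pigd"].to_numpy(dtype=float)
    test_y = test_table["pigd"].to_numpy(dtype=float)
    tr, te, y_tr, scaler = _prepare_fold(train_f, train_y, test_f, reduction)
    pred = fit_predict_svr(tr, y_tr, te, spec)
    return metrics(scaler.transform(test_y), pred)


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Wilcoxon signed-rank (paired) or Mann-Whitney U (unpaired), two-sided.

    Exact p-values for n <= 25, normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison needs equal-length samples")
        diffs = a - b
        if np.all(diffs == 0):
            logger.warning("all paired differences are zero; p = 1")
            return 0.0, 1.0
        method = "exact" if len(a) <= 25 else "approx"
        res = stats.wilcoxon(a, b, method=method)
    else:
        method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def feature_target_correlations(table: pd.DataFrame, target_col: str = "pigd") -> pd.DataFrame:
    """Pearson r and two-sided p per feature, sorted by |r| descending.

    Adds a Benjamini-Hochberg adjusted column for reference (raw p-values
    remain the reported quantity).
    """
    if len(table) < 4:
        raise ValueError("need at least 4 rows")
    target = table[target_col].to_numpy(dtype=float)
    records = []
    for name in FEATURE_NAMES:
        x = table[name].to_numpy(dtype=float)
        if x.std() == 0 or target.std() == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(x, target)
        component = name.rsplit("_", 1)[1] if "_" in name else ""
        records.append({"feature": name, "component": component, "r": float(r), "p": float(p)})
    out = pd.DataFrame(records)
    out = out.reindex(out.r.abs().sort_values(ascending=False).index).reset_index(drop=True)
    # Benjamini-Hochberg step-up
    m = len(out)
    order = out.p.to_numpy().argsort()
    adj = np.empty(m)
    prev = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        k = m - rank_from_last
        prev = min(prev, out.p.iloc[idx] * m / k)
        adj[idx] = prev
    out["p_bh"] = adj
    return out
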