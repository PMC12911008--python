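"""End-to-end analysis stages over a simulated cohort.

Glue layer used by the command-line interface, the test suite and the
reproduction script: build prediction tasks (features + labels + auxiliary
covariates) from a cohort, run cross-validated model comparisons, grouped
permutation importance across folds, and the trajectory analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .composites import binarize_outcomes
from .features import FeatureBundle, build_feature_bundle
from .fusion import FusionClassifier, ModelConfig
from .importance import aggregate_importance, permutation_importance
from .simulate import SimulatedCohort
from .validation import (
    CVReport, cross_validate, fold_preprocess, make_strata, stratified_kfold, _inner_split,
)

__all__ = [
    "compact_config",
    "outcome_changes",
    "PredictionTask",
    "make_prediction_task",
    "run_cv",
    "importance_across_folds",
]

OUTCOME_COLUMNS = {"motor": "total_motor_pct", "ef": "ef_composite"}


def compact_config(variant: str = "multimodal", seed: int = 0, **overrides) -> ModelConfig:
    """Desk-scale network configuration.

    Same architecture family as the full model (conv -> pool -> dense
    channel encoders, 128-64-32 fusion head) with a narrower convolution (8
    filters, stride 4) and a 40-epoch cap — the configuration the package's
    own simulation studies run at. Pass overrides for any field.
    """
    base = dict(variant=variant, conv_filters=8, conv_stride=4, max_epochs=80,
                early_stop_patience=15, dropout_rate=0.15, seed=seed)
    base.update(overrides)
    return ModelConfig(**base)


def outcome_changes(table: pd.DataFrame, baseline_wave: int = 1, final_wave: int = 3) -> pd.DataFrame:
    """Observed 12-month change scores per participant (never imputed)."""
    w1 = table[table["wave"] == baseline_wave].set_index("participant_id")
    w3 = table[table["wave"] == final_wave].set_index("participant_id")
    out = pd.DataFrame(index=w1.index)
    for name, col in OUTCOME_COLUMNS.items():
        out[f"change_{name}"] = w3[col].reindex(w1.index) - w1[col]
    return out


@dataclass
class PredictionTask:
    """Aligned features, labels and auxiliaries for one outcome."""

    outcome: str
    bundle: FeatureBundle
    labels: np.ndarray
    aux: pd.DataFrame
    changes: pd.Series


def make_prediction_task(
    cohort: SimulatedCohort,
    outcome: str = "motor",
    density: float = 0.15,
    n_null: int = 10,
    seed: int = 0,
    bundle: FeatureBundle | None = None,
) -> PredictionTask:
    """Baseline features + median-split 12-month outcome labels.

    Participants without an observed change score are excluded from the task
    (labels are never imputed). Pass a prebuilt ``bundle`` to reuse feature
    extraction across outcomes and model variants.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    if bundle is None:
        bundle = build_feature_bundle(cohort, wave=1, density=density, n_null=n_null, seed=seed)
    changes = outcome_changes(cohort.table)[f"change_{outcome}"]
    labels_df = binarize_outcomes(changes)
    pos = {pid: i for i, pid in enumerate(bundle.ids)}
    keep_ids = [pid for pid in labels_df.index if pid in pos]
    idx = np.array([pos[pid] for pid in keep_ids])
    sub = bundle.subset(idx)
    w1 = cohort.table[cohort.table["wave"] == 1].set_index("participant_id")
    aux = w1.loc[keep_ids, ["age_months", "sex", "ses", "mean_fd", "scan_state"]].reset_index(drop=True)
    return PredictionTask(
        outcome=outcome, bundle=sub,
        labels=labels_df.loc[keep_ids, "label"].to_numpy(),
        aux=aux, changes=labels_df.loc[keep_ids, "change"],
    )


def run_cv(
    task: PredictionTask,
    variants=("multimodal", "connectivity_only", "behavioral_only"),
    base_cfg: ModelConfig | None = None,
    k: int = 5,
    m: int = 20,
    m_train: int = 5,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Stratified k-fold comparison of model variants on one task."""
    base_cfg = base_cfg or compact_config(seed=seed)
    strata = make_strata(task.aux["age_months"].to_numpy(float), task.labels)
    plan = stratified_kfold(task.labels, strata, k=k, seed=seed)
    out = {}
    for variant in variants:
        cfg = replace(base_cfg, variant=variant)
        rep = cross_validate(task.bundle, task.labels, cfg, plan, aux=task.aux,
                             m=m, m_train=m_train, seed=seed)
        rep.outcome = task.outcome
        out[variant] = rep
    return out


def cv_report_frame(reports: dict[str, dict[str, CVReport]]) -> pd.DataFrame:
    """Flat table: outcome x variant x scope rows with metric mean +/- SD."""
    rows = []
    for outcome, by_variant in reports.items():
        for variant, rep in by_variant.items():
            f = rep.frame.copy()
            f.insert(0, "variant", variant)
            f.insert(0, "outcome", outcome)
            rows.append(f)
    return pd.concat(rows, ignore_index=True)


def importance_across_folds(
    task: PredictionTask,
    cfg: ModelConfig | None = None,
    k: int = 5,
    m: int = 20,
    n_perm: int = 100,
    seed: int = 0,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Grouped permutation importance averaged over CV folds.

    Per fold: preprocess, train one network on the first completed training
    set (with the inner early-stopping split), and measure per-group test-set
    accuracy drops over ``n_perm`` shuffles; fold tables are aggregated with
    the 5-point substantive flag and Kendall's W of fold rankings (stored in
    ``result.attrs['kendalls_w']``).
    """
    cfg = cfg or compact_config(seed=seed)
    strata = make_strata(task.aux["age_months"].to_numpy(float), task.labels)
    plan = stratified_kfold(task.labels, strata, k=k, seed=seed)
    groups = groups or task.bundle.group_map
    tables = []
    for f, (train_idx, test_idx) in enumerate(plan.folds()):
        tb, sb = task.bundle.subset(train_idx), task.bundle.subset(test_idx)
        ta = task.aux.iloc[train_idx].reset_index(drop=True)
        sa = task.aux.iloc[test_idx].reset_index(drop=True)
        prep = fold_preprocess(tb, sb, ta, sa, m=m, seed=seed * 1000 + f)
        y_tr, y_te = task.labels[train_idx], task.labels[test_idx]
        inner = make_strata(ta["age_months"].to_numpy(float), y_tr)
        tr, va = _inner_split(train_idx.size, inner, 0.15, seed * 1000 + f)
        if va is None or len(np.unique(y_tr[tr])) < 2:
            tr, va = np.arange(train_idx.size), None
        ctrain = prep.completed_train[0]
        res = FusionClassifier(
            ctrain.subset(tr), y_tr[tr],
            replace(cfg, seed=cfg.seed + 97 * f),
            val=None if va is None else ctrain.subset(va),
            y_val=None if va is None else y_tr[va],
        ).fit()
        tables.append(permutation_importance(
            res, prep.transformed_test[0], y_te, groups=groups,
            n_perm=n_perm, seed=seed + f,
        ))
    return aggregate_importance(tables)
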