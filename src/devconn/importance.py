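"""Grouped permutation feature importance and rank concordance.

Importance of a feature group is the drop in test-set prediction accuracy
(percentage points) when the group's columns are jointly row-shuffled,
averaged over repeated random permutations. Groups whose mean drop exceeds 5
points are flagged as substantive contributors. Agreement of the group
rankings across cross-validation folds is summarized by Kendall's
coefficient of concordance W.

Accuracy is the degraded metric by default; AUC-based importance is
available via ``metric="auc"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureBundle
from .fusion import FusionResults
from .validation import evaluate

__all__ = ["permutation_importance", "kendalls_w", "aggregate_importance", "IMPORTANCE_THRESHOLD"]

#: substantive-contribution threshold, in accuracy percentage points
IMPORTANCE_THRESHOLD = 5.0


def permutation_importance(
    results: FusionResults,
    bundle: FeatureBundle,
    labels,
    groups: dict | None = None,
    n_perm: int = 100,
    seed: int = 0,
    metric: str = "accuracy",
) -> pd.DataFrame:
    """Per-group accuracy drop on one test set.

    Parameters
    ----------
    results : FusionResults
        A trained model; only groups touching its active channels matter
        (permuting an unused channel provably changes nothing).
    bundle, labels : preprocessed test-fold features and true classes.
    groups : dict, optional
        ``name -> (channel, column indices)``; defaults to the bundle's
        group map. Groups must reference valid columns of their channel.
    n_perm : int
        Number of random permutations per group (>= 2).

    Returns a DataFrame with columns group, importance (percentage points),
    perm_sd, baseline and permuted accuracy.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    groups = groups or bundle.group_map
    y = np.asarray(labels, dtype=int).ravel()
    metric_ix = {"accuracy": 0, "auc": 1}[metric]
    baseline = evaluate(y, results.predict_proba(bundle))[metric_ix]
    rng = np.random.default_rng(seed)
    rows = []
    for name, (channel, idx) in groups.items():
        idx = np.asarray(idx, dtype=int)
        arr = getattr(bundle, channel)
        if idx.size and idx.max() >= arr.shape[1]:
            raise ValueError(f"group {name!r} references unknown columns of channel {channel!r}")
        scores = np.empty(n_perm)
        work = bundle.copy()
        for b in range(n_perm):
            perm = rng.permutation(bundle.n)
            warr = getattr(work, channel)
            warr[:, idx] = arr[perm][:, idx]
            scores[b] = evaluate(y, results.predict_proba(work))[metric_ix]
            warr[:, idx] = arr[:, idx]
        drop = 100.0 * (baseline - scores.mean())
        rows.append({
            "group": name, "channel": channel, "importance": drop,
            "perm_sd": 100.0 * scores.std(ddof=1),
            "baseline": 100.0 * baseline, "permuted": 100.0 * scores.mean(),
        })
    return pd.DataFrame(rows)


def aggregate_importance(fold_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-fold mean +/- SD of group importance, with the 5-point flag and
    the Kendall's W of fold-wise group rankings attached as metadata."""
    merged = pd.concat([t.assign(fold=i) for i, t in enumerate(fold_tables)], ignore_index=True)
    out = (
        merged.groupby("group", sort=False)
        .agg(channel=("channel", "first"),
             importance_mean=("importance", "mean"),
             importance_sd=("importance", "std"))
        .reset_index()
    )
    out["substantive"] = out["importance_mean"] > IMPORTANCE_THRESHOLD
    rank_matrix = np.vstack([
        pd.Series(-t.set_index("group")["importance"]).rank().reindex(out["group"]).to_numpy()
        for t in fold_tables
    ])
    out.attrs["kendalls_w"] = kendalls_w(rank_matrix)
    return out.sort_values("importance_mean", ascending=False).reset_index(drop=True)


def kendalls_w(rankings: np.ndarray) -> float:
    """Kendall's coefficient of concordance with the standard tie correction.

    ``rankings`` is (k raters, g items) of ranks (ties as mid-ranks).
    W = 12 S / (k^2 (g^3 - g) - k * sum_T) with S the sum of squared
    deviations of item rank sums and T_j = sum(t^3 - t) over tie groups of
    rater j.
    """
    r = np.asarray(rankings, dtype=float)
    if r.ndim != 2:
        raise ValueError("rankings must be a k x g matrix")
    k, g = r.shape
    if g < 2:
        raise ValueError("need at least 2 items to rank")
    sums = r.sum(axis=0)
    s = ((sums - sums.mean()) ** 2).sum()
    tie_term = 0.0
    for j in range(k):
        _, counts = np.unique(r[j], return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = k**2 * (g**3 - g) - k * tie_term
    if denom <= 0:
        return 0.0
    return float(12.0 * s / denom)
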