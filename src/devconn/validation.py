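"""Leakage-free evaluation protocol.

Splits are stratified by age group x outcome class. All preprocessing that
estimates parameters — multiple imputation of missing predictors and z-score
feature scaling — is fit strictly inside each training fold and applied to
the held-out fold with the train-fitted parameters. Outcome labels are never
imputed: participants without an observed change score are excluded from the
task upstream, and this module hard-errors if a label column reaches the
imputable block.

Cross-validation is the primary evaluation (fold-wise mean +/- SD); the
70/15/15 holdout split is provided as a separate utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .features import FeatureBundle
from .fusion import FusionClassifier, ModelConfig

__all__ = [
    "FoldPlan",
    "CVReport",
    "holdout_split",
    "stratified_kfold",
    "fold_preprocess",
    "FoldPreprocessResult",
    "evaluate",
    "cross_validate",
    "make_strata",
]

#: column names that must never enter the imputation model
LABEL_COLUMNS = frozenset({"label", "motor_class", "ef_class", "change_motor", "change_ef", "outcome"})

#: feature channels subject to item-level missingness (connectivity and graph
#: features derive from complete baseline matrices)
IMPUTABLE_CHANNELS = ("motor", "cog")

AUX_COLUMNS = ("age_months", "sex", "ses", "mean_fd", "scan_state")


def make_strata(age_months: np.ndarray, labels: np.ndarray | None = None) -> np.ndarray:
    """Age-group (3-4y vs 5-6y) by outcome-class stratification labels."""
    age_band = np.where(np.asarray(age_months) < 60.0, "3-4y", "5-6y")
    if labels is None:
        return age_band
    return np.array([f"{a}|{int(l)}" for a, l in zip(age_band, np.asarray(labels))])


# ---------------------------------------------------------------------------
# splits


def holdout_split(n: int, fractions=(0.70, 0.15, 0.15), strata=None, seed: int = 0):
    """Stratified 70/15/15 split with floor-rule sizes.

    train = floor(f1*n), val = floor(f2*n), test = remainder; so n=256 gives
    (179, 38, 39). Returns three disjoint, exhaustive index arrays.
    """
    if n < 10:
        raise ValueError("holdout split needs n >= 10")
    if abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sizes = [int(np.floor(fractions[0] * n)), int(np.floor(fractions[1] * n))]
    sizes.append(n - sum(sizes))
    strata = np.zeros(n, dtype=int) if strata is None else np.asarray(strata)
    rng = np.random.default_rng(seed)

    # per-stratum largest-remainder allocation, then global adjustment to the
    # exact floor-rule totals
    out = [[], [], []]
    uniq = pd.unique(strata)
    alloc = {}
    for s in uniq:
        members = rng.permutation(np.flatnonzero(strata == s))
        ns = members.size
        quota = np.array([ns * f for f in fractions])
        counts = np.floor(quota).astype(int)
        rem = np.argsort(-(quota - counts))
        for j in rem[: ns - counts.sum()]:
            counts[j] += 1
        alloc[s] = [members, counts]
    totals = np.sum([c for _, c in alloc.values()], axis=0)
    # shift surplus members between splits (largest strata first)
    order = sorted(uniq, key=lambda s: -alloc[s][0].size)
    for _ in range(n):
        over = int(np.argmax(totals - sizes))
        under = int(np.argmin(totals - sizes))
        if totals[over] <= sizes[over]:
            break
        for s in order:
            if alloc[s][1][over] > 0:
                alloc[s][1][over] -= 1
                alloc[s][1][under] += 1
                totals[over] -= 1
                totals[under] += 1
                break
    for s in uniq:
        members, counts = alloc[s]
        pos = 0
        for j in range(3):
            out[j].extend(members[pos:pos + counts[j]].tolist())
            pos += counts[j]
    return tuple(np.sort(np.array(o, dtype=int)) for o in out)


@dataclass
class FoldPlan:
    """Participant-level k-fold assignment with stratification labels."""

    assignments: np.ndarray  # fold id per participant position
    strata: np.ndarray
    k: int = 5
    seed: int = 0

    def folds(self):
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


def stratified_kfold(labels, strata=None, k: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic stratified k-fold plan.

    Strata with fewer than k members are merged into a single pooled stratum
    (the documented fallback) so every stratum can appear in every fold.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    strata = labels.astype(str) if strata is None else np.asarray(strata).astype(str)
    counts = pd.Series(strata).value_counts()
    small = set(counts[counts < k].index)
    if small:
        # pool undersized strata; if the pool is itself undersized, fold it
        # into the largest stratum so every stratum has >= k members
        pooled = "_merged" if counts[list(small)].sum() >= k else counts.idxmax()
        strata = np.array([s if s not in small else pooled for s in strata])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(n), strata)):
        assignments[test] = f
    return FoldPlan(assignments=assignments, strata=strata, k=k, seed=seed)


# ---------------------------------------------------------------------------
# fold-internal preprocessing


@dataclass
class FoldPreprocessResult:
    """m completed+scaled training sets and the matching transformed test sets.

    ``scaler_means``/``scaler_scales`` (per imputation, per channel) and
    ``completed_train`` are fit on training data only — the leakage guard
    asserts they are bit-identical under any perturbation of test features.
    """

    completed_train: list            # list of m FeatureBundle
    transformed_test: list           # list of m FeatureBundle
    scaler_means: list               # list of m {channel: ndarray}
    scaler_scales: list
    dropped_columns: list = field(default_factory=list)


def _check_no_labels(df: pd.DataFrame | None):
    if df is None:
        return
    bad = LABEL_COLUMNS & set(df.columns)
    if bad:
        raise ValueError(f"label column(s) {sorted(bad)} must never be imputed")


def _aux_design(aux: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix of the imputation auxiliaries."""
    cols = [
        aux["age_months"].to_numpy(float),
        (aux["sex"].to_numpy() == "M").astype(float),
        (aux["ses"].to_numpy() == "middle").astype(float),
        (aux["ses"].to_numpy() == "high").astype(float),
        aux["mean_fd"].to_numpy(float),
        (aux["scan_state"].to_numpy() == "awake").astype(float),
    ]
    return np.column_stack(cols)


def fold_preprocess(
    train: FeatureBundle,
    test: FeatureBundle,
    train_aux: pd.DataFrame | None = None,
    test_aux: pd.DataFrame | None = None,
    m: int = 20,
    seed: int = 0,
) -> FoldPreprocessResult:
    """Fold-internal multiple imputation + z-scaling.

    Missing motor/cognitive cells are imputed by iterative chained
    conditional-mean models with stochastic residual draws (m imputations,
    auxiliaries as predictors), fit on the training fold only; test-fold
    missing values are filled by the train-fitted imputer. Scaling means/SDs
    come from each completed training set. With no missing data the m
    completed sets are identical scaled copies of the input.
    """
    _check_no_labels(train_aux)
    _check_no_labels(test_aux)
    n_motor = train.motor.shape[1]

    def imp_block(b: FeatureBundle, aux):
        parts = [b.motor, b.cog]
        if aux is not None:
            parts.append(_aux_design(aux))
        return np.concatenate(parts, axis=1)

    x_train = imp_block(train, train_aux)
    x_test = imp_block(test, test_aux)
    n_imp_cols = train.motor.shape[1] + train.cog.shape[1]

    dropped = [int(j) for j in range(n_imp_cols) if np.all(np.isnan(x_train[:, j]))]
    if dropped:
        warnings.warn(f"column(s) {dropped} entirely missing in training fold; filled with 0")
        x_train[:, dropped] = np.nan_to_num(x_train[:, dropped])
        x_test[:, dropped] = np.nan_to_num(x_test[:, dropped])

    any_missing = np.isnan(x_train).any() or np.isnan(x_test).any()
    rng = np.random.default_rng(seed)

    completed_train, transformed_test, means_list, scales_list = [], [], [], []
    for i in range(m):
        if any_missing:
            imputer = IterativeImputer(
                sample_posterior=True, max_iter=10,
                random_state=int(rng.integers(2**31 - 1)), skip_complete=True,
            )
            ct = imputer.fit_transform(x_train)
            tt = imputer.transform(x_test)
        else:
            ct, tt = x_train.copy(), x_test.copy()
        tb = train.copy()
        sb = test.copy()
        tb.motor, tb.cog = ct[:, :n_motor], ct[:, n_motor:n_imp_cols]
        sb.motor, sb.cog = tt[:, :n_motor], tt[:, n_motor:n_imp_cols]

        means, scales = {}, {}
        for ch in ("conn", "graph", "motor", "cog"):
            a = getattr(tb, ch)
            mu = a.mean(axis=0)
            sd = a.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            setattr(tb, ch, (a - mu) / sd)
            setattr(sb, ch, (getattr(sb, ch) - mu) / sd)
            means[ch], scales[ch] = mu, sd
        completed_train.append(tb)
        transformed_test.append(sb)
        means_list.append(means)
        scales_list.append(scales)

    return FoldPreprocessResult(
        completed_train=completed_train, transformed_test=transformed_test,
        scaler_means=means_list, scaler_scales=scales_list, dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# metrics


def evaluate(y_true, probabilities) -> tuple[float, float, float]:
    """(accuracy at 0.5, rank-statistic AUC with ties counted half, class-1 F1)."""
    y = np.asarray(y_true, dtype=int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    if y.size != p.size:
        raise ValueError("length mismatch between labels and probabilities")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present in y_true")
    pred = (p >= 0.5).astype(int)
    acc = float((pred == y).mean())
    ranks = rankdata(p)
    n1 = int(y.sum())
    n0 = y.size - n1
    auc = float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    f1 = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
    return acc, auc, float(f1)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    """Fold-wise metrics with age-stratified sub-rows."""

    frame: pd.DataFrame          # scope x (acc/auc/f1 mean and sd)
    per_fold: pd.DataFrame       # one row per fold x scope
    pooled: pd.DataFrame         # participant-level pooled test predictions
    variant: str = "multimodal"
    outcome: str = "outcome"

    def plot(self, metric: str = "accuracy", ax=None):
        """Fold-wise metric distribution per scope; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scopes = self.frame["scope"].tolist()
        for i, scope in enumerate(scopes):
            vals = self.per_fold.loc[self.per_fold["scope"] == scope, metric]
            ax.scatter(np.full(len(vals), i), vals, s=12, alpha=0.7)
            ax.hlines(vals.mean(), i - 0.25, i + 0.25, colors="k")
        ax.set_xticks(range(len(scopes)), scopes)
        ax.set_ylabel(metric)
        ax.set_title(f"{self.variant} / {self.outcome}")
        return ax


def _inner_split(n, strata, frac, seed):
    """Stratified inner train/validation split with graceful degradation.

    Falls back from full strata to a coarser stratification and finally to a
    plain shuffle when the fold is too small to stratify; returns
    (train_idx, None) when no usable validation split exists (early stopping
    then monitors training loss).
    """
    strata = np.asarray(strata).astype(str)
    n_val = max(2, int(round(frac * n)))
    if n - n_val < 2:
        return np.arange(n), None
    candidates = [strata, np.array([s.split("|")[-1] for s in strata])]
    for cand in candidates:
        try:
            sss = StratifiedShuffleSplit(n_splits=1, test_size=n_val, random_state=seed)
            return next(sss.split(np.zeros(n), cand))
        except ValueError:
            continue
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return order[n_val:], order[:n_val]


def cross_validate(
    bundle: FeatureBundle,
    labels,
    cfg: ModelConfig,
    plan: FoldPlan,
    aux: pd.DataFrame | None = None,
    m: int = 20,
    m_train: int = 5,
    inner_val_frac: float = 0.15,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold evaluation with fold-internal preprocessing.

    Per fold: preprocess (m imputations), train the network on ``m_train``
    completed sets (each with a stratified 15% inner validation split for
    early stopping), average the predicted test-fold probabilities over the
    trained networks, and score the pooled probabilities. Reports mean +/- SD
    across folds overall and within the two age bands.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.size != bundle.n:
        raise ValueError("labels must align with the bundle")
    m_train = min(m_train, m)
    age_band = (
        np.where(aux["age_months"].to_numpy(float) < 60.0, "3-4y", "5-6y")
        if aux is not None else np.full(bundle.n, "all")
    )

    fold_rows, pooled_rows = [], []
    for f, (train_idx, test_idx) in enumerate(plan.folds()):
        tb, sb = bundle.subset(train_idx), bundle.subset(test_idx)
        ta = aux.iloc[train_idx].reset_index(drop=True) if aux is not None else None
        sa = aux.iloc[test_idx].reset_index(drop=True) if aux is not None else None
        prep = fold_preprocess(tb, sb, ta, sa, m=m, seed=seed * 1000 + f)
        y_train, y_test = labels[train_idx], labels[test_idx]

        probs = np.zeros(test_idx.size)
        for i in range(m_train):
            ctrain = prep.completed_train[i]
            inner_strata = make_strata(
                ta["age_months"].to_numpy(float) if ta is not None else np.zeros(train_idx.size),
                y_train,
            )
            tr, va = _inner_split(train_idx.size, inner_strata, inner_val_frac,
                                  seed * 1000 + f * 10 + i)
            if va is None or len(np.unique(y_train[tr])) < 2:
                tr, va = np.arange(train_idx.size), None
            model = FusionClassifier(
                ctrain.subset(tr), y_train[tr],
                cfg.__class__(**{**cfg.__dict__, "seed": cfg.seed + 97 * f + i}),
                val=None if va is None else ctrain.subset(va),
                y_val=None if va is None else y_train[va],
            )
            res = model.fit()
            probs += res.predict_proba(prep.transformed_test[i])
        probs /= m_train

        acc, auc, f1 = evaluate(y_test, probs)
        fold_rows.append({"fold": f, "scope": "overall", "accuracy": acc, "auc_roc": auc, "f1": f1,
                          "n": test_idx.size})
        for band in ("3-4y", "5-6y"):
            sel = age_band[test_idx] == band
            if sel.sum() >= 4 and len(np.unique(y_test[sel])) == 2:
                a, u, f1b = evaluate(y_test[sel], probs[sel])
                fold_rows.append({"fold": f, "scope": band, "accuracy": a, "auc_roc": u,
                                  "f1": f1b, "n": int(sel.sum())})
        pooled_rows.append(pd.DataFrame({
            "participant_id": bundle.ids[test_idx], "fold": f,
            "y_true": y_test, "probability": probs, "age_band": age_band[test_idx],
        }))

    per_fold = pd.DataFrame(fold_rows)
    summary = []
    for scope in ["overall", "3-4y", "5-6y"]:
        sub = per_fold[per_fold["scope"] == scope]
        if sub.empty:
            continue
        summary.append({
            "scope": scope, "n_folds": len(sub),
            **{f"{met}_mean": sub[col].mean() for met, col in
               [("accuracy", "accuracy"), ("auc_roc", "auc_roc"), ("f1", "f1")]},
            **{f"{met}_sd": sub[col].std(ddof=1) for met, col in
               [("accuracy", "accuracy"), ("auc_roc", "auc_roc"), ("f1", "f1")]},
        })
    return CVReport(
        frame=pd.DataFrame(summary), per_fold=per_fold,
        pooled=pd.concat(pooled_rows, ignore_index=True),
        variant=cfg.variant,
    )
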