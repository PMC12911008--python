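"""Developmental-trajectory statistics.

Covers four analyses downstream of the cohort table:

* per-participant growth slopes (score change per month) and the dual
  >1-SD accelerated / <1-SD slower growth classification,
* partial correlations between trajectories controlling for age, sex, SES,
  head motion and scan state,
* a natural-cubic-spline random-intercept model of connectivity on age
  (df=3, interior knots at 48 and 60 months) compared against a linear-age
  model by the dAIC > 10 rule,
* within- vs between-network connectivity change contrasts (paired t).

Growth slopes are per-participant ordinary least squares on months since
baseline — exactly reproducible, which the classification rule requires; a
shrinkage option pulls slopes toward the grand mean for noisy two-wave
participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "growth_slopes",
    "classify_growth",
    "partial_correlation",
    "PartialCorrelation",
    "natural_spline_basis",
    "fit_spline_lmm",
    "SplineModelFit",
    "network_change_contrasts",
    "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# growth slopes and classification


def growth_slopes(
    table: pd.DataFrame,
    motor_col: str = "total_motor_pct",
    ef_col: str = "ef_composite",
    shrinkage: float = 0.0,
) -> pd.DataFrame:
    """Per-participant OLS slope of each score on months since baseline.

    Participants contribute a slope for a domain when they have >= 2 observed
    waves for that score; others are omitted with a reason. ``shrinkage`` in
    [0, 1) optionally pulls slopes toward the grand mean slope.

    Returns a DataFrame indexed by participant with motor_slope, ef_slope
    (points/month), n_waves_motor, n_waves_ef, and an ``omitted`` attrs
    table listing excluded participants.
    """
    rows, omitted = [], []
    for pid, sub in table.groupby("participant_id"):
        rec = {"participant_id": pid}
        for name, col in (("motor", motor_col), ("ef", ef_col)):
            obs = sub.dropna(subset=[col])
            if len(obs) >= 2:
                slope = np.polyfit(obs["months"].to_numpy(float), obs[col].to_numpy(float), 1)[0]
                rec[f"{name}_slope"] = float(slope)
                rec[f"n_waves_{name}"] = len(obs)
            else:
                rec[f"{name}_slope"] = np.nan
                rec[f"n_waves_{name}"] = len(obs)
                omitted.append({"participant_id": pid, "domain": name,
                                "reason": f"only {len(obs)} observed wave(s)"})
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("participant_id")
    if shrinkage:
        for c in ("motor_slope", "ef_slope"):
            gm = out[c].mean()
            out[c] = (1 - shrinkage) * out[c] + shrinkage * gm
    out.attrs["omitted"] = pd.DataFrame(omitted)
    return out


def classify_growth(records: pd.DataFrame) -> pd.DataFrame:
    """Dual-domain growth classes from slope moments.

    accelerated: both slopes > sample mean + 1 SD; slower: both < mean - 1 SD;
    otherwise typical. Moments are taken over participants with both slopes
    (the classified set); participants missing a slope get no class.
    """
    out = records.copy()
    both = out.dropna(subset=["motor_slope", "ef_slope"])
    if len(both) < 3:
        raise ValueError("need >= 3 participants with both slopes to classify")
    out["growth_class"] = pd.NA
    mu_m, sd_m = both["motor_slope"].mean(), both["motor_slope"].std(ddof=1)
    mu_e, sd_e = both["ef_slope"].mean(), both["ef_slope"].std(ddof=1)
    if sd_m == 0 or sd_e == 0:
        warnings.warn("degenerate zero-SD slopes; all participants classed typical")
        out.loc[both.index, "growth_class"] = "typical"
        return out
    acc = (both["motor_slope"] > mu_m + sd_m) & (both["ef_slope"] > mu_e + sd_e)
    slo = (both["motor_slope"] < mu_m - sd_m) & (both["ef_slope"] < mu_e - sd_e)
    cls = np.where(acc, "accelerated", np.where(slo, "slower", "typical"))
    out.loc[both.index, "growth_class"] = cls
    return out


# ---------------------------------------------------------------------------
# partial correlation


@dataclass(frozen=True)
class PartialCorrelation:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_covariates: int


def _expand_covariates(covariates) -> np.ndarray:
    """Design matrix from array/DataFrame covariates; categoricals dummied."""
    if covariates is None:
        return np.empty((0, 0))
    if isinstance(covariates, pd.DataFrame):
        num = covariates.select_dtypes(include=[np.number])
        cat = covariates.select_dtypes(exclude=[np.number])
        parts = [num.to_numpy(float)] if num.shape[1] else []
        if cat.shape[1]:
            parts.append(pd.get_dummies(cat, drop_first=True).to_numpy(float))
        return np.column_stack(parts) if parts else np.empty((len(covariates), 0))
    c = np.asarray(covariates, dtype=float)
    return c.reshape(len(c), -1)


def partial_correlation(x, y, covariates=None, alpha: float = 0.05) -> PartialCorrelation:
    """Pearson correlation of x and y after removing the covariates.

    Both variables are residualized on [intercept | covariates] by least
    squares (pseudo-inverse, with a rank warning if collinear); the residual
    correlation is reported with a Fisher-z confidence interval using
    SE = 1/sqrt(n - k - 3) and a two-sided t-test on n - k - 2 degrees of
    freedom, k = number of (expanded) covariate columns.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    c = _expand_covariates(covariates)
    n, k = x.size, c.shape[1] if c.size else 0
    if n <= k + 3:
        raise ValueError(f"need n > n_covariates + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n)] + ([c] if k else []))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear covariates; residualizing with the pseudo-inverse")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the covariates (zero residual)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - k - 3)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return PartialCorrelation(r=r, ci_low=float(lo), ci_high=float(hi), p=p, n=n, n_covariates=k)


# ---------------------------------------------------------------------------
# spline mixed model


def natural_spline_basis(x, interior_knots=(48.0, 60.0), boundary_knots=None) -> np.ndarray:
    """Natural cubic spline basis (df = number of interior knots + 1).

    Standard truncated-power construction with the natural (linear beyond
    the boundary, zero second derivative at the boundaries) constraint:
    with knots xi_1 < ... < xi_K (boundaries first/last),

        d_k(x) = [(x - xi_k)^3_+ - (x - xi_K)^3_+] / (xi_K - xi_k)
        basis  = [x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}]

    Two interior knots give the 3-column (df=3) basis.
    """
    x = np.asarray(x, dtype=float).ravel()
    if boundary_knots is None:
        boundary_knots = (x.min(), x.max())
    knots = np.sort(np.r_[boundary_knots[0], interior_knots, boundary_knots[1]])
    if knots[0] >= min(interior_knots) or knots[-1] <= max(interior_knots):
        raise ValueError("interior knots must lie strictly inside the boundary knots")
    K = knots.size

    def d(k):
        return (np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[K - 1], 0) ** 3) / (
            knots[K - 1] - knots[k]
        )

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


@dataclass
class SplineModelFit:
    """Random-intercept Gaussian model fit (ML), with AIC = -2 llf + 2 p.

    ``n_params`` counts fixed effects plus the random-intercept variance and
    the residual variance.
    """

    fe_params: pd.Series
    random_intercept_var: float
    residual_var: float
    llf: float
    n_params: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2 * self.llf + 2 * self.n_params

    @property
    def bic_n(self):  # set post-fit
        return getattr(self, "_nobs", np.nan)

    @property
    def bic(self) -> float:
        return -2 * self.llf + np.log(self.bic_n) * self.n_params


def _fit_mixed(endog, exog, names, groups) -> SplineModelFit:
    res = None
    err = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(endog, exog, groups=groups)
                res = model.fit(reml=False, method=method, maxiter=500)
            if np.isfinite(res.llf):
                break
        except (np.linalg.LinAlgError, ValueError) as e:  # singular Hessian etc.
            err = e
            res = None
    if res is None or not np.isfinite(res.llf):
        raise RuntimeError(f"mixed-model fit did not converge ({err})")
    fit = SplineModelFit(
        fe_params=pd.Series(res.fe_params, index=names),
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        llf=float(res.llf),
        n_params=len(names) + 2,
        converged=bool(res.converged),
    )
    fit._nobs = len(endog)
    return fit


def _covariate_design(table: pd.DataFrame):
    cols, names = [], []
    if "sex" in table:
        cols.append((table["sex"].to_numpy() == "M").astype(float)); names.append("sex[M]")
    if "ses" in table:
        for lev in ("middle", "high"):  # low = reference
            cols.append((table["ses"].to_numpy() == lev).astype(float)); names.append(f"ses[{lev}]")
    if "mean_fd" in table:
        cols.append(table["mean_fd"].to_numpy(float)); names.append("mean_fd")
    if "scan_state" in table:
        cols.append((table["scan_state"].to_numpy() == "awake").astype(float)); names.append("scan_state[awake]")
    return cols, names


def fit_spline_lmm(
    table: pd.DataFrame,
    value_col: str,
    age_col: str = "age_months",
    group_col: str = "participant_id",
    interior_knots=(48.0, 60.0),
    aic_rule: float = 10.0,
):
    """Spline vs linear age trajectory, random intercept per participant.

    Fits ``value ~ ns(age, df=3) + sex + SES + mean_FD + scan_state`` and the
    same model with a linear age term, both by maximum likelihood (so the
    likelihoods are comparable), and prefers the spline iff
    AIC_linear - AIC_spline > ``aic_rule``.

    Returns (spline_fit, linear_fit, delta_aic, preferred).
    """
    df = table.dropna(subset=[value_col]).copy()
    age = df[age_col].to_numpy(float)
    if not (age.min() < min(interior_knots) and age.max() > max(interior_knots)):
        raise ValueError("spline knots must lie inside the observed age range")
    endog = df[value_col].to_numpy(float)
    groups = df[group_col].to_numpy()
    cov_cols, cov_names = _covariate_design(df)

    spline = natural_spline_basis(age, interior_knots=interior_knots)
    # scale age columns to years to keep the optimizer well conditioned
    exog_s = np.column_stack([np.ones(len(df)), spline / 12.0] + cov_cols)
    names_s = ["intercept", "ns1", "ns2", "ns3"] + cov_names
    exog_l = np.column_stack([np.ones(len(df)), age / 12.0] + cov_cols)
    names_l = ["intercept", "age_years"] + cov_names

    fit_s = _fit_mixed(endog, exog_s, names_s, groups)
    fit_l = _fit_mixed(endog, exog_l, names_l, groups)
    delta = fit_l.aic - fit_s.aic
    preferred = "spline" if delta > aic_rule else "linear"
    return fit_s, fit_l, float(delta), preferred


# ---------------------------------------------------------------------------
# network change contrasts


def _block_mean(values: np.ndarray, partition: np.ndarray, a: int, b: int) -> float:
    if a == b:
        idx = np.flatnonzero(partition == a)
        sub = values[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(idx.size, k=1)
        return float(sub[iu, ju].mean()) if iu.size else np.nan
    ia, ib = np.flatnonzero(partition == a), np.flatnonzero(partition == b)
    return float(values[np.ix_(ia, ib)].mean())


def network_change_contrasts(
    matrices: dict,
    partition: np.ndarray,
    network_names=None,
    wave_a: int = 1,
    wave_b: int = 3,
) -> pd.DataFrame:
    """Per-block connectivity change (wave_b - wave_a) with paired t-tests.

    ``matrices`` maps (participant_id, wave) to ConnectivityMatrix. Only
    participants with both waves contribute. Rows cover every within- and
    between-network block; BH-adjusted p-values are appended.
    """
    k = int(np.max(partition)) + 1
    names = list(network_names) if network_names is not None else [f"N{i}" for i in range(k)]
    pids = sorted({p for (p, w) in matrices if w == wave_a} & {p for (p, w) in matrices if w == wave_b})
    if not pids:
        raise ValueError("no participants with both waves")
    rows = []
    for a in range(k):
        for b in range(a, k):
            deltas = np.array([
                _block_mean(matrices[(p, wave_b)].values, partition, a, b)
                - _block_mean(matrices[(p, wave_a)].values, partition, a, b)
                for p in pids
            ])
            if deltas.std(ddof=1) > 0:
                t, p = stats.ttest_1samp(deltas, 0.0)
            else:
                t, p = 0.0, 1.0
            rows.append({
                "block": names[a] if a == b else f"{names[a]}-{names[b]}",
                "kind": "within" if a == b else "between",
                "mean_delta": deltas.mean(), "sd_delta": deltas.std(ddof=1),
                "t": float(t), "p": float(p), "n": len(pids),
            })
    out = pd.DataFrame(rows)
    out["p_bh"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_ix in range(m - 1, -1, -1):
        i = order[rank_ix]
        running = min(running, p[i] * m / (rank_ix + 1))
        adj[i] = running
    return adj
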