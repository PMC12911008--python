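"""Seeded synthetic longitudinal cohorts of preschool development.

Emulates a three-wave (baseline, 6-month, 12-month) developmental cohort of
children aged 3-6 years: per-participant brain connectivity matrices with a
7-network block structure and age/scan-state-dependent block means, motor
percentiles and executive-function task scores calibrated to per-age-group
norms, monotone attrition, and MAR item missingness driven by observed
auxiliaries (SES, head motion, scan state).

The generative backbone is a scalar latent factor eta per child:

* baseline connectivity in sensorimotor-centred blocks is shifted by
  ``eta * effect_size_connectivity * conn_eta_delta``;
* every behavioral score carries a weak baseline loading on eta and a
  12-month growth increment ``(months/12) * effect_size_outcome * eta`` (in
  SD units), so baseline connectivity is predictive of 12-month behavioral
  change with a dialable effect size, and ``effect_size=0`` yields a
  signal-free cohort for null calibration.

Behavioral scores decompose (in z units, at baseline variance exactly 1) as

    z = lam0*eta + a_g*ability + a_m*task_trait + 0.5*noise

with lam0 = 0.3*effect_size_outcome and the stable remainder split 70/30
between a child-general ability factor and a task-specific trait. The shared
ability factor is what keeps behavioral-only prediction of eta-driven change
weaker than connectivity-based prediction: averaging many tasks cannot
average away a common factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "CohortSpec",
    "ParticipantState",
    "NETWORK_NAMES",
    "MOTOR_COLUMNS",
    "COGNITIVE_COLUMNS",
    "network_partition",
    "generate_cohort",
    "generate_connectivity",
    "generate_timeseries",
    "apply_attrition",
    "inject_missingness",
    "simulate_cohort",
    "SimulatedCohort",
]

NETWORK_NAMES = ("SomMot", "Vis", "DorsAttn", "VentAttn", "Default", "Control", "LimbicSubcort")

AGE_GROUPS = (3, 4, 5, 6)
#: baseline age-group probabilities (58/71/69/58 of 256)
AGE_GROUP_PROBS = (58 / 256, 71 / 256, 69 / 256, 58 / 256)
SES_LEVELS = ("low", "middle", "high")

#: months-of-age cutoff between natural-sleep and awake-with-video scanning
SCAN_STATE_CUTOFF_MONTHS = 60


def default_behavior_norms() -> dict:
    """Per-age-group (3/4/5/6 y) mean and SD for each named measure.

    ``direction`` is the sign of the latent growth loading (-1 for switch
    cost, where development means faster switching); ``clip`` bounds keep
    scores on their natural scale.
    """

    def m(means, sds, clip=(None, None), direction=1.0):
        return {"mean": tuple(means), "sd": tuple(sds), "clip": clip, "direction": direction}

    return {
        # --- motor (MABC-2-like percentiles) ---
        "fine_motor_pct": m((38.2, 45.6, 52.4, 56.3), (23.7, 25.8, 26.9, 27.1), (0, 100)),
        "gross_motor_pct": m((41.7, 48.3, 53.1, 54.9), (22.4, 24.6, 26.8, 28.2), (0, 100)),
        "balance_pct": m((40.8, 47.2, 52.3, 54.1), (24.3, 26.7, 28.4, 29.6), (0, 100)),
        # --- cognitive / executive function ---
        "ef_composite": m((84.3, 92.8, 101.2, 106.5), (14.2, 15.6, 16.9, 18.3)),
        "digit_span": m((2.5, 3.2, 4.1, 4.6), (0.7, 0.8, 0.9, 1.0), (0, None)),
        "visuospatial_span": m((2.8, 3.5, 4.3, 4.8), (0.8, 0.9, 1.0, 1.1), (0, None)),
        "gonogo_accuracy": m((62.4, 69.7, 76.8, 79.3), (18.2, 19.1, 19.8, 20.4), (0, 100)),
        "ant_score": m((55.0, 61.0, 67.0, 71.0), (15.0, 15.5, 16.0, 16.5)),
        "dccs_switch_cost": m((385.0, 324.0, 289.0, 268.0), (112.0, 94.0, 87.0, 82.0), (1, None), -1.0),
        "fist_score": m((8.2, 9.0, 9.8, 10.4), (2.5, 2.6, 2.7, 2.8), (0, None)),
        "nepsy_attention": m((8.6, 9.3, 9.9, 10.4), (2.8, 2.9, 3.0, 3.0), (1, 19)),
        "nepsy_statue": m((8.4, 9.2, 10.0, 10.5), (2.7, 2.8, 2.9, 3.0), (1, 19)),
        "nepsy_designs": m((8.3, 9.1, 9.8, 10.3), (2.9, 2.9, 3.0, 3.1), (1, 19)),
    }


# filler subscores are synthetic derivatives (parent score + noise) that pad
# the inventory to the modeled 16 motor / 12 cognitive features; the named
# battery does not enumerate all 16/12, so fillers are labeled as synthetic
_MOTOR_FILLERS = {
    "fine_item1": "fine_motor_pct", "fine_item2": "fine_motor_pct", "fine_item3": "fine_motor_pct",
    "gross_item1": "gross_motor_pct", "gross_item2": "gross_motor_pct", "gross_item3": "gross_motor_pct",
    "balance_item1": "balance_pct", "balance_item2": "balance_pct", "balance_item3": "balance_pct",
    "agility_item1": "total_motor_pct", "agility_item2": "total_motor_pct", "agility_item3": "total_motor_pct",
}
_COG_FILLERS = {"cog_sub1": "digit_span", "cog_sub2": "gonogo_accuracy"}

MOTOR_COLUMNS = (
    "fine_motor_pct", "gross_motor_pct", "balance_pct", "total_motor_pct",
    *_MOTOR_FILLERS.keys(),
)
COGNITIVE_COLUMNS = (
    "digit_span", "visuospatial_span", "gonogo_accuracy", "ant_score",
    "dccs_switch_cost", "fist_score", "nepsy_attention", "nepsy_statue",
    "nepsy_designs", "ef_composite", *_COG_FILLERS.keys(),
)
BEHAVIOR_COLUMNS = MOTOR_COLUMNS + COGNITIVE_COLUMNS

assert len(MOTOR_COLUMNS) == 16 and len(COGNITIVE_COLUMNS) == 12


@dataclass(frozen=True)
class ParticipantState:
    """Per-participant, per-wave latent generator state."""

    id: int
    age_months: float
    sex: str
    ses: str
    mean_fd: float
    latent_factor: float

    @property
    def scan_state(self) -> str:
        # deterministic function of age: sleep below the 5-year cutoff
        return "sleep" if self.age_months < SCAN_STATE_CUTOFF_MONTHS else "awake"

    @property
    def age_group(self) -> int:
        return int(np.clip(np.floor(self.age_months / 12.0), AGE_GROUPS[0], AGE_GROUPS[-1]))


@dataclass
class CohortSpec:
    """Study-condition dial board for the synthetic cohort generator."""

    n_baseline: int = 256
    n_regions: int = 90
    n_networks: int = 7
    age_range: tuple = (3.0, 6.0)
    wave_months: tuple = (0, 6, 12)
    retention: tuple = (0.887, 0.789)
    missing_rates: tuple = (0.113, 0.211)
    effect_size_connectivity: float = 0.5
    effect_size_outcome: float = 0.5
    behavior_norms: dict = field(default_factory=default_behavior_norms)
    fd_by_age: tuple = (0.32, 0.28, 0.24, 0.21)
    fd_sd_by_age: tuple = (0.18, 0.15, 0.12, 0.10)
    ses_probs: tuple = (0.203, 0.551, 0.246)
    prob_female: float = 0.508
    # connectivity structure dials
    block_jitter_sd: float = 0.06
    edge_noise_sd: float = 0.10
    conn_eta_delta: float = 0.06
    visual_awake_boost: float = 0.03
    sensorimotor_within_change: float = 0.07   # wave3 - wave1 within-SomMot
    visual_within_change: float = 0.05
    control_default_change: float = -0.04
    limbic_subcort_change: float = 0.01
    sommot_ventattn_traj: tuple = (0.15, 0.22)  # age 3y -> 5y ramp
    sommot_subcort_levels: tuple = (0.12, 0.16)  # young (<5y) / old step
    control_default_levels: tuple = (0.11, 0.07)
    seed: int = 0

    def __post_init__(self):
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be positive")
        for r in self.retention:
            if not 0 < r <= 1:
                raise ValueError(f"retention proportions must be in (0, 1], got {r}")
        if not all(a > b for a, b in zip(self.retention, self.retention[1:])):
            raise ValueError("retention must be strictly decreasing across waves")
        for r in self.missing_rates:
            if not 0 <= r <= 1:
                raise ValueError(f"missing rates must be in [0, 1], got {r}")
        for e in (self.effect_size_connectivity, self.effect_size_outcome):
            if not 0 <= e <= 1:
                raise ValueError("effect sizes must be in [0, 1]")
        if self.n_regions < self.n_networks:
            raise ValueError("every network needs at least one region")
        if abs(sum(self.ses_probs) - 1) > 1e-9:
            raise ValueError("ses_probs must sum to 1")

    @property
    def n_waves(self) -> int:
        return len(self.wave_months)


def network_partition(n_regions: int, n_networks: int = 7) -> np.ndarray:
    """Contiguous near-equal network blocks; every network nonempty."""
    if n_regions < n_networks:
        raise ValueError("every network needs at least one region")
    sizes = np.full(n_networks, n_regions // n_networks)
    sizes[: n_regions % n_networks] += 1
    return np.repeat(np.arange(n_networks), sizes)


# ---------------------------------------------------------------------------
# block-mean structure


def _block_means(spec: CohortSpec, age_months: float, scan_state: str, months: float, eta: float) -> np.ndarray:
    """7x7 matrix of block-mean connectivity for one participant-wave."""
    k = spec.n_networks
    B = np.full((k, k), 0.08)
    within = [0.32, 0.34, 0.28, 0.26, 0.30, 0.28, 0.25]
    for i in range(k):
        B[i, i] = within[i % 7]

    names = {n: i for i, n in enumerate(NETWORK_NAMES[:k])}

    def setpair(a, b, v):
        if a in names and b in names:
            B[names[a], names[b]] = B[names[b], names[a]] = v

    young = age_months < SCAN_STATE_CUTOFF_MONTHS
    # SomMot-VentAttn: linear rise across 3-5y, flat after (the systematic
    # sensorimotor strengthening trajectory)
    lo, hi = spec.sommot_ventattn_traj
    frac = np.clip((age_months - 36.0) / 24.0, 0.0, 1.0)
    setpair("SomMot", "VentAttn", lo + (hi - lo) * frac)
    # SomMot-subcortical: young/old step (0.12 -> 0.16)
    setpair("SomMot", "LimbicSubcort", spec.sommot_subcort_levels[0 if young else 1])
    # Control-Default segregation: young/old step (0.11 -> 0.07)
    setpair("Control", "Default", spec.control_default_levels[0 if young else 1])
    # DorsAttn-VentAttn inverted-U peaking in the 4-5y window
    setpair("DorsAttn", "VentAttn", 0.17 - 8e-5 * (age_months - 54.0) ** 2)
    setpair("DorsAttn", "Control", 0.14 - 5e-5 * (age_months - 54.0) ** 2)

    # longitudinal wave increments (per 12 months)
    t = months / 12.0
    if "SomMot" in names:
        B[names["SomMot"], names["SomMot"]] += spec.sensorimotor_within_change * t
    if "Vis" in names:
        B[names["Vis"], names["Vis"]] += spec.visual_within_change * t
        if scan_state == "awake":
            B[names["Vis"], names["Vis"]] += spec.visual_awake_boost
    if "Control" in names and "Default" in names:
        B[names["Control"], names["Default"]] += spec.control_default_change * t
        B[names["Default"], names["Control"]] = B[names["Control"], names["Default"]]
    if "LimbicSubcort" in names:
        B[names["LimbicSubcort"], names["LimbicSubcort"]] += spec.limbic_subcort_change * t

    # latent-factor loading on sensorimotor-centred blocks
    d = spec.conn_eta_delta * spec.effect_size_connectivity * eta
    if "SomMot" in names:
        B[names["SomMot"], names["SomMot"]] += d
        for other in ("VentAttn", "LimbicSubcort"):
            if other in names:
                B[names["SomMot"], names[other]] += d
                B[names[other], names["SomMot"]] = B[names["SomMot"], names[other]]
    return B


def generate_connectivity(
    state: ParticipantState,
    spec: CohortSpec,
    months: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ConnectivityMatrix:
    """One symmetric unit-diagonal connectivity matrix for a participant-wave.

    Entry (i, j) = block mean + participant-wave block jitter + edge noise,
    clipped to (-1, 1). ``months`` is time since baseline (longitudinal block
    increments scale with it).
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, int(state.id), int(round(months))])
        )
    labels = network_partition(spec.n_regions, spec.n_networks)
    B = _block_means(spec, state.age_months, state.scan_state, months, state.latent_factor)
    jitter = rng.normal(0.0, spec.block_jitter_sd, size=B.shape)
    jitter = (jitter + jitter.T) / np.sqrt(2.0)
    block = B + jitter
    vals = block[np.ix_(labels, labels)].copy()
    noise = rng.normal(0.0, spec.edge_noise_sd, size=vals.shape)
    iu, ju = np.triu_indices(spec.n_regions, k=1)
    vals[iu, ju] += noise[iu, ju]
    vals[ju, iu] = vals[iu, ju]
    np.clip(vals, -0.99, 0.99, out=vals)
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(vals, network_of_region=labels)


def _nearest_pd_correlation(c: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair, renormalized to unit diag."""
    w, v = np.linalg.eigh((c + c.T) / 2)
    if w.min() > min_eig:
        return c
    warnings.warn("target correlation matrix not positive definite; applying nearest-PD repair")
    w = np.clip(w, min_eig, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_timeseries(
    state: ParticipantState,
    n_timepoints: int = 170,
    spec: CohortSpec | None = None,
    target: ConnectivityMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Region x time Gaussian series whose population correlation is the
    participant's target connectivity matrix.

    The sample correlation of the output converges to the target as
    n_timepoints grows; non-positive-definite targets are repaired by
    eigenvalue clipping with a warning.
    """
    if spec is None:
        spec = CohortSpec()
    if target is None:
        target = generate_connectivity(state, spec)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, int(state.id), 7919])
        )
    corr = _nearest_pd_correlation(target.values)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((corr.shape[0], int(n_timepoints)))
    return L @ z


# ---------------------------------------------------------------------------
# behavioral table


def _norm_for(spec: CohortSpec, name: str, age_group: int) -> tuple[float, float, tuple, float]:
    cfg = spec.behavior_norms[name]
    gi = AGE_GROUPS.index(age_group)
    return cfg["mean"][gi], cfg["sd"][gi], cfg["clip"], cfg.get("direction", 1.0)


def _clip(vals, bounds):
    lo, hi = bounds
    return np.clip(vals, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)


def generate_cohort(spec: CohortSpec, include_connectivity: bool = True) -> tuple[pd.DataFrame, dict]:
    """Complete three-wave cohort: long-format table + connectivity matrices.

    Returns
    -------
    table : DataFrame
        One row per participant x wave; wave-1 rows complete by construction.
    matrices : dict
        ``(participant_id, wave) -> ConnectivityMatrix`` (empty when
        ``include_connectivity`` is off, for large behavioral-only draws).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_baseline
    lo_y, hi_y = spec.age_range

    group = rng.choice(len(AGE_GROUPS), size=n, p=AGE_GROUP_PROBS)
    base_age = np.array([AGE_GROUPS[g] for g in group]) * 12.0 + rng.uniform(0, 12, size=n)
    base_age = np.clip(base_age, lo_y * 12, hi_y * 12 + 11.99)
    sex = np.where(rng.random(n) < spec.prob_female, "F", "M")
    ses = rng.choice(SES_LEVELS, size=n, p=spec.ses_probs)
    eta = rng.standard_normal(n)
    ability = rng.standard_normal(n)

    lam0 = 0.3 * spec.effect_size_outcome
    resid = max(0.0, 1.0 - lam0**2 - 0.25)
    a_coef = np.sqrt(resid * 0.7)   # child-general ability share
    c_coef = np.sqrt(resid * 0.3)   # task-specific trait share

    named = [c for c in BEHAVIOR_COLUMNS if c in spec.behavior_norms]
    traits = {name: rng.standard_normal(n) for name in named}
    # common expected growth per month (norm span over the 3y->6y age range):
    # the deterministic part of change is identical for every child, so with
    # effect_size=0 the 12-month change carries no baseline information
    growth_rate = {
        name: (spec.behavior_norms[name]["mean"][-1] - spec.behavior_norms[name]["mean"][0]) / 36.0
        for name in named
    }

    rows = []
    matrices: dict[tuple[int, int], ConnectivityMatrix] = {}
    conn_rngs = np.random.SeedSequence(spec.seed).spawn(n * spec.n_waves)

    for i in range(n):
        for w, months in enumerate(spec.wave_months, start=1):
            age_m = base_age[i] + months
            age_group = int(np.clip(np.floor(age_m / 12.0), AGE_GROUPS[0], AGE_GROUPS[-1]))
            gi = AGE_GROUPS.index(age_group)
            fd_mu, fd_sd = spec.fd_by_age[gi], spec.fd_sd_by_age[gi]
            # gamma keeps FD positive with matched mean/SD
            shape = (fd_mu / fd_sd) ** 2
            fd = float(rng.gamma(shape, fd_sd**2 / fd_mu))
            state = ParticipantState(
                id=i, age_months=float(age_m), sex=str(sex[i]), ses=str(ses[i]),
                mean_fd=fd, latent_factor=float(eta[i]),
            )
            rec = {
                "participant_id": i,
                "wave": w,
                "months": float(months),
                "age_months": float(age_m),
                "age_group": age_group,
                "sex": state.sex,
                "ses": state.ses,
                "scan_state": state.scan_state,
                "mean_fd": fd,
                "latent_factor": float(eta[i]),
            }
            growth = (months / 12.0) * spec.effect_size_outcome * eta[i]
            base_group = int(np.clip(np.floor(base_age[i] / 12.0), AGE_GROUPS[0], AGE_GROUPS[-1]))
            for name in named:
                # norms anchored at the baseline age group; later waves add
                # the common growth rate (baseline cross-section stays
                # calibrated to the configured per-age norms)
                mu, sd, bounds, direction = _norm_for(spec, name, base_group)
                z = (
                    lam0 * eta[i]
                    + a_coef * ability[i]
                    + c_coef * traits[name][i]
                    + 0.5 * rng.standard_normal()
                    + direction * growth
                )
                rec[name] = float(_clip(mu + growth_rate[name] * months + sd * z, bounds))
            rec["total_motor_pct"] = float(
                np.mean([rec["fine_motor_pct"], rec["gross_motor_pct"], rec["balance_pct"]])
            )
            for filler, parent in {**_MOTOR_FILLERS, **_COG_FILLERS}.items():
                if parent in spec.behavior_norms:
                    _, sd, bounds, _ = _norm_for(spec, parent, age_group)
                else:  # total_motor_pct
                    sd, bounds = 25.0, (0, 100)
                rec[filler] = float(_clip(rec[parent] + 0.3 * sd * rng.standard_normal(), bounds))
            rows.append(rec)
            if include_connectivity:
                matrices[(i, w)] = generate_connectivity(
                    state, spec, months=months,
                    rng=np.random.default_rng(conn_rngs[i * spec.n_waves + (w - 1)]),
                )

    table = pd.DataFrame(rows)
    ordered = [c for c in table.columns if c not in BEHAVIOR_COLUMNS] + list(BEHAVIOR_COLUMNS)
    return table[ordered], matrices


# ---------------------------------------------------------------------------
# attrition & missingness


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _aux_dropout_weight(df: pd.DataFrame) -> np.ndarray:
    """Logistic-score weights from observed auxiliaries only (MAR engine)."""
    fd = df["mean_fd"].to_numpy()
    fd_z = (fd - fd.mean()) / (fd.std() + 1e-12)
    s = 0.6 * fd_z
    s = s + np.where(df["ses"].to_numpy() == "low", 0.4, 0.0)
    s = s - np.where(df["ses"].to_numpy() == "high", 0.3, 0.0)
    s = s + np.where(df["scan_state"].to_numpy() == "awake", 0.1, 0.0)
    w = np.exp(s)
    return w / w.sum()


def apply_attrition(table: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Monotone dropout reproducing the configured retention counts exactly.

    Wave-2 and wave-3 record counts equal round-half-up(retention * n); a
    participant who misses wave 2 never returns at wave 3. Dropout weights
    depend only on observed baseline auxiliaries (FD, SES, scan state), never
    on outcome values.
    """
    for r in spec.retention:
        if not 0 < r <= 1:
            raise ValueError("retention proportions must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 101]))
    base = table[table["wave"] == 1]
    n = base["participant_id"].nunique()
    keep_counts = [_round_half_up(r * n) for r in spec.retention]

    ids = base["participant_id"].to_numpy()
    w = _aux_dropout_weight(base)
    out = table.copy()
    dropped: set = set()
    for wave_idx, keep in enumerate(keep_counts, start=2):
        n_drop_total = n - keep
        remaining = np.array([i for i in ids if i not in dropped])
        extra = n_drop_total - len(dropped)
        if extra > 0:
            probs = w[np.isin(ids, remaining)]
            probs = probs / probs.sum()
            new_drop = rng.choice(remaining, size=extra, replace=False, p=probs)
            dropped.update(int(d) for d in new_drop)
        mask = (out["wave"] >= wave_idx) & (out["participant_id"].isin(dropped))
        out = out[~mask]
    return out.reset_index(drop=True)


def inject_missingness(table: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Item-level MAR masking on top of attrition.

    The wave-level missing fraction (dropout plus item masking, counted over
    behavioral cells of the full baseline roster) is brought up to the
    configured rate; masked cells are chosen with probability a logistic
    function of observed auxiliaries only. Wave-1 cells are never masked.
    """
    out = table.copy()
    n = table.loc[table["wave"] == 1, "participant_id"].nunique()
    cols = [c for c in BEHAVIOR_COLUMNS if c in table.columns]
    n_cols = len(cols)
    for wave_idx, rate in zip(range(2, 2 + len(spec.missing_rates)), spec.missing_rates):
        wave_df = out[out["wave"] == wave_idx]
        n_retained = len(wave_df)
        dropout_frac = 1 - n_retained / n
        # target count of missing cells at this wave (over the full roster)
        target_cells = rate * n * n_cols
        current_cells = (n - n_retained) * n_cols
        extra = int(round(target_cells - current_cells))
        tol = 0.5 * n_cols  # half a participant's worth of cells
        if extra < -tol:
            raise ValueError(
                f"missing rate {rate} at wave {wave_idx} is below the dropout-implied "
                f"floor {dropout_frac:.3f}"
            )
        if extra <= 0 or n_retained == 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 202, wave_idx]))
        w_rec = _aux_dropout_weight(wave_df)
        cell_p = np.repeat(w_rec / n_cols, n_cols)
        cell_p /= cell_p.sum()
        n_cells = n_retained * n_cols
        extra = min(extra, n_cells)
        chosen = rng.choice(n_cells, size=extra, replace=False, p=cell_p)
        row_pos = wave_df.index.to_numpy()[chosen // n_cols]
        col_pos = [cols[c] for c in (chosen % n_cols)]
        for r, c in zip(row_pos, col_pos):
            out.loc[r, c] = np.nan
    return out


# ---------------------------------------------------------------------------
# intake sample flow


@dataclass(frozen=True)
class SampleFlow:
    """Recruitment-to-baseline accounting after quality control."""

    n_scanned: int
    n_excluded_motion: int
    n_excluded_incomplete: int
    n_excluded_technical: int
    n_final: int
    motion_reasons: tuple = ()

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_motion + self.n_excluded_incomplete + self.n_excluded_technical


def sample_flow(
    n_scanned: int = 283,
    n_motion_fail: int = 18,
    n_incomplete: int = 6,
    n_technical: int = 3,
    seed: int = 0,
) -> SampleFlow:
    """Apply the motion QC rule to a simulated intake.

    Draws motion summaries for ``n_scanned`` scans, ``n_motion_fail`` of
    which exceed a QC threshold (high mean FD or too many high-FD volumes),
    runs `qc_filter`, and books the additional incomplete-assessment and
    technical-failure exclusions. The default counts reproduce a typical
    preschool neuroimaging intake: 283 scanned, 27 excluded, 256 retained.
    """
    from .connectivity import MotionSummary, qc_filter

    if n_motion_fail + n_incomplete + n_technical > n_scanned:
        raise ValueError("exclusions exceed the scanned sample")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_scanned):
        if i < n_motion_fail:
            if rng.random() < 0.7:  # high mean FD
                records.append(MotionSummary(float(rng.uniform(0.51, 1.2)), float(rng.uniform(0, 0.2))))
            else:  # too many spike volumes
                records.append(MotionSummary(float(rng.uniform(0.1, 0.5)), float(rng.uniform(0.21, 0.6))))
        else:
            records.append(MotionSummary(float(rng.uniform(0.05, 0.5)), float(rng.uniform(0, 0.2))))
    retained, excluded = qc_filter(records)
    return SampleFlow(
        n_scanned=n_scanned,
        n_excluded_motion=len(excluded),
        n_excluded_incomplete=n_incomplete,
        n_excluded_technical=n_technical,
        n_final=len(retained) - n_incomplete - n_technical,
        motion_reasons=tuple(r for _, r in excluded),
    )


# ---------------------------------------------------------------------------
# convenience wrapper


@dataclass
class SimulatedCohort:
    """A fully generated study dataset."""

    spec: CohortSpec
    table: pd.DataFrame            # observed table (attrition + masking applied)
    complete_table: pd.DataFrame   # pre-masking ground truth (for MAR checks)
    matrices: dict                 # (participant_id, wave) -> ConnectivityMatrix

    @property
    def partition(self) -> np.ndarray:
        return network_partition(self.spec.n_regions, self.spec.n_networks)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """generate_cohort -> apply_attrition -> inject_missingness, seeded."""
    full, matrices = generate_cohort(spec)
    retained = apply_attrition(full, spec)
    observed = inject_missingness(retained, spec)
    keys = set(zip(observed["participant_id"], observed["wave"]))
    matrices = {k: v for k, v in matrices.items() if k in keys}
    return SimulatedCohort(spec=spec, table=observed, complete_table=full, matrices=matrices)
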