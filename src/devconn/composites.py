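"""Behavioral composites and developmental outcome labels.

The executive-function (EF) composite is a reliability-weighted mean of three
domain z-scores — working memory (WM), inhibitory control (IC), cognitive
flexibility (CF) — with weights given by each domain's internal-consistency
reliability (Cronbach's alpha):

    raw = (a_WM * z_WM + a_IC * z_IC + a_CF * z_CF) / (a_WM + a_IC + a_CF)

The raw composite is then linearly rescaled so that a reference sample has
mean exactly 100 and SD exactly 15 (the familiar IQ-like metric).

Developmental outcomes are binary median splits of the observed 12-month
change scores; change scores are never imputed, so participants without an
observed change are simply absent from the label set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityWeights",
    "DEFAULT_WEIGHTS",
    "age_standardize",
    "ef_composite",
    "rescale_to_metric",
    "binarize_outcomes",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class ReliabilityWeights:
    """Cronbach-alpha weights for the three EF domains, each in (0, 1]."""

    alpha_wm: float
    alpha_ic: float
    alpha_cf: float
    source: str = "default"

    def __post_init__(self):
        for name in ("alpha_wm", "alpha_ic", "alpha_cf"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_wm, self.alpha_ic, self.alpha_cf])


# Per-domain default: mean of the two task alphas within each domain
# (WM: digit span 0.82, visuospatial span 0.78; IC: go/no-go 0.85, attention
# network test 0.81; CF: card sort 0.79, flexible item selection 0.76).
DEFAULT_WEIGHTS = ReliabilityWeights(
    alpha_wm=(0.82 + 0.78) / 2,
    alpha_ic=(0.85 + 0.81) / 2,
    alpha_cf=(0.79 + 0.76) / 2,
    source="battery task alphas, domain means",
)


def age_standardize(raw, norm_mean: float, norm_sd: float):
    """z = (raw - norm_mean) / norm_sd against age-group norms."""
    if norm_sd <= 0:
        raise ValueError("norm_sd must be positive")
    return (np.asarray(raw, dtype=float) - norm_mean) / norm_sd


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha from an (n, k) item-score matrix."""
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 2:
        raise ValueError("need at least two items")
    item_var = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return k / (k - 1) * (1 - item_var / total_var)


def ef_composite(
    z_wm,
    z_ic,
    z_cf,
    weights: ReliabilityWeights = DEFAULT_WEIGHTS,
    rescale_sample: np.ndarray | None = None,
) -> np.ndarray:
    """Reliability-weighted EF composite, optionally rescaled to 100/15.

    Parameters
    ----------
    z_wm, z_ic, z_cf : array-like
        Domain z-scores (published-norm or within-sample; caller's choice).
    weights : ReliabilityWeights
        Domain reliabilities; invariant to multiplying all three by a
        positive constant.
    rescale_sample : ndarray, optional
        Raw composites defining the 100/15 metric. If omitted, the input's
        own raw composites are used as the reference sample. Pass the
        training-sample composites to score new observations on an existing
        metric.

    Returns
    -------
    ndarray of rescaled composite scores (or the raw weighted mean if the
    reference sample is a single value, which cannot define a scale).
    """
    z = np.vstack([np.asarray(z_wm, float), np.asarray(z_ic, float), np.asarray(z_cf, float)])
    a = weights.as_array()
    raw = (a[:, None] * z).sum(axis=0) / a.sum()
    ref = raw if rescale_sample is None else np.asarray(rescale_sample, dtype=float)
    return rescale_to_metric(raw, ref)


def ef_composite_raw(z_wm, z_ic, z_cf, weights: ReliabilityWeights = DEFAULT_WEIGHTS):
    """The unrescaled weighted-mean composite."""
    z = np.vstack([np.asarray(z_wm, float), np.asarray(z_ic, float), np.asarray(z_cf, float)])
    a = weights.as_array()
    return (a[:, None] * z).sum(axis=0) / a.sum()


def rescale_to_metric(values: np.ndarray, reference: np.ndarray, mean: float = 100.0, sd: float = 15.0):
    """Linear map making ``reference`` have the target mean and SD exactly."""
    reference = np.asarray(reference, dtype=float)
    if reference.size < 2:
        raise ValueError("rescale sample must contain at least 2 scores")
    ref_sd = reference.std(ddof=0)
    if ref_sd == 0:
        raise ValueError("rescale sample has zero variance")
    return mean + sd * (np.asarray(values, float) - reference.mean()) / ref_sd


def binarize_outcomes(changes: pd.Series | dict | np.ndarray) -> pd.DataFrame:
    """Median-split binary classes from observed change scores.

    Class 1 iff change strictly exceeds the sample median of non-missing
    changes; exact ties with the median get class 0 (fixed, documented
    policy). Missing changes are dropped, never imputed.
    """
    s = pd.Series(changes, dtype=float).dropna()
    if s.size < 2:
        raise ValueError("need at least 2 observed change scores")
    med = s.median()
    return pd.DataFrame({"change": s, "label": (s > med).astype(int)})
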