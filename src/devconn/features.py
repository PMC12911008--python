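"""Per-participant feature bundles for the fusion classifier.

A bundle stacks four channels for n participants:

* ``conn``  — the P(P-1)/2 upper-triangle connectivity values,
* ``graph`` — the 12 scalar topology metrics,
* ``motor`` — 16 motor assessment scores,
* ``cog``   — 12 cognitive/executive scores,

plus a feature-group map that partitions every column exactly once. Groups
cover the four channels and, within the connectivity channel, the named
network blocks (e.g. ``conn:SomMot-VentAttn``) so that block-level
permutation-importance statements are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graph as graph_metrics
from .connectivity import upper_triangle_pairs, vectorize_upper
from .simulate import COGNITIVE_COLUMNS, MOTOR_COLUMNS, NETWORK_NAMES, SimulatedCohort

__all__ = ["FeatureBundle", "build_feature_bundle", "connectivity_block_groups"]

CHANNELS = ("conn", "graph", "motor", "cog")


@dataclass
class FeatureBundle:
    """Stacked per-participant feature channels (rows aligned across channels)."""

    ids: np.ndarray
    conn: np.ndarray
    graph: np.ndarray
    motor: np.ndarray
    cog: np.ndarray
    group_map: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.ids)
        for ch in CHANNELS:
            arr = getattr(self, ch)
            if arr.shape[0] != n:
                raise ValueError(f"channel {ch!r} has {arr.shape[0]} rows for {n} participants")
        if self.graph.shape[1] != 12:
            raise ValueError("graph channel must have exactly 12 features")
        if not self.group_map:
            self.group_map = {ch: (ch, np.arange(getattr(self, ch).shape[1])) for ch in CHANNELS}

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "FeatureBundle":
        idx = np.asarray(idx)
        return FeatureBundle(
            ids=self.ids[idx], conn=self.conn[idx], graph=self.graph[idx],
            motor=self.motor[idx], cog=self.cog[idx], group_map=self.group_map,
        )

    def channels(self, names=CHANNELS) -> dict:
        return {ch: getattr(self, ch) for ch in names}

    def copy(self) -> "FeatureBundle":
        return FeatureBundle(
            ids=self.ids.copy(), conn=self.conn.copy(), graph=self.graph.copy(),
            motor=self.motor.copy(), cog=self.cog.copy(), group_map=self.group_map,
        )


def connectivity_block_groups(partition: np.ndarray) -> dict:
    """Edge-index groups of the connectivity vector by network block pair."""
    p = partition.size
    pairs = upper_triangle_pairs(p)
    a = partition[pairs[:, 0]]
    b = partition[pairs[:, 1]]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    groups = {}
    k = int(partition.max()) + 1
    names = NETWORK_NAMES[:k]
    for i in range(k):
        for j in range(i, k):
            idx = np.flatnonzero((lo == i) & (hi == j))
            if idx.size:
                label = f"conn:{names[i]}" if i == j else f"conn:{names[i]}-{names[j]}"
                groups[label] = ("conn", idx)
    return groups


def build_feature_bundle(
    cohort: SimulatedCohort,
    wave: int = 1,
    density: float = 0.15,
    n_null: int = 50,
    seed: int = 0,
    block_groups: bool = True,
) -> FeatureBundle:
    """Extract the four feature channels from one assessment wave.

    Graph metrics are computed on each participant's thresholded matrix with
    a seeded null ensemble of size ``n_null``. Participants without a
    connectivity matrix at the wave are skipped.
    """
    tab = cohort.table[cohort.table["wave"] == wave].set_index("participant_id")
    ids, conn_rows, graph_rows, motor_rows, cog_rows = [], [], [], [], []
    for pid in tab.index:
        key = (pid, wave)
        if key not in cohort.matrices:
            continue
        m = cohort.matrices[key]
        conn_rows.append(vectorize_upper(m))
        g = graph_metrics.threshold_graph(m, density=density)
        graph_rows.append(graph_metrics.global_metrics(g, n_null=n_null, seed=seed + int(pid)))
        motor_rows.append(tab.loc[pid, list(MOTOR_COLUMNS)].to_numpy(dtype=float))
        cog_rows.append(tab.loc[pid, list(COGNITIVE_COLUMNS)].to_numpy(dtype=float))
        ids.append(pid)

    bundle = FeatureBundle(
        ids=np.array(ids),
        conn=np.vstack(conn_rows),
        graph=np.vstack(graph_rows),
        motor=np.vstack(motor_rows),
        cog=np.vstack(cog_rows),
    )
    gm = {
        "graph": ("graph", np.arange(12)),
        "motor": ("motor", np.arange(len(MOTOR_COLUMNS))),
        "cog": ("cog", np.arange(len(COGNITIVE_COLUMNS))),
    }
    if block_groups:
        gm.update(connectivity_block_groups(cohort.partition))
    else:
        gm["conn"] = ("conn", np.arange(bundle.conn.shape[1]))
    bundle.group_map = gm
    return bundle


def bundle_to_frame(bundle: FeatureBundle) -> pd.DataFrame:
    """Flat DataFrame view (columns prefixed by channel) for file output."""
    cols = {}
    for ch in CHANNELS:
        arr = getattr(bundle, ch)
        for j in range(arr.shape[1]):
            cols[f"{ch}_{j:05d}"] = arr[:, j]
    return pd.DataFrame(cols, index=pd.Index(bundle.ids, name="participant_id"))
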