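"""Graph metrics: shortest paths, global efficiency, within-module degree z.

All metrics operate on binary (hop-count) graphs, matching the
density-thresholded graphs produced by :mod:`ctcnet.connectivity`.
Global efficiency is the mean inverse shortest-path length over ordered
node pairs (1/inf = 0 for unreachable pairs), so it is well defined on
fragmented graphs; fragmented subjects are flagged and summarized
separately rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import BrainGraph
from .errors import DataError

__all__ = [
    "GraphMetricsResult",
    "shortest_path_lengths",
    "global_efficiency",
    "within_module_degree_z",
    "compute_metrics",
    "fragmentation_summary",
]


def shortest_path_lengths(G: BrainGraph) -> np.ndarray:
    """Hop-count distance matrix (np.inf where unreachable, 0 diagonal)."""
    adj = G.adjacency.astype(float)
    d = _csgraph_shortest_path(adj, method="D", directed=False, unweighted=True)
    return d


def global_efficiency(G: BrainGraph) -> float:
    """E = (1 / (n(n-1))) * sum_{i != j} 1 / d_ij, in [0, 1]."""
    n = G.n
    if n < 2:
        raise DataError("global efficiency needs at least 2 nodes")
    d = shortest_path_lengths(G)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def within_module_degree_z(
    G: BrainGraph, partition: dict[str, str] | None = None
) -> dict[str, float]:
    """Standardized within-module degree per node.

    For node i in module m: z_i = (k_i - mean_m(k)) / sd_m(k), with k the
    degree counting only edges inside m and sd the population (divide-by-n)
    standard deviation.  Nodes in modules with zero degree spread (including
    singleton modules) get z = 0.
    """
    partition = partition or G.partition
    if partition is None:
        raise DataError("no module partition supplied")
    missing = [lab for lab in G.labels if lab not in partition]
    if missing:
        raise DataError(f"partition is missing node(s): {', '.join(missing)}")

    idx = {lab: i for i, lab in enumerate(G.labels)}
    modules: dict[str, list[str]] = {}
    for lab in G.labels:
        modules.setdefault(partition[lab], []).append(lab)

    z: dict[str, float] = {}
    for members in modules.values():
        rows = [idx[m] for m in members]
        sub = G.adjacency[np.ix_(rows, rows)]
        kappa = sub.sum(axis=1).astype(float)
        sd = float(kappa.std())  # population SD
        mean = float(kappa.mean())
        for m, k in zip(members, kappa):
            z[m] = 0.0 if sd == 0.0 else float((k - mean) / sd)
    return z


@dataclass
class GraphMetricsResult:
    subject_id: str
    global_efficiency: float
    within_module_degree_z: dict[str, float]
    disconnected_nodes: list[str]
    density_used: float

    @property
    def fragmented(self) -> bool:
        return bool(self.disconnected_nodes)


def compute_metrics(
    G: BrainGraph,
    subject_id: str = "",
    partition: dict[str, str] | None = None,
) -> GraphMetricsResult:
    return GraphMetricsResult(
        subject_id=subject_id,
        global_efficiency=global_efficiency(G),
        within_module_degree_z=within_module_degree_z(G, partition)
        if (partition or G.partition)
        else {},
        disconnected_nodes=G.isolated(),
        density_used=G.density,
    )


def fragmentation_summary(
    results: pd.DataFrame, decimals: int = 0
) -> pd.DataFrame:
    """Counts and proportions of subjects with disconnected nodes.

    ``results`` needs columns ``subject_id``, ``sex`` and ``fragmented``
    (boolean).  Returns one row per sex plus an ``all`` row with columns
    ``n``, ``n_fragmented`` and ``percent`` (rounded to ``decimals``).
    """
    if results.empty:
        raise DataError("fragmentation summary needs at least one subject")
    rows = []
    groups = [("all", results)] + [
        (sex, grp) for sex, grp in results.groupby("sex", sort=True)
    ]
    for name, grp in groups:
        n = len(grp)
        k = int(grp["fragmented"].sum())
        rows.append(
            {
                "group": name,
                "n": n,
                "n_fragmented": k,
                "percent": round(100.0 * k / n, decimals),
            }
        )
    return pd.DataFrame(rows)
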