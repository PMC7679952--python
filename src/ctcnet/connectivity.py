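"""Functional connectivity: Fisher-z matrices and density-thresholded graphs.

Pairwise Pearson correlations between ROI time courses are Fisher-z
transformed (``atanh``, with r clipped away from +/-1) into a symmetric
connectivity matrix.  Graphs are built by proportional density
thresholding: the top ``ceil(d * n(n-1)/2)`` *positive* z-values become
binary edges (negative correlations are never admitted, following common
connectomics practice).  The minimum admissible density for a subject is
the smallest grid density at which no region is left isolated; subjects
for whom no such density exists are reported as fragmented, with the
persistently disconnected regions listed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .synthetic import TimeSeriesPanel

__all__ = [
    "ConnectivityMatrix",
    "BrainGraph",
    "FragmentationReport",
    "compute_connectivity",
    "threshold_at_density",
    "find_minimum_density",
    "significance_graph",
    "mean_connectivity",
    "DEFAULT_DENSITY_GRID",
]

logger = logging.getLogger(__name__)

#: r is clipped to +/-(1 - R_CLIP) before the Fisher transform so duplicated
#: or perfectly anti-correlated signals yield finite z.
R_CLIP = 1e-7

DEFAULT_DENSITY_GRID: tuple[float, ...] = tuple(
    round(0.05 + 0.01 * i, 2) for i in range(46)
)  # 0.05 .. 0.50


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    n_timepoints: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataError("connectivity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise DataError("connectivity matrix must be symmetric")
        if not np.isfinite(v).all():
            raise DataError("connectivity matrix must be finite")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def pairs(self):
        """All unordered region pairs (i < j) in lexicographic label order
        with their z-values."""
        order = np.argsort(self.labels)
        for a in range(self.n):
            for b in range(a + 1, self.n):
                i, j = order[a], order[b]
                yield (self.labels[i], self.labels[j], self.values[i, j])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.columns), values=df.to_numpy(float))


@dataclass
class BrainGraph:
    """Binary undirected graph at a density threshold, with an optional
    module partition."""

    labels: list[str]
    adjacency: np.ndarray
    partition: dict[str, str] | None = None
    target_density: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape != (len(self.labels), len(self.labels)):
            raise DataError("adjacency shape does not match labels")
        if not (a == a.T).all():
            raise DataError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        possible = self.n * (self.n - 1) // 2
        return self.n_edges / possible if possible else 0.0

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def isolated(self) -> list[str]:
        deg = self.degrees()
        return [lab for lab, d in zip(self.labels, deg) if d == 0]

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.adjacency[i, j]:
                    a, b = sorted((self.labels[i], self.labels[j]))
                    out.append((a, b))
        return sorted(out)


@dataclass
class FragmentationReport:
    """Emitted when no grid density connects every region."""

    subject_id: str | None
    grid: tuple[float, ...]
    disconnected: list[str]
    graph_at_max: BrainGraph | None = None


def compute_connectivity(panel: TimeSeriesPanel) -> ConnectivityMatrix:
    """Fisher-z transformed Pearson correlation matrix of a panel.

    Raises :class:`DataError` listing any zero-variance region.
    """
    panel.validate()
    flat = panel.zero_variance_regions()
    if flat:
        raise DataError(
            f"zero-variance region(s) in panel {panel.subject_id}: {', '.join(flat)}"
        )
    x = panel.data.to_numpy(float)
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -(1 - R_CLIP), 1 - R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetry
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        labels=list(panel.data.columns), values=z, n_timepoints=len(panel.data)
    )


def mean_connectivity(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean matrix (for group-mean thresholding mode)."""
    if not matrices:
        raise DataError("need at least one connectivity matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise DataError("matrices have mismatched region labels")
    return ConnectivityMatrix(
        labels=list(labels),
        values=np.mean([m.values for m in matrices], axis=0),
    )


def _ranked_positive_pairs(C: ConnectivityMatrix) -> list[tuple[float, str, str]]:
    """Positive entries sorted by descending z, ties broken by lexicographic
    region-pair order (exact reproducibility)."""
    idx = {lab: i for i, lab in enumerate(C.labels)}
    pairs = []
    for a, b, z in C.pairs():
        if z > 0:
            pairs.append((z, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(z, a, b, idx[a], idx[b]) for z, a, b in pairs]


def threshold_at_density(
    C: ConnectivityMatrix,
    d: float,
    partition: dict[str, str] | None = None,
) -> BrainGraph:
    """Binarize a connectivity matrix at proportional density ``d``.

    The ``ceil(d * n(n-1)/2)`` largest positive z-values become edges.  If
    fewer positive entries exist than requested, all of them are used and
    a warning is logged (achieved density < d).
    """
    if not 0 < d <= 1:
        raise ConfigurationError(f"density must lie in (0, 1], got {d}")
    n = C.n
    requested = math.ceil(d * n * (n - 1) / 2)
    ranked = _ranked_positive_pairs(C)
    if len(ranked) < requested:
        logger.warning(
            "requested %d edges at density %.3f but only %d positive entries",
            requested,
            d,
            len(ranked),
        )
    adj = np.zeros((n, n), dtype=bool)
    for z, a, b, i, j in ranked[:requested]:
        adj[i, j] = adj[j, i] = True
    return BrainGraph(labels=list(C.labels), adjacency=adj, partition=partition,
                      target_density=d)


def find_minimum_density(
    C: ConnectivityMatrix,
    grid: tuple[float, ...] | list[float] = DEFAULT_DENSITY_GRID,
    partition: dict[str, str] | None = None,
    subject_id: str | None = None,
) -> tuple[float, BrainGraph] | FragmentationReport:
    """Smallest grid density whose graph has no isolated region.

    Returns ``(d_min, graph)`` on success; if even the largest grid
    density leaves regions isolated, returns a :class:`FragmentationReport`
    listing them (by edge-set monotonicity they are isolated at every
    smaller density too).
    """
    grid = tuple(grid)
    if not grid:
        raise ConfigurationError("density grid must be non-empty")
    if any(not 0 < d <= 1 for d in grid):
        raise ConfigurationError("density grid values must lie in (0, 1]")
    if list(grid) != sorted(grid):
        raise ConfigurationError("density grid must be ascending")
    for d in grid:
        g = threshold_at_density(C, d, partition=partition)
        if not g.isolated():
            return d, g
    g_max = threshold_at_density(C, grid[-1], partition=partition)
    return FragmentationReport(
        subject_id=subject_id,
        grid=grid,
        disconnected=g_max.isolated(),
        graph_at_max=g_max,
    )


def significance_graph(
    C: ConnectivityMatrix,
    alpha: float = 0.05,
    partition: dict[str, str] | None = None,
) -> BrainGraph:
    """Alternative thresholding mode: keep positive edges whose correlation
    is significant after Benjamini-Hochberg FDR at level ``alpha``.

    Requires ``C.n_timepoints`` (the sample size behind each correlation).
    """
    from statsmodels.stats.multitest import multipletests

    if C.n_timepoints is None:
        raise DataError("significance thresholding needs n_timepoints on the matrix")
    n_t = C.n_timepoints
    pairs = [(a, b, z) for a, b, z in C.pairs()]
    r = np.tanh(np.array([z for _, _, z in pairs]))
    df = n_t - 2
    t = r * np.sqrt(df / np.clip(1 - r**2, 1e-12, None))
    p = 2 * stats.t.sf(np.abs(t), df)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    idx = {lab: i for i, lab in enumerate(C.labels)}
    adj = np.zeros((C.n, C.n), dtype=bool)
    for (a, b, z), keep in zip(pairs, reject):
        if keep and z > 0:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    return BrainGraph(labels=list(C.labels), adjacency=adj, partition=partition)
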