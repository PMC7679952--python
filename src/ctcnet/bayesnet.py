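"""Score-based effective-connectivity estimation.

A linear-Gaussian Bayesian network is fit to ROI time courses by greedy
hill-climbing over single-edge moves (add / delete / reverse), scored by
the decomposable Gaussian BIC

    score(j | P) = -(n/2) * log(RSS_j / n) - (|P| + 2)/2 * log(n)

(one variance plus an intercept plus |P| coefficients per node; higher is
better).  Search restarts from random acyclic graphs to escape local
optima; restart 0 always starts from the empty graph, so the returned
model never scores below it.

Because edge direction between two Gaussian variables is not identifiable
on its own, structural comparisons are also reported at the equivalence
-class level (skeleton + v-structures), which is exactly what the data can
distinguish.

Subject pooling for stratified and whole-cohort fits: each subject's
regional time courses are z-standardized, then rows are concatenated.
Per-subject connectivity weights are the regression coefficients of each
child on its parents in the common model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .synthetic import TimeSeriesPanel

__all__ = [
    "DAGModel",
    "AnovaResult",
    "gaussian_bic_score",
    "node_bic_score",
    "hill_climb_structure",
    "learn_stratified",
    "fit_common_model",
    "estimate_edge_weights",
    "interaction_anova",
    "skeleton",
    "v_structures",
    "structural_hamming_distance",
    "compare_structures",
    "standardize_panel",
    "pool_panels",
    "find_edges_between",
]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class DAGModel:
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]  # (parent, child)
    per_node_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("DAGModel edges contain a cycle")

    @property
    def total_score(self) -> float:
        return float(sum(self.per_node_scores.values()))

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == node))

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "edges": sorted(self.edges),
            "per_node_scores": self.per_node_scores,
            "total_score": self.total_score,
        }


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA with interaction (Type II SS)."""

    terms: dict[str, dict[str, float]]  # term -> {F, p, df}
    residual_df: float
    edge: tuple[str, str] | None = None

    def f(self, term: str) -> float:
        return self.terms[term]["F"]

    def p(self, term: str) -> float:
        return self.terms[term]["p"]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(float), list(data.columns)
    x = np.asarray(data, dtype=float)
    return x, [f"x{i}" for i in range(x.shape[1])]


def node_bic_score(x: np.ndarray, child: int, parents: tuple[int, ...]) -> float:
    """Gaussian BIC contribution of one node given its parent set."""
    n = x.shape[0]
    y = x[:, child]
    if parents:
        design = np.column_stack([np.ones(n), x[:, list(parents)]])
    else:
        design = np.ones((n, 1))
    coef, rss_arr, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise DataError(f"singular parent design for node index {child}")
    if rss_arr.size:
        rss = float(rss_arr[0])
    else:
        rss = float(((y - design @ coef) ** 2).sum())
    rss = max(rss, 1e-300)  # guard exact interpolation
    k = len(parents) + 2  # coefficients + intercept + variance
    return -(n / 2.0) * np.log(rss / n) - (k / 2.0) * np.log(n)


def gaussian_bic_score(data, dag: DAGModel) -> float:
    """Total Gaussian BIC of a DAG on a samples x nodes data table.

    The score decomposes over nodes and is invariant to the column order
    of the data table (columns are matched to DAG nodes by name when a
    DataFrame is given).
    """
    x, cols = _as_matrix(data)
    if x.shape[0] <= x.shape[1] + max((len(dag.parents(v)) for v in dag.nodes), default=0):
        raise DataError("need more samples than nodes + max parent-set size")
    if not np.isfinite(x).all():
        raise DataError("data must be finite")
    idx = {c: i for i, c in enumerate(cols)}
    total = 0.0
    for node in dag.nodes:
        ps = tuple(idx[p] for p in dag.parents(node))
        total += node_bic_score(x, idx[node], ps)
    return float(total)


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------


class _Search:
    """Greedy single-edge-move search with per-node score caching."""

    def __init__(self, x: np.ndarray, nodes: list[str], forbidden: set[tuple[str, str]]):
        self.x = x
        self.nodes = nodes
        self.idx = {n: i for i, n in enumerate(nodes)}
        self.forbidden = forbidden
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def node_score(self, child: str, parents: frozenset[str]) -> float:
        key = (self.idx[child], tuple(sorted(self.idx[p] for p in parents)))
        if key not in self._cache:
            self._cache[key] = node_bic_score(self.x, key[0], key[1])
        return self._cache[key]

    def climb(self, parents: dict[str, frozenset[str]], max_iter: int) -> dict[str, frozenset[str]]:
        nodes = self.nodes
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for c, ps in parents.items():
            g.add_edges_from((p, c) for p in ps)
        scores = {c: self.node_score(c, ps) for c, ps in parents.items()}

        for _ in range(max_iter):
            best_delta = 0.0
            best_move = None
            for a in nodes:
                for b in nodes:
                    if a == b:
                        continue
                    if a in parents[b]:
                        # delete a -> b
                        delta = self.node_score(b, parents[b] - {a}) - scores[b]
                        if delta > best_delta + 1e-9:
                            best_delta, best_move = delta, ("delete", a, b)
                        # reverse a -> b (must keep acyclicity)
                        if (b, a) not in self.forbidden:
                            g.remove_edge(a, b)
                            ok = not nx.has_path(g, a, b)
                            g.add_edge(a, b)
                            if ok:
                                delta = (
                                    self.node_score(b, parents[b] - {a})
                                    - scores[b]
                                    + self.node_score(a, parents[a] | {b})
                                    - scores[a]
                                )
                                if delta > best_delta + 1e-9:
                                    best_delta, best_move = delta, ("reverse", a, b)
                    else:
                        # add a -> b
                        if (a, b) in self.forbidden:
                            continue
                        if nx.has_path(g, b, a):
                            continue
                        delta = self.node_score(b, parents[b] | {a}) - scores[b]
                        if delta > best_delta + 1e-9:
                            best_delta, best_move = delta, ("add", a, b)
            if best_move is None:
                break
            op, a, b = best_move
            if op == "add":
                parents[b] = parents[b] | {a}
                g.add_edge(a, b)
            elif op == "delete":
                parents[b] = parents[b] - {a}
                g.remove_edge(a, b)
            else:  # reverse
                parents[b] = parents[b] - {a}
                parents[a] = parents[a] | {b}
                g.remove_edge(a, b)
                g.add_edge(b, a)
                scores[a] = self.node_score(a, parents[a])
            scores[b] = self.node_score(b, parents[b])
        return parents


def _random_start(
    nodes: list[str], rng: np.random.Generator, forbidden: set[tuple[str, str]]
) -> dict[str, frozenset[str]]:
    """Random DAG: random topological order, each admissible forward edge
    kept with probability 0.3."""
    order = list(rng.permutation(nodes))
    parents = {n: set() for n in nodes}
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if (a, b) in forbidden:
                continue
            if rng.random() < 0.3:
                parents[b].add(a)
    return {n: frozenset(ps) for n, ps in parents.items()}


def hill_climb_structure(
    data,
    restarts: int = 10,
    max_iter: int = 200,
    seed: int = 0,
    forbidden_edges: set[tuple[str, str]] | None = None,
) -> DAGModel:
    """Learn a DAG by greedy hill-climbing with random restarts.

    Restart 0 starts from the empty graph; subsequent restarts start from
    random DAGs drawn deterministically from ``seed``.  The best-scoring
    model across restarts is returned (ties resolved to the earliest
    restart), so results are reproducible given the seed.
    """
    if restarts < 1:
        raise ConfigurationError("restarts must be >= 1")
    x, cols = _as_matrix(data)
    if not np.isfinite(x).all():
        raise DataError("data must be finite")
    forbidden = set(forbidden_edges or ())
    search = _Search(x, cols, forbidden)
    rng = np.random.default_rng(seed)

    best: dict[str, frozenset[str]] | None = None
    best_score = -np.inf
    for r in range(restarts):
        if r == 0:
            start = {n: frozenset() for n in cols}
        else:
            start = _random_start(cols, rng, forbidden)
        parents = search.climb(dict(start), max_iter)
        score = sum(search.node_score(c, ps) for c, ps in parents.items())
        if score > best_score + 1e-9:
            best, best_score = parents, score
    edges = frozenset((p, c) for c, ps in best.items() for p in ps)
    per_node = {c: search.node_score(c, ps) for c, ps in best.items()}
    return DAGModel(nodes=tuple(cols), edges=edges, per_node_scores=per_node)


# ---------------------------------------------------------------------------
# structure comparison
# ---------------------------------------------------------------------------


def skeleton(dag: DAGModel) -> frozenset[frozenset[str]]:
    return frozenset(frozenset(e) for e in dag.edges)


def v_structures(dag: DAGModel) -> frozenset[tuple[str, str, str]]:
    """Colliders a -> c <- b with a, b non-adjacent, as (a, c, b), a < b."""
    adj = skeleton(dag)
    out = set()
    for node in dag.nodes:
        ps = dag.parents(node)
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                a, b = sorted((ps[i], ps[j]))
                if frozenset((a, b)) not in adj:
                    out.add((a, node, b))
    return frozenset(out)


def structural_hamming_distance(d1: DAGModel, d2: DAGModel) -> int:
    """Edge additions + deletions + reversals separating two DAGs."""
    e1, e2 = set(d1.edges), set(d2.edges)
    s1 = {frozenset(e) for e in e1}
    s2 = {frozenset(e) for e in e2}
    added = len(s2 - s1)
    removed = len(s1 - s2)
    reversed_ = sum(
        1 for e in e1 if frozenset(e) in s2 and e not in e2
    )
    return added + removed + reversed_


def compare_structures(d1: DAGModel, d2: DAGModel) -> dict:
    """Edge-level and equivalence-class-level differences d1 -> d2."""
    e1, e2 = set(d1.edges), set(d2.edges)
    s1, s2 = skeleton(d1), skeleton(d2)
    return {
        "added": sorted(tuple(e) for e in e2 - e1 if frozenset(e) not in s1),
        "removed": sorted(tuple(e) for e in e1 - e2 if frozenset(e) not in s2),
        "reversed": sorted(tuple(e) for e in e1 if frozenset(e) in s2 and e not in e2),
        "shd": structural_hamming_distance(d1, d2),
        "skeleton_equal": s1 == s2,
        "v_structures_equal": v_structures(d1) == v_structures(d2),
        "equivalence_class_equal": s1 == s2 and v_structures(d1) == v_structures(d2),
    }


# ---------------------------------------------------------------------------
# pooling, stratified and common fits
# ---------------------------------------------------------------------------


def standardize_panel(panel: TimeSeriesPanel) -> pd.DataFrame:
    """Per-subject z-standardization of each region's time course."""
    data = panel.data
    std = data.std(axis=0, ddof=0)
    flat = list(std.index[std.to_numpy() == 0.0])
    if flat:
        raise DataError(f"zero-variance region(s) in {panel.subject_id}: {flat}")
    return (data - data.mean(axis=0)) / std


def pool_panels(panels: list[TimeSeriesPanel]) -> pd.DataFrame:
    if not panels:
        raise DataError("no panels to pool")
    frames = [standardize_panel(p) for p in panels]
    cols = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != cols:
            raise DataError("panels have mismatched region labels")
    return pd.concat(frames, ignore_index=True)


def learn_stratified(
    panels_by_group: dict[str, list[TimeSeriesPanel]],
    restarts: int = 10,
    seed: int = 0,
    **kwargs,
) -> tuple[dict[str, DAGModel], dict[tuple[str, str], dict]]:
    """Per-stratum structure learning plus pairwise structural comparison.

    Every stratum must contain at least one subject.  Strata are fit on
    the concatenation of subject-standardized time courses; comparisons
    report added/removed/reversed edges, structural Hamming distance and
    equivalence-class agreement for every stratum pair.
    """
    for group, panels in panels_by_group.items():
        if not panels:
            raise DataError(f"stratum {group!r} has no subjects")
    models = {
        group: hill_climb_structure(
            pool_panels(panels), restarts=restarts, seed=seed, **kwargs
        )
        for group, panels in panels_by_group.items()
    }
    names = sorted(models)
    comparisons = {
        (a, b): compare_structures(models[a], models[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return models, comparisons


def fit_common_model(
    panels: list[TimeSeriesPanel], restarts: int = 10, seed: int = 0, **kwargs
) -> DAGModel:
    """Best-fit common structure for the whole cohort (pooled fit)."""
    return hill_climb_structure(pool_panels(panels), restarts=restarts, seed=seed, **kwargs)


def estimate_edge_weights(
    common: DAGModel,
    panels: list[TimeSeriesPanel],
    standardize: bool = True,
    min_timepoints: int | None = None,
) -> pd.DataFrame:
    """Per-subject connectivity weights under the common model.

    Each child is regressed (with intercept) on its common-model parents
    within each subject's panel; the coefficients are recorded per edge.
    ``standardize=True`` (default) fits on z-standardized series, giving
    scale-free coefficients comparable across subjects; ``False`` fits on
    the raw series, recovering generative coefficients directly.  Children
    with no parents emit no rows.  Subjects with too few timepoints are
    skipped with a warning.
    """
    max_parents = max((len(common.parents(v)) for v in common.nodes), default=0)
    needed = min_timepoints if min_timepoints is not None else max(10, max_parents + 2)
    rows = []
    for panel in panels:
        if len(panel.data) < needed:
            warnings.warn(
                f"subject {panel.subject_id}: only {len(panel.data)} timepoints, skipped"
            )
            continue
        data = standardize_panel(panel) if standardize else panel.data
        for child in common.nodes:
            parents = common.parents(child)
            if not parents:
                continue
            y = data[child].to_numpy(float)
            design = np.column_stack(
                [np.ones(len(y))] + [data[p].to_numpy(float) for p in parents]
            )
            coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
            if rank < design.shape[1]:
                warnings.warn(
                    f"subject {panel.subject_id}: singular design for {child}, skipped"
                )
                continue
            for p, w in zip(parents, coef[1:]):
                rows.append(
                    {
                        "subject_id": panel.subject_id,
                        "parent": p,
                        "child": child,
                        "weight": float(w),
                    }
                )
    return pd.DataFrame(rows, columns=["subject_id", "parent", "child", "weight"])


def find_edges_between(
    common: DAGModel, label_a: str, label_b: str
) -> list[tuple[str, str]]:
    """Common-model edges joining regions whose names contain the two
    labels, in either orientation (direction is recorded by the returned
    (parent, child) order)."""
    out = []
    for p, c in sorted(common.edges):
        if (label_a in p and label_b in c) or (label_b in p and label_a in c):
            out.append((p, c))
    return out


# ---------------------------------------------------------------------------
# interaction ANOVA
# ---------------------------------------------------------------------------


def interaction_anova(
    weights: pd.Series | np.ndarray,
    sex: pd.Series | np.ndarray,
    impaired: pd.Series | np.ndarray,
    edge: tuple[str, str] | None = None,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA of edge weights: sex x impairment.

    Type II sums of squares (appropriate for unbalanced cells).  Requires
    at least 2 observations per crossed cell so the interaction term is
    estimable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "weight": np.asarray(weights, dtype=float),
            "sex": np.asarray(sex).astype(str),
            "impaired": np.asarray(impaired).astype(bool),
        }
    )
    counts = df.groupby(["sex", "impaired"], observed=True).size()
    for s in df["sex"].unique():
        for imp in (False, True):
            n_cell = int(counts.get((s, imp), 0))
            if n_cell < 2:
                raise DataError(
                    f"cell sex={s}, impaired={imp} has {n_cell} subject(s); need >= 2"
                )
    fit = smf.ols("weight ~ C(sex) * C(impaired)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    name_map = {
        "C(sex)": "sex",
        "C(impaired)": "impairment",
        "C(sex):C(impaired)": "interaction",
    }
    terms = {}
    for raw, name in name_map.items():
        row = table.loc[raw]
        terms[name] = {
            "F": float(row["F"]),
            "p": float(row["PR(>F)"]),
            "df": float(row["df"]),
        }
    return AnovaResult(
        terms=terms,
        residual_df=float(table.loc["Residual", "df"]),
        edge=edge,
    )
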