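"""End-to-end orchestration: simulate -> connectivity -> graph metrics ->
permutation inference -> effective connectivity -> cohort statistics.

A single global seed deterministically derives one seed per stage (stage
-name hashing), so any stage can be rerun in isolation from the seeds
recorded in the manifest.  All numeric outputs are CSV/JSON; rerunning an
identical config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .errors import ConfigurationError
from .regions import CTC_PARTITION, CTC_REGIONS, NETWORKS
from . import bayesnet, cohort_stats, connectivity, metrics, permutation, synthetic

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_all", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "connectivity", "graphs", "permtest", "bayesnet", "stats")


@dataclass
class RunConfig:
    out_dir: str = "ctcnet_run"
    seed: int = 0
    # cohort
    n_male: int = 87
    n_female: int = 89
    impairment_prevalence: float | None = None
    n_timepoints: int = 174
    include_language_network: bool = False
    # connectivity
    density_grid: list[float] = field(
        default_factory=lambda: list(connectivity.DEFAULT_DENSITY_GRID)
    )
    partition: dict[str, str] = field(default_factory=lambda: dict(CTC_PARTITION))
    # permutation
    n_perm: int = 2000
    perm_sided: str = "one"
    # bayesnet
    restarts: int = 10
    # stats
    impairment_threshold: float = synthetic.IMPAIRMENT_THRESHOLD
    fdr_method: str = "by"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def cohort_spec(self) -> synthetic.CohortSpec:
        return synthetic.CohortSpec(
            n_male=self.n_male,
            n_female=self.n_female,
            impairment_prevalence=self.impairment_prevalence,
            n_timepoints=self.n_timepoints,
            seed=self.stage_seed("simulate"),
        )

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seeds: dict[str, int]
    outputs: dict[str, list[str]]
    warnings: list[str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns a list of failures (empty if
    the config is valid)."""
    failures = []
    if config.n_male <= 0 or config.n_female <= 0:
        failures.append("cohort sizes must be positive")
    if config.n_timepoints <= 8:
        failures.append("n_timepoints must exceed the number of regions")
    if not config.density_grid:
        failures.append("density grid is empty")
    else:
        if any(not 0 < d <= 1 for d in config.density_grid):
            failures.append("density grid values must lie in (0, 1]")
        if list(config.density_grid) != sorted(config.density_grid):
            failures.append("density grid must be ascending")
    unknown_regions = set(config.partition) - set(CTC_REGIONS)
    if unknown_regions:
        failures.append(f"unknown region(s) in partition: {sorted(unknown_regions)}")
    missing_regions = set(CTC_REGIONS) - set(config.partition)
    if missing_regions:
        failures.append(f"partition missing region(s): {sorted(missing_regions)}")
    if config.n_perm < 1:
        failures.append("n_perm must be >= 1")
    if config.perm_sided not in ("one", "two"):
        failures.append("perm_sided must be 'one' or 'two'")
    if config.restarts < 1:
        failures.append("restarts must be >= 1")
    if config.fdr_method not in ("by", "bh"):
        failures.append("fdr_method must be 'by' or 'bh'")
    if config.impairment_prevalence is not None and not (
        0 <= config.impairment_prevalence <= 1
    ):
        failures.append("impairment_prevalence must lie in [0, 1]")
    return failures


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, manifest: RunManifest):
    dataset = synthetic.generate_dataset(
        config.cohort_spec(), include_language=config.include_language_network
    )
    files = dataset.write(out / "cohort")
    manifest.outputs["simulate"] = [f"cohort/{f}" for f in files]
    return dataset


def _graph_stage_for_network(
    config: RunConfig,
    panels,
    subjects: pd.DataFrame,
    partition: dict[str, str] | None,
):
    """Connectivity + metrics for one network; metrics are computed at the
    cohort-common minimum density (the largest per-subject minimum), with
    fragmented subjects flagged and still scored."""
    grid = tuple(config.density_grid)
    conn = {}
    d_mins = {}
    fragmented = {}
    for panel in panels:
        C = connectivity.compute_connectivity(panel)
        conn[panel.subject_id] = C
        result = connectivity.find_minimum_density(
            C, grid, partition=partition, subject_id=panel.subject_id
        )
        if isinstance(result, connectivity.FragmentationReport):
            fragmented[panel.subject_id] = result.disconnected
        else:
            d_mins[panel.subject_id] = result[0]
    common_density = max(d_mins.values()) if d_mins else grid[-1]
    rows = []
    node_rows = []
    for panel in panels:
        g = connectivity.threshold_at_density(
            conn[panel.subject_id], common_density, partition=partition
        )
        m = metrics.compute_metrics(g, subject_id=panel.subject_id, partition=partition)
        rows.append(
            {
                "subject_id": panel.subject_id,
                "global_efficiency": m.global_efficiency,
                "density_used": m.density_used,
                "fragmented": panel.subject_id in fragmented,
                "n_disconnected": len(m.disconnected_nodes),
                "d_min": d_mins.get(panel.subject_id, np.nan),
            }
        )
        for node, z in m.within_module_degree_z.items():
            node_rows.append(
                {"subject_id": panel.subject_id, "node": node, "within_module_degree_z": z}
            )
    table = pd.DataFrame(rows).merge(
        subjects[["subject_id", "sex", "impaired"]], on="subject_id"
    )
    return conn, table, pd.DataFrame(node_rows), common_density, fragmented


def _write_connectivity(out: Path, conn: dict, name: str, manifest: RunManifest):
    rows = []
    for sid, C in sorted(conn.items()):
        for a, b, z in C.pairs():
            rows.append({"subject_id": sid, "region_a": a, "region_b": b, "fisher_z": z})
    path = out / f"connectivity_{name}.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    manifest.outputs["connectivity"].append(path.name)


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage on a synthetic cohort and write one results
    directory with a manifest.  Raises on any stage failure."""
    failures = validate_config(config)
    if failures:
        raise ConfigurationError("invalid config: " + "; ".join(failures))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        stage_seeds={s: config.stage_seed(s) for s in STAGES},
        outputs={s: [] for s in STAGES},
        warnings=[],
    )

    # -- simulate ----------------------------------------------------------
    logger.info("stage simulate")
    dataset = _stage_simulate(config, out, manifest)
    subjects = dataset.subjects

    # -- connectivity + graphs --------------------------------------------
    logger.info("stage connectivity/graphs")
    analysis_sets = {"ctc": (dataset.panels, config.partition)}
    if config.include_language_network and dataset.language_panels:
        analysis_sets["language"] = (
            dataset.language_panels,
            NETWORKS["language"]["partition"],
        )
    graph_tables = {}
    for name, (panels, partition) in analysis_sets.items():
        conn, table, node_z, common_density, fragmented = _graph_stage_for_network(
            config, panels, subjects, partition
        )
        graph_tables[name] = table
        _write_connectivity(out, conn, name, manifest)
        table.to_csv(out / f"graph_metrics_{name}.csv", index=False)
        node_z.to_csv(out / f"node_metrics_{name}.csv", index=False)
        manifest.outputs["graphs"] += [
            f"graph_metrics_{name}.csv",
            f"node_metrics_{name}.csv",
        ]
        for sid, regions in sorted(fragmented.items()):
            manifest.warnings.append(
                f"{name}: subject {sid} fragmented (disconnected: {', '.join(regions)})"
            )
        frag = metrics.fragmentation_summary(table[["subject_id", "sex", "fragmented"]])
        frag.to_csv(out / f"fragmentation_{name}.csv", index=False)
        manifest.outputs["graphs"].append(f"fragmentation_{name}.csv")
        meta = {"common_density": common_density, "n_fragmented": len(fragmented)}
        (out / f"graphs_meta_{name}.json").write_text(json.dumps(meta, indent=2))
        manifest.outputs["graphs"].append(f"graphs_meta_{name}.json")

    # -- permutation test --------------------------------------------------
    logger.info("stage permtest")
    ctc_table = graph_tables["ctc"]
    grouping = ctc_table.set_index("subject_id")["impaired"]
    result, summary = permutation.efficiency_group_comparison(
        ctc_table,
        grouping,
        n_perm=config.n_perm,
        sided=config.perm_sided,
        seed=config.stage_seed("permtest"),
    )
    result.to_json(out / "permtest_global_efficiency.json")
    (out / "permtest_summary.json").write_text(json.dumps(summary, indent=2))
    manifest.outputs["permtest"] = [
        "permtest_global_efficiency.json",
        "permtest_summary.json",
    ]

    # -- effective connectivity -------------------------------------------
    logger.info("stage bayesnet")
    by_group: dict[str, list] = {}
    group_of = {
        row["subject_id"]: f"{row['sex']}_{'impaired' if row['impaired'] else 'unimpaired'}"
        for _, row in subjects.iterrows()
    }
    for panel in dataset.panels:
        by_group.setdefault(group_of[panel.subject_id], []).append(panel)
    bn_seed = config.stage_seed("bayesnet")
    empty = [g for g in synthetic.GROUPS if not by_group.get(g)]
    bn_dir = out / "bayesnet"
    bn_dir.mkdir(exist_ok=True)
    if empty:
        manifest.warnings.append(
            f"stratified learning skipped (empty strata: {', '.join(empty)})"
        )
    else:
        models, comparisons = bayesnet.learn_stratified(
            by_group, restarts=config.restarts, seed=bn_seed
        )
        for group, model in models.items():
            (bn_dir / f"stratified_{group}.json").write_text(
                json.dumps(model.to_dict(), indent=2)
            )
            manifest.outputs["bayesnet"].append(f"bayesnet/stratified_{group}.json")
        comp_payload = {f"{a}|{b}": c for (a, b), c in comparisons.items()}
        (bn_dir / "stratified_comparison.json").write_text(
            json.dumps(comp_payload, indent=2)
        )
        manifest.outputs["bayesnet"].append("bayesnet/stratified_comparison.json")

    common = bayesnet.fit_common_model(
        dataset.panels, restarts=config.restarts, seed=bn_seed
    )
    (bn_dir / "common_model.json").write_text(json.dumps(common.to_dict(), indent=2))
    manifest.outputs["bayesnet"].append("bayesnet/common_model.json")

    weights = bayesnet.estimate_edge_weights(common, dataset.panels)
    weights.to_csv(bn_dir / "edge_weights.csv", index=False)
    manifest.outputs["bayesnet"].append("bayesnet/edge_weights.csv")

    anova_payload = {}
    cbl_edges = bayesnet.find_edges_between(common, "cerebellum", "dlpfc")
    if cbl_edges:
        sub_meta = subjects.set_index("subject_id")
        mask = weights.apply(
            lambda r: (r["parent"], r["child"]) in cbl_edges, axis=1
        )
        per_subject = (
            weights[mask].groupby("subject_id")["weight"].mean().rename("weight")
        )
        merged = sub_meta.join(per_subject, how="inner")
        try:
            anova = bayesnet.interaction_anova(
                merged["weight"], merged["sex"], merged["impaired"]
            )
            anova_payload = {
                "edges": [list(e) for e in cbl_edges],
                "terms": anova.terms,
                "residual_df": anova.residual_df,
            }
        except Exception as exc:  # degenerate cells on tiny cohorts
            manifest.warnings.append(f"interaction ANOVA skipped: {exc}")
    else:
        manifest.warnings.append("no cerebellum-DLPFC edge in the common model")
    (bn_dir / "anova_cerebellum_dlpfc.json").write_text(
        json.dumps(anova_payload, indent=2)
    )
    manifest.outputs["bayesnet"].append("bayesnet/anova_cerebellum_dlpfc.json")

    # -- cohort statistics -------------------------------------------------
    logger.info("stage stats")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    impairment = cohort_stats.classify_impairment(
        dataset.neurocog, threshold=config.impairment_threshold
    )
    impairment.to_frame().to_csv(stats_dir / "impairment.csv", index=False)
    manifest.outputs["stats"].append("stats/impairment.csv")

    sex_of = subjects.set_index("subject_id")["sex"]
    prop_rows, test_rows = [], []
    for measure in sorted(dataset.neurocog["measure"].unique()):
        mscores = dataset.neurocog[dataset.neurocog["measure"] == measure]
        for sex in ("male", "female"):
            sel = mscores[mscores["subject_id"].map(sex_of) == sex]
            if len(sel) < 2:
                continue
            flags = sel["z"] < config.impairment_threshold
            ci = cohort_stats.impairment_proportion_ci(int(flags.sum()), len(sel))
            prop_rows.append(
                {
                    "measure": measure,
                    "sex": sex,
                    "k": ci.k,
                    "n": ci.n,
                    "percent": round(ci.proportion, 2),
                    "ci_low": round(ci.ci_low, 2),
                    "ci_high": round(ci.ci_high, 2),
                }
            )
            t, df, p = cohort_stats.one_sample_vs_reference(sel["z"])
            test_rows.append(
                {"measure": measure, "sex": sex, "t": t, "df": df, "p": p}
            )
    tests = pd.DataFrame(test_rows)
    adjusted, reject = cohort_stats.fdr_correct(
        tests["p"].to_numpy(), method=config.fdr_method
    )
    tests["p_fdr"] = adjusted
    tests["significant"] = reject
    pd.DataFrame(prop_rows).to_csv(stats_dir / "impairment_proportions.csv", index=False)
    tests.to_csv(stats_dir / "reference_tests.csv", index=False)
    manifest.outputs["stats"] += [
        "stats/impairment_proportions.csv",
        "stats/reference_tests.csv",
    ]

    glm_rows = []
    for measure, region in (
        ("rey_osterrieth_copy", "cerebellum_L_volume"),
        ("rey_osterrieth_copy", "cerebellum_R_volume"),
        ("dominant_hand_speed", "cerebellum_L_volume"),
        ("symbol_search", "cerebellum_R_volume"),
        ("digit_backward", "cerebellum_R_volume"),
    ):
        for sex in ("male", "female"):
            fit = cohort_stats.glm_brain_exposure(
                subjects, dataset.neurocog, measure, region, stratum=sex
            )
            for term in fit.coefficients.index:
                glm_rows.append(
                    {
                        "outcome": measure,
                        "region": region,
                        "sex": sex,
                        "term": term,
                        "beta": fit.beta(term),
                        "se": fit.se(term),
                        "p": fit.p(term),
                    }
                )
    pd.DataFrame(glm_rows).to_csv(stats_dir / "glm_brain_exposure.csv", index=False)
    manifest.outputs["stats"].append("stats/glm_brain_exposure.csv")

    corr_rows = []
    construct_scores = (
        dataset.neurocog.groupby(["subject_id", "construct"])["z"].mean().unstack()
    )
    for name, table in graph_tables.items():
        eff = table.set_index("subject_id")["global_efficiency"]
        for construct in construct_scores.columns:
            joined = pd.concat([eff, construct_scores[construct]], axis=1).dropna()
            if joined.iloc[:, 0].nunique() < 2 or joined.iloc[:, 1].nunique() < 2:
                continue
            r, p = cohort_stats.correlate(joined.iloc[:, 0], joined.iloc[:, 1])
            corr_rows.append(
                {"network": name, "construct": construct, "r": r, "p": p, "n": len(joined)}
            )
    corr = pd.DataFrame(corr_rows)
    if not corr.empty:
        adj, rej = cohort_stats.fdr_correct(corr["p"].to_numpy(), method=config.fdr_method)
        corr["p_fdr"] = adj
        corr["significant"] = rej
    corr.to_csv(stats_dir / "efficiency_correlations.csv", index=False)
    manifest.outputs["stats"].append("stats/efficiency_correlations.csv")

    manifest.write(out / "manifest.json")
    return manifest
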