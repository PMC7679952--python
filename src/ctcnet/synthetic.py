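"""Synthetic cohort generator.

The real study population — survivors of childhood acute lymphoblastic
leukemia treated on a chemotherapy-only protocol — is not publicly
deposited, so every downstream stage of this package is exercised on
synthetic data whose statistical structure matches what the analyses
assume:

* a subject table (sex, ages, intracranial volume, regional morphometry,
  dexamethasone/methotrexate exposure, intrathecal count) whose means and
  spreads emulate the published survivor cohort;
* age-adjusted neurocognitive z-scores drawn per measure from configurable
  linear models ``z = mean + sum(beta * covariate) + noise``;
* ROI time series generated from group-specific linear-Gaussian directed
  networks over the 8-region cerebello-thalamo-cortical circuit.  All
  groups share a common structure (cerebellum -> thalamus,
  cerebellum -> DLPFC, precuneus -> DLPFC, per hemisphere) except impaired
  females, whose cerebellum--DLPFC edge is reversed (DLPFC -> cerebellum)
  and attenuated and whose DLPFC--precuneus edge is absent.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import derive_seed
from .errors import ConfigurationError, DataError
from .regions import CTC_REGIONS, LANGUAGE_REGIONS

__all__ = [
    "EffectConfig",
    "CohortSpec",
    "GroundTruthNetwork",
    "TimeSeriesPanel",
    "MeasureSpec",
    "NeurocogModel",
    "SyntheticDataset",
    "generate_cohort",
    "build_ground_truth",
    "simulate_timeseries",
    "generate_neurocog",
    "generate_dataset",
    "GROUPS",
    "EXECUTIVE_MEASURES",
    "IMPAIRMENT_THRESHOLD",
]

GROUPS = (
    "male_unimpaired",
    "male_impaired",
    "female_unimpaired",
    "female_impaired",
)

#: Executive-function measures entering the impairment rule.
EXECUTIVE_MEASURES = (
    "number_letter_switch",
    "color_word_switch",
    "verbal_fluency",
    "digit_backward",
    "rey_osterrieth_copy",
    "twenty_questions",
)

#: Any executive z strictly below this value classifies a subject as
#: impaired (operational 10th percentile of the age-adjusted z).
IMPAIRMENT_THRESHOLD = -1.3


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectConfig:
    """Group-specific edge rewiring and effect sizes for the generator.

    baseline_weight
        Coefficient on every edge of the shared ground-truth structure.
    reversed_weight
        Coefficient on the reversed DLPFC -> cerebellum edge in impaired
        females.  Smaller than baseline because the planted group effect is
        a change in both direction *and* strength of coupling (a pure
        direction flip within a linear-Gaussian model is Markov-equivalent
        and hence undetectable from observational data alone).
    noise_sd
        Residual standard deviation of every node.
    ar_coef
        Optional AR(1) smoothing of node innovations (0 = white noise).
    """

    baseline_weight: float = 0.5
    reversed_weight: float = 0.25
    noise_sd: float = 1.0
    ar_coef: float = 0.0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("effect_config.noise_sd must be > 0")
        if not 0 <= self.ar_coef < 1:
            raise ConfigurationError("effect_config.ar_coef must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults reproduce the study conditions: 87 male and 89 female
    survivors; 174 fMRI volumes (six minutes of rest at TR 2.06 s, a
    derived default since the retained volume count is not reported);
    impairment derived from generated executive scores unless an explicit
    per-sex prevalence is supplied.
    """

    n_male: int = 87
    n_female: int = 89
    impairment_prevalence: float | dict[str, float] | None = None
    n_regions: int = 8
    n_timepoints: int = 174
    seed: int = 0
    effect_config: EffectConfig = field(default_factory=EffectConfig)

    def prevalence_for(self, sex: str) -> float | None:
        if self.impairment_prevalence is None:
            return None
        if isinstance(self.impairment_prevalence, dict):
            return float(self.impairment_prevalence[sex])
        return float(self.impairment_prevalence)

    def validate(self) -> None:
        if self.n_male <= 0:
            raise ConfigurationError("n_male must be positive")
        if self.n_female <= 0:
            raise ConfigurationError("n_female must be positive")
        if self.n_regions <= 0:
            raise ConfigurationError("n_regions must be positive")
        if self.n_timepoints <= self.n_regions:
            raise ConfigurationError("n_timepoints must exceed n_regions")
        for sex in ("male", "female"):
            p = self.prevalence_for(sex)
            if p is not None and not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"impairment_prevalence for {sex} must lie in [0, 1]"
                )
        self.effect_config.validate()


# ---------------------------------------------------------------------------
# ground-truth directed networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A linear-Gaussian structural model: acyclic weighted digraph plus
    per-node residual noise."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # (parent, child)
    weights: dict[tuple[str, str], float]
    noise_sd: dict[str, float]

    def validate(self) -> None:
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise ConfigurationError("ground-truth network contains a cycle")
        for e in self.edges:
            if not np.isfinite(self.weights[e]):
                raise ConfigurationError(f"non-finite weight on edge {e}")
        for node, sd in self.noise_sd.items():
            if sd <= 0:
                raise ConfigurationError(f"noise_sd for {node} must be > 0")
        if self.spectral_radius() >= 1.0:
            raise ConfigurationError(
                "weight matrix spectral radius must be < 1 for stationarity"
            )

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def weight_matrix(self) -> np.ndarray:
        """W[i, j] = coefficient of parent i in the equation of child j."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        w = np.zeros((len(self.nodes), len(self.nodes)))
        for (parent, child), coef in self.weights.items():
            w[idx[parent], idx[child]] = coef
        return w

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.weight_matrix()))))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_digraph()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": list(self.nodes),
            "edges": [
                {"parent": p, "child": c, "weight": self.weights[(p, c)]}
                for p, c in self.edges
            ],
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthNetwork":
        payload = json.loads(Path(path).read_text())
        edges = tuple((e["parent"], e["child"]) for e in payload["edges"])
        weights = {(e["parent"], e["child"]): float(e["weight"]) for e in payload["edges"]}
        return cls(
            nodes=tuple(payload["nodes"]),
            edges=edges,
            weights=weights,
            noise_sd={k: float(v) for k, v in payload["noise_sd"].items()},
        )


def _ctc_baseline_edges() -> list[tuple[str, str]]:
    edges = []
    for h in ("L", "R"):
        edges += [
            (f"cerebellum_{h}", f"thalamus_{h}"),
            (f"cerebellum_{h}", f"dlpfc_{h}"),
            (f"precuneus_{h}", f"dlpfc_{h}"),
        ]
    return edges


def build_ground_truth(
    group: str,
    effect_config: EffectConfig | None = None,
    custom_edges: dict[tuple[str, str], float] | None = None,
) -> GroundTruthNetwork:
    """Ground-truth effective-connectivity structure for one group.

    Unimpaired groups and impaired males share the common structure
    (cerebellum and precuneus both condition DLPFC activity; the cerebellum
    drives the thalamus).  In impaired females the cerebellum--DLPFC edge
    is reversed and attenuated and the DLPFC--precuneus edge is absent.

    ``custom_edges`` overrides the edge/weight map entirely (validated for
    acyclicity), for experiments with alternative planted structures.
    """
    cfg = effect_config or EffectConfig()
    cfg.validate()
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}; expected one of {GROUPS}")

    if custom_edges is not None:
        weights = dict(custom_edges)
    elif group == "female_impaired":
        weights = {}
        for h in ("L", "R"):
            weights[(f"cerebellum_{h}", f"thalamus_{h}")] = cfg.baseline_weight
            weights[(f"dlpfc_{h}", f"cerebellum_{h}")] = cfg.reversed_weight
    else:
        weights = {e: cfg.baseline_weight for e in _ctc_baseline_edges()}

    net = GroundTruthNetwork(
        nodes=tuple(CTC_REGIONS),
        edges=tuple(weights),
        weights=weights,
        noise_sd={r: cfg.noise_sd for r in CTC_REGIONS},
    )
    net.validate()
    return net


def build_language_network(weight: float = 0.25, noise_sd: float = 1.0) -> GroundTruthNetwork:
    """Weakly coupled control network (identical in every group): within
    each hemisphere BA44 -> BA45 and BA40 -> BA44."""
    weights = {}
    for h in ("L", "R"):
        weights[(f"ba44_{h}", f"ba45_{h}")] = weight
        weights[(f"ba40_{h}", f"ba44_{h}")] = weight
    net = GroundTruthNetwork(
        nodes=tuple(LANGUAGE_REGIONS),
        edges=tuple(weights),
        weights=weights,
        noise_sd={r: noise_sd for r in LANGUAGE_REGIONS},
    )
    net.validate()
    return net


# ---------------------------------------------------------------------------
# time-series simulation
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesPanel:
    """Per-subject ROI time-series matrix (timepoints x regions)."""

    subject_id: str
    data: pd.DataFrame

    def validate(self) -> None:
        if self.data.isna().any().any():
            raise DataError(f"panel {self.subject_id}: missing values")
        if self.data.shape[1] < 2:
            raise DataError(f"panel {self.subject_id}: need >= 2 regions")

    def zero_variance_regions(self) -> list[str]:
        std = self.data.std(axis=0, ddof=0)
        return list(std.index[std.to_numpy() == 0.0])

    @property
    def regions(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, subject_id: str | None = None) -> "TimeSeriesPanel":
        path = Path(path)
        return cls(subject_id=subject_id or path.stem, data=pd.read_csv(path))


def simulate_timeseries(
    network: GroundTruthNetwork,
    n_timepoints: int,
    seed: int,
    subject_id: str = "sim",
    ar_coef: float | None = None,
) -> TimeSeriesPanel:
    """Simulate ROI signals from a linear-Gaussian structural model.

    Each timepoint is generated by evaluating nodes in topological order:
    ``child = sum(weight * parent) + noise``.  With ``ar_coef > 0`` the
    node innovations follow a stationary AR(1) process (variance held at
    ``noise_sd**2``), giving temporally smoothed signals whose
    contemporaneous dependence structure is unchanged.
    """
    if n_timepoints < 10:
        raise ConfigurationError("n_timepoints must be >= 10")
    network.validate()
    rho = 0.0 if ar_coef is None else float(ar_coef)
    rng = np.random.default_rng(seed)
    nodes = list(network.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    sds = np.array([network.noise_sd[n] for n in nodes])

    noise = rng.standard_normal((n_timepoints, len(nodes)))
    if rho:
        if not 0 <= rho < 1:
            raise ConfigurationError("ar_coef must be in [0, 1)")
        smoothed = np.empty_like(noise)
        smoothed[0] = noise[0]
        scale = np.sqrt(1.0 - rho**2)
        for t in range(1, n_timepoints):
            smoothed[t] = rho * smoothed[t - 1] + scale * noise[t]
        noise = smoothed
    noise *= sds

    x = np.zeros_like(noise)
    parents = {n: [] for n in nodes}
    for parent, child in network.edges:
        parents[child].append(parent)
    for node in network.topological_order():
        j = idx[node]
        x[:, j] = noise[:, j]
        for parent in parents[node]:
            x[:, j] += network.weights[(parent, node)] * x[:, idx[parent]]

    return TimeSeriesPanel(subject_id=subject_id, data=pd.DataFrame(x, columns=nodes))


# ---------------------------------------------------------------------------
# subject table
# ---------------------------------------------------------------------------

# Morphometry emulation: per-sex (mean, SD) for regional volumes (mm^3) and
# cortical thicknesses (mm) in survivors, loosely anchored to published
# survivor-cohort summaries; intracranial volume is a free scale parameter.
_MORPHOMETRY = {
    "male": {
        "icv": (1.55e6, 1.3e5),
        "cerebellum_L_volume": (77437.0, 6030.0),
        "cerebellum_R_volume": (77232.0, 6390.0),
        "thalamus_L_volume": (8001.0, 829.0),
        "thalamus_R_volume": (8142.0, 907.0),
        "precuneus_L_thickness": (2.60, 0.18),
        "precuneus_R_thickness": (2.57, 0.17),
        "dlpfc_L_thickness": (2.86, 0.17),
        "dlpfc_R_thickness": (2.85, 0.16),
    },
    "female": {
        "icv": (1.40e6, 1.2e5),
        "cerebellum_L_volume": (70611.0, 6540.0),
        "cerebellum_R_volume": (70525.0, 6390.0),
        "thalamus_L_volume": (7457.0, 801.0),
        "thalamus_R_volume": (7546.0, 971.0),
        "precuneus_L_thickness": (2.48, 0.35),
        "precuneus_R_thickness": (2.59, 0.17),
        "dlpfc_L_thickness": (2.88, 0.19),
        "dlpfc_R_thickness": (2.88, 0.20),
    },
}

#: Columns treated as volumetric (coupled to intracranial volume).
_ICV_COUPLING = 0.3

_EXPOSURES = {
    # exposure scales are free parameters; chosen so regression
    # coefficients of realistic magnitude are numerically stable
    "dex_auc": (6000.0, 1500.0),  # g x hr / L scaled
    "mtx_auc": (4000.0, 1200.0),
}


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the subject table.

    Returns exactly ``n_male + n_female`` records.  If the spec states an
    impairment prevalence, the ``impaired`` flag is a per-sex binomial
    draw (scores generated later are made consistent with it); otherwise
    the flag starts ``False`` and is derived from generated executive
    scores by :func:`generate_dataset`.
    """
    spec.validate()
    rng = np.random.default_rng(derive_seed(spec.seed, "cohort"))
    rows = []
    for sex, n in (("male", spec.n_male), ("female", spec.n_female)):
        morph = _MORPHOMETRY[sex]
        icv_mean, icv_sd = morph["icv"]
        icv_z = rng.standard_normal(n)
        age_dx = np.clip(rng.normal(6.8, 4.5, n), 1.0, 18.0)
        years_since = np.clip(rng.normal(7.7, 1.7, n), 5.0, 12.0)
        prevalence = spec.prevalence_for(sex)
        if prevalence is None:
            impaired = np.zeros(n, dtype=bool)
        else:
            impaired = rng.random(n) < prevalence
        for i in range(n):
            rec = {
                "subject_id": f"{sex[0].upper()}{i + 1:03d}",
                "sex": sex,
                "age_dx": round(float(age_dx[i]), 2),
                "age_eval": round(float(age_dx[i] + years_since[i]), 2),
                "icv": float(icv_mean + icv_sd * icv_z[i]),
            }
            for col, (mu, sd) in morph.items():
                if col == "icv":
                    continue
                rec[col] = float(
                    mu
                    + sd * _ICV_COUPLING * icv_z[i]
                    + sd * np.sqrt(1 - _ICV_COUPLING**2) * rng.standard_normal()
                )
            for col, (mu, sd) in _EXPOSURES.items():
                rec[col] = float(np.clip(rng.normal(mu, sd), 0.0, None))
            rec["it_count"] = int(rng.integers(13, 26))
            rec["impaired"] = bool(impaired[i])
            rows.append(rec)
    table = pd.DataFrame(rows)
    if (table["age_eval"] < table["age_dx"]).any():
        raise ConfigurationError("generated age_eval < age_dx")  # pragma: no cover
    return table


# ---------------------------------------------------------------------------
# neurocognitive scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasureSpec:
    """One neurocognitive measure: per-sex reference mean/SD of the
    age-adjusted z-score plus optional linear covariate effects.

    ``betas`` maps subject-table column -> slope; covariates are centered
    at their per-sex cohort mean before the slope applies, so configured
    means stay interpretable as group means.  All z-scores are stored with
    lower = worse (timed measures sign-flipped at ingestion).
    """

    name: str
    construct: str
    executive: bool
    mean: dict[str, float]
    sd: dict[str, float]
    betas: dict[str, float] = field(default_factory=dict)


def _default_measures() -> tuple[MeasureSpec, ...]:
    # (male mean, male sd, female mean, female sd) emulating the survivor
    # cohort's published score distributions
    table = {
        "number_letter_switch": ("flexibility", True, -0.74, 1.14, -0.38, 1.23),
        "color_word_switch": ("flexibility", True, -0.34, 0.95, -0.07, 1.03),
        "verbal_fluency": ("fluency", True, -0.49, 1.03, -0.25, 0.93),
        "categorical_fluency": ("fluency", False, 0.03, 1.15, -0.01, 0.99),
        "digit_backward": ("working_memory", True, -0.33, 1.03, -0.25, 0.96),
        "spatial_backward": ("working_memory", False, -0.05, 0.98, -0.02, 1.00),
        "rey_osterrieth_copy": ("organization", True, -2.44, 2.37, -2.33, 2.45),
        "twenty_questions": ("organization", True, -0.12, 1.11, -0.24, 0.94),
        "tower": ("organization", False, -0.18, 0.87, -0.05, 0.83),
        "dominant_hand_speed": ("motor_speed", False, -1.48, 1.50, -1.16, 1.57),
        "symbol_search": ("visual_speed", False, -0.25, 1.06, 0.14, 0.99),
        "digit_symbol": ("visual_motor", False, -0.70, 0.90, -0.10, 0.93),
        "number_sequencing": ("visual_motor", False, -0.25, 0.99, -0.18, 1.15),
        "letter_sequencing": ("visual_motor", False, -0.47, 1.18, -0.23, 1.12),
    }
    # modest planted brain-exposure effects (z units per covariate unit)
    betas = {
        "rey_osterrieth_copy": {"cerebellum_L_volume": 5e-5, "dex_auc": -5e-5},
        "dominant_hand_speed": {"cerebellum_L_volume": 5e-5},
        "symbol_search": {"cerebellum_R_volume": 4e-5},
    }
    return tuple(
        MeasureSpec(
            name=name,
            construct=construct,
            executive=execu,
            mean={"male": mm, "female": fm},
            sd={"male": ms, "female": fs},
            betas=betas.get(name, {}),
        )
        for name, (construct, execu, mm, ms, fm, fs) in table.items()
    )


@dataclass(frozen=True)
class NeurocogModel:
    measures: tuple[MeasureSpec, ...] = field(default_factory=_default_measures)

    def measure(self, name: str) -> MeasureSpec:
        for m in self.measures:
            if m.name == name:
                return m
        raise ConfigurationError(f"unknown measure {name!r}")

    @property
    def executive_measures(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measures if m.executive)


def _measure_means(
    subjects: pd.DataFrame, measure: MeasureSpec, centers: dict[str, pd.Series]
) -> np.ndarray:
    mu = subjects["sex"].map(measure.mean).to_numpy(float)
    for cov, beta in measure.betas.items():
        if cov not in subjects.columns:
            raise DataError(f"measure {measure.name!r} references missing covariate {cov!r}")
        centered = subjects[cov].to_numpy(float) - centers[cov].to_numpy(float)
        mu = mu + beta * centered
    return mu


def generate_neurocog(
    subjects: pd.DataFrame,
    model: NeurocogModel | None = None,
    seed: int = 0,
    condition_on_impairment: bool = False,
    threshold: float = IMPAIRMENT_THRESHOLD,
    max_rounds: int = 500,
) -> pd.DataFrame:
    """Generate the long-format neurocognitive z-score table.

    With ``condition_on_impairment=True`` the executive scores of each
    subject are rejection-sampled until they agree with the subject's
    pre-assigned ``impaired`` flag (impaired: at least one executive z
    below the threshold; unimpaired: none), so label and score are always
    consistent.  Unconditional generation (the default) leaves labels to
    be derived from the scores.
    """
    model = model or NeurocogModel()
    rng = np.random.default_rng(derive_seed(seed, "neurocog"))
    n = len(subjects)
    # per-sex covariate centers used for beta centering
    numeric = subjects.select_dtypes("number")
    centers = {
        col: subjects.groupby("sex")[col].transform("mean") for col in numeric.columns
    }

    sds = {}
    means = {}
    scores = {}
    for m in model.measures:
        means[m.name] = _measure_means(subjects, m, centers)
        sds[m.name] = subjects["sex"].map(m.sd).to_numpy(float)
        scores[m.name] = means[m.name] + sds[m.name] * rng.standard_normal(n)

    if condition_on_impairment:
        execu = list(model.executive_measures)
        target = subjects["impaired"].to_numpy(bool)
        for _ in range(max_rounds):
            mat = np.column_stack([scores[m] for m in execu])
            derived = (mat < threshold).any(axis=1)
            bad = derived != target
            if not bad.any():
                break
            for m in execu:
                redraw = means[m][bad] + sds[m][bad] * rng.standard_normal(int(bad.sum()))
                scores[m][bad] = redraw
        else:  # pragma: no cover - vanishingly unlikely at default settings
            raise RuntimeError("rejection sampling failed to match impairment labels")

    records = []
    for m in model.measures:
        for sid, z in zip(subjects["subject_id"], scores[m.name]):
            records.append(
                {"subject_id": sid, "measure": m.name, "construct": m.construct, "z": float(z)}
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    spec: CohortSpec
    subjects: pd.DataFrame
    neurocog: pd.DataFrame
    networks: dict[str, GroundTruthNetwork]
    panels: list[TimeSeriesPanel]
    language_panels: list[TimeSeriesPanel] | None = None

    def group_of(self, subject_id: str) -> str:
        row = self.subjects.set_index("subject_id").loc[subject_id]
        return f"{row['sex']}_{'impaired' if row['impaired'] else 'unimpaired'}"

    def write(self, out_dir: str | Path) -> list[str]:
        """Write subjects/neurocog CSVs, network JSONs, one CSV per panel
        and a manifest; returns the list of files written (relative)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        self.subjects.to_csv(out / "subjects.csv", index=False)
        written.append("subjects.csv")
        self.neurocog.to_csv(out / "neurocog.csv", index=False)
        written.append("neurocog.csv")
        (out / "networks").mkdir(exist_ok=True)
        for group, net in self.networks.items():
            net.to_json(out / "networks" / f"{group}.json")
            written.append(f"networks/{group}.json")
        (out / "panels").mkdir(exist_ok=True)
        for panel in self.panels:
            panel.to_csv(out / "panels" / f"{panel.subject_id}.csv")
            written.append(f"panels/{panel.subject_id}.csv")
        if self.language_panels:
            (out / "language_panels").mkdir(exist_ok=True)
            for panel in self.language_panels:
                panel.to_csv(out / "language_panels" / f"{panel.subject_id}.csv")
                written.append(f"language_panels/{panel.subject_id}.csv")
        manifest = {
            "n_subjects": int(len(self.subjects)),
            "seed": self.spec.seed,
            "n_timepoints": self.spec.n_timepoints,
            "panels": [p.subject_id for p in self.panels],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        written.append("manifest.json")
        return written


def generate_dataset(
    spec: CohortSpec,
    model: NeurocogModel | None = None,
    include_language: bool = False,
) -> SyntheticDataset:
    """Generate a complete synthetic study: subjects, scores, ground-truth
    networks, and per-subject ROI time series.

    When the spec states no impairment prevalence (the default), the
    ``impaired`` label is derived from the generated executive scores
    (any executive z < -1.3), so labels and scores are consistent by
    construction and prevalence is emergent.
    """
    spec.validate()
    model = model or NeurocogModel()
    subjects = generate_cohort(spec)
    condition = spec.impairment_prevalence is not None
    neurocog = generate_neurocog(
        subjects,
        model,
        seed=spec.seed,
        condition_on_impairment=condition,
    )
    if not condition:
        execu = set(model.executive_measures)
        flagged = (
            neurocog[neurocog["measure"].isin(execu)]
            .assign(flag=lambda d: d["z"] < IMPAIRMENT_THRESHOLD)
            .groupby("subject_id")["flag"]
            .any()
        )
        subjects = subjects.assign(
            impaired=subjects["subject_id"].map(flagged).fillna(False).astype(bool)
        )

    networks = {g: build_ground_truth(g, spec.effect_config) for g in GROUPS}
    panels = []
    language_panels = [] if include_language else None
    lang_net = build_language_network() if include_language else None
    for _, row in subjects.iterrows():
        sid = row["subject_id"]
        group = f"{row['sex']}_{'impaired' if row['impaired'] else 'unimpaired'}"
        panels.append(
            simulate_timeseries(
                networks[group],
                spec.n_timepoints,
                seed=derive_seed(spec.seed, f"panel:{sid}"),
                subject_id=sid,
                ar_coef=spec.effect_config.ar_coef,
            )
        )
        if include_language:
            language_panels.append(
                simulate_timeseries(
                    lang_net,
                    spec.n_timepoints,
                    seed=derive_seed(spec.seed, f"language:{sid}"),
                    subject_id=sid,
                )
            )
    return SyntheticDataset(
        spec=spec,
        subjects=subjects,
        neurocog=neurocog,
        networks=networks,
        panels=panels,
        language_panels=language_panels,
    )
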