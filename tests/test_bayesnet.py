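"""Structure learning: BIC oracle, hill-climbing, stratified comparison,
edge weights, interaction ANOVA."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from ctcnet.bayesnet import (
    DAGModel,
    compare_structures,
    estimate_edge_weights,
    find_edges_between,
    fit_common_model,
    gaussian_bic_score,
    hill_climb_structure,
    interaction_anova,
    learn_stratified,
    node_bic_score,
    skeleton,
    structural_hamming_distance,
    v_structures,
)
from ctcnet.errors import DataError
from ctcnet.synthetic import (
    CohortSpec,
    EffectConfig,
    build_ground_truth,
    generate_dataset,
    simulate_timeseries,
)


def all_dags(nodes):
    """Enumerate every labeled DAG on the given nodes (oracle)."""
    pairs = [(a, b) for a, b in product(nodes, nodes) if a != b]
    for r in range(len(pairs) + 1):
        for subset in combinations(pairs, r):
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(subset)
            if nx.is_directed_acyclic_graph(g):
                yield frozenset(subset)


def best_dag_score_oracle(data, nodes):
    best = -np.inf
    for edges in all_dags(nodes):
        model = DAGModel(nodes=tuple(nodes), edges=edges)
        score = gaussian_bic_score(data, model)
        best = max(best, score)
    return best


class TestGaussianBicScore:
    def test_empty_graph_matches_direct_formula(self, rng):
        n = 400
        x = rng.standard_normal((n, 3))
        data = pd.DataFrame(x, columns=list("abc"))
        model = DAGModel(nodes=("a", "b", "c"), edges=frozenset())
        expected = sum(
            -(n / 2) * np.log(np.var(x[:, j])) - np.log(n) for j in range(3)
        )
        assert gaussian_bic_score(data, model) == pytest.approx(expected, rel=1e-10)

    def test_true_parent_strictly_improves_score(self, rng):
        n = 1000
        a = rng.standard_normal(n)
        b = 0.8 * a + rng.standard_normal(n)
        data = pd.DataFrame({"a": a, "b": b})
        empty = DAGModel(nodes=("a", "b"), edges=frozenset())
        with_edge = DAGModel(nodes=("a", "b"), edges=frozenset({("a", "b")}))
        assert gaussian_bic_score(data, with_edge) > gaussian_bic_score(data, empty)

    def test_invariant_to_column_order(self, rng):
        x = rng.standard_normal((200, 3))
        data = pd.DataFrame(x, columns=list("abc"))
        model = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("a", "c")}))
        assert gaussian_bic_score(data, model) == pytest.approx(
            gaussian_bic_score(data[["c", "a", "b"]], model), rel=1e-12
        )

    def test_score_decomposes_over_nodes(self, rng):
        """A single-edge change only moves the affected node's score."""
        x = rng.standard_normal((300, 3))
        before = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("a", "b")}))
        after = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("a", "b"), ("a", "c")}))
        data = pd.DataFrame(x, columns=list("abc"))
        delta_total = gaussian_bic_score(data, after) - gaussian_bic_score(data, before)
        delta_node = node_bic_score(x, 2, (0,)) - node_bic_score(x, 2, ())
        assert delta_total == pytest.approx(delta_node, rel=1e-10)

    def test_cyclic_model_rejected(self):
        with pytest.raises(DataError, match="cycle"):
            DAGModel(nodes=("a", "b"), edges=frozenset({("a", "b"), ("b", "a")}))


class TestHillClimb:
    def test_independent_noise_yields_empty_graph(self):
        # BIC admits a spurious edge only when a sample correlation exceeds
        # ~sqrt(log(n)/n) by chance, so the empty graph should dominate
        # across repeated seeds (and never grow beyond a single false edge)
        n_empty = 0
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal((1000, 4))
            model = hill_climb_structure(
                pd.DataFrame(x, columns=list("abcd")), restarts=3, seed=seed
            )
            n_empty += model.edges == frozenset()
            assert len(model.edges) <= 1
        assert n_empty >= 8

    def test_collider_identified(self, rng):
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x3 = x1 + x2 + rng.standard_normal(n)
        data = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        model = hill_climb_structure(data, restarts=5, seed=0)
        assert ("x1", "x3") in model.edges
        assert ("x2", "x3") in model.edges
        assert frozenset(("x1", "x2")) not in skeleton(model)

    def test_matches_exhaustive_dag_oracle_on_three_nodes(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(200)
            b = 0.7 * a + rng.standard_normal(200)
            c = 0.5 * b + rng.standard_normal(200)
            data = pd.DataFrame({"a": a, "b": b, "c": c})
            model = hill_climb_structure(data, restarts=5, seed=seed)
            assert model.total_score == pytest.approx(
                best_dag_score_oracle(data, ("a", "b", "c")), rel=1e-9
            )

    def test_never_scores_below_empty_graph(self, rng):
        x = rng.standard_normal((150, 5))
        data = pd.DataFrame(x, columns=list("abcde"))
        model = hill_climb_structure(data, restarts=4, seed=1)
        empty = DAGModel(nodes=tuple("abcde"), edges=frozenset())
        assert model.total_score >= gaussian_bic_score(data, empty) - 1e-9

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((300, 4))
        x[:, 1] += 0.6 * x[:, 0]
        data = pd.DataFrame(x, columns=list("abcd"))
        m1 = hill_climb_structure(data, restarts=5, seed=42)
        m2 = hill_climb_structure(data, restarts=5, seed=42)
        assert m1.edges == m2.edges
        assert m1.total_score == m2.total_score

    def test_forbidden_edges_respected(self, rng):
        n = 1500
        a = rng.standard_normal(n)
        b = 0.9 * a + 0.3 * rng.standard_normal(n)
        data = pd.DataFrame({"a": a, "b": b})
        model = hill_climb_structure(
            data, restarts=3, seed=0, forbidden_edges={("a", "b"), ("b", "a")}
        )
        assert model.edges == frozenset()

    def test_non_finite_data_rejected(self):
        data = pd.DataFrame({"a": [1.0, np.nan, 2.0] * 10, "b": np.ones(30)})
        with pytest.raises(DataError):
            hill_climb_structure(data, restarts=1, seed=0)


class TestStructureComparison:
    def test_shd_counts_moves(self):
        d1 = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("a", "b"), ("b", "c")}))
        d2 = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("b", "a")}))
        # reverse a->b, delete b->c
        assert structural_hamming_distance(d1, d2) == 2

    def test_v_structures_require_nonadjacent_parents(self):
        collider = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("a", "c"), ("b", "c")}))
        assert v_structures(collider) == frozenset({("a", "c", "b")})
        shielded = DAGModel(
            nodes=("a", "b", "c"), edges=frozenset({("a", "c"), ("b", "c"), ("a", "b")})
        )
        assert v_structures(shielded) == frozenset()

    def test_equivalence_class_comparison(self):
        chain1 = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("a", "b"), ("b", "c")}))
        chain2 = DAGModel(nodes=("a", "b", "c"), edges=frozenset({("b", "a"), ("b", "c")}))
        comp = compare_structures(chain1, chain2)
        assert comp["skeleton_equal"] and comp["equivalence_class_equal"]
        assert comp["shd"] == 1  # one reversal at the raw-DAG level


class TestStratifiedLearning:
    def test_planted_rewiring_distinguishes_female_strata(self):
        """The identifiable signature of the impaired-female rewiring: the
        DLPFC--precuneus adjacency and the collider at DLPFC disappear."""
        cfg = EffectConfig()
        nets = {
            "female_unimpaired": build_ground_truth("female_unimpaired", cfg),
            "female_impaired": build_ground_truth("female_impaired", cfg),
        }
        panels = {
            g: [simulate_timeseries(net, 400, seed=100 + i, subject_id=f"{g}{i}") for i in range(4)]
            for g, net in nets.items()
        }
        models, comparisons = learn_stratified(panels, restarts=3, seed=1)
        skel_unimp = skeleton(models["female_unimpaired"])
        skel_imp = skeleton(models["female_impaired"])
        assert frozenset(("dlpfc_L", "precuneus_L")) in skel_unimp
        assert frozenset(("dlpfc_L", "precuneus_L")) not in skel_imp
        assert ("cerebellum_L", "dlpfc_L", "precuneus_L") in v_structures(
            models["female_unimpaired"]
        )
        comp = comparisons[("female_impaired", "female_unimpaired")]
        assert comp["shd"] > 0

    def test_identical_data_gives_identical_models(self, rng):
        net = build_ground_truth("male_unimpaired")
        panels = [simulate_timeseries(net, 300, seed=7, subject_id="s")]
        models, comparisons = learn_stratified(
            {"g1": panels, "g2": panels}, restarts=2, seed=3
        )
        assert models["g1"].edges == models["g2"].edges
        assert comparisons[("g1", "g2")]["shd"] == 0

    def test_empty_stratum_rejected(self):
        with pytest.raises(DataError, match="g2"):
            learn_stratified({"g1": [simulate_timeseries(build_ground_truth("male_unimpaired"), 50, seed=1)], "g2": []})


class TestEdgeWeights:
    def test_generating_weight_recovered_raw_scale(self):
        net = build_ground_truth("male_unimpaired")
        common = DAGModel(nodes=net.nodes, edges=frozenset(net.edges))
        panel = simulate_timeseries(net, 500, seed=55, subject_id="s1")
        w = estimate_edge_weights(common, [panel], standardize=False)
        for _, row in w.iterrows():
            assert row["weight"] == pytest.approx(0.5, abs=0.1)

    def test_absent_generating_edge_estimated_near_zero(self):
        net = build_ground_truth("male_unimpaired", custom_edges={})
        common = DAGModel(
            nodes=net.nodes, edges=frozenset({("cerebellum_L", "dlpfc_L")})
        )
        panel = simulate_timeseries(net, 500, seed=56, subject_id="s1")
        w = estimate_edge_weights(common, [panel], standardize=False)
        assert abs(w["weight"].iloc[0]) < 0.1

    def test_parentless_children_emit_no_rows(self):
        net = build_ground_truth("male_unimpaired")
        common = DAGModel(nodes=net.nodes, edges=frozenset(net.edges))
        panel = simulate_timeseries(net, 200, seed=57, subject_id="s1")
        w = estimate_edge_weights(common, [panel])
        assert set(w["child"]) == {"thalamus_L", "thalamus_R", "dlpfc_L", "dlpfc_R"}

    def test_short_panel_skipped_with_warning(self):
        net = build_ground_truth("male_unimpaired")
        common = DAGModel(nodes=net.nodes, edges=frozenset(net.edges))
        short = simulate_timeseries(net, 12, seed=58, subject_id="tiny")
        with pytest.warns(UserWarning, match="tiny"):
            w = estimate_edge_weights(common, [short], min_timepoints=50)
        assert w.empty

    def test_find_edges_between_matches_either_orientation(self):
        model = DAGModel(
            nodes=("cerebellum_L", "dlpfc_L", "precuneus_L"),
            edges=frozenset({("dlpfc_L", "cerebellum_L"), ("precuneus_L", "dlpfc_L")}),
        )
        assert find_edges_between(model, "cerebellum", "dlpfc") == [
            ("dlpfc_L", "cerebellum_L")
        ]


class TestInteractionAnova:
    @staticmethod
    def balanced_frame(cell_means, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (sex, imp), mu in cell_means.items():
            for _ in range(n):
                rows.append(
                    {"sex": sex, "impaired": imp, "weight": mu + noise * rng.standard_normal()}
                )
        return pd.DataFrame(rows)

    def test_pure_interaction_dominates_as_noise_vanishes(self):
        cells = {
            ("male", False): 0.0,
            ("male", True): 0.0,
            ("female", False): 0.0,
            ("female", True): 1.0,
        }
        df = self.balanced_frame(cells, noise=1e-6, seed=1)
        res = interaction_anova(df["weight"], df["sex"], df["impaired"])
        assert res.f("interaction") > 1e6
        assert res.p("interaction") < 1e-10
        # the (0,0,0,delta) pattern loads main effects and interaction equally
        assert res.f("sex") == pytest.approx(res.f("interaction"), rel=1e-3)

    def test_null_interaction_f_near_one_on_average(self):
        rng = np.random.default_rng(5)
        fs = []
        for i in range(200):
            cells = {(s, i2): 0.0 for s in ("male", "female") for i2 in (False, True)}
            df = self.balanced_frame(cells, n=8, noise=1.0, seed=int(rng.integers(2**31)))
            fs.append(interaction_anova(df["weight"], df["sex"], df["impaired"]).f("interaction"))
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_balanced_design_matches_sums_of_squares_oracle(self):
        cells = {
            ("male", False): 0.2,
            ("male", True): 0.5,
            ("female", False): 0.1,
            ("female", True): 1.1,
        }
        n = 7
        df = self.balanced_frame(cells, n=n, noise=0.4, seed=9)
        res = interaction_anova(df["weight"], df["sex"], df["impaired"])

        # textbook balanced two-way decomposition (types coincide)
        y = df["weight"].to_numpy()
        grand = y.mean()
        means = df.groupby(["sex", "impaired"], observed=True)["weight"].mean()
        a_means = df.groupby("sex", observed=True)["weight"].mean()
        b_means = df.groupby("impaired", observed=True)["weight"].mean()
        ss_a = 2 * n * ((a_means - grand) ** 2).sum()
        ss_b = 2 * n * ((b_means - grand) ** 2).sum()
        ss_ab = n * sum(
            (means[(s, i)] - a_means[s] - b_means[i] + grand) ** 2
            for s, i in means.index
        )
        ss_e = sum(
            ((df[(df["sex"] == s) & (df["impaired"] == i)]["weight"] - means[(s, i)]) ** 2).sum()
            for s, i in means.index
        )
        df_e = len(y) - 4
        for term, ss in (("sex", ss_a), ("impairment", ss_b), ("interaction", ss_ab)):
            f_oracle = (ss / 1) / (ss_e / df_e)
            assert res.f(term) == pytest.approx(f_oracle, rel=1e-8)

    def test_sparse_cell_rejected_with_cell_name(self):
        cells = {
            ("male", False): 0.0,
            ("male", True): 0.0,
            ("female", False): 0.0,
            ("female", True): 0.0,
        }
        df = self.balanced_frame(cells, n=3, noise=1.0)
        df = df[~((df["sex"] == "female") & df["impaired"])]
        with pytest.raises(DataError, match="female"):
            interaction_anova(df["weight"], df["sex"], df["impaired"])


class TestCommonModelRoundTrip:
    def test_common_model_contains_cerebellum_dlpfc_edge(self):
        spec = CohortSpec(n_male=12, n_female=12, n_timepoints=150, seed=77)
        ds = generate_dataset(spec)
        common = fit_common_model(ds.panels, restarts=2, seed=3)
        assert find_edges_between(common, "cerebellum", "dlpfc")
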