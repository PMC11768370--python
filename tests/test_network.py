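"""Distance-correlation network: oracles, signs, permutation p, Leiden."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metabopk.network import (
    build_edges,
    build_graph,
    community_report,
    distance_correlation,
    graph_to_json,
    leiden_partition,
    signed_association,
    validate_tripartite,
)


from conftest import brute_force_dcor


class TestDistanceCorrelation:
    def test_self_dependence(self, rng):
        x = rng.normal(size=20)
        assert distance_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        assert distance_correlation(x, 3 * x + 2) == pytest.approx(1.0, abs=1e-12)
        assert distance_correlation(x, -2 * x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert distance_correlation(x, y) == pytest.approx(
                distance_correlation(y, x), abs=1e-12
            )

    def test_independent_normals_small(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            if distance_correlation(x, y) < 0.15:
                hits += 1
        assert hits >= 99

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n) if rng.random() < 0.5 else x**2 + rng.normal(size=n)
            assert distance_correlation(x, y) == pytest.approx(
                brute_force_dcor(list(x), list(y)), abs=1e-12
            )

    def test_constant_input_zero(self):
        assert distance_correlation(np.ones(10), np.arange(10.0)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            distance_correlation(np.arange(5.0), np.arange(6.0))


class TestSignedAssociation:
    def test_negative_linear(self, rng):
        x = rng.normal(size=20)
        d, sign, p, amb = signed_association(x, -2 * x, n_perms=99, rng=rng)
        assert d == pytest.approx(1.0, abs=1e-12)
        assert sign == "-" and not amb
        assert p == pytest.approx(1 / 100)

    def test_symmetric_quadratic_ambiguous_sign(self):
        # y = x² on a symmetric design: Pearson r = 0 exactly, dCor > 0
        x = np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        rng = np.random.default_rng(0)
        d, sign, p, amb = signed_association(x, x**2, n_perms=199, rng=rng)
        assert d > 0.3
        assert amb

    def test_constant_vector(self):
        rng = np.random.default_rng(0)
        d, sign, p, amb = signed_association(
            np.ones(10), np.arange(10.0), n_perms=49, rng=rng
        )
        assert (d, p, amb) == (0.0, 1.0, True)

    def test_permutation_p_superuniform_under_null(self, rng):
        # Monte-Carlo: P(p ≤ α) ≤ α (+MC slack) for the permutation test
        B = 199
        pvals = []
        for _ in range(200):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            _, _, p, _ = signed_association(x, y, n_perms=B, rng=rng)
            pvals.append(p)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            frac = (pvals <= alpha).mean()
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 200)


class TestBuildEdges:
    def _tables(self, rng, n_subj=37, n_met=8, n_par=4):
        subjects = [f"S{i}" for i in range(n_subj)]
        M = pd.DataFrame(
            rng.normal(size=(n_subj, n_met)),
            index=subjects,
            columns=[f"m{i}" for i in range(n_met)],
        )
        P = pd.DataFrame(
            rng.normal(size=(n_subj, n_par)),
            index=subjects,
            columns=[f"p{i}" for i in range(n_par)],
        )
        classes = {f"p{i}": ("PK" if i % 2 == 0 else "trait") for i in range(n_par)}
        return M, P, classes

    def test_planted_noiseless_edges_only_retained(self, rng):
        M, P, classes = self._tables(rng)
        M["m0"] = 2.0 * P["p0"] + 1.0
        M["m1"] = -P["p1"] ** 3
        edges = build_edges(M, P, classes, n_perms=999, seed=3)
        retained = edges[edges["retained"]]
        got = {(r.metabolite_id, r.parameter_name, r.sign) for r in retained.itertuples()}
        assert ("m0", "p0", "+") in got
        assert ("m1", "p1", "-") in got
        # perfect edges achieve the permutation floor p = 1/(B+1)
        sub = edges.set_index(["metabolite_id", "parameter_name"])
        assert sub.loc[("m0", "p0"), "p"] == pytest.approx(1 / 1000)
        assert sub.loc[("m0", "p0"), "d"] == pytest.approx(1.0, abs=1e-12)
        # nothing else sneaks past d > 0.5 with 37 subjects of pure noise
        assert len(retained) == 2

    def test_dmin_one_only_perfect_pairs(self, rng):
        M, P, classes = self._tables(rng, n_met=4, n_par=2)
        M["m0"] = P["p0"] * 5
        edges = build_edges(M, P, classes, d_min=1.0 - 1e-9, n_perms=199, seed=0)
        retained = edges[edges["retained"]]
        assert set(zip(retained["metabolite_id"], retained["parameter_name"])) == {
            ("m0", "p0")
        }

    def test_too_few_subjects(self, rng):
        M, P, classes = self._tables(rng, n_subj=3)
        with pytest.raises(ValueError):
            build_edges(M, P, classes, n_perms=9)

    def test_deterministic_under_seed(self, rng):
        M, P, classes = self._tables(rng, n_met=3, n_par=2)
        e1 = build_edges(M, P, classes, n_perms=99, seed=5)
        e2 = build_edges(M, P, classes, n_perms=99, seed=5)
        pd.testing.assert_frame_equal(e1, e2)


def two_clique_graph():
    """Two 4-cliques joined by a single bridge, unit weights."""
    G = nx.Graph()
    left = [f"L{i}" for i in range(4)]
    right = [f"R{i}" for i in range(4)]
    for grp in (left, right):
        for u, v in itertools.combinations(grp, 2):
            G.add_edge(u, v, weight=1.0)
    G.add_edge("L0", "R0", weight=1.0)
    for n in G.nodes:
        G.nodes[n]["node_class"] = "metabolite"
    return G, left, right


def exhaustive_max_modularity(G):
    """Brute-force maximum Newman modularity over all node partitions."""
    nodes = list(G.nodes)
    best_q, best_part = -np.inf, None

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
            yield [[first]] + smaller

    for part in partitions(nodes):
        q = nx.community.modularity(G, [set(c) for c in part], weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


class TestLeiden:
    def test_two_cliques_match_exhaustive_optimum(self):
        G, left, right = two_clique_graph()
        partition, q = leiden_partition(G, seed=0)
        best_q, best_part = exhaustive_max_modularity(G)
        assert q == pytest.approx(best_q, abs=1e-12)
        groups = {}
        for node, mod in partition.items():
            groups.setdefault(mod, set()).add(node)
        assert set(map(frozenset, groups.values())) == {
            frozenset(left),
            frozenset(right),
        }

    def test_single_edge_graph_one_module(self):
        # for K2 the 1-module partition (Q = 0) beats two singletons (Q = −1/2)
        G = nx.Graph()
        G.add_edge("a", "b", weight=1.0)
        for n in G.nodes:
            G.nodes[n]["node_class"] = "metabolite"
        partition, q = leiden_partition(G, seed=0)
        assert partition == {"a": 0, "b": 0}
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_no_module_spans_components(self, rng):
        G = nx.disjoint_union_all(
            [nx.complete_graph(4), nx.complete_graph(3), nx.path_graph(3)]
        )
        G = nx.relabel_nodes(G, {n: f"n{n}" for n in G.nodes})
        nx.set_node_attributes(G, "metabolite", "node_class")
        nx.set_edge_attributes(G, 1.0, "weight")
        partition, _ = leiden_partition(G, seed=1)
        for comp in nx.connected_components(G):
            mods = {partition[n] for n in comp}
            for other in nx.connected_components(G):
                if comp != other:
                    assert mods.isdisjoint({partition[n] for n in other})

    def test_deterministic_partition(self, rng):
        G = nx.gnp_random_graph(30, 0.15, seed=9)
        G = nx.relabel_nodes(G, {n: f"n{n}" for n in G.nodes})
        nx.set_node_attributes(G, "metabolite", "node_class")
        for u, v in G.edges:
            G.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
        p1, q1 = leiden_partition(G, seed=4)
        p2, q2 = leiden_partition(G, seed=4)
        assert p1 == p2 and q1 == q2

    def test_beats_greedy_local_move_baseline(self, rng):
        # Leiden must reach at least the modularity of one greedy local-move
        # sweep (the first Louvain phase) on random weighted graphs
        wins = 0
        for trial in range(50):
            G = nx.gnp_random_graph(14, 0.25, seed=100 + trial)
            if G.number_of_edges() == 0:
                continue
            G = nx.relabel_nodes(G, {n: f"n{n}" for n in G.nodes})
            nx.set_node_attributes(G, "metabolite", "node_class")
            for u, v in G.edges:
                G.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
            _, q_leiden = leiden_partition(G, seed=0)
            q_greedy = greedy_local_move_modularity(G)
            assert q_leiden >= q_greedy - 1e-10
            wins += 1
        assert wins > 40


def greedy_local_move_modularity(G):
    """One-pass greedy node moves from singletons (Louvain phase 1)."""
    part = {n: i for i, n in enumerate(G.nodes)}

    def q_of(p):
        groups = {}
        for n, c in p.items():
            groups.setdefault(c, set()).add(n)
        return nx.community.modularity(G, groups.values(), weight="weight")

    improved = True
    while improved:
        improved = False
        for n in G.nodes:
            current = q_of(part)
            best_c, best_q = part[n], current
            for nb in G.neighbors(n):
                trial = dict(part)
                trial[n] = part[nb]
                tq = q_of(trial)
                if tq > best_q + 1e-12:
                    best_q, best_c = tq, part[nb]
            if best_c != part[n]:
                part[n] = best_c
                improved = True
    return q_of(part)


class TestGraphStructure:
    def test_tripartite_validation(self):
        G = nx.Graph()
        G.add_node("m", node_class="metabolite")
        G.add_node("kel", node_class="PK")
        G.add_node("age", node_class="trait")
        G.add_edge("m", "kel")
        G.add_edge("m", "age")
        validate_tripartite(G)  # metabolite-centered star is fine
        G.add_edge("kel", "age")
        with pytest.raises(ValueError, match="tripartite"):
            validate_tripartite(G)

    def test_empty_edge_table_report(self):
        edges = pd.DataFrame(
            columns=[
                "metabolite_id", "parameter_name", "parameter_class",
                "d", "sign", "sign_ambiguous", "p", "q", "retained",
            ]
        )
        G = build_graph(edges)
        partition, q = leiden_partition(G)
        report = community_report(G, partition)
        assert report["n_modules"] == 0 and report["n_edges"] == 0

    def test_report_edge_counts_partition_edges(self, rng):
        M = pd.DataFrame(
            rng.normal(size=(20, 3)), index=range(20), columns=["m0", "m1", "m2"]
        )
        P = pd.DataFrame(
            rng.normal(size=(20, 2)), index=range(20), columns=["p0", "p1"]
        )
        M["m0"] = P["p0"]
        M["m1"] = -P["p1"]
        edges = build_edges(
            M, P, {"p0": "PK", "p1": "trait"}, n_perms=199, seed=0
        )
        G = build_graph(edges)
        partition, _ = leiden_partition(G)
        report = community_report(G, partition)
        within = sum(m["n_within_edges"] for m in report["modules"].values())
        assert within + report["n_cross_module_edges"] == report["n_edges"]

    def test_graph_json_roundtrip(self, tmp_path, rng):
        M = pd.DataFrame(rng.normal(size=(15, 2)), columns=["m0", "m1"])
        P = pd.DataFrame(rng.normal(size=(15, 1)), columns=["p0"])
        M["m0"] = 2 * P["p0"]
        edges = build_edges(M, P, {"p0": "PK"}, n_perms=199, seed=0)
        G = build_graph(edges)
        partition, _ = leiden_partition(G)
        payload = graph_to_json(G, partition, tmp_path / "g.json")
        import json

        back = json.loads((tmp_path / "g.json").read_text())
        assert back == payload
        assert {n["node_class"] for n in back["nodes"]} == {"metabolite", "PK"}
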