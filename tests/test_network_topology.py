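"""Centrality catalog vs definition-level oracles, selection, clustering."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from bbbkit.network_topology import (CENTRALITY_CATALOG, CentralityConfig,
                                     InfluenceNetwork, cluster_nodes,
                                     compute_centralities, diffusion_degree,
                                     jaccard_clustering_similarity, rank_nodes,
                                     select_informative_measure)
from bbbkit.synthgen import NetworkGroundTruth, gen_network


def small_connected_graphs(max_nodes=6):
    """All connected simple graphs with 4..max_nodes nodes (graph atlas)."""
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if 4 <= n <= max_nodes and g.number_of_edges() and nx.is_connected(g):
            yield g


# ---------------------------------------------------------------------------
# definition-level oracle implementations (deliberately naive)


def oracle_shortest_path_lengths(g):
    """All-pairs shortest paths by enumerating simple paths with itertools."""
    nodes = list(g.nodes)
    dist = {}
    for s, t in itertools.combinations(nodes, 2):
        best = None
        for k in range(1, len(nodes)):
            for mid in itertools.permutations([v for v in nodes if v not in (s, t)], k - 1):
                path = (s, *mid, t)
                if all(g.has_edge(a, b) for a, b in zip(path, path[1:])):
                    best = k
                    break
            if best is not None:
                break
        dist[(s, t)] = dist[(t, s)] = best
    return dist


def oracle_betweenness(g):
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # enumerate every simple path, keep the shortest ones
        paths = []
        for k in range(1, n):
            for mid in itertools.permutations([v for v in nodes if v not in (s, t)], k - 1):
                path = (s, *mid, t)
                if all(g.has_edge(a, b) for a, b in zip(path, path[1:])):
                    paths.append(path)
            if paths:
                break
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: s / norm for v, s in score.items()}


def oracle_matrix_scores(g):
    """Spectral-definition oracles computed from the dense adjacency matrix."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    deg = a.sum(axis=1)
    # eigenvector: Perron vector, unit Euclidean norm
    w, v = np.linalg.eigh(a)
    pv = np.abs(v[:, np.argmax(w)])
    pv = pv / np.linalg.norm(pv)
    # Katz: (I - alpha*A)^-1 * 1, normalised, same alpha rule as the package
    alpha = 0.85 / max(abs(w))
    katz = np.linalg.solve(np.eye(len(nodes)) - alpha * a, np.ones(len(nodes)))
    katz = katz / np.linalg.norm(katz)
    # PageRank: dense power iteration
    p = np.ones(len(nodes)) / len(nodes)
    m = a / deg[:, None]
    for _ in range(500):
        p = 0.15 / len(nodes) + 0.85 * m.T @ p
    # subgraph centrality: diagonal of exp(A)
    sub = np.diag(expm(a))
    return nodes, {"eigenvector": pv, "katz": katz, "pagerank": p, "subgraph": sub}


def oracle_laplacian_energy_drop(g):
    def energy(h):
        degs = np.array([d for _, d in h.degree()], dtype=float)
        return float((degs ** 2 + degs).sum())

    full = energy(g)
    return {v: (full - energy(nx.restricted_view(g, [v], []))) / full
            for v in g}


def oracle_diffusion(g, lam):
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    d = a.sum(axis=1)
    dd = lam * (d + a @ d)
    return dict(zip(sorted(g.nodes), dd))


class TestDiffusionDegree:
    def test_star_hand_case(self):
        g = nx.star_graph(3)  # hub 0
        dd = diffusion_degree(g, 1.0)
        assert dd[0] == 6.0
        assert all(dd[i] == 4.0 for i in (1, 2, 3))

    def test_triangle_symmetry(self):
        dd = diffusion_degree(nx.cycle_graph(3), 1.0)
        assert set(dd.values()) == {6.0}

    def test_lambda_scales_linearly_ranking_invariant(self):
        g = nx.barabasi_albert_graph(30, 2, seed=1)
        dd1 = diffusion_degree(g, 1.0)
        dd3 = diffusion_degree(g, 3.0)
        assert all(dd3[v] == pytest.approx(3 * dd1[v]) for v in g)

    def test_matches_adjacency_matrix_oracle_on_all_small_graphs(self):
        for g in small_connected_graphs():
            dd = diffusion_degree(g, 1.0)
            oracle = oracle_diffusion(g, 1.0)
            assert all(dd[v] == pytest.approx(oracle[v]) for v in g)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            diffusion_degree(nx.path_graph(4), 0.0)


class TestCatalog:
    def test_star_hub_maximal_under_every_measure(self):
        net = InfluenceNetwork(nx.star_graph(3))
        cfg = CentralityConfig(normalization="minmax")
        cm = compute_centralities(net, cfg)
        for measure in cm.columns:
            assert cm.loc[0, measure] == cm[measure].max(), measure

    def test_cycle_all_nodes_identical(self):
        net = InfluenceNetwork(nx.cycle_graph(6))
        cm = compute_centralities(net, CentralityConfig(normalization="minmax"))
        assert np.allclose(cm.to_numpy(), cm.to_numpy()[0], atol=1e-9)

    def test_degree_closeness_harmonic_against_hand_definitions(self):
        for g in small_connected_graphs(5):
            net = InfluenceNetwork(g)
            n = g.number_of_nodes()
            dist = oracle_shortest_path_lengths(g)
            raw = {name: CENTRALITY_CATALOG[name](net.graph, CentralityConfig())
                   for name in ("degree", "closeness", "harmonic")}
            for v in g:
                others = [u for u in g if u != v]
                assert raw["degree"][v] == pytest.approx(g.degree(v) / (n - 1))
                total = sum(dist[(v, u)] for u in others)
                assert raw["closeness"][v] == pytest.approx((n - 1) / total)
                assert raw["harmonic"][v] == pytest.approx(
                    sum(1 / dist[(v, u)] for u in others))

    def test_betweenness_against_path_enumeration(self):
        for g in small_connected_graphs(5):
            got = nx.betweenness_centrality(g)
            oracle = oracle_betweenness(g)
            assert all(got[v] == pytest.approx(oracle[v]) for v in g)

    def test_spectral_measures_against_matrix_oracles(self):
        cfg = CentralityConfig()
        for g in small_connected_graphs(5):
            nodes, oracle = oracle_matrix_scores(g)
            for name in ("eigenvector", "katz", "pagerank", "subgraph"):
                got = CENTRALITY_CATALOG[name](g, cfg)
                got_v = np.array([got[v] for v in nodes])
                ref = np.asarray(oracle[name])
                tol = 1e-4 if name == "pagerank" else 1e-6
                assert np.allclose(got_v, ref, rtol=tol, atol=tol), name

    def test_laplacian_against_energy_drop_oracle(self):
        cfg = CentralityConfig()
        for g in small_connected_graphs(5):
            got = CENTRALITY_CATALOG["laplacian"](g, cfg)
            oracle = oracle_laplacian_energy_drop(g)
            assert all(got[v] == pytest.approx(oracle[v]) for v in g)

    def test_local_measures_against_hand_definitions(self):
        cfg = CentralityConfig()
        for g in small_connected_graphs(5):
            deg = dict(g.degree())
            lev = CENTRALITY_CATALOG["leverage"](g, cfg)
            lob = CENTRALITY_CATALOG["lobby"](g, cfg)
            sl = CENTRALITY_CATALOG["semi_local"](g, cfg)
            for v in g:
                assert lev[v] == pytest.approx(np.mean(
                    [(deg[v] - deg[u]) / (deg[v] + deg[u]) for u in g[v]]))
                ks = [k for k in range(1, deg[v] + 1)
                      if sum(1 for u in g[v] if deg[u] >= k) >= k]
                assert lob[v] == (max(ks) if ks else 0)
                n2 = {w: len(set(nx.single_source_shortest_path_length(
                    g, w, cutoff=2)) - {w}) for w in g}
                q = {u: sum(n2[w] for w in g[u]) for u in g}
                assert sl[v] == pytest.approx(sum(q[u] for u in g[v]))

    def test_disconnected_input_uses_largest_component_with_warning(self):
        g = nx.union(nx.path_graph(5), nx.relabel_nodes(nx.path_graph(3),
                                                        {0: "a", 1: "b", 2: "c"}))
        with pytest.warns(UserWarning, match="largest connected component"):
            net = InfluenceNetwork(g)
        assert net.was_disconnected
        assert net.graph.number_of_nodes() == 5

    def test_isomorphic_relabeling_preserves_scores(self):
        g = nx.barabasi_albert_graph(20, 2, seed=3)
        mapping = {i: f"N{99 - i}" for i in range(20)}
        h = nx.relabel_nodes(g, mapping)
        cm_g = compute_centralities(InfluenceNetwork(g))
        cm_h = compute_centralities(InfluenceNetwork(h))
        for i in range(20):
            assert np.allclose(cm_g.loc[i].to_numpy(),
                               cm_h.loc[mapping[i]].to_numpy(), atol=1e-8)


class TestSelection:
    def test_only_varying_column_selected(self, rng):
        deg = np.arange(20, dtype=float)
        cm = pd.DataFrame({
            "degree": deg + rng.normal(0, 0.1, 20),
            "b": np.zeros(20),
            "c": np.zeros(20),
        })
        sel = select_informative_measure(cm)
        assert sel.measure == "degree"

    def test_duplicated_columns_tie_reported_first_wins(self):
        col = np.arange(10, dtype=float)
        cm = pd.DataFrame({"degree": col, "copy": col})
        sel = select_informative_measure(cm)
        assert sel.measure == "degree"
        assert set(sel.tied_measures) == {"degree", "copy"}

    def test_zero_variance_rejected(self):
        cm = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            select_informative_measure(cm)

    def test_selected_measure_ranks_planted_hub_first(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            net = gen_network(NetworkGroundTruth(n_nodes=50, seed=seed,
                                                 hub_id="HUB"))
            cm = compute_centralities(net)
            sel = select_informative_measure(cm)
            ranking = rank_nodes(net, measure=sel.measure)
            hits += ranking.index[0] == "HUB"
        assert hits >= 0.95 * n_seeds


class TestClustering:
    def test_two_blobs_recovered_perfectly(self, rng):
        a = rng.normal(0, 0.1, size=(10, 3))
        b = rng.normal(5, 0.1, size=(10, 3))
        cm = pd.DataFrame(np.vstack([a, b]),
                          index=[f"n{i}" for i in range(20)])
        res = cluster_nodes(cm, k_range=range(2, 6))
        assert res.k == 2
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_rows_rejected(self):
        cm = pd.DataFrame(np.ones((6, 2)))
        with pytest.raises(ValueError):
            cluster_nodes(cm)

    def test_row_permutation_invariance_up_to_relabeling(self, rng):
        x = np.vstack([rng.normal(0, 0.2, (8, 2)), rng.normal(4, 0.2, (8, 2))])
        idx = [f"n{i}" for i in range(16)]
        cm = pd.DataFrame(x, index=idx)
        perm = rng.permutation(16)
        cm_p = cm.iloc[perm]
        a = cluster_nodes(cm, k_range=[2]).labels
        b = cluster_nodes(cm_p, k_range=[2]).labels.loc[idx]
        assert jaccard_clustering_similarity(a.to_numpy(), b.to_numpy()) == 1.0


class TestJaccard:
    def test_identical_clusterings(self):
        assert jaccard_clustering_similarity([1, 1, 2], [5, 5, 9]) == 1.0

    def test_singletons_vs_nontrivial_is_zero(self):
        assert jaccard_clustering_similarity([1, 2, 3, 4], [1, 1, 2, 2]) == 0.0

    def test_hand_pair_enumeration_case(self):
        # together-in-both {(1,2)}; together-in-either {(1,2),(3,4),(1,3),(2,3)}
        assert jaccard_clustering_similarity([1, 1, 2, 2],
                                             [1, 1, 1, 2]) == pytest.approx(1 / 4)

    def test_symmetry_and_brute_force_agreement(self, rng):
        def brute(a, b):
            n = len(a)
            both = either = 0
            for i, j in itertools.combinations(range(n), 2):
                ta, tb = a[i] == a[j], b[i] == b[j]
                both += ta and tb
                either += ta or tb
            return 1.0 if either == 0 else both / either

        for _ in range(20):
            a = rng.integers(0, 4, 12)
            b = rng.integers(0, 4, 12)
            j1 = jaccard_clustering_similarity(a, b)
            assert j1 == pytest.approx(brute(a, b))
            assert j1 == pytest.approx(jaccard_clustering_similarity(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard_clustering_similarity([1, 2], [1, 2, 3])


class TestRanking:
    def test_planted_hub_is_top_deletion_node(self):
        net = gen_network(NetworkGroundTruth(n_nodes=60, seed=4, hub_id="CRKL"))
        ranking = rank_nodes(net, measure="diffusion_degree")
        assert ranking.index[0] == "CRKL"
        assert ranking.loc["CRKL", "top_deletion"]

    def test_no_deletion_flags_still_ranks(self):
        g = nx.barabasi_albert_graph(20, 2, seed=2)
        ranking = rank_nodes(InfluenceNetwork(g), measure="degree")
        assert len(ranking) == 20
        assert not ranking["top_deletion"].any()

    def test_ties_broken_lexicographically(self):
        g = nx.cycle_graph(["b", "a", "d", "c"])
        ranking = rank_nodes(InfluenceNetwork(g), measure="degree")
        assert list(ranking.index) == ["a", "b", "c", "d"]

    def test_hub_recovery_rate_by_diffusion_degree(self):
        hits = 0
        for seed in range(100):
            net = gen_network(NetworkGroundTruth(n_nodes=50, seed=seed,
                                                 hub_id="HUB"))
            dd = diffusion_degree(net.graph, 1.0)
            hits += max(dd, key=lambda v: (dd[v], v)) == "HUB"
        assert hits >= 95
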