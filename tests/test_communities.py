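import itertools
import random

import networkx as nx
import numpy as np
import pytest

from feastkit.communities import (
    cap_community_sizes,
    compute_silhouettes,
    detect_communities,
    form_meta_communities,
    greedy_modularity_partition,
    grid_search_communities,
)
from feastkit.fixtures import PlantedDesign, generate_fea
from feastkit.models import Community, OverlapNetwork
from feastkit.overlap import build_term_network, pairwise_overlap_matrix

from conftest import mk_term


def _net_from_graph(g, threshold=0.5, metric="OC"):
    for n in g.nodes:
        g.nodes[n].setdefault("goi", frozenset({"x"}))
    return OverlapNetwork(graph=g, metric=metric, threshold=threshold)


def _node(i):
    return ("GO", f"T{i:02d}")


def _weighted_modularity(g, partition):
    m2 = sum(d for _, d in g.degree(weight="weight"))
    if m2 == 0:
        return 0.0
    q = 0.0
    for part in partition:
        sub = g.subgraph(part)
        w_in = sum(d["weight"] for _, _, d in sub.edges(data=True))
        w_tot = sum(g.degree(n, weight="weight") for n in part)
        q += w_in / (m2 / 2) - (w_tot / m2) ** 2
    return q


def _all_partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _all_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1:]
        yield partial + [{first}]


class TestGreedyPartition:
    def test_edgeless_network_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(_node(i) for i in range(5))
        parts = greedy_modularity_partition(_net_from_graph(g))
        assert sorted(map(sorted, parts)) == [[_node(i)] for i in range(5)]

    def test_single_clique_is_one_part(self):
        g = nx.Graph()
        for a, b in itertools.combinations(range(3), 2):
            g.add_edge(_node(a), _node(b), weight=0.9)
        parts = greedy_modularity_partition(_net_from_graph(g))
        assert parts == [{_node(i) for i in range(3)}]

    def test_two_cliques_match_exhaustive_modularity_optimum(self):
        """Two 4-cliques joined by one weak edge: the greedy partition must
        equal the globally modularity-optimal partition found by enumerating
        every partition of the 8 nodes."""
        g = nx.Graph()
        for block, offset in ((0, 0), (1, 4)):
            for a, b in itertools.combinations(range(offset, offset + 4), 2):
                g.add_edge(_node(a), _node(b), weight=0.9)
        g.add_edge(_node(0), _node(4), weight=0.5)
        best = max(_all_partitions(list(g.nodes)),
                   key=lambda p: _weighted_modularity(g, p))
        greedy = greedy_modularity_partition(_net_from_graph(g))
        assert sorted(map(sorted, greedy)) == sorted(map(sorted, best))
        assert sorted(map(sorted, greedy)) == [
            [_node(i) for i in range(4)], [_node(i) for i in range(4, 8)]]


def _clique_graph(n, weight):
    g = nx.Graph()
    for a, b in itertools.combinations(range(n), 2):
        g.add_edge(_node(a), _node(b), weight=weight)
    return g


class TestSizeCap:
    def test_partition_within_cap_unchanged(self):
        g = _clique_graph(4, 0.8)
        net = _net_from_graph(g)
        part = [{_node(i) for i in range(4)}]
        assert cap_community_sizes(net, part, max_size=5) == part

    def test_uniform_clique_split_covers_all_nodes(self):
        """A 10-clique of uniform weight 0.6 dissolves once the local
        threshold is raised past the edge weight; the result must still obey
        the cap and cover every node."""
        g = _clique_graph(10, 0.6)
        net = _net_from_graph(g)
        part = [{_node(i) for i in range(10)}]
        capped = cap_community_sizes(net, part, max_size=5)
        assert all(len(p) <= 5 for p in capped)
        covered = set().union(*capped)
        assert covered == set(g.nodes)
        assert sum(len(p) for p in capped) == 10  # disjoint cover

    def test_saturated_clique_falls_back_to_degree_chunking(self):
        """A clique of weight-1.0 edges never splits by threshold raising;
        at local threshold 1.0 the degree-ordered chunking fallback applies
        (uniform degrees here, so chunks follow lexicographic node order)."""
        g = _clique_graph(10, 1.0)
        net = _net_from_graph(g)
        part = [{_node(i) for i in range(10)}]
        capped = cap_community_sizes(net, part, max_size=5)
        assert sorted(map(sorted, capped)) == [
            [_node(i) for i in range(5)], [_node(i) for i in range(5, 10)]]

    def test_separate_cliques_at_cap_unchanged(self):
        g = nx.Graph()
        for offset in (0, 3):
            for a, b in itertools.combinations(range(offset, offset + 3), 2):
                g.add_edge(_node(a), _node(b), weight=0.8)
        net = _net_from_graph(g)
        part = greedy_modularity_partition(net)
        assert cap_community_sizes(net, part, max_size=3) == sorted(
            part, key=lambda p: sorted(p)[0])

    def test_heterogeneous_clique_splits_by_threshold_raising(self):
        """Two tight 4-cliques glued by mid-weight edges: raising the local
        threshold separates them before the chunking fallback is needed."""
        g = nx.Graph()
        for offset in (0, 4):
            for a, b in itertools.combinations(range(offset, offset + 4), 2):
                g.add_edge(_node(a), _node(b), weight=0.95)
        for a in range(4):
            for b in range(4, 8):
                g.add_edge(_node(a), _node(b), weight=0.6)
        net = _net_from_graph(g)
        capped = cap_community_sizes(net, [set(g.nodes)], max_size=4)
        assert sorted(map(sorted, capped)) == [
            [_node(i) for i in range(4)], [_node(i) for i in range(4, 8)]]


class TestDetect:
    def test_planted_blocks_recovered_exactly(self):
        fea, labels = generate_fea(PlantedDesign(seed=5))
        net = build_term_network(fea.terms, "OC", 0.5)
        communities, unclustered = detect_communities(net, max_size=10)
        assert not unclustered
        assert len(communities) == 4
        detected = {c.community_id: c.members for c in communities}
        planted = {}
        for key, block in labels.items():
            planted.setdefault(block, set()).add(key)
        assert sorted(map(sorted, detected.values())) == sorted(
            map(sorted, planted.values()))

    def test_all_disjoint_terms_unclustered(self):
        terms = [mk_term(f"T{i}", [f"x{i}"]) for i in range(6)]
        net = build_term_network(terms, "OC", 0.5)
        communities, unclustered = detect_communities(net, max_size=5)
        assert communities == []
        assert len(unclustered) == 6

    def test_single_pair_forms_single_community(self):
        terms = [mk_term("A", ["g1", "g2"]), mk_term("B", ["g1", "g2", "g3"])]
        terms += [mk_term(f"L{i}", [f"z{i}"]) for i in range(3)]
        net = build_term_network(terms, "OC", 0.5)
        communities, unclustered = detect_communities(net, max_size=5)
        assert len(communities) == 1
        assert communities[0].members == frozenset({("GO", "A"), ("GO", "B")})
        assert communities[0].goi_union == frozenset({"g1", "g2", "g3"})
        assert len(unclustered) == 3

    def test_partition_validity_and_determinism(self):
        fea, _ = generate_fea(PlantedDesign(seed=9, between_overlap_target=0.2))
        net = build_term_network(fea.terms, "OC", 0.5)
        runs = [detect_communities(net, max_size=5) for _ in range(2)]
        (c1, u1), (c2, u2) = runs
        assert [(c.community_id, c.members) for c in c1] == [
            (c.community_id, c.members) for c in c2]
        assert u1 == u2
        seen = set(u1)
        for c in c1:
            assert 2 <= len(c.members) <= 5
            assert not (c.members & seen)
            seen |= c.members
        assert seen == set(net.graph.nodes)


def _make_communities(groups):
    out = []
    for i, members in enumerate(groups, start=1):
        out.append(Community(community_id=f"C{i:03d}",
                             members=frozenset(members),
                             goi_union=frozenset({"g"})))
    return out


class TestMetaCommunities:
    def _terms_with_cross(self, cross_genes):
        """Two 2-term blocks; blocks share `cross_genes` of 10 genes."""
        shared = [f"s{i}" for i in range(cross_genes)]
        a = [f"a{i}" for i in range(10 - cross_genes)] + shared
        b = [f"b{i}" for i in range(10 - cross_genes)] + shared
        return [mk_term("A0", a), mk_term("A1", a),
                mk_term("B0", b), mk_term("B1", b)]

    @pytest.mark.parametrize("cross, n_meta", [(3, 1), (1, 0)])
    def test_weak_residual_band(self, cross, n_meta):
        terms = self._terms_with_cross(cross)  # cross OC = cross/10
        net = build_term_network(terms, "OC", 0.5)
        communities, _ = detect_communities(net, max_size=5)
        assert len(communities) == 2
        mat = pairwise_overlap_matrix(terms, "OC")
        metas = form_meta_communities(communities, mat, 0.25, 0.5,
                                      net.cross_db_strong_links)
        assert len(metas) == n_meta
        if n_meta:
            assert metas[0].member_communities == frozenset(
                c.community_id for c in communities)

    def test_chained_weak_links_are_transitive(self):
        shared_ab = [f"p{i}" for i in range(3)]
        shared_bc = [f"q{i}" for i in range(3)]
        a = [f"a{i}" for i in range(7)] + shared_ab
        b = [f"b{i}" for i in range(4)] + shared_ab + shared_bc
        c = [f"c{i}" for i in range(7)] + shared_bc
        terms = [mk_term(f"{tag}{i}", genes)
                 for tag, genes in (("A", a), ("B", b), ("C", c))
                 for i in range(2)]
        net = build_term_network(terms, "OC", 0.5)
        communities, _ = detect_communities(net, max_size=5)
        assert len(communities) == 3
        mat = pairwise_overlap_matrix(terms, "OC")
        metas = form_meta_communities(communities, mat, 0.25, 0.5, {})
        assert len(metas) == 1
        assert metas[0].member_communities == frozenset(
            c.community_id for c in communities)

    def test_cross_database_strong_link_joins_communities(self):
        go = [mk_term("G0", [f"g{i}" for i in range(10)], database="GO"),
              mk_term("G1", [f"g{i}" for i in range(10)], database="GO")]
        kegg = [mk_term("K0", [f"g{i}" for i in range(9)] + ["k"], database="KEGG"),
                mk_term("K1", [f"g{i}" for i in range(9)] + ["k"], database="KEGG")]
        net = build_term_network(go + kegg, "OC", 0.5, multi_db_agglomeration=False)
        communities, _ = detect_communities(net, max_size=5)
        assert len(communities) == 2
        mat = pairwise_overlap_matrix(go + kegg, "OC")
        # cross-database overlap 0.9 >= threshold: not a weak link, but a
        # recorded strong link must still merge the two communities
        metas = form_meta_communities(communities, mat, 0.25, 0.5,
                                      net.cross_db_strong_links)
        assert len(metas) == 1

    def test_matches_transitive_closure_oracle(self):
        r = random.Random(42)
        for _ in range(20):
            n = r.randint(2, 10)
            groups = [{("GO", f"T{i}_{j}") for j in range(2)} for i in range(n)]
            keys = sorted(k for g in groups for k in g)
            import pandas as pd
            pos = {k: i for i, k in enumerate(keys)}
            arr = np.eye(len(keys))
            link_level = {}
            for i in range(n):
                for j in range(i + 1, n):
                    w = r.choice([0.0, 0.1, 0.3, 0.45, 0.6])
                    link_level[(i, j)] = w
                    for ka in groups[i]:
                        for kb in groups[j]:
                            arr[pos[ka], pos[kb]] = arr[pos[kb], pos[ka]] = w
            mat = pd.DataFrame(arr, index=keys, columns=keys)
            communities = _make_communities(groups)
            metas = form_meta_communities(communities, mat, 0.25, 0.5, {})
            # oracle: transitive closure of the pairwise weak-link predicate
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for (i, j), w in link_level.items():
                if 0.25 <= w < 0.5:
                    g.add_edge(i, j)
            expected = sorted(
                sorted(communities[i].community_id for i in cc)
                for cc in nx.connected_components(g) if len(cc) >= 2
            )
            got = sorted(sorted(m.member_communities) for m in metas)
            assert got == expected


class TestSilhouettes:
    def test_perfect_separation_gives_all_ones(self):
        terms = [mk_term(f"A{i}", ["a1", "a2", "a3"]) for i in range(3)]
        terms += [mk_term(f"B{i}", ["b1", "b2", "b3"]) for i in range(3)]
        net = build_term_network(terms, "OC", 0.5)
        communities, _ = detect_communities(net, max_size=5)
        sil = compute_silhouettes(terms, communities, "OC")
        assert all(v == pytest.approx(1.0) for v in sil.values.values())
        assert sil.overall_mean == pytest.approx(1.0)

    def test_uniform_overlap_gives_all_zeros(self):
        # every pair of terms overlaps identically (same shared core)
        terms = [mk_term(f"T{i}", ["core1", "core2", f"u{i}", f"v{i}"])
                 for i in range(4)]
        communities = _make_communities([
            {("GO", "T0"), ("GO", "T1")}, {("GO", "T2"), ("GO", "T3")}])
        sil = compute_silhouettes(terms, communities, "OC")
        assert all(v == pytest.approx(0.0) for v in sil.values.values())

    def test_fewer_than_two_communities_skipped(self):
        terms = [mk_term("A", ["x"]), mk_term("B", ["x"])]
        communities = _make_communities([{("GO", "A"), ("GO", "B")}])
        assert compute_silhouettes(terms, communities, "OC") is None

    def test_matches_sklearn_on_random_instances(self):
        from sklearn.metrics import silhouette_samples

        fea, _ = generate_fea(PlantedDesign(seed=3, between_overlap_target=0.3,
                                            within_overlap_target=0.75))
        net = build_term_network(fea.terms, "OC", 0.5)
        communities, unclustered = detect_communities(net, max_size=10)
        sil = compute_silhouettes(fea.terms, communities, "OC")
        mat = pairwise_overlap_matrix(fea.terms, "OC")
        clustered = sorted(k for c in communities for k in c.members)
        idx = [list(mat.index).index(k) for k in clustered]
        dist = (1.0 - mat.to_numpy())[np.ix_(idx, idx)]
        np.fill_diagonal(dist, 0.0)
        labels = [sil.community_of[k] for k in clustered]
        expected = silhouette_samples(dist, labels, metric="precomputed")
        got = np.array([sil.values[k] for k in clustered])
        assert np.allclose(got, expected)
        assert all(-1.0 <= v <= 1.0 for v in sil.values.values())


class TestGridSearch:
    def test_grid_has_one_cell_per_parameter_pair(self, structured_fea):
        grid = grid_search_communities(structured_fea.terms, [0.3, 0.5, 0.7],
                                       [5, 10], "OC")
        assert set(grid.cells) == {(t, s) for t in (0.3, 0.5, 0.7)
                                   for s in (5, 10)}

    def test_cell_reproduces_main_run(self, structured_fea):
        net = build_term_network(structured_fea.terms, "OC", 0.5)
        communities, unclustered = detect_communities(net, max_size=10)
        grid = grid_search_communities(structured_fea.terms, [0.5], [10], "OC")
        cell = grid.cells[(0.5, 10)]
        assert cell.n_communities == len(communities)
        assert cell.n_unclustered == len(unclustered)
        assert cell.sizes == tuple(sorted(
            (len(c.members) for c in communities), reverse=True))

    def test_unclustered_monotone_in_threshold(self):
        fea, _ = generate_fea(PlantedDesign(seed=8))
        thresholds = [0.3, 0.5, 0.7, 0.9]
        grid = grid_search_communities(fea.terms, thresholds, [10], "OC")
        counts = [grid.cells[(t, 10)].n_unclustered for t in thresholds]
        assert counts == sorted(counts)
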