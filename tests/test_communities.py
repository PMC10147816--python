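"""Community detection, consensus, lateralized splitting, homolog symmetry."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import dogconn as dc
from dogconn.communities import _child_seeds
from dogconn.errors import DegenerateGraphError, InsufficientDataError

from conftest import spearman_oracle


def two_cliques(n=5):
    g = nx.disjoint_union(nx.complete_graph(n), nx.complete_graph(n))
    g.add_edge(0, n)
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def planted_blocks(n_blocks=4, size=10, p_in=0.8, p_out=0.05, seed=0):
    sizes = [size] * n_blocks
    g = nx.stochastic_block_model(
        sizes, np.full((n_blocks, n_blocks), p_out) + np.eye(n_blocks) * (p_in - p_out),
        seed=seed,
    )
    nx.set_edge_attributes(g, 1.0, "weight")
    truth = {node: node // size for node in g.nodes()}
    return g, truth


class TestDetect:
    def test_two_cliques_split_cleanly(self):
        part = dc.detect_communities(two_cliques(), resolution=1.0, seed=0)
        assert part.n_modules == 2
        assert len({part.labels[i] for i in range(5)}) == 1
        assert len({part.labels[i] for i in range(5, 10)}) == 1

    def test_single_clique_is_one_module(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert dc.detect_communities(g, seed=0).n_modules == 1

    def test_planted_blocks_recovered(self):
        g, truth = planted_blocks(seed=3)
        part = dc.detect_communities(g, resolution=1.0, seed=1)
        nodes = sorted(g.nodes())
        ari = adjusted_rand_score([truth[n] for n in nodes], [part.labels[n] for n in nodes])
        assert ari == 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(DegenerateGraphError):
            dc.detect_communities(nx.empty_graph(5))


class TestModularity:
    def test_single_module_is_zero(self):
        g = nx.gnp_random_graph(10, 0.4, seed=0)
        nx.set_edge_attributes(g, 1.0, "weight")
        labels = {n: 0 for n in g}
        assert dc.modularity_score(g, labels, resolution=1.0) == pytest.approx(0.0)

    def test_two_triangles_hand_computation(self):
        # two K3's joined by one edge: m=7; per clique e_c=3, d_c=7
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (0, 3)])
        nx.set_edge_attributes(g, 1.0, "weight")
        labels = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        expect = 2 * (3 / 7 - (7 / 14) ** 2)
        assert dc.modularity_score(g, labels, resolution=1.0) == pytest.approx(expect)

    def test_label_permutation_invariance(self):
        g, _ = planted_blocks(seed=5)
        part = dc.detect_communities(g, seed=2)
        remap = {n: (m + 3) % part.n_modules for n, m in part.labels.items()}
        q1 = dc.modularity_score(g, part.labels, 1.0)
        q2 = dc.modularity_score(g, remap, 1.0)
        assert q1 == pytest.approx(q2)

    def test_matches_igraph(self):
        igraph = pytest.importorskip("igraph")
        g, _ = planted_blocks(seed=8)
        part = dc.detect_communities(g, resolution=0.6, seed=4)
        nodes = sorted(g.nodes())
        ig = igraph.Graph(edges=list(g.edges()), n=len(nodes))
        membership = [part.labels[n] for n in nodes]
        expect = ig.modularity(membership, resolution=0.6)
        assert dc.modularity_score(g, part.labels, 0.6) == pytest.approx(expect)


class TestConsensus:
    def test_stable_graph_equals_single_run(self):
        g = two_cliques()
        cons = dc.consensus_partition(g, resolution=1.0, n_repeats=5, seed=3)
        single = dc.detect_communities(g, resolution=1.0, seed=_child_seeds(3, 5, 0)[0])
        assert cons.labels == single.labels

    def test_single_repeat_equals_detect(self):
        g, _ = planted_blocks(seed=2)
        cons = dc.consensus_partition(g, resolution=1.0, n_repeats=1, seed=9)
        single = dc.detect_communities(g, resolution=1.0, seed=_child_seeds(9, 1, 0)[0])
        assert cons.labels == single.labels

    def test_deterministic(self):
        g, _ = planted_blocks(p_in=0.5, p_out=0.15, seed=6)
        a = dc.consensus_partition(g, 1.0, n_repeats=8, seed=5)
        b = dc.consensus_partition(g, 1.0, n_repeats=8, seed=5)
        assert a.labels == b.labels

    def test_consensus_no_worse_than_median_single_run(self):
        deltas = []
        for rep in range(20):
            g, truth = planted_blocks(p_in=0.45, p_out=0.12, seed=100 + rep)
            nodes = sorted(g.nodes())
            tr = [truth[n] for n in nodes]
            cons = dc.consensus_partition(g, 1.0, n_repeats=10, seed=rep)
            cons_ari = adjusted_rand_score(tr, [cons.labels[n] for n in nodes])
            singles = [
                adjusted_rand_score(
                    tr,
                    [dc.detect_communities(g, 1.0, seed=1000 * rep + k).labels[n] for n in nodes],
                )
                for k in range(10)
            ]
            deltas.append(cons_ari - float(np.median(singles)))
        assert np.mean(deltas) >= 0


class TestSplitLateralized:
    def test_no_lateralized_modules_is_identity(self, tiny_meta):
        # cliques over the hemisphere-mixed modules only; twin-module nodes
        # stay isolated singletons, which are not split candidates
        g = nx.Graph()
        g.add_nodes_from(tiny_meta.names)
        groups = tiny_meta.groups
        for module in ("alpha", "beta"):
            members = [n for n in tiny_meta.names if groups[n] == module]
            for i, u in enumerate(members):
                for v in members[i + 1 :]:
                    g.add_edge(u, v, weight=1.0)
        part = dc.consensus_partition(g, 1.0, n_repeats=3, seed=0)
        with pytest.warns(UserWarning, match="lateralized"):
            out = dc.split_lateralized(g, part, tiny_meta, top_k=2)
        assert out.n_modules == part.n_modules
        assert out.modules() == part.modules()

    def test_clique_module_survives_unsplit(self, tiny_meta):
        groups = tiny_meta.groups
        left = [n for n in tiny_meta.names if groups[n] == "tau_L"]
        g = nx.Graph()
        g.add_nodes_from(tiny_meta.names)
        for i, u in enumerate(left):
            for v in left[i + 1 :]:
                g.add_edge(u, v, weight=1.0)
        part = dc.consensus_partition(g, 1.0, n_repeats=3, seed=1)
        with pytest.warns(UserWarning):
            out = dc.split_lateralized(g, part, tiny_meta, top_k=2)
        left_labels = {out.labels[n] for n in left}
        assert len(left_labels) == 1

    def test_split_never_decreases_count_nor_mixes_modules(self, default_run):
        meta, _, res = default_run
        l1, fin = res.layer1, res.final
        assert fin.n_modules >= l1.n_modules
        # every final module is contained in exactly one layer-1 module
        for mod in range(fin.n_modules):
            parents = {l1.labels[n] for n in fin.members(mod)}
            assert len(parents) == 1


class TestCommunityDensity:
    def test_four_nodes_three_edges(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3)])
        part = dc.CommunityPartition({n: 0 for n in g}, 0.0, 1, 1.0, 1, 0)
        tab = dc.community_density(g, part)
        assert tab.loc[0, "density"] == pytest.approx(0.5)

    def test_clique_module_density_one(self):
        g = nx.complete_graph(5)
        part = dc.CommunityPartition({n: 0 for n in g}, 0.0, 1, 1.0, 1, 0)
        assert dc.community_density(g, part).loc[0, "density"] == 1.0

    def test_matches_bruteforce_pair_count(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(30, 0.2, seed=12)
        labels = {n: int(rng.integers(0, 4)) for n in g}
        # relabel contiguously by size as CommunityPartition requires
        from dogconn.communities import _canonical_labels

        comms = {}
        for n, m in labels.items():
            comms.setdefault(m, set()).add(n)
        labels = _canonical_labels(list(comms.values()))
        part = dc.CommunityPartition(labels, 0.0, 1, 1.0, 1, 0)
        tab = dc.community_density(g, part).set_index("module")
        for mod in range(part.n_modules):
            comm = part.members(mod)
            n = len(comm)
            brute = sum(
                1 for u in comm for v in comm if u < v and g.has_edge(u, v)
            )
            expect = 0.0 if n < 2 else 2 * brute / (n * (n - 1))
            assert tab.loc[mod, "density"] == pytest.approx(expect)

    def test_node_counts_sum_to_n(self, default_run):
        _, _, res = default_run
        tab = pd.DataFrame(res.report.community_density)
        assert tab["n_nodes"].sum() == res.report.n_nodes


class TestHomologSymmetry:
    def _mirror_graph(self, meta):
        g = nx.Graph()
        g.add_nodes_from(meta.names)
        pairs = meta.pairs()
        for k in range(len(pairs) - 1):
            for offset in range(1, min(3, len(pairs) - k)):
                w = 1.0 + k + offset
                g.add_edge(pairs[k][0], pairs[k + offset][0], weight=w)
                g.add_edge(pairs[k][1], pairs[k + offset][1], weight=w)
        return g

    def test_perfect_mirror_gives_rho_one(self, tiny_meta):
        g = self._mirror_graph(tiny_meta)
        sym = dc.homolog_symmetry(g, tiny_meta)
        assert sym["rho_degree"] == pytest.approx(1.0)
        assert sym["rho_weight"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, tiny_meta):
        rng = np.random.default_rng(8)
        g = nx.Graph()
        g.add_nodes_from(tiny_meta.names)
        names = tiny_meta.names
        for _ in range(60):
            u, v = rng.choice(names, 2, replace=False)
            if not g.has_edge(u, v):
                g.add_edge(u, v, weight=float(rng.uniform(1, 5)))
        deg = dict(g.degree())
        wdeg = dict(g.degree(weight="weight"))
        pairs = [p for p in tiny_meta.pairs() if deg[p[0]] + deg[p[1]] > 0]
        sym = dc.homolog_symmetry(g, tiny_meta)
        assert sym["rho_degree"] == pytest.approx(
            spearman_oracle([deg[l] for l, _ in pairs], [deg[r] for _, r in pairs])
        )
        assert sym["rho_weight"] == pytest.approx(
            spearman_oracle([wdeg[l] for l, _ in pairs], [wdeg[r] for _, r in pairs])
        )

    def test_constant_side_warns_nan(self, tiny_meta):
        g = nx.Graph()
        g.add_nodes_from(tiny_meta.names)
        pairs = tiny_meta.pairs()[:4]
        lefts = [l for l, _ in pairs]
        for other in lefts[1:]:
            g.add_edge(lefts[0], other, weight=1.0)  # left degrees vary (3,1,1,1)
        mid = tiny_meta.midline_names()[0]
        for _, r in pairs:
            g.add_edge(r, mid, weight=1.0)  # right degrees constant (1,1,1,1)
        with pytest.warns(UserWarning, match="constant"):
            sym = dc.homolog_symmetry(g, tiny_meta)
        assert math.isnan(sym["rho_degree"])
        assert math.isnan(sym["rho_weight"])

    def test_too_few_pairs_rejected(self, tiny_meta):
        g = nx.Graph()
        g.add_nodes_from(tiny_meta.names)
        l, r = tiny_meta.pairs()[0]
        g.add_edge(l, r, weight=1.0)
        with pytest.raises(InsufficientDataError):
            dc.homolog_symmetry(g, tiny_meta)


def test_strong_homolog_coupling_orders_weight_above_degree_correlation():
    """With strong bilateral coupling the left/right weighted-degree
    correlation exceeds the binary-degree correlation, both positive."""
    meta = dc.default_metadata(seed=3)
    spec = dc.default_generator_spec(
        meta, n_subjects=15, n_timepoints=150, homolog_coupling=0.7, seed=3
    )
    cohort = dc.generate_timeseries(meta, spec)
    mats = [dc.semipartial_matrix(ts) for ts in cohort]
    stats = dc.group_edge_stats(mats, n_perm=500, seed=3)
    edges = dc.threshold_edges(stats)
    g = dc.build_graph(edges, meta)
    sym = dc.homolog_symmetry(g, meta)
    assert sym["rho_weight"] > sym["rho_degree"] > 0
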