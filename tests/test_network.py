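"""Scale-free cutoff selection, module detection and annotation density."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coregnet import (
    annotation_interaction_density,
    build_network,
    density_null_test,
    detect_modules,
    read_gmt,
    select_scale_free_cutoff,
)
from coregnet.network import (
    InsufficientNetworkError,
    UNASSIGNED,
    UndefinedDensityError,
    scale_free_fit,
    write_edgelist,
    write_partition,
)


def _pairs_frame(edges_with_fdr):
    return pd.DataFrame(
        [{"gene_i": f"G{u}", "gene_j": f"G{v}", "n": 5, "fdr": f}
         for (u, v), f in edges_with_fdr]
    )


def powerlaw_plus_noise_pairs(seed=0, n_nodes=2000):
    """Power-law subgraph injected at fdr 1e-4 plus ER noise at fdr 0.2."""
    rng = np.random.default_rng(seed)
    deg = np.clip(rng.zipf(2.5, n_nodes), 1, 150)
    if deg.sum() % 2:
        deg[0] += 1
    g = nx.Graph(nx.configuration_model(deg, seed=seed))
    g.remove_edges_from(nx.selfloop_edges(g))
    edges = [((u, v), 1e-4) for u, v in g.edges()]
    noise = nx.gnm_random_graph(n_nodes, 1200, seed=seed + 1)
    seen = set(g.edges())
    for u, v in noise.edges():
        if (u, v) not in seen and (v, u) not in seen:
            edges.append(((u, v), 0.2))
    return _pairs_frame(edges)


CANDIDATES = [1e-4, 1e-3, 1e-2, 0.05, 0.3]


class TestScaleFreeCutoff:
    def test_scan_isolates_powerlaw_subgraph(self):
        pairs = powerlaw_plus_noise_pairs(seed=0)
        cutoff, report = select_scale_free_cutoff(pairs, CANDIDATES)
        assert cutoff <= 1e-3
        best = report.loc[report["fdr"] == cutoff].iloc[0]
        assert best["r_squared"] >= 0.8
        assert best["slope"] < 0

    def test_pure_random_graph_fits_worse(self):
        pl = powerlaw_plus_noise_pairs(seed=1)
        _, pl_report = select_scale_free_cutoff(pl, CANDIDATES)
        er = _pairs_frame(
            [((u, v), 1e-4) for u, v in
             nx.gnm_random_graph(2000, 6000, seed=2).edges()]
        )
        _, er_report = select_scale_free_cutoff(er, CANDIDATES)
        assert er_report["r_squared"].max() < pl_report["r_squared"].max()

    def test_single_candidate_returned(self):
        pairs = powerlaw_plus_noise_pairs(seed=3)
        cutoff, _ = select_scale_free_cutoff(pairs, [0.05])
        assert cutoff == 0.05

    def test_edge_count_monotone_in_cutoff(self):
        pairs = powerlaw_plus_noise_pairs(seed=4)
        counts = [build_network(pairs, f).number_of_edges() for f in CANDIDATES]
        assert counts == sorted(counts)

    def test_insufficient_network_raises(self):
        pairs = _pairs_frame([((0, 1), 0.9), ((1, 2), 0.8)])
        with pytest.raises(InsufficientNetworkError):
            select_scale_free_cutoff(pairs, [1e-4, 1e-3])

    def test_fit_handles_degenerate_degrees(self):
        g = nx.path_graph(4)
        r2, slope = scale_free_fit(g)
        assert np.isnan(r2) and np.isnan(slope)


def _clique_pair(bridge=False):
    g = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(10))
    if bridge:
        g.add_edge(0, 10)
    return g


class TestDetectModules:
    def test_disjoint_cliques_are_two_modules(self):
        part = detect_modules(_clique_pair(bridge=False), seed=0)
        assert len(set(part.values())) == 2
        assert len({part[n] for n in range(10)}) == 1
        assert len({part[n] for n in range(10, 20)}) == 1

    def test_bridged_cliques_stay_separate(self):
        # modularity of the two-clique split beats the one-module partition
        g = _clique_pair(bridge=True)
        two = [set(range(10)), set(range(10, 20))]
        assert nx.community.modularity(g, two) > nx.community.modularity(
            g, [set(g.nodes())]
        )
        part = detect_modules(g, seed=0)
        assert len({part[n] for n in range(10)}) == 1
        assert len({part[n] for n in range(10, 20)}) == 1
        assert part[0] != part[10]

    def test_partition_covers_nodes_and_is_deterministic(self):
        g = nx.gnm_random_graph(60, 180, seed=5)
        a = detect_modules(g, seed=3)
        b = detect_modules(g, seed=3)
        assert a == b
        assert set(a) == set(g.nodes())

    def test_small_modules_unassigned(self):
        g = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(3))
        part = detect_modules(g, min_module_size=5, seed=0)
        assert all(part[n] == UNASSIGNED for n in range(10, 13))
        assert all(part[n] != UNASSIGNED for n in range(10))

    def test_unsplittable_oversized_module_terminates(self):
        g = nx.complete_graph(12)
        part = detect_modules(g, max_module_size=5, seed=0)
        assert len(set(part.values())) >= 1  # terminated without infinite loop
        assert set(part) == set(g.nodes())

    def test_modularity_at_least_trivial(self):
        g = nx.gnm_random_graph(50, 120, seed=9)
        part = detect_modules(g, min_module_size=1, seed=1)
        comms = {}
        for n, m in part.items():
            comms.setdefault(m, set()).add(n)
        assert nx.community.modularity(g, comms.values()) >= 0.0

    def test_empty_graph(self):
        assert detect_modules(nx.Graph()) == {}


ANNOT = {
    "a": {"t1"}, "b": {"t1", "t2"}, "c": {"t2"}, "d": {"t3"}, "e": {"t3"},
}


class TestAnnotationDensity:
    def test_hand_graph_density(self):
        # 5 edges, 4 with both endpoints annotated, 2 of those share a term
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "x")])
        assert annotation_interaction_density(g, ANNOT) == pytest.approx(2 / 4)

    def test_every_edge_shares(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        assert annotation_interaction_density(g, ANNOT) == 1.0

    def test_no_shared_terms(self):
        g = nx.Graph([("a", "d"), ("c", "e")])
        assert annotation_interaction_density(g, ANNOT) == 0.0

    def test_unannotated_edges_error(self):
        g = nx.Graph([("x", "y")])
        with pytest.raises(UndefinedDensityError):
            annotation_interaction_density(g, ANNOT)


class TestDensityNullTest:
    def _module_aligned(self):
        # two term-aligned cliques: observed density 1, ER nulls mix terms
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(16)})
        annot = {f"G{i}": ({"m1"} if i < 8 else {"m2"}) for i in range(16)}
        return g, annot

    def test_planted_modules_beat_every_null(self):
        g, annot = self._module_aligned()
        res = density_null_test(g, annot, n_random=99, seed=0)
        assert res.observed == 1.0
        assert (res.null_densities < res.observed).all()
        assert res.p_value == pytest.approx(1 / 100)

    def test_common_term_everywhere_is_never_significant(self):
        g = nx.gnm_random_graph(12, 20, seed=1)
        annot = {n: {"t"} for n in g.nodes()}
        res = density_null_test(g, annot, n_random=19, seed=0)
        assert res.observed == 1.0
        assert (res.null_densities == 1.0).all()
        assert res.p_value == 1.0

    def test_seed_determinism_and_rewire_null(self):
        g, annot = self._module_aligned()
        a = density_null_test(g, annot, n_random=20, seed=7)
        b = density_null_test(g, annot, n_random=20, seed=7)
        np.testing.assert_array_equal(a.null_densities, b.null_densities)
        rw = density_null_test(g, annot, n_random=10, seed=7, null="rewire")
        assert 0 <= rw.p_value <= 1


class TestIO:
    def test_read_gmt(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "term1\tdesc\tg1\tg2\tg3\n"
            "term2\tdesc\tg2\tg4\n"
        )
        annot = read_gmt(gmt)
        assert annot["g2"] == {"term1", "term2"}
        assert annot["g4"] == {"term2"}
        assert "g5" not in annot

    def test_exports(self, tmp_path):
        pairs = _pairs_frame([((0, 1), 0.01), ((1, 2), 0.02)])
        g = build_network(pairs, 0.05)
        write_edgelist(g, tmp_path / "e.tsv")
        edges = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(edges) == 2 and {"gene_i", "gene_j", "fdr"} <= set(edges.columns)
        part = detect_modules(g, min_module_size=1, seed=0)
        write_partition(part, tmp_path / "p.tsv")
        back = pd.read_csv(tmp_path / "p.tsv", sep="\t")
        assert set(back["gene"]) == set(g.nodes())
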