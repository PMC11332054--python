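import itertools

import networkx as nx
import numpy as np
import pytest

import mcmkit as mk
from mcmkit.sensitivity import SensitivityResult

# ---------------------------------------------------------------------------
# Independent brute-force oracles (edge-list loops, no networkx)
# ---------------------------------------------------------------------------

_TRIAD_REPS = {
    "003": [],
    "012": [(0, 1)],
    "102": [(0, 1), (1, 0)],
    "021D": [(1, 0), (1, 2)],
    "021U": [(0, 1), (2, 1)],
    "021C": [(0, 1), (1, 2)],
    "111D": [(0, 1), (1, 0), (2, 1)],
    "111U": [(0, 1), (1, 0), (1, 2)],
    "030T": [(0, 1), (2, 1), (0, 2)],
    "030C": [(1, 0), (2, 1), (0, 2)],
    "201": [(0, 1), (1, 0), (1, 2), (2, 1)],
    "120D": [(1, 0), (1, 2), (0, 2), (2, 0)],
    "120U": [(0, 1), (2, 1), (0, 2), (2, 0)],
    "120C": [(0, 1), (1, 2), (0, 2), (2, 0)],
    "210": [(0, 1), (1, 2), (2, 1), (0, 2), (2, 0)],
    "300": [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)],
}
_PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def _canon(edges):
    best = None
    es = set(edges)
    for perm in itertools.permutations(range(3)):
        pes = {(perm[a], perm[b]) for a, b in es}
        m = tuple((u, v) in pes for u, v in _PAIRS)
        if best is None or m < best:
            best = m
    return best


_CANON_TO_NAME = {}
for _name, _edges in _TRIAD_REPS.items():
    for _perm in itertools.permutations(range(3)):
        _CANON_TO_NAME[_canon([(_perm[u], _perm[v]) for u, v in _edges])] = _name


def oracle_metrics(nodes, edges):
    """Direct-formula metrics from a plain edge list."""
    n = len(nodes)
    L = len(edges)
    eset = set(edges)
    return {
        "connectance": L / (n * (n - 1)) if n > 1 else 0.0,
        "reciprocity": (sum(1 for u, v in edges if (v, u) in eset) / L) if L else 0.0,
        "link_density": L / n,
        "degree": {
            v: {
                "in": sum(1 for a, b in edges if b == v),
                "out": sum(1 for a, b in edges if a == v),
                "total": sum(1 for a, b in edges if v in (a, b)),
            }
            for v in nodes
        },
    }


def oracle_triads(nodes, edges):
    """Classify every 3-subset by canonical form; count connected classes."""
    counts = dict.fromkeys(mk.CONNECTED_TRIADS, 0)
    for trio in itertools.combinations(sorted(nodes), 3):
        remap = {x: i for i, x in enumerate(trio)}
        sub = [(remap[u], remap[v]) for u, v in edges if u in remap and v in remap]
        name = _CANON_TO_NAME[_canon(sub)]
        if name in counts:
            counts[name] += 1
    return counts


def all_digraphs(n):
    """Every simple directed graph on n labelled nodes."""
    pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
    for bits in range(2 ** len(pairs)):
        yield [pairs[i] for i in range(len(pairs)) if bits >> i & 1]


def graph_of(nodes, edges):
    G = nx.DiGraph()
    G.add_nodes_from(nodes)
    G.add_edges_from(edges)
    return G


# ---------------------------------------------------------------------------


def make_result(targets, responders, retained_pairs, slopes=None):
    nt, nr = len(targets), len(responders)
    ret = np.zeros((nt, nr), dtype=bool)
    slp = np.zeros((nt, nr))
    r2 = np.zeros((nt, nr))
    p = np.ones((nt, nr))
    for (i, j), s in zip(retained_pairs, slopes or [1.0] * len(retained_pairs)):
        ret[i, j] = True
        slp[i, j] = s
        r2[i, j] = 0.9
        p[i, j] = 1e-6
    return SensitivityResult(
        targets=[f"t{i}" for i in range(nt)],
        target_nodes=list(targets),
        responders=list(responders),
        slopes=slp, r_squared=r2, p_values=p,
        slope_ses=np.zeros((nt, nr)), retained=ret,
        baseline_means=np.arange(1.0, nr + 1),
    )


class TestBuildNetwork:
    def test_no_retained_entries_gives_edgeless_graph(self):
        res = make_result(["A", "B"], ["A", "B"], [])
        G = mk.build_network(res)
        assert set(G.nodes) == {"A", "B"}
        assert G.number_of_edges() == 0

    def test_two_retained_offdiagonals_give_two_edges(self):
        nodes = ["A", "B", "C"]
        res = make_result(nodes, nodes, [(0, 1), (2, 0)], slopes=[1.5, -0.5])
        G = mk.build_network(res)
        assert G.number_of_edges() == 2
        assert G["A"]["B"]["weight"] == 1.5
        assert G["C"]["A"]["weight"] == -0.5

    def test_self_effects_become_node_attributes(self):
        res = make_result(["A"], ["A"], [(0, 0)], slopes=[-3.0])
        G = mk.build_network(res)
        assert G.number_of_edges() == 0
        assert G.nodes["A"]["self_effect"] == -3.0

    def test_self_loops_optional(self):
        res = make_result(["A"], ["A"], [(0, 0)], slopes=[-3.0])
        G = mk.build_network(res, include_self_loops=True)
        assert G.has_edge("A", "A")

    def test_node_abundance_attribute(self):
        res = make_result(["A", "B"], ["A", "B"], [])
        G = mk.build_network(res)
        assert G.nodes["B"]["abundance"] == 2.0


class TestNetworkMetrics:
    def test_empty_graph_zeros(self):
        G = graph_of(["a", "b", "c"], [])
        m = mk.network_metrics(G)
        assert m["connectance"] == 0.0
        assert m["reciprocity"] == 0.0
        assert m["link_density"] == 0.0

    def test_mutual_pair_among_three(self):
        G = graph_of("ABC", [("A", "B"), ("B", "A")])
        m = mk.network_metrics(G)
        assert m["connectance"] == pytest.approx(2 / 6)
        assert m["reciprocity"] == 1.0
        assert m["link_density"] == pytest.approx(2 / 3)

    def test_complete_digraph_saturates_connectance(self):
        n = 4
        G = graph_of(range(n), [(u, v) for u in range(n) for v in range(n) if u != v])
        assert mk.network_metrics(G)["connectance"] == 1.0

    def test_single_node_flagged_degenerate(self):
        m = mk.network_metrics(graph_of(["x"], []))
        assert m["connectance"] == 0.0
        assert m["degenerate"]

    def test_relabeling_preserves_network_level_metrics(self):
        edges = [("A", "B"), ("B", "C"), ("C", "A"), ("B", "A")]
        G1 = graph_of("ABC", edges)
        mapping = {"A": "x", "B": "y", "C": "z"}
        G2 = graph_of("xyz", [(mapping[u], mapping[v]) for u, v in edges])
        m1, m2 = mk.network_metrics(G1), mk.network_metrics(G2)
        for key in ("connectance", "reciprocity", "link_density", "modularity"):
            assert m1[key] == pytest.approx(m2[key])
        assert mk.motif_census(G1) == mk.motif_census(G2)

    def test_removing_edge_never_increases_connectance(self):
        edges = [("A", "B"), ("B", "C"), ("C", "A")]
        G = graph_of("ABC", edges)
        base = mk.network_metrics(G)["connectance"]
        for e in edges:
            H = G.copy()
            H.remove_edge(*e)
            assert mk.network_metrics(H)["connectance"] <= base


class TestMotifCensus:
    def test_empty_graph_all_zero(self):
        census = mk.motif_census(graph_of("ABC", []))
        assert all(v == 0 for v in census.values())

    def test_single_path_is_one_021C(self):
        census = mk.motif_census(graph_of("ABC", [("A", "B"), ("B", "C")]))
        assert census["021C"] == 1
        assert sum(census.values()) == 1

    def test_full_triangle_is_300(self):
        edges = [(u, v) for u in "ABC" for v in "ABC" if u != v]
        census = mk.motif_census(graph_of("ABC", edges))
        assert census["300"] == 1
        assert sum(census.values()) == 1


class TestAgainstBruteForce:
    @pytest.mark.parametrize("n", [2, 3])
    def test_all_small_digraphs_match_oracle(self, n):
        nodes = list(range(n))
        for edges in all_digraphs(n):
            G = graph_of(nodes, edges)
            got = mk.network_metrics(G)
            want = oracle_metrics(nodes, edges)
            for key in ("connectance", "reciprocity", "link_density"):
                assert got[key] == pytest.approx(want[key]), (edges, key)
            assert got["degree"] == want["degree"]
            if n >= 3:
                assert mk.motif_census(G) == oracle_triads(nodes, edges)

    def test_five_node_random_graphs_match_oracle(self):
        rng = np.random.default_rng(17)
        nodes = list(range(5))
        for _ in range(60):
            edges = [
                (u, v) for u in nodes for v in nodes
                if u != v and rng.random() < 0.4
            ]
            G = graph_of(nodes, edges)
            got = mk.network_metrics(G)
            want = oracle_metrics(nodes, edges)
            for key in ("connectance", "reciprocity", "link_density"):
                assert got[key] == pytest.approx(want[key])
            assert mk.motif_census(G) == oracle_triads(nodes, edges)


def test_export_writes_graphml_edges_and_metrics(tmp_path):
    res = make_result(["A", "B"], ["A", "B"], [(0, 1)], slopes=[2.0])
    G = mk.build_network(res)
    mk.export_network(G, tmp_path)
    assert (tmp_path / "network.graphml").exists()
    assert (tmp_path / "edges.csv").exists()
    assert (tmp_path / "metrics.json").exists()
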