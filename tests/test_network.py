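"""CDR3 similarity graphs: edges, clusters, expansion flags, round trips."""

import itertools

import numpy as np
import pytest

from repdiv.annotate import AnnotatedSequence
from repdiv.network import (
    build_graph,
    count_clusters,
    export_graph,
    flag_expanded,
    load_graph,
)
from repdiv.simulate import SimulationConfig, simulate_repertoire


def _ann(seq, cdr3_aa, cdr3_nt="", v="V1", j="J1", dup=1):
    return AnnotatedSequence(
        sequence_id=seq,
        seq_nt=seq,
        v_call=v,
        j_call=j,
        v_identity=1.0,
        j_identity=1.0,
        n_v_mutations=0,
        cdr3_nt=cdr3_nt or cdr3_aa,  # stand-in when the nt key is unused
        cdr3_aa=cdr3_aa,
        productive=True,
        duplicate_count=dup,
    )


def _brute_force_clusters(keys):
    """Oracle: transitive closure over the <=1-mismatch relation."""
    n = len(keys)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        a, b = keys[i], keys[j]
        if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) <= 1:
            parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def test_single_mismatch_linking():
    seqs = [_ann("s1", "ARDYW"), _ann("s2", "ARDFW"), _ann("s3", "GGGGW")]
    g = build_graph(seqs)
    assert g.n_vertices == 3
    assert g.n_edges == 1  # ARDYW-ARDFW only
    assert count_clusters(g) == 2


def test_empty_input():
    g = build_graph([])
    assert g.n_vertices == 0
    assert count_clusters(g) == 0


def test_identical_sequences_collapse_to_one_vertex():
    seqs = [_ann("s", "ARDYW", dup=1) for _ in range(4)]
    g = build_graph(seqs)
    assert g.n_vertices == 1
    assert g.n_edges == 0
    assert count_clusters(g) == 1
    assert g.total_weight == 4


def test_unequal_lengths_never_linked():
    g = build_graph([_ann("s1", "ARDY"), _ann("s2", "ARDYW")])
    assert g.n_edges == 0
    assert count_clusters(g) == 2


def test_distinct_nt_same_cdr3_are_linked():
    # two different nucleotide sequences with the same CDR3 aa: distance 0
    g = build_graph([_ann("AAA", "ARDY"), _ann("CCC", "ARDY")])
    assert g.n_vertices == 2
    assert g.n_edges == 1
    assert count_clusters(g) == 1


def test_matches_brute_force_oracle_on_random_sets():
    rng = np.random.default_rng(0)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(100):
        n = int(rng.integers(2, 51))
        keys = [
            "".join(rng.choice(alphabet, size=int(rng.integers(8, 21))))
            for _ in range(n)
        ]
        seqs = [_ann(f"s{i}-{k}", k) for i, k in enumerate(keys)]
        g = build_graph(seqs)
        assert count_clusters(g) == _brute_force_clusters(keys)


def test_nt_rule_refines_aa_rule(germline):
    """Single-nucleotide neighbours are also single-amino-acid neighbours,
    so every nt_1mm edge persists under cdr3_aa_1mm (on stop-free data)."""
    config = SimulationConfig(n_naive_clones=30, n_molecules=250, shm_rate=0.01, seed=19)
    rep = simulate_repertoire(germline, config)
    from repdiv.annotate import annotate_all

    annots, _ = annotate_all(
        [(f"m{m.molecule_id}", m.seq_nt) for m in rep.molecules], germline
    )
    g_nt = build_graph(annots, edge_rule="nt_1mm")
    g_aa = build_graph(annots, edge_rule="cdr3_aa_1mm")

    def vertex_seq(g, v):
        return g.graph.nodes[v]["key"]

    # map vertices by underlying nucleotide sequence (same vertex set)
    nt_pairs = {
        frozenset((a, b)) for a, b in g_nt.graph.edges()
    }
    aa_pairs = {
        frozenset((a, b)) for a, b in g_aa.graph.edges()
    }
    assert nt_pairs <= aa_pairs
    assert g_aa.n_clusters <= g_nt.n_clusters


class TestClusterRecovery:
    def test_low_shm_recovers_clone_count_exactly(self, germline):
        config = SimulationConfig(
            n_naive_clones=50,
            n_molecules=300,
            shm_rate=0.001,
            seed=23,
            min_cdr3_aa_hamming=3,
        )
        rep = simulate_repertoire(germline, config)
        from repdiv.annotate import annotate_all

        annots, _ = annotate_all(
            [(f"m{m.molecule_id}", m.seq_nt) for m in rep.molecules], germline
        )
        g = build_graph(annots)
        assert count_clusters(g) == 50

    def test_high_shm_fragments_upward(self, germline):
        config = SimulationConfig(
            n_naive_clones=50,
            n_molecules=300,
            shm_rate=0.03,
            seed=23,
            min_cdr3_aa_hamming=3,
        )
        rep = simulate_repertoire(germline, config)
        from repdiv.annotate import annotate_all

        annots, _ = annotate_all(
            [(f"m{m.molecule_id}", m.seq_nt) for m in rep.molecules], germline
        )
        g = build_graph(annots)
        assert count_clusters(g) >= 50


class TestExpandedFlags:
    def test_inclusive_boundary_at_half_percent(self):
        seqs = [_ann("big", "ARDYW", dup=5)] + [
            _ann(f"s{i}", f"K{i:03d}X", dup=1) for i in range(199)
        ]
        g = build_graph(seqs)
        flag_expanded(g, total_molecules=1000)
        flags = {g.graph.nodes[v]["key"]: g.graph.nodes[v]["expanded"] for v in g.graph.nodes}
        assert flags["ARDYW"] is True  # exactly 0.5% of 1000: inclusive

    def test_below_boundary_not_flagged(self):
        g = build_graph([_ann("big", "ARDYW", dup=4)])
        flag_expanded(g, total_molecules=1000)
        assert g.graph.nodes[0]["expanded"] is False

    def test_uniform_weights_below_200_vertices_all_flagged(self):
        seqs = [_ann(f"s{i}", f"A{i:04d}") for i in range(150)]
        g = build_graph(seqs)
        flag_expanded(g)  # total = 150, each 1/150 ≈ 0.67% >= 0.5%
        assert all(d for _, d in g.graph.nodes(data="expanded"))


class TestExportRoundTrip:
    @pytest.mark.parametrize("fmt", ["graphml", "edgelist"])
    def test_round_trip_preserves_structure(self, tmp_path, fmt):
        seqs = [_ann("s1", "ARDYW", dup=3), _ann("s2", "ARDFW"), _ann("s3", "GGGGW")]
        g = build_graph(seqs)
        flag_expanded(g)
        path = tmp_path / f"g.{fmt}"
        export_graph(g, path, fmt=fmt)
        g2 = load_graph(path, fmt=fmt)
        assert g2.n_vertices == g.n_vertices
        assert g2.n_edges == g.n_edges
        assert g2.n_clusters == g.n_clusters

    @pytest.mark.parametrize("fmt", ["graphml", "edgelist"])
    def test_fuzzed_random_graphs_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(5)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for rep in range(25):
            n = int(rng.integers(1, 30))
            keys = [
                "".join(rng.choice(alphabet, size=int(rng.integers(6, 10))))
                for _ in range(n)
            ]
            seqs = [_ann(f"s{i}-{k}", k, dup=int(rng.integers(1, 5))) for i, k in enumerate(keys)]
            g = build_graph(seqs)
            path = tmp_path / f"g{rep}.{fmt}"
            export_graph(g, path, fmt=fmt)
            g2 = load_graph(path, fmt=fmt)
            assert (g2.n_vertices, g2.n_edges, g2.n_clusters) == (
                g.n_vertices,
                g.n_edges,
                g.n_clusters,
            )


def test_adding_edges_never_increases_clusters():
    seqs = [_ann(f"s{i}", k) for i, k in enumerate(["AAAA", "AAAC", "CCCC", "GGGG"])]
    g = build_graph(seqs)
    before = count_clusters(g)
    g.graph.add_edge(2, 3)
    assert len(list(__import__("networkx").connected_components(g.graph))) <= before
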