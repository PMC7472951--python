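"""CDR3 similarity networks and cluster (naive-lineage) counting.

Each distinct sequence is a vertex weighted by its molecule count; two
vertices are linked when their CDR3s have equal length and Hamming distance
at most one — i.e. they differ in no more than one amino acid (default
rule) or one nucleotide (alternative rule).  Connected components of this
graph ("clusters") group sequences that plausibly descend from one common
activated naive B cell, so the cluster count estimates the number of
distinct activated naive lineages in the sample.

The two edge rules reflect the two descriptions in circulation for this
kind of analysis (single amino-acid difference vs single nucleotide
difference); the amino-acid rule is the default and every report should
name the rule used.  Matching is substitution-only (equal lengths, Hamming
distance), never indel-tolerant.

Highly expanded vertices are flagged at a frequency of at least 0.5% of
the sample's molecules — inclusive, unlike the strictly-exceeds rule used
for the large-clone diversity count; both boundary conventions are
deliberate and tested.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from repdiv.annotate import AnnotatedSequence

EDGE_RULES = ("cdr3_aa_1mm", "nt_1mm")
VERTEX_LEVELS = ("distinct_nt", "clonotype")


@dataclasses.dataclass
class RepertoireGraph:
    """A sequence-similarity graph with component labels.

    ``graph`` is an undirected networkx graph whose nodes are integer vertex
    indices with attributes ``key`` (the similarity key), ``weight``
    (molecule count) and, after :func:`flag_expanded`, ``expanded``.
    """

    graph: nx.Graph
    edge_rule: str
    vertex_level: str
    cluster_labels: Dict[int, int]

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_labels.values())) if self.cluster_labels else 0

    @property
    def total_weight(self) -> int:
        return sum(w for _, w in self.graph.nodes(data="weight"))


def _similarity_edges(keys: Sequence[str]) -> List[Tuple[int, int]]:
    """Pairs of indices whose keys have equal length and Hamming distance <= 1.

    Neighborhood hashing: two equal-length strings are within Hamming
    distance one iff they share a variant with one position masked, so each
    key is filed under all its masked variants and edges are drawn inside
    buckets.  Exact and O(n * L) in the number of masked variants.
    """
    buckets: Dict[Tuple[int, int, str], List[int]] = defaultdict(list)
    for idx, key in enumerate(keys):
        for pos in range(len(key)):
            masked = key[:pos] + "\x00" + key[pos + 1 :]
            buckets[(len(key), pos, masked)].append(idx)
    edges = set()
    for members in buckets.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def build_graph(
    seqs: Sequence[AnnotatedSequence],
    edge_rule: str = "cdr3_aa_1mm",
    vertex_level: str = "distinct_nt",
) -> RepertoireGraph:
    """Build the similarity graph of a sample.

    ``vertex_level='distinct_nt'`` keeps one vertex per distinct nucleotide
    sequence (vertex weight = its molecule count); ``'clonotype'`` collapses
    vertices sharing a similarity key.  The similarity key is the CDR3
    amino-acid sequence under ``cdr3_aa_1mm`` and the CDR3 nucleotide
    sequence under ``nt_1mm``.  Vertex order follows first appearance, so
    construction is deterministic.
    """
    if edge_rule not in EDGE_RULES:
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    if vertex_level not in VERTEX_LEVELS:
        raise ValueError(f"unknown vertex level {vertex_level!r}")

    def sim_key(s: AnnotatedSequence) -> str:
        return s.cdr3_aa if edge_rule == "cdr3_aa_1mm" else s.cdr3_nt

    vertices: Dict[str, int] = {}  # vertex identity key -> index
    keys: List[str] = []
    weights: List[int] = []
    for s in seqs:
        ident = s.seq_nt if vertex_level == "distinct_nt" else sim_key(s)
        if ident in vertices:
            weights[vertices[ident]] += s.duplicate_count
        else:
            vertices[ident] = len(keys)
            keys.append(sim_key(s))
            weights.append(s.duplicate_count)

    g = nx.Graph()
    for idx, (key, w) in enumerate(zip(keys, weights)):
        g.add_node(idx, key=key, weight=w)
    g.add_edges_from(_similarity_edges(keys))

    labels: Dict[int, int] = {}
    for comp_id, comp in enumerate(
        sorted(nx.connected_components(g), key=min)
    ):
        for v in comp:
            labels[v] = comp_id
    nx.set_node_attributes(g, labels, "cluster")
    return RepertoireGraph(
        graph=g, edge_rule=edge_rule, vertex_level=vertex_level, cluster_labels=labels
    )


def count_clusters(g: RepertoireGraph) -> int:
    """Number of connected components of the similarity graph."""
    return nx.number_connected_components(g.graph)


def flag_expanded(
    g: RepertoireGraph, total_molecules: Optional[int] = None, threshold: float = 0.005
) -> RepertoireGraph:
    """Flag vertices holding at least ``threshold`` of the sample's molecules.

    Inclusive boundary ("at least 0.5%"), in contrast to the strict rule of
    the large-clone diversity count.  ``total_molecules`` defaults to the
    graph's total vertex weight.
    """
    total = g.total_weight if total_molecules is None else total_molecules
    for v, w in g.graph.nodes(data="weight"):
        g.graph.nodes[v]["expanded"] = bool(total > 0 and w / total >= threshold)
    return g


def export_graph(g: RepertoireGraph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or an edge-list TSV (with a vertex table).

    The edge-list format writes vertex records (``V idx key weight cluster
    expanded``) followed by edge records (``E idx idx``), so isolated
    vertices survive a round trip.
    """
    if fmt == "graphml":
        nx.write_graphml(g.graph, str(path))
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write(f"# edge_rule={g.edge_rule} vertex_level={g.vertex_level}\n")
            for v, data in g.graph.nodes(data=True):
                fh.write(
                    f"V\t{v}\t{data['key']}\t{data['weight']}\t"
                    f"{data.get('cluster', '')}\t{int(data.get('expanded', False))}\n"
                )
            for a, b in g.graph.edges():
                fh.write(f"E\t{a}\t{b}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def load_graph(path: str | Path, fmt: str = "graphml") -> RepertoireGraph:
    """Re-import a graph written by :func:`export_graph`."""
    if fmt == "graphml":
        raw = nx.read_graphml(str(path))
        g = nx.Graph()
        for node, data in raw.nodes(data=True):
            g.add_node(int(node), **data)
        g.add_edges_from((int(a), int(b)) for a, b in raw.edges())
        edge_rule, vertex_level = "cdr3_aa_1mm", "distinct_nt"
    elif fmt == "edgelist":
        g = nx.Graph()
        edge_rule, vertex_level = "cdr3_aa_1mm", "distinct_nt"
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("edge_rule="):
                            edge_rule = tok.split("=", 1)[1]
                        elif tok.startswith("vertex_level="):
                            vertex_level = tok.split("=", 1)[1]
                    continue
                parts = line.split("\t")
                if parts[0] == "V":
                    g.add_node(
                        int(parts[1]),
                        key=parts[2],
                        weight=int(parts[3]),
                        cluster=int(parts[4]) if parts[4] else None,
                        expanded=bool(int(parts[5])),
                    )
                elif parts[0] == "E":
                    g.add_edge(int(parts[1]), int(parts[2]))
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    labels = {}
    for comp_id, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for v in comp:
            labels[v] = comp_id
    return RepertoireGraph(
        graph=g, edge_rule=edge_rule, vertex_level=vertex_level, cluster_labels=labels
    )


def plot_graph(g: RepertoireGraph, path: str | Path, seed: int = 0) -> None:
    """Static rendering: vertex area proportional to weight, expanded
    vertices highlighted.  Intended for small and medium graphs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(g.graph, seed=seed)
    weights = [d for _, d in g.graph.nodes(data="weight")]
    max_w = max(weights) if weights else 1
    sizes = [20 + 180 * w / max_w for w in weights]
    colors = [
        "#f5c518" if g.graph.nodes[v].get("expanded") else "#4477aa"
        for v in g.graph.nodes
    ]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx_edges(g.graph, pos, ax=ax, alpha=0.4, width=0.5)
    nx.draw_networkx_nodes(g.graph, pos, ax=ax, node_size=sizes, node_color=colors)
    ax.set_axis_off()
    ax.set_title(
        f"{g.n_vertices} vertices, {g.n_edges} edges, {g.n_clusters} clusters "
        f"({g.edge_rule})"
    )
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
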