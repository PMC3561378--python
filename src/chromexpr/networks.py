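"""Gene-gene contact networks for gene sets.

A contact network is the undirected graph whose nodes are all genes of a
set (isolated genes included) and whose edges are the inter-chromosomal
links between them above a count threshold, weighted by link frequency.
Functionally coherent sets form one dense connected subgraph (high
edges-per-node), while e.g. dubious ORFs scatter into isolated nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .mapping import GeneLinkTable
from .types import GeneSet, GenomeAnnotation

logger = logging.getLogger("chromexpr")


@dataclass
class ContactNetwork:
    term_id: str
    graph: nx.Graph  # nodes: all set genes in the annotation; edge attr "frequency"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges_per_node(self) -> float:
        # isolated genes stay in the denominator: sparseness of a set is
        # informative only relative to all its members
        return self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def component_sizes(self) -> list[int]:
        return sorted((len(c) for c in nx.connected_components(self.graph)), reverse=True)


def build_network(
    gene_set,
    link_table: GeneLinkTable,
    annotation: GenomeAnnotation,
    min_count: float = 5,
) -> ContactNetwork:
    """Induced subgraph of the gene-link graph on the set's genes."""
    if isinstance(gene_set, GeneSet):
        term_id, genes = gene_set.term_id, gene_set.genes
    else:
        term_id, genes = "custom", set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    known = set(annotation.gene_ids)
    nodes = sorted(g for g in genes if g in known)
    if not nodes:
        raise ValueError(f"no genes of set {term_id!r} found in annotation")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_set = set(nodes)
    lf = link_table.links
    sel = ((lf["frequency"] >= min_count)
           & lf["gene_a"].isin(node_set) & lf["gene_b"].isin(node_set))
    for row in lf[sel].itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, frequency=row.frequency)
    logger.info("network %s: %d nodes, %d edges", term_id, g.number_of_nodes(),
                g.number_of_edges())
    return ContactNetwork(term_id, g)


def network_stats(network: ContactNetwork) -> dict:
    comps = network.component_sizes()
    largest = comps[0] if comps else 0
    isolated = sum(1 for n in network.graph.nodes if network.graph.degree(n) == 0)
    return {
        "term_id": network.term_id,
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "edges_per_node": network.edges_per_node,
        "n_isolated": isolated,
        "n_connected_nodes": network.n_nodes - isolated,
        "largest_component": largest,
        "largest_component_fraction": largest / network.n_nodes if network.n_nodes else 0.0,
        "component_sizes": comps,
    }


def export_network(network: ContactNetwork, path, format: str = "edgelist") -> None:
    """Write the network deterministically (lexicographic node/edge order).

    ``edgelist``: TSV (gene_a, gene_b, weight); ``dot``: Graphviz DOT with
    the frequency as edge weight attribute.
    """
    edges = sorted(
        (min(a, b), max(a, b), d["frequency"]) for a, b, d in network.graph.edges(data=True)
    )
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for a, b, w in edges:
                fh.write(f"{a}\t{b}\t{w!r}\n")
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write(f'graph "{network.term_id}" {{\n')
            for node in sorted(network.graph.nodes):
                fh.write(f'  "{node}";\n')
            for a, b, w in edges:
                fh.write(f'  "{a}" -- "{b}" [weight={w!r}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network_edgelist(path, term_id: str = "imported",
                          nodes=None) -> ContactNetwork:
    """Inverse of the edgelist export (isolated nodes via ``nodes``)."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(sorted(nodes))
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, frequency=row.weight)
    return ContactNetwork(term_id, g)
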