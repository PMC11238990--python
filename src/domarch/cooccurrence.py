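"""Domain co-occurrence network construction and export.

Nodes are domain types weighted by how often they occur across the
analyzed proteins; edges count how often two domain types sit next to each
other (consecutive positions in an architecture). A domain repeated twice
in a row yields a self-loop. The exported GraphML (node attribute
``occurrence``, edge attribute ``frequency``) loads directly into
Cytoscape.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .model import Architecture


@dataclass
class CooccurrenceNetwork:
    """Weighted co-occurrence graph over domain types.

    ``nodes`` maps a domain name to its total occurrence count; ``edges``
    maps an unordered name pair (sorted tuple; self-pairs allowed) to its
    adjacency count.
    """

    nodes: Counter = field(default_factory=Counter)
    edges: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references a missing node")

    @property
    def total_instances(self) -> int:
        return sum(self.nodes.values())

    @property
    def total_adjacencies(self) -> int:
        return sum(self.edges.values())


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_network(
    architectures: Sequence[Architecture], per_protein: bool = True
) -> CooccurrenceNetwork:
    """Accumulate occurrence and adjacency counts over a set of assemblies.

    With ``per_protein=True`` (default) each assembly contributes once per
    member protein, so node sizes reflect how common a domain is in the
    dataset; with ``per_protein=False`` each distinct assembly contributes
    exactly once.
    """
    net = CooccurrenceNetwork()
    for asm in architectures:
        weight = max(asm.member_count, 1) if per_protein else 1
        names = asm.ordered_names
        for name in names:
            net.nodes[name] += weight
        for a, b in zip(names, names[1:]):
            net.edges[_edge_key(a, b)] += weight
    net.validate()
    return net


def to_networkx(net: CooccurrenceNetwork) -> nx.Graph:
    graph = nx.Graph()
    for name in sorted(net.nodes):
        graph.add_node(name, occurrence=int(net.nodes[name]))
    for (a, b) in sorted(net.edges):
        graph.add_edge(a, b, frequency=int(net.edges[(a, b)]))
    return graph


def export_graph(
    net: CooccurrenceNetwork, path: str | Path, format: str = "graphml"
) -> None:
    """Export the network as GraphML or as an edge-list TSV.

    GraphML carries ``occurrence`` on nodes and ``frequency`` on edges and
    round-trips losslessly through :func:`read_graphml`. The TSV has
    columns ``source target frequency``.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif format == "edge-tsv":
        with open(path, "w") as handle:
            handle.write("source\ttarget\tfrequency\n")
            for (a, b) in sorted(net.edges):
                handle.write(f"{a}\t{b}\t{net.edges[(a, b)]}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graphml(path: str | Path) -> CooccurrenceNetwork:
    """Read a GraphML file written by :func:`export_graph` back into counts."""
    graph = nx.read_graphml(path)
    net = CooccurrenceNetwork()
    for name, data in graph.nodes(data=True):
        net.nodes[name] = int(data["occurrence"])
    for a, b, data in graph.edges(data=True):
        net.edges[_edge_key(a, b)] = int(data["frequency"])
    net.validate()
    return net
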