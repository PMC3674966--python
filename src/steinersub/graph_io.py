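"""Reading, writing and simplifying interaction networks.

Networks are held as :class:`networkx.Graph` objects with opaque string node
IDs (Entrez gene IDs and gene symbols both pass through unparsed).  All
readers produce *simple* undirected graphs: edge directions are ignored,
self-loops dropped and duplicate edges collapsed.

Supported text formats:

* **SIF** (Simple Interaction Format, used by Cytoscape and Pathway Commons
  exports): ``source <sep> interaction-type <sep> target [<sep> target ...]``,
  or a single field for an isolated node.  The interaction-type column is
  discarded on read; the writer emits type ``pp``.
* **Edge list**: two whitespace-separated columns per line.
* **Node list**: one node ID per line.

Lines starting with ``#`` are treated as comments in edge and node lists.
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx

__all__ = [
    "Network",
    "SIFParseError",
    "read_sif",
    "write_sif",
    "read_edge_list",
    "write_edge_list",
    "read_node_list",
    "largest_connected_component",
]

#: Alias for the in-memory network container.
Network = nx.Graph


class SIFParseError(ValueError):
    """Raised for a malformed SIF line (exactly two fields)."""


def _add_edge_simplified(net: Network, u: str, v: str) -> None:
    net.add_node(u)
    net.add_node(v)
    if u != v:
        net.add_edge(u, v)


def read_sif(path: str | os.PathLike) -> Network:
    """Read a SIF file into a simplified undirected network.

    Each non-empty line has either a single field (an isolated node) or at
    least three whitespace/tab-separated fields ``source type target...``; a
    line with *k* target fields yields *k* edges.  Self-loops are dropped and
    duplicate edges (in either orientation) collapsed.

    Raises
    ------
    SIFParseError
        If a line has exactly two fields, naming the line number.
    """
    net = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) == 1:
                net.add_node(fields[0])
            elif len(fields) == 2:
                raise SIFParseError(
                    f"{path}: line {lineno}: expected 1 or >=3 fields, got 2"
                )
            else:
                source = fields[0]
                for target in fields[2:]:
                    _add_edge_simplified(net, source, target)
    return net


def write_sif(net: Network, path: str | os.PathLike) -> None:
    """Write a network as SIF with interaction type ``pp``.

    Edges are written one per line in sorted order; isolated nodes as
    single-field lines, so that ``read_sif(write_sif(net))`` round-trips.
    """
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\tpp\t{v}\n")
        for node in sorted(n for n in net.nodes() if net.degree(n) == 0):
            fh.write(f"{node}\n")


def read_edge_list(path: str | os.PathLike) -> Network:
    """Read a two-column whitespace-separated edge list (``#`` comments)."""
    net = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                net.add_node(fields[0])
            elif len(fields) == 2:
                _add_edge_simplified(net, *fields)
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 1 or 2 fields, "
                    f"got {len(fields)}"
                )
    return net


def write_edge_list(net: Network, path: str | os.PathLike) -> None:
    """Write a two-column edge list (isolated nodes as single fields)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")
        for node in sorted(n for n in net.nodes() if net.degree(n) == 0):
            fh.write(f"{node}\n")


def read_node_list(path: str | os.PathLike) -> set[str]:
    """Read a node list, one ID per line; ``#`` comments and blanks skipped.

    Membership of the IDs in any particular network is *not* checked here;
    that happens when a problem instance is constructed.
    """
    nodes: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                nodes.add(line.split()[0])
    return nodes


def largest_connected_component(net: Network) -> Network:
    """Induced sub-network on the largest connected component.

    Ties between equally large components are broken in favor of the one
    whose lexicographically smallest node ID is smallest.  An empty network
    is returned unchanged (as a new empty graph).
    """
    if net.number_of_nodes() == 0:
        return nx.Graph()
    best = max(
        nx.connected_components(net),
        key=lambda comp: (len(comp), _neg_lex(min(comp))),
    )
    return net.subgraph(best).copy()


class _neg_lex(str):
    """Order-reversing wrapper so max() prefers the *smallest* string."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)
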