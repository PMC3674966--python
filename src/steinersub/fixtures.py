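"""Packaged toy networks used in examples, tests and the CLI.

``ar_hdac9_graph`` is the small protein-interaction neighborhood linking the
androgen receptor (AR) to HDAC9, relevant to male pattern baldness: AR and
HDAC9 are each connected to seven shared interactors (NRPI1, HDAC1, HDAC3,
NCOR1, SUMO1, NCOR12, HDAC4), so with terminals {AR, HDAC9} there are seven
distinct minimal Steiner trees of two edges each — the canonical worked
example of solution non-uniqueness.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["ar_hdac9_graph", "path5_graph", "cycle4_graph", "FIXTURES"]

AR_HDAC9_INTERMEDIATES = (
    "NRPI1",
    "HDAC1",
    "HDAC3",
    "NCOR1",
    "SUMO1",
    "NCOR12",
    "HDAC4",
)


def ar_hdac9_graph() -> nx.Graph:
    """AR–HDAC9 interaction neighborhood: 9 nodes, 14 edges."""
    g = nx.Graph()
    for x in AR_HDAC9_INTERMEDIATES:
        g.add_edge("AR", x)
        g.add_edge(x, "HDAC9")
    return g


def path5_graph() -> nx.Graph:
    """Path A–B–C–D–E."""
    g = nx.Graph()
    nx.add_path(g, ["A", "B", "C", "D", "E"])
    return g


def cycle4_graph() -> nx.Graph:
    """4-cycle A–B–C–D–A."""
    g = nx.Graph()
    nx.add_cycle(g, ["A", "B", "C", "D"])
    return g


FIXTURES = {
    "fig2": ar_hdac9_graph,
    "path5": path5_graph,
    "cycle4": cycle4_graph,
}
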