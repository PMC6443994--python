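"""Background interaction network I/O."""

from __future__ import annotations

import logging

import networkx as nx

__all__ = ["read_network", "write_edge_list"]

log = logging.getLogger(__name__)


def read_network(path) -> nx.Graph:
    """Read an undirected background network from a two-column edge list.

    Whitespace- or tab-delimited, one interaction per line; SIF lines
    (``A interaction_type B``) are accepted by taking the first and last
    fields.  Duplicate edges (in either orientation) are collapsed and
    self-loops dropped with a logged count.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno} has fewer than two fields"
                )
            u, v = fields[0], fields[-1]
            if u == v:
                n_self += 1
                continue
            g.add_edge(u, v)
    if n_self:
        log.warning("dropped %d self-loop line(s) from %s", n_self, path)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no interactions found")
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write an undirected network as a sorted two-column TSV edge list."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")
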