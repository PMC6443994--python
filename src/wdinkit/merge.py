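"""Merging tissue core modules into a merged core module (MCM).

An interaction from any tissue's core module enters the MCM when its
local context is shared between at least one pair of modules: the
per-interaction Jaccard index between modules A and B must exceed the
threshold alpha.  Admitted edges carry one weight per source tissue, so
downstream classification can compare dysregulation direction across
tissues.

The per-interaction Jaccard index is not a single canonical object; three
strategies are provided:

``neighborhood`` (default)
    For edge e = (u, v) and module X, let S_X(e) be the union of u's and
    v's neighbor sets within X (empty when neither endpoint is in X);
    the index is |S_A ∩ S_B| / |S_A ∪ S_B|.  This is per-interaction and
    per-module-pair and varies smoothly with shared local context, which
    is what an alpha sweep needs.
``adjacent_edges``
    Same construction on the sets of edges incident to u or v.
``edge_set``
    Plain Jaccard of the two modules' full edge sets — constant across
    interactions for a given pair; retained for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .modules import CoreModule, avg_clustering

__all__ = [
    "MergedCoreModule",
    "DEFAULT_ALPHAS",
    "interaction_jaccard",
    "merge_core_modules",
    "sweep_alpha",
]

log = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.3, 0.2, 0.1, 0.05)


@dataclass
class MergedCoreModule:
    """Cross-tissue merged module: edges with per-tissue weights.

    ``graph`` edge attributes: ``weights`` (dict tissue -> WDIN weight for
    the tissues whose core module contains the edge) and, once the
    classifier has run, ``category``.
    """

    graph: nx.Graph
    alpha: float
    tissues: list[str] = field(default_factory=list)

    @property
    def edges(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def weights_of(self, u: str, v: str) -> dict[str, float]:
        return dict(self.graph.edges[u, v]["weights"])


def _context_sets(e, mod: CoreModule, strategy: str):
    u, v = e
    g = mod.graph
    if strategy == "neighborhood":
        s: set = set()
        for x in (u, v):
            if x in g:
                s |= set(g.neighbors(x))
        return s
    if strategy == "adjacent_edges":
        s = set()
        for x in (u, v):
            if x in g:
                s |= {tuple(sorted(ed)) for ed in g.edges(x)}
        return s
    if strategy == "edge_set":
        return {tuple(sorted(ed)) for ed in g.edges()}
    raise ValueError(f"unknown strategy {strategy!r}")


def interaction_jaccard(
    e, mod_a: CoreModule, mod_b: CoreModule, strategy: str = "neighborhood"
) -> float:
    """Jaccard index of one interaction's context between two modules."""
    e = tuple(sorted(e))
    if e not in mod_a.edges and e not in mod_b.edges:
        raise ValueError(f"edge {e} present in neither module")
    sa = _context_sets(e, mod_a, strategy)
    sb = _context_sets(e, mod_b, strategy)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def merge_core_modules(
    mods, alpha: float = 0.1, strategy: str = "neighborhood"
) -> MergedCoreModule:
    """Merge >= 2 core modules, admitting edges whose interaction Jaccard
    exceeds ``alpha`` (strictly) for at least one module pair.

    Admitted edges carry the WDIN weight of every tissue whose core
    module contains them.  An empty result is returned with a warning
    rather than an error.
    """
    mods = list(mods)
    if len(mods) < 2:
        raise ValueError("need at least two core modules to merge")
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    tissues = [m.tissue for m in mods]
    if len(set(tissues)) != len(tissues):
        raise ValueError(f"duplicate tissue labels among modules: {tissues}")

    union_edges = set().union(*(m.edges for m in mods))
    g = nx.Graph()
    for e in sorted(union_edges):
        admitted = False
        for ma, mb in combinations(mods, 2):
            if e not in ma.edges and e not in mb.edges:
                continue
            if interaction_jaccard(e, ma, mb, strategy) > alpha:
                admitted = True
                break
        if not admitted:
            continue
        weights = {
            m.tissue: m.graph.edges[e]["weight"] for m in mods if e in m.edges
        }
        g.add_edge(*e, weights=weights)
    if g.number_of_edges() == 0:
        log.warning("merged core module is empty at alpha=%s", alpha)
    return MergedCoreModule(g, alpha, tissues)


def sweep_alpha(
    mods, alphas=DEFAULT_ALPHAS, strategy: str = "neighborhood"
) -> tuple[pd.DataFrame, float]:
    """Build the MCM at each alpha and report its size and clustering.

    Returns the sweep table (alpha, mcm_nodes, mcm_edges,
    clustering_coefficient; empty MCMs score 0) and the recommended alpha
    — the clustering-coefficient argmax, ties resolved toward the larger
    (stricter) threshold.
    """
    alphas = sorted(set(alphas), reverse=True)
    if not alphas:
        raise ValueError("no alphas to sweep")
    rows = []
    best_alpha, best_cc = alphas[0], -1.0
    for a in alphas:
        mcm = merge_core_modules(mods, alpha=a, strategy=strategy)
        cc = avg_clustering(mcm.graph)
        rows.append(
            {
                "alpha": a,
                "mcm_nodes": mcm.graph.number_of_nodes(),
                "mcm_edges": mcm.graph.number_of_edges(),
                "clustering_coefficient": cc,
            }
        )
        if cc > best_cc:  # strict: first (largest) alpha wins ties
            best_alpha, best_cc = a, cc
    return pd.DataFrame(rows), best_alpha
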