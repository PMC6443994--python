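"""Cross-network similarity: edge-overlap S-score, node Venn counts, Jaccard.

Two networks are compared by edge presence alone (weights ignored).  With
N1 and N2 edges and n edges common to both, the directional overlap
ratios are x1 = n/N1 and x2 = n/N2 and the S-score is their harmonic
mean, 2*x1*x2/(x1+x2) — 1 for identical edge sets, 0 for disjoint ones
(the n = 0 case is defined as 0 by continuity).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OverlapSummary", "s_score", "venn_nodes", "jaccard", "normalize_edges"]


@dataclass(frozen=True)
class OverlapSummary:
    n_common: int
    n1: int
    n2: int
    x1: float
    x2: float
    s: float


def normalize_edges(edges) -> frozenset:
    """Canonicalize an edge collection to a set of unordered pairs."""
    return frozenset(tuple(sorted((u, v))) for u, v in edges)


def s_score(a, b) -> OverlapSummary:
    """Harmonic-mean edge-overlap score between two edge sets.

    Symmetric in its arguments; both sets must be nonempty.
    """
    ea, eb = normalize_edges(a), normalize_edges(b)
    if not ea or not eb:
        raise ValueError("edge sets must be nonempty")
    n = len(ea & eb)
    x1 = n / len(ea)
    x2 = n / len(eb)
    s = 0.0 if n == 0 else 2.0 * x1 * x2 / (x1 + x2)
    return OverlapSummary(n, len(ea), len(eb), x1, x2, s)


def venn_nodes(nets) -> dict[str, int]:
    """Region counts of the Venn diagram of 2 or 3 node sets.

    Keys are membership patterns like ``"100"`` or ``"111"`` (one digit
    per input set, in order); the regions partition the union.
    """
    sets = [set(s) for s in nets]
    if len(sets) not in (2, 3):
        raise ValueError(f"need 2 or 3 sets, got {len(sets)}")
    universe = set().union(*sets)
    counts: dict[str, int] = {}
    k = len(sets)
    for bits in range(1, 2**k):
        key = format(bits, f"0{k}b")
        counts[key] = 0
    for item in universe:
        key = "".join("1" if item in s else "0" for s in sets)
        counts[key] += 1
    return counts


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; requires at least one nonempty set."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("both sets empty: Jaccard undefined")
    return len(sa & sb) / len(sa | sb)
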