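"""Random walk with restart (RWR) on the WDIN: gene and edge prioritization.

The walker starts from a uniform distribution over seed genes (known
disease genes present in the network) and at each step either restarts at
the seeds with probability ``gamma`` or moves along an edge chosen with
probability proportional to the transformed edge weight:

    p_{s+1} = (1 - gamma) * M p_s + gamma * (1 - eta) * p0

where M is the weight-normalized transition matrix, M(u, v) =
t(w(u,v)) / sum_{x in N(v)} t(w(x,v)).  Each column of M over a
non-isolated node sums to one, so with ``eta = 0`` probability mass is
conserved at every iteration.  (For an undirected network this M equals
the transpose of the row-normalized transition matrix, which is the form
some texts write; the two conventions coincide here.)  Candidate genes —
all WDIN nodes outside the seed set — are ranked by descending
steady-state probability; WDIN edges are then ranked by the mean of their
endpoints' rank values, ascending, so position 1 is the most
disease-associated edge.

WDIN weights can be negative (lost correlation); a raw weight cannot be a
transition probability, so the default transform takes the absolute value
— the magnitude of dysregulation — with ``shifted`` ((w+2)/4) and
``unweighted`` alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "RWRConfig",
    "NodeRanking",
    "EdgeRanking",
    "transition_matrix",
    "rwr",
    "rwr_linear_oracle",
    "rank_edges",
    "validate_ranking",
]

log = logging.getLogger(__name__)

_TRANSFORMS = {
    "absolute": lambda w: np.abs(w),
    "shifted": lambda w: (w + 2.0) / 4.0,
    "unweighted": lambda w: np.ones_like(w),
}


@dataclass(frozen=True)
class RWRConfig:
    """Random-walk parameters.

    gamma
        Restart probability in (0, 1); 0.3 balances seed proximity against
        global topology and is the default.
    eta
        Scales the restart mass by (1 - eta).  Any eta in [0, 1) rescales
        all steady-state scores uniformly and leaves ranks unchanged;
        default 0, which gives the standard conservative RWR.
    tol
        L1 convergence tolerance between successive iterates.
    max_iter
        Iteration cap; exceeded -> error reporting the residual.
    """

    gamma: float = 0.3
    eta: float = 0.0
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if not 0 <= self.eta < 1:
            raise ValueError(f"eta must be in [0, 1), got {self.eta}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class NodeRanking:
    """Steady-state scores and candidate ranks from one RWR run.

    ``scores`` covers every WDIN node; ``ranks`` covers candidates only
    (rank 1 = highest score), with score ties broken by gene symbol so
    runs are bit-reproducible.
    """

    scores: pd.Series
    ranks: pd.Series
    seeds: list[str]
    n_iter: int = 0
    #: L1 mass (sum of p) after each iteration, for conservation checks.
    mass_history: list[float] = field(default_factory=list)

    @property
    def candidates(self) -> list[str]:
        return list(self.ranks.index)


@dataclass
class EdgeRanking:
    """WDIN edges ordered by the mean rank value of their endpoints.

    ``table`` columns: gene_u, gene_v, edge_index, order — ascending by
    edge_index (ties: lexicographic gene pair), order = 1-based position.
    """

    table: pd.DataFrame

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.table["gene_u"], self.table["gene_v"]))


def _node_order(w: nx.Graph) -> list[str]:
    return sorted(w.nodes())


def transition_matrix(
    w: nx.Graph, weight_transform: str = "absolute"
) -> tuple[np.ndarray, list[str]]:
    """Column-normalized transition matrix of a weighted WDIN.

    Returns the dense matrix and the node order (sorted gene symbols)
    defining its axes.  Entry (u, v) is the probability of stepping to u
    from v: transformed weight of edge uv over the transformed weight sum
    of v's incident edges.
    """
    if w.number_of_nodes() == 0:
        raise ValueError("empty network")
    try:
        t = _TRANSFORMS[weight_transform]
    except KeyError:
        raise ValueError(
            f"weight_transform must be one of {sorted(_TRANSFORMS)}, "
            f"got {weight_transform!r}"
        ) from None
    nodes = _node_order(w)
    # NaN marks non-edges so a genuine zero-weight edge is still seen
    a = nx.to_numpy_array(w, nodelist=nodes, weight="weight", nonedge=np.nan)
    mask = ~np.isnan(a)
    ta = np.where(mask, t(np.nan_to_num(a)), 0.0)
    colsum = ta.sum(axis=0)
    bad = np.flatnonzero(mask.any(axis=0) & (colsum == 0))
    if bad.size:
        raise ValueError(
            f"node {nodes[bad[0]]!r}: transformed incident weights sum to 0; "
            "cannot normalize its transition column"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(colsum > 0, ta / colsum, 0.0)
    return m, nodes


def _seed_vector(
    w: nx.Graph, seeds, nodes: list[str]
) -> tuple[np.ndarray, list[str]]:
    present = sorted(set(seeds) & set(nodes))
    dropped = sorted(set(seeds) - set(nodes))
    if dropped:
        log.warning("%d seed gene(s) absent from WDIN: %s", len(dropped),
                    dropped[:10])
    if not present:
        raise ValueError("no seed gene is present in the WDIN")
    p0 = np.zeros(len(nodes))
    pos = {g: i for i, g in enumerate(nodes)}
    for g in present:
        p0[pos[g]] = 1.0 / len(present)
    return p0, present


def _ranking_from_scores(
    scores: np.ndarray, nodes: list[str], present_seeds: list[str]
) -> tuple[pd.Series, pd.Series]:
    s = pd.Series(scores, index=nodes, name="score")
    cand = s.drop(index=present_seeds)
    # descending score, ties by gene symbol: deterministic
    order = sorted(cand.index, key=lambda g: (-cand[g], g))
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=order, name="rank", dtype=int
    )
    return s, ranks


def rwr(
    w: nx.Graph,
    seeds,
    cfg: RWRConfig = RWRConfig(),
    weight_transform: str = "absolute",
) -> NodeRanking:
    """Iterative RWR: propagate from the seed set to L1 convergence.

    Seeds absent from the WDIN are dropped with a warning; at least one
    must remain.  Raises if the iteration has not converged within
    ``cfg.max_iter`` steps.
    """
    m, nodes = transition_matrix(w, weight_transform)
    p0, present = _seed_vector(w, seeds, nodes)
    restart = cfg.gamma * (1.0 - cfg.eta) * p0
    p = p0.copy()
    mass = []
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.gamma) * (m @ p) + restart
        mass.append(float(p_next.sum()))
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < cfg.tol:
            break
    else:
        raise RuntimeError(
            f"RWR did not converge in {cfg.max_iter} iterations "
            f"(residual {delta:.3e})"
        )
    log.info("RWR converged in %d iterations", it)
    scores, ranks = _ranking_from_scores(p, nodes, present)
    return NodeRanking(scores, ranks, present, n_iter=it, mass_history=mass)


def rwr_linear_oracle(
    w: nx.Graph,
    seeds,
    cfg: RWRConfig = RWRConfig(),
    weight_transform: str = "absolute",
    max_nodes: int = 2000,
) -> NodeRanking:
    """Closed-form RWR via a dense linear solve: (I - (1-gamma) M) p = restart.

    Exact steady state of the iteration in :func:`rwr`; intended as an
    independent cross-check on small networks (guarded at ``max_nodes``).
    """
    if w.number_of_nodes() > max_nodes:
        raise ValueError(
            f"dense solve guarded at {max_nodes} nodes, "
            f"got {w.number_of_nodes()}"
        )
    m, nodes = transition_matrix(w, weight_transform)
    p0, present = _seed_vector(w, seeds, nodes)
    a = np.eye(len(nodes)) - (1.0 - cfg.gamma) * m
    p = np.linalg.solve(a, cfg.gamma * (1.0 - cfg.eta) * p0)
    scores, ranks = _ranking_from_scores(p, nodes, present)
    return NodeRanking(scores, ranks, present, n_iter=0)


def rank_edges(
    w: nx.Graph, nr: NodeRanking, seed_rank_policy: str = "seeds_first"
) -> EdgeRanking:
    """Rank WDIN edges by the average rank value of their two endpoints.

    Seed genes carry no candidate rank; under the default ``seeds_first``
    policy they are assigned rank 0 (maximally disease-associated, being
    the known disease genes), under ``drop_seed_edges`` every edge touching
    a seed is excluded.  Ties in the edge index break by lexicographic
    gene pair.
    """
    if seed_rank_policy not in ("seeds_first", "drop_seed_edges"):
        raise ValueError(f"unknown seed_rank_policy {seed_rank_policy!r}")
    seed_set = set(nr.seeds)
    rank_of = dict(nr.ranks)
    rows = []
    for u, v in w.edges():
        u, v = min(u, v), max(u, v)
        if seed_rank_policy == "drop_seed_edges" and (
            u in seed_set or v in seed_set
        ):
            continue
        ru = 0.0 if u in seed_set else float(rank_of[u])
        rv = 0.0 if v in seed_set else float(rank_of[v])
        rows.append((u, v, (ru + rv) / 2.0))
    rows.sort(key=lambda r: (r[2], r[0], r[1]))
    table = pd.DataFrame(rows, columns=["gene_u", "gene_v", "edge_index"])
    table["order"] = np.arange(1, len(table) + 1)
    return EdgeRanking(table)


def validate_ranking(
    nr: NodeRanking, test_genes, k: int
) -> tuple[int, float]:
    """Enrichment of an external disease-gene list among the top-k candidates.

    Overlap between ``test_genes`` and the seed set is removed with a
    warning (seeds are excluded from the ranking).  Returns the number of
    hits in the top-k and the one-sided hypergeometric tail probability
    P(X >= hits) of drawing k candidates from the full candidate set with
    the covered test genes as successes.
    """
    tests = set(test_genes)
    if not tests:
        raise ValueError("empty test gene set")
    overlap = tests & set(nr.seeds)
    if overlap:
        log.warning("removed %d test gene(s) overlapping the seed set",
                    len(overlap))
        tests -= overlap
    candidates = set(nr.candidates)
    n_cand = len(candidates)
    if k > n_cand:
        raise ValueError(f"k={k} exceeds number of candidates {n_cand}")
    covered = tests & candidates
    top_k = {g for g, r in nr.ranks.items() if r <= k}
    hits = len(top_k & covered)
    # P(X >= hits), X ~ Hypergeom(N=n_cand, K=|covered|, n=k)
    p = float(hypergeom.sf(hits - 1, n_cand, len(covered), k))
    return hits, min(p, 1.0)
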