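import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wdinkit.expression import (
    ExpressionMatrix,
    RankNormalizedMatrix,
    rank_normalize,
)


def make_expression(values, condition_of, tissue="adipose"):
    """ExpressionMatrix from a dict {gene: [values]} and sample conditions."""
    samples = list(condition_of)
    df = pd.DataFrame(values, index=samples).T
    return ExpressionMatrix(df, dict(condition_of), tissue)


def z_from_values(rows, tissue="adipose"):
    """RankNormalizedMatrix built directly from per-gene value vectors.

    ``rows``: {gene: {condition: values}}.  Downstream correlations
    re-rank within each condition, so any vectors with the desired
    within-condition orderings fix the Spearman correlations exactly.
    """
    conds = list(next(iter(rows.values())))
    samples, labels = [], {}
    data = {g: [] for g in rows}
    for cond in conds:
        n = len(next(iter(rows.values()))[cond])
        for i in range(n):
            s = f"{cond}_{i}"
            samples.append(s)
            labels[s] = cond
            for g in rows:
                data[g].append(float(rows[g][cond][i]))
    df = pd.DataFrame(data, index=samples).T
    return RankNormalizedMatrix(df, labels, tissue)


def weighted_graph(edges):
    """nx.Graph from (u, v, weight) triples with WDIN-style attributes."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w),
                   r_normal=0.0, r_disease=float(w),
                   status="active" if w > 0 else "inactive")
    return g


def random_wdin(n, p, seed, weight_low=-1.0, weight_high=1.0):
    """Random connected-ish weighted graph with nonzero weights."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g.remove_nodes_from(list(nx.isolates(g)))
    out = nx.Graph()
    for u, v in g.edges():
        w = 0.0
        while w == 0.0:
            w = float(rng.uniform(weight_low, weight_high))
        out.add_edge(f"N{u:04d}", f"N{v:04d}", weight=w,
                     r_normal=0.0, r_disease=w,
                     status="active" if w > 0 else "inactive")
    return out


def brute_avg_clustering(g):
    """Independent clustering oracle: explicit triangle enumeration."""
    if g.number_of_nodes() == 0:
        return 0.0
    vals = []
    for v in g:
        nb = list(g.neighbors(v))
        d = len(nb)
        if d < 2:
            vals.append(0.0)
            continue
        tri = sum(
            1
            for i in range(d)
            for j in range(i + 1, d)
            if g.has_edge(nb[i], nb[j])
        )
        vals.append(2.0 * tri / (d * (d - 1)))
    return sum(vals) / g.number_of_nodes()


@pytest.fixture
def small_matrix():
    """3 genes x 6 samples, two conditions of 3 samples each."""
    cond = {f"S{i}": ("GK" if i < 3 else "WK") for i in range(6)}
    values = {
        "g1": [5.0, 1.0, 9.0, 2.0, 7.0, 3.0],
        "g2": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "g3": [9.0, 8.0, 7.0, 6.0, 5.0, 4.0],
    }
    return make_expression(values, cond)


@pytest.fixture
def small_z(small_matrix):
    return rank_normalize(small_matrix)
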