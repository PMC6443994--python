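"""Weighted diverse interaction network (WDIN) construction.

A *diverse interaction* is a background-network edge whose two genes are
strongly rank-correlated in one phenotype (|rho| >= ``hi``) but weakly in
the other (|rho| < ``lo``).  Each retained edge is weighted by the change
in Spearman correlation, disease minus normal, so the weight lies in
[-2, 2]; a positive weight means correlation gained under disease (an
*active* edge), a negative weight means correlation lost (*inactive*).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .expression import RankNormalizedMatrix

__all__ = [
    "condition_correlation",
    "detect_diverse_edges",
    "write_wdin",
    "read_wdin",
]

log = logging.getLogger(__name__)

WDIN_COLUMNS = ["gene_u", "gene_v", "r_normal", "r_disease", "weight", "status"]


def condition_correlation(
    z: RankNormalizedMatrix, gene_u: str, gene_v: str, condition: str
) -> float:
    """Spearman correlation of two genes restricted to one condition's samples.

    Returns NaN (the "undefined" marker) when either gene is constant
    within the condition.  Because Spearman re-ranks within the selected
    samples, computing it on normalized ranks or on raw expression gives
    the same value.
    """
    samples = z.samples_in(condition)
    if len(samples) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(samples)} samples; need >= 3"
        )
    u = z.values.loc[gene_u, samples].to_numpy(dtype=float)
    v = z.values.loc[gene_v, samples].to_numpy(dtype=float)
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return float("nan")
    return float(spearmanr(u, v).statistic)


def _spearman_rows(values: np.ndarray) -> np.ndarray:
    """Row-standardized within-condition ranks; NaN rows mark zero variance.

    After this transform the Spearman correlation of genes i and j is the
    dot product of rows i and j divided by the number of samples.
    """
    ranks = rankdata(values, method="average", axis=1).astype(float)
    mu = ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ranks - mu) / sd
    out[np.ravel(sd == 0)] = np.nan
    return out


def detect_diverse_edges(
    z: RankNormalizedMatrix,
    bg: nx.Graph,
    disease: str,
    hi: float = 0.8,
    lo: float = 0.2,
    use_absolute: bool = True,
) -> nx.Graph:
    """Screen every background edge for diverse interactions.

    Parameters
    ----------
    z
        Rank-normalized expression for one tissue.
    bg
        Undirected background interaction network.
    disease
        Which of the matrix's two condition labels is the disease
        phenotype; the other label is taken as normal.
    hi, lo
        Correlation thresholds: strong means ``|rho| >= hi`` (or
        ``rho >= hi`` when ``use_absolute`` is off), weak means
        ``|rho| < lo`` (resp. ``rho < lo``).  Require ``0 <= lo < hi <= 1``.
    use_absolute
        Test correlation magnitude rather than signed value, so strong
        negative co-expression also counts as "strongly correlated".

    Returns
    -------
    networkx.Graph
        The WDIN: only nodes incident to a retained edge are kept.  Edge
        attributes: ``r_normal``, ``r_disease``, ``weight`` (disease minus
        normal) and ``status`` (``active``/``inactive``).  Graph attributes
        record the tissue, condition labels and thresholds.
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    conds = z.conditions
    if disease not in conds:
        raise ValueError(f"disease label {disease!r} not among {conds}")
    normal = conds[0] if conds[1] == disease else conds[1]

    genes = z.values.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    zn = _spearman_rows(z.values[z.samples_in(normal)].to_numpy(dtype=float))
    zd = _spearman_rows(z.values[z.samples_in(disease)].to_numpy(dtype=float))
    n_norm = zn.shape[1]
    n_dis = zd.shape[1]

    wdin = nx.Graph(
        tissue=z.tissue,
        disease=disease,
        normal=normal,
        hi=hi,
        lo=lo,
        use_absolute=use_absolute,
    )
    n_missing = 0
    n_undefined = 0
    for u, v in bg.edges():
        iu, iv = gene_pos.get(u), gene_pos.get(v)
        if iu is None or iv is None:
            n_missing += 1
            continue
        r_n = float(zn[iu] @ zn[iv]) / n_norm
        r_d = float(zd[iu] @ zd[iv]) / n_dis
        if np.isnan(r_n) or np.isnan(r_d):
            n_undefined += 1
            continue
        a_n, a_d = (abs(r_n), abs(r_d)) if use_absolute else (r_n, r_d)
        if (a_n >= hi and a_d < lo) or (a_d >= hi and a_n < lo):
            weight = r_d - r_n
            wdin.add_edge(
                u,
                v,
                r_normal=r_n,
                r_disease=r_d,
                weight=weight,
                status="active" if weight > 0 else "inactive",
            )
    if n_missing:
        log.info("skipped %d background edges with genes absent from matrix",
                 n_missing)
    if n_undefined:
        log.info("skipped %d edges with undefined within-condition correlation",
                 n_undefined)
    return wdin


def write_wdin(wdin: nx.Graph, path) -> None:
    """Write a WDIN as a weighted edge-list TSV (sorted, reproducible)."""
    rows = [
        {
            "gene_u": min(u, v),
            "gene_v": max(u, v),
            "r_normal": d["r_normal"],
            "r_disease": d["r_disease"],
            "weight": d["weight"],
            "status": d["status"],
        }
        for u, v, d in wdin.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=WDIN_COLUMNS)
    df = df.sort_values(["gene_u", "gene_v"], ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_wdin(path, tissue: str = "") -> nx.Graph:
    """Read a WDIN written by :func:`write_wdin`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_u": str, "gene_v": str})
    g = nx.Graph(tissue=tissue)
    for row in df.itertuples(index=False):
        g.add_edge(
            row.gene_u,
            row.gene_v,
            r_normal=float(row.r_normal),
            r_disease=float(row.r_disease),
            weight=float(row.weight),
            status=row.status,
        )
    return g
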