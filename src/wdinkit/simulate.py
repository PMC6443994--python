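"""Synthetic two-condition expression data with planted diverse interactions.

The generator emulates the study design the pipeline targets: per tissue,
a disease and a control cohort profiled on the same genes, with a known
background interaction network.  A subset of scaffold edges is *planted*:
the gene pair is drawn from a bivariate Gaussian with correlation
``r_high`` in its designated high condition and ``r_low`` in the other,
so the pair is a true diverse interaction with a known direction
(high condition = disease -> the edge should come out active).  All
other genes are mutually independent apart from an optional weak shared
factor giving every non-planted pair a common ``background_r``.

Planted pairs are required to be endpoint-disjoint (a matching): this
keeps every planted correlation exact without solving for a joint
covariance.  Gaussian margins mean the Spearman correlation of a planted
pair is (6/pi)*asin(r/2), slightly below the Pearson target (0.95 ->
about 0.942); recovery thresholds should be read on that scale.

All randomness flows from a single spec-level seed through named
substreams, so outputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "PlantedEdge",
    "SimulationSpec",
    "simulate_scaffold",
    "plant_edges",
    "simulate_expression",
    "simulate_study",
]

DEFAULT_TISSUES = ("adipose", "muscle", "liver")


@dataclass(frozen=True)
class PlantedEdge:
    """A scaffold edge carrying a true diverse correlation."""

    gene_u: str
    gene_v: str
    r_high: float = 0.95
    r_low: float = 0.0
    high_condition: str = "GK"

    def __post_init__(self):
        if not (abs(self.r_high) <= 1 and abs(self.r_low) <= 1):
            raise ValueError("planted correlations must lie in [-1, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_u, self.gene_v)))

    def expected_status(self, disease: str) -> str:
        """active when correlation is gained under disease, else inactive."""
        return "active" if self.high_condition == disease else "inactive"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic two-phenotype experiment.

    Defaults describe the condition the package is validated under:
    a 200-gene scaffold at mean degree 4, 100 samples per condition per
    tissue, 30 planted edges per tissue at r_high 0.95 / r_low 0, unit
    marginal noise, no background correlation.
    """

    n_genes: int = 200
    n_samples: int = 100  # per condition per tissue
    mean_degree: float = 4.0
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    disease: str = "GK"
    normal: str = "WK"
    n_planted: int = 30  # per tissue
    n_shared: int = 10  # of n_planted, the same gene pairs in every tissue
    r_high: float = 0.95
    r_low: float = 0.0
    background_r: float = 0.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.n_samples < 3:
            raise ValueError("need >= 3 samples per condition")
        if self.mean_degree <= 0:
            raise ValueError("mean degree must be positive")
        if self.disease == self.normal:
            raise ValueError("condition labels must differ")
        if not 0 <= self.background_r < 1:
            raise ValueError("background_r must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.n_shared <= self.n_planted:
            raise ValueError("need 0 <= n_shared <= n_planted")

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.disease, self.normal)


def _rng(spec: SimulationSpec, *key) -> np.random.Generator:
    """Named substream of the spec-level seed; order-independent."""
    material = [spec.rng_seed] + [
        int.from_bytes(str(k).encode(), "little") % (2**32) for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence(material))


def simulate_scaffold(spec: SimulationSpec) -> nx.Graph:
    """Erdős–Rényi background network with the spec's expected mean degree.

    Nodes are zero-padded gene symbols G0001..; edge probability is
    mean_degree / (n - 1).
    """
    p = spec.mean_degree / (spec.n_genes - 1)
    if p > 1:
        raise ValueError(
            f"mean degree {spec.mean_degree} infeasible for {spec.n_genes} genes"
        )
    rng = _rng(spec, "scaffold")
    width = len(str(spec.n_genes))
    names = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    # upper-triangle Bernoulli draw, vectorized and seed-stable
    iu, iv = np.triu_indices(spec.n_genes, k=1)
    keep = rng.random(iu.size) < p
    for a, b in zip(iu[keep], iv[keep]):
        g.add_edge(names[a], names[b])
    return g


def _choose_matching(
    scaffold: nx.Graph,
    rng: np.random.Generator,
    k: int,
    used: set[str],
) -> list[tuple[str, str]]:
    """k scaffold edges with mutually distinct endpoints, avoiding ``used``."""
    if k == 0:
        return []
    edges = sorted(tuple(sorted(e)) for e in scaffold.edges())
    order = rng.permutation(len(edges))
    chosen: list[tuple[str, str]] = []
    for i in order:
        u, v = edges[i]
        if u in used or v in used:
            continue
        chosen.append((u, v))
        used.update((u, v))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError(
            f"scaffold supports only {len(chosen)} additional endpoint-"
            f"disjoint planted edges; requested {k}"
        )
    return chosen


def plant_edges(
    spec: SimulationSpec, scaffold: nx.Graph, tissue: str
) -> list[PlantedEdge]:
    """Choose an endpoint-disjoint set of scaffold edges to perturb.

    Half the planted edges (rounded up) gain correlation under disease,
    the rest under the normal condition, so both active and inactive
    ground-truth edges exist.
    """
    rng = _rng(spec, "plant", tissue)
    chosen = _choose_matching(scaffold, rng, spec.n_planted, set())
    planted = []
    for j, (u, v) in enumerate(chosen):
        high = spec.disease if j < (spec.n_planted + 1) // 2 else spec.normal
        planted.append(
            PlantedEdge(u, v, spec.r_high, spec.r_low, high_condition=high)
        )
    return planted


def _validate_disjoint(planted: list[PlantedEdge]) -> None:
    seen: dict[str, tuple] = {}
    for pe in planted:
        for g in pe.pair:
            if g in seen:
                raise ValueError(
                    f"gene {g!r} shared by planted pairs {seen[g]} and "
                    f"{pe.pair}: conflicting correlation constraints"
                )
            seen[g] = pe.pair


def simulate_expression(
    spec: SimulationSpec,
    scaffold: nx.Graph,
    planted: list[PlantedEdge],
    tissue: str,
) -> ExpressionMatrix:
    """Draw one tissue's gene-by-sample matrix over both conditions.

    Planted pairs get their per-condition bivariate-Gaussian correlation;
    every other gene is N(0, noise_sd^2), optionally sharing a weak
    common factor that induces ``background_r`` between non-planted
    pairs.
    """
    for pe in planted:
        e = pe.pair
        if not scaffold.has_edge(*e):
            raise ValueError(f"planted edge {e} is not in the scaffold")
    _validate_disjoint(planted)

    genes = sorted(scaffold.nodes())
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted_genes = {g for pe in planted for g in pe.pair}
    blocks = []
    sample_names = []
    condition_of = {}
    for cond in (spec.normal, spec.disease):  # fixed order: reproducible
        rng = _rng(spec, "expr", tissue, cond)
        x = rng.normal(size=(len(genes), spec.n_samples))
        if spec.background_r > 0:
            f = rng.normal(size=spec.n_samples)
            b = spec.background_r
            for g in genes:
                if g not in planted_genes:
                    i = gene_pos[g]
                    x[i] = np.sqrt(b) * f + np.sqrt(1 - b) * x[i]
        for pe in planted:
            r = pe.r_high if cond == pe.high_condition else pe.r_low
            i, j = gene_pos[pe.gene_u], gene_pos[pe.gene_v]
            x[j] = r * x[i] + np.sqrt(1 - r * r) * x[j]
        blocks.append(spec.noise_sd * x)
        for s in range(spec.n_samples):
            name = f"{tissue}_{cond}_{s + 1:03d}"
            sample_names.append(name)
            condition_of[name] = cond
    values = pd.DataFrame(
        np.hstack(blocks), index=genes, columns=sample_names
    )
    return ExpressionMatrix(values, condition_of, tissue)


def simulate_study(spec: SimulationSpec):
    """Full synthetic study: scaffold, per-tissue expression, ground truth.

    ``n_shared`` of each tissue's planted edges are the same gene pairs in
    every tissue, with an independent per-tissue direction (which
    condition is the high one), so the merged module has genuinely
    common and differential cross-tissue edges; the remaining planted
    edges are tissue-specific, half gaining correlation under disease
    and half under the normal condition.

    Returns ``(scaffold, matrices, truth)`` where ``matrices`` maps tissue
    to :class:`ExpressionMatrix` and ``truth`` maps tissue to its planted
    edges.
    """
    scaffold = simulate_scaffold(spec)
    shared = _choose_matching(
        scaffold, _rng(spec, "plant", "shared"), spec.n_shared, set()
    )
    shared_used = {g for e in shared for g in e}
    matrices = {}
    truth = {}
    n_extra = spec.n_planted - spec.n_shared
    for tissue in spec.tissues:
        rng = _rng(spec, "plant", tissue)
        extras = _choose_matching(scaffold, rng, n_extra, set(shared_used))
        planted = [
            PlantedEdge(
                u, v, spec.r_high, spec.r_low,
                high_condition=(
                    spec.disease if rng.random() < 0.5 else spec.normal
                ),
            )
            for u, v in shared
        ]
        planted += [
            PlantedEdge(
                u, v, spec.r_high, spec.r_low,
                high_condition=(
                    spec.disease if j < (n_extra + 1) // 2 else spec.normal
                ),
            )
            for j, (u, v) in enumerate(extras)
        ]
        matrices[tissue] = simulate_expression(spec, scaffold, planted, tissue)
        truth[tissue] = planted
    return scaffold, matrices, truth
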