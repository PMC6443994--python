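"""End-to-end orchestration: simulate/load -> WDINs -> RWR -> modules -> MCM.

Ties the stage modules together in the order a study runs them, and
provides scoring helpers against simulated ground truth plus a
fingerprint used to demonstrate bit-reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .classify import classification_table, classify_edges
from .expression import ExpressionMatrix, rank_normalize
from .merge import DEFAULT_ALPHAS, MergedCoreModule, merge_core_modules, sweep_alpha
from .modules import DEFAULT_FRACTIONS, CoreModule, select_core_module
from .rwr import EdgeRanking, NodeRanking, RWRConfig, rank_edges, rwr
from .simulate import PlantedEdge, SimulationSpec, simulate_study
from .wdin import detect_diverse_edges

__all__ = ["PipelineResult", "run_pipeline", "run_synthetic_study",
           "score_recovery", "default_seed_genes"]


@dataclass
class PipelineResult:
    """Everything one end-to-end run produces."""

    wdins: dict[str, nx.Graph]
    node_rankings: dict[str, NodeRanking]
    edge_rankings: dict[str, EdgeRanking]
    core_modules: dict[str, CoreModule]
    module_sweeps: dict[str, pd.DataFrame]
    alpha_sweep: pd.DataFrame | None
    recommended_alpha: float | None
    mcm: MergedCoreModule | None
    mcm_table: pd.DataFrame | None
    mcm_summary: dict | None
    seeds: dict[str, list[str]] = field(default_factory=dict)

    def fingerprint(self) -> str:
        """SHA-256 over a canonical text serialization of every output.

        Two runs with the same inputs and seed must produce the same
        fingerprint — the pipeline's determinism contract.
        """
        h = hashlib.sha256()
        for tissue in sorted(self.wdins):
            w = self.wdins[tissue]
            for u, v in sorted(tuple(sorted(e)) for e in w.edges()):
                d = w.edges[u, v]
                h.update(
                    f"{tissue}|{u}|{v}|{d['r_normal']!r}|{d['r_disease']!r}"
                    f"|{d['weight']!r}|{d['status']}\n".encode()
                )
            nr = self.node_rankings[tissue]
            for g in nr.ranks.index:
                h.update(f"{tissue}|{g}|{nr.ranks[g]}|{nr.scores[g]!r}\n".encode())
            h.update(
                self.edge_rankings[tissue].table.to_csv(index=False).encode()
            )
            cm = self.core_modules[tissue]
            h.update(f"{tissue}|{cm.fraction!r}|{cm.clustering_coefficient!r}"
                     f"|{sorted(cm.edges)!r}\n".encode())
            h.update(self.module_sweeps[tissue].to_csv(index=False).encode())
        if self.alpha_sweep is not None:
            h.update(self.alpha_sweep.to_csv(index=False).encode())
            h.update(repr(self.recommended_alpha).encode())
        if self.mcm_table is not None:
            h.update(self.mcm_table.to_csv(index=False).encode())
            h.update(json.dumps(self.mcm_summary, sort_keys=True).encode())
        return h.hexdigest()


def default_seed_genes(
    truth: dict[str, list[PlantedEdge]], fraction: float = 1 / 3
) -> dict[str, list[str]]:
    """Designate part of the planted neighbourhood as "known" disease genes.

    One endpoint of each of the first ``fraction`` of a tissue's planted
    edges plays the role of the curated seed list; the partner genes and
    all remaining planted genes are left as candidates the walker should
    pull toward the top of the ranking.
    """
    seeds = {}
    for tissue, planted in truth.items():
        k = max(1, round(len(planted) * fraction))
        seeds[tissue] = sorted(pe.pair[0] for pe in planted[:k])
    return seeds


def run_pipeline(
    matrices: dict[str, ExpressionMatrix],
    background: nx.Graph,
    seeds: dict[str, list[str]],
    disease: str,
    hi: float = 0.8,
    lo: float = 0.2,
    use_absolute: bool = True,
    cfg: RWRConfig = RWRConfig(),
    weight_transform: str = "absolute",
    fractions=DEFAULT_FRACTIONS,
    alphas=DEFAULT_ALPHAS,
    alpha: float | None = None,
    merge_strategy: str = "neighborhood",
    tie_method: str = "average",
) -> PipelineResult:
    """Run every stage on per-tissue expression matrices.

    ``alpha`` fixes the merge threshold; when None the alpha sweep's
    recommendation is used.  With fewer than two tissues the merge and
    classification stages are skipped (fields left None).
    """
    wdins, node_rankings, edge_rankings = {}, {}, {}
    core_modules, module_sweeps = {}, {}
    for tissue in sorted(matrices):
        z = rank_normalize(matrices[tissue], tie_method=tie_method)
        w = detect_diverse_edges(
            z, background, disease, hi=hi, lo=lo, use_absolute=use_absolute
        )
        nr = rwr(w, seeds[tissue], cfg, weight_transform=weight_transform)
        er = rank_edges(w, nr)
        cm, sweep = select_core_module(w, er, fractions, tissue=tissue)
        wdins[tissue] = w
        node_rankings[tissue] = nr
        edge_rankings[tissue] = er
        core_modules[tissue] = cm
        module_sweeps[tissue] = sweep

    alpha_sweep = recommended = mcm = table = summary = None
    if len(matrices) >= 2:
        mods = [core_modules[t] for t in sorted(core_modules)]
        alpha_sweep, recommended = sweep_alpha(mods, alphas, merge_strategy)
        use_alpha = alpha if alpha is not None else recommended
        mcm = merge_core_modules(mods, alpha=use_alpha, strategy=merge_strategy)
        classify_edges(mcm)
        table, summary = classification_table(mcm)
    return PipelineResult(
        wdins=wdins,
        node_rankings=node_rankings,
        edge_rankings=edge_rankings,
        core_modules=core_modules,
        module_sweeps=module_sweeps,
        alpha_sweep=alpha_sweep,
        recommended_alpha=recommended,
        mcm=mcm,
        mcm_table=table,
        mcm_summary=summary,
        seeds=seeds,
    )


def run_synthetic_study(
    spec: SimulationSpec, **pipeline_kwargs
) -> tuple[PipelineResult, dict[str, list[PlantedEdge]]]:
    """Simulate a study under ``spec`` and run the full pipeline on it."""
    scaffold, matrices, truth = simulate_study(spec)
    seeds = default_seed_genes(truth)
    result = run_pipeline(
        matrices, scaffold, seeds, disease=spec.disease, **pipeline_kwargs
    )
    return result, truth


def score_recovery(
    wdin: nx.Graph, planted: list[PlantedEdge], disease: str
) -> dict[str, float]:
    """Recall/precision of planted diverse edges and sign accuracy.

    ``sign_accuracy`` is the fraction of recovered planted edges whose
    active/inactive status matches the planted direction (high condition
    = disease should surface as an active edge).
    """
    truth_edges = {pe.pair: pe.expected_status(disease) for pe in planted}
    found = {tuple(sorted(e)) for e in wdin.edges()}
    hits = found & set(truth_edges)
    recall = len(hits) / len(truth_edges) if truth_edges else 0.0
    precision = len(hits) / len(found) if found else 0.0
    correct = sum(
        1 for e in hits if wdin.edges[e]["status"] == truth_edges[e]
    )
    return {
        "recall": recall,
        "precision": precision,
        "sign_accuracy": correct / len(hits) if hits else 0.0,
        "n_recovered": float(len(hits)),
        "n_wdin_edges": float(len(found)),
    }
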