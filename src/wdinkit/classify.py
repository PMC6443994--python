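"""Cross-tissue categorization of merged-core-module edges.

Each MCM edge is dysregulated (present in the core module) in one or more
tissues, with a signed weight per tissue: positive = correlation gained
under disease (active), negative = correlation lost (inactive).  The
categories:

- ``specific:<tissue>`` — dysregulated in exactly one tissue;
- ``common`` — dysregulated in >= 2 tissues, all with the same sign
  (the same direction of dysfunction everywhere);
- ``differential`` — dysregulated in >= 2 tissues with both signs
  occurring (active in one tissue, inactive in another).

These form a partition: every edge gets exactly one label.
"""

from __future__ import annotations

import pandas as pd

from .merge import MergedCoreModule

__all__ = ["classify_edges", "category_of", "classification_table"]


def category_of(weights: dict[str, float]) -> str:
    """Category label from an edge's per-tissue weight map."""
    if not weights:
        raise ValueError("edge with no supporting tissue")
    if any(w == 0 for w in weights.values()):
        zero = sorted(t for t, w in weights.items() if w == 0)
        raise ValueError(f"zero weight in tissue(s) {zero}: invalid WDIN edge")
    if len(weights) == 1:
        (tissue,) = weights
        return f"specific:{tissue}"
    signs = {w > 0 for w in weights.values()}
    return "common" if len(signs) == 1 else "differential"


def classify_edges(mcm: MergedCoreModule) -> MergedCoreModule:
    """Assign a category to every MCM edge, in place; returns the MCM."""
    for u, v, d in mcm.graph.edges(data=True):
        d["category"] = category_of(d["weights"])
    return mcm


def classification_table(
    mcm: MergedCoreModule,
) -> tuple[pd.DataFrame, dict]:
    """Tabulate classified edges and summarize counts.

    Returns a per-edge DataFrame (gene_u, gene_v, one weight column per
    tissue, category) and a summary dict with per-category counts and,
    for every tissue pair, the number of differential and common edges
    the pair supports (an edge present in three tissues contributes to
    each of its pairs by that pair's own sign concordance).
    """
    tissues = mcm.tissues
    rows = []
    for u, v, d in sorted(mcm.graph.edges(data=True)):
        if "category" not in d:
            raise ValueError("run classify_edges before tabulating")
        row = {"gene_u": min(u, v), "gene_v": max(u, v)}
        for t in tissues:
            row[f"weight_{t}"] = d["weights"].get(t)
        row["category"] = d["category"]
        rows.append(row)
    cols = ["gene_u", "gene_v", *(f"weight_{t}" for t in tissues), "category"]
    table = pd.DataFrame(rows, columns=cols)
    table = table.sort_values(["gene_u", "gene_v"], ignore_index=True)

    by_category = table["category"].value_counts().to_dict() if len(table) else {}
    pair_counts = {}
    for i, ta in enumerate(tissues):
        for tb in tissues[i + 1:]:
            diff = common = 0
            for _, _, d in mcm.graph.edges(data=True):
                w = d["weights"]
                if ta in w and tb in w:
                    if (w[ta] > 0) == (w[tb] > 0):
                        common += 1
                    else:
                        diff += 1
            pair_counts[f"{ta}|{tb}"] = {
                "differential": diff,
                "common": common,
            }
    summary = {
        "n_edges": int(len(table)),
        "by_category": {k: int(v) for k, v in by_category.items()},
        "tissue_pairs": pair_counts,
    }
    return table, summary
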