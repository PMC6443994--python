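# wdinkit

Cross-tissue analysis of *diverse interactions* — gene pairs whose
co-expression differs sharply between two phenotypes — for two-condition
expression studies (e.g., diabetic vs. control cohorts profiled in
several tissues over a common protein–protein interaction network).

Classic co-expression screens keep pairs that correlate across **all**
samples and miss pairs that correlate in one biological state but not
the other. `wdinkit` targets exactly those pairs and carries them
through a multi-level comparison: network level (how similar are the
disease networks of different tissues?), gene level (which genes sit
closest to the known disease genes?), and module level (which compact
set of interactions is shared or flipped between tissues?).

## Method

1. **Rank normalization.** Each sample (array) is reduced to
   within-sample ranks, standardized to z-scores
   `z = (rank − μ)/σ` with the mean and population standard deviation of
   the column's rank vector. This removes platform- and tissue-specific
   dynamic range; all correlations downstream are Spearman correlations
   of these ranks.
2. **Weighted diverse interaction network (WDIN).** For every edge of a
   background interactome, Spearman correlation is computed separately
   under the normal and disease conditions. An edge is kept when it is
   strongly correlated in one condition (|ρ| ≥ `hi`, default 0.8) and
   weakly in the other (|ρ| < `lo`, default 0.2). Its weight is
   `ρ_disease − ρ_normal` ∈ [−2, 2]: positive = correlation gained under
   disease (*active* edge), negative = lost (*inactive*).
3. **Random walk with restart (RWR).** With column-normalized transition
   matrix `M(u,v) = |w(u,v)| / Σ_x |w(x,v)|` and restart probability
   γ = 0.3 from a uniform seed distribution p₀ over known disease genes,
   iterate `p ← (1−γ)·M·p + γ(1−η)·p₀` to convergence. Candidate genes
   are ranked by steady-state probability; edges by the mean rank of
   their endpoints (seeds rank 0).
4. **Core module.** Sweeping the top 2.5%…25% of ranked edges (step
   2.5%), take each subnetwork's maximum connected component and keep
   the one with the largest average local clustering coefficient —
   a minimal, densely knit disease module per tissue.
5. **Merged core module (MCM).** An interaction enters the MCM when its
   per-interaction Jaccard index (overlap of its endpoints' neighbor
   sets between two tissue modules) exceeds α for at least one module
   pair; α is chosen by a clustering-coefficient sweep over
   {0.3, 0.2, 0.1, 0.05}. MCM edges carry one weight per tissue and are
   classified **tissue-specific** (one tissue), **differential**
   (≥ 2 tissues, discordant signs) or **common** (≥ 2 tissues,
   concordant signs).

Networks are compared by the S-score, the harmonic mean of the
directional edge-overlap ratios `x₁ = n/N₁`, `x₂ = n/N₂`.

A synthetic-data module generates two-condition, multi-tissue expression
with planted diverse interactions on a random scaffold, so the whole
pipeline is testable without external data.

## Worked example

```python
import wdinkit as wk
from wdinkit.simulate import SimulationSpec

spec = SimulationSpec(n_genes=150, n_samples=60, n_planted=18,
                      n_shared=8, rng_seed=123)
result, truth = wk.run_synthetic_study(spec)

for tissue in sorted(result.wdins):
    w = result.wdins[tissue]
    sc = wk.score_recovery(w, truth[tissue], spec.disease)
    print(f"{tissue}: WDIN {w.number_of_edges()} edges / "
          f"{w.number_of_nodes()} nodes, recall {sc['recall']:.2f}, "
          f"precision {sc['precision']:.2f}")
print("MCM categories:", result.mcm_summary["by_category"])
print(result.mcm_table.to_string(index=False))
```

prints

```
adipose: WDIN 15 edges / 30 nodes, recall 0.83, precision 1.00
liver: WDIN 15 edges / 30 nodes, recall 0.83, precision 1.00
muscle: WDIN 14 edges / 28 nodes, recall 0.78, precision 1.00
MCM categories: {'differential': 1}
gene_u gene_v  weight_adipose  weight_liver  weight_muscle     category
  G013   G069       -0.963422      1.057322       0.986646 differential
```

Of the 18 planted diverse pairs per tissue, 14–15 are recovered with no
false positives; the retained cross-tissue interaction G013–G069 lost
correlation under disease in adipose (weight < 0) but gained it in liver
and muscle — a *differential* dysregulation the per-tissue analyses
cannot see.

The same workflow is scriptable from the shell:

```bash
wdinkit simulate --seed 5 --outdir fixtures/
wdinkit build-wdin --matrix fixtures/expression_adipose.tsv \
    --metadata fixtures/metadata_adipose.tsv --network fixtures/scaffold.tsv \
    --disease GK --out wdin_adipose.tsv
wdinkit rwr --wdin wdin_adipose.tsv --seeds seeds.txt --out ranks.tsv
wdinkit rank-edges --wdin wdin_adipose.tsv --node-ranks ranks.tsv --out eranks.tsv
wdinkit core-module --wdin wdin_adipose.tsv --edge-ranks eranks.tsv \
    --out module_adipose.tsv
wdinkit merge --module module_adipose.tsv --module module_muscle.tsv \
    --module module_liver.tsv --alpha 0.1 --out mcm.tsv
wdinkit classify --mcm mcm.tsv --out classified.tsv --summary-out summary.json
```

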