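# Methods notes

## Rank normalization

Each sample column is ranked ascending over all genes present in the
input matrix (the most highly expressed gene gets the largest rank),
ties resolved by mid-ranks by default (`average`; `min`/`max`
selectable), then standardized by the mean and **population** standard
deviation of the column's rank vector. The population convention is
deliberate — the rank vector is the entire population of the column,
not a sample from one — and the choice only rescales every column by
the same factor, so the Spearman correlations computed downstream are
unaffected either way. The convention is recorded on the output object
(`sd_convention`). Matrices with missing cells are rejected rather than
imputed, and a constant sample column (σ = 0) is a hard error naming
the sample.

## Diverse-edge screening

Within-condition correlations are Spearman: values are re-ranked inside
each condition and Pearson is taken on those ranks (ties mid-ranked),
which makes the screen invariant to any strictly monotone
transformation of the raw data. The "strongly correlated" test is by
default on |ρ| — strong negative co-expression counts as strong — with
a signed alternative behind `use_absolute=False`; the thresholds
`hi = 0.8` and `lo = 0.2` are defaults, not constants, and are recorded
in the WDIN's graph attributes. Edges with an undefined correlation
(zero variance within a condition) or with a gene missing from the
matrix are skipped with logged counts. Only nodes incident to a
retained edge are kept. Note the two directional tests make the screen
symmetric: correlation may be high in either condition, and the weight
sign records which.

No significance test is applied to the correlation difference; the
screen is a plain double threshold. A Fisher z-test or permutation FDR
would be a natural extension but is out of scope.

## Random walk with restart

The transition matrix is column-normalized over transformed weights:
`M(u,v) = t(w(u,v)) / Σ_{x∈N(v)} t(w(x,v))`. WDIN weights may be
negative, and a raw negative weight cannot be a transition probability,
so the default transform is `t = |·|` — the magnitude of dysregulation
is what should attract the walker. `(w+2)/4` (`shifted`) and constant 1
(`unweighted`) are available alternatives.

For an undirected network this column-normalized `M` is exactly the
transpose of the row-normalized random-walk matrix, so the iteration

    p ← (1 − γ)·M·p + γ·(1 − η)·p₀

is the standard conservative random walk with restart: with η = 0 the
column sums of `M` are 1 and total probability is preserved at every
step (asserted to 1e-9 in the tests). The parameter η only rescales the
restart mass, multiplying the steady state by (1 − η) uniformly — ranks
are invariant to it — and defaults to 0. γ defaults to 0.3. Convergence
is declared when the L1 change between iterates falls below 1e-10
(default), with a hard error, not a silent truncation, at the iteration
cap. A dense linear solve of `(I − (1−γ)M) p = γ(1−η)p₀` is provided as
an independent oracle (guarded to ≤ 2000 nodes) and the two routes are
required to agree to 1e-8.

Score ties in the candidate ranking are broken by gene symbol, so runs
are bit-reproducible. For edge ranking, seed genes carry rank 0 under
the default `seeds_first` policy — they are by definition maximally
disease-associated, so edges touching them are disease-proximal — with
`drop_seed_edges` as the conservative alternative. Edge-index ties
break by lexicographic gene pair.

`validate_ranking` is a one-sided hypergeometric tail: the probability
of at least the observed number of external disease genes among the
top-k candidates, drawing k from all candidates with the covered
test genes as successes. Test genes overlapping the seed set are
removed first (seeds are not ranked).

## Core module and merging

The top-k% edge prefixes (2.5%…25% by 2.5%, cutoff = ⌈fraction ×
edges⌉) are nested by construction; each prefix's maximum connected
component (most nodes; ties → more edges, then lexicographically
smallest node set) is scored by the **average local** (Watts–Strogatz)
clustering coefficient, counting degree-< 2 nodes as zero. The
average-local flavor is chosen because a sparse random graph on N nodes
has average clustering near 1/N, which is the benchmark the selection
implicitly compares against; global transitivity is available through
networkx if wanted. Coefficient ties across fractions resolve toward
the smaller fraction — the more minimal module.

The per-interaction Jaccard index used for merging is not a uniquely
determined construction; the default defines, for edge e = (u, v) and
module X, the context set S_X(e) as the union of u's and v's neighbor
sets within X (empty when neither endpoint is in X) and takes
J = |S_A ∩ S_B| / |S_A ∪ S_B|. This is per-interaction and per-module
pair and varies smoothly with shared local wiring, which is what an
α sweep needs; a plain edge-set Jaccard (constant per pair) and an
adjacent-edge variant are implemented as selectable strategies.
Admission uses strict inequality (J > α) for at least one module pair;
the sweep reports the clustering coefficient of the MCM at each α
(empty MCM scores 0) and recommends the argmax, ties toward the larger
(stricter) α. MCM(α) is monotone non-increasing in α by construction.

Edge categories partition the MCM: present in one tissue →
`specific:<tissue>`; present in ≥ 2 tissues with discordant weight
signs → `differential`; concordant → `common`. An edge present in three
tissues with mixed signs is globally differential; the per-tissue-pair
summary additionally reports each pair's own concordance counts.
A zero weight is impossible for a retained WDIN edge and is rejected
defensively.

## Synthetic data

The generator emulates a two-phenotype, multi-tissue microarray study:
per tissue, a disease (`GK`) and a control (`WK`) cohort measured on
the same genes over an Erdős–Rényi scaffold standing in for a curated
interactome. Defaults — 200 genes at mean degree 4, 100 samples per
condition per tissue, 30 planted edges per tissue at Pearson 0.95 in
the high condition and 0 in the other, unit marginal noise — are the
conditions under which the package's recovery guarantees are stated.

Planted pairs are endpoint-disjoint (a matching) and drawn from
bivariate Gaussians, which keeps every planted correlation exact
without solving a joint covariance; a low-rank latent-factor generator
is the documented extension point for overlapping structure. An
optional weak global factor gives all non-planted genes a common
`background_r`. Two consequences matter for interpreting tests:

- Gaussian margins mean the planted Spearman correlation is
  (6/π)·asin(r/2), slightly below the Pearson target (0.95 → ≈ 0.942),
  so recovery thresholds are effectively tested against that value.
- A matching has no triangles, so WDINs built from these simulations
  have clustering 0 at every swept fraction and the core-module
  machinery degenerates to the top-ranked edge; the clustering-driven
  selection logic is therefore validated on constructed fixtures with
  known dense tops, and the simulation exercises plumbing,
  reproducibility and recovery instead. Passing tests consequently
  show correctness of each stage's contract, not that real tissues
  contain dense modules.

In `simulate_study`, a configurable number of planted pairs
(`n_shared`, default 10 of 30) are the same gene pairs in every tissue
with an independently drawn per-tissue direction, so merged modules
contain genuinely common and differential cross-tissue edges; the rest
are tissue-specific, half gaining and half losing correlation under
disease. All randomness flows from one integer seed through named,
order-independent substreams; every output is bit-identical under the
same spec.

## Numerical and degenerate-input choices

- Correlation of a within-condition constant gene is NaN and the edge
  is skipped, never imputed.
- S-score with zero common edges is defined as 0 (continuity from
  below); empty edge sets are errors, not zeros.
- Empty-graph average clustering is 0 by convention, consistent with
  the α-sweep reporting 0 for empty merges.
- Hypergeometric tail at k = 0 is exactly 1.
- All orderings that could tie (scores, edge indices, components,
  fractions, α) have documented deterministic tie-breaks.

## Validation problem sizes

The test battery uses 20 random graphs of ≤ 200 nodes for the RWR
oracle comparison, 500 random graphs of ≤ 12 nodes for exhaustive
clustering checks, 50 replicates each at N = 100 and 200 for the 1/N
scaling band, and 10 simulation seeds at the default design conditions
for recovery — sizes chosen so the whole suite and the acceptance
script each complete in seconds while keeping sampling error well
inside the asserted bands.
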