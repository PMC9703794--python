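# Methods

`conet` implements an integrative two-condition transcriptome analysis:
per-dataset differential expression across a compendium of case/control
studies, cross-dataset integration statistics, consensus co-expression
network inference per condition, and comparative network analysis
(differential centrality, bridge genes, modules, enrichment, druggability).
This note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Differential expression and integration

Each dataset is tested gene-wise with a moderated two-group t-statistic:
the pooled per-gene variance s²_g (df d_g = n₁+n₂−2) is shrunk toward a
prior fitted by moments across genes. Writing e_g = log s²_g −
ψ(d_g/2) + log(d_g/2), the prior df d₀ solves ψ′(d₀/2) = var(e) − ψ′(d_g/2)
(via a Newton inversion of the trigamma function) and s₀² follows from
mean(e); the posterior variance is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) and
the statistic has d₀+d_g df. This reproduces the standard empirical-Bayes
moderated t (verified against the reference R implementation to ~1e-12 in
the test suite); a plain Welch t is available as `method="welch"`. Genes
with zero residual variance in both arms get p = 1 when the arm means are
equal, p = 0 otherwise. P values are Benjamini–Hochberg adjusted within a
dataset; a gene is differentially expressed (DE) at adjusted p ≤ α
(default 0.05).

Cross-dataset statistics per gene:

* **occurrence** — number of datasets in which the gene is DE;
* **consistency** Cg = |upDatasets − downDatasets|, with full consistency
  when min(up, down) = 0;
* **significance score** ss = |log2FC| · (−log10 adjusted p), a
  non-negative deregulation magnitude (adjusted p floored at 1e-300). The
  score is used for ranking, so only its magnitude matters; defining it as
  a signed quantity would make down-regulated genes rank backwards.

Genes are ordered by occurrence, ties broken by larger median ss and then
gene id. Gene-set alteration frequency counts, per set, the datasets in
which the set is significantly overrepresented among that dataset's DEGs
(upper-tail hypergeometric, BH-adjusted across sets within the dataset,
adjusted p ≤ 0.05).

Cross-platform merging restricts to genes common to all datasets and
mean-adjusts by batch: per gene and batch the batch mean is removed and the
grand mean added back, leaving within-batch variances untouched.

## Consensus network inference

Per condition, the scaled compendium slice feeds an ensemble of 7
association estimators × 3 inference algorithms = 21 member networks:

* absolute Pearson, Spearman and Kendall (τ-b) correlations;
* mutual information I(X;Y) = H(X)+H(Y)−H(X,Y) on per-gene equal-frequency
  discretized data under four entropy estimators — empirical plug-in,
  Miller–Madow (plug-in + (occupied−1)/(2n) per term), Schürmann–Grassberger
  (plug-in on Dirichlet-smoothed frequencies, pseudo-count 1/K per cell),
  and James–Stein shrinkage toward the uniform distribution with the
  analytic optimal intensity. Entropies are in nats; negative MI estimates
  (possible under the bias corrections) are floored at 0.
* CLR (edge score √(max(0,z_i)² + max(0,z_j)²) with z the within-row
  z-score), ARACNE (Data Processing Inequality: the strictly weakest edge
  of each triangle is removed when it is more than `eps` below both
  others; marking uses the original weights), and MRNET (per-target greedy
  max-relevance/min-redundancy forward selection, edge score = the MRMR
  criterion at selection time, symmetrized by max, selection stops when the
  best criterion is ≤ 0).

The consensus is a Borda aggregation: each member ranks all gene pairs by
decreasing weight (average ranks on ties; absent edges share the worst,
tied rank), the consensus score is the mean rank, and the top
⌊density · n(n−1)/2⌋ pairs become edges with weight 1 − (meanrank−1)/M ∈
(0,1]. The default density 0.043 matches the sparsity regime of large-scale
skin co-expression consensus networks; for planted-structure recovery
studies the density should instead be sized to the planted structure (see
`CompendiumConfig.suggested_density`), since a cut far below the structural
pair fraction cannot represent the planted topology.

Numerical choices that matter:

* **Discretization.** Default ⌈√n⌉ bins. For MI-based inference at n ≈ 150
  samples this gives ~169 joint cells — more cells than samples — so the MI
  estimates are undersampled and the Miller–Madow occupancy correction
  (≈ −0.3 nats) dominates mid-strength signals. Recovery analyses therefore
  pass `mi_bins ≈ n^(1/3)` (6 bins at n = 150, 36 joint cells), which keeps
  the joint table well populated. This is a property of MI estimation, not
  of any particular dataset.
* **DPI tolerance.** `eps = 0` reproduces the strict DPI. With estimation
  noise, triangles whose two strong edges are nearly equal prune true edges
  about half the time; the recovery analyses use `eps = 0.1`, in the range
  recommended for the original DPI, to protect near-ties while still
  removing clearly indirect edges.
* Correlations enter as absolute values so all 7 estimators are
  "strength" scales comparable under ranking.

Communities are detected with Walktrap (random-walk length 4, cut at the
maximum-modularity level) on the weighted consensus; isolated nodes become
singletons; modules below 10 genes are kept but flagged excluded from
enrichment. Module ids are 1-based in decreasing size order.

## Comparative network analysis

Centralities (betweenness, harmonic closeness, degree) are computed on the
unweighted consensus topology; betweenness is the unnormalized
shortest-path pair count and harmonic closeness is well defined on
disconnected graphs. Per measure, integer ranks 1..N (most central first,
ties broken by gene id); each gene is summarized by the median of its three
ranks, and the differential centrality of a gene is |median rank in case −
median rank in control|, sorted descending.

A **bridge gene** is a non-DE gene adjacent to k ≥ 2 DEGs; it connects
C(k,2) DEG pairs (a strict variant counts only non-adjacent DEG pairs).
Case-specific bridges are the set difference of the two conditions' bridge
gene sets. The DEG set feeding the bridge analysis is "DE in ≥ K datasets";
K defaults to a majority of datasets (⌈n/2⌉) and is configurable — at the
23-dataset scale of real compendia a fixed K ≈ 10 is the equivalent choice.

Enrichment uses two one-sided tests: a one-sample Kolmogorov–Smirnov test
of a gene set's normalized rank positions against uniform (alternative:
shifted toward the top; exact D⁺ p values), and the upper-tail
hypergeometric overrepresentation test; BH adjustment is applied across
the tests of one analysis. Cross-network module similarity scores every
module pair by the hypergeometric p of its gene-content overlap.

The knowledge-base layer assembles a boolean gene × set membership matrix
from per-category GMT collections and tests every (module, set) pair by
ORA, or by KS-GSEA over a module-membership ranking (module members first,
both blocks ordered by a supplied gene ranking) — the ranking underlying
published cell-type-signature GSEAs of this kind is rarely printed, so it
is an explicit argument here.

Druggability: drug–target rows are joined onto the partition (targets
outside the universe dropped but counted), restricted to module-specific
drugs (all in-network targets in one module; a strict variant disqualifies
drugs with out-of-network targets), and summarized per module by ATC
level-2 class counts (first three characters of the code; a drug with
several codes counts once per distinct class) and by the drugs/genes ratio
with module size as denominator.

## The synthetic compendium generator

The generator produces multi-dataset two-condition compendia with known
ground truth. Expression is Gaussian on the log2 scale: baseline ~ N(7,1)
per gene, additive batch shift ~ N(0, batch_sd) per (gene, dataset),
latent-factor co-expression, and residual noise sd `noise_sd`. The model is
specified in **variance shares**: each factor is assigned a share of a
gene's variance per condition, the residual always has sd `noise_sd`, and
the correlation of two genes sharing a factor equals the geometric mean of
their shares exactly — adding a factor never silently dilutes previously
planted correlations.

Default study conditions: 5 datasets × (30+30) samples, 400 genes, 40 DEGs
shifted by 2 log2 units (sign fixed per gene, identical in every dataset),
four 40-gene modules at within-module correlation 0.7, 10 hub-switch
genes, 10 bridge genes, batch sd 1.0, noise sd 0.5.

The correlation architecture is condition-resolved (see the module
docstring for full detail):

* modules exist in both conditions; in the non-lesional condition module
  pairs are additionally coupled (share 0.5) — co-regulated in health,
  decoupled in lesion;
* hub-switch genes load two module factors in the lesional condition
  (loading signs arranged so no two hubs are statistically near-duplicate,
  which would make redundancy-penalizing inference prune their edges) and
  form a small peripheral block of their own in the non-lesional one;
* DEGs form lesional-only cliques (the substrate bridges connect) and
  non-lesional weak blocks among themselves;
* bridges load one DEG-clique factor in the lesional condition and are
  ordinary background-block members otherwise;
* background genes form condition-shared weak blocks, and a global
  backbone factor (per-gene share drawn once) makes the consensus network
  one giant component with a smooth, condition-stable degree continuum.
  Module genes participate in the backbone with a fixed share (0.2) but a
  random loading *sign*: each module gene is anchored into the giant
  component (anchoring only needs association magnitude), while the signed
  contributions average out across module pairs, so the mean within-module
  correlation stays at the requested level (individual pairs spread
  symmetrically around it, as in real modules with heterogeneous internal
  correlation).

Two asymmetries are deliberate. First, every gene carries *some* stable
structure in *every* condition: row-normalized inference (CLR) hands fully
unstructured genes compensatory chance edges, which would both randomize
the planted centrality switches and manufacture spurious non-lesional
bridges. Second, the non-lesional structural pair budget is kept at least
as large as the lesional one (via the module couplings), so at a single
consensus density the non-lesional network fills with genuine structure
and the unavoidable chance edges concentrate in the lesional network,
where the condition-specific statistics are insensitive to them.

What the generator does **not** emulate: probe-level artifacts, platform
differences beyond additive batch shifts, heavy-tailed or heteroscedastic
noise, correlated batch×condition confounding, partially overlapping gene
panels across datasets, and dependence between the DEG panel and the
module structure (all planted classes are disjoint gene sets). Passing the
recovery tests therefore shows that the pipeline detects these structures
when they are present at the stated signal-to-noise ratio — not that real
compendia satisfy the model.

## Problem sizes and defaults

Desk-scale analyses (tests, acceptance script) use the 400-gene defaults;
a full pipeline run at these sizes takes ~20 s on one CPU, dominated by
the 21-member ensembles of the two conditions. The implementation is
vectorized (one-hot joint-histogram accumulation for MI, sample-pair sign
matrices for Kendall) and scales to a few thousand genes; the published
full-scale regime (7310 genes, 21 members) is outside the intended desk
footprint.

## Known limitations

* The moment-based prior fit can return an infinite prior df when the
  variance dispersion across genes is sub-chi-square; the statistic then
  degenerates to a z-test, as in the reference implementation.
* MRNET's stop-at-zero rule prunes aggressively on dense association
  matrices; members are rank-aggregated, so this only shifts the
  consensus mildly, but single-member MRNET networks are sparse.
* The consensus is O(E·n²) in time; ARACNE is O(n³).
* Bridge discovery is threshold-free by construction (adjacency at the
  consensus cut); its stability therefore inherits the density choice.
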