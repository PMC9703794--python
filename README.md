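# conet

Consensus co-expression network analysis of two-condition transcriptome
compendia.

Chronic inflammatory skin disease is typically studied by contrasting
lesional with non-lesional skin from the same patients across many
independent microarray cohorts. Single-gene differential expression only
reveals part of the deregulation: the *co-expression relationships* among
genes also rewire between the two tissue states. `conet` is a Python
package for systems-biology groups who want to run that comparison end to
end on such a compendium — or on synthetic compendia with known planted
structure, which the package can generate itself to validate every step.

## The method

Given expression matrices from `D` datasets, each with lesional and
non-lesional arms (log2 scale):

1. **Per-dataset differential expression** — moderated two-group t-test
   (empirical-Bayes variance shrinkage) with Benjamini–Hochberg
   adjustment; a gene is DE at adjusted p ≤ 0.05.
2. **Integration** — per gene: occurrence (number of datasets where DE),
   consistency score `Cg = |upDatasets − downDatasets|`, and a per-dataset
   significance score `ss = |log2FC| · (−log10 adjpval)` ranking the
   strength of deregulation; per gene set: the number of datasets in which
   the set is overrepresented among the DEGs.
3. **Consensus networks** — after batch mean-adjustment, one network per
   condition from an ensemble of 3 inference algorithms (CLR, ARACNE,
   MRNET) × 7 association estimators (Pearson/Spearman/Kendall, mutual
   information under empirical, Miller–Madow, Schürmann–Grassberger and
   shrinkage entropy estimators), aggregated by Borda mean edge rank and
   cut at a target density; Walktrap communities.
4. **Comparative analysis** — per gene, the median of its betweenness /
   closeness / degree ranks in each network and the absolute difference of
   the two medians (differentially central genes); bridge genes (non-DE
   genes adjacent to ≥ 2 DEGs, counting C(k,2) connected DEG pairs) and
   their lesional-specific subset; KS-GSEA and hypergeometric
   overrepresentation of gene sets over modules; cross-network module
   similarity by gene content.
5. **Druggability** — drug–target tables mapped onto modules, restricted
   to module-specific drugs (all in-network targets in one module), and
   profiled by ATC level-2 class and drugs/genes ratio.

See `docs/methods.md` for the models, estimators and design choices.

## Worked example

Run the full pipeline on a synthetic compendium (5 datasets of 30+30
samples, 400 genes, 40 planted DEGs, four 40-gene modules, 10 hub-switch
genes, 10 bridge genes):

```python
from conet import PipelineConfig, run_pipeline
from conet.synthetic import CompendiumConfig

study = CompendiumConfig()           # the defaults above
cfg = PipelineConfig(
    out_dir="run",
    seed=1,
    synthetic=study,
    consensus_density=study.suggested_density(margin=1.0),
    aracne_eps=0.1,
    mi_bins=6,
)
report = run_pipeline(cfg)
print(report["stages"]["networks"]["edges"])
print(report["stages"]["bridges"])
```

prints

```
{'lesional': 8655, 'non_lesional': 8655}
{'n_bridges_case': 76, 'n_bridges_ctrl': 50, 'n_case_specific': 70}
```

i.e. both consensus networks are cut at 8655 edges, 76 genes bridge DEG
pairs in the lesional network, and 70 of them do so in the lesional
network only — the candidate list the method exists to produce (with the
default study it contains the planted bridge genes). The output directory
holds one TSV per stage: per-dataset DE tables, the occurrence/consistency
table, edge lists, module assignments, centrality and differential
centrality tables, bridge tables, enrichment results and the druggability
profile, plus `report.json` with every stage's parameters and counts.

The same workflow is available from the shell:

```bash
conet run-all --config config.yaml --seed 1 --out run
conet simulate --config config.yaml     # synthetic data only
```

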