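# bromebiogeo

Community-ecology analysis of prokaryotic ASV tables from tank
bromeliads — the small aquatic microecosystems that form in the leaf
axils of epiphytic plants. Each plant is a discrete habitat patch, which
makes bromeliad tanks a natural laboratory for asking whether microbial
communities assemble neutrally (random draws from a shared regional
pool) or are shaped by the environment of the forest the plant grows in.

The package is written for microbial ecologists working with amplicon
count tables (ASVs × samples) plus taxonomy, sample metadata and water
chemistry. It covers the downstream statistics of such a survey:

* **Table handling** — TSV I/O, the <1,000-read sample filter,
  proportions, rank aggregation, pooling of taxa under 1% into "others".
* **Diversity** — seeded rarefaction without replacement, effective
  number of species (inverse Simpson, ENS = 1/Σpᵢ²), Bray-Curtis
  distances, Kruskal-Wallis tests.
* **Null-model biogeography** — the analytical core:
  * mean Jaccard overlap, MJO = mean over sample pairs of |A∩B|/|A∪B|,
    tested against a *multinomial regional-pool null* that redraws each
    sample's ASV identities in proportion to their mean relative
    abundance while preserving per-sample richness and read totals
    exactly;
  * generalized (N-community) Morisita-Horn similarity
    C₂N = Σᵢ[(Σⱼpᵢⱼ)² − Σⱼpᵢⱼ²] / [(N−1)·ΣᵢΣⱼpᵢⱼ²],
    tested against a *row/column proportional null* that scatters the
    grand read total over matrix cells with probability ∝ rowsumᵢ·colsumⱼ;
  * per-ASV coefficient of variation of relative abundances, averaged
    over occurring ASVs, per forest and globally.
  Observed values in the lower tail of 1,000 shuffles indicate
  segregation — samples sharing fewer taxa than random assembly
  predicts.
* **PERMANOVA & PCA** — McArdle-Anderson pseudo-F on Gower-centered
  distance matrices for forest type and single environmental covariates;
  PCA of the tank-water physicochemistry.
* **Community structure** — core community (ASVs in every sample),
  forest-exclusivity Venn partition, silhouette-optimal hierarchical
  clustering of row-normalized ASV profiles.
* **Function annotation** — a FAPROTAX-style rule engine mapping
  taxonomy to putative metabolic groups (a miniature curated rules file
  ships with the package), with read-weighted functional composition and
  core functional groups.
* **Synthetic communities** — a generator of niche-structured and
  neutral datasets with known ground truth, used by the test suite and
  the analysis scripts in place of sequencing data.

## Worked example

```python
import bromebiogeo as bb

cfg = bb.study_shaped_config(seed=17)      # 17 samples, 5 forests, pool 5,000
ds = bb.generate_niche(cfg)                # counts + taxonomy + env + rules

t = bb.filter_low_depth(ds.counts, 1000)   # drops the 3 shallow libraries
rare = bb.rarefy(t, bb.min_depth(t), seed=17)

mjo = bb.mjo_test(rare, reps=1000, seed=17)
print(mjo.observed, mjo.null_values.mean(), mjo.format_p("low"))
# 0.1709...  0.3063...  < 0.001
```

The observed mean Jaccard overlap (0.17) lies far below every one of the
1,000 null communities (null mean 0.31): samples share far fewer ASVs
than random sampling of the regional pool predicts, i.e. the communities
are segregated by forest. The same dataset run through the numbered
drivers in `analysis/` (each writes its table under `results/`) prints,
among others:

```
global MJO = 0.171, null mean 0.306, segregation p < 0.001
CV between-forest (global) = 2.36; within-forest 0.59-0.79
MA = 0.146, null mean 0.951, segregation p < 0.001
PERMANOVA forest       R2 = 0.990  p = 0.0001
87.5% of ASVs occur in a single forest
profile clustering chose k = 5 (silhouette 0.585)
```

— abundance variability is higher between than within forests, the
Morisita index confirms segregation, forest type explains community
composition, and the ASV profiles cluster into one block per forest.

The same pipeline is available from the shell:

```bash
bromebiogeo simulate --mode niche --study-shaped --seed 17 --out-dir sim/
bromebiogeo filter --counts sim/counts.tsv --min-reads 1000 --out filtered.tsv
bromebiogeo biogeo --counts filtered.tsv --metadata sim/metadata.tsv \
    --reps 1000 --seed 17 --out biogeo.tsv
```

## Layout

```
src/bromebiogeo/   library (tables_io, diversity, biogeography,
                   community_structure, ordination_stats,
                   function_annotation, synthetic_data, cli)
analysis/          numbered narrative drivers (01_simulate ... 07_functions)
results/           small output tables written by the drivers
tests/             pytest suite incl. oracle and calibration checks
docs/methods.md    models, null models, parameter choices, limitations
```
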