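# Methods

This note documents the statistical machinery of `bromebiogeo`: the
models and null models it implements, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the
numerical and design choices made where conventions diverge.

## Data model and filters

The central object is an integer count table of ASVs × samples with a
sample → forest mapping. Samples with fewer than 1,000 total reads are
discarded before any statistic is computed; ASV rows that become
all-zero after sample removal are *kept* (and flagged in the log) so
that row indices stay stable across pipeline stages — the biogeography
operations ignore all-zero rows internally. Relative abundances are
per-sample proportions; taxa contributing less than 1% of the
dataset-wide **mean** proportion are pooled into "others" (the cutoff is
applied dataset-wide, not per sample, so per-sample totals are conserved
exactly).

## Rarefaction and alpha diversity

Rarefaction draws each sample down to a common depth **without
replacement** (multivariate hypergeometric), so rarefied column sums hit
the target exactly; the draw is seeded and bit-reproducible. The common
depth defaults to the minimum retained sample total. Alpha diversity is
the effective number of species ENS = 1/Σpᵢ² (inverse Simpson): the
number of equally abundant taxa with the same dominance. Group
differences in ENS use the tie-corrected Kruskal-Wallis test. ENS is
computed on a single rarefaction draw by default (averaging over
multiple draws changes values by well under the between-sample spread at
~10⁴ reads); Bray-Curtis distances are computed on proportions so that
residual depth differences do not masquerade as turnover.

## Null-model biogeography

Three statistics describe co-occurrence structure:

* **MJO** — mean over unordered sample pairs of the Jaccard similarity
  of presence sets (global, or within one forest).
* **CV** — for each ASV occurring in a scope, the standard deviation
  over mean of its relative abundances across the scope's samples
  (zeros included, sample SD with n−1); the reported value is the mean
  over occurring ASVs. Within-forest CVs use one forest's samples, the
  global CV uses all samples.
* **MA** — the N-community Morisita-Horn
  C₂N = Σᵢ[(Σⱼpᵢⱼ)² − Σⱼpᵢⱼ²]/[(N−1)ΣᵢΣⱼpᵢⱼ²] on per-sample
  proportions, equal to the classic two-community Morisita-Horn at
  N = 2. The C₂N form was chosen as the canonical multi-community
  generalisation; 1 means identical compositions, 0 complete
  segregation.

Each of MJO and MA is compared with 1,000 shuffled tables:

* The **multinomial regional-pool null** (for MJO) redraws, for every
  sample, its observed number of occupied ASVs from the pool without
  replacement with probability proportional to mean relative abundance
  (mean over samples of per-sample proportions), then allocates the
  sample's reads multinomially over the drawn ASVs; zero cells are
  repaired by moving a read from the currently largest cell, so
  per-sample richness **and** totals are preserved exactly. The
  regional pool is preserved in expectation, not exactly — exact joint
  preservation of the occupied-ASV union is impossible under
  independent per-sample draws, and richness and depth are the
  constraints that drive Jaccard overlap.
* The **row/column proportional null** (for MA) places the grand read
  total into cells with probability rowsumᵢ·colsumⱼ/T², preserving the
  grand total exactly and the margins in expectation. It is sampled by
  the exact factorisation "column totals first, then rows within
  columns".

p-values are reported two ways: the literal shuffle fractions
p_low = #{null ≤ obs}/reps and p_high = #{null ≥ obs}/reps, and the
observation-inclusive (k+1)/(reps+1) estimates which never return an
exact zero; a zero fraction is printed as "< 1/reps". The 1,000-shuffle
loops run in compiled (numba) kernels; for the MJO null only the
without-replacement draws are needed because the zero-count repair
guarantees presence = drawn set, which is what makes 100-seed
experiments tractable on one CPU.

### Calibration, and a deliberate caveat about plug-in weights

When the MJO null's pool weights are the *true* data-generating weights,
the test is exactly calibrated: data drawn from the null yield uniform
p_low (the suite checks Kolmogorov-Smirnov distance < 0.1 over 500
replicates) and nominal rejection rates at α = 0.05. Applied to field data,
however, the pool weights must be estimated from the tested table
itself. That plug-in step makes the test anticonservative for
segregation: the estimation noise is shared by all null communities, so
null samples overlap systematically more than independently sampled
data do, and on truly neutral data the plug-in test can reject at far
above nominal rates (approaching 100% at study-like depths in our
experiments). This is a property of the published method, not of this
implementation; the MA test has no free parameters beyond the table
margins and calibrates cleanly as-is. Consequently:

* `mjo_test` defaults to plug-in weights (the applied mode, faithful to
  how the method is used on real data — where the pool is by definition
  the observed ASVs);
* an explicit `pool_weights` argument supports conditional testing, and
  all calibration tests use it with the generating pool;
* a small plug-in p-value alone should be read as "segregation is at
  least this surprising under the estimated pool", and effect sizes
  (observed vs. null mean) should accompany it.

## PERMANOVA and PCA

PERMANOVA uses the McArdle-Anderson trace formulation: the squared
dissimilarities are Gower-centered into G, a hat matrix H is built from
the design (group indicators, or intercept + covariate for a single
numeric predictor), and pseudo-F = [tr(HGH)/(m−1)]/[tr((I−H)G(I−H))/(n−m)]
with m model columns. Working directly with traces of G handles the
negative-eigenvalue mass of non-Euclidean Bray-Curtis matrices without
corrections. Predictors are tested one at a time (marginal design);
samples missing an environmental value are dropped for that variable's
test and the n used is reported. The permutation p is
observation-inclusive, (1 + #{F* ≥ F})/(1 + nperm), and never zero; an
exact mode enumerates all n! label permutations for small n. A
saturated design (one group per sample) returns R² = 1 with p = 1,
since every permutation is a relabeling of a perfect fit. Environmental
PCA centers (and by default unit-scales) the variables; signs are fixed
by making the largest-magnitude loading of each component positive.

## Community structure

The core community is the set of ASVs with nonzero counts in every
sample, reported with per-sample proportions; it is computed on the
unrarefied filtered table by default (a rarefied table can be passed
instead — rarefaction can only shrink the core). The Venn partition
assigns every occupied ASV to the exact subset of forests where it
occurs. Profile clustering removes ASVs present in only one sample,
divides each remaining ASV's abundance vector by its own total, and
applies average-linkage hierarchical clustering on Euclidean distances
(both configurable); k is chosen to maximise the mean silhouette over
k = 2..10, with ties resolved toward the smallest k, and rows are sorted
by ASV id first so the result is independent of input order.

## Function annotation

A rules file maps functional groups to taxon patterns; a pattern is a
semicolon-separated rank path that matches a lineage if it occurs as a
contiguous run of ranks anywhere in it (case-insensitive), so a
family-level pattern catches every genus and species beneath that
family — the same extrapolation logic as literature-curated databases
like FAPROTAX, without their wildcard/exception grammar (a deliberate
simplification; the parser is a single extension point). ASVs may match
several groups; each (ASV, group) assignment contributes the ASV's read
count to that group's stream (an unweighted per-ASV mode exists), and
per-sample proportions are taken over all assignment streams. Groups
under 1% of total assignments pool into "others"; unassignable ASVs are
discarded from the proportions and reported as an unassigned fraction.
The bundled miniature rules file (17 groups, from chemoheterotrophy and
fermentation to methanogenesis, sulfate respiration, ureolysis and
parasitism) is a small curated stand-in written for this package.

## Synthetic communities

`generate_niche` emulates the survey regime the pipeline targets: five
forests along an elevation gradient; 5+3+3+3+3 samples (17, of which
three libraries can be forced below the 1,000-read cutoff to mirror the
field design); a regional pool of 5,000 ASVs with lognormal(0, 1.5)
abundances (heavy tail: a few dominant taxa, thousands of rare ones);
85% of non-core pool ASVs private to one forest; a 12-ASV core planted
in every sample (one read moved from the largest cell where needed, so
depth is conserved); per-sample depths uniform on 9,843–30,000 reads;
environmental variables as forest means plus Gaussian noise, with
temperature decreasing along the gradient and pH/salinity/IC carrying
group structure; taxonomy strings drawn from a lineage bank matched to
the bundled rules file, with a deliberately large unassignable
fraction. Sampling weights multiply the pool abundance by a ×6 boost
for a forest's own private ASVs and ×0.4 for shared ASVs; these two
constants were fixed at design time so that the *occupied* single-forest
fraction tracks the configured exclusivity (0.87 measured at 0.85
configured — private ASVs are occupied more readily than shared ones,
and some shared ASVs land in a single forest by chance) and shared taxa
carry a few percent of reads. `generate_neutral` drops all structure:
every sample is a multinomial draw from one shared pool and the
environment is noise around global means. Ground truth (per-ASV home
forest, core membership, true pool abundance) ships with every dataset.

What the generator does **not** emulate: within-forest heterogeneity is
much weaker than in real surveys (samples of a forest share one
sampling distribution), so forest-level PERMANOVA R² runs near 1 and
within-forest overlap near 0.7, higher than field values; there is no
sequencing-error, chimera or compositionality model; taxonomy is a
small bank, not a phylogeny. Passing tests therefore demonstrate that
the statistics detect the structure they claim to detect under known
ground truth — not that field data will show effects of this size.

## Problem sizes and tolerances in the test suite

Closed-form identities are checked to 1e-12, brute-force oracle
equivalence (Bray-Curtis, Jaccard/MJO, CV, C₂N) to 1e-12 on random
10×6 tables, and PERMANOVA p against full label enumeration exactly at
n = 4 and 6. Calibration experiments use 200 replicate datasets
(reps = 200) for the two null tests on ~80-ASV/8-sample tables and 500
neutral datasets (nperm = 500) for PERMANOVA type-I error, sizes at
which the suite completes on a single CPU. Structure recovery runs 100
generator seeds at the survey design (exclusivity 0.85, five forests,
14 samples, every library at 9,843 reads) with a 2,500-ASV pool —
segregation detection does not depend on pool size, and this keeps the
100-seed experiment to ~8 minutes; the analysis drivers and the
acceptance script run the full 5,000-ASV pool. All randomness flows
from explicit seeds; repeated runs are bit-identical.
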