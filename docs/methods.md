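# Methods

This note documents the statistical procedures implemented in `selnet`,
the choices made where the methodology was genuinely open, and what the
synthetic-data experiments do and do not establish.

## Normalization and filtering

Gene-level integer counts (genes × samples) are normalized by
upper-quartile scale factors: per sample, the 75th percentile of its
counts over the genes that are nonzero in at least one sample, divided by
the library size. Factors are centered to geometric mean 1; the effective
library size is library size × centered factor; CPM = count / effective
library size × 10⁶. Percentiles use linear interpolation between order
statistics (numpy's default), stated so that independent implementations
can agree bit-for-bit. log2 CPM adds a pseudocount of 1 inside the
logarithm — conventional, and it avoids −∞ for zero counts.

Genes enter the networks only if their mean CPM over all samples (both
lines pooled — the inclusion criterion is per region, not per line) is
strictly greater than 1. An all-zero sample is a hard error; all-zero
genes are retained through normalization and removed by the filter.

## Coexpression networks

Per line, the gene–gene Pearson correlation of log2 CPM is computed over
that line's samples (≥ 3 required; zero-variance genes are excluded with
a logged list). The network is **unsigned**: adjacency `a_ij = |r_ij|^β`.
The default soft power is β = 6, the standard operating point for
unsigned weighted networks; β can instead be chosen by the scale-free
criterion (smallest β whose connectivity distribution fits a power law
with r² ≥ 0.8 and negative slope), but on block-structured data the
criterion keeps improving with β while module resolution degrades, so the
fixed default is preferred and the chosen β is always recorded.

The scale-free fit discretizes connectivity `k` (off-diagonal row sums)
into 10 equal-width bins and regresses log10 bin frequency on log10 mean
`k` per bin, dropping empty bins; a sequence with fewer than three
distinct values is degenerate and fails with r² = 0. The network-level
gate is the fit on the **consensus** connectivity distribution; per-line
fits are reported alongside. When the gate fails, the modules are kept
but hub, connectivity, and wiring analyses for that network are skipped
with a warning and the run continues — the handling used for a brain
region whose data do not follow a power law.

Topological overlap is the standard unsigned TOM,
`T_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_u a_iu a_uj`, unit diagonal. The cross-line consensus
quantile-normalizes each line's strict-upper-triangle TOM distribution to
the mean of the sorted distributions and takes the component-wise
minimum; identical inputs therefore reproduce the common TOM exactly.

Module detection is a simplified dynamic tree cut: average-linkage
hierarchical clustering of `1 − consensus`, scanning ~60 cut heights
across the dendrogram and keeping the cut whose number of *qualifying*
modules is closest to the target count (default 25; minimum module size
default 100 genes in the pipeline). A cluster qualifies only if its mean
intra-cluster similarity is at least 1.5× the global off-diagonal mean —
without this cohesion gate, structureless data collapse into one giant
pseudo-module instead of staying unassigned. A final rescue stage (the
analog of the PAM stage of dynamic hybrid cutting) re-assigns each grey
gene to its most similar module when its mean similarity reaches the 5th
percentile of the members' own intra-module similarity. Labels are
arbitrary colors ordered by size; `grey` is reserved for unassigned
genes and carries no meaning across networks.

## Cosplicing networks

A gene's splicing state in a sample is its exon-proportion vector (exon
count / gene total; each exon weighted equally). Samples whose gene total
falls below 10 reads are masked (uniform placeholder, excluded from
distances). Per gene, samples are compared by Euclidean distance on
these vectors (Manhattan and Canberra are available switches; Euclidean
is the simplest metric consistent with equal exon weighting). The edge
between two genes is the Mantel correlation — Pearson correlation of the
vectorized strict upper triangles of their sample-by-sample distance
matrices; it is undefined (and the pair excluded) when either matrix is
constant. Single-exon genes cannot participate. The Mantel matrix then
flows through the same soft-threshold / TOM / consensus / module
machinery, with the same power-law gate; no permutation is attached at
network-construction time (adjacency needs the statistic, not a
p-value).

## Culling, connectivity, hubs

Genes are sorted by total connectivity (consensus-scale adjacency summed
over lines) and the shortest prefix carrying ≥ 90% of summed
connectivity is retained; boundary ties are broken deterministically by
input order. Per line, `k_total` is the off-diagonal adjacency row sum,
`k_within` restricts partners to the gene's module, and relative
connectivity `k_rel = k_within / max k_within` within the module (per
line) — the max-normalization is what produces a statistic "on a scale
from zero to one" with the most connected gene of each module at 1. Hubs
are genes at or above the 90th percentile of `k_within` within their
module. Line comparisons of mean total/intramodular connectivity use a
paired two-sided Wilcoxon signed-rank test across genes (nonparametric,
robust to the heavy right skew of connectivity).

## Differential tests

**Expression.** Per-gene Welch t-test on log2 CPM between lines with BH
FDR, directions split by the sign of the mean difference. This is a
deliberate, simple stand-in exposed behind a narrow interface; count-GLM
tests can be plugged in without touching callers.

**Wiring.** Edges live on the unsigned [0, 1] scale of the weighted
network, so an edge change between lines is `||r_H| − |r_L||`; the
per-gene statistic is the number of partners with a change ≥ 0.5. The
null permutes line labels over the pooled samples and recomputes both
correlation matrices, one seeded schedule shared by all genes so
gene-level p-values are comparable. Permutations are **balanced** — each
pseudo-line draws half of its samples from each true line, as in
SAM-style permutation testing. The reason is power, not validity: an
unbalanced split partially reconstitutes a planted line difference, so
the null of a truly rewired gene inherits a heavy tail that scales with
the split imbalance; balancing removes exactly that component, and
type-I calibration under the global null is verified empirically by the
simulation suite. The cosplicing variant applies the same contract with
Mantel edges, re-deriving each permuted line's distances from one
precomputed all-sample distance pool.

**Splicing.** For gene g with E exons, `D_g = (1/E) Σ_e |mean_H(p_e) −
mean_L(p_e)|` — the exon-equal L1 distance between line-mean usage
vectors, means over unmasked samples. Same balanced permutation null.
Note a geometric constraint of this statistic: two probability vectors
differ by at most 2 in L1, so `D_g ≤ 2/E`; large per-exon shifts are
only possible for genes with few exons.

All permutation p-values use the add-one convention `(b+1)/(B+1)`: valid,
never zero, with floor `1/(B+1)`. BH FDR is applied across genes within
each analysis. The pipeline default is B = 10,000; tests and the
acceptance script use 200–2,000 to hold runtime, sizes stated below.

## Enrichment and protection

Each module × flagged-set 2×2 table over the culled network's gene
universe gets exact one-tailed hypergeometric p-values in both
directions; the odds ratio gets a 0.5 continuity correction only when a
zero cell would make it undefined (flagged). P-values are Bonferroni
corrected by the number of modules tested. A module is **enriched** when
the corrected upper tail falls below α (default 0.01) and **protected**
(from the effects of selection) when the corrected lower tail does; the
two calls are mutually exclusive by construction. Cell-type marker sets
are consumed as user-supplied GMT files and are not bundled.

## Selection-phenotype statistics

Intake is concentration (mg/L) × volume (L) / body weight (kg);
preference is drug volume over total fluid volume. Realized heritability
regresses cumulative response `R_t` (offspring mean − founder mean) on
cumulative selection differential `S_t = Σ (selected parent mean −
population mean)`; the least-squares slope is h². The intercept is
fitted and reported by default (a through-origin variant is a flag) —
the regression-through-data choice leaves the slope interpretable when
the first generation over- or under-responds.

ΔΔCt: fold of sample i is `2^−(ΔCt_i − mean ΔCt of the reference
group)`, so one cycle below the reference mean (more transcript) is fold
2. Verbal descriptions of this method sometimes invert the sign
("reference average minus each value" under a negative power), which
would assign fold < 1 to higher-expressing samples; the implementation
keeps the conventional orientation and logs that choice at runtime.

## The synthetic-data generators

`simulate_count_dataset` draws negative-binomial counts (dispersion 0.05,
appropriate for inbred-line biological replicates; library sizes
log-normal around 10⁶) whose log2 means carry per-module latent Gaussian
factors. Loadings are signed, with signs chosen to balance the
abundance-weighted loading sum per module so the module signal cancels
out of the library total and survives CPM normalization. Loadings are
also inflated to compensate the predictable count-noise variance, so the
requested within-module correlation (default 0.6) is realized on the
observed log2 CPM scale rather than attenuated by it.

Two design modes are exposed. In the default **fixed design**
(`calibrate_correlations=True`), factor traces are standardized within
line and residuals are drawn orthogonal to the gene's own factor trace:
planted correlations are exact by construction, which is what a power
analysis of the wiring test needs — otherwise O(1/√24) realization noise
creates module-wide and gene-wide correlation dips that dominate the
operating characteristic. In the **random design**
(`calibrate_correlations=False`) realizations are sampled freely, giving
a broader, more data-like connectivity distribution (this is the mode
under which the scale-free criterion selects a power in the usual 4–12
range).

Planted effects: DE genes get ± half the log2 fold change per line
(alternating directions); rewired (DW) genes have their loading flipped
and attenuated in the HIGH line, `α = −(1 − Δ/c)`, which moves the
unsigned edge weight with every module partner by exactly Δ — this
requires `Δ ≤ c`, and the generator rejects configurations where an edge
would have to lose more weight than it has. The wiring power experiments
therefore use c = 0.8 with Δ = 0.7.

`simulate_exon_dataset` draws per-gene totals (log-normal around 500
reads) and multinomial exon counts whose proportion vectors blend a
baseline profile toward the reversal of its sorted self, driven by a
logistic per-module latent splicing state shared within line — this
plants the shared-splicing groups that cosplicing module detection must
recover. The mixing term is centered within line, so planted line-mean
differences are untouched by it. DS genes get line profiles whose mean
per-exon |difference| equals the requested shift exactly (amplitude
limited to keep proportions positive); because `D ≤ 2/E`, DS genes are
drawn only from genes with few enough exons, and infeasible requests are
rejected. Splicing-rewired genes follow a private state trace in the
HIGH line instead of the module's.

`simulate_breeding` is a variance-replenishing infinitesimal model:
phenotype = genetic + environmental with `var(g) = h²σ²`; each
generation the top fraction by phenotype is selected and offspring
genetic values are drawn about the selected parents' mean genetic value
with the base genetic variance, so the expected response is exactly
`h²·S` and the realized-heritability slope is unbiased. Bulmer-effect
variance erosion is deliberately not modeled — the estimator, not
quantitative-genetic dynamics, is under test. Defaults follow a
mass-selection design (120 founders, 26 selected, four phenotyped
offspring generations). A noise-free mode replaces sampling with a
deterministic quantile spread of genetic values, keeping variance alive
so "R = h²·S exactly, slope exactly 1" holds over multiple generations.

What the generators do **not** emulate: batch and sex effects, gene
length biases, isoform-resolution structure, correlated library
composition artifacts, or genetic relatedness among samples. Passing
tests on these simulations therefore establish internal correctness and
operating characteristics under the stated model, not performance on
real tissue data.

## Problem sizes and seeds

The deterministic reference simulation is 5 modules × 200 genes at
within-module correlation 0.6, 24 + 24 samples. Power experiments use
250 genes (5 × 50, c = 0.8, 10% planted, Δr = 0.7, log2FC = 2) and 500
genes for splicing (10% planted, shift 0.3), with 2,000 permutations.
Null calibration uses replicate 500-gene simulations with 200
permutations each. Heritability recovery averages 200 replicate
simulated studies. All randomness flows from single seeds through
`numpy.random.SeedSequence` substreams; a fixed seed reproduces every
table byte-for-byte.

## Known limitations

* The DE test is a Welch t on log2 CPM, not a count GLM; at very low
  counts its calibration degrades before a negative-binomial test's
  would.
* Module detection is a static-cut approximation of dynamic tree cut;
  deeply nested module structure may be merged or greyed.
* The Mantel matrix drops genes with any masked sample (to keep one
  shared pair set per line); with many low-count genes this is
  conservative.
* Mean-CPM filtering and upper-quartile normalization assume reasonably
  deep libraries; single-cell-scale sparsity is out of scope.
* `compare_mean_connectivity` treats genes as paired observations;
  connectivity values are not independent across genes, so its p-values
  are descriptive rather than strictly calibrated — as is standard for
  this comparison.
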