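# Methods

## Viral identification

Evidence arrives pre-summarized per contig (protein counts, viral-homology
hit counts, sorter category, k-mer score and p-value, BUSCO hit and gene
counts); the upstream search tools themselves are out of scope. The
decision rule is the union of three criteria, read literally from their
thresholds: the homology fractions ("at least 50%", "at least 3") are
inclusive, the k-mer bounds (score > 0.9, p < 0.05) strict, and the
BUSCO-ratio removal bound (≥ 5%) inclusive. A contig with zero predicted
genes gets BUSCO ratio 0 — absence of genes is absence of contamination
evidence, not evidence of contamination. Contigs shorter than 5,000 bp
(configurable) are dropped at ingest. These choices make the rule monotone:
adding viral evidence can never un-retain a contig, a property the suite
checks by randomized search.

## vOTU clustering

Viral contigs are clustered at ≥95% nucleotide identity and ≥80% coverage.
Coverage is measured against the **shorter** sequence, the convention that
lets genome fragments join their parent. Clustering is greedy centroid,
longest-first: contigs are visited by length descending (ties broken
lexicographically by id) and join the first established representative
reaching both thresholds, so the representative is by construction the
longest member and the procedure is deterministic and independent of input
order. Habitat catalogs merge by re-clustering the union of
representatives and unioning members.

Pairwise similarity uses a banded fit (semi-global) edit-distance
alignment of the shorter sequence inside the longer, then trims the
aligned columns to the best-scoring contiguous window under +1 per match
and −1 per mismatch or gap column. Identity is matches over window
columns; coverage is the window's share of the shorter sequence; `N`
never counts as a match. Pairs whose full-length fit distance exceeds a
25% ceiling are reported as (0, 0): a pair reaching 95% identity over
≥80% of the shorter sequence can accumulate at most ~24% total edits, so
the ceiling can not discard a clusterable pair. The test suite
cross-checks the trimmed-window identity against an exact local
Smith–Waterman alignment (match +1, mismatch −1, gap open −5, extend −2)
on 2-kb pairs; the two agree within ±0.005 at 2% divergence.

## Taxonomy vote

Each protein votes once through its best reference hit (bit score ≥ 50,
ties by score then family name). A family is assigned when its vote count
strictly exceeds one third of **all** predicted proteins of the vOTU (not
just the assigned ones); count ties resolve by larger summed score and
otherwise fall back to Unclassified. Family-level abundance sums member
vOTU abundances, including an Unclassified bucket, so per-sample totals
are conserved.

## Abundance

The relative abundance of a vOTU is its length-normalized read density
renormalized within the sample. Dividing instead by total mapped reads
(the alternative normalizer) differs only by a per-sample constant, so the
row-normalized proportion is reported and the mapped-read fraction (mapped
/ high-quality reads) is kept as a separate per-sample statistic. Presence
in a habitat means a nonzero count in at least one sample (no detection
threshold); high-abundance filters (> 0.01% for differential screens,
> 0.05% for networks and classifiers) are strict inequalities on the mean
over **all** samples, zeros included, computed globally by default with a
per-habitat option.

## Diversity, ordination, PERMANOVA

Rarefaction draws without replacement (multivariate hypergeometric);
alpha diversity (observed vOTUs and Shannon in nats) is averaged over
replicates at a common depth, defaulting to the shallowest sample's
total — the depth grid for rarefaction curves is fully configurable
because no single canonical grid exists. Beta diversity is Bray–Curtis on
relative abundances; a pair of all-zero profiles is defined as distance 0
with a warning. PCA standardizes columns (toggleable) and drops constant
ones.

dbRDA embeds the distance matrix by principal coordinates, drops
negative-eigenvalue axes (no Lingoes/Cailliez correction — the simplest
defensible treatment), and projects the embedding onto the centered group
design; constrained axes (CAP1, CAP2, …) are eigenvectors of the fitted
cross-product, with explained fractions relative to total positive
inertia. envfit reports r² = 1 − SS_within/SS_total of the first two axis
scores around group centroids with a label-permutation p. Note that
running envfit on the dbRDA's own constrained axes is circular (r² ≈ 1 by
construction); the acceptance script therefore fits it on the PCA
ordination.

PERMANOVA partitions the Gower-centered −D²/2 matrix by an arbitrary
centered design: categorical labels become one-hot indicators, numeric
covariates enter as regression terms (the adonis convention), so
SS_model = tr(GH) with H the design's hat matrix. Effect sizes are
R² = SS_model/SS_total with the Ezekiel adjustment
1 − (1−R²)(n−1)/(n−m−1); the cited permutation-based adjustment for
constrained ordination is not replicated. All permutation tests use the
+1 convention, so p ≥ 1/(n_perm+1), and take a caller-supplied seed.

## Differential tests and FDR

Two-group comparisons are two-sided Wilcoxon rank-sum: exact null
distribution when both groups have ≤25 tie-free values, otherwise the
normal approximation with continuity correction. Multi-group comparisons
are tie-corrected Kruskal–Wallis. All p-value families use
Benjamini–Hochberg, one family per (habitat, level, test) screen; the
empirical-null local-fdr machinery some workflows use for comparative
tests is deliberately not reproduced — BH is deterministic, standard, and
already the convention for the network families here. A feature is
"significant among cohorts" on the KW adjusted p < 0.05 by default, with
all pairwise results reported alongside.

## Networks and effect sizes

Virus–bacterium networks are built within each (cohort, habitat) stratum
(≥5 samples required) over all high-abundance pairs; Spearman rho uses
midranks with a t-approximation p (an exact permutation p is available for
n ≤ 8). Each network is one BH family; edges are kept at adjusted
p < 0.05 and signed by rho. The clinical-index network pools cohorts
within a habitat. Edge-set comparisons key edges by unordered endpoint
pair. Covariate effect sizes are single-term PERMANOVAs per covariate and
habitat, BH-adjusted within a panel; numeric covariates are not
discretized.

## Classification

Random forests (500 trees, √p feature subsampling, no class weighting —
the cited implementation's defaults, all exposed) are evaluated by
leave-one-out cross-validation: each sample's positive-class probability
comes from a forest trained on the other samples, and ROC/AUC (trapezoid)
pools the out-of-fold scores. Feature panels are selected **once** on the
full data (high-abundance taxa significant in the matching pairwise
screen), mirroring common marker-study practice; this leaks selection
information into the evaluation, which is why the suite also verifies by
a poisoning probe that the LOOCV itself never trains on the held-out
sample.

## Synthetic data

The generator emulates the study design end-to-end with recorded truth.
Defaults, chosen once as the study conditions: 30 subjects per cohort
sampled in all three habitats (270 samples); 40 seed genomes of 5–20 kb
each yielding 1–3 copies mutated at 2% substitutions (well inside the 5%
clustering radius) with optional end-truncation to ≥80% length, plus 20
unrelated decoy contigs; negative-binomial counts (size k = 1, i.e. heavy
over-dispersion) with log-normal feature means (ln-scale σ = 1.5),
per-habitat baseline profiles, and log-normal per-sample depth factors;
planted differential features multiply their mean by fold 8 in one
cohort; planted virus–bacterium edges and taxon–clinical links act
through shared Gaussian latent factors mapped through negative-binomial
quantiles (a Gaussian copula with latent correlation 0.8, which controls
the rank correlation Spearman measures); habitat-typical mapped-read
fractions (≈6%, 9.5%, 14%) set the high-quality read totals; 55% of vOTUs
get a dominant planted family in the synthetic protein-vote table. All
outputs are byte-deterministic given the config seed.

What the generator does **not** emulate: read-level sequencing error,
assembly chimerism or fragmentation beyond simple truncation, real
taxonomic composition, compositional closure effects beyond row
normalization, or covariate confounding between cohorts. Passing tests
therefore demonstrate correctness of the statistical machinery and the
decision rules under a controlled over-dispersed model — not performance
on real viromes.

## Problem sizes

The test suite runs the full pipeline at 10 subjects/cohort and the
power/calibration suites at the stated study conditions (30
subjects/cohort, 1,000 null simulations at n = 30 with 20 features, 50
random genome sets for the clustering oracle). The acceptance script uses
the default 30-subject configuration throughout and reports each
quantity's problem size alongside its value.

## Known limitations

- The greedy centroid clusterer approximates the unpublished "in-house"
  procedure; with well-separated synthetic cliques it equals brute-force
  clique truth, but on a continuum of divergences greedy and
  single-linkage answers differ.
- Fit-alignment coverage is near 1 whenever the shorter sequence aligns
  end-to-end; identity is then the operative threshold. Truly local
  repeats or chimeric joins would need the full local-chain machinery.
- PERMANOVA here is single-term; no sequential (Type-I) multi-term
  partitioning.
- The LOOCV evaluation inherits the selection-leak of select-once feature
  panels; a nested selection per fold is available via the library but is
  not the default, to match standard practice.
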