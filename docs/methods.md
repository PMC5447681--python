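# Methods

This note documents the models and procedures implemented in `altinet`,
the assumptions behind them, the tunable parameters and their defaults,
what the synthetic-data generators do and do not emulate, and the design
choices made where the analysis was genuinely under-determined.

## Study design assumed throughout

A paired two-group design: each subject is sampled at two timepoints
(`pre` and `post` exposure to high altitude) and belongs to one diagnosis
group (`AMS` or `non-AMS`, with AMS defined by a Lake Louise Score ≥ 3
including headache). The design table therefore requires exactly one pre
and one post sample per subject. The transcriptome arm defaults to 5
subjects per group; the cytokine validation arm to 22 subjects (12 AMS,
10 non-AMS).

## Read QC

Three whole-read filters in fixed order — (1) adapter, (2) unknown bases,
(3) low quality — each read counted under the first rule that removes it.

* *Adapter rule.* "Contains an adapter" is operationalized as an exact
  substring match of any configured adapter prefix of length
  ≥ `min_adaptor_overlap` (default 10) anywhere in the read. A longer
  prefix occurring implies its 10-mer prefix occurs, so only the 10-mer is
  searched. Full adapter-alignment/trimming is deliberately out of scope:
  reads are kept or dropped whole.
* *Unknown-base rule.* Removed iff count(N)/length **>** 0.10. The
  inequality is strict: a 100 bp read with exactly 10 Ns is kept.
* *Low-quality rule.* A base is low-quality when its Phred score is ≤ 5;
  the read is removed iff the low-quality fraction is **>** 0.50. Again
  strict: exactly 50% is kept.

Phred+33 is the default encoding. Paired-end mates are filtered
independently. Filtering is idempotent and permutation-equivariant, and
loosening any threshold can only keep more reads; the test suite asserts
all three properties.

## Quantification

RPKM: `count / [(length_bp/10³) · (library_size/10⁶)]`. Library sizes
default to column sums of the supplied count matrix, since true
mapped-read totals are rarely available downstream of counting. All
correlation- and feature-space work uses log₂(RPKM + 1); the pseudocount
is configurable. RPKM is used (rather than TPM) because it is the
normalization the analysis around it assumes; no cross-sample
normalization beyond library size is attempted.

## Boundary-density differential expression

For one group, per gene: A = mean log₂ expression over the group's pre and
post samples, M = mean(post) − mean(pre). Genes with no expression change
concentrate in a dense cloud in the (A, M) plane; changed genes sit in its
sparse boundary. The detector:

1. standardizes A and M to unit variance (default on, so the two axes
   contribute comparably);
2. estimates local density at each point as k/(n·π·r_k²), with r_k the
   distance to the k-th nearest neighbour and k = ⌈√n⌉ by default;
3. declares the points above the `density_quantile` (default 0.05)
   quantile of density the *core* and the rest the *boundary*;
4. calls a boundary gene DE iff its |M| exceeds the `effect_quantile`
   (default 0.95) quantile of |M| among core genes — this screens out
   boundary points that are extreme only in average expression.

Consequences worth knowing: the boundary can hold at most a
`density_quantile` fraction of the genes, which caps the number of DE
calls (the null false-call fraction is bounded by the same budget); the
method is deterministic and reports no p-values, so no multiple-testing
correction applies. The per-gene `score` column (mean of the |M| rank and
the inverse density rank) is provided for ROC-style evaluation only and
plays no role in calling. With duplicated points r_k can be zero; such
points get infinite density (deep core). If *all* points coincide there is
no boundary and nothing is called, with a warning.

The effect threshold is computed from the core of the current run, so the
threshold moves slightly as `density_quantile` changes; in practice (and
in the seeded tests) shrinking the boundary never adds calls.

## Enrichment and term clustering

Enrichment of a query gene set against a user-supplied GMT collection
uses the hypergeometric upper tail P[X ≥ k] with population N (universe),
K marked (term size), n drawn (query size). The *EASE* variant jackknifes
the overlap (k → max(k−1, 0)), so a single-gene overlap can never appear
enriched. Query genes outside the universe are dropped with a warning.

Terms are then clustered on the agreement of their memberships: Cohen's
kappa between the binary membership vectors of each term pair, restricted
to the query genes; terms with ≥ `seed_size` partners at kappa ≥
`kappa_threshold` seed groups; groups sharing ≥ `linkage` of the smaller
group's members merge until a fixed point (pairs are scanned in canonical
order, so the outcome is independent of input order); remaining terms
become singleton clusters, and a term may appear in several clusters. The
defaults (0.50, 3, 0.50) correspond to a "medium" classification
stringency. Each cluster's enrichment score is −log₁₀ of the geometric
mean of its members' EASE p-values; clusters with score ≥ 1.3 (geometric
mean p ≤ 10^−1.3 ≈ 0.05) are flagged as kept. No further multiple-testing
correction is applied — the score filter is the selection rule.

## Co-expression networks and differential connectivity

Adjacency: a_ij = |pearson(x_i, x_j)|^β, unsigned, with β = 6 by default
(β = 1 gives a raw-correlation network); zero-variance genes are excluded
with a warning. Topological overlap:

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu·a_uj,   k_i = Σ_{u≠i} a_iu,   t_ii = 1,

which upweights pairs sharing neighbours. Connectivity is the sum of a
gene's connection strengths with all other genes; tables report both raw
k and k/max(k). Networks are exported as three-column undirected edge
lists loadable by VisANT and generic graph tools. In the pipeline the
networks are built from the post-exposure (high-altitude) samples of each
group, over the DE-gene union.

Differential connectivity between groups is tested by permutation:
observed per-gene difference of connectivities, null built by pooling the
two groups' samples and re-splitting them into the original sizes B times,
p = (1 + #{|diff*| ≥ |diff|})/(B + 1), Benjamini–Hochberg across genes,
significance at q ≤ 0.05. Two deliberate choices:

* **The test statistic is adjacency connectivity, not TOM connectivity**
  (both networks are still reported as TOMs). TOM connectivity of a gene
  rises whenever its *neighbours* form a module, because the
  shared-neighbour term l_ij accumulates products of the gene's noise-level
  edges with the module's strong edges. With a module present in only one
  group, that lifts the TOM connectivity of every gene adjacent to the
  module and makes a TOM-based permutation test anticonservative for
  non-module genes (measured here: ~13% of background genes flagged at a
  nominal 5%). Adjacency connectivity changes only through a gene's own
  edges and keeps the background at the nominal rate while still flagging
  every module gene. `statistic="tom"` restores the TOM-based variant.
* **No cross-network normalization by default.** Dividing by max(k) ties
  every gene's statistic to the network's single most-connected gene: a
  strong module in one group rescales *all* of that group's connectivities
  and shifts every gene's difference (measured here: ~69% of background
  genes flagged). `normalize=True` is available for comparing networks of
  very different density, with that caveat.

Permutation p-values are bounded below by 1/(B+1); B ≥ 20 is enforced and
B = 500–1000 recommended. Under an exchangeable null the pooled p-value
distribution is approximately uniform (KS-checked in the tests).

## Cohort statistics

All tests are two-sided. Paired pre/post comparisons apply a Shapiro–Wilk
test to the differences at α = 0.05: normal-looking differences get the
paired t-test, otherwise the Wilcoxon signed-rank test (zero differences
dropped; exact null distribution when n ≤ 25 and no ties, else normal
approximation with continuity correction). Degenerate inputs are handled
explicitly: all-zero differences return p = 1 with a warning; a non-zero
constant difference (where both the gate and the t statistic are
undefined) returns the sign-test bound 2·0.5ⁿ with a warning. An exact
signed-rank null pmf (dynamic programming over the 2ⁿ sign assignments) is
included as an independent cross-check of the exact branch.

The cytokine–severity association is the Pearson product–moment
correlation of per-subject change (post − pre) against the Lake Louise
Score, with p from t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom;
`pearson_p_from_r` exposes the same computation for published r values
(the convention adopted: "r(22)" denotes n = 22 subjects, df = 20).
Group contrasts available only as published mean (SD) summaries use the
pooled-variance two-sample t-test from summary statistics.

## Synthetic data: what is emulated, and what is not

`SimConfig` defaults are the study conditions the generators emulate.

* **Counts** (`simulate_counts`): negative binomial with Var = μ + αμ²
  (α = 0.1), per-gene baseline means log-uniform on [5, 500], 2,000 genes,
  5 subjects per group, and a log-normal per-subject size factor
  (sd 0.15 on the log scale) shared by that subject's pre and post
  samples — the feature that makes paired analysis worthwhile. Planted DE
  genes have their post-timepoint mean multiplied by 2^±2 in their
  group(s); exclusive fractions 0.05 (AMS) and 0.04 (non-AMS) plus a
  common fraction 0.015 reproduce the qualitative structure of two
  overlapping DE programmes with a modest common core. Truth-set sizes
  are exactly ⌊fraction·n_genes⌋.
* **Co-expression** (`simulate_coexpression`): a 30-gene module driven in
  group 1 only by a shared per-sample latent factor of sd 5 against unit
  noise (within-module correlation 25/26 ≈ 0.96); group 2 module genes
  are independent with the same marginal variance; 20 samples per group.
* **Cytokine cohort** (`simulate_cytokine_cohort`): 22 subjects (12 AMS
  with LLS = 3 + Binomial(7, 0.4), 10 non-AMS with LLS ∈ {0,1,2}),
  baseline concentrations log-normal around 20 pg/mL, and change =
  b·LLS + ε with b = r·σ_ε/(σ_LLS·√(1−r²)) so the population correlation
  equals the −0.52 target exactly (with σ_ε = 0 the relation is perfectly
  linear and sample r = sign(target)).
* **FASTQ** (`simulate_fastq`): 4-line Phred+33 records with *exact*
  planted counts (⌊rate·n⌋) of adapter-bearing, high-N (strictly > 10% N)
  and low-quality (strictly > 50% of bases at Q ≤ 5) reads; clean reads
  have no N and no base below Q30, and all non-adapter reads are
  rejection-sampled against every 10-mer of the adapter so the filter's
  truth comparison is exact by construction.

Not emulated: sequencing error profiles, isoform structure, GC/length
biases, alignment artifacts, batch effects, real genome gene content, and
dependence between the DE programme and the co-expression module (they
are generated by separate routines). Passing the planted-truth tests
therefore demonstrates the algorithms' correctness and calibration under
this generative model, not their performance on real libraries.

## Problem sizes and numerics

The test suite and `scripts/acceptance.py` use: 20 replicates × 500
permutations (200 genes, 20 + 20 samples) for the type-I error of the
differential-connectivity test; one 200-gene planted-module run at B = 500
for its power; 20 null replicates of 2,000 genes plus one planted run of
2,000 genes (100 DE) for the DE detector; 1,000 simulated cohorts for the
correlation calibration; 20 random 8-gene matrices against a triple-loop
oracle (tolerance 1e−12) for the TOM algebra; and a 500-gene end-to-end
pipeline run executed twice for byte-level determinism. These sizes give
stable Monte-Carlo estimates (the stochastic rates move by well under
their tolerance across seeds) while keeping the whole suite under a
minute of compute.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline fans one global seed out to
per-stage seeds by CRC32 of the stage name, keeping every derived seed
below 2³¹. TSVs are written with a fixed float format (`%.10g`) so
identical analyses are byte-identical. Known limitations: the DE
detector's call count is capped by its boundary budget (an intrinsic
property, not a bug); kappa clustering on very large term collections is
quadratic in the number of terms; and the permutation test's resolution
is 1/(B+1).
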