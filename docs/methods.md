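# Methods

`trexp` analyses gene-by-library read-count matrices of the kind produced
by sequencing several cDNA libraries (organs, conditions) from one
organism, and complements the expression side with a molecular-rate
toolkit for asking whether one lineage evolves faster than its relatives.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data validation does and does not show.

## Count model and normalization

Counts x_ij (gene i, library j) are treated as a multinomial draw per
library: the library total N_j is fixed by the sequencing run and reads
fall on genes with library-specific probabilities. The synthetic generator
follows exactly this structure (`simulate_count_matrix`), which keeps
column totals exact; Poisson sampling was rejected for that reason. No
overdispersion beyond multinomial sampling is modelled — real biological
replicates typically show extra-multinomial variance, so type-I rates
measured here are a best case for real data.

Baseline expression weights default to log-normal(meanlog 0, sdlog 1.5),
giving the long right tail (a few very abundant transcripts, many rare
ones) that real transcriptomes show and that the entropy measures need to
be meaningful.

Before cross-library comparison, counts are full-quantile normalized:
every library's sorted value vector is replaced by the across-library mean
of the order statistics, so all libraries share one distribution. Ties
within a library receive the mean of the reference values over their tied
ranks, which preserves ties and within-library rank order. Two
consequences worth knowing:

* with ties present, the sorted columns are *not* exactly identical
  afterwards and a second pass is not exactly a no-op — the
  distribution-equality and idempotence guarantees (to 1e-12) hold for
  tie-free columns, which continuous or long-tailed data approximate well;
* quantile normalization on data where nearly all genes share one
  expression level (massive ties) is degenerate and can erase real
  signal; the PEG-recovery benchmark therefore runs the R test on raw
  draws, which is exact there because the simulated library totals are
  equal (depth scaling would be a no-op).

The simpler `library_total_scale` (scale each column to a common total) is
kept as the classical baseline comparator.

## The R test and gene calls

For one gene, R = Σ_j x_j ln( x_j / (N_j f) ) with f = Σ x_j / Σ N_j and
0·ln 0 = 0 — the log-likelihood ratio between library-specific and common
expression proportions. 2R is asymptotically chi-square with m − 1 degrees
of freedom (m = number of libraries), which supplies p-values. R is applied
to the normalized (real-valued) matrix with column sums as effective
totals; the formula is well-defined for positive reals, so normalized
values are not re-rounded.

Calls built on R, with defaults r_min = 8, fold_min = 2, α = 0.05:

* **PEG** (preferentially expressed gene): R ≥ r_min, the focal library is
  the unique maximum of the gene's values, and the focal value is ≥
  fold_min times the *mean* of the other libraries. "Versus the mean"
  is our reading of a fold against "the other sets" jointly; a
  per-library-pairwise reading would be stricter. Ties at the maximum
  yield no call (conservative), so each gene is a PEG of at most one
  library.
* **ubiquitous**: at least one read in every library and *all* m(m−1)/2
  pairwise two-library R tests non-significant at α. The plural
  "all tests" is interpreted as the full pairwise set — the most
  stringent reading.
* **stress-responsive**: R over all libraries ≥ r_min and the stress
  library's fold against the mean of the organ libraries ≥ fold_min or
  ≤ 1/fold_min (changes in either direction count).

At the default r_min = 8 the implied two-sided tail (2R = 16, df 3) is
~0.001, so with ~2,000 tested genes only a couple of null genes are
expected to pass R alone; the fold filter removes most of those.

The qRT-PCR helper `ddct` implements relative quantification
2^−ΔΔCt = 2^−[(Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_control],
vectorized over genes, for validating calls against wet-lab assays.

## Entropy profile

With p_ij = x_ij / Σ_i x_ij per library (t libraries), all in bits:

* diversity H_j = −Σ_i p_ij log2 p_ij;
* gene specificity S_i = (1/t) Σ_j (p_ij/p̄_i) log2(p_ij/p̄_i), where
  p̄_i is the across-library mean frequency — 0 for uniform expression,
  log2 t for a gene private to one library;
* specialization δ_j = Σ_i p_ij S_i, the expression-weighted mean
  specificity of what a library expresses.

Base-2 logarithms are used throughout (the natural unit for an
entropy-based comparison; the quantities are otherwise base-invariant up
to scale). Genes with zero total expression are dropped before S and δ.
Frequencies default to normalized counts; raw counts can be passed
directly since the transform is per-column.

## Category enrichment

One-sided hypergeometric over-representation: a category with K of N
universe genes and k of n query genes scores p = P(X ≥ k),
X ~ Hypergeometric(N, K, n) (scipy's survival function; verified against
exact integer enumeration to < 1e-12 relative for all N ≤ 60). Bonferroni
correction multiplies by the number of categories with K ≥ 1 in the
universe — observed categories, not a notional full catalogue — and
significance is declared below the corrected cutoff (default 0.01).
Multi-category genes count once per category; the default universe is all
annotated genes.

## Rate analysis

**Column filtering.** `clean_alignment_blocks` is a deliberately simple
conservation/gap filter standing in for block-filtering tools: keep
columns with gap/ambiguity fraction ≤ max_gap_fraction (default 0) and
majority-base frequency ≥ min_conservation (default 0.5) among resolved
residues, then drop kept runs shorter than min_block_length (default 10).
It removes regions of dubious positional homology but implements none of
the flank-conservation heuristics of the full tools.

**LogDet distance.** From the joint base-pair frequency table F of a
sequence pair (pairwise deletion of gap/N sites),
d = −¼ [ ln det F − ½ Σ_x (ln f_A(x) + ln f_B(x)) ]. LogDet stays
additive when base composition drifts between lineages, which matters
precisely when substitution processes differ across the tree. det F ≤ 0
(saturation) and zero marginals raise explicit errors naming the pair.

**UPGMA.** Classical average-linkage agglomeration; node heights are half
the between-cluster average distance, so the output is ultrametric. Ties
in the minimum distance break on the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest member), making the
tree deterministic. Because UPGMA assumes a clock, a rate-accelerated
lineage shows an inflated terminal branch — and, when strongly
accelerated, clusters in the wrong place entirely. Note that the two
leaves of a first merge necessarily share one height: a *mildly*
accelerated taxon that still joins its sister first cannot show the
longest terminal branch; the diagnostic works when the acceleration is
large relative to the local splits (the regime of interest).

**F81 machinery.** Transition probabilities
P_xy(t) = e^{−βt}[x=y] + (1−e^{−βt})π_y with β = 1/(1−Σπ²); branch
lengths are expected substitutions/site. The simulator draws the root
from π and resamples each site along a branch with probability
1 − e^{−βt} — the exact kernel, not an approximation. Only F81 is
implemented; it exercises the relative-rate logic fully, and richer
models (F84/GTR/Γ) would change p-values only marginally at the
divergences considered.

**Relative-rate test.** For taxa A, B and an outgroup O the 3-taxon star
likelihood Σ_s π_s P_sA(a) P_sB(b) P_sO(c) is maximized freely and under
the clock constraint a = b; 2ΔlnL is referred to chi-square(1).
Equilibrium frequencies are fixed at the empirical mean composition of
the three sequences (the "fixed rates" reading) rather than ML-estimated.
Optimization is multi-start L-BFGS-B on branch lengths bounded in
[0, 10] with lnL tolerance ~1e-8 (four fixed starts; the 64-pattern
likelihood makes each fit cheap and the surface is unimodal in practice).
Only a − b is identifiable on a star tree, so the reported rate ratio
â/b̂ depends on node placement and should be read as indicative; the LRT
and p-value are the inferential quantities.

## Validation benchmarks (trexp.benchmarks)

Every stage is validated on synthetic data with known truth; the study
conditions are fixed in `benchmarks.py` and reported by
`scripts/acceptance.py`:

* null calibration: 2,000 log-normal-baseline null genes, 4 libraries of
  10⁴ reads → type-I rate at the chi-square 0.95 quantile ≈ 0.05;
* PEG recovery: 2,000 equal-weight genes at expected baseline 25
  reads/library (totals 5×10⁴), 100 planted 4-fold PEGs → sensitivity
  ≥ 0.9, false-positive rate ≤ 0.01;
* quantile normalization: distribution equality and idempotence ≤ 1e-12
  on tie-free data, tie case by hand enumeration;
* entropy: closed-form extremes and a brute-force double-loop δ oracle
  to 1e-12 over 100 random matrices;
* hypergeometric tail: exact integer enumeration, all N ≤ 60, ≤ 1e-12;
* LogDet: hand-computed table; mean over 100 F81 pairs (t = 0.1, 10⁵
  sites) within 0.005 of truth;
* UPGMA: exact recovery of 100 random ultrametric trees (≤ 16 leaves);
* relative rate: likelihood vs enumeration ≤ 1e-10; type-I within 3 SE
  of 0.05 over 200 clock replicates (10 kb); power ≥ 0.9 and mean rate
  ratio 3 ± 0.5 under 3× acceleration;
* end to end: a library with 100 near-private planted genes tops δ in
  ≥ 95/100 runs; a 3×-accelerated taxon on a 5-taxon clock tree (5 kb)
  is UPGMA-longest and relative-rate significant (p < 0.05) in ≥ 90/100
  runs.

Problem sizes are desk-scale by design — large enough for the asymptotics
to bite, small enough that the whole suite runs in a couple of minutes.

**What passing does not show.** The generator draws independent
multinomial libraries from a fixed truth; real tag/EST data add
assembly ambiguity, chimeric contigs, within-condition biological
variance and composition effects none of which are modelled. Likewise the
F81 simulations match the inference model exactly; on real alignments,
model misspecification (rate heterogeneity, non-stationarity) inflates
relative-rate LRTs, which is why such studies report p-value bounds
across several models rather than one number.

## Known limitations

* No replicate-aware or overdispersed differential-expression model; the
  R test compares libraries, not conditions with replicates.
* Enrichment assumes exchangeable genes (no gene-length or abundance
  bias correction).
* The relative-rate test handles one triplet at a time; genome-scale
  scans should correct the resulting p-values for multiplicity.
* UPGMA is used deliberately as a clock diagnostic, not as a credible
  phylogeny estimator.
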