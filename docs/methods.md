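# Methods

This document records the statistical model behind the synthetic data
generator, the exact conventions adopted for each analysis step, the default
parameters and why they were chosen, and the package's known limitations.

## 1. Synthetic community model

`omicdiv.simulate` generates feature-by-sample count tables with the temporal
structure the pipeline is meant to detect. The model, per sample:

1. **Season-specific taxon sets.** A pool of `n_taxa_pool` taxa is partitioned
   into per-season active sets of size `richness_by_season[season]`. Adjacent
   seasons share `1 − turnover` of the smaller set (default turnover 0.7), so
   community composition turns over between seasons while retaining some
   overlap.
2. **Lognormal rank abundance.** Within a season, active taxa receive lognormal
   weights (`lognormal_sigma`, default 1.5), normalized to proportions.
   A lognormal species-abundance distribution is the standard default for
   marine bacterioplankton and yields realistic singleton fractions (~40–55% of
   observed features at depths of a few thousand reads).
3. **Pinned dominant taxon.** One designated taxon is reassigned exactly
   `dominant_fraction` (default 0.25) of the mass, with the remainder rescaled.
   This makes the "one OTU dominates a quarter of the community" structure exact
   in expectation rather than a lucky draw.
4. **Diel effects.** Each `DielEffect(taxon, season, fold)` multiplies the
   taxon's proportion by `fold` in night samples of that season, and the other
   taxa are rescaled so the night:day proportion ratio of the affected taxon is
   *exactly* `fold` before sampling noise. `planted_base` pins the affected
   taxon's day-time proportion so the fold-change is recoverable at finite depth
   (see §6).
5. **Multinomial sampling.** Counts are drawn multinomially at `depth` reads per
   sample (default 4070, the smallest 16S sample depth in the reference survey),
   so column sums are exact — a property the rarefaction and coverage code can
   rely on. All draws flow from a single `numpy` Generator seeded from
   `spec.seed`; identical spec + seed reproduces byte-identical tables.

`seasonal_preset(seed)` is the configuration used by the acceptance
simulations: pool 1100, winter/spring/summer richness 550/200/180, one
winter-diel taxon at 15-fold with a 3% day-time share, six samples
(3 seasons × day/night).

**Read-level generators.** `generate_amplicon_reads` emits
MID + forward primer + taxon-specific insert + distal primer, with optional
substitution errors, N injection, and a corrupted fraction (wrong MID, short, or
low quality; corrupted reads draw qualities at mean 25 vs 38) to exercise every
filter rule. `generate_shotgun_fragments` samples codon-aligned substrings of
stop-free synthetic coding references in proportion to per-sample gene weights,
recording per-fragment gene truth; a metatranscriptome variant applies
night-time expression multipliers.

## 2. Read quality control

Amplicon rule order (first failing rule is charged in the report): exact MID
prefix → exact proximal primer → distal primer within ≤1 mismatch searched in
the terminal 1.5×-primer-length window → no N in the trimmed insert → trimmed
length ≥ 50 nt → trimmed mean quality ≥ 30 (reads without qualities skip this
rule and are counted). Boundary semantics follow the printed inequalities
strictly ("<50 nt", "<30"). An MID map in which one barcode is a prefix of
another is rejected as a configuration error because demultiplexing would be
ambiguous.

Shotgun rules: N-fraction > 10% → length < 75 bp → any single base > 60% →
exact sequence duplicates (first occurrence kept, ids and qualities ignored).
Filtering is idempotent and the report conserves reads
(input = passed + Σ rejections).

## 3. pORFs and clustering

- **pORFs** are maximal stop-free translated segments strictly longer than 40
  amino acids from any of the six reading frames; no start codon is required
  because shotgun fragments rarely contain gene starts. Codons containing any
  non-ACGT base translate to `X` and count toward the length (upstream QC
  already caps N content). Coordinates are reported on the forward strand,
  0-based half-open.
- **Protein families** use CD-HIT-style greedy clustering: sequences sorted by
  (length desc, sequence, id) join the first cluster whose representative they
  match at ≥ identity with coverage of the representative ≥ 0.80. Identity is
  measured against the shorter sequence (CD-HIT's convention) from a
  semi-global alignment with free end gaps (match +1, mismatch −1, gap open −5,
  extend −1); coverage is the aligned span on the longer sequence over its
  length. A 95% pass over all pORFs is followed by a 60% pass over the 95%
  representatives; families with ≤ 2 total members are dropped from the family
  matrix. Because the processing order is re-derived internally, the partition
  is independent of input order, and it is verified against a brute-force
  oracle.
- **OTUs**: pairwise global-alignment distances
  (mismatches + internal gap columns)/alignment length with terminal gap columns
  excluded; 2% single-linkage preclustering (abundance-descending, transitive)
  absorbs likely sequencing variants into abundant parents; then
  abundance-weighted average-linkage agglomeration is cut at 3/6/10%.
  Weighting by precluster abundance makes the agglomeration equivalent to UPGMA
  on the abundance-expanded data, so preclustering does not distort the linkage.

## 4. Diversity indices

All indices operate on rarefied counts (multivariate hypergeometric subsampling
without replacement; upsampling is an error). Good's coverage is implemented as
*C = (1 − n₁/N) × 100* — the printed formula "C = 1−(ni/N)×100" parses to a
negative quantity if read literally, and the adopted parenthesization reproduces
every packaged coverage value. Margalef *d = (S − 1)/ln N* was adopted because
it reproduces every packaged richness-index cell; Simpson dominance uses the
bias-corrected form *λ′ = Σ nᵢ(nᵢ−1)/(N(N−1))* (the plug-in Σpᵢ² is available
via a flag).

## 5. Multivariate comparison

Similarities are kept on the 0–100 percent scale; dissimilarity = 100 −
similarity everywhere.

- **SIMPROF**: at each UPGMA node with ≥ 3 samples, the ordered pairwise
  Bray–Curtis similarity profile is compared to the mean profile from 1000
  within-feature permutations (each feature's values permuted independently
  across samples); the statistic is π = Σ_r |S₍r₎ − S̄₍r₎| and the p-value
  ranks the observed π among 999 independent permuted π values with the
  observed included: p = (1 + #{π_perm ≥ π_obs})/(999 + 1). Descent stops below
  non-significant nodes; two-sample nodes are untestable by construction. The
  permutation engine is vectorized over blocks of 250 permuted matrices.
  Calibration is verified by simulation (type-I error ≈ α within 2 s.e. over
  200 null matrices).
- **ANOSIM** uses mid-ranks of all pairwise dissimilarities;
  R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2. `n_perms=None`
  enumerates all label permutations exhaustively; otherwise the p-value counts
  the observed labelling in numerator and denominator, so p ≥ 1/(n_perms+1).
- **SIMPER**: for each between-group sample pair (j,k), feature i contributes
  100·|y_ij − y_ik| / Σᵢ(y_ij + y_ik); contributions are averaged over pairs.
  The per-feature contributions sum exactly to the mean pairwise Bray–Curtis
  dissimilarity between the groups, and contribution percentages sum to 100.
- **NMDS** minimizes Kruskal stress-1 with isotonic regression of configuration
  distances on the dissimilarity order (primary tie treatment), using
  scikit-learn's SMACOF for the iterations. Restart policy: the first start is
  the classical-MDS (principal coordinates) configuration; one start is the best
  (k−1)-dimensional solution padded with a zero column — this guarantees the
  reported stress is non-increasing in k, since a zero column leaves
  configuration distances unchanged; remaining starts are random. If an initial
  configuration already has lower stress-1 than the SMACOF output (possible on
  perfectly embeddable inputs where SMACOF's own loss differs from stress-1),
  the initial configuration is kept.
- UPGMA ties are broken by the lexicographically smallest merged leaf-name set,
  making dendrograms reproducible.

## 6. Design decisions in the acceptance simulations

- **Planted diel taxon at a 3% day share.** The recovered fold-change at depth
  4070 is a ratio of two multinomial counts; at the survey-like share of ~0.4%
  the log-ratio standard deviation (~0.26) would make ±20% recovery fail in a
  third of replicates regardless of implementation correctness. At a 3% day
  share the log-ratio s.d. is ≈ 0.09, giving ≈ 97% recovery within ±20% — the
  test then measures pipeline correctness, not shot noise. This was computed
  from the binomial variance before the acceptance thresholds were run.
- **SIMPROF power construction**: two groups of 4 samples, gamma(1, 10) feature
  abundances, a 15-fold shift on 30% of features — the magnitude matching the
  planted diel effect. Criterion tests use 200/199 permutations per test purely
  for runtime; with 199 test permutations the rejection rule p ≤ 0.05 has exact
  level 10/200 under exchangeability.
- **Problem sizes** (read-level stages at depth 120–150 reads, ≤ 80 dereplicated
  inserts for OTUs, gene pool 40) are the package's own choices: pairwise
  alignment clustering is quadratic and these sizes keep the full pipeline and
  test suite within minutes on one CPU while still exercising every rule.

## 7. What the generator does and does not emulate

Emulated: lognormal rank-abundance with realistic singleton fractions; seasonal
turnover with winter > summer richness; exact dominance and diel fold-changes in
expectation; multiplexed read structure (MIDs, primers, substitution errors,
N injection, corrupted reads); codon-aligned stop-free coding fragments with
per-gene expression structure.

Not emulated: chimeras, pyrosequencing homopolymer error profiles, rRNA
contamination of metatranscriptomes, phylogenetically structured sequence
similarity between taxa (taxon references are independent random sequences, so
synthetic OTU counts are not calibrated to real 16S divergence), and
environmental covariates.

## 8. Other limitations

- The greedy clustering is exact but quadratic; there is no k-mer prefilter, so
  inputs beyond ~10⁴ sequences are impractical.
- SIMPROF p-values are permutation-resolution-limited (≥ 1/(n_test_perms+1)),
  and with six samples ANOSIM's smallest achievable p is bounded by the number
  of distinct labelings.
- Simpson evenness is reported with the bias-corrected λ′; whether a plug-in
  variant better matches any particular published table cannot be decided
  without the raw abundance vectors, so both are computed.
- The packaged reference table (`omicdiv/data/survey_diversity_tables.tsv`)
  stores printed values as strings so each check compares at its printed
  precision; one combined-sample coverage total that is internally inconsistent
  in its source was excluded from the fixtures.
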