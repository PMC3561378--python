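# Methods

## Problem setting and data model

Chromosome-conformation-capture experiments (4C/Hi-C) report pairs of
genomic loci found in spatial proximity; each pair carries a *count
frequency* — the number of sequenced ligation fragments supporting the
contact — interpreted as a proxy for contact probability.  The pipeline
asks whether genes whose loci touch in trans (on different chromosomes)
are co-expressed across a large expression compendium, and whether
functionally coherent gene sets are enriched in such mutual contacts.
Intra-chromosomal contacts are excluded throughout the core analyses:
sequence proximity alone induces co-expression (shared chromatin
environment, read-through, copy-number), and restricting to trans pairs
removes that confounder.

Coordinates are 1-based inclusive everywhere (GFF3/SGD convention).
Contacts are unordered; records are canonicalized so that the
lexicographically smaller `(chrom, pos)` locus comes first, and
canonicalization is idempotent.

## Contact → gene mapping

A gene is assigned to a contact locus when its distance to the locus is at
most `offset_bp`.  Two anchor conventions are provided:

* **boundary** (default): distance from the locus to the gene interval
  `[start, end]` (0 if inside).  This is the natural reading of "within an
  offset of the gene" and is the default because regulatory contacts can
  act on either gene end.
* **five_prime**: distance to the strand-aware 5′ end, used by the sliding
  window-position profile that probes asymmetry around transcription
  starts.

Every gene at end A is paired with every gene at end B (all overlapping
genes are kept — yeast genes are dense and a 500 bp offset frequently
reaches two genes).  A gene assigned to both ends never pairs with itself;
such self-pairs are counted and logged.  Multiple contacts supporting one
gene pair collapse to a single link whose frequency is by default the
**max** of supporting counts — so "linked at level f" means *some* contact
reaches f — with **sum** available.  The count threshold is `>= min_count`
(default 5) everywhere.  Filtering is monotone: raising the threshold or
shrinking the offset can only remove links.

The assignment uses vectorized per-chromosome interval-distance arrays; an
exhaustive triple-loop implementation is kept in the test suite as an
independent oracle and the two are compared exactly on randomized toy
genomes across offsets, thresholds, anchor modes and aggregations.

## Co-expression statistics

Expression intensities (linear scale) are normalized by dividing every
sample by its mean over non-missing values; the operation is idempotent
and a `from_log2` flag first maps log2 data back to linear scale.
Pair co-expression is the Pearson correlation of two gene profiles.  With
complete data this is a dot product of standardized rows; with missing
values each pair falls back to its jointly observed samples and is
excluded below 30 shared samples (pairwise-complete policy).  Pairs with a
zero-variance profile are excluded and logged.

The **background** ("genome-wide average") is the mean correlation over
*all* trans gene pairs, linked pairs included — the linked set is compared
against the population it is drawn from, not its complement.  Above a
configurable cap (10⁶ pairs) the background is estimated from a seeded
uniform subsample and the output records which mode ran.  Distributional
significance uses the two-sample Kolmogorov–Smirnov test between linked
and background correlation samples.

Derived analyses reuse this engine:

* **Frequency-threshold curve** — mean linked correlation at increasing
  count thresholds; row f = 0 is the background.
* **Offset sweep / window-position profile** — assignment-parameter
  robustness; the window profile slides a fixed-width window (default
  4000 bp) along the transcription direction relative to the 5′ end.
* **Chromosome-pair regression** — per chromosome pair, mean trans
  correlation against links per kbp of summed chromosome length
  (`(L_i + L_j)/1000`); the association is summarized by Pearson r across
  the C(n,2) pairs with t = r·√((n−2)/(1−r²)) and a one-tailed p (the
  hypothesis is directional: more contact, more co-expression).
* **Expression-rank enrichment** — genes binned by mean normalized
  expression; a bin's link-endpoint count (degree sum, since the effect is
  attributed to individual genes' expression level) against size-matched
  random groups.
* **Centromere–telomere profile** — each gene's relative arm position is
  |gene midpoint − centromere midpoint| / arm length, arms anchored at the
  centromere midpoint and the chromosome ends (coordinate 1 or the
  chromosome length); genes inside the centromere sit at 0.  Bin-wise mean
  correlation of same-bin trans pairs measures how much
  centromere/telomere clustering alone could explain the global signal.
* **Exclusion sensitivity** — recompute the linked and background means
  with listed gene pairs masked, or listed genes removed, and report the
  deltas (e.g. to show duplicated gene pairs do not drive the result).

## Contact-matrix normalization

The contact map is a symmetric locus × locus matrix of summed counts
(diagonal excluded).  Three normalizations address fragment-level
experimental bias:

* **linear**: M′ᵢⱼ = Mᵢⱼ/(Σᵢ·Σⱼ) with row/column sums;
* **Euclidean**: the same with row/column 2-norms;
* **SCN**: iterate column-normalize then row-normalize (unit Euclidean
  norm) until the largest entry change drops below `tol` (default 1e-6,
  max 100 iterations), then symmetrize as (M + Mᵀ)/2.

Zero rows/columns are left untouched and flagged.  For symmetric input the
row statistics are reused for the columns, which keeps the output bitwise
symmetric and makes the linear normalization's scale-invariance of entry
ranking exact in floating point.  On dense matrices SCN reaches unit
row/column norms within ~1e-8 in a handful of iterations; on very sparse
fragment-level maps the Sinkhorn-type iteration contracts slowly and may
hit the iteration cap, in which case the result is returned with
`converged=False` and a warning — the ranking robustness analysis is
unaffected.  Top-N selection ranks trans locus pairs by normalized weight
(ties broken by the lexicographic locus key, deterministic across
platforms) and maps them to distinct gene pairs; its output table carries
the real-valued normalized weight in the frequency column.

## Monte-Carlo gene-set enrichment

For a gene set the observed statistic is the number of links (frequency ≥
threshold) with **both** endpoints in the set.  The null draws `n_perm`
(default 1000) random gene groups, uniformly without replacement from all
annotated genes (the whole-genome frame; an expressed-genes frame can be
had by passing a restricted annotation), each matched to the resolved set
size.  Reported per set × threshold: expected mean and SD over groups,
ratio = observed/expected, Z = (observed − mean)/SD, and an add-one
empirical p-value.  Because the enrichment/depletion direction is chosen
from the data, the reported `p_empirical` doubles the smaller one-sided
tail (capped at 1) so that the null rate at level α is α, not 2α — the
test suite checks this calibration over 200 null sets.  A normal-tail
p-value from Z (`z_p_normal`) is reported alongside for resolutions finer
than 1/n_perm; it assumes approximate normality of the permutation null.
Each (term, threshold) pair derives its own RNG stream from the master
seed by stable hashing, so results are independent of evaluation order.

## Contact networks

A gene set's contact network is the undirected graph on *all* its
annotated genes (isolated nodes included — a set's sparseness is only
meaningful relative to its full membership) with edges for links above the
threshold, weighted by frequency.  Reported: edges per node, isolated-node
count, component sizes.  Exports (edge-list TSV, DOT) are deterministically
ordered.  Component structure is validated against a union-find oracle.

## Resampling significance

* **Random-link null**: each replicate draws the observed number of
  distinct trans gene pairs uniformly (without replacement — links are
  distinct physical interactions) and takes the mean pair correlation;
  the ensemble mean/SD locate the genome-wide mean and its spread at the
  observed sample size.  Pair correlations do not change between
  replicates, so they are computed once and replicates resample the means,
  which makes large ensembles cheap without changing the statistic.
* **Bootstrap**: replicates keep ⌊frac·n⌋ of the measured links (default
  frac 0.5) without replacement and recompute the mean linked correlation;
  skewness is reported as a near-normality diagnostic.  The replicate SD
  follows the finite-population formula Var = (S²/k)(1 − k/n), verified in
  the tests by the √3 SD ratio between frac 0.25 and 0.5.
* **Separation**: (observed − null mean)/null SD summarizes how far the
  measured statistic sits outside the null ensemble.

Random draws happen at the gene-pair level, matching the statistic being
computed; both procedures are bit-reproducible for a given seed.

## Synthetic data generator

The generator emulates the statistical structure the pipeline detects,
with exported ground truth:

* **Genome** — a deterministic gene grid (default 10 chromosomes × 50
  genes of 1500 bp with 1000 bp intergenic spacing, alternating strands),
  centromeres at 0.4 of each chromosome, and a seeded 10% of genes flagged
  *dubious*.  The intergenic spacing exceeds twice the default offset, so
  planted loci never spill onto neighbouring genes.
* **Expression** — one latent factor per module:
  gene g in module m has latent √ρ·F_m + √(1−ρ)·ε_g, mapped to positive
  intensities as `baseline + exp(shift·latent)` (default baseline 4,
  shift 0.25).  The exponential attenuates the latent pair correlation by
  (e^{ρs²}−1)/(e^{s²}−1) (≈2% at s = 0.25); the additive baseline mimics
  the stable bulk of real intensity compendia (nonspecific background and
  high-abundance housekeeping signal), keeping per-sample means nearly
  constant.  Sample-mean normalization necessarily removes each factor's
  cross-gene common mode, attenuating pair correlation by roughly
  (1−q)²ρ/((1−q)²ρ + 1−ρ) for a module holding a fraction q of the genes;
  configurations that must *observe* the planted ρ therefore use many
  small modules (q ≈ 2%) and a mild shift.  A single factor per module
  suffices because only pairwise Pearson correlation is measured.
* **Modules** — non-dubious genes drawn round-robin over a random subset
  of chromosomes per module (default half).  This makes nearly all
  same-module pairs trans, and — because each module lives on its own
  chromosome subset — link density and co-expression co-vary across
  chromosome pairs, the coupling the chromosome-pair regression detects.
* **Contacts** — every trans gene pair receives a contact with the
  background probability (default 0.02); same-module pairs at
  multiplier × background (default 2×, or an explicit module rate).
  Counts are Poisson truncated to ≥ 1 (every sequenced contact was seen at
  least once), λ = 4 background and 10 for modules; in stratified mode
  each module belongs to a count stratum with its own λ and ρ, producing
  a rising frequency-threshold curve.  Each gene carries a fixed set of
  restriction-site loci (default 2) from which contacts draw, so loci
  recur across contacts as real digestion fragments do and the contact
  matrix accumulates structure beyond single entries.  Dubious genes are
  excluded from modules, making them contact-depleted.
* **Gene sets** — each module as an enriched term, size-matched random
  null terms, and the dubious set.

Defaults (500 genes, 200 samples, 5 modules of 40) were chosen so the full
pipeline runs in seconds on one CPU while every planted effect clears its
Monte-Carlo noise floor.  The enrichment-recovery configuration in the
tests uses two modules of 80 genes on a 4% background rate because a ratio
band of ±20% around 2 requires an expected intra-group link count of order
100 (SD(ratio) ≈ √(2/E)); the co-expression-recovery configuration uses
the small-module regime described above.

What the generator does **not** emulate: realistic gene-length and
expression-level distributions (profiles are homoscedastic lognormal),
distance-dependent intra-chromosomal contact decay (cis contacts are
simply absent by default), fragment-length or GC bias in counts, probe
sets with missing values, or polymer-physics constraints on which loci can
co-locate.  Passing tests therefore demonstrate that the statistical
machinery recovers planted structure of the stated kind and size — not
that real contact maps contain such structure, nor robustness to
experimental biases beyond what the three matrix normalizations address.

## Numerical and design choices

* Empirical p-values use the add-one convention, never 0; the two-sided
  doubling is described above.
* Degenerate inputs: the all-genes set gives ratio exactly 1 with SD 0 (Z
  undefined, reported missing); thresholds with no surviving pairs emit a
  row with n = 0 and a missing mean; empty link tables are an error for
  analyses whose statistic would be undefined.
* Randomness: `numpy.random.default_rng` throughout; every public
  operation with randomness takes an explicit seed; per-term streams are
  hashed from the master seed.
* Background subsampling, when triggered, records its seed and mode in the
  output object.
* The CLI is a thin wrapper over the library: each subcommand reads the
  standard formats, calls one library entry point, and writes TSVs plus a
  JSON manifest (config, seed, input SHA-256 checksums).

## Known limitations

* The locus-level contact matrix treats input coordinates as point loci;
  whether they denote restriction-site cut positions or fragment midpoints
  is left to input preparation.
* Probe→gene collapsing averages profiles (deterministic and
  order-independent); alternatives (strongest probe, median) are not
  implemented.
* GO structure is consumed as flat sets; no DAG propagation.
* No multiple-testing correction across terms by default (per-term values
  are reported raw, as the enrichment ratios are descriptive; a BH column
  can be added downstream from the emitted table).
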