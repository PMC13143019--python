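# Methods

`hybarrier` detects candidate Bateson–Dobzhansky–Muller incompatibilities
(BDMIs) in a natural hybrid population of haploid males, relates them to
long-term barrier windows from a demographic genome scan, compares their
interaction network to the Orr model of incompatibility accumulation, and
quantifies ancestry sorting. This note documents the statistical model, the
synthetic hybrid-swarm generator that provides ground truth, the numerical
choices, and the limits of what the bundled experiments demonstrate.

## The two-locus scan

Hybrid males are haploid, so each genome is a single recombinant haplotype
mosaic of the two parental species' ancestries. At a pair of
ancestry-informative markers (AIMs) the four two-locus ancestry classes
00/01/10/11 have complete-case frequencies g_ij. The scan statistic is

    X(2) = g_r · g_R − g00 · g11,

where r is the rarer and R the commoner recombinant class (01/10).
Algebraically this equals −D, the negative of the ancestry linkage
disequilibrium: it is negative exactly when the parental classes jointly
exceed the recombinant product, the footprint left when selection removes a
recombinant combination. It is symmetric under both the 01↔10 and the
global 0↔1 relabelings and zero at full symmetry. The closed form is
deliberately isolated in one function (`scan.pair_stat`); everything
downstream consumes only the per-pair scalar, so an alternative form can be
substituted without touching the pipeline. D′ is the standard normalized
LD of the two ancestry indicators. Pairs monomorphic in the complete-case
subset, or with fewer than half the samples called at both sites, are
unusable and excluded from every average.

Because a causal incompatibility distorts linked sites around it, calls are
made on pairs of windows of 20 consecutive AIMs (400 cross comparisons per
pair). A window pair is a candidate when

1. its mean X(2) is at or below the ceiling (−0.005 at the base of the
   23-value grid −0.0600 … −0.0050, step 0.0025);
2. its fraction of comparisons below −0.005 strictly exceeds the 99th
   percentile of 1,000 resamples of 400 X(2) values from the genome-wide
   pool;
3. its count of AIMs with ≥1 below-threshold comparison strictly exceeds
   the 99th percentile of 1,000 resamples of 40 genome-wide AIMs split into
   two pseudo-windows of 20 (the resampled geometry mirrors the observed
   statistic; how resampled AIMs should be paired is otherwise
   underdetermined, so this choice is recorded here).

Candidate windows become intervals (one record per candidate-pair
membership) merged under strict overlap; a merged region's degree is the
number of records absorbed. `make_windows` defaults to disjoint 20-AIM
blocks; a `step` argument produces sliding windows, whose spans overlap and
therefore merge into larger regions. Sliding windows (step 5) are used for
the network experiments: they let a multi-window incompatibility region
absorb its internally linked window pairs as self-pairs (dropped) instead
of spurious chain edges. Worth noting: the window-comparison count reported
for this method's original application (13,325,703) equals C(5163, 2)
exactly, which is what ~20-AIM windows sliding by ~4 AIMs over ~21k AIMs
produce — sliding windows appear to be the original geometry, though the
disjoint reading remains this package's default window contract.

## Why the operating regime matters

With n = 286 samples, the sampling noise of D̂ at two loci with minor
ancestry frequencies near 0.5 has standard deviation ≈ 0.015 — three times
the −0.005 ceiling. The criteria only discriminate when the genome-wide
pool of AIM pairs produces mostly |X(2)| ≪ 0.005, i.e. when most AIMs are
near-fixed within the hybrid population. That is the documented state of
the target system: an old, strongly sorted hybrid population where
segregating ancestry persists only in limited regions. The generator
therefore sorts the genomic background (below); the scan's calibration and
power claims hold in that regime, not for a maximally admixed population.

## The synthetic hybrid swarm

Discrete non-overlapping generations; diploid parents; haploid males are
single gametes (hymenopteran males arise from unfertilized eggs). Defaults:

| parameter | default | meaning |
|---|---|---|
| n_chromosomes × n_sites | 12 × 120 | site grid; all sites become AIMs at prop_fixed_diff = 1 |
| chrom_length_bp | 2 Mb | with map_length_cM = 33.3 per chromosome |
| pop_size | 5,000 diploids | breeding population per generation |
| n_hybrid_males | 286 | sampled haploid males |
| generations | 25 | swarm age at sampling |
| admixture_p0 | 0.5 | founding proportion of species-1 haplotypes |
| sorting_strength | 0.7 | standardized selection gradient on background ancestry |
| sorting_burnin | 5 | neutral generations before sorting applies |
| transmission_selection | 0.1 | share of s exposed in the breeding pool |
| planted_balancing | 0.8 | restoring force at planted loci |

Meiosis: crossover count per chromosome ~ Poisson(map_length_cM/100),
positions uniform, start haplotype random. Parental panels: a fraction
`prop_fixed_diff` of sites alternatively fixed; the rest have a frequency
difference uniform on [0, 0.9], so only fixed sites reach the 0.95 AIM
threshold; diploid panel genotypes are binomial draws.

Selection. An incompatibility acts in cis: a haplotype carrying the
incompatible two-locus combination takes a (1 − s) viability factor.
Sampled males express the full s (a male carrying a lethal combination is
never sampled); the breeding pool is exposed to only
`transmission_selection` × s. The asymmetry is deliberate: a fully
transmitted lethal incompatibility purges one of its own alleles within
roughly ten generations and leaves nothing to detect at generation 25, so
persistent detectable incompatibilities must be expressed mainly in the
haploid (dead-end drone) caste — which is also where hemizygous expression
makes them most visible in this system.

Background sorting. After a neutral burn-in, parents are weighted by
exp(β·z) where z is the per-generation z-score of the individual's mean
ancestry over the sorting sites (soft selection; intensity constant as
variance erodes). Chromosomes carrying planted loci sort toward the
ancestry opposite each locus's contribution to its incompatible
combination, keeping the combination locally rare — a combination at high
frequency would have purged itself. Sites within `sorting_exclusion_bp` of
a planted locus are excluded from the trait, and a frequency-dependent
balancing term holds each planted locus near its anchor frequency
(`anchor_a`/`anchor_b`, default 0.5). The balancing term is a stand-in for
whatever maintains polymorphism at real segregating incompatibility regions
(spatial structure, influx, multi-allelism); it is not a mechanistic claim.
`sorting_regions` restricts the trait to explicit regions instead, which
the sorting-contrast experiment uses to plant fully sorted barrier windows
on a segregating background.

What the generator does not emulate: overlapping generations, polygyny and
nest structure, coalescent-realistic parental divergence, AIM density
variation, temporal pooling of samples (configurable in principle, off by
default), and any real linkage map beyond uniform Poisson recombination.
Passing tests therefore show that the statistics behave as designed under
a faithful caricature of the study system, not that they would perform
identically on real data.

## Interval statistics

All coordinates are 0-based half-open. Merge unites strictly overlapping
records; book-ended records stay separate. The circularization bootstrap
rotates every feature on a chromosome by one shared uniform fractional
offset (rounded to integer bp) of the effective length — the data extent
when set, else the chromosome — splitting records that span the wrap point.
Empirical p-values are p = max(k/reps, 1/reps) with k the tail count, both
tails reported, the smaller flagged with its direction (never doubled).
The centromere test compares observed feature-center-to-centromere-center
distances against the pooled distances of rotated features with a one-sided
rank-sum test (alternative: observed smaller). Chromosome-level enrichment
cannot be tested by within-chromosome rotation (rotation never moves bp
between chromosomes — the degenerate case is flagged), so its default null
reassigns features to chromosomes with probability proportional to length.

## Network analysis

Nodes are merged candidate regions; one edge per candidate window pair
collapsed to region endpoints, parallel edges collapsed with multiplicity
kept as weight, self-pairs dropped. The Orr null matches
P = d̄/(|V| − 1) and grows networks by sequential attachment with
independent probability P (equivalently G(n, P)). Mean path length averages
over ordered reachable pairs; betweenness is unnormalized with endpoints
excluded (both are the igraph-dialect defaults and are pinned against a
brute-force BFS oracle in the tests). The degree–m_e test takes every
(region, barrier-window) overlap as a data point and permutes m_e over the
observed degrees. Node ancestry classes use hybrid-index thresholds
0.2/0.8 (the lower threshold is sometimes printed with a stray minus sign
in this literature; it is read as 0.2 since the hybrid index lives in
[0, 1]).

The hub experiment plants a hub *region*: five tightly linked focal loci,
each lethal with two partner regions. A single focal locus cannot carry
many lethal partnerships — its minor-ancestry males survive with
probability ∏(1 − s·q_k), which vanishes with degree — but a linked cluster
keeps per-locus exposure low while the merged region accumulates degree 10.
The network is read at the −0.0075 ceiling, where planted-signal pairs
(mean X(2) ≈ −0.02) are well separated from the sampling noise of
segregating region pairs, mirroring the practice of analyzing the network
at a stricter mid-grid cutoff rather than the base −0.005.

## Ancestry sorting

Sorting sites are those where one species' allele frequency is below 0.2
and the other's above 0.8 (the printed rule "<0.2 or >0.8" is ambiguous;
this reading — a relaxed AIM definition — is the default and the predicate
is pluggable). Per window, each individual's hybrid index is its mean
non-missing ancestry; D̄ is the across-individual sample variance (n − 1
denominator); windows with fewer than two individuals carrying a defined
index are excluded. Nonbarrier windows are split into
k = max(1, round(L/target)) equal pieces with target equal to the mean
barrier-window size, so window length does not drive the contrast. The null
rotates the barrier track and recomputes the rotated-window mean D̄.

## Numerical and testing choices

- All randomness flows through explicit seeds or `numpy.random.Generator`
  objects; identical configurations reproduce outputs byte-for-byte.
- The all-pairs X(2)/D′ computation is a vectorized matrix formulation,
  pinned element-by-element against the scalar definition in the tests.
- Candidacy criteria use strict inequalities exactly as specified; call
  sets are nested across the cutoff grid by construction.
- Calibration tests operationalize "≈ nominal" as an exact binomial test of
  the observed rejection count against the nominal rate, failing below
  p = 0.001: empirical-CDF p-values on tied or discrete statistics are
  conservative by construction, so only gross miscalibration should fail.
- Neutral-calibration caveat: the 99th-percentile criteria resample values
  i.i.d. from the pool, while real window pairs share drift LD; at breeding
  populations of ~2,000 the neutral exceedance rate inflates to ~2%, and
  the default pop_size of 5,000 (reasonable for a large polygynous
  multi-nest swarm) keeps it near the nominal 1%. On real data with small
  effective size the criteria should be expected to run anti-conservative.
- Problem sizes in the bundled experiments (12 × 120 sites, 3–10 replicate
  swarms, 200-rep calibration sets) are chosen to keep the full validation
  suite in the minutes range on one CPU while leaving every detection
  margin wide; the experiments module records the exact conditions.

## Known limitations

- The X(2) default form is −D; the original statistic is defined in
  companion code that is not reproduced here. All window-level machinery is
  agnostic to the substitution.
- Region degree (records absorbed at merge) and graph degree (incident
  edges after collapsing) are related but distinct quantities; both are
  exposed.
- The trimming-to-extent step asserts nothing about how much chromosome
  survives trimming (data-dependent).
- With disjoint windows, adjacent segregating windows on the same
  chromosome produce genuine linked-LD candidate pairs ("chains"); sliding
  windows absorb them into regions. Neither behavior is an error — they are
  two readings of the window geometry, and both are available.
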