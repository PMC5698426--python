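# Methods

## Model and assumptions

The classifier treats each called variant in a tumor-only exome as either a
true somatic mutation or an artifact, using only per-site statistics — no
read-level data and no matched normal. Three assumptions carry the method:

1. **Recurrence of mutated sites.** Tumors of one cancer type share mutation
   sites, so a catalog of reported mutations is informative: an exact
   catalog match (dNM = 0) is accepted as a true mutation outright, and
   sites recur often enough across a cohort that a per-site test has
   replicates.
2. **Sparsity of true mutations.** Somatic mutation rates are tiny
   (~3 × 10⁻⁷ per base), so a called variant that is *close to but not at* a
   known mutation (small positive dNM) is more likely an alignment or
   calling artifact clustered around a real site than a second independent
   mutation. Intermutation distances in real cohorts have megabase-scale
   medians, which is what makes a sub-kilobase dNM suspicious.
3. **Strand symmetry of real variants.** For a real mutation the
   forward-minus-reverse count difference of ALT reads behaves like that of
   REF reads across tumors (median ≈ 0); machine artifacts are strand-biased
   consistently across tumors, detectable both per-sample (FS) and
   cohort-wise (the Mann–Whitney strand test).

Because validation of a candidate mutation is expensive, the training
objective α(1 − cFPR) + (1 − α)TPR makes the sensitivity/false-call
trade-off explicit; cFPR is the clinically relevant error: the fraction of
artifact *calls* that survive filtering.

## Decision rule details

All cutoff comparisons are strict; boundary values pass, mirroring the
printed hard-filter rules. Missing statistics pass their cutoff (the GATK
convention — rank-sum annotations are undefined at homozygous-ALT sites, and
the cohort strand test is undefined for sites seen in a single tumor).
ReadPosRankSum is consulted only by the hard-filter baseline, not by the
trained rule: in the pilot analysis the method derives from, every variant
it filtered was also filtered by FS. The trained cutoffs *replace* the GATK
defaults rather than stacking on them — the trained QD cutoffs (≈0.05–0.2)
sit far below the default 2.0, which only makes sense as a replacement.

Catalog matching normalizes alleles by suffix-then-prefix trimming
(left-alignment without reference context). dNM requires an exact normalized
(chrom, pos, ref, alt) match to return 0; a colocated entry with different
alleles yields 1 bp. Distances are same-chromosome only; a chromosome with
no catalog entries yields +inf (which passes the dNM band, as any distance
≥ dnm_min does).

## Statistics

- **FS**: two-sided Fisher exact P under the probability-mass rule (sum of
  all tables with probability ≤ the observed table's), computed by
  `scipy.stats.fisher_exact`; Phred-scaled and capped at 500 when p
  underflows. The test suite checks it against an independent hypergeometric
  enumeration.
- **Rank-sum z** (MQRankSum-style): mid-ranks, tie-corrected variance,
  0.5 continuity correction applied toward zero; negative when ALT-linked
  values are stochastically smaller. Implemented directly since no library
  exposes the z under exactly this convention.
- **Cohort strand test**: two-sided Mann–Whitney comparing per-tumor ALT
  forward-minus-reverse differences with REF differences at one site. Exact
  U distribution when both groups have ≤ 8 tie-free observations (cheap and
  exact where cohort recurrence typically lands), tie-corrected normal
  approximation with continuity correction otherwise. Identical samples
  short-circuit to p = 1.
- **dNM**: binary search (`numpy.searchsorted`) over per-chromosome sorted
  position arrays; verified against a linear scan in the tests.

## Training

The search space is a per-statistic box partitioned into the segment counts
1000 (dNM), 60 (FS), 50 (MQ), 100 (MQRankSum), 20 (QD) and 6 (Mann–Whitney
P); candidate cutoffs are the segment grid points. The bounds are not part
of the published partition and were chosen to contain both the GATK defaults
and all published trained values: dNM [1, 10⁴] bp, FS [0, 300], MQ [0, 70],
MQRankSum [−20, 10], QD [0, 4], MW-P [0.001, 0.3].

The optimizer is a standard global-best particle swarm: particles move
continuously inside the box and are snapped to the segment grid at
evaluation time, reconciling the discretized space with ordinary PSO
dynamics. Coefficients are constriction-style defaults — inertia 0.72,
cognitive = social = 1.49 — with velocities clamped to the box width; the
published description fixes only the scale (4,000 particles, 500
generations), which the `PSOConfig` defaults reproduce. Fitness evaluation
is fully vectorized over particles × variants, so scaled-down swarms
(100–200 particles, 25–50 generations) used throughout the tests and the
acceptance script converge in seconds; on separable training sets they
attain the exhaustive-grid optimum (checked on enumerable reduced spaces).

α is selected by sweeping 0, 0.1, …, 1 with leave-one-tumor-out
cross-validation and maximizing the mean cross-validated MCC (ties toward
smaller α); the selection criterion is configurable because the published
procedure does not state one, and MCC is the method's own headline metric.
After selection the thresholds are retrained on all ten tumors — also a
choice the source procedure leaves open. The indel recipe trains on a seeded
50 reported + 10 artifact sample and tests on the remainder; since those
variants carry no tumor grouping, its α sweep uses a seeded 10-way random
partition instead of tumor folds.

All randomness — stratified tumor sampling, indel splits, swarm
initialization — flows from one integer seed via spawned `SeedSequence`
children, so every trained threshold set is exactly reproducible.

## Synthetic cohorts

The generator emulates the study conditions at desk scale: ten tumors with a
2/3/2/3 stage mix, ~267 called variants per tumor, ~10% true mutations, a
2,000-site known-mutation catalog on a 120 Mb three-contig genome, and
indel pools of 539 reported + 112 artifacts. Per variant it draws strand
counts (Poisson depth, mean 60; allelic fraction uniform on [0.2, 0.6]),
computes FS *from those counts*, and draws the remaining annotations from
truncated class-conditional normals. Sites come from shared pools
(pool size = 1.5 × the per-tumor count), so a site recurs in ~6–7 of 10
tumors and the cohort strand test has replicates.

Class structure: 90% of true mutations sit exactly at catalog sites
(dNM = 0); the rest are ≥ 20 kb from any known site. Artifacts are split
between near-catalog placement (10–900 bp, the dNM band) and far placement;
their ALT reads split 0.9/0.1 across strands (REF stays 0.5), driving both
FS and the cohort strand test; their QD (mean 2.5, sd 1.2), MQ, MQRankSum
and ReadPosRankSum distributions deliberately *straddle* the GATK default
cutoffs, so the hard-filter baseline catches only part of the class
(cFPR ≈ 0.5) and the catalog and strand statistics carry the rest of the
separation — the regime the method exists for.

What the generator does **not** emulate: read-level errors and their
correlation structure, sequence-context mutational signatures, copy-number
and purity effects on allelic fraction, annotation noise on true mutations
(their annotations are clean, so the baseline's TPR is not depressed as it
is on real tumors), and inter-tumor heterogeneity of artifact mechanisms.
Passing tests therefore demonstrate correctness of the statistics, the rule,
the optimizer and the pipeline — and recoverability of planted separations —
not performance on real exomes.

## Numerical choices and degenerate inputs

- Zero-denominator metrics (TPR, cFPR, precision, and every MCC factor) are
  defined as 0 so cohort sweeps never divide by zero.
- FS is clamped to [0, 500]; p values are clamped to [0, 1].
- Degenerate Fisher tables (an all-zero margin) give p = 1, FS = 0; a fully
  zero table is an error.
- A training set or fold without both classes is an error, as is
  cross-validation with fewer than two tumors, a stage with fewer tumors
  than the sampling plan requests, or fewer indels than the split needs.
- `fpr_per_mb` takes the sampled reference-site count explicitly; the 10%
  site sample is a fixed-size draw (`round(fraction × N)`) so denominators
  are deterministic.
- PSO with 0 generations returns the best grid-snapped particle of the
  initial population; the best-so-far trajectory is non-decreasing by
  construction.

## Problem sizes

Tests and the acceptance script run the pipeline at reduced scale — swarms
of 40–200 particles over 5–50 generations, cohorts of 300–2,700 variants,
catalogs of 300–10,000 sites — sizes at which the optimizer demonstrably
reaches grid optima and the pipeline completes in seconds while exercising
every code path. The full-scale defaults (4,000 particles, 500 generations)
remain available through `PSOConfig`.

## Known limitations

- The cohort strand test pools tumors by site; singleton sites are untestable
  and always pass, so a non-recurrent strand-biased artifact is caught only
  by FS or the annotation cutoffs.
- Which GATK annotation field supplies strand-resolved counts is
  configurable (default: a 4-integer SAC-style FORMAT field) because no
  single convention is universal.
- Whether tumors lacking the ALT allele should contribute REF differences to
  the strand test is ambiguous; here only tumors carrying the call
  contribute, which is what the generator emulates.
- The indel rule shares the SNV search-space bounds for its four statistics;
  published indel cutoffs fall inside them.
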