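# Methods

## Model and workflow

`ampliphase` reconstructs the two (or more) full-length allele sequences of
a polymorphic amplicon from one heterozygous sample, using accurate short
reads for base-level evidence and full-length long reads for phase. The
workflow assumes targeted amplicon data: every long read spans (nearly) the
whole locus, and short reads are fragments of the same amplicon. Phasing is
driven entirely by heterozygous positions (HPs) detected in the short
reads; indels and homopolymer-length differences between alleles are *not*
treated as HPs — they are resolved downstream by iterative per-haplotype
consensus and by explicit run-length evidence.

Stages, with the parameters that matter (all exposed on `RunConfig`):

1. **Sample-specific reference.** Short reads are mapped to the generic
   locus reference and a majority-rule consensus is called. Optional
   coverage subsampling (`target_coverage`, off by default) keeps a read
   only while some position it spans is below the target, in seeded random
   order — sampling by coverage, not read count.
2. **HP detection.** A position is an HP when, among non-deletion counts at
   depth ≥ `min_depth_hp` (20), the second most frequent base reaches
   `maf` (0.2). Deletions never count as alleles; a third allele above the
   threshold is reported but not used (clustering expects a known number of
   alleles).
3. **Long-read genotyping.** The base of each long read at each HP is read
   from a ±12 bp window realigned with affine gap scores (match +2,
   mismatch −4, gap open −4, extend −1). Whole-read edit-distance
   alignments place bases near indel errors ambiguously; local realignment
   restores the base-to-column correspondence (measured: ~87% per-HP
   accuracy at 85% read accuracy, versus ~69% from raw alignment columns).
   Reads covering < `min_read_cov` (90%) of HPs are discarded first, then
   HPs covered by < `min_hp_cov` (30%) of surviving reads — each filter
   once, in that order.
4. **Linkage exclusion.** Pairwise Cramér's V between HP genotype columns
   (χ² without continuity correction — V is a descriptive score, not a
   test; pairs sharing < 10 reads are missing and imputed as 0 with a
   warning). The V-matrix is split into two groups by Ward clustering on
   1 − V and the low-linkage group is excluded when the groups' mean
   intra-cluster V differs by more than `linkage_gap` (0.4); the split is
   repeated on the survivors because artefacts sometimes peel off one at a
   time. Ward was chosen after measurement: with two injected artefact
   columns at depth 50, average linkage absorbs one artefact into the true
   block in most replicates, Ward separates them in all. A singleton
   group's intra-linkage is taken as its mean V to the other group, making
   the rule total. Real runs of the default scenario show true-HP gaps up
   to ≈0.31, so 0.4 also guards against excluding genuine HPs under allele
   imbalance.
5. **Clustering.** The position-specific distance matrix weights a
   disagreement at HP *p* between bases *a* ≠ *b* by w_p(a)·w_p(b),
   rescaled so the largest product at *p* is 1; distances are means over
   co-covered HPs (pairs sharing < 3 HPs are missing, imputed as the
   matrix maximum). Average-linkage hierarchical clustering is cut at the
   largest relative merge-height gap (a simplified adaptive branch pruning:
   no convincing gap ⇒ one cluster, a homozygosity candidate); clusters
   below `min_cluster_size` (max(5, 5% of reads)) merge into their nearest
   cluster; if more clusters than expected remain, the `expected_n`
   mutually most distant are retained greedily (ties: larger cluster, then
   lower id). Membership coefficients re-score *all* reads against the
   retained clusters' PWMs; with two clusters the coefficient is
   (S_A − S_B)/(S_A + S_B) (0 if both scores are 0). Pruning keeps, per
   cluster, reads above the `retain_quantile` (0.25) quantile of |coef|
   and above the absolute floor `coef_floor` (0.2) — chimeras sit near 0.
   A chimera whose breakpoint falls outside the HP span is genotypically
   identical to a pure read and cannot be detected by any HP-based method;
   such reads are also harmless wherever the alleles agree.
6. **Iterative drafts.** Per haplotype, the retained long reads are mapped
   to the consensus of the previous round (`n_iter` = 2; iteration stops
   early at zero changes, reported as the edit distance between successive
   consensuses). Mapping references are always called without IUPAC
   ambiguity codes (plain majority) so they stay on the {A,C,G,T,N}
   alphabet; ambiguity codes appear only in final polished output.
7. **Polishing.** Short reads partition by majority vote over the HPs they
   cover (ties and HP-free reads are copied to every haplotype — so every
   read lands in ≥ 1 partition); the vote reduces to the single-HP rule for
   reads covering one HP. Each partition polishes its draft by majority
   consensus; polishing iterates (≤ 3 passes) until the consensus is a
   fixed point of its own mapping, which also resolves uncalled N tails
   that would otherwise repel reads. Insertions are spliced when the
   insertion event exceeds half the local depth and one allele dominates
   among the insertion-carrying reads; conflicting alleles are flagged
   instead.

## Homopolymer arbitration

Long-read column consensus systematically shortens homopolymers, and
HP-free short reads are shared between haplotypes, so a one-unit
homopolymer difference far from every HP leaves each haplotype's
insertion/deletion evidence near 50:50 — a coin flip for column-wise
calling. Runs of ≥ 6 bases whose indel evidence falls in the ambiguous
zone (fractions 0.3–0.7, or a majority insertion without a dominant
length) are settled explicitly, in order of evidence quality:

1. the run-length mode over *uniquely assigned* spanning short reads
   (essentially exact);
2. with two haplotypes, jointly: the union histogram of spanning short
   reads (each read counted once across both partitions) fixes the
   candidate length pair; a haplotype settled by unique reads eliminates
   the other candidate for its sister; otherwise the haplotype whose
   retained long reads have the larger mean run length takes the longer
   candidate (a sign decision — no absolute calibration needed; the
   per-read run-length distributions differ by ~1 with σ ≈ 1.2, so ~25
   reads separate the means by several standard errors);
3. single-haplotype fallback: the bias-corrected long-read mean,
   length ≈ mean count / (1 − p_del − p_sub + p_ins/4), with the error
   rates estimated from the haplotype's own alignment statistics.

Settled runs are protected from column-wise deletion-dropping and
insertion-splicing (the residual ~50% signals from shared reads stay
visible in the problem report); runs with no deciding evidence are left
unchanged and flagged as homopolymer problems. The final homopolymer check
compares each ≥ `min_hp_len` (8) run's consensus length with the mode over
spanning reads (preferring uniquely assigned reads; ties break toward the
consensus length, then smaller) and flags disagreement.

## Reporting, editing, checkout

All residual signals are problem positions: residual heterozygosity
(IUPAC), unresolved/conflicting insertions, deletion signals (informational
below majority, blocking when a base was dropped), homopolymer
inconsistencies. `remap_and_verify` re-maps the frozen read partitions
against user-edited references — read composition never changes — and
reports remaining problems plus positions where the fresh consensus
disagrees with the edit. `checkout` refuses while blocking problems remain
unless forced, and stamps the output with the run id and config hash.

## Mapping

Production mapping uses edlib (bit-parallel edit distance, infix mode), the
role an external mapper plays in a cluster deployment; alignment ends are
soft-clipped to the maximal-scoring segment (+1 match / −2 otherwise),
emulating a local mapper: a read tail forced across a structural-deletion
junction becomes a mismatch run and is clipped rather than polluting
pileups. N in a reference is a wildcard, so uncalled positions do not repel
the reads that could resolve them. Pre-aligned SAM from an external mapper
is accepted as an alternative (`--mapper sam:<dir>`). The package also
ships a banded affine-gap semi-global aligner (free end gaps on the read,
deterministic tie-breaking match > mismatch > del > ins) validated against
an unbanded dynamic-programming oracle; it is exact but not optimised for
kilobase-scale mapping, and insertions longer than the band are not
representable by it.

## Simulator

The simulator defines the validation conditions: a random 5 kb generic
reference; two haplotypes separated by 10 SNVs (assigned round-robin so the
haplotypes differ at every SNV and each also deviates from the generic
reference), one 50 bp deletion, and a homopolymer tract of 12 vs 13 bases;
short reads of 300 bp at 500× total depth with 0.2% substitution error;
60 full-length long reads at 85% accuracy with ONT error composition
23/31/46 (PacBio preset 6/50/54). Choices made where no external value
existed: short-read fragment starts are uniform over
[−(read_len−1), L−1] and clipped (flat coverage across the termini, as
fragmentation of a full-length amplicon produces; fragments < 30 bp
dropped); SNVs keep ≥ 30 bp from indel/homopolymer junctions, where local
alignment is intrinsically ambiguous, and ≥ 300 bp from the amplicon ends;
long-read errors are homogeneous per base with type drawn from the stated
ratio — exactly auditable, unlike trained error models, but without
homopolymer-length-dependent error enrichment or quality-score structure.
PCR chimeras replace a read pair from different haplotypes with one read
switching template at a uniform interior breakpoint (10–90%); their ids are
recorded so pruning can be audited. What passing tests show is therefore
recovery under *idealised but stated* error models; real data add
context-dependent error, coverage bias and primer artefacts that the
simulator does not emulate.

## Error metrics

Assembled haplotypes are attributed to truth haplotypes by global alignment
identity (optimal assignment). Differences to the attributed target are
enumerated under affine-gap global alignment (substitutions per position,
one event per contiguous indel — unit-cost alignment would scatter a
kb-scale deletion across accidental matches); a difference whose allele
matches the alternative truth haplotype at the homologous position is
switch-classified, and maximal runs of consecutive switch-classified
differences count as one phase-switch error; everything else is a mismatch
error. Rates divide by the number of events between the target truth
haplotype and the generic reference (the maximum possible errors); units
whose truth equals the generic reference are excluded with a warning, and
means across units are unweighted. Percent reductions are reported to two
decimals with half-up rounding.

## Numerical choices and degenerate inputs

Consensus: runner-up base ≥ (1 − `tie_ratio`) of depth (default 0.75 ⇒
25%) triggers an IUPAC call; depth < `min_depth_consensus` (3) is called N;
deletion-majority columns are dropped from the ungapped output with their
coordinates preserved in the report. Zero-coverage matrices, empty HP sets
(homozygous fallback emits a single consensus), all-reads-filtered, and
checkout with unresolved problems all raise explicit errors. All
randomness flows from a single seed (subsampling, simulation); re-running a
pipeline with the same seed reproduces the final FASTA byte for byte.

## Problem sizes used in validation

The acceptance battery runs 25 seeded replicates of the 5 kb default
scenario (~half a minute each), 3 chimera runs at 10% chimeras, 50
artefact-exclusion replicates, and 200 aligner-oracle instances of ≤ 30 bp.
The unit-test suite exercises the same components on smaller instances
(including a full pipeline run on a 1.5 kb locus).

## Known limitations

- Homopolymer differences with no nearby HP and no usable long-read margin
  remain flagged but unresolved; with > 2 expected alleles the joint
  arbitration falls back to per-haplotype evidence.
- Chimeras whose breakpoint leaves at most one HP on the minority side are
  undetectable by construction — their genotype is within the noise floor
  of a clean read with a single genotyping error. With 10 HPs and uniform
  interior breakpoints this affects roughly 10–15% of chimeras, so measured
  elimination rates run ~85–100% per seed; such chimeras are also benign
  wherever the two alleles agree, and the final sequences match the
  chimera-free run.
- The built-in simulator's homogeneous error model understates structured
  long-read error (e.g. run-length-dependent indels); the homopolymer
  machinery is therefore additionally exercised with forced-error fixtures.
- Long-read-only mode phases and assembles but is flagged "unpolished";
  single-base accuracy is limited by long-read consensus (~0.01–0.1%
  residual error) and may not reach submission quality.
- For > 2 alleles the signed membership coefficient generalizes to the
  best-versus-second-best score margin, which loses the symmetric sign
  interpretation.
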