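# Methods

## The validation problem and the two frequency indices

An *amplicon* is one individual × locus PCR product sequenced as a pool of
reads. At a single-copy diploid locus it contains one or two true alleles;
everything else in it is either an error derivative of those alleles or a
carryover of a true allele from another amplicon. The package's central
statistics are

* **RPAF** — the relative per-amplicon frequency of a variant: its read
  count divided by the amplicon's total;
* **MPAF** — the mean per-amplicon frequency: the unweighted mean of a
  variant's RPAFs over the amplicons that possess it.

True alleles are common both within amplicons (RPAF near 0.5 or 1) and,
because MPAF only averages over amplicons that contain the variant, their
MPAF stays high even when the allele is rare in the population. Artifacts
are rare on both axes. Carryover contaminants are the diagnostic exception:
high MPAF (they are true alleles elsewhere) with locally low RPAF.

## Classification cascade

Within each amplicon, variants are ranked by read count (ties by variant
id). The top two are provisional parentals. Every other variant is tested
in order:

1. **Homopolymer indel**: pure-indel alignment difference from a parental
   (edlib CIGAR), every indel adjacent to a single-base run of length ≥ 3 in
   the parent — the classic pyrosequencing error.
2. **Point derivative**: edit distance ≤ `d_max` (default 2) from a
   parental.
3. **Chimera**: exactly expressible as prefix-of-one-parental +
   suffix-of-the-other (smallest breakpoint reported).
4. **Contamination suspect**: MPAF ≥ `mpaf_flag` (default 0.05) and local
   RPAF < `rpaf_susp` (default 0.10) while the same sequence reaches RPAF ≥
   `rpaf_high` (default 0.25) in some other amplicon. The 0.25 bound
   operationalises "dominant elsewhere": a true allele in a balanced
   heterozygote sits near 0.5, so 0.25 tolerates substantial amplification
   bias without catching artifacts.
5. Otherwise: **true allele** if MPAF ≥ `mpaf_flag` and RPAF ≥ `rpaf_susp`,
   else **unresolved**.

Two deliberate asymmetries. First, the MPAF flag is descriptive, not a
filter: suspects are resolved by replicate PCRs (a suspect absent from a
replicate is a contaminant and is dropped; one validated in a replicate is
kept), never deleted on frequency alone — a fixed RPAF cutoff would cause
allelic dropout. A variant flagged suspect in *every* replicate remains
suspicious and is dropped, on the argument that independent PCRs rarely
suffer the same carryover. Second, amplicons left with more than two
validated alleles after replication are excluded as inconclusive rather
than force-called.

The cascade approximates judgements that were historically made by manual
alignment; it is deterministic, order-invariant (lexical tie-breaks
throughout) and total — every variant in every amplicon gets exactly one
label.

## Locus copy number

The rank-frequency profile averages, over amplicons, the within-amplicon
frequency of the rank-r variant; amplicons with fewer than r variants
contribute 0 at rank r so the means stay comparable across amplicons. With
two alleles per amplicon the mean frequency collapses between ranks 2 and 3;
the drop ratio mean(rank 2)/mean(rank 3) ≥ 3 (default) is read as
"single locus", anything else as ambiguous (possible duplication).

## Depth sufficiency

`min_reads_for_confidence(k, m, c, a)` returns the smallest depth T such
that, when T reads split multinomially among k equifrequent true alleles
(total mass 1 − a, the remainder being an artifact class), every true allele
receives ≥ m reads with probability ≥ c. The tail is computed exactly by
inclusion–exclusion over the alleles' failure events (joint lower-tail sums
with ≤ m^k terms), so it is feasible for the realistic k ≤ 4, m ≤ ~10. The
default genotype-acceptance threshold in the pipeline is 18 reads; the
parameterisation behind any published threshold varies with (k, m, c, a),
which is why the operation exposes all four.

## Population genetics

* **Heterozygosity**: H_O is the observed heterozygote fraction; H_E is the
  unbiased (2n/(2n−1))(1 − Σp̂²); F_IS is Weir & Cockerham's (1984)
  within-population f from the b (between individuals within population) and
  c (within individuals) components summed over alleles.
* **HWE, heterozygote excess**: the U score is implemented as
  U = −Σ_a n_aa/p̂_a, a monotone transform of the weighted homozygote count;
  conditioned on the allele counts this is equivalent to the score statistic
  for the heterozygote-excess alternative, and larger U means more
  heterozygous. The null re-pairs the 2n allele copies at random (Levene),
  Monte-Carlo by default with p = (b+1)/(m+1) including the observed array,
  or by exhaustive enumeration of all pairings for 2n ≤ 12 (used as the
  oracle in tests). Monomorphic loci return p = 1 by convention.
* **Null alleles**: EM treating each observed homozygote as a mixture of a
  true homozygote and a heterozygote with a non-amplifying allele (expected
  null fraction 2p₀/(p_i + 2p₀) under HWE); total amplification failures can
  be supplied as blank counts. Convergence when the largest frequency change
  drops below `tol`.
* **Linkage disequilibrium**: haplotype frequencies by Excoffier–Slatkin EM
  over the phase ambiguity of double heterozygotes; the LRT statistic is
  2(logL_EM − logL_independent) with the independence likelihood evaluated
  at the products of the marginal allele frequencies. The null distribution
  permutes one locus's genotypes among individuals; p = (b+1)/(m+1). The EM
  is batched over all permutations (one matrix iteration updates every
  permuted dataset), is initialised at the linkage-equilibrium product
  (nudged off the exact point), and iterates each dataset until its own
  convergence. Degrees of freedom are reported as (k_A−1)(k_B−1); df
  bookkeeping for unphased EM LRTs is not standardised across
  implementations, which is why the test's p-value is permutation-based
  rather than χ²-based. Missing genotypes are removed listwise per locus
  pair.
* **F_ST**: pairwise Weir–Cockerham θ (variance components a, b, c summed
  over alleles), permutation p-values by shuffling group labels. Groups
  with fewer than two typed individuals are excluded and flagged.

## Selection

Site counts per codon follow the pathway convention: at each codon position
the synonymous fraction is computed among the non-stop single-base changes,
each position carrying unit mass, so every sense codon has s + n = 3 sites.
Between two codons, all orderings of the differing positions are enumerated;
orderings through a stop codon are discarded and the synonymous /
non-synonymous step counts are averaged over the legal orderings with equal
weights. If no ordering is legal (possible only for a handful of codon
pairs), the codon pair is excluded and flagged. Pairwise proportions pN =
nd/N, pS = sd/S are Jukes–Cantor corrected (undefined, flagged, at p ≥ 3/4)
and averaged over all sequence pairs; saturated pairs are dropped from the
mean and counted in the result's flags.

Standard errors are a bootstrap over codon sites within the analysed
partition (default 1000 replicates) rather than an analytical variance —
the bootstrap respects the partition restriction and the pathway averaging
without further approximation. The Z-test is one-tailed for positive
selection by default (Z = (dN−dS)/√(SE²+SE²), p = 1 − Φ(Z)); a two-sided
option exists.

Site masks (ABS, PSS) are inputs: 1-based codon coordinates on the
alignment, each named set paired with its complement. The package does not
infer positively selected sites — random-sites codon models are out of its
scope. Gap handling is complete deletion alignment-wide (the two-codon
insertion polymorphism appears as gap columns in non-carrier sequences and
those codon columns are removed before counting); pairwise deletion is
available behind a warning because it makes per-partition counts
non-additive.

## Phylogeny

Amino-acid distances are Poisson-corrected, d = −ln(1−p); p = 1 yields an
infinite (saturated) distance, which the tree builder refuses with an
explicit error rather than clamping. Neighbour joining follows Saitou–Nei
with the Q criterion; ties in Q are broken by the lexically lowest pair of
cluster representatives (the smallest leaf label in each cluster), making
the topology deterministic. The final three clusters are joined as the
root trifurcation, so the tree is unrooted in spirit. Negative branch
lengths are retained, not clamped to zero — clamping would break the exact
recovery of additive matrices that the tests rely on. Bootstrap supports
are bipartition frequencies (as percentages) over column-resampled
alignments mapped onto the full-data tree; Newick output writes supports as
internal node labels, hiding those under a display threshold (default used
for figures: 50).

## Rarefaction

Each replicate draws a random permutation of the typed individuals and
scores its prefixes, so within a replicate the distinct-allele count is
monotone in effort and the full-sample point has zero spread; the curve
reports mean ± SD across replicates (SD across replicates, not an analytic
approximation). The mean at effort n is, in expectation, exactly
Σ_a (1 − C(N−k_a, n)/C(N, n)) where k_a counts individuals carrying allele
a, which the tests verify on small tables.

## The synthetic generator

The generator emulates the study conditions the validation cascade was
designed for: ~100 individuals, one or two single-copy loci with allele
pools of ~17 and ~22 sequences of 162 bp (the second pool carrying a
two-codon insertion in 7 of 22 alleles), negative-binomial depth with mean
200 (454-run scale; dispersion 10), Beta(20, 20) allelic balance in
heterozygotes to mimic amplification bias, and Dirichlet-distributed allele
frequencies. Per-read corruption rates default to 2% point derivatives
(1–2 substitutions), 1% homopolymer-adjacent indels (runs ≥ 3), 1% chimeras
(heterozygotes only, one uniform breakpoint), and a 3% per-amplicon chance
of carryover giving ~4% of reads to one foreign allele. No study reports
per-class artifact rates for this platform; these defaults were chosen once
to reproduce the qualitative regime in which artifacts are individually
rare but collectively outnumber true alleles several-fold among unique
sequences (the simulated cohorts yield a few hundred unique variants per
hundred amplicons, of which under two dozen are real, and a before-sorting
MPAF/amplicon-count correlation near 0.8 that collapses after sorting).
Corrupted reads are reassigned from parental reads — never added — so
counts always sum to the drawn depth, and a parent is never drained below
five reads. Every variant of every amplicon receives exactly one ledger
label, and identical (truth, config) inputs reproduce byte-identical
output.

What the generator does not emulate: base-call quality, flowgrams, primer
and barcode structure, run-to-run batch effects, systematic (sequence-
dependent) error hotspots beyond homopolymers, and locus duplication. Tests
passing on this generator therefore show that the cascade is correct under
its stated assumptions, not that those assumptions exhaust real 454 data.

## Numerical and design choices

* All stochastic steps take explicit integer seeds; derived seeds are fixed
  offsets of a global seed, and every pipeline output is stamped with a
  hash of the scientific configuration (paths excluded) plus the seed.
* Permutation p-values always use (b+1)/(m+1), never 0.
* The EM convergence default is `tol = 1e-8` on frequencies; the LD
  type-I calibration (1000 simulations × 1000 permutations) relaxes it to
  1e-6, which changes LRT statistics far below the resolution of a
  1000-permutation comparison.
* Calibration simulations use 8 alleles (HWE) and 4 + 4 alleles (LD) at
  n = 50 — allele-rich loci being the regime of interest — where the
  conditional tests' discreteness is mild; measured type-I error is
  0.04–0.06 at nominal 0.05.
* The acceptance script scales two slow checks down (400 HWE and 200 LD
  calibration simulations, 50 NJ matrices) relative to the test suite's
  1000/1000/100, keeping its runtime near one minute.
* Degenerate inputs fail loudly: empty read sets, zero-read amplicons,
  mixed-locus cohorts, non-normalised frequencies, saturated distances,
  stop-containing codon alignments, unknown mask partitions.

## Known limitations

* The cascade attributes artifacts only to the two most abundant variants
  of an amplicon; an artifact of a contaminant, or a parental that is
  itself an artifact in a very degraded amplicon, can be mislabelled (the
  truth-ledger recall on default simulations is ~99%, not 100%).
* `resolve_with_replicates` intersects validated alleles; it cannot rescue
  an allele that dropped out of every replicate.
* The NG86 site-count convention (stop-excluded denominators, unit mass per
  position) matches the common software implementations; published variants
  differ in how stop-adjacent mass is redistributed, which changes dN/dS in
  the third decimal for typical MHC alignments.
* The U-score test is one-sided for heterozygote excess only; deficiency
  testing would negate the statistic.
* NJ tie-breaking is well-defined but arbitrary; on non-additive matrices
  different tie rules can yield different (equally valid) topologies.
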