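# mhc-ampcall

Genotyping highly polymorphic MHC loci from NGS amplicon data is dominated
by a validation problem: PCR and sequencing generate artefactual sequences
(1–2 bp point derivatives, homopolymer indels, single-breakpoint chimeras)
and DNA carryover plants *true* alleles into the wrong amplicons, so a naive
read-frequency cutoff either keeps artifacts or throws away real alleles.
`mhc-ampcall` implements a per-amplicon validation strategy for such data —
typically 454/amplicon sequencing of MHC class II exon 2 (DRB/DQB-like loci,
162–170 bp, 1–2 alleles per individual at a non-duplicated locus) — plus the
downstream immunogenetic analyses such genotypes feed, and a synthetic
amplicon generator with a complete truth ledger so the whole chain is
testable end to end without any sequencing data.

## What it computes

**Allele validation (`ampsort`).** For every unique sequence the package
computes two frequency indices: the *relative per-amplicon frequency*
(RPAF), its share of reads within one amplicon, and the *mean per-amplicon
frequency* (MPAF), its RPAF averaged over all amplicons possessing it.
Variants are then classified per amplicon: sequences within a small edit
distance of a parental allele, differing by a homopolymer-adjacent indel, or
composable as `parentA[0:i) + parentB[i:end)` are artifacts; a globally
common (MPAF ≥ 0.05) but locally rare (RPAF < 0.10) sequence that dominates
some other amplicon carries the carryover-contamination signature and is
flagged — never auto-deleted — for replicate PCR resolution. A
rank-frequency profile (mean within-amplicon frequency of the 1st…k-th most
common variant) assesses locus copy number: a sharp drop after rank 2 means
a single locus. Minimum sequencing depth comes from an exact multinomial
tail model: the smallest read count *T* such that every one of *k*
equifrequent true alleles receives ≥ *m* reads with probability ≥ the chosen
confidence.

**Population genetics (`popgen`).** Allele frequencies; observed and
unbiased expected heterozygosity with Weir & Cockerham's within-population
*f* (F<sub>IS</sub>); an exact U-score test of heterozygote excess whose null
conditions on the observed allele counts (Levene), by Monte-Carlo or full
enumeration; EM (Dempster) null-allele frequency; Excoffier–Slatkin EM
haplotype frequencies for unphased two-locus data; a permutation
likelihood-ratio test of linkage disequilibrium, 2(logL̂ − logL₀); and
pairwise Weir–Cockerham θ (F<sub>ST</sub>) with permutation p-values.

**Selection (`selection`).** Nei–Gojobori (1986) pathway counting of
synonymous/non-synonymous sites and substitutions — every stop-free ordering
of the changes between two codons weighted equally — with Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3), averaged over all sequence pairs, on
user-supplied codon partitions (antigen-binding sites vs the rest,
positively selected sites vs the rest). Standard errors come from a
bootstrap over codon sites, and the codon-based Z-test
Z = (dN − dS)/√(SE²(dN) + SE²(dS)) tests dN > dS.

**Phylogeny (`phylo`).** Poisson-corrected amino-acid distances
(d = −ln(1 − p)), Saitou–Nei neighbour joining with a documented
deterministic tie rule, bipartition bootstrap supports over column
resamples, Newick output with a display threshold for supports.

**Allelic richness (`richness`).** Permutation rarefaction: distinct alleles
among *n* randomly drawn individuals, mean ± SD over replicates, matching
the hypergeometric expectation Σ_a (1 − C(N−k_a, n)/C(N, n)).

**Simulator (`simdata`).** Allele pools (optionally with a two-codon
in-frame insertion in part of the pool), Hardy–Weinberg genotypes, and
per-amplicon read sets with negative-binomial depth, Beta-distributed
allelic balance in heterozygotes, and the four corruption channels above —
each emitted variant tagged in a truth ledger (`true`, `point`,
`homopolymer`, `chimera`, `contaminant`).

## Worked example

```python
import numpy as np
from mhc_ampcall import simdata, ampsort, popgen

pool = simdata.generate_allele_pool("DQB", n_alleles=22, length=162,
                                    insertion_fraction=7/22, seed=1)
freqs = np.random.default_rng(2).dirichlet(np.ones(22) * 3)
truth = simdata.generate_population(pool, n_individuals=100,
                                    allele_freqs=freqs, seed=3)
readsets = simdata.generate_amplicons(
    truth, simdata.SimConfig(n_individuals=100, seed=4))

prof = ampsort.rank_frequency_profile(readsets)
gt, report = ampsort.call_genotypes(readsets, truth.sequences)
table = popgen.genotype_frame(gt)
ho, he, fis = popgen.heterozygosity(table, "DQB")
hwe = popgen.hwe_u_test(table, "DQB", n_mc=1000, seed=5)
```

Output (with these seeds):

```
unique variants: 615
rank-profile drop ratio: 54.7 -> verdict: single locus
call statuses: {'OK': 99, 'NEEDS_REPLICATE': 1}
exact-genotype recovery: 100.0%
Ho=0.96 He=0.94 Fis=-0.019  HWE excess p=0.33
min reads (2 alleles, >=5 copies, 95%): 17
```

Reading this: 100 amplicons yielded 615 unique sequences, most of them rare
artifacts; the within-amplicon frequency profile collapses after rank 2
(drop ratio 54.7), so the locus is single-copy. The cascade validates 1–2
alleles everywhere (one amplicon carries an unresolved contamination suspect
and would be replicated in practice), recovering every true genotype. The
resulting cohort is in Hardy–Weinberg proportions (F<sub>IS</sub> ≈ 0, no
heterozygote excess, p = 0.33), as expected from random-mating simulation.
The depth model says 17 reads suffice for a heterozygote at 95% confidence
when every true allele must be seen five times.

A pipeline driver and CLI chain every stage from one YAML config:

```bash
mhc-ampcall all --config config.yaml --seed 1 --out-dir out/
```

writing amplicon tables, variant statistics, classifications, genotypes, QC
report, per-locus population genetics, partitioned dN/dS tables, a
bootstrap NJ tree (Newick) and rarefaction curves, each stamped with the
config hash and seed.

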