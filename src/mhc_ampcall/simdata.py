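"""Synthetic MHC amplicon-sequencing data with a known truth ledger.

The generator emulates the structure of a 454-style amplicon experiment on one
or two non-duplicated MHC class II loci: each amplicon (one individual x locus
PCR product, possibly replicated) carries reads for its 1-2 true alleles at
roughly balanced proportions, plus rare artifact reads derived from the
parental sequences (1-2 bp point derivatives, homopolymer-adjacent indels,
single-breakpoint chimeras in heterozygotes) and occasional cross-amplicon
carryover of a foreign true allele at low within-amplicon frequency.

Every emitted variant carries exactly one label in the truth ledger
(``true``, ``point``, ``homopolymer``, ``chimera``, ``contaminant``), so the
whole validation cascade downstream can be scored against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._codon import SENSE_CODONS, has_internal_stop

__all__ = [
    "AllelePool",
    "SimConfig",
    "TruthSet",
    "LedgerEntry",
    "generate_allele_pool",
    "generate_population",
    "generate_amplicons",
]

_BASES = "ACGT"

#: ledger labels a simulated variant may carry
LABELS = ("true", "point", "homopolymer", "chimera", "contaminant")


@dataclass(frozen=True)
class AllelePool:
    """A locus's pool of true allele sequences.

    Non-carrier alleles share one length; alleles in ``insertion_carriers``
    carry a 6-base (two-codon) in-frame insertion, mimicking the fragment
    length polymorphism seen at DQB-like loci.
    """

    locus_id: str
    alleles: tuple[tuple[str, str], ...]  # (allele_id, sequence)
    insertion_carriers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.alleles]
        if len(set(ids)) != len(ids):
            raise ValueError("allele ids must be unique")
        seqs = [s for _, s in self.alleles]
        if len(set(seqs)) != len(seqs):
            raise ValueError("allele sequences must be pairwise distinct")
        base = {len(s) for a, s in self.alleles if a not in self.insertion_carriers}
        ins = {len(s) for a, s in self.alleles if a in self.insertion_carriers}
        if len(base) > 1 or len(ins) > 1:
            raise ValueError("inconsistent sequence lengths within pool")
        if base and ins and ins.pop() != base.pop() + 6:
            raise ValueError("insertion carriers must be exactly 6 bases longer")
        for _, s in self.alleles:
            if has_internal_stop(s):
                raise ValueError("allele contains an internal stop codon")

    @property
    def allele_ids(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.alleles)

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class SimConfig:
    """Rates and laws governing one simulated sequencing campaign.

    depth_mean/depth_dispersion parameterise a negative binomial reads-per-
    amplicon law (dispersion -> inf approaches Poisson). Error rates are
    per-read probabilities; ``contamination_rate`` is per amplicon.
    """

    n_individuals: int = 100
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0
    err_point: float = 0.02
    err_homopolymer: float = 0.01
    chimera_rate: float = 0.01
    contamination_rate: float = 0.03
    contamination_frac: float = 0.04
    balance_beta: float = 20.0  # Beta(b, b) allelic balance in heterozygotes
    homopolymer_min_run: int = 3
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("err_point", "err_homopolymer", "chimera_rate",
                     "contamination_rate", "contamination_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class LedgerEntry:
    amplicon_id: str
    variant_id: str
    label: str  # one of LABELS
    parents: tuple[str, ...] = ()
    breakpoint: int | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown ledger label {self.label!r}")


@dataclass
class TruthSet:
    """True genotypes plus, after read simulation, the artifact ledger."""

    pools: dict[str, AllelePool]
    genotypes: dict[tuple[str, str], tuple[str, str]]  # (individual, locus) -> pair
    ledger: list[LedgerEntry] = field(default_factory=list)
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)  # locus -> id -> seq

    @property
    def individuals(self) -> list[str]:
        return sorted({i for i, _ in self.genotypes})

    @property
    def loci(self) -> list[str]:
        return sorted(self.pools)

    def merge(self, other: "TruthSet") -> "TruthSet":
        """Combine single-locus truth sets over the same individuals."""
        if set(self.pools) & set(other.pools):
            raise ValueError("overlapping loci")
        return TruthSet(
            pools={**self.pools, **other.pools},
            genotypes={**self.genotypes, **other.genotypes},
        )


def _random_inframe_sequence(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def generate_allele_pool(
    locus_id: str,
    n_alleles: int,
    length: int = 162,
    insertion_fraction: float = 0.0,
    seed: int = 0,
    *,
    backbone: str | None = None,
    max_tries: int = 10_000,
) -> AllelePool:
    """Draw a pool of distinct, stop-free, in-frame allele sequences.

    ``length`` is the base (non-carrier) length after the primer-trim
    convention and must be divisible by 3; real MHC class II exon-2 amplicons
    fall in the 162-170 bp range. ``insertion_fraction`` of the alleles
    (rounded) carry a two-codon insertion after codon 8, making them exactly
    6 bases longer. Passing a shared ``backbone`` makes pools of different
    loci homologous (as paralogous MHC loci are), keeping cross-locus
    distances unsaturated.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if length % 3 or length < 9:
        raise ValueError("length must be divisible by 3 and >= 9")
    if not 0.0 <= insertion_fraction <= 1.0:
        raise ValueError("insertion_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_ins = int(round(insertion_fraction * n_alleles))
    n_codons = length // 3

    # Start from one backbone and mutate codons so the pool looks like a
    # family of related alleles rather than unrelated random strings.
    if backbone is not None:
        if len(backbone) != length or has_internal_stop(backbone):
            raise ValueError("backbone must be stop-free and match length")
    else:
        backbone = _random_inframe_sequence(rng, n_codons)
    seqs: list[str] = []
    seen: set[str] = set()
    tries = 0
    while len(seqs) < n_alleles:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {n_alleles} distinct stop-free sequences "
                f"of length {length}"
            )
        codons = [backbone[i : i + 3] for i in range(0, length, 3)]
        n_mut = int(rng.integers(1, max(2, n_codons // 4)))
        pos = rng.choice(n_codons, size=min(n_mut, n_codons), replace=False)
        for p in pos:
            codons[p] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
        s = "".join(codons)
        if s in seen:
            continue
        seen.add(s)
        seqs.append(s)

    ids = [f"{locus_id}*{i + 1:03d}" for i in range(n_alleles)]
    carriers = set(ids[:n_ins])
    insertion = _random_inframe_sequence(rng, 2)
    alleles = []
    for aid, s in zip(ids, seqs):
        if aid in carriers:
            s = s[:24] + insertion + s[24:]  # after codon 8, in frame
            while has_internal_stop(s):  # insertion junction cannot create one,
                insertion = _random_inframe_sequence(rng, 2)  # but stay safe
                s = s[:24] + insertion + s[24:]
        alleles.append((aid, s))
    return AllelePool(locus_id, tuple(alleles), frozenset(carriers))


def generate_population(
    pool: AllelePool,
    n_individuals: int,
    allele_freqs,
    seed: int = 0,
) -> TruthSet:
    """Draw Hardy-Weinberg genotypes: two independent allele copies each.

    Pairs are stored unordered (sorted by allele id). Observed heterozygosity
    converges to 1 - sum(p^2) as the sample grows.
    """
    freqs = np.asarray(allele_freqs, dtype=float)
    if freqs.shape != (len(pool),):
        raise ValueError("allele_freqs length must match pool size")
    if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("allele_freqs must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    ids = pool.allele_ids
    genotypes: dict[tuple[str, str], tuple[str, str]] = {}
    draws = rng.choice(len(ids), size=(n_individuals, 2), p=freqs)
    for i in range(n_individuals):
        ind = f"ind{i + 1:04d}"
        a, b = sorted((ids[draws[i, 0]], ids[draws[i, 1]]))
        genotypes[(ind, pool.locus_id)] = (a, b)
    return TruthSet(pools={pool.locus_id: pool}, genotypes=genotypes)


@dataclass
class AmpliconReadSet:
    """One PCR product's sequencing outcome: variant id -> read count."""

    amplicon_id: str
    individual_id: str
    locus_id: str
    run_id: str
    replicate_index: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("read set must contain at least one variant")
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("read counts must be positive")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """(start, length) of maximal single-base runs of length >= min_run."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j - i))
        i = j
    return runs


def _point_derivative(rng: np.random.Generator, seq: str) -> str:
    n_mut = int(rng.integers(1, 3))  # 1 or 2 substitutions
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    s = list(seq)
    for p in pos:
        alts = [b for b in _BASES if b != s[p]]
        s[p] = alts[rng.integers(0, 3)]
    return "".join(s)


def _homopolymer_derivative(
    rng: np.random.Generator, seq: str, min_run: int
) -> str | None:
    runs = _homopolymer_runs(seq, min_run)
    if not runs:
        return None
    start, length = runs[rng.integers(0, len(runs))]
    if rng.random() < 0.5:  # insertion of one extra run base
        return seq[:start] + seq[start] + seq[start:]
    return seq[:start] + seq[start + 1 :]  # deletion of one run base


def _chimera_derivative(
    rng: np.random.Generator, pa: str, pb: str
) -> tuple[str, int] | None:
    if len(pa) != len(pb):
        return None  # length polymorphism: template switch breaks frame, skip
    n = len(pa)
    for _ in range(20):
        i = int(rng.integers(1, n))
        if rng.random() < 0.5:
            cand = pa[:i] + pb[i:]
        else:
            cand = pb[:i] + pa[i:]
        if cand != pa and cand != pb:
            return cand, i
    return None


def generate_amplicons(truth: TruthSet, config: SimConfig) -> list[AmpliconReadSet]:
    """Simulate per-amplicon read sets and fill in the truth ledger.

    Read counts always sum to the drawn depth: artifact and contaminant reads
    are reassigned from parental reads, never added on top. Chimeras arise
    only in heterozygotes; contaminant alleles are drawn from the pool minus
    the individual's own genotype.
    """
    rng = np.random.default_rng(config.seed)
    truth.ledger = []
    truth.sequences = {}
    out: list[AmpliconReadSet] = []
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)

    for locus in truth.loci:
        pool = truth.pools[locus]
        pool_seqs = pool.sequences
        seq_registry: dict[str, str] = {}  # sequence -> variant_id
        locus_seqs: dict[str, str] = {}  # variant_id -> sequence
        for aid, s in pool.alleles:
            seq_registry[s] = aid
            locus_seqs[aid] = s
        artifact_counter = 0

        def _variant_id(seq: str) -> str:
            nonlocal artifact_counter
            vid = seq_registry.get(seq)
            if vid is None:
                artifact_counter += 1
                vid = f"{locus}_art{artifact_counter:04d}"
                seq_registry[seq] = vid
                locus_seqs[vid] = seq
            return vid

        for ind in truth.individuals:
            geno = truth.genotypes.get((ind, locus))
            if geno is None:
                continue
            a1, a2 = geno
            for rep in range(1, config.n_replicates + 1):
                amp_id = f"{ind}|{locus}|r{rep}"
                run_id = f"run{rep}"
                depth = max(1, int(rng.negative_binomial(nb_n, nb_p)))

                counts: dict[str, int] = {}
                labels: dict[str, LedgerEntry] = {}
                if a1 == a2:
                    counts[a1] = depth
                else:
                    w = rng.beta(config.balance_beta, config.balance_beta)
                    n1 = int(rng.binomial(depth, w))
                    n1 = min(max(n1, 0), depth)
                    if n1 > 0:
                        counts[a1] = n1
                    if depth - n1 > 0:
                        counts[a2] = depth - n1
                for aid in counts:
                    labels[aid] = LedgerEntry(amp_id, aid, "true")

                parents = [p for p in (a1, a2) if p in counts]

                def _steal_read(parent: str) -> bool:
                    """Move one read off a parent; refuse to exhaust it."""
                    if counts.get(parent, 0) <= 5:
                        return False
                    counts[parent] -= 1
                    return True

                def _add_artifact(seq: str, label: str, par: tuple[str, ...],
                                  steal_from: str, bp: int | None = None) -> None:
                    vid = seq_registry.get(seq)
                    if vid in (a1, a2):
                        return  # collided with a true allele: skip the event
                    if not _steal_read(steal_from):
                        return
                    vid = _variant_id(seq)
                    counts[vid] = counts.get(vid, 0) + 1
                    if vid not in labels:
                        labels[vid] = LedgerEntry(amp_id, vid, label, par, bp)

                def _pick_parent() -> str:
                    weights = np.array([counts[p] for p in parents], dtype=float)
                    weights /= weights.sum()
                    return parents[rng.choice(len(parents), p=weights)]

                # point-mutation derivatives
                for _ in range(rng.binomial(depth, config.err_point)):
                    par = _pick_parent()
                    _add_artifact(_point_derivative(rng, pool_seqs[par]),
                                  "point", (par,), steal_from=par)
                # homopolymer indels
                for _ in range(rng.binomial(depth, config.err_homopolymer)):
                    par = _pick_parent()
                    der = _homopolymer_derivative(
                        rng, pool_seqs[par], config.homopolymer_min_run)
                    if der is None:
                        continue
                    _add_artifact(der, "homopolymer", (par,), steal_from=par)
                # chimeras (heterozygotes only)
                if len(parents) == 2:
                    for _ in range(rng.binomial(depth, config.chimera_rate)):
                        der = _chimera_derivative(
                            rng, pool_seqs[a1], pool_seqs[a2])
                        if der is None:
                            continue
                        seq, bp = der
                        _add_artifact(seq, "chimera", (a1, a2),
                                      steal_from=_pick_parent(), bp=bp)
                # cross-amplicon carryover of a foreign true allele
                if rng.random() < config.contamination_rate:
                    foreign = [x for x in pool.allele_ids if x not in (a1, a2)]
                    if foreign:
                        cont = foreign[rng.integers(0, len(foreign))]
                        n_cont = max(1, int(round(config.contamination_frac * depth)))
                        moved = 0
                        for _ in range(n_cont):
                            if not _steal_read(_pick_parent()):
                                break
                            moved += 1
                        if moved:
                            counts[cont] = counts.get(cont, 0) + moved
                            labels[cont] = LedgerEntry(
                                amp_id, cont, "contaminant", (cont,))

                out.append(AmpliconReadSet(
                    amplicon_id=amp_id, individual_id=ind, locus_id=locus,
                    run_id=run_id, replicate_index=rep, counts=counts))
                truth.ledger.extend(labels[v] for v in sorted(labels))

        truth.sequences[locus] = locus_seqs
    return out
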