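"""Per-amplicon allele validation for NGS amplicon genotyping.

This is the heart of the package. Rather than discarding variants below a
global frequency threshold, every variant is judged both across amplicons
(MPAF: its within-amplicon frequency averaged over all amplicons possessing
it) and within each amplicon (RPAF: its relative read frequency there):

* artifacts (point derivatives, homopolymer indels, chimeras) sit close in
  sequence space to one of the two parental alleles of their amplicon and are
  rare both within and across amplicons;
* carryover contaminants are true alleles of *other* amplicons, so they show
  the signature of high MPAF combined with locally low RPAF;
* suspected contaminants are never auto-dropped - they are resolved by
  replicate PCRs, and amplicons whose artifact inflation leaves more than two
  validated alleles are excluded.

A rank-frequency profile across amplicons assesses locus copy number (a
single-copy locus shows a sharp frequency drop after rank 2), and a
multinomial tail model gives the minimum sequencing depth at which every true
allele is seen often enough at a chosen confidence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy import stats

from .simdata import AmpliconReadSet, _homopolymer_runs

__all__ = [
    "AmpliconReadSet",
    "VariantRecord",
    "SortConfig",
    "Classification",
    "GenotypeCall",
    "GenotypeTable",
    "RankProfile",
    "compute_rpaf",
    "compute_variant_stats",
    "rank_frequency_profile",
    "detect_chimera",
    "classify_variants",
    "resolve_with_replicates",
    "min_reads_for_confidence",
    "call_genotypes",
    "sorting_diagnostics",
]

TRUE_ALLELE = "TRUE_ALLELE"
ARTIFACT_POINT = "ARTIFACT_POINT"
ARTIFACT_HOMOPOLYMER = "ARTIFACT_HOMOPOLYMER"
ARTIFACT_CHIMERA = "ARTIFACT_CHIMERA"
CONTAMINANT_SUSPECT = "CONTAMINANT_SUSPECT"
UNRESOLVED = "UNRESOLVED"

ARTIFACT_LABELS = (ARTIFACT_POINT, ARTIFACT_HOMOPOLYMER, ARTIFACT_CHIMERA)


@dataclass
class VariantRecord:
    """Global frequency profile of one unique sequence across a cohort."""

    variant_id: str
    sequence: str | None
    mpaf: float
    n_amplicons: int
    rpaf_by_amplicon: dict[str, float]


@dataclass(frozen=True)
class SortConfig:
    """Thresholds of the validation cascade (all configurable, none hidden)."""

    mpaf_flag: float = 0.05       # descriptive MPAF flag, not an auto-filter
    rpaf_susp: float = 0.10       # locally-rare bound for contaminant suspects
    rpaf_high: float = 0.25       # "high RPAF elsewhere" contaminant evidence
    d_max: int = 2                # max edit distance for point-artifact match
    homopolymer_min_run: int = 3
    depth_threshold: int = 18     # minimum reads for a reliable genotype
    drop_ratio_threshold: float = 3.0  # rank-2/rank-3 drop for single-locus call


@dataclass
class Classification:
    """Labels for every variant of one amplicon (a total function)."""

    amplicon_id: str
    labels: dict[str, str]
    parents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    breakpoints: dict[str, int] = field(default_factory=dict)

    def variants_with(self, label: str) -> list[str]:
        return sorted(v for v, l in self.labels.items() if l == label)


@dataclass
class GenotypeCall:
    individual_id: str
    locus_id: str
    alleles: tuple[str, ...]
    status: str  # OK | NEEDS_REPLICATE | EXCLUDED | LOW_DEPTH | UNRESOLVED
    reason: str = ""


@dataclass
class GenotypeTable:
    calls: dict[tuple[str, str], GenotypeCall]

    def to_frame(self):
        import pandas as pd

        rows = []
        for (ind, locus), c in sorted(self.calls.items()):
            a = list(c.alleles) + [None, None]
            rows.append({"individual": ind, "locus": locus,
                         "allele1": a[0], "allele2": a[1] if len(c.alleles) != 1 else a[0],
                         "status": c.status, "reason": c.reason})
        return pd.DataFrame(rows)


def compute_rpaf(readset: AmpliconReadSet) -> dict[str, float]:
    """Relative per-amplicon frequency of each variant (sums to 1)."""
    total = readset.total_reads
    if total <= 0:
        raise ValueError("read set has zero total reads")
    return {v: c / total for v, c in sorted(readset.counts.items())}


def compute_variant_stats(
    readsets: list[AmpliconReadSet],
    sequences: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """MPAF (unweighted mean of RPAFs over amplicons possessing the variant)
    and amplicon counts for every variant in a single-locus cohort."""
    if not readsets:
        raise ValueError("no read sets given")
    loci = {r.locus_id for r in readsets}
    if len(loci) > 1:
        raise ValueError(f"mixed loci in cohort: {sorted(loci)}")
    rpafs: dict[str, dict[str, float]] = {}
    for rs in readsets:
        for v, f in compute_rpaf(rs).items():
            rpafs.setdefault(v, {})[rs.amplicon_id] = f
    records = []
    for v in sorted(rpafs):
        by_amp = rpafs[v]
        records.append(VariantRecord(
            variant_id=v,
            sequence=None if sequences is None else sequences.get(v),
            mpaf=float(np.mean(list(by_amp.values()))),
            n_amplicons=len(by_amp),
            rpaf_by_amplicon=dict(sorted(by_amp.items())),
        ))
    return records


@dataclass
class RankProfile:
    """Mean within-amplicon frequency (and mean MPAF) by abundance rank."""

    mean_rpaf: list[float]   # index 0 = rank 1
    mean_mpaf: list[float]
    drop_ratio: float        # mean rank-2 RPAF / mean rank-3 RPAF
    verdict: str             # "single locus" | "ambiguous"


def rank_frequency_profile(
    readsets: list[AmpliconReadSet],
    k_max: int = 6,
    drop_ratio_threshold: float = 3.0,
) -> RankProfile:
    """Rank variants within each amplicon by read count (ties broken by
    variant id) and average the rank-r frequency across amplicons; amplicons
    with fewer than r variants contribute 0 at rank r, keeping the means
    comparable. A sharp drop between ranks 2 and 3 indicates a single,
    non-duplicated locus."""
    if not readsets:
        raise ValueError("no read sets given")
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    stats_by_id = {r.variant_id: r for r in compute_variant_stats(readsets)}
    rpaf_rows = np.zeros((len(readsets), k_max))
    mpaf_rows = np.zeros((len(readsets), k_max))
    for i, rs in enumerate(readsets):
        ranked = sorted(rs.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        total = rs.total_reads
        for r, (v, c) in enumerate(ranked[:k_max]):
            rpaf_rows[i, r] = c / total
            mpaf_rows[i, r] = stats_by_id[v].mpaf
    mean_rpaf = rpaf_rows.mean(axis=0)
    mean_mpaf = mpaf_rows.mean(axis=0)
    drop = math.inf if mean_rpaf[2] == 0 else float(mean_rpaf[1] / mean_rpaf[2])
    verdict = "single locus" if drop >= drop_ratio_threshold else "ambiguous"
    return RankProfile(list(mean_rpaf), list(mean_mpaf), drop, verdict)


def detect_chimera(candidate: str, parent_a: str, parent_b: str) -> int | None:
    """Smallest breakpoint i such that the candidate equals one parent's
    prefix joined to the other parent's suffix; None if no single-breakpoint
    composition exists or the candidate equals a parent."""
    if parent_a == parent_b:
        raise ValueError("parents must be distinct")
    if candidate in (parent_a, parent_b):
        return None
    best: int | None = None
    for pa, pb in ((parent_a, parent_b), (parent_b, parent_a)):
        if len(candidate) != len(pa) or len(pa) != len(pb):
            continue
        n = len(candidate)
        lcp = 0
        while lcp < n and candidate[lcp] == pa[lcp]:
            lcp += 1
        lcs = 0
        while lcs < n and candidate[n - 1 - lcs] == pb[n - 1 - lcs]:
            lcs += 1
        i = max(1, n - lcs)
        if i <= min(lcp, n - 1):
            if best is None or i < best:
                best = i
    return best


def _indel_touches_homopolymer(candidate: str, parent: str, min_run: int) -> bool:
    """True if candidate differs from parent only by indels, each adjacent to
    a homopolymer run of length >= min_run in the parent."""
    res = edlib.align(candidate, parent, task="path")
    if res["editDistance"] < 1:
        return False
    ops = []
    pos = 0  # position in parent
    import re

    for m in re.finditer(r"(\d+)([=XID])", res["cigar"]):
        ln, op = int(m.group(1)), m.group(2)
        if op in "=X":
            if op == "X":
                return False  # substitutions present: not a pure indel
            pos += ln
        elif op == "D":  # deletion from parent
            ops.append(pos)
            pos += ln
        elif op == "I":  # insertion relative to parent
            ops.append(pos)
    if not ops:
        return False
    runs = _homopolymer_runs(parent, min_run)
    for p in ops:
        if not any(start - 1 <= p <= start + length for start, length in runs):
            return False
    return True


def _edit_distance(a: str, b: str, k: int) -> int:
    d = edlib.align(a, b, k=k)["editDistance"]
    return d if d >= 0 else k + 1


def classify_variants(
    readset: AmpliconReadSet,
    global_stats: dict[str, VariantRecord],
    sequences: dict[str, str],
    config: SortConfig = SortConfig(),
) -> Classification:
    """Label every variant of one amplicon.

    Cascade: (1) the two most abundant variants are provisional parentals;
    (2) a non-parental within ``d_max`` edits of a parental, or differing by a
    homopolymer-adjacent indel, or composable as a single-breakpoint chimera
    of the two parentals, is an artifact attributed to its parental(s);
    (3) a remaining variant that is globally common (MPAF >= mpaf_flag) but
    locally rare (RPAF < rpaf_susp) while reaching RPAF >= rpaf_high in some
    other amplicon is a carryover-contaminant suspect; (4) remaining variants
    with adequate MPAF and RPAF are true alleles; (5) anything else is
    unresolved. Deterministic; ties broken by variant id.
    """
    rpaf = compute_rpaf(readset)
    for v in readset.counts:
        if v not in global_stats:
            raise ValueError(f"missing global stats for variant {v!r}")
        if v not in sequences:
            raise ValueError(f"missing sequence for variant {v!r}")
    ranked = sorted(readset.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    parentals = [v for v, _ in ranked[:2]]

    labels: dict[str, str] = {}
    parents: dict[str, tuple[str, ...]] = {}
    breakpoints: dict[str, int] = {}

    for v, _count in ranked:
        if v in parentals:
            continue
        seq = sequences[v]
        # homopolymer indel vs either parental (checked before generic edits:
        # a 1-edit indel next to a run is the classic pyrosequencing error)
        hp = [p for p in parentals
              if _indel_touches_homopolymer(seq, sequences[p], config.homopolymer_min_run)
              and _edit_distance(seq, sequences[p], config.d_max) <= config.d_max]
        if hp:
            labels[v] = ARTIFACT_HOMOPOLYMER
            parents[v] = (hp[0],)
            continue
        near = [(p, _edit_distance(seq, sequences[p], config.d_max))
                for p in parentals]
        near = [(p, d) for p, d in near if d <= config.d_max]
        if near:
            near.sort(key=lambda pd: (pd[1], pd[0]))
            labels[v] = ARTIFACT_POINT
            parents[v] = (near[0][0],)
            continue
        if len(parentals) == 2 and sequences[parentals[0]] != sequences[parentals[1]]:
            bp = detect_chimera(seq, sequences[parentals[0]], sequences[parentals[1]])
            if bp is not None:
                labels[v] = ARTIFACT_CHIMERA
                parents[v] = tuple(parentals)
                breakpoints[v] = bp
                continue
        rec = global_stats[v]
        if rec.mpaf >= config.mpaf_flag and rpaf[v] < config.rpaf_susp:
            high_elsewhere = any(
                amp != readset.amplicon_id and f >= config.rpaf_high
                for amp, f in rec.rpaf_by_amplicon.items())
            if high_elsewhere:
                labels[v] = CONTAMINANT_SUSPECT
                continue
        if rec.mpaf >= config.mpaf_flag and rpaf[v] >= config.rpaf_susp:
            labels[v] = TRUE_ALLELE
        else:
            labels[v] = UNRESOLVED

    for v in parentals:
        rec = global_stats[v]
        if rec.mpaf >= config.mpaf_flag:
            # a "parental" that is globally common but locally marginal and
            # dominant elsewhere is still a contamination suspect
            if rpaf[v] < config.rpaf_susp and any(
                    amp != readset.amplicon_id and f >= config.rpaf_high
                    for amp, f in rec.rpaf_by_amplicon.items()):
                labels[v] = CONTAMINANT_SUSPECT
            else:
                labels[v] = TRUE_ALLELE
        else:
            labels[v] = UNRESOLVED
    return Classification(readset.amplicon_id, labels, parents, breakpoints)


def resolve_with_replicates(
    calls_per_replicate: list[Classification],
    individual_id: str,
    locus_id: str,
) -> GenotypeCall:
    """Merge replicate PCRs of one (individual, locus).

    True-allele sets are intersected; a contaminant suspect absent from (or
    never validated in) another replicate is demoted and dropped; more than
    two alleles persisting across replicates excludes the amplicon; replicates
    agreeing on no allele at all are unresolved, never averaged.
    """
    if len(calls_per_replicate) < 2:
        raise ValueError("need at least two replicates to resolve")
    true_sets = [set(c.variants_with(TRUE_ALLELE)) for c in calls_per_replicate]
    core = set.intersection(*true_sets)
    # a suspect seen as TRUE (or suspect) in every replicate is rescued
    for v in set.union(*(set(c.variants_with(CONTAMINANT_SUSPECT))
                         for c in calls_per_replicate)):
        if all(c.labels.get(v) in (TRUE_ALLELE, CONTAMINANT_SUSPECT)
               for c in calls_per_replicate):
            if all(c.labels.get(v) == CONTAMINANT_SUSPECT for c in calls_per_replicate):
                continue  # consistently suspicious: drop
            core.add(v)
    core_t = tuple(sorted(core))
    if len(core_t) == 0:
        return GenotypeCall(individual_id, locus_id, (), UNRESOLVED,
                            "replicates share no validated allele")
    if len(core_t) > 2:
        return GenotypeCall(individual_id, locus_id, core_t, "EXCLUDED",
                            f"{len(core_t)} alleles persist across replicates")
    return GenotypeCall(individual_id, locus_id, core_t, "OK")


def min_reads_for_confidence(
    n_alleles: int,
    min_copies: int,
    confidence: float = 0.95,
    artifact_rate: float = 0.0,
    t_max: int = 10_000,
) -> int:
    """Smallest depth T such that, splitting T reads multinomially among
    ``n_alleles`` equifrequent true alleles (total mass 1 - artifact_rate)
    plus an artifact class, every true allele receives at least ``min_copies``
    reads with probability >= ``confidence``. Exact tail computation via
    inclusion-exclusion over the alleles' failure events."""
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if not 0 <= artifact_rate < 1:
        raise ValueError("artifact_rate must be in [0, 1)")
    if min_copies < 0:
        raise ValueError("min_copies must be >= 0")
    if min_copies == 0:
        return 1
    p = (1.0 - artifact_rate) / n_alleles

    def prob_all_at_least(T: int) -> float:
        # P(min_i X_i >= m) = sum_j (-1)^j C(k,j) P(X_1 < m, ..., X_j < m)
        total = 0.0
        for j in range(n_alleles + 1):
            if j * p >= 1.0 + 1e-12 and j > 0:
                pass
            tail = _joint_lower_tail(T, p, j, min_copies)
            total += (-1) ** j * math.comb(n_alleles, j) * tail
        return total

    T = n_alleles * min_copies
    while T <= t_max:
        if prob_all_at_least(T) >= confidence:
            return T
        T += 1
    raise RuntimeError("no depth below t_max reaches the requested confidence")


def _joint_lower_tail(T: int, p: float, j: int, m: int) -> float:
    """P(X_1 < m, ..., X_j < m) for j multinomial cells of probability p each."""
    if j == 0:
        return 1.0
    rest = 1.0 - j * p
    if rest < 0:
        rest = 0.0
    logp = math.log(p) if p > 0 else -math.inf
    logrest = math.log(rest) if rest > 0 else -math.inf
    total = 0.0
    for xs in itertools.product(range(m), repeat=j):
        s = sum(xs)
        if s > T:
            continue
        logterm = math.lgamma(T + 1) - math.lgamma(T - s + 1)
        for x in xs:
            logterm -= math.lgamma(x + 1)
            logterm += x * logp
        if T - s > 0:
            if rest == 0.0:
                continue
            logterm += (T - s) * logrest
        total += math.exp(logterm)
    return total


def call_genotypes(
    readsets: list[AmpliconReadSet],
    sequences: dict[str, dict[str, str]],
    config: SortConfig = SortConfig(),
) -> tuple[GenotypeTable, dict]:
    """Classify a full cohort and emit per-(individual, locus) genotypes.

    Amplicons under the depth threshold are LOW_DEPTH and replaced by an
    adequate replicate when one exists. Multiple adequate replicates are
    merged by :func:`resolve_with_replicates`; single amplicons with
    unresolved suspects or >2 validated alleles are flagged NEEDS_REPLICATE.
    A QC report tallies amplicons and calls per status.
    """
    by_locus: dict[str, list[AmpliconReadSet]] = {}
    for rs in readsets:
        by_locus.setdefault(rs.locus_id, []).append(rs)

    calls: dict[tuple[str, str], GenotypeCall] = {}
    report = {"n_amplicons": len(readsets), "low_depth_amplicons": 0,
              "by_status": {}, "classified_labels": {}}

    for locus in sorted(by_locus):
        cohort = by_locus[locus]
        seqs = sequences[locus]
        stats_ = {r.variant_id: r for r in compute_variant_stats(cohort, seqs)}
        groups: dict[tuple[str, str], list[AmpliconReadSet]] = {}
        for rs in cohort:
            groups.setdefault((rs.individual_id, rs.locus_id), []).append(rs)
        for (ind, loc), group in sorted(groups.items()):
            adequate = [rs for rs in group
                        if rs.total_reads >= config.depth_threshold]
            report["low_depth_amplicons"] += len(group) - len(adequate)
            if not adequate:
                calls[(ind, loc)] = GenotypeCall(
                    ind, loc, (), "LOW_DEPTH",
                    f"all {len(group)} amplicon(s) under "
                    f"{config.depth_threshold} reads")
                continue
            cls = [classify_variants(rs, stats_, seqs, config) for rs in adequate]
            for c in cls:
                for lab in c.labels.values():
                    report["classified_labels"][lab] = (
                        report["classified_labels"].get(lab, 0) + 1)
            if len(cls) >= 2:
                calls[(ind, loc)] = resolve_with_replicates(cls, ind, loc)
            else:
                c = cls[0]
                true_ = c.variants_with(TRUE_ALLELE)
                susp = c.variants_with(CONTAMINANT_SUSPECT)
                if len(true_) > 2:
                    calls[(ind, loc)] = GenotypeCall(
                        ind, loc, tuple(true_), "NEEDS_REPLICATE",
                        f"{len(true_)} validated alleles in a single amplicon")
                elif len(true_) == 0:
                    calls[(ind, loc)] = GenotypeCall(
                        ind, loc, (), UNRESOLVED, "no validated allele")
                elif susp:
                    calls[(ind, loc)] = GenotypeCall(
                        ind, loc, tuple(true_), "NEEDS_REPLICATE",
                        f"unresolved contamination suspect(s): {','.join(susp)}")
                else:
                    calls[(ind, loc)] = GenotypeCall(ind, loc, tuple(true_), "OK")
    for c in calls.values():
        report["by_status"][c.status] = report["by_status"].get(c.status, 0) + 1
    return GenotypeTable(calls), report


@dataclass
class CorrelationSummary:
    r: float | None
    p: float | None
    n: int
    flag: str = ""


@dataclass
class SortingDiagnostics:
    before: CorrelationSummary
    after: CorrelationSummary


def _mpaf_amplicon_corr(records: list[VariantRecord]) -> CorrelationSummary:
    if len(records) < 3:
        raise ValueError("need at least 3 variants")
    mpaf = np.array([r.mpaf for r in records])
    namp = np.array([r.n_amplicons for r in records], dtype=float)
    if np.ptp(mpaf) == 0 or np.ptp(namp) == 0:
        return CorrelationSummary(None, None, len(records), "zero variance")
    r, p = stats.pearsonr(mpaf, namp)
    return CorrelationSummary(float(r), float(p), len(records))


def sorting_diagnostics(
    records_before: list[VariantRecord],
    records_after: list[VariantRecord],
) -> SortingDiagnostics:
    """Pearson correlation between each variant's MPAF and the number of
    amplicons possessing it, before and after allele sorting. Artifacts have
    both low MPAF and few amplicons, so the correlation is expected positive
    before sorting and much weaker afterwards."""
    return SortingDiagnostics(
        before=_mpaf_amplicon_corr(records_before),
        after=_mpaf_amplicon_corr(records_after),
    )


def sorting_summary(
    n_total: int,
    n_below_flag: int,
    n_artifacts_above: int,
    n_contaminants_above: int,
) -> dict:
    """Bookkeeping of an allele-sorting campaign from its tally sheet:
    variants below the MPAF flag are all eliminated, and of those above it
    the listed artifacts and contaminants are removed, leaving the retained
    true alleles. Percentages are rounded to the nearest integer."""
    above = n_total - n_below_flag
    retained = above - n_artifacts_above - n_contaminants_above
    eliminated = n_total - retained
    if retained < 0:
        raise ValueError("tallies exceed the number of variants above the flag")
    return {
        "n_total": n_total,
        "n_above_flag": above,
        "retained": retained,
        "eliminated": eliminated,
        "pct_below_flag": round(100 * n_below_flag / n_total),
        "pct_eliminated": round(100 * eliminated / n_total),
    }
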