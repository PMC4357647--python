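"""Codon-level tests of positive selection on MHC allele alignments.

dN and dS follow the Nei-Gojobori (1986) evolutionary-pathway method: for a
codon pair differing at d positions, all d! orderings of the changes are
enumerated, orderings passing through a termination codon are discarded, and
synonymous/non-synonymous step counts are averaged over the remaining
pathways with equal weights. Proportions are corrected for multiple hits
with Jukes-Cantor, averaged over all sequence pairs, and compared by a
codon-based Z-test with bootstrap (over codon sites) standard errors.

Antigen-binding sites (ABS) and positively selected sites (PSS) enter as
user-supplied codon-position masks; the package does not infer them.
Gap handling is complete deletion alignment-wide by default (pairwise
deletion available with a warning), so the two-codon insertion polymorphism
is simply carried as gap columns in non-carrier sequences.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as _st

from ._codon import GENETIC_CODE, STOP_CODONS, translate_codon

__all__ = [
    "CodonAlignment",
    "SiteMask",
    "DnDsResult",
    "ng86_sites",
    "ng86_pair",
    "jukes_cantor",
    "partition_dnds",
    "z_test_selection",
    "variable_sites",
    "mean_pairwise_distance",
]

_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Equal-length, in-frame nucleotide sequences ('-' for alignment gaps)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.sequences.values()}
        if not self.sequences:
            raise ValueError("empty alignment")
        if len(lens) != 1:
            raise ValueError("aligned sequences must have equal length")
        (self.length,) = lens
        if self.length % 3:
            raise ValueError("alignment length must be divisible by 3")
        for sid, s in self.sequences.items():
            ungapped = s.replace("-", "")
            if len(ungapped) % 3:
                raise ValueError(f"{sid}: gaps break the reading frame")
            aa = [GENETIC_CODE.get(ungapped[i:i + 3]) for i in range(0, len(ungapped), 3)]
            if "*" in aa:
                raise ValueError(f"{sid}: internal stop codon")

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, sid: str, index: int) -> str:
        """1-based codon access."""
        return self.sequences[sid][3 * (index - 1): 3 * index]

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from .io import read_fasta

        return cls(read_fasta(path))

    def translated(self) -> dict[str, str]:
        out = {}
        for sid, s in self.sequences.items():
            out[sid] = "".join(translate_codon(s[i:i + 3]) if s[i:i + 3] != "---"
                               else "-" for i in range(0, len(s), 3))
        return out

    def gap_free_codon_columns(self) -> list[int]:
        """1-based codon columns with no gap in any sequence."""
        cols = []
        for c in range(1, self.n_codons + 1):
            if all("-" not in self.codon(sid, c) for sid in self.sequences):
                cols.append(c)
        return cols


@dataclass
class SiteMask:
    """Named codon-position partitions (1-based, on the alignment).

    Each named set and its complement over ``all_codons`` form a disjoint
    cover, e.g. ABS / non-ABS and PSS / non-PSS.
    """

    n_codons: int
    partitions: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sites in self.partitions.items():
            bad = [s for s in sites if not 1 <= s <= self.n_codons]
            if bad:
                raise ValueError(f"{name}: codon indices out of range: {bad}")

    def codons(self, partition: str) -> frozenset[int]:
        if partition in self.partitions:
            return self.partitions[partition]
        if partition.startswith("non-") and partition[4:] in self.partitions:
            return frozenset(range(1, self.n_codons + 1)) - self.partitions[partition[4:]]
        if partition == "all":
            return frozenset(range(1, self.n_codons + 1))
        raise KeyError(f"unknown partition {partition!r}")


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the fraction of possible single-base changes that are
    synonymous, with changes to termination codons excluded from the
    denominator; each position carries unit mass, so s + n = 3.
    """
    codon = codon.upper()
    if codon not in GENETIC_CODE or codon in STOP_CODONS:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_ok = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            n_ok += 1
            if GENETIC_CODE[alt] == aa:
                n_syn += 1
        if n_ok:
            syn += n_syn / n_ok
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_pair_diffs(ca: str, cb: str) -> tuple[float, float, bool]:
    """(syn, nonsyn) substitution counts between two sense codons averaged
    over all stop-free shortest pathways; flag True if no pathway is legal
    (the codon pair is then excluded)."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0, False
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = ca
        syn = nsyn = 0
        legal = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                legal = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if legal:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, True
    return syn_tot / n_paths, nsyn_tot / n_paths, False


def ng86_pair(
    seq_a: str,
    seq_b: str,
    codon_indices: list[int] | None = None,
):
    """Nei-Gojobori pathway counts for one sequence pair.

    Returns (S, N, sd, nd, pS, pN): averaged synonymous/nonsynonymous site
    counts of the two sequences, pathway-averaged substitution counts, and
    the proportions pS = sd/S, pN = nd/N. ``codon_indices`` (1-based)
    restricts the computation to a partition; codon columns containing gaps
    in either sequence are skipped, as are (rare, flagged elsewhere) codon
    pairs whose every pathway crosses a termination codon."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    if len(seq_a) % 3:
        raise ValueError("length must be divisible by 3")
    n_codons = len(seq_a) // 3
    idx = codon_indices if codon_indices is not None else range(1, n_codons + 1)
    S = N = sd = nd = 0.0
    for c in idx:
        ca = seq_a[3 * (c - 1): 3 * c].upper()
        cb = seq_b[3 * (c - 1): 3 * c].upper()
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon at codon {c}")
        s_a, n_a = ng86_sites(ca)
        s_b, n_b = ng86_sites(cb)
        syn, nsyn, excluded = _codon_pair_diffs(ca, cb)
        if excluded:
            continue
        S += (s_a + s_b) / 2.0
        N += (n_a + n_b) / 2.0
        sd += syn
        nd += nsyn
    ps = sd / S if S > 0 else math.nan
    pn = nd / N if N > 0 else math.nan
    return S, N, sd, nd, ps, pn


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns NaN (saturated) for p >= 3/4.
    """
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DnDsResult:
    partition: str
    n_codons: int
    dn: float
    ds: float
    se_dn: float
    se_ds: float
    z: float | None = None
    p_value: float | None = None
    flags: list[str] = field(default_factory=list)


def _pair_site_arrays(aln: CodonAlignment, codons: list[int]):
    """Per sequence pair and codon column: site counts (S, N) and pathway-
    averaged substitution counts (sd, nd); gapped or all-stop-pathway codons
    contribute zero. Shape (n_pairs, n_codons)."""
    ids = aln.ids
    pairs = list(itertools.combinations(ids, 2))
    shape = (len(pairs), len(codons))
    S = np.zeros(shape)
    N = np.zeros(shape)
    sd = np.zeros(shape)
    nd = np.zeros(shape)
    for pi, (a, b) in enumerate(pairs):
        sa, sb = aln.sequences[a], aln.sequences[b]
        for ci, c in enumerate(codons):
            ca = sa[3 * (c - 1): 3 * c].upper()
            cb = sb[3 * (c - 1): 3 * c].upper()
            if "-" in ca or "-" in cb:
                continue
            syn, nsyn, excluded = _codon_pair_diffs(ca, cb)
            if excluded:
                continue
            s_a, n_a = ng86_sites(ca)
            s_b, n_b = ng86_sites(cb)
            S[pi, ci] = (s_a + s_b) / 2.0
            N[pi, ci] = (n_a + n_b) / 2.0
            sd[pi, ci] = syn
            nd[pi, ci] = nsyn
    return S, N, sd, nd


def _jc_vec(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan)
    ok = p < 0.75
    out[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return out


def _mean_dnds_from_arrays(S, N, sd, nd, col_idx) -> tuple[float, float, int]:
    """Mean over pairs of JC-corrected pN/pS summed over the sampled codon
    columns; saturated (or siteless) pairs are dropped and counted."""
    Ssum = S[:, col_idx].sum(axis=1)
    Nsum = N[:, col_idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(Ssum > 0, sd[:, col_idx].sum(axis=1) / Ssum, np.nan)
        pn = np.where(Nsum > 0, nd[:, col_idx].sum(axis=1) / Nsum, np.nan)
    dn = _jc_vec(pn)
    ds = _jc_vec(ps)
    ok = ~(np.isnan(dn) | np.isnan(ds))
    n_dropped = int((~ok).sum())
    if not ok.any():
        return math.nan, math.nan, n_dropped
    return float(dn[ok].mean()), float(ds[ok].mean()), n_dropped


def partition_dnds(
    aln: CodonAlignment,
    mask: SiteMask,
    partition: str,
    n_boot: int = 1000,
    seed: int = 0,
    gap_policy: str = "complete",
) -> DnDsResult:
    """Mean pairwise JC-corrected dN and dS over one codon partition, with
    bootstrap (over codon sites within the partition) standard errors and the
    codon-based Z-test of positive selection (HA: dN > dS)."""
    if gap_policy == "complete":
        usable = set(aln.gap_free_codon_columns())
    elif gap_policy == "pairwise":
        warnings.warn("pairwise deletion makes site counts pair-dependent; "
                      "partitions may not sum to the whole alignment")
        usable = set(range(1, aln.n_codons + 1))
    else:
        raise ValueError("gap_policy must be 'complete' or 'pairwise'")
    codons = sorted(mask.codons(partition) & usable)
    if len(codons) < 2:
        raise ValueError(f"partition {partition!r} has fewer than 2 usable codons")
    if len(aln.sequences) < 2:
        raise ValueError("need at least 2 sequences")

    S, N, sd, nd = _pair_site_arrays(aln, codons)
    full = np.arange(len(codons))
    dn, ds, n_sat = _mean_dnds_from_arrays(S, N, sd, nd, full)
    flags = [f"{n_sat} saturated pair(s) excluded"] if n_sat else []

    rng = np.random.default_rng(seed)
    boot_dn = np.empty(n_boot)
    boot_ds = np.empty(n_boot)
    for i in range(n_boot):
        sample = rng.integers(0, len(codons), size=len(codons))
        boot_dn[i], boot_ds[i], _ = _mean_dnds_from_arrays(S, N, sd, nd, sample)
    se_dn = float(np.nanstd(boot_dn, ddof=1)) if n_boot > 1 else math.nan
    se_ds = float(np.nanstd(boot_ds, ddof=1)) if n_boot > 1 else math.nan
    res = DnDsResult(partition, len(codons), dn, ds, se_dn, se_ds, flags=flags)
    try:
        res.z, res.p_value = z_test_selection(res)
    except ValueError as e:
        res.flags.append(str(e))
    return res


def z_test_selection(result: DnDsResult, alternative: str = "greater"):
    """Codon-based Z-test: Z = (dN - dS)/sqrt(SE_dN^2 + SE_dS^2).

    ``alternative='greater'`` (default) is the one-tailed test of positive
    selection (HA: dN > dS), so a negative Z yields p > 0.5;
    ``'two-sided'`` is also available."""
    var = result.se_dn**2 + result.se_ds**2
    if not var > 0 or math.isnan(var):
        raise ValueError("zero or undefined bootstrap variance")
    z = (result.dn - result.ds) / math.sqrt(var)
    if alternative == "greater":
        p = float(_st.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * _st.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return float(z), p


def _columns(seqs: dict[str, str]) -> list[tuple[str, ...]]:
    mat = list(seqs.values())
    return [tuple(s[i] for s in mat) for i in range(len(mat[0]))]


def variable_sites(aln: CodonAlignment, level: str = "nucleotide"):
    """Number and proportion of columns with >= 2 distinct non-gap states."""
    if level == "nucleotide":
        seqs = aln.sequences
    elif level in ("amino acid", "aa"):
        seqs = aln.translated()
    else:
        raise ValueError("level must be 'nucleotide' or 'amino acid'")
    cols = _columns(seqs)
    n_var = sum(1 for col in cols if len({x for x in col if x != "-"}) >= 2)
    return n_var, n_var / len(cols)


def mean_pairwise_distance(aln: CodonAlignment, level: str = "nucleotide"):
    """Mean and SD of the raw count of differences over all sequence pairs,
    complete-deletion of gap-containing columns."""
    if level == "nucleotide":
        seqs = aln.sequences
    elif level in ("amino acid", "aa"):
        seqs = aln.translated()
    else:
        raise ValueError("level must be 'nucleotide' or 'amino acid'")
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    cols = _columns(seqs)
    keep = [i for i, col in enumerate(cols) if "-" not in col]
    dists = []
    for a, b in itertools.combinations(ids, 2):
        sa, sb = seqs[a], seqs[b]
        dists.append(sum(1 for i in keep if sa[i] != sb[i]))
    return float(np.mean(dists)), float(np.std(dists))
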