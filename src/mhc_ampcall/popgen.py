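"""Population-genetic statistics on validated genotype tables.

Tables are long-format pandas DataFrames with columns
``individual, group, locus, allele1, allele2`` (one row per individual and
locus; homozygotes repeat the allele; missing genotypes have NaN alleles).

Implemented here: allele frequencies, observed/unbiased expected
heterozygosity with a Weir & Cockerham within-population f (Fis), an exact
U-score test for heterozygote excess with a Monte-Carlo (or, for tiny
samples, fully enumerated) Levene null, EM estimation of null-allele
frequency, EM haplotype frequencies for unphased two-locus data, a
permutation likelihood-ratio test of linkage disequilibrium, and pairwise
Weir-Cockerham FST with permutation p-values. All permutation p-values use
the (b + 1)/(m + 1) estimator and are reproducible under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "allele_frequencies",
    "heterozygosity",
    "hwe_u_test",
    "null_allele_em",
    "em_haplotype_freqs",
    "ld_lrt",
    "pairwise_fst",
    "HweResult",
    "LdResult",
    "FstResult",
    "genotype_frame",
]

TABLE_COLS = ("individual", "group", "locus", "allele1", "allele2")


def genotype_frame(table, default_group: str = "all") -> pd.DataFrame:
    """Coerce an ampsort GenotypeTable or DataFrame to the long format."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        if "group" not in df.columns:
            df["group"] = default_group
        return df
    rows = []
    for (ind, locus), call in sorted(table.calls.items()):
        if call.status != "OK":
            a1 = a2 = None
        else:
            a = sorted(call.alleles)
            a1, a2 = (a[0], a[0]) if len(a) == 1 else (a[0], a[1])
        rows.append({"individual": ind, "group": default_group, "locus": locus,
                     "allele1": a1, "allele2": a2})
    return pd.DataFrame(rows)


def _locus_slice(df: pd.DataFrame, locus: str, group: str | None = None) -> pd.DataFrame:
    sub = df[df["locus"] == locus]
    if group is not None:
        sub = sub[sub["group"] == group]
    sub = sub.dropna(subset=["allele1", "allele2"])
    return sub


def allele_frequencies(df: pd.DataFrame, locus: str, group: str | None = None) -> pd.Series:
    """Allele copy frequencies (homozygotes count twice); missing ignored."""
    sub = _locus_slice(df, locus, group)
    if sub.empty:
        raise ValueError(f"no typed individuals for locus {locus!r}"
                         + (f" in group {group!r}" if group else ""))
    copies = pd.concat([sub["allele1"], sub["allele2"]])
    freqs = copies.value_counts(normalize=True).sort_index()
    freqs.name = locus
    return freqs


def _wc_f_components(sub: pd.DataFrame) -> tuple[float, float]:
    """Weir & Cockerham (1984) single-population b and c sums over alleles."""
    n = len(sub)
    copies = pd.concat([sub["allele1"], sub["allele2"]])
    p = copies.value_counts(normalize=True)
    b_sum = c_sum = 0.0
    for a, pa in p.items():
        het = float(((sub["allele1"] == a) ^ (sub["allele2"] == a)).mean())
        b = (n / (n - 1)) * (pa * (1 - pa) - (2 * n - 1) / (4 * n) * het)
        c = het / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def heterozygosity(df: pd.DataFrame, locus: str, group: str | None = None):
    """Observed heterozygosity, unbiased expected heterozygosity
    (2n/(2n-1))(1 - sum p^2), and the Weir & Cockerham within-population f
    (Fis). Monomorphic loci return He = 0 and Fis = None."""
    sub = _locus_slice(df, locus, group)
    n = len(sub)
    if n < 2:
        raise ValueError("need at least 2 typed individuals")
    ho = float((sub["allele1"] != sub["allele2"]).mean())
    p = allele_frequencies(df, locus, group)
    he = (2 * n / (2 * n - 1)) * (1.0 - float((p**2).sum()))
    if len(p) < 2:
        return ho, 0.0, None
    b_sum, c_sum = _wc_f_components(sub)
    fis = None if (b_sum + c_sum) == 0 else 1.0 - c_sum / (b_sum + c_sum)
    return ho, he, fis


@dataclass
class HweResult:
    u: float
    p_value: float
    n_permutations: int
    ho: float
    he: float
    fis: float | None
    method: str = "monte-carlo"


def _u_score(a: np.ndarray, b: np.ndarray, inv_p: np.ndarray) -> np.ndarray:
    """Heterozygote-excess U score: minus the 1/p-weighted homozygote count
    (larger U = more heterozygous than expected given the allele counts)."""
    hom = a == b
    return -np.where(hom, inv_p[a], 0.0).sum(axis=-1)


def hwe_u_test(
    df: pd.DataFrame,
    locus: str,
    n_mc: int = 1000,
    seed: int = 0,
    group: str | None = None,
    method: str = "monte-carlo",
) -> HweResult:
    """Exact U-score test for heterozygote excess.

    The null distribution conditions on the observed allele counts (Levene):
    allele copies are re-paired at random into genotypic arrays. The one-sided
    p-value for heterozygote excess is the proportion of null arrays with
    U >= observed; the Monte-Carlo version includes the observed array
    ((b + 1)/(m + 1)). ``method='enumeration'`` enumerates all pairings of
    the 2n copies exactly (only for 2n <= 12)."""
    sub = _locus_slice(df, locus, group)
    alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
    ho, he, fis = heterozygosity(df, locus, group) if len(sub) >= 2 else (0, 0, None)
    if len(alleles) < 2:
        return HweResult(0.0, 1.0, 0, ho, he, fis, "monomorphic")
    code = {a: i for i, a in enumerate(alleles)}
    a_obs = sub["allele1"].map(code).to_numpy()
    b_obs = sub["allele2"].map(code).to_numpy()
    copies = np.concatenate([a_obs, b_obs])
    counts = np.bincount(copies, minlength=len(alleles))
    inv_p = len(copies) / counts.astype(float)  # 1 / p_a
    u_obs = float(_u_score(a_obs, b_obs, inv_p))

    if method == "enumeration":
        if len(copies) > 12:
            raise ValueError("enumeration mode only for 2n <= 12")
        ge = tot = 0
        probs = []
        for perm in _perfect_matchings(list(copies)):
            a = np.array([x for x, _ in perm])
            b = np.array([y for _, y in perm])
            u = float(_u_score(a, b, inv_p))
            tot += 1
            if u >= u_obs - 1e-9:
                ge += 1
        return HweResult(u_obs, ge / tot, tot, ho, he, fis, "enumeration")

    rng = np.random.default_rng(seed)
    m = len(sub)
    keys = rng.random((n_mc, len(copies)))
    order = np.argsort(keys, axis=1)
    shuffled = copies[order]
    a = shuffled[:, :m]
    b = shuffled[:, m:]
    u_null = _u_score(a, b, inv_p)
    b_ge = int(np.sum(u_null >= u_obs - 1e-9))
    p = (b_ge + 1) / (n_mc + 1)
    return HweResult(u_obs, p, n_mc, ho, he, fis, "monte-carlo")


def _perfect_matchings(items: list):
    """All pairings of an even-length list of labeled allele copies."""
    if not items:
        yield []
        return
    first = items[0]
    for i in range(1, len(items)):
        rest = items[1:i] + items[i + 1:]
        for sub in _perfect_matchings(rest):
            yield [(first, items[i])] + sub


def null_allele_em(
    df: pd.DataFrame,
    locus: str,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    group: str | None = None,
    n_blank: int = 0,
):
    """EM (Dempster et al.) maximum-likelihood frequency of a null allele.

    Observed homozygotes are modelled as a HWE mixture of true homozygotes
    and heterozygotes carrying one non-amplifying allele; ``n_blank``
    individuals with total amplification failure count as null homozygotes.
    Returns (estimate, converged)."""
    sub = _locus_slice(df, locus, group)
    if len(sub) < 2:
        raise ValueError("need at least 2 typed individuals")
    alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
    k = len(alleles)
    code = {a: i for i, a in enumerate(alleles)}
    a1 = sub["allele1"].map(code).to_numpy()
    a2 = sub["allele2"].map(code).to_numpy()
    hom_counts = np.bincount(a1[a1 == a2], minlength=k).astype(float)
    het_copy_counts = (np.bincount(a1[a1 != a2], minlength=k)
                       + np.bincount(a2[a1 != a2], minlength=k)).astype(float)
    n_tot = len(sub) + n_blank
    two_n = 2.0 * n_tot

    p = np.full(k, 1.0 / (k + 1))
    p0 = 1.0 / (k + 1)
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_null = np.where(hom_counts > 0, 2 * p0 / (p + 2 * p0), 0.0)
        x = hom_counts * frac_null  # expected null heterozygotes per allele
        copies = het_copy_counts + 2 * (hom_counts - x) + x
        null_copies = float(x.sum()) + 2.0 * n_blank
        new_p = copies / two_n
        new_p0 = null_copies / two_n
        delta = abs(new_p0 - p0) + float(np.abs(new_p - p).max())
        p, p0 = new_p, new_p0
        if delta < tol:
            converged = True
            break
    return float(p0), converged


# ---------------------------------------------------------------------------
# Two-locus EM haplotype frequencies and the LD likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass
class _TwoLocusData:
    """Genotype-class bookkeeping for fast batched EM."""

    hap_labels: list[tuple[str, str]]
    class_count: int
    pair_i1: np.ndarray      # haplotype index 1 per phase pair
    pair_i2: np.ndarray
    pair_mult: np.ndarray    # 1 for i1 == i2, else 2
    pair_class: np.ndarray   # genotype class per phase pair
    incidence: np.ndarray    # (n_pairs, n_haps) copy-count matrix
    class_of_pair: np.ndarray  # (n_pairs, n_class) 0/1 pair->class matrix
    gA: np.ndarray           # per-individual single-locus genotype codes
    gB: np.ndarray
    nA: int                  # number of single-locus genotype classes
    nB: int


def _prepare_two_locus(df: pd.DataFrame, locus_a: str, locus_b: str) -> tuple[_TwoLocusData, np.ndarray]:
    a = _locus_slice(df, locus_a).set_index("individual")
    b = _locus_slice(df, locus_b).set_index("individual")
    common = sorted(set(a.index) & set(b.index))  # listwise deletion
    if not common:
        raise ValueError("no individuals typed at both loci")
    a = a.loc[common]
    b = b.loc[common]
    alleles_a = sorted(set(a["allele1"]) | set(a["allele2"]))
    alleles_b = sorted(set(b["allele1"]) | set(b["allele2"]))
    ca = {x: i for i, x in enumerate(alleles_a)}
    cb = {x: i for i, x in enumerate(alleles_b)}
    ka, kb = len(alleles_a), len(alleles_b)

    def _geno_codes(frame, code, k):
        g1 = frame["allele1"].map(code).to_numpy()
        g2 = frame["allele2"].map(code).to_numpy()
        lo = np.minimum(g1, g2)
        hi = np.maximum(g1, g2)
        return lo * k + hi  # unordered genotype code

    gA = _geno_codes(a, ca, ka)
    gB = _geno_codes(b, cb, kb)

    hap_labels = [(x, y) for x in alleles_a for y in alleles_b]
    hap_index = {(i, j): i * kb + j for i in range(ka) for j in range(kb)}

    # enumerate phase pairs per joint genotype class
    pair_i1, pair_i2, pair_mult, pair_class = [], [], [], []
    n_class = (ka * ka) * (kb * kb)
    for la1 in range(ka):
        for la2 in range(la1, ka):
            for lb1 in range(kb):
                for lb2 in range(lb1, kb):
                    cls = (la1 * ka + la2) * (kb * kb) + (lb1 * kb + lb2)
                    phases = {((la1, lb1), (la2, lb2)), ((la1, lb2), (la2, lb1))}
                    for h1, h2 in phases:
                        i1, i2 = hap_index[h1], hap_index[h2]
                        if i1 > i2:
                            i1, i2 = i2, i1
                        pair_i1.append(i1)
                        pair_i2.append(i2)
                        pair_mult.append(1 if i1 == i2 else 2)
                        pair_class.append(cls)
    pair_i1 = np.array(pair_i1)
    pair_i2 = np.array(pair_i2)
    pair_mult = np.array(pair_mult, dtype=float)
    pair_class = np.array(pair_class)
    order = np.argsort(pair_class, kind="stable")
    pair_i1, pair_i2 = pair_i1[order], pair_i2[order]
    pair_mult, pair_class = pair_mult[order], pair_class[order]
    nh = ka * kb
    incidence = np.zeros((len(pair_i1), nh))
    for r, (i1, i2) in enumerate(zip(pair_i1, pair_i2)):
        incidence[r, i1] += 1
        incidence[r, i2] += 1
    class_of_pair = np.zeros((len(pair_i1), n_class))
    class_of_pair[np.arange(len(pair_i1)), pair_class] = 1.0

    data = _TwoLocusData(hap_labels, n_class, pair_i1, pair_i2, pair_mult,
                         pair_class, incidence, class_of_pair, gA, gB,
                         ka * ka, kb * kb)
    joint = gA * (kb * kb) + gB
    counts = np.bincount(joint, minlength=n_class).astype(float)
    return data, counts


def _em_haplo_batch(
    data: _TwoLocusData,
    class_counts: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    trace: list | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM over phase-ambiguous two-locus genotypes, batched over datasets.

    class_counts: (B, n_class) genotype-class count matrices sharing one
    class structure. Returns (hap_freqs (B, n_haps), logL (B,), converged).
    If ``trace`` is a list, the per-iteration logL of the first dataset is
    appended to it."""
    cc = np.atleast_2d(class_counts)
    B = cc.shape[0]
    n2 = cc.sum(axis=1, keepdims=True) * 2.0
    nh = data.incidence.shape[1]
    # initialise at the linkage-equilibrium product of the marginal allele
    # frequencies (identical for all permuted datasets of one table)
    ka = int(math.isqrt(data.nA))
    kb = int(math.isqrt(data.nB))
    pa = np.bincount(np.concatenate([data.gA // ka, data.gA % ka]),
                     minlength=ka).astype(float)
    pb = np.bincount(np.concatenate([data.gB // kb, data.gB % kb]),
                     minlength=kb).astype(float)
    pa /= pa.sum()
    pb /= pb.sum()
    h = np.tile((pa[:, None] * pb[None, :]).ravel(), (B, 1))
    # nudge off the stationary product point so EM can leave it
    h = 0.99 * h + 0.01 / nh
    pc = data.pair_class
    converged = np.zeros(B, dtype=bool)
    cnt_pairs = cc[:, pc]  # class count gathered per pair row, (B, P)

    def _class_prob(hh):
        p_pair = data.pair_mult * hh[:, data.pair_i1] * hh[:, data.pair_i2]
        return p_pair, p_pair @ data.class_of_pair

    def _logl(class_prob):
        with np.errstate(divide="ignore"):
            return np.where(
                cc > 0, cc * np.log(np.maximum(class_prob, 1e-300)), 0.0
            ).sum(axis=1)

    active = np.arange(B)
    for _ in range(max_iter):
        ha = h[active]
        p_pair, class_prob = _class_prob(ha)
        class_prob_per_pair = class_prob[:, pc]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(class_prob_per_pair > 0,
                         p_pair / class_prob_per_pair, 0.0) * cnt_pairs[active]
        new_ha = (w @ data.incidence) / n2[active]
        done = np.abs(new_ha - ha).max(axis=1) < tol
        h[active] = new_ha
        if trace is not None and active[0] == 0:
            trace.append(float(_logl(_class_prob(h[:1])[1])[0]))
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    logl = _logl(_class_prob(h)[1])
    return h, logl, converged


def em_haplotype_freqs(
    df: pd.DataFrame,
    locus_a: str,
    locus_b: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
    trace: list | None = None,
):
    """Excoffier-Slatkin EM haplotype frequencies for unphased two-locus
    genotype data. Returns (freqs dict, logL, converged); the log-likelihood
    is non-decreasing across iterations (pass ``trace=[]`` to capture it)."""
    data, counts = _prepare_two_locus(df, locus_a, locus_b)
    h, logl, conv = _em_haplo_batch(data, counts[None, :], tol, max_iter, trace)
    freqs = {lab: float(f) for lab, f in zip(data.hap_labels, h[0])}
    return freqs, float(logl[0]), bool(conv[0])


@dataclass
class LdResult:
    statistic: float
    df: int
    p_value: float
    n_permutations: int
    hap_freqs: dict
    logl_linked: float
    logl_independent: float


def _logl_independent(data: _TwoLocusData, class_counts: np.ndarray) -> np.ndarray:
    """Log-likelihood under linkage equilibrium: haplotype frequencies are
    the products of the marginal allele frequencies (invariant to the
    permutations used for the null distribution)."""
    cc = np.atleast_2d(class_counts)
    ka = int(math.isqrt(data.nA))
    kb = int(math.isqrt(data.nB))
    # marginal allele counts from genotype codes (same for all permutations)
    gA, gB = data.gA, data.gB
    pa = np.bincount(np.concatenate([gA // ka, gA % ka]), minlength=ka).astype(float)
    pb = np.bincount(np.concatenate([gB // kb, gB % kb]), minlength=kb).astype(float)
    pa /= pa.sum()
    pb /= pb.sum()
    h0 = (pa[:, None] * pb[None, :]).ravel()
    p_pair = data.pair_mult * h0[data.pair_i1] * h0[data.pair_i2]
    starts = np.searchsorted(data.pair_class, np.arange(data.class_count))
    class_prob = np.add.reduceat(p_pair, starts)
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(class_prob, 1e-300))
    return (cc * lp[None, :]).sum(axis=1)


def ld_lrt(
    df: pd.DataFrame,
    locus_a: str,
    locus_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> LdResult:
    """Likelihood-ratio test of linkage disequilibrium for unphased data.

    statistic = 2(logL_EM - logL_independent); the null distribution is built
    by permuting one locus's genotypes among individuals ``n_perm`` times,
    re-fitting the EM each time (batched). p = (b + 1)/(m + 1). df is
    reported as (kA - 1)(kB - 1); note that df bookkeeping for unphased EM
    LRTs differs across implementations."""
    data, counts = _prepare_two_locus(df, locus_a, locus_b)
    ka = int(math.isqrt(data.nA))
    kb = int(math.isqrt(data.nB))
    if ka < 2 or kb < 2:
        raise ValueError("need >= 2 alleles at each locus")
    h, logl1, _ = _em_haplo_batch(data, counts[None, :], tol, max_iter)
    logl0 = _logl_independent(data, counts[None, :])
    stat = max(0.0, 2.0 * float(logl1[0] - logl0[0]))

    rng = np.random.default_rng(seed)
    n = len(data.gA)
    keys = rng.random((n_perm, n))
    order = np.argsort(keys, axis=1)
    gB_perm = data.gB[order]
    joint = data.gA[None, :] * data.nB + gB_perm
    flat = joint + (np.arange(n_perm)[:, None] * data.class_count)
    cc = np.bincount(flat.ravel(), minlength=n_perm * data.class_count)
    cc = cc.reshape(n_perm, data.class_count).astype(float)
    _, logl1_p, _ = _em_haplo_batch(data, cc, tol, max_iter)
    logl0_p = _logl_independent(data, cc)
    stats_null = np.maximum(0.0, 2.0 * (logl1_p - logl0_p))
    b = int(np.sum(stats_null >= stat - 1e-9))
    p = (b + 1) / (n_perm + 1)
    freqs = {lab: float(f) for lab, f in zip(data.hap_labels, h[0])}
    return LdResult(stat, (ka - 1) * (kb - 1), p, n_perm, freqs,
                    float(logl1[0]), float(logl0[0]))


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    groups: list[str]
    theta: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    excluded: list[tuple[str, str]] = field(default_factory=list)


def _wc_theta(a1: np.ndarray, a2: np.ndarray, pop: np.ndarray, k: int) -> float:
    """Weir & Cockerham (1984) theta for r populations, summed over alleles."""
    r = pop.max() + 1
    n_i = np.bincount(pop, minlength=r).astype(float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    a_sum = d_sum = 0.0
    for al in range(k):
        x1 = (a1 == al).astype(float)
        x2 = (a2 == al).astype(float)
        cnt = np.bincount(pop, weights=x1 + x2, minlength=r)
        p_i = cnt / (2 * n_i)
        het = np.bincount(pop, weights=(x1 != x2).astype(float), minlength=r) / n_i
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * het).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        d_sum += a + b + c
    return float(a_sum / d_sum) if d_sum != 0 else 0.0


def pairwise_fst(
    df: pd.DataFrame,
    locus: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> FstResult:
    """Pairwise Weir-Cockerham theta between subpopulations with permutation
    p-values (p = fraction of group-label permutations with theta_perm >=
    theta_obs, (b + 1)/(m + 1)). Groups with fewer than 2 typed individuals
    are excluded and flagged."""
    sub = _locus_slice(df, locus)
    groups = sorted(sub["group"].unique())
    sizes = sub.groupby("group").size()
    ok_groups = [g for g in groups if sizes.get(g, 0) >= 2]
    excluded_pairs = [(g1, g2) for g1, g2 in itertools.combinations(groups, 2)
                      if g1 not in ok_groups or g2 not in ok_groups]
    theta = pd.DataFrame(0.0, index=groups, columns=groups)
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups)
    alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
    code = {a: i for i, a in enumerate(alleles)}
    rng = np.random.default_rng(seed)
    for g1, g2 in itertools.combinations(ok_groups, 2):
        pair = sub[sub["group"].isin([g1, g2])]
        a1 = pair["allele1"].map(code).to_numpy()
        a2 = pair["allele2"].map(code).to_numpy()
        pop = (pair["group"] == g2).to_numpy().astype(int)
        th = _wc_theta(a1, a2, pop, len(alleles))
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(pop)
            if _wc_theta(a1, a2, perm, len(alleles)) >= th - 1e-12:
                b += 1
        p = (b + 1) / (n_perm + 1)
        theta.loc[g1, g2] = theta.loc[g2, g1] = th
        pvals.loc[g1, g2] = pvals.loc[g2, g1] = p
    return FstResult(groups, theta, pvals, n_perm, excluded_pairs)
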