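"""Rarefaction of allelic richness versus sampling effort.

The curve answers "how many distinct alleles would we have seen had we
sampled n individuals?": for each replicate a random permutation of the
typed individuals is drawn and prefixes of increasing size are scored, so
within a replicate the count is monotone in effort and the full-sample point
has zero spread. The mean at effort n equals, in expectation, the
hypergeometric value sum_a (1 - C(N - k_a, n)/C(N, n)) with k_a carriers of
allele a among the N typed individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RarefactionCurve", "rarefaction_curve", "allele_counts_by_group",
           "hypergeometric_expected_richness"]


@dataclass
class RarefactionCurve:
    locus: str
    efforts: list[int]
    mean: list[float]
    sd: list[float]
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"effort": self.efforts, "mean": self.mean,
                             "sd": self.sd})

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        m = np.array(self.mean)
        s = np.array(self.sd)
        ax.plot(self.efforts, m, **kwargs)
        ax.plot(self.efforts, m + s, ls=":", color=kwargs.get("color"))
        ax.plot(self.efforts, m - s, ls=":", color=kwargs.get("color"))
        ax.set_xlabel("individuals sampled")
        ax.set_ylabel("distinct alleles")
        return ax


def rarefaction_curve(
    df: pd.DataFrame,
    locus: str,
    step: int = 10,
    n_reps: int = 100,
    seed: int = 0,
    max_effort: int | None = None,
) -> RarefactionCurve:
    """Permutation rarefaction: draw individuals without replacement and
    count distinct alleles at efforts step, 2*step, ..., N. Individuals
    missing the locus genotype are excluded before drawing; an effort grid
    beyond N is truncated with a warning."""
    if step < 1:
        raise ValueError("step must be >= 1")
    sub = df[(df["locus"] == locus)].dropna(subset=["allele1", "allele2"])
    if sub.empty:
        raise ValueError(f"no typed individuals at locus {locus!r}")
    n = len(sub)
    top = max_effort if max_effort is not None else n
    if top > n:
        warnings.warn(f"effort {top} exceeds the {n} typed individuals; truncated")
        top = n
    efforts = sorted(set(list(range(step, top + 1, step)) + [top]))
    a1 = pd.factorize(pd.concat([sub["allele1"], sub["allele2"]]))[0]
    g1, g2 = a1[:n], a1[n:]
    n_alleles = int(a1.max()) + 1
    rng = np.random.default_rng(seed)
    counts = np.empty((n_reps, len(efforts)))
    for r in range(n_reps):
        order = rng.permutation(n)
        seen = np.zeros(n_alleles, dtype=bool)
        k = 0
        e_i = 0
        for pos, ind in enumerate(order, start=1):
            for al in (g1[ind], g2[ind]):
                if not seen[al]:
                    seen[al] = True
                    k += 1
            while e_i < len(efforts) and efforts[e_i] == pos:
                counts[r, e_i] = k
                e_i += 1
    return RarefactionCurve(
        locus=locus,
        efforts=efforts,
        mean=[float(x) for x in counts.mean(axis=0)],
        sd=[float(x) for x in counts.std(axis=0)],
        n_replicates=n_reps,
        seed=seed,
    )


def hypergeometric_expected_richness(df: pd.DataFrame, locus: str, effort: int) -> float:
    """Closed-form expected distinct-allele count at the given effort:
    sum over alleles of 1 - C(N - k_a, n)/C(N, n)."""
    from math import comb

    sub = df[(df["locus"] == locus)].dropna(subset=["allele1", "allele2"])
    n_ind = len(sub)
    if not 1 <= effort <= n_ind:
        raise ValueError("effort out of range")
    total = 0.0
    alleles = set(sub["allele1"]) | set(sub["allele2"])
    for a in alleles:
        k = int(((sub["allele1"] == a) | (sub["allele2"] == a)).sum())
        total += 1.0 - comb(n_ind - k, effort) / comb(n_ind, effort)
    return total


def allele_counts_by_group(df: pd.DataFrame, locus: str, grouping: str = "group") -> pd.DataFrame:
    """Allele x group copy-count matrix; column sums equal twice the number
    of typed individuals per group."""
    if grouping not in df.columns:
        raise KeyError(f"unknown grouping column {grouping!r}")
    sub = df[df["locus"] == locus].dropna(subset=["allele1", "allele2"])
    long = pd.concat([
        sub[[grouping, "allele1"]].rename(columns={"allele1": "allele"}),
        sub[[grouping, "allele2"]].rename(columns={"allele2": "allele"}),
    ])
    return pd.crosstab(long["allele"], long[grouping])
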