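import numpy as np
import pandas as pd
import pytest

from mhc_ampcall import simdata


def make_cohort(n_individuals=100, n_loci=2, seed=42, n_replicates=1, **rates):
    """Two-locus synthetic cohort at default artifact rates."""
    truth = None
    for i in range(n_loci):
        pool = simdata.generate_allele_pool(
            f"L{i + 1}", 17 if i == 0 else 22, 162,
            0.0 if i == 0 else 7 / 22, seed=seed + i)
        freqs = np.random.default_rng(seed + 100 + i).dirichlet(
            np.ones(len(pool)) * 3)
        t = simdata.generate_population(pool, n_individuals, freqs,
                                        seed=seed + 200 + i)
        truth = t if truth is None else truth.merge(t)
    cfg = simdata.SimConfig(n_individuals=n_individuals, seed=seed + 300,
                            n_replicates=n_replicates, **rates)
    readsets = simdata.generate_amplicons(truth, cfg)
    return truth, readsets


@pytest.fixture(scope="session")
def default_cohort():
    """100 individuals, 2 loci, depth ~200, default artifact rates."""
    return make_cohort()


@pytest.fixture(scope="session")
def noiseless_cohort():
    return make_cohort(
        n_individuals=60, seed=7, err_point=0.0, err_homopolymer=0.0,
        chimera_rate=0.0, contamination_rate=0.0)


def geno_df(pairs, locus="L", group="all", start=0):
    """Long-format genotype frame from a list of (a1, a2) pairs."""
    rows = []
    for i, (a1, a2) in enumerate(pairs, start=start):
        a1, a2 = sorted((a1, a2))
        rows.append({"individual": f"i{i}", "group": group, "locus": locus,
                     "allele1": a1, "allele2": a2})
    return pd.DataFrame(rows)


def hwe_df(freqs, n, seed, locus="L", group="all", labels=None, start=0):
    """Random-mating genotype table at the given allele frequencies."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, float)
    labels = labels or [f"a{k}" for k in range(len(freqs))]
    draws = rng.choice(len(freqs), size=(n, 2), p=freqs / freqs.sum())
    return geno_df([(labels[a], labels[b]) for a, b in draws],
                   locus=locus, group=group, start=start)
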