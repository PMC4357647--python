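"""Validation cascade: MPAF/RPAF arithmetic, chimera detection against a
brute-force oracle, the classification cascade on constructed amplicons and
on simulated cohorts scored against the truth ledger, depth sufficiency and
replicate resolution."""

import math

import numpy as np
import pytest

from mhc_ampcall import ampsort, simdata
from mhc_ampcall.ampsort import (
    ARTIFACT_CHIMERA, ARTIFACT_POINT, CONTAMINANT_SUSPECT, TRUE_ALLELE,
    AmpliconReadSet, SortConfig,
)

from conftest import make_cohort


def rs(amp, counts, ind=None, locus="L", rep=1):
    return AmpliconReadSet(
        amplicon_id=amp, individual_id=ind or amp.split("|")[0],
        locus_id=locus, run_id=f"run{rep}", replicate_index=rep,
        counts=counts)


_RNG = np.random.default_rng(12345)


def rand_seq(n=162):
    return "".join("ACGT"[i] for i in _RNG.integers(0, 4, n))


class TestRpafMpaf:
    def test_rpaf_arithmetic(self):
        got = ampsort.compute_rpaf(rs("a|L|r1", {"A": 40, "B": 40, "C": 20}))
        assert got == {"A": 0.4, "B": 0.4, "C": 0.2}

    def test_single_variant_rpaf_one(self):
        assert ampsort.compute_rpaf(rs("a|L|r1", {"X": 18})) == {"X": 1.0}

    def test_rpaf_sums_to_one(self, default_cohort):
        _, readsets = default_cohort
        for readset in readsets[:50]:
            assert sum(ampsort.compute_rpaf(readset).values()) == \
                pytest.approx(1.0, abs=1e-12)

    def test_mpaf_is_unweighted_mean_of_rpafs(self):
        sets = [rs("a1|L|r1", {"V": 40, "W": 60}),
                rs("a2|L|r1", {"V": 20, "W": 80})]
        rec = {r.variant_id: r for r in ampsort.compute_variant_stats(sets)}
        assert rec["V"].mpaf == pytest.approx(0.3)
        assert rec["V"].n_amplicons == 2

    def test_mpaf_single_amplicon_equals_rpaf(self):
        sets = [rs("a1|L|r1", {"V": 69, "W": 31})]
        rec = {r.variant_id: r for r in ampsort.compute_variant_stats(sets)}
        assert rec["V"].mpaf == pytest.approx(0.69)

    def test_amplicon_order_invariance(self):
        sets = [rs("a1|L|r1", {"V": 40, "W": 60}),
                rs("a2|L|r1", {"V": 20, "X": 80})]
        fwd = ampsort.compute_variant_stats(sets)
        rev = ampsort.compute_variant_stats(sets[::-1])
        assert fwd == rev

    def test_mixed_loci_rejected(self):
        with pytest.raises(ValueError, match="mixed loci"):
            ampsort.compute_variant_stats(
                [rs("a|L|r1", {"A": 1}), rs("b|M|r1", {"A": 1}, locus="M")])

    def test_mpaf_consistent_with_stored_rpafs(self, default_cohort):
        _, readsets = default_cohort
        one_locus = [r for r in readsets if r.locus_id == "L1"]
        for rec in ampsort.compute_variant_stats(one_locus):
            assert rec.mpaf == pytest.approx(
                np.mean(list(rec.rpaf_by_amplicon.values())), abs=1e-15)


class TestRankProfile:
    def test_single_locus_no_noise_rank3_zero(self, noiseless_cohort):
        _, readsets = noiseless_cohort
        one = [r for r in readsets if r.locus_id == "L1"]
        prof = ampsort.rank_frequency_profile(one)
        assert prof.mean_rpaf[2] == 0.0
        assert math.isinf(prof.drop_ratio)
        assert prof.verdict == "single locus"

    def test_duplicated_locus_is_ambiguous(self):
        rng = np.random.default_rng(0)
        sets = []
        for i in range(40):  # two merged loci: 4 alleles per amplicon
            picks = rng.choice(12, size=4, replace=False)
            counts = {f"v{p:02d}": int(rng.integers(40, 60)) for p in picks}
            sets.append(rs(f"a{i}|L|r1", counts))
        prof = ampsort.rank_frequency_profile(sets)
        assert prof.drop_ratio < 3.0
        assert prof.verdict == "ambiguous"

    def test_ties_broken_lexically_deterministic(self):
        sets = [rs("a|L|r1", {"B": 50, "A": 50, "C": 50})]
        p1 = ampsort.rank_frequency_profile(sets)
        p2 = ampsort.rank_frequency_profile(list(sets))
        assert p1 == p2
        assert p1.mean_rpaf[:3] == [pytest.approx(1 / 3)] * 3


def chimera_oracle(cand, pa, pb):
    """Exhaustive breakpoint scan."""
    if cand in (pa, pb) or len({len(cand), len(pa), len(pb)}) != 1:
        return None
    hits = [i for i in range(1, len(pa))
            if cand == pa[:i] + pb[i:] or cand == pb[:i] + pa[i:]]
    return min(hits) if hits else None


class TestDetectChimera:
    def test_simple_breakpoint(self):
        assert ampsort.detect_chimera("AAATTT", "AAAAAA", "TTTTTT") == 3

    def test_candidate_equal_to_parent_is_none(self):
        assert ampsort.detect_chimera("AAAAAA", "AAAAAA", "TTTTTT") is None

    def test_matches_exhaustive_oracle_on_random_trials(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            pa, pb = rand_seq(60), rand_seq(60)
            i = int(rng.integers(1, 60))
            cand = pa[:i] + pb[i:] if rng.random() < 0.5 else pb[:i] + pa[i:]
            assert ampsort.detect_chimera(cand, pa, pb) == \
                chimera_oracle(cand, pa, pb)

    def test_false_positive_rate_near_zero_on_random_162mers(self):
        fp = 0
        for _ in range(2000):
            pa, pb, cand = rand_seq(), rand_seq(), rand_seq()
            got = ampsort.detect_chimera(cand, pa, pb)
            assert got == chimera_oracle(cand, pa, pb)
            fp += got is not None
        assert fp == 0

    def test_length_mismatch_returns_none(self):
        assert ampsort.detect_chimera("AAAT", "AAAAA", "TTTTT") is None


def _mini_cohort():
    """Three amplicons over five clearly distinct sequences plus one
    1-substitution derivative of P1."""
    p1, p2, c, d, e = (rand_seq() for _ in range(5))
    x = "G" + p1[1:] if p1[0] != "G" else "T" + p1[1:]
    seqs = {"P1": p1, "P2": p2, "C": c, "D": d, "E": e, "X": x}
    sets = [
        rs("amp1|L|r1", {"P1": 90, "P2": 85, "X": 5, "C": 6}),
        rs("amp2|L|r1", {"C": 100, "D": 90}),
        rs("amp3|L|r1", {"C": 80, "E": 80}),
    ]
    stats = {r.variant_id: r for r in ampsort.compute_variant_stats(sets)}
    return seqs, sets, stats


class TestClassify:
    def test_point_artifact_attributed_to_parent(self):
        seqs, sets, stats = _mini_cohort()
        cls = ampsort.classify_variants(sets[0], stats, seqs)
        assert cls.labels["P1"] == TRUE_ALLELE
        assert cls.labels["P2"] == TRUE_ALLELE
        assert cls.labels["X"] == ARTIFACT_POINT
        assert cls.parents["X"] == ("P1",)

    def test_high_mpaf_low_rpaf_flags_contaminant(self):
        seqs, sets, stats = _mini_cohort()
        cls = ampsort.classify_variants(sets[0], stats, seqs)
        # C: RPAF 6/186 = 0.03 here, but dominant in amp2 and amp3
        assert cls.labels["C"] == CONTAMINANT_SUSPECT

    def test_chimera_of_the_two_parentals(self):
        seqs, sets, stats = _mini_cohort()
        chim = seqs["P1"][:80] + seqs["P2"][80:]
        seqs2 = dict(seqs, CH=chim)
        sets2 = sets[:1] + [rs("amp1b|L|r1",
                               {"P1": 90, "P2": 85, "CH": 4})] + sets[1:]
        stats2 = {r.variant_id: r for r in ampsort.compute_variant_stats(sets2)}
        cls = ampsort.classify_variants(sets2[1], stats2, seqs2)
        assert cls.labels["CH"] == ARTIFACT_CHIMERA
        assert cls.breakpoints["CH"] <= 80

    def test_every_variant_gets_exactly_one_label(self, default_cohort):
        truth, readsets = default_cohort
        one = [r for r in readsets if r.locus_id == "L1"]
        seqs = truth.sequences["L1"]
        stats = {r.variant_id: r
                 for r in ampsort.compute_variant_stats(one, seqs)}
        for readset in one[:30]:
            cls = ampsort.classify_variants(readset, stats, seqs)
            assert set(cls.labels) == set(readset.counts)

    def test_cohort_recall_against_truth_ledger(self, default_cohort):
        truth, readsets = default_cohort
        ledger = {(e.amplicon_id, e.variant_id): e.label
                  for e in truth.ledger}
        n_true = n_true_ok = n_art = n_art_ok = 0
        for locus in truth.loci:
            one = [r for r in readsets if r.locus_id == locus]
            seqs = truth.sequences[locus]
            stats = {r.variant_id: r
                     for r in ampsort.compute_variant_stats(one, seqs)}
            for readset in one:
                cls = ampsort.classify_variants(readset, stats, seqs)
                for v, lab in cls.labels.items():
                    truth_lab = ledger[(readset.amplicon_id, v)]
                    if truth_lab == "true":
                        n_true += 1
                        n_true_ok += lab == TRUE_ALLELE
                    elif truth_lab in ("point", "homopolymer", "chimera"):
                        n_art += 1
                        n_art_ok += lab.startswith("ARTIFACT_")
        assert n_true_ok / n_true >= 0.95
        assert n_art_ok / n_art >= 0.95

    def test_missing_global_stats_raise(self):
        seqs, sets, stats = _mini_cohort()
        del stats["X"]
        with pytest.raises(ValueError, match="missing global stats"):
            ampsort.classify_variants(sets[0], stats, seqs)


def _cls(amp, labels):
    return ampsort.Classification(amp, dict(labels))


class TestReplicates:
    def test_suspect_absent_in_replicate_dropped(self):
        c1 = _cls("a|L|r1", {"A": TRUE_ALLELE, "B": TRUE_ALLELE,
                             "C": CONTAMINANT_SUSPECT})
        c2 = _cls("a|L|r2", {"A": TRUE_ALLELE, "B": TRUE_ALLELE})
        call = ampsort.resolve_with_replicates([c1, c2], "a", "L")
        assert call.alleles == ("A", "B")
        assert call.status == "OK"

    def test_identical_replicates_reproduce_the_call(self):
        c = _cls("a|L|r1", {"A": TRUE_ALLELE, "B": TRUE_ALLELE})
        call = ampsort.resolve_with_replicates([c, c], "a", "L")
        assert call.alleles == ("A", "B") and call.status == "OK"

    def test_persistent_extra_alleles_excluded(self):
        c = _cls("a|L|r1", {"A": TRUE_ALLELE, "B": TRUE_ALLELE,
                            "C": TRUE_ALLELE})
        call = ampsort.resolve_with_replicates([c, c], "a", "L")
        assert call.status == "EXCLUDED"

    def test_disagreeing_replicates_unresolved(self):
        c1 = _cls("a|L|r1", {"A": TRUE_ALLELE, "B": TRUE_ALLELE})
        c2 = _cls("a|L|r2", {"C": TRUE_ALLELE, "D": TRUE_ALLELE})
        call = ampsort.resolve_with_replicates([c1, c2], "a", "L")
        assert call.status == "UNRESOLVED"

    def test_noiseless_replicates_fully_concordant(self):
        truth, readsets = make_cohort(
            n_individuals=30, n_loci=1, seed=31, n_replicates=2,
            err_point=0.0, err_homopolymer=0.0, chimera_rate=0.0,
            contamination_rate=0.0)
        gt, _ = ampsort.call_genotypes(readsets, truth.sequences)
        matches = [set(gt.calls[k].alleles) == set(v)
                   for k, v in truth.genotypes.items()]
        assert all(matches)
        assert all(c.status == "OK" for c in gt.calls.values())


class TestMinReads:
    def test_single_allele_single_copy(self):
        assert ampsort.min_reads_for_confidence(1, 1, 0.95, 0.0) == 1

    def test_two_alleles_five_copies_binomial_tail(self):
        # smallest T with P(5 <= X <= T-5) >= 0.95, X ~ Bin(T, 1/2)
        assert ampsort.min_reads_for_confidence(2, 5, 0.95, 0.0) == 17

    def test_monotone_in_confidence(self):
        lo = ampsort.min_reads_for_confidence(2, 5, 0.95, 0.0)
        hi = ampsort.min_reads_for_confidence(2, 5, 0.99, 0.0)
        assert hi >= lo

    def test_artifact_mass_increases_requirement(self):
        base = ampsort.min_reads_for_confidence(2, 5, 0.95, 0.0)
        noisy = ampsort.min_reads_for_confidence(2, 5, 0.95, 0.2)
        assert noisy > base


class TestCallGenotypes:
    def test_depth_17_below_threshold_is_low_depth(self):
        seqs = {"L": {"A": rand_seq(), "B": rand_seq()}}
        sets = [rs("i1|L|r1", {"A": 17}, ind="i1"),
                rs("i2|L|r1", {"A": 100, "B": 90}, ind="i2")]
        gt, report = ampsort.call_genotypes(sets, seqs)
        assert gt.calls[("i1", "L")].status == "LOW_DEPTH"
        assert report["low_depth_amplicons"] == 1

    def test_low_depth_amplicon_rescued_by_adequate_replicate(self):
        seqs = {"L": {"A": rand_seq(), "B": rand_seq()}}
        sets = [rs("i1|L|r1", {"A": 10}, ind="i1"),
                rs("i1|L|r2", {"A": 60, "B": 55}, ind="i1", rep=2),
                rs("i2|L|r1", {"A": 100, "B": 90}, ind="i2")]
        gt, _ = ampsort.call_genotypes(sets, seqs)
        assert gt.calls[("i1", "L")].status == "OK"
        assert gt.calls[("i1", "L")].alleles == ("A", "B")

    def test_noiseless_cohort_reproduces_truth_exactly(self, noiseless_cohort):
        truth, readsets = noiseless_cohort
        gt, _ = ampsort.call_genotypes(readsets, truth.sequences)
        for k, g in truth.genotypes.items():
            assert set(gt.calls[k].alleles) == set(g)

    def test_default_rates_recovery_at_least_95pct(self, default_cohort):
        truth, readsets = default_cohort
        gt, _ = ampsort.call_genotypes(readsets, truth.sequences)
        ok = [set(gt.calls[k].alleles) == set(g)
              for k, g in truth.genotypes.items()]
        assert np.mean(ok) >= 0.95


class TestDiagnostics:
    def test_correlation_positive_before_and_reduced_after(self, default_cohort):
        truth, readsets = default_cohort
        one = [r for r in readsets if r.locus_id == "L1"]
        seqs = truth.sequences["L1"]
        before = ampsort.compute_variant_stats(one, seqs)
        true_ids = {e.variant_id for e in truth.ledger if e.label == "true"}
        after = [r for r in before if r.variant_id in true_ids]
        diag = ampsort.sorting_diagnostics(before, after)
        assert diag.before.r > 0 and diag.before.p < 0.05
        assert diag.after.r < diag.before.r

    def test_constant_mpaf_flagged_undefined(self):
        recs = [ampsort.VariantRecord(f"v{i}", None, 0.5, i + 1, {})
                for i in range(5)]
        for r in recs:
            r.mpaf = 0.5
        diag = ampsort.sorting_diagnostics(recs, recs)
        assert diag.before.r is None and diag.before.flag == "zero variance"

    def test_runs_fast_at_study_scale(self, default_cohort):
        import time

        truth, readsets = default_cohort
        one = [r for r in readsets if r.locus_id == "L1"]
        recs = ampsort.compute_variant_stats(one)
        t0 = time.time()
        ampsort.sorting_diagnostics(recs, recs)
        assert time.time() - t0 < 1.0


class TestSortingSummary:
    def test_arithmetic_identity(self):
        s = ampsort.sorting_summary(321, 286, 13, 5)
        assert s["retained"] == 17
        assert s["eliminated"] == 304
        assert s["pct_eliminated"] == 95

    def test_overdrawn_tallies_rejected(self):
        with pytest.raises(ValueError):
            ampsort.sorting_summary(10, 8, 2, 1)
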