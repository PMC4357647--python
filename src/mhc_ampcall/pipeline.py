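"""End-to-end driver: simulate -> stats -> classify -> genotype -> downstream.

Every stage reads and writes plain-text artifacts under ``config.out_dir``,
stamped with the config hash and seed, and logs per-stage tallies
(variants retained/eliminated, call statuses) at INFO level. The whole run
is deterministic under a fixed global seed; per-stage seeds are derived from
it by fixed offsets.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ampsort, phylo, popgen, richness, selection, simdata
from .io import PipelineConfig, readsets_to_frame, write_fasta, write_table

log = logging.getLogger("mhc_ampcall")

__all__ = ["run_pipeline"]

_STAGE_ORDER = ["simulate", "stats", "classify", "genotype", "popgen",
                "selection", "tree", "rarefy"]


def _aligned_pool_sequences(pool: simdata.AllelePool) -> dict[str, str]:
    """Pool sequences as one codon alignment: non-carriers of the two-codon
    insertion get a 6-base gap at the insertion point (after codon 8)."""
    if not pool.insertion_carriers:
        return dict(pool.alleles)
    out = {}
    for aid, s in pool.alleles:
        out[aid] = s if aid in pool.insertion_carriers else s[:24] + "------" + s[24:]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns artifact paths.

    Raises on the first stage failure (no partial-result masking)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config.stamp()
    stages = [s for s in _STAGE_ORDER if s in config.stages]
    artifacts: dict[str, str] = {}
    rng = np.random.default_rng(config.seed)

    # --- simulate ---------------------------------------------------------
    pools: dict[str, simdata.AllelePool] = {}
    truth: simdata.TruthSet | None = None
    backbones: dict[int, str] = {}  # per length: loci are paralogues
    for i, (locus, locus_cfg) in enumerate(sorted(config.loci.items())):
        length = locus_cfg.get("length", 162)
        if length not in backbones:
            backbones[length] = simdata._random_inframe_sequence(
                np.random.default_rng(config.seed + 900), length // 3)
        pool = simdata.generate_allele_pool(
            locus, locus_cfg["n_alleles"], length,
            locus_cfg.get("insertion_fraction", 0.0), seed=config.seed + 1000 + i,
            backbone=backbones[length])
        freqs = rng.dirichlet(np.ones(len(pool)))
        t = simdata.generate_population(
            pool, config.n_individuals, freqs, seed=config.seed + 2000 + i)
        pools[locus] = pool
        truth = t if truth is None else truth.merge(t)
    readsets = simdata.generate_amplicons(truth, config.sim_config())
    log.info("simulated %d amplicons over %d loci", len(readsets), len(pools))

    if "simulate" in stages:
        write_table(readsets_to_frame(readsets), out / "amplicons.tsv", stamp)
        all_seqs = {vid: s for locus in truth.sequences
                    for vid, s in truth.sequences[locus].items()}
        write_fasta(all_seqs, out / "variants.fasta")
        ledger = pd.DataFrame([{
            "amplicon_id": e.amplicon_id, "variant_id": e.variant_id,
            "label": e.label, "parents": ",".join(e.parents),
            "breakpoint": e.breakpoint} for e in truth.ledger])
        write_table(ledger, out / "truth_ledger.tsv", stamp)
        truth_rows = [{"individual": i_, "locus": l_, "allele1": g[0],
                       "allele2": g[1]}
                      for (i_, l_), g in sorted(truth.genotypes.items())]
        write_table(pd.DataFrame(truth_rows), out / "truth_genotypes.tsv", stamp)
        artifacts["amplicons"] = str(out / "amplicons.tsv")

    by_locus: dict[str, list] = {}
    for rs in readsets:
        by_locus.setdefault(rs.locus_id, []).append(rs)

    # --- stats ------------------------------------------------------------
    if "stats" in stages:
        rows = []
        for locus in sorted(by_locus):
            recs = ampsort.compute_variant_stats(
                by_locus[locus], truth.sequences[locus])
            rows += [{"locus": locus, "variant_id": r.variant_id,
                      "sequence": r.sequence, "mpaf": r.mpaf,
                      "n_amplicons": r.n_amplicons} for r in recs]
            prof = ampsort.rank_frequency_profile(by_locus[locus])
            log.info("%s: %d variants; rank-profile drop %.2f -> %s",
                     locus, len(recs), prof.drop_ratio, prof.verdict)
        write_table(pd.DataFrame(rows), out / "variant_stats.tsv", stamp)
        artifacts["variant_stats"] = str(out / "variant_stats.tsv")

    # --- classify / genotype ---------------------------------------------
    table = None
    if any(s in stages for s in ("classify", "genotype", "popgen", "rarefy")):
        gt, report = ampsort.call_genotypes(
            readsets, truth.sequences, config.sort_config())
        if "classify" in stages:
            rows = []
            for locus in sorted(by_locus):
                seqs = truth.sequences[locus]
                stats_ = {r.variant_id: r for r in
                          ampsort.compute_variant_stats(by_locus[locus], seqs)}
                for rs in by_locus[locus]:
                    cls = ampsort.classify_variants(
                        rs, stats_, seqs, config.sort_config())
                    for vid, lab in sorted(cls.labels.items()):
                        rows.append({
                            "amplicon_id": rs.amplicon_id, "variant_id": vid,
                            "label": lab,
                            "parents": ",".join(cls.parents.get(vid, ())),
                            "breakpoint": cls.breakpoints.get(vid)})
            write_table(pd.DataFrame(rows), out / "classification.tsv", stamp)
            artifacts["classification"] = str(out / "classification.tsv")
        if "genotype" in stages:
            write_table(gt.to_frame(), out / "genotypes.tsv", stamp)
            (out / "qc_report.json").write_text(json.dumps(report, indent=2))
            log.info("genotype statuses: %s", report["by_status"])
            artifacts["genotypes"] = str(out / "genotypes.tsv")
        table = popgen.genotype_frame(gt)

    # --- popgen -----------------------------------------------------------
    if "popgen" in stages:
        rows = []
        loci = sorted(pools)
        for locus in loci:
            ho, he, fis = popgen.heterozygosity(table, locus)
            hwe = popgen.hwe_u_test(table, locus, n_mc=config.n_perm,
                                    seed=config.seed + 3000)
            null, _ = popgen.null_allele_em(table, locus)
            rows.append({"locus": locus, "Ho": ho, "He": he, "Fis": fis,
                         "hwe_u": hwe.u, "hwe_p": hwe.p_value,
                         "null_freq": null})
        write_table(pd.DataFrame(rows), out / "popgen_per_locus.tsv", stamp)
        if len(loci) >= 2:
            ld = popgen.ld_lrt(table, loci[0], loci[1], n_perm=config.n_perm,
                               seed=config.seed + 3100)
            (out / "ld_test.json").write_text(json.dumps({
                "statistic": ld.statistic, "df": ld.df, "p": ld.p_value,
                "n_permutations": ld.n_permutations}, indent=2))
        artifacts["popgen"] = str(out / "popgen_per_locus.tsv")

    # --- selection --------------------------------------------------------
    if "selection" in stages:
        rows = []
        for locus in sorted(pools):
            aligned = _aligned_pool_sequences(pools[locus])
            aln = selection.CodonAlignment(aligned)
            n_abs = min(11, aln.n_codons - 2)
            abs_sites = frozenset(
                int(x) + 1 for x in
                np.random.default_rng(config.seed + 4000).choice(
                    aln.n_codons, size=n_abs, replace=False))
            mask = selection.SiteMask(aln.n_codons, {"ABS": abs_sites})
            for part in ("ABS", "non-ABS", "all"):
                r = selection.partition_dnds(
                    aln, mask, part, n_boot=config.n_boot,
                    seed=config.seed + 4100)
                rows.append({"locus": locus, "partition": part,
                             "n_codons": r.n_codons, "dN": r.dn, "dS": r.ds,
                             "SE_dN": r.se_dn, "SE_dS": r.se_ds, "Z": r.z,
                             "P": r.p_value})
        write_table(pd.DataFrame(rows), out / "selection.tsv", stamp)
        artifacts["selection"] = str(out / "selection.tsv")

    # --- tree -------------------------------------------------------------
    if "tree" in stages:
        aa = {}
        for locus in sorted(pools):
            aln = selection.CodonAlignment(_aligned_pool_sequences(pools[locus]))
            for sid, s in aln.translated().items():
                aa[sid] = s
        # pad loci alignments to a common length with terminal gaps
        width = max(len(s) for s in aa.values())
        aa = {k: v + "-" * (width - len(v)) for k, v in aa.items()}
        tree = phylo.bootstrap_support(aa, n_reps=min(config.n_boot, 1000),
                                       seed=config.seed + 5000,
                                       gap_policy="pairwise")
        (out / "alleles.nwk").write_text(phylo.write_newick(tree, 50.0))
        artifacts["tree"] = str(out / "alleles.nwk")

    # --- rarefy -----------------------------------------------------------
    if "rarefy" in stages:
        frames = []
        for locus in sorted(pools):
            curve = richness.rarefaction_curve(
                table, locus, step=config.rarefaction_step,
                n_reps=config.rarefaction_reps, seed=config.seed + 6000)
            f = curve.to_frame()
            f.insert(0, "locus", locus)
            frames.append(f)
        write_table(pd.concat(frames), out / "rarefaction.tsv", stamp)
        artifacts["rarefaction"] = str(out / "rarefaction.tsv")

    return artifacts
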