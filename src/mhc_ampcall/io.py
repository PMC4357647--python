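"""Readers, writers and configuration shared by the pipeline stages.

Interchange formats are deliberately plain: FASTA for sequences, TSV (tab
separated, header row, '#' comment/metadata lines) for tables, Newick for
trees. Every table written by the pipeline is stamped with the config hash
and the global seed so a run can be audited. Codon coordinates are 1-based
everywhere.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "PipelineConfig",
    "read_mask_tsv",
    "readsets_to_frame",
    "frame_to_readsets",
]

_IUPAC = set("ACGTURYSWKMBDHVN-acgturyswkmbdhvn*")


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}; rejects duplicate ids and
    non-IUPAC characters with the offending line number."""
    seqs: dict[str, str] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise ValueError(f"{path}:{lineno}: empty sequence id")
                if current in seqs:
                    raise ValueError(f"{path}:{lineno}: duplicate id {current!r}")
                seqs[current] = ""
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                bad = set(line) - _IUPAC
                if bad:
                    raise ValueError(
                        f"{path}:{lineno}: non-IUPAC characters {sorted(bad)}")
                seqs[current] += line.upper()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in header_comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_mask_tsv(path, n_codons: int):
    """Site-mask TSV with columns (partition, codon_index), 1-based."""
    from .selection import SiteMask

    df = read_table(path)
    parts: dict[str, set[int]] = {}
    for _, row in df.iterrows():
        parts.setdefault(str(row["partition"]), set()).add(int(row["codon_index"]))
    return SiteMask(n_codons, {k: frozenset(v) for k, v in parts.items()})


@dataclass
class PipelineConfig:
    """Everything a full pipeline run depends on, serialisable to YAML."""

    seed: int = 0
    out_dir: str = "out"
    # simulation
    n_individuals: int = 100
    loci: dict = field(default_factory=lambda: {
        "DRB": {"n_alleles": 17, "length": 162, "insertion_fraction": 0.0},
        "DQB": {"n_alleles": 22, "length": 162, "insertion_fraction": 7 / 22},
    })
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0
    err_point: float = 0.02
    err_homopolymer: float = 0.01
    chimera_rate: float = 0.01
    contamination_rate: float = 0.03
    contamination_frac: float = 0.04
    n_replicates: int = 1
    # sorting thresholds
    mpaf_flag: float = 0.05
    rpaf_susp: float = 0.10
    rpaf_high: float = 0.25
    d_max: int = 2
    depth_threshold: int = 18
    # downstream
    n_perm: int = 1000
    n_boot: int = 200
    rarefaction_step: int = 10
    rarefaction_reps: int = 100
    stages: list = field(default_factory=lambda: [
        "simulate", "stats", "classify", "genotype", "popgen", "selection",
        "tree", "rarefy"])

    def validate(self) -> None:
        from .simdata import SimConfig

        self.sim_config()  # runs SimConfig validation
        for f in ("mpaf_flag", "rpaf_susp", "rpaf_high"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.depth_threshold < 1 or self.d_max < 0:
            raise ValueError("bad threshold")
        known = {"simulate", "stats", "classify", "genotype", "popgen",
                 "selection", "tree", "rarefy"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def sim_config(self):
        from .simdata import SimConfig

        return SimConfig(
            n_individuals=self.n_individuals,
            depth_mean=self.depth_mean,
            depth_dispersion=self.depth_dispersion,
            err_point=self.err_point,
            err_homopolymer=self.err_homopolymer,
            chimera_rate=self.chimera_rate,
            contamination_rate=self.contamination_rate,
            contamination_frac=self.contamination_frac,
            n_replicates=self.n_replicates,
            seed=self.seed,
        )

    def sort_config(self):
        from .ampsort import SortConfig

        return SortConfig(
            mpaf_flag=self.mpaf_flag, rpaf_susp=self.rpaf_susp,
            rpaf_high=self.rpaf_high, d_max=self.d_max,
            depth_threshold=self.depth_threshold)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        data = asdict(self)
        data.pop("out_dir")
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def stamp(self) -> list[str]:
        return [f"config_hash={self.config_hash}", f"seed={self.seed}"]


def readsets_to_frame(readsets) -> pd.DataFrame:
    rows = []
    for rs in readsets:
        for vid, cnt in sorted(rs.counts.items()):
            rows.append({
                "amplicon_id": rs.amplicon_id, "individual": rs.individual_id,
                "locus": rs.locus_id, "run": rs.run_id,
                "replicate": rs.replicate_index, "variant_id": vid,
                "count": cnt})
    return pd.DataFrame(rows)


def frame_to_readsets(df: pd.DataFrame):
    from .simdata import AmpliconReadSet

    out = []
    for amp_id, grp in df.groupby("amplicon_id", sort=True):
        first = grp.iloc[0]
        out.append(AmpliconReadSet(
            amplicon_id=str(amp_id), individual_id=str(first["individual"]),
            locus_id=str(first["locus"]), run_id=str(first["run"]),
            replicate_index=int(first["replicate"]),
            counts={str(r["variant_id"]): int(r["count"])
                    for _, r in grp.iterrows()}))
    return out
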