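"""Universal genetic code helpers shared by the simulator and the selection module.

Only the standard (universal) nuclear code is supported: the target loci are
nuclear MHC class II exons.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_BASES = "ACGT"

_std = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, '*' for termination codons
GENETIC_CODE: dict[str, str] = dict(_std.forward_table)
for _stop in _std.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_std.stop_codons)
SENSE_CODONS = tuple(sorted(c for c, a in GENETIC_CODE.items() if a != "*"))


def translate_codon(codon: str) -> str:
    """Translate one codon; gap codons ('---') map to '-'."""
    if codon == "---":
        return "-"
    try:
        return GENETIC_CODE[codon.upper()]
    except KeyError:
        raise ValueError(f"not a translatable codon: {codon!r}") from None


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string (length divisible by 3)."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


def has_internal_stop(seq: str) -> bool:
    return "*" in translate(seq)
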