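"""Codon-level classification of coding SNPs (standard nuclear genetic code).

Used to check whether an exonic substitution is synonymous (e.g. ATT -> ATC,
both isoleucine), missense, or nonsense (stop gain).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

__all__ = ["CodonChange", "classify_codon_change", "translate_codon"]

_STOP = "*"
_TABLE = dict(standard_dna_table.forward_table)
for _codon in standard_dna_table.stop_codons:
    _TABLE[_codon] = _STOP


def _check_codon(codon: str, which: str) -> str:
    c = codon.upper()
    if len(c) != 3 or not set(c) <= set("ACGT"):
        raise ValueError(f"{which} codon {codon!r} is not a 3-letter A/C/G/T string")
    return c


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for a stop codon."""
    return _TABLE[_check_codon(codon, "the")]


@dataclass(frozen=True)
class CodonChange:
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | missense | nonsense


def classify_codon_change(ref_codon: str, alt_codon: str) -> CodonChange:
    """Classify a codon substitution on the coding strand.

    Synonymous iff both codons encode the same (non-stop) amino acid;
    a stop gain is nonsense; anything else is missense.
    """
    ref = _check_codon(ref_codon, "ref")
    alt = _check_codon(alt_codon, "alt")
    ref_aa, alt_aa = _TABLE[ref], _TABLE[alt]
    if alt_aa == _STOP and ref_aa != _STOP:
        effect = "nonsense"
    elif ref_aa == alt_aa and alt_aa != _STOP:
        effect = "synonymous"
    else:
        effect = "missense"
    return CodonChange(ref, alt, ref_aa, alt_aa, effect)
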