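"""Codon utilities: translation and deterministic reverse translation.

Reverse translation uses a single preferred codon per residue (an
E. coli-biased table) so that emitted oligonucleotides are deterministic and
round-trip back to the designed amino-acid sequence.  The table is a plain
dict and can be replaced by the caller.
"""

from __future__ import annotations

from typing import Mapping

from Bio.Seq import Seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: One preferred codon per standard residue (E. coli class-II bias).
PREFERRED_CODONS: dict[str, str] = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

STOP_CODONS = ("TAA", "TAG", "TGA")


def translate(nt: str) -> str:
    """Translate a nucleotide string (trimmed to a codon multiple)."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def reverse_translate(protein: str, table: Mapping[str, str] | None = None) -> str:
    """Encode a protein with one codon per residue.

    Raises ``KeyError``-derived ``ValueError`` if a residue is missing from
    the table (the table must be total over the residues used).
    """
    table = PREFERRED_CODONS if table is None else table
    try:
        return "".join(table[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} missing from codon table") from None
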