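"""Validated domain containers and file readers/writers.

Four containers flow through the pipeline:

* :class:`GermlineCDRSet` — named germline CDR amino-acid sequences per region;
* :class:`NaturalRepertoire` — observed CDR amino-acid sequences for one
  region, redundancy preserved;
* :class:`FrameworkScaffold` — the four framework regions (FR1-FR4) of one
  chain at both protein and nucleotide level;
* :class:`DesignedRepertoire` — a simulated, PTM-filtered CDR repertoire.

File formats are deliberately plain: TSV with a header or FASTA for
sequences, FASTA for frameworks (nucleotide records named ``<chain>|FR<i>``).
All amino-acid sequences are validated against the 20-letter alphabet;
ambiguity codes and stop symbols are rejected rather than dropped, because
the downstream design mathematics assume the standard alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .codons import AA_ALPHABET, translate
from .regions import CdrRegion, Chain

_AA_RE = re.compile(rf"^[{AA_ALPHABET}]+$")


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class ValidationError(ValueError):
    """A parsed value violates a container invariant."""


def _check_protein(seq: str, where: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValidationError(f"{where}: empty sequence")
    if not _AA_RE.match(seq):
        bad = sorted(set(seq) - set(AA_ALPHABET))
        raise ValidationError(f"{where}: invalid residue letter(s) {bad} in {seq!r}")
    return seq


# ---------------------------------------------------------------------------
# Germline sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GermlineCdr:
    region: CdrRegion
    name: str
    sequence: str


@dataclass
class GermlineCDRSet:
    """Named germline CDR amino-acid sequences, grouped by region."""

    entries: list[GermlineCdr]

    def __post_init__(self) -> None:
        seen: set[tuple[CdrRegion, str]] = set()
        checked = []
        for e in self.entries:
            seq = _check_protein(e.sequence, f"germline {e.name}")
            key = (e.region, e.name)
            if key in seen:
                raise ValidationError(f"duplicate germline name {e.name!r} in {e.region}")
            seen.add(key)
            checked.append(GermlineCdr(e.region, e.name, seq))
        self.entries = checked

    def for_region(self, region: CdrRegion) -> list[GermlineCdr]:
        return [e for e in self.entries if e.region is region]

    def regions(self) -> list[CdrRegion]:
        return sorted({e.region for e in self.entries}, key=lambda r: r.name)

    def __len__(self) -> int:
        return len(self.entries)


def load_germline_set(path: str | Path, format: str | None = None) -> GermlineCDRSet:
    """Read a germline set from TSV (region, name, sequence) or FASTA.

    FASTA headers use ``<region>|<name>``, e.g. ``>H1|DP47-H1``.  The format
    is inferred from the suffix when not given.
    """
    path = Path(path)
    fmt = format or ("fasta" if path.suffix.lower() in {".fa", ".fasta"} else "tsv")
    entries: list[GermlineCdr] = []
    if fmt == "tsv":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines:
            raise ParseError(f"{path}: empty file")
        start = 1 if lines[0].lower().startswith("region") else 0
        for lineno, line in enumerate(lines[start:], start=start + 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            region, name, seq = (p.strip() for p in parts)
            entries.append(GermlineCdr(CdrRegion.from_label(region), name, seq))
    elif fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                region, name = rec.id.split("|", 1)
            except ValueError:
                raise ParseError(f"{path}: FASTA id {rec.id!r} is not '<region>|<name>'") from None
            entries.append(GermlineCdr(CdrRegion.from_label(region), name, str(rec.seq)))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not entries:
        raise ParseError(f"{path}: no germline records found")
    return GermlineCDRSet(entries)


def save_germline_set(gset: GermlineCDRSet, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("fasta" if path.suffix.lower() in {".fa", ".fasta"} else "tsv")
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("region\tname\tsequence\n")
            for e in gset.entries:
                fh.write(f"{e.region.label}\t{e.name}\t{e.sequence}\n")
    else:
        recs = [SeqRecord(Seq(e.sequence), id=f"{e.region.label}|{e.name}", description="")
                for e in gset.entries]
        SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Natural repertoires
# ---------------------------------------------------------------------------

@dataclass
class NaturalRepertoire:
    """Observed CDR amino-acid sequences for one region (redundancy kept)."""

    region: CdrRegion
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError(f"{self.region}: empty repertoire")
        self.sequences = [_check_protein(s, f"{self.region} repertoire") for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)


def load_repertoire(path: str | Path, region: CdrRegion) -> NaturalRepertoire:
    """Read a repertoire from FASTA or one-sequence-per-line text."""
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    if text.lstrip().startswith(">"):
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        seqs = [line.strip() for line in text.splitlines() if line.strip()]
    return NaturalRepertoire(region, seqs)


def save_repertoire(rep: NaturalRepertoire, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=f"{rep.region.label}_{i:06d}", description="")
            for i, s in enumerate(rep.sequences)]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Framework scaffolds
# ---------------------------------------------------------------------------

FR_NAMES = ("FR1", "FR2", "FR3", "FR4")

#: Ordered anchor names: the terminal windows that flank the three CDRs.
ANCHOR_NAMES = ("fr1_end", "fr2_start", "fr2_end", "fr3_start", "fr3_end", "fr4_start")


@dataclass
class FrameworkScaffold:
    """One chain's four framework regions at protein and nucleotide level.

    ``anchor_len`` is the length of the terminal window used to locate
    framework/CDR boundaries in sequencing reads (default 5 residues).
    """

    chain: Chain
    fr_protein: tuple[str, str, str, str]
    fr_nucleotide: tuple[str, str, str, str]
    anchor_len: int = 5

    def __post_init__(self) -> None:
        if len(self.fr_protein) != 4 or len(self.fr_nucleotide) != 4:
            raise ValidationError("scaffold needs exactly FR1..FR4")
        self.fr_protein = tuple(_check_protein(p, f"{self.chain.value} FR") for p in self.fr_protein)
        nts = []
        for i, nt in enumerate(self.fr_nucleotide):
            nt = nt.strip().upper()
            if len(nt) % 3:
                raise ValidationError(
                    f"{self.chain.value} FR{i + 1}: nucleotide length {len(nt)} not a multiple of 3")
            prot = translate(nt)
            if "*" in prot:
                raise ValidationError(f"{self.chain.value} FR{i + 1}: internal stop codon")
            if prot != self.fr_protein[i]:
                raise ValidationError(
                    f"{self.chain.value} FR{i + 1}: translation {prot!r} != protein {self.fr_protein[i]!r}")
            nts.append(nt)
        self.fr_nucleotide = tuple(nts)
        if self.anchor_len < 1 or any(len(p) < self.anchor_len for p in self.fr_protein):
            raise ValidationError("anchor_len must be >= 1 and <= every FR length")

    def anchors(self) -> list[tuple[str, str]]:
        """The six (name, window) anchors in domain order."""
        k = self.anchor_len
        p = self.fr_protein
        return [
            ("fr1_end", p[0][-k:]), ("fr2_start", p[1][:k]), ("fr2_end", p[1][-k:]),
            ("fr3_start", p[2][:k]), ("fr3_end", p[2][-k:]), ("fr4_start", p[3][:k]),
        ]

    def protein_flanks(self, region: CdrRegion, n: int) -> tuple[str, str]:
        """Framework residues adjoining a CDR: last *n* of the upstream FR and
        first *n* of the downstream FR."""
        i = region.index  # CDRi sits between FR(i) and FR(i+1)
        if n == 0:
            return "", ""
        return self.fr_protein[i - 1][-n:], self.fr_protein[i][:n]

    def nucleotide_flanks(self, region: CdrRegion, n_nt: int) -> tuple[str, str]:
        i = region.index
        up, down = self.fr_nucleotide[i - 1], self.fr_nucleotide[i]
        if n_nt > len(up) or n_nt > len(down):
            raise ValidationError(f"flank of {n_nt} nt exceeds FR length")
        return (up[-n_nt:] if n_nt else ""), (down[:n_nt] if n_nt else "")


def load_frameworks(path: str | Path, anchor_len: int = 5) -> list[FrameworkScaffold]:
    """Read scaffolds from a nucleotide FASTA with ids ``<chain>|FR<i>``."""
    by_chain: dict[Chain, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            chain_s, fr = rec.id.split("|", 1)
        except ValueError:
            raise ParseError(f"{path}: FASTA id {rec.id!r} is not '<chain>|FR<i>'") from None
        chain = Chain(chain_s.lower())
        by_chain.setdefault(chain, {})[fr.upper()] = str(rec.seq).upper()
    scaffolds = []
    for chain, frs in by_chain.items():
        missing = [f for f in FR_NAMES if f not in frs]
        if missing:
            raise ParseError(f"{path}: chain {chain.value} missing {missing}")
        nts = tuple(frs[f] for f in FR_NAMES)
        prots = tuple(translate(nt) for nt in nts)
        scaffolds.append(FrameworkScaffold(chain, prots, nts, anchor_len=anchor_len))
    if not scaffolds:
        raise ParseError(f"{path}: no framework records found")
    return scaffolds


def save_frameworks(scaffolds: Iterable[FrameworkScaffold], path: str | Path) -> None:
    recs = []
    for sc in scaffolds:
        for name, nt in zip(FR_NAMES, sc.fr_nucleotide):
            recs.append(SeqRecord(Seq(nt), id=f"{sc.chain.value}|{name}", description=""))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Designed repertoires
# ---------------------------------------------------------------------------

@dataclass
class DesignedRepertoire:
    """A simulated CDR repertoire.  ``sequences`` keeps redundancy (the
    "Total" of a design table); ``unique_count`` is derived.

    The designer guarantees every sequence passed its PTM policy; the
    container itself only enforces the alphabet.
    """

    region: CdrRegion
    sequences: list[str]
    unique_count: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError(f"{self.region}: empty designed repertoire")
        self.sequences = [_check_protein(s, f"{self.region} design") for s in self.sequences]
        self.unique_count = len(set(self.sequences))

    @property
    def total(self) -> int:
        return len(self.sequences)

    def unique_sequences(self) -> set[str]:
        return set(self.sequences)

    def lengths(self) -> set[int]:
        return {len(s) for s in self.sequences}


def load_designed_repertoire(path: str | Path, region: CdrRegion) -> DesignedRepertoire:
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ParseError(f"{path}: no designed sequences found")
    return DesignedRepertoire(region, seqs)


def save_designed_repertoire(rep: DesignedRepertoire, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=f"{rep.region.label}_{i:06d}", description="")
            for i, s in enumerate(rep.sequences)]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def load_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read merged nucleotide reads from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
    if not reads:
        raise ParseError(f"{path}: no reads found")
    return reads


def save_reads(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".fq", ".fastq"}:
        recs = []
        for rid, seq in reads:
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            recs.append(rec)
        SeqIO.write(recs, str(path), "fastq")
    else:
        recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads]
        SeqIO.write(recs, str(path), "fasta")
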