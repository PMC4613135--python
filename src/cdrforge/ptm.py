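"""Post-translational-modification (PTM) liability motif scanning.

The liabilities handled are the classic antibody developability motifs:

* N-linked glycosylation sequon ``N-X-[ST]`` with ``X != P`` (``glyc``);
* Asp-Gly isomerization (``DG``), Asn-Gly deamidation (``NG``) and
  Asp-Pro backbone cleavage (``DP``) dipeptides;
* oxidation-prone single residues Cys (``Cys``) and Met (``Met``).

Met is tolerated at two positions where it is common or predominant in
natural antibodies: Kabat H34 (the 4th residue of the 5-residue CDR-H1) and
Kabat H100 (the first residue of the terminal 3-mer of CDR-H3).  Scanning
can include a window of framework residues on either side of the CDR so
that motifs straddling the CDR/framework junction are caught.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GermlineCDRSet, GermlineCdr, GermlineCDRSet as _G
from .regions import CdrRegion

MOTIF_KINDS = ("glyc", "DG", "NG", "DP", "Cys", "Met")


@dataclass(frozen=True)
class PtmHit:
    """One motif occurrence.  ``start`` is 0-based in the scanned string
    (left flank + CDR + right flank)."""

    motif_kind: str
    start: int
    span: int


@dataclass(frozen=True)
class PtmPolicy:
    """Which motifs are liabilities and where Met is exempt.

    ``exemptions`` are (region, local 1-based position) pairs at which Met is
    allowed; a negative position counts from the end of the CDR (-1 is the
    last residue), so the CDR-H3 exemption is written (H3, -3): the third
    residue from the end, i.e. Kabat H100.  ``junction_flank`` framework
    residues are appended on each side of the CDR before scanning (2 covers
    every dipeptide and the 3-residue sequon crossing a boundary).
    """

    dipeptide_motifs: tuple[str, ...] = ("DG", "NG", "DP")
    banned_residues: tuple[str, ...] = ("C", "M")
    scan_glyc: bool = True
    exemptions: tuple[tuple[CdrRegion, int], ...] = (
        (CdrRegion.H1, 4),
        (CdrRegion.H3, -3),
    )
    junction_flank: int = 2

    def exempt_indices(self, region: CdrRegion | None, seq_len: int) -> set[int]:
        """0-based CDR positions at which Met is allowed for this region."""
        out: set[int] = set()
        if region is None:
            return out
        for reg, pos in self.exemptions:
            if reg is region:
                idx = pos - 1 if pos > 0 else seq_len + pos
                if 0 <= idx < seq_len:
                    out.add(idx)
        return out


DEFAULT_POLICY = PtmPolicy()


def scan_ptm(seq: str, region: CdrRegion | None = None,
             policy: PtmPolicy = DEFAULT_POLICY,
             left_flank: str = "", right_flank: str = "") -> list[PtmHit]:
    """Scan a CDR (plus junction flanks) for PTM liability motifs.

    Hits lying entirely inside a flank are not reported; only hits
    overlapping the CDR itself count.  Returned positions are 0-based in
    ``left_flank + seq + right_flank``.
    """
    s = left_flank + seq + right_flank
    lo, hi = len(left_flank), len(left_flank) + len(seq)  # CDR half-open span
    exempt = {len(left_flank) + i for i in policy.exempt_indices(region, len(seq))}
    hits: list[PtmHit] = []

    def overlaps(start: int, span: int) -> bool:
        return start < hi and start + span > lo

    for i, ch in enumerate(s):
        if policy.scan_glyc and ch == "N" and i + 3 <= len(s):
            if s[i + 1] != "P" and s[i + 2] in "ST" and overlaps(i, 3):
                hits.append(PtmHit("glyc", i, 3))
        if i + 2 <= len(s):
            di = s[i:i + 2]
            if di in policy.dipeptide_motifs and overlaps(i, 2):
                hits.append(PtmHit(di, i, 2))
        if ch == "C" and "C" in policy.banned_residues and overlaps(i, 1):
            hits.append(PtmHit("Cys", i, 1))
        if ch == "M" and "M" in policy.banned_residues and i not in exempt and overlaps(i, 1):
            hits.append(PtmHit("Met", i, 1))
    return hits


def sanitize_germline(germlines: GermlineCDRSet, policy: PtmPolicy = DEFAULT_POLICY) -> GermlineCDRSet:
    """Replace deamidation/isomerization dipeptides in germline CDRs with SG.

    Germline CDRs (notably CDR-H2) can themselves carry NG/DG motifs; before
    simulation each such dipeptide is substituted with Ser-Gly, left to
    right, repeatedly until none remain.  Other motif kinds are untouched at
    this stage — they are handled by rejection during design.
    """
    targets = tuple(m for m in ("DG", "NG") if m in policy.dipeptide_motifs)
    entries = []
    for e in germlines.entries:
        seq = e.sequence
        while True:
            positions = [seq.find(m) for m in targets]
            positions = [p for p in positions if p >= 0]
            if not positions:
                break
            p = min(positions)
            seq = seq[:p] + "SG" + seq[p + 2:]
        entries.append(GermlineCdr(e.region, e.name, seq))
    return _G(entries)
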