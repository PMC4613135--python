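"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a fixture germline
CDR set, framework scaffolds, natural repertoires drawn from explicit
usage/mutation parameters, and error-bearing sequencing reads of an
assembled library.  Because the generating parameters are known, the
profiler can be checked for parameter recovery and the read annotator for
classification calibration.

The fixture germline CDRs and frameworks are hand-written, human-like
sequences with realistic lengths (synthetic stand-ins; no claim is made
that they equal real V-gene database entries, which ship with restrictive
terms and are not reproduced here).  Default repertoire sizes emulate a
realistic mature-repertoire download: 8,846 heavy, 3,110 kappa and 2,440
lambda variable domains.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping

from .codons import reverse_translate
from .designer import DEFAULT_LINKER, simulate_h3, _mutate_prefix
from .io import (DesignedRepertoire, FrameworkScaffold, GermlineCDRSet, GermlineCdr,
                 NaturalRepertoire)
from .profiler import H3Profile, ShmProfile
from .regions import CdrRegion, Chain

# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

#: Hand-written synthetic germline CDRs per region (region -> [(name, seq)]).
#: Within a region, equal-length entries are kept at pairwise Hamming
#: distance >= 3 (>= 4 for the short, heavily mutated CDR-H1) so that
#: closest-ancestor assignment of mutated offspring is near-unambiguous
#: (as with real germline families).
FIXTURE_GERMLINES: dict[str, list[tuple[str, str]]] = {
    "H1": [("VH-a", "SYAMS"), ("VH-b", "DYWIG"), ("VH-c", "TNSVH")],
    "H2": [("VH-a", "AISGSGGSTYYADSVKG"), ("VH-b", "VISYDGSNKYYADSVKG"),
           ("VH-c", "WINPNSGGTNYAQKFQG"), ("VH-d", "GISWNSGSIGYADSVKG")],
    "K1": [("VK-a", "RASQSVSSYLA"), ("VK-b", "RASQGISNYLA"),
           ("VK-c", "QASQDISNYLN"), ("VK-d", "RASQSVSSSYLA"),
           ("VK-e", "KSSQSVLYSSNNKNYLA")],
    "K2": [("VK-a", "AASSLQS"), ("VK-b", "GASSRAT"),
           ("VK-c", "KVSTRES"), ("VK-d", "DTSNLET")],
    "K3": [("VK-a", "QQYNSYPLT"), ("VK-b", "QQSYSTPLT"),
           ("VK-c", "QQRSNWPLT"), ("VK-d", "QQYGSSPIT")],
    "L1": [("VL-a", "SGSSSNIGSNYVY"), ("VL-b", "TGSSSNIGAGYDV"),
           ("VL-c", "TGSSSDVGGYNYVS")],
    "L2": [("VL-a", "GNSNRPS"), ("VL-b", "RNNQRPS"),
           ("VL-c", "DVSKRAT"), ("VL-d", "EGSHLQS")],
    "L3": [("VL-a", "QSYDSSLSG"), ("VL-b", "SSYTSSSTLV"),
           ("VL-c", "AAWDDSLSGPV"), ("VL-d", "QSYDSSLSGSV")],
}

#: Hand-written synthetic framework regions (FR1..FR4 protein) per chain.
FIXTURE_FRAMEWORKS: dict[Chain, tuple[str, str, str, str]] = {
    Chain.HEAVY: (
        "EVQLLESGGGLVQPGGSLRLSCAAS",
        "WVRQAPGKGLEWVS",
        "RFTISRDNSKNTLYLQMNSLRAEDTAVYYCAK",
        "WGQGTLVTVSS",
    ),
    Chain.KAPPA: (
        "EIVLTQSPGTLSLSPGERATLSC",
        "WYQQKPGQAPRLLIY",
        "GIPDRFSGSGSGTDFTLTISRLEPEDFAVYYC",
        "FGQGTKVEIK",
    ),
    Chain.LAMBDA: (
        "QSVLTQPPSVSGAPGQRVTISC",
        "WYQQLPGTAPKLLIY",
        "GVPDRFSGSKSGTSASLAITGLQAEDEADYYC",
        "FGGGTKLTVL",
    ),
}

#: Realistic mature-repertoire sizes used as generator defaults.
DEFAULT_REPERTOIRE_SIZES: dict[Chain, int] = {
    Chain.HEAVY: 8846, Chain.KAPPA: 3110, Chain.LAMBDA: 2440,
}

#: Per-position total substitution rates per region (generator defaults,
#: chosen so expected mutations/CDR sit in the natural 0.5-2.5 range).
DEFAULT_REGION_RATES: dict[CdrRegion, float] = {
    CdrRegion.H1: 0.16, CdrRegion.H2: 0.13,
    CdrRegion.K1: 0.06, CdrRegion.K2: 0.07, CdrRegion.K3: 0.07,
    CdrRegion.L1: 0.075, CdrRegion.L2: 0.09, CdrRegion.L3: 0.09,
}


def germline_fixture() -> GermlineCDRSet:
    entries = [GermlineCdr(CdrRegion.from_label(lbl), name, seq)
               for lbl, pairs in FIXTURE_GERMLINES.items() for name, seq in pairs]
    return GermlineCDRSet(entries)


def scaffold_fixture(anchor_len: int = 5) -> dict[Chain, FrameworkScaffold]:
    out = {}
    for chain, frs in FIXTURE_FRAMEWORKS.items():
        nts = tuple(reverse_translate(p) for p in frs)
        out[chain] = FrameworkScaffold(chain, frs, nts, anchor_len=anchor_len)
    return out


# ---------------------------------------------------------------------------
# Natural-repertoire generation
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSpec:
    """Generating truth for one region's natural repertoire.

    ``substitution`` has the same shape as an estimated SHM spectrum:
    per germline, per position, a map residue -> probability of observing
    that (non-germline) residue; the map's sum is the position's total
    mutation rate.
    """

    region: CdrRegion
    usage: dict[str, float]
    substitution: dict[str, list[dict[str, float]]]
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.usage.values()) - 1.0) > 1e-9:
            raise ValueError("usage must sum to 1")
        for g, cols in self.substitution.items():
            for p, col in enumerate(cols):
                if sum(col.values()) > 1.0 + 1e-9 or any(v < 0 for v in col.values()):
                    raise ValueError(f"{g} position {p}: rates must lie in [0,1]")


_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_repertoire_spec(region: CdrRegion, germlines: GermlineCDRSet,
                         mean_rate: float | None = None, n: int | None = None,
                         seed: int = 0) -> RepertoireSpec:
    """Build a generating spec over a germline set.

    Usage follows a geometric-ish decay over the region's germlines; each
    position gets a total substitution rate jittered around ``mean_rate``
    and split over three target residues with random weights.  Everything is
    drawn from ``seed`` so the truth is reproducible.
    """
    entries = germlines.for_region(region)
    if not entries:
        raise ValueError(f"no germlines for region {region}")
    rng = random.Random(seed * 97 + list(CdrRegion).index(region))
    if mean_rate is None:
        mean_rate = DEFAULT_REGION_RATES.get(region, 0.08)
    if n is None:
        n = DEFAULT_REPERTOIRE_SIZES[region.chain]

    weights = [0.6 ** i for i in range(len(entries))]
    tot = sum(weights)
    usage = {e.name: w / tot for e, w in zip(entries, weights)}

    substitution: dict[str, list[dict[str, float]]] = {}
    for e in entries:
        cols = []
        for aa in e.sequence:
            rate = mean_rate * rng.uniform(0.5, 1.5)
            targets = rng.sample([b for b in _AA if b != aa], 3)
            raw = [rng.uniform(0.2, 1.0) for _ in targets]
            s = sum(raw)
            cols.append({t: rate * w / s for t, w in zip(targets, raw)})
        substitution[e.name] = cols
    return RepertoireSpec(region, usage, substitution, n=n, seed=seed)


def spec_to_profile(spec: RepertoireSpec, germlines: GermlineCDRSet) -> ShmProfile:
    """View a generating spec as an SHM profile (the generating truth)."""
    gseq = {e.name: e.sequence for e in germlines.for_region(spec.region)}
    missing = [g for g in spec.usage if g not in gseq]
    if missing:
        raise ValueError(f"usage names {missing} absent from germline set")
    length_dist: dict[int, float] = {}
    for g, u in spec.usage.items():
        L = len(gseq[g])
        length_dist[L] = length_dist.get(L, 0.0) + u
    return ShmProfile(spec.region, dict(spec.usage), dict(spec.substitution),
                      {g: gseq[g] for g in spec.usage}, length_dist,
                      n_observations=spec.n)


def generate_natural_repertoire(spec: RepertoireSpec, germlines: GermlineCDRSet
                                ) -> NaturalRepertoire:
    """Draw ``spec.n`` sequences: usage-drawn germline, independent
    per-position substitutions.  Byte-identical under the same seed."""
    profile = spec_to_profile(spec, germlines)
    rng = random.Random(spec.seed)
    names = sorted(spec.usage)
    w = [spec.usage[g] for g in names]
    seqs = []
    for _ in range(spec.n):
        g = rng.choices(names, weights=w, k=1)[0]
        seqs.append(_mutate_prefix(profile, g, None, rng))
    return NaturalRepertoire(spec.region, seqs)


# ---------------------------------------------------------------------------
# CDR-H3 generation
# ---------------------------------------------------------------------------

#: CDR-H3-like residue composition (Gly/Tyr/Ser/Asp/Arg-rich).
H3_COMPOSITION: dict[str, float] = {
    "G": 0.14, "Y": 0.12, "S": 0.12, "D": 0.10, "R": 0.08, "A": 0.08,
    "L": 0.06, "T": 0.06, "V": 0.05, "P": 0.04, "W": 0.04, "F": 0.04,
    "E": 0.03, "I": 0.03, "N": 0.02, "H": 0.02, "K": 0.02, "Q": 0.02,
    "M": 0.015, "C": 0.015,
}

#: Terminal 3-mer units (J-segment tails; Phe/Met-Asp-Tyr/Val consensus).
H3_TERMINAL_UNITS: dict[str, float] = {
    "FDY": 0.30, "MDV": 0.20, "FDI": 0.12, "LDY": 0.10, "FDS": 0.08,
    "YDY": 0.06, "VDY": 0.05, "FDL": 0.05, "IDY": 0.04,
}

#: Length distribution over 9..20, peaked at 12-13.
H3_LENGTH_DIST: dict[int, float] = dict(zip(range(9, 21), (
    0.05, 0.09, 0.12, 0.14, 0.14, 0.12, 0.10, 0.08, 0.06, 0.04, 0.03, 0.03)))


def make_h3_truth(seed: int = 0, length_dist: Mapping[int, float] | None = None,
                  terminal_len: int = 3) -> H3Profile:
    """The generating CDR-H3 positional model: per-length columns jittered
    around the base composition, plus the terminal-unit table."""
    rng = random.Random(seed * 89 + 3)
    ld = dict(length_dist or H3_LENGTH_DIST)
    positional = {}
    for L in sorted(ld):
        cols = []
        for _ in range(L - terminal_len):
            raw = {a: f * rng.uniform(0.7, 1.3) for a, f in H3_COMPOSITION.items()}
            s = sum(raw.values())
            cols.append({a: v / s for a, v in raw.items()})
        positional[L] = cols
    return H3Profile(ld, positional, dict(H3_TERMINAL_UNITS), terminal_len=terminal_len)


def generate_h3_repertoire(truth: H3Profile, n: int, seed: int = 0) -> NaturalRepertoire:
    rng = random.Random(seed)
    return NaturalRepertoire(CdrRegion.H3, [simulate_h3(truth, rng) for _ in range(n)])


# ---------------------------------------------------------------------------
# Library read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Error model for simulated merged reads of an assembled scFv library.

    Substitution/insertion/deletion rates are per CDR nucleotide: synthesis
    errors live in the array-synthesized oligonucleotides, i.e. the CDR
    spans, while the PCR-derived framework and linker segments are taken as
    faithful.  ``stop_inject_rate`` is a per-read probability of replacing
    one random CDR codon with a stop codon.  With ``proofread`` true, reads
    with any out-of-frame or stop-containing CDR are discarded, emulating
    the enrichment effect of one round of anti-tag display panning.
    """

    designs: Mapping[CdrRegion, DesignedRepertoire]
    light_chain: Chain = Chain.KAPPA
    depth: int = 1000
    substitution_rate: float = 0.0
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    stop_inject_rate: float = 0.0
    proofread: bool = False
    seed: int = 0
    linker: str = DEFAULT_LINKER

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.deletion_rate,
                  self.insertion_rate, self.stop_inject_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must lie in [0,1]")


_STOPS = ("TAA", "TAG", "TGA")


def _mutate_segment(seg: str, rng: random.Random, sub: float, dele: float, ins: float) -> str:
    if sub == dele == ins == 0.0:
        return seg
    out = []
    for ch in seg:
        r = rng.random()
        if r < dele:
            pass
        elif r < dele + sub:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
        if ins and rng.random() < ins:
            out.append(rng.choice("ACGT"))
    return "".join(out)


def generate_library_reads(spec: ReadSimSpec, scaffolds: Mapping[Chain, FrameworkScaffold],
                           codon_table: Mapping[str, str] | None = None
                           ) -> list[tuple[str, str]]:
    """Simulate ``spec.depth`` merged reads of assembled scFv clones.

    Each read draws one designed CDR per region (with the design's
    redundancy), reverse-translates, assembles
    FRs+CDRs+linker at nucleotide level, then applies the error model to the
    CDR spans.  With ``proofread`` the out-of-frame reads are dropped, so
    fewer than ``depth`` reads may be returned.  Deterministic under seed.
    """
    if spec.depth == 0:
        return []
    heavy_regions = CdrRegion.for_chain(Chain.HEAVY)
    light_regions = CdrRegion.for_chain(spec.light_chain)
    all_regions = (*heavy_regions, *light_regions)
    for region in all_regions:
        if region not in spec.designs or not spec.designs[region].sequences:
            raise ValueError(f"design missing or empty for {region}")

    hsc, lsc = scaffolds[Chain.HEAVY], scaffolds[spec.light_chain]
    linker_nt = reverse_translate(spec.linker, codon_table)
    rng = random.Random(spec.seed)
    reads: list[tuple[str, str]] = []

    for i in range(spec.depth):
        cdr_nt = {r: reverse_translate(rng.choice(spec.designs[r].sequences), codon_table)
                  for r in all_regions}
        if spec.stop_inject_rate and rng.random() < spec.stop_inject_rate:
            r = rng.choice(all_regions)
            seg = cdr_nt[r]
            codon = rng.randrange(len(seg) // 3)
            cdr_nt[r] = seg[:codon * 3] + rng.choice(_STOPS) + seg[codon * 3 + 3:]
        mutated = {r: _mutate_segment(cdr_nt[r], rng, spec.substitution_rate,
                                      spec.deletion_rate, spec.insertion_rate)
                   for r in all_regions}
        if spec.proofread and not all(_cdr_in_frame(mutated[r]) for r in all_regions):
            continue
        h = hsc.fr_nucleotide
        l = lsc.fr_nucleotide
        read = (h[0] + mutated[heavy_regions[0]] + h[1] + mutated[heavy_regions[1]]
                + h[2] + mutated[heavy_regions[2]] + h[3] + linker_nt
                + l[0] + mutated[light_regions[0]] + l[1] + mutated[light_regions[1]]
                + l[2] + mutated[light_regions[2]] + l[3])
        reads.append((f"read_{i:06d}", read))
    return reads


def _cdr_in_frame(nt: str) -> bool:
    if not nt or len(nt) % 3:
        return False
    return all(nt[j:j + 3] not in _STOPS for j in range(0, len(nt), 3))
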