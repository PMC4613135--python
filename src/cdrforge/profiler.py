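"""Estimation of the statistics the CDR designer samples from.

Given a natural repertoire of CDR amino-acid sequences, this module
estimates:

* germline **usage**: how often each germline CDR is the closest ancestor of
  an observed sequence (length-matched minimal-Hamming assignment);
* the somatic-hypermutation **spectrum**: for each germline and position,
  the frequency with which each of the 19 non-germline residues is observed;
* **length distributions**;
* the CDR-H3 **positional profile**: per-length per-position amino-acid
  frequencies over the first (length - 3) residues, plus a pooled frequency
  table of the terminal 3-residue units (the Kabat 100-102 tail, which
  derives from the J segment and is treated as a single unit);
* the light-chain CDR3 **tail profile**: per-position frequencies of the
  last two-to-three residues (the J-proximal part), used with the
  germline-based head model in the hybrid light-CDR3 simulator.

CDR-H3 gets its own model because V(D)J junctional diversity makes germline
assignment of H3 impractical.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

from .io import GermlineCDRSet, NaturalRepertoire, ValidationError
from .regions import CdrRegion, Chain

logger = logging.getLogger(__name__)

PROFILE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Germline assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GermlineAssignment:
    observed: str
    germline_name: str  # "unassigned" when no equal-length germline exists
    mismatch_count: int
    mismatch_positions: tuple[tuple[int, str], ...]  # (0-based position, observed residue)

    @property
    def assigned(self) -> bool:
        return self.germline_name != "unassigned"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def assign_germline(observed: str, germlines: GermlineCDRSet, region: CdrRegion) -> GermlineAssignment:
    """Assign the closest equal-length germline ancestor.

    Among germlines of the region with the same length as ``observed``, the
    one with the fewest mismatches wins; ties break lexicographically by
    germline name.  With no equal-length germline the sequence is
    "unassigned".
    """
    if not observed:
        raise ValueError("empty observed sequence")
    candidates = [e for e in germlines.for_region(region) if len(e.sequence) == len(observed)]
    if not germlines.for_region(region):
        raise ValueError(f"no germlines available for region {region}")
    if not candidates:
        return GermlineAssignment(observed, "unassigned", 0, ())
    best = min(candidates, key=lambda e: (hamming(observed, e.sequence), e.name))
    mism = tuple((i, o) for i, (o, g) in enumerate(zip(observed, best.sequence)) if o != g)
    return GermlineAssignment(observed, best.name, len(mism), mism)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class ShmProfile:
    """Germline usage + per-position substitution spectra + length distribution.

    ``spectrum[g][p][a]`` is the fraction of observations assigned to
    germline ``g`` that carry residue ``a`` (different from the germline
    residue) at position ``p``; summing over ``a`` gives the total mutation
    rate at that position, necessarily <= 1.
    """

    region: CdrRegion
    usage: dict[str, float]
    spectrum: dict[str, list[dict[str, float]]]
    germline_sequences: dict[str, str]
    length_dist: dict[int, float]
    n_observations: int
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.usage.values()) - 1.0) > 1e-9:
            raise ValidationError("usage frequencies must sum to 1")
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValidationError("length distribution must sum to 1")
        for g, cols in self.spectrum.items():
            for p, col in enumerate(cols):
                tot = sum(col.values())
                if tot > 1.0 + 1e-9 or any(v < 0 for v in col.values()):
                    raise ValidationError(f"{g} position {p}: substitution frequencies invalid")


@dataclass
class H3Profile:
    """Per-length positional frequencies + pooled terminal 3-mer units."""

    length_dist: dict[int, float]
    positional: dict[int, list[dict[str, float]]]
    terminal_units: dict[str, float]
    terminal_len: int = 3

    def __post_init__(self) -> None:
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValidationError("H3 length distribution must sum to 1")
        if self.terminal_units and abs(sum(self.terminal_units.values()) - 1.0) > 1e-9:
            raise ValidationError("terminal unit frequencies must sum to 1")
        for length, cols in self.positional.items():
            for p, col in enumerate(cols):
                if col and abs(sum(col.values()) - 1.0) > 1e-9:
                    raise ValidationError(f"length {length} position {p}: column must sum to 1")


@dataclass
class L3TailProfile:
    """Per-length positional frequencies of the light-CDR3 tail."""

    region: CdrRegion
    tail_len: dict[int, int]
    tail_positional: dict[int, list[dict[str, float]]]

    def __post_init__(self) -> None:
        for length, cols in self.tail_positional.items():
            if len(cols) != self.tail_len[length]:
                raise ValidationError(f"length {length}: tail table width != tail_len")
            for p, col in enumerate(cols):
                if abs(sum(col.values()) - 1.0) > 1e-9:
                    raise ValidationError(f"length {length} tail position {p}: column must sum to 1")


def default_l3_split_rule(length: int) -> int:
    """Tail length of a light CDR3: 2 residues for CDRs of length <= 9, else 3."""
    return 2 if length <= 9 else 3


# ---------------------------------------------------------------------------
# Profile builders
# ---------------------------------------------------------------------------

def build_shm_profile(rep: NaturalRepertoire, germlines: GermlineCDRSet,
                      pooled: bool = False) -> ShmProfile:
    """Estimate usage and per-position substitution spectra from a repertoire.

    Sequences with no equal-length germline are excluded from usage and
    spectra (their count is kept in ``n_unassigned``).  With ``pooled=True``
    the substitution spectrum is estimated jointly across germlines of the
    same length and shared back to each (usage stays per-germline).
    """
    assignments = [assign_germline(s, germlines, rep.region) for s in rep.sequences]
    assigned = [a for a in assignments if a.assigned]
    if not assigned:
        raise ValueError(f"{rep.region}: no sequence assignable to any germline")
    n_unassigned = len(assignments) - len(assigned)

    gseq = {e.name: e.sequence for e in germlines.for_region(rep.region)}
    counts = Counter(a.germline_name for a in assigned)
    usage = {g: c / len(assigned) for g, c in counts.items()}

    sub_counts: dict[str, list[Counter]] = {
        g: [Counter() for _ in gseq[g]] for g in counts
    }
    for a in assigned:
        for pos, residue in a.mismatch_positions:
            sub_counts[a.germline_name][pos][residue] += 1

    spectrum: dict[str, list[dict[str, float]]] = {}
    if pooled:
        # pool mismatch counts across germlines of equal length, at positions
        # where the germline residues differ the pooled rate is still applied
        pooled_counts: dict[int, list[Counter]] = defaultdict(lambda: [])
        pooled_n: dict[int, int] = Counter()
        for g, c in counts.items():
            L = len(gseq[g])
            if not pooled_counts[L]:
                pooled_counts[L] = [Counter() for _ in range(L)]
            for p in range(L):
                pooled_counts[L][p].update(sub_counts[g][p])
            pooled_n[L] += c
        for g, c in counts.items():
            L = len(gseq[g])
            spectrum[g] = [
                {a_: n / pooled_n[L] for a_, n in pooled_counts[L][p].items() if a_ != gseq[g][p]}
                for p in range(L)
            ]
    else:
        for g, c in counts.items():
            spectrum[g] = [
                {a_: n / c for a_, n in sub_counts[g][p].items()}
                for p in range(len(gseq[g]))
            ]

    len_counts = Counter(len(a.observed) for a in assigned)
    length_dist = {L: c / len(assigned) for L, c in len_counts.items()}
    return ShmProfile(rep.region, usage, spectrum,
                      {g: gseq[g] for g in counts}, length_dist,
                      n_observations=len(assigned), n_unassigned=n_unassigned)


def _column_frequencies(seqs: list[str], positions: int) -> list[dict[str, float]]:
    cols: list[Counter] = [Counter() for _ in range(positions)]
    for s in seqs:
        for p in range(positions):
            cols[p][s[p]] += 1
    return [{a: c / len(seqs) for a, c in col.items()} for col in cols]


def build_h3_profile(rep: NaturalRepertoire, length_range: tuple[int, int] = (9, 20),
                     terminal_len: int = 3) -> H3Profile:
    """Build the positional/terminal-unit model of heavy-chain CDR3.

    Positional frequencies are computed per length over the first
    ``length - terminal_len`` positions; the terminal units are pooled
    across lengths.  The length distribution is restricted to
    ``length_range`` and renormalized.
    """
    if rep.region is not CdrRegion.H3:
        raise ValueError(f"H3 profile requires an H3 repertoire, got {rep.region}")
    lo, hi = length_range
    kept = [s for s in rep.sequences if lo <= len(s) <= hi and len(s) >= terminal_len]
    if not kept:
        raise ValueError(f"no CDR-H3 sequences within length range {length_range}")

    by_len: dict[int, list[str]] = defaultdict(list)
    for s in kept:
        by_len[len(s)].append(s)
    positional = {L: _column_frequencies(seqs, L - terminal_len) for L, seqs in by_len.items()}
    if terminal_len:
        tails = Counter(s[-terminal_len:] for s in kept)
        terminal_units = {t: c / len(kept) for t, c in tails.items()}
    else:
        terminal_units = {}
    length_dist = {L: len(seqs) / len(kept) for L, seqs in by_len.items()}
    return H3Profile(length_dist, positional, terminal_units, terminal_len=terminal_len)


def build_l3_tail_profile(rep: NaturalRepertoire,
                          split_rule: Mapping[int, int] | Callable[[int], int] | None = None
                          ) -> L3TailProfile:
    """Per-length positional frequencies of the last 2-3 light-CDR3 residues."""
    if not (rep.region.index == 3 and rep.region.chain is not Chain.HEAVY):
        raise ValueError(f"L3 tail profile requires a light CDR3 repertoire, got {rep.region}")

    def tail_of(length: int) -> int | None:
        if split_rule is None:
            return default_l3_split_rule(length)
        if callable(split_rule):
            return split_rule(length)
        return split_rule.get(length)

    by_len: dict[int, list[str]] = defaultdict(list)
    for s in rep.sequences:
        t = tail_of(len(s))
        if t is None:
            logger.warning("%s: length %d absent from split rule; sequences excluded",
                           rep.region, len(s))
            continue
        by_len[len(s)].append(s)
    if not by_len:
        raise ValueError(f"{rep.region}: no sequences covered by the split rule")

    tail_len = {L: tail_of(L) for L in by_len}
    tail_positional = {
        L: _column_frequencies([s[-tail_len[L]:] for s in seqs], tail_len[L])
        for L, seqs in by_len.items()
    }
    return L3TailProfile(rep.region, tail_len, tail_positional)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def profile_to_dict(profile) -> dict:
    if isinstance(profile, ShmProfile):
        return {
            "format_version": PROFILE_FORMAT_VERSION, "kind": "shm",
            "region": profile.region.label, "usage": profile.usage,
            "spectrum": profile.spectrum,
            "germline_sequences": profile.germline_sequences,
            "length_dist": {str(k): v for k, v in profile.length_dist.items()},
            "n_observations": profile.n_observations,
            "n_unassigned": profile.n_unassigned,
        }
    if isinstance(profile, H3Profile):
        return {
            "format_version": PROFILE_FORMAT_VERSION, "kind": "h3",
            "length_dist": {str(k): v for k, v in profile.length_dist.items()},
            "positional": {str(k): v for k, v in profile.positional.items()},
            "terminal_units": profile.terminal_units,
            "terminal_len": profile.terminal_len,
        }
    if isinstance(profile, L3TailProfile):
        return {
            "format_version": PROFILE_FORMAT_VERSION, "kind": "l3_tail",
            "region": profile.region.label,
            "tail_len": {str(k): v for k, v in profile.tail_len.items()},
            "tail_positional": {str(k): v for k, v in profile.tail_positional.items()},
        }
    raise TypeError(f"not a profile: {type(profile)!r}")


def profile_from_dict(doc: dict):
    kind = doc.get("kind")
    if kind == "shm":
        return ShmProfile(
            CdrRegion.from_label(doc["region"]), doc["usage"], doc["spectrum"],
            doc["germline_sequences"],
            {int(k): v for k, v in doc["length_dist"].items()},
            doc["n_observations"], doc.get("n_unassigned", 0),
        )
    if kind == "h3":
        return H3Profile(
            {int(k): v for k, v in doc["length_dist"].items()},
            {int(k): v for k, v in doc["positional"].items()},
            doc["terminal_units"], doc.get("terminal_len", 3),
        )
    if kind == "l3_tail":
        return L3TailProfile(
            CdrRegion.from_label(doc["region"]),
            {int(k): v for k, v in doc["tail_len"].items()},
            {int(k): v for k, v in doc["tail_positional"].items()},
        )
    raise ValueError(f"unknown profile kind {kind!r}")


def save_profile(profile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile_to_dict(profile), indent=1))


def load_profile(path: str | Path):
    return profile_from_dict(json.loads(Path(path).read_text()))
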