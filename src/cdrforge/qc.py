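"""NGS-based QC of a constructed CDR library.

Merged nucleotide reads are annotated by translating all three reading
frames and locating six framework *anchors* — the 5-residue terminal windows
of FR1..FR4 that flank the CDRs — allowing a configurable number of point
mismatches per window.  The segment between two adjacent anchors is a CDR.
Because an indel shifts the reading frame only downstream of itself, each
anchor is searched in all three frames and the earliest hit (in nucleotide
coordinates, left to right) wins; this keeps downstream CDRs recoverable
after an upstream frameshift.

Per CDR three nested flags are computed:

* ``in_frame`` — inter-anchor nucleotide length is a multiple of three and
  contains no stop codon;
* ``designed_length`` — in frame and the translated length occurs in the
  designed repertoire;
* ``designed_sequence`` — exact membership in the designed repertoire.

On top of the annotations the module computes the library report
(per-region percentages and design coverage), mutation statistics against
the germline set, PTM motif percentages, designed-vs-observed frequency
agreement (r-squared), redundancy spectra, and the desk estimators for the
functional and PTM-free fractions of assembled scFv clones.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import translate
from .io import DesignedRepertoire, FrameworkScaffold, GermlineCDRSet
from .profiler import assign_germline
from .ptm import DEFAULT_POLICY, PtmPolicy, scan_ptm, MOTIF_KINDS
from .regions import CdrRegion, Chain

# ---------------------------------------------------------------------------
# Read annotation
# ---------------------------------------------------------------------------

@dataclass
class CdrCall:
    resolved: bool = False
    sequence: str | None = None
    nt_length: int | None = None
    in_frame: bool = False
    designed_length: bool = False
    designed_sequence: bool = False


@dataclass
class ReadAnnotation:
    read_id: str
    chain: Chain | None
    frame: int | None
    cdrs: dict[CdrRegion, CdrCall]
    has_stop: bool = False
    fr_mismatches: int = 0
    fr_residues: int = 0
    anchors_found: int = 0


def _hamming_leq(a: str, b: str, limit: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def _find_anchor(prots: Sequence[str], anchor: str, min_nt: int, max_mm: int):
    """Best occurrence of an anchor window across all three frames at or
    after ``min_nt``: fewest mismatches first, then earliest nucleotide
    position.  Exact matches therefore beat spurious near-matches, while a
    point-mutated anchor is still found.  Returns (nt_start, frame, aa_index)
    or None."""
    k = len(anchor)
    best = None  # (mm, nt_start, frame, aa_index)
    for f in range(3):
        p = prots[f]
        start_aa = max(0, -(-(min_nt - f) // 3))  # ceil((min_nt - f)/3)
        exact = p.find(anchor, start_aa)
        if exact >= 0:
            cand = (0, f + 3 * exact, f, exact)
            if best is None or cand < best:
                best = cand
        if max_mm > 0 and (best is None or best[0] > 0):
            limit = exact if exact >= 0 else len(p) - k + 1
            for j in range(start_aa, max(limit, 0)):
                mm = _hamming_leq(p[j:j + k], anchor, max_mm)
                if mm is not None:
                    cand = (mm, f + 3 * j, f, j)
                    if best is None or cand < best:
                        best = cand
                    break
    if best is None:
        return None
    return best[1], best[2], best[3]


def _span_in_frame(read: str, start: int, end: int) -> tuple[bool, str | None]:
    n = end - start
    if n <= 0 or n % 3:
        return False, None
    aa = translate(read[start:end])
    if "*" in aa:
        return False, None
    return True, aa


def annotate_read(read: str | tuple[str, str], scaffold: FrameworkScaffold,
                  designs: Mapping[CdrRegion, DesignedRepertoire] | None = None,
                  max_anchor_mismatch: int = 1) -> ReadAnnotation:
    """Annotate one merged read against one chain's scaffold.

    A read in which fewer than two anchors are found gets ``frame None`` and
    all flags false (never an exception).  ``designs`` may be None, in which
    case the designed_* flags stay false.
    """
    read_id, seq = (read if isinstance(read, tuple) else ("read", read))
    seq = seq.upper()
    prots = [translate(seq[f:]) for f in range(3)]
    regions = CdrRegion.for_chain(scaffold.chain)
    k = scaffold.anchor_len

    found: dict[str, tuple[int, int, int]] = {}
    min_nt = 0
    for name, window in scaffold.anchors():
        hit = _find_anchor(prots, window, min_nt, max_anchor_mismatch)
        if hit is not None:
            found[name] = hit
            min_nt = hit[0] + 3 * k

    ann = ReadAnnotation(read_id, scaffold.chain, None,
                         {r: CdrCall() for r in regions},
                         anchors_found=len(found))
    if len(found) < 2:
        return ann

    frame_votes = Counter(hit[1] for hit in found.values())
    ann.frame = frame_votes.most_common(1)[0][0]

    # CDR i lies between anchor 2(i-1) (an FR end) and anchor 2i-1 (an FR start)
    names = [a for a, _ in scaffold.anchors()]
    for i, region in enumerate(regions, start=1):
        left_name, right_name = names[2 * (i - 1)], names[2 * i - 1]
        if left_name not in found or right_name not in found:
            continue
        left_end = found[left_name][0] + 3 * k
        right_start = found[right_name][0]
        call = ann.cdrs[region]
        call.resolved = True
        call.nt_length = right_start - left_end
        call.in_frame, aa = _span_in_frame(seq, left_end, right_start)
        call.sequence = aa
        design = designs.get(region) if designs else None
        if call.in_frame and design is not None:
            call.designed_length = len(aa) in design.lengths()
            call.designed_sequence = call.designed_length and aa in design.unique_sequences()

    # stop codons over the whole anchored span, in the frame of its first anchor
    first = min(found.values())
    last_name = [n for n in names if n in found][-1]
    last_end = found[last_name][0] + 3 * k
    span_aa = translate(seq[first[0]:last_end])
    ann.has_stop = "*" in span_aa

    _count_fr_mutations(ann, seq, scaffold, found)
    return ann


def _count_fr_mutations(ann: ReadAnnotation, seq: str, scaffold: FrameworkScaffold,
                        found: Mapping[str, tuple[int, int, int]]) -> None:
    """Compare recoverable framework segments to the reference FRs."""
    k = scaffold.anchor_len
    frs = scaffold.fr_protein

    def compare(start_nt: int, ref: str) -> None:
        end_nt = start_nt + 3 * len(ref)
        if start_nt < 0 or end_nt > len(seq):
            return
        obs = translate(seq[start_nt:end_nt])
        ann.fr_mismatches += sum(a != b for a, b in zip(obs, ref))
        ann.fr_residues += len(ref)

    if "fr1_end" in found:
        compare(found["fr1_end"][0] + 3 * k - 3 * len(frs[0]), frs[0])
    for fr_i, (s_name, e_name) in ((1, ("fr2_start", "fr2_end")), (2, ("fr3_start", "fr3_end"))):
        if s_name in found and e_name in found:
            start, end = found[s_name][0], found[e_name][0] + 3 * k
            if end - start == 3 * len(frs[fr_i]):
                compare(start, frs[fr_i])
    if "fr4_start" in found:
        compare(found["fr4_start"][0], frs[3])


def annotate_reads(reads: Iterable[tuple[str, str]], scaffold: FrameworkScaffold,
                   designs: Mapping[CdrRegion, DesignedRepertoire] | None = None,
                   max_anchor_mismatch: int = 1) -> list[ReadAnnotation]:
    return [annotate_read(r, scaffold, designs, max_anchor_mismatch) for r in reads]


# ---------------------------------------------------------------------------
# Library summary (design-fidelity table)
# ---------------------------------------------------------------------------

@dataclass
class RegionStats:
    processed: int = 0
    in_frame_pct: float | None = None
    designed_length_pct: float | None = None
    designed_sequence_pct: float | None = None
    design_coverage_pct: float | None = None


@dataclass
class ChainStats:
    reads: int = 0
    functional_pct: float | None = None      # all three CDRs in frame, no stop
    redundancy_spectrum: dict[int, int] = field(default_factory=dict)
    unique_pct: float | None = None          # unique domains / functional reads


@dataclass
class QcReport:
    regions: dict[CdrRegion, RegionStats] = field(default_factory=dict)
    chains: dict[Chain, ChainStats] = field(default_factory=dict)

    def region_table(self) -> pd.DataFrame:
        rows = {}
        for region, st in self.regions.items():
            rows[region.label] = {
                "processed": st.processed,
                "in_frame_pct": st.in_frame_pct,
                "designed_length_pct": st.designed_length_pct,
                "designed_sequence_pct": st.designed_sequence_pct,
                "design_coverage_pct": st.design_coverage_pct,
            }
        return pd.DataFrame(rows)


def summarize_library(annotations: Iterable[ReadAnnotation],
                      designs: Mapping[CdrRegion, DesignedRepertoire] | None = None
                      ) -> QcReport:
    """Per-region percentages and per-chain functional/redundancy statistics.

    Percentages are over reads in which the region was resolvable (both
    flanking anchors found); a region never resolved reports None, not zero.
    Design coverage is the fraction of designed unique sequences observed at
    least once.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotations to summarize")
    report = QcReport()

    per_region: dict[CdrRegion, list[CdrCall]] = defaultdict(list)
    observed: dict[CdrRegion, set[str]] = defaultdict(set)
    by_chain: dict[Chain, list[ReadAnnotation]] = defaultdict(list)
    for ann in annotations:
        if ann.chain is not None:
            by_chain[ann.chain].append(ann)
        for region, call in ann.cdrs.items():
            if call.resolved:
                per_region[region].append(call)
                if call.sequence:
                    observed[region].add(call.sequence)

    for region, calls in per_region.items():
        n = len(calls)
        st = RegionStats(processed=n)
        st.in_frame_pct = 100.0 * sum(c.in_frame for c in calls) / n
        st.designed_length_pct = 100.0 * sum(c.designed_length for c in calls) / n
        st.designed_sequence_pct = 100.0 * sum(c.designed_sequence for c in calls) / n
        if designs and region in designs:
            uniq = designs[region].unique_sequences()
            st.design_coverage_pct = 100.0 * len(uniq & observed[region]) / len(uniq)
        report.regions[region] = st

    for chain, anns in by_chain.items():
        st = ChainStats(reads=len(anns))
        regions = CdrRegion.for_chain(chain)

        def _call(a: ReadAnnotation, r: CdrRegion) -> CdrCall:
            return a.cdrs.get(r, CdrCall())

        functional = [a for a in anns
                      if all(_call(a, r).in_frame for r in regions) and not a.has_stop]
        st.functional_pct = 100.0 * len(functional) / len(anns)
        domains = Counter(tuple(_call(a, r).sequence for r in regions)
                          for a in functional)
        if domains:
            st.redundancy_spectrum = dict(Counter(domains.values()))
            st.unique_pct = 100.0 * len(domains) / sum(domains.values())
        report.chains[chain] = st
    return report


# ---------------------------------------------------------------------------
# Mutation statistics
# ---------------------------------------------------------------------------

@dataclass
class MutationStats:
    mean_by_region: dict[CdrRegion, float]
    mean_by_length: dict[CdrRegion, dict[int, float]]
    rate_by_region: dict[CdrRegion, float]      # mutations per CDR residue
    n_by_region: dict[CdrRegion, int]
    fr_rate_by_chain: dict[Chain, float] = field(default_factory=dict)


def mutation_statistics(sequences_by_region: Mapping[CdrRegion, Sequence[str]],
                        germlines: GermlineCDRSet,
                        annotations: Iterable[ReadAnnotation] | None = None
                        ) -> MutationStats:
    """Average mismatches to the closest equal-length germline, per region
    and length class.  Regions with no germlines (CDR-H3) are skipped.
    With annotations, framework mutation/residue rates per chain are added.
    """
    mean_by_region, mean_by_length, rate_by_region, n_by_region = {}, {}, {}, {}
    for region, seqs in sequences_by_region.items():
        if not germlines.for_region(region):
            continue
        counts_by_len: dict[int, list[int]] = defaultdict(list)
        residues = 0
        for s in seqs:
            a = assign_germline(s, germlines, region)
            if a.assigned:
                counts_by_len[len(s)].append(a.mismatch_count)
                residues += len(s)
        all_counts = [c for v in counts_by_len.values() for c in v]
        if not all_counts:
            continue
        mean_by_region[region] = float(np.mean(all_counts))
        mean_by_length[region] = {L: float(np.mean(v)) for L, v in sorted(counts_by_len.items())}
        rate_by_region[region] = sum(all_counts) / residues
        n_by_region[region] = len(all_counts)
    stats = MutationStats(mean_by_region, mean_by_length, rate_by_region, n_by_region)
    if annotations is not None:
        mm: dict[Chain, int] = Counter()
        res: dict[Chain, int] = Counter()
        for ann in annotations:
            if ann.chain is not None and ann.fr_residues:
                mm[ann.chain] += ann.fr_mismatches
                res[ann.chain] += ann.fr_residues
        stats.fr_rate_by_chain = {c: mm[c] / res[c] for c in res}
    return stats


# ---------------------------------------------------------------------------
# PTM statistics
# ---------------------------------------------------------------------------

def ptm_statistics(sequences_by_region: Mapping[CdrRegion, Sequence[str]],
                   policy: PtmPolicy = DEFAULT_POLICY) -> pd.DataFrame:
    """Percentage of sequences per region containing each PTM motif kind.

    Rows are motif kinds plus ``Total`` (sequences with at least one hit of
    any kind; a sequence with several motifs counts once in Total, so Total
    is at most the sum of the motif rows).  Scanning is CDR-local (no
    junction flanks) with the policy's Met exemptions applied.
    """
    table: dict[str, dict[str, float]] = {}
    for region, seqs in sequences_by_region.items():
        if not len(seqs):
            continue
        kind_counts: Counter = Counter()
        any_count = 0
        for s in seqs:
            hits = scan_ptm(s, region, policy)
            if hits:
                any_count += 1
                for kind in {h.motif_kind for h in hits}:
                    kind_counts[kind] += 1
        col = {kind: 100.0 * kind_counts.get(kind, 0) / len(seqs) for kind in MOTIF_KINDS}
        col["Total"] = 100.0 * any_count / len(seqs)
        table[region.label] = col
    return pd.DataFrame(table).reindex(list(MOTIF_KINDS) + ["Total"])


# ---------------------------------------------------------------------------
# Designed-vs-observed comparison
# ---------------------------------------------------------------------------

@dataclass
class DesignComparison:
    r_squared: float | None
    frequency_pairs: list[tuple[str, float, float]]  # (sequence, designed f, observed f)
    designed_length_dist: dict[int, float]
    observed_length_dist: dict[int, float]
    redundancy_spectrum: dict[int, int]


def compare_design(annotations: Iterable[ReadAnnotation], region: CdrRegion,
                   design: DesignedRepertoire) -> DesignComparison:
    """Agreement between designed and observed CDR frequencies for one region.

    r-squared is the squared Pearson correlation between designed and
    observed relative frequencies over the designed sequences actually
    observed (sequences outside the design are excluded).  Undefined (None)
    with fewer than 3 shared sequences.
    """
    observed = Counter()
    for ann in annotations:
        call = ann.cdrs.get(region)
        if call is not None and call.in_frame and call.sequence:
            observed[call.sequence] += 1
    if not observed:
        raise ValueError(f"{region}: no in-frame CDR observations")

    designed = Counter(design.sequences)
    shared = sorted(set(designed) & set(observed))
    n_obs = sum(observed.values())
    pairs = [(s, designed[s] / design.total, observed[s] / n_obs) for s in shared]
    if len(shared) >= 3:
        d = np.array([p[1] for p in pairs])
        o = np.array([p[2] for p in pairs])
        if d.std() == 0 or o.std() == 0:
            r2 = None
        else:
            r2 = float(np.corrcoef(d, o)[0, 1] ** 2)
    else:
        r2 = None

    def length_dist(counter: Counter) -> dict[int, float]:
        tot = sum(counter.values())
        by_len = Counter()
        for s, c in counter.items():
            by_len[len(s)] += c
        return {L: c / tot for L, c in sorted(by_len.items())}

    return DesignComparison(
        r_squared=r2,
        frequency_pairs=pairs,
        designed_length_dist=length_dist(designed),
        observed_length_dist=length_dist(observed),
        redundancy_spectrum=dict(Counter(observed.values())),
    )


def proportion_comparison(count1: int, n1: int, count2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test (e.g. selected vs unselected rates)."""
    from statsmodels.stats.proportion import proportions_ztest
    stat, pval = proportions_ztest([count1, count2], [n1, n2], alternative="two-sided")
    return float(stat), float(pval)


# ---------------------------------------------------------------------------
# Desk estimators
# ---------------------------------------------------------------------------

def _as_region_map(values: Mapping) -> dict[CdrRegion, float]:
    out = {}
    for k, v in values.items():
        region = k if isinstance(k, CdrRegion) else CdrRegion.from_label(str(k))
        out[region] = float(v)
    return out


def estimate_functional_fractions(in_frame_pct: Mapping) -> dict[str, float | None]:
    """Functional-domain and functional-scFv estimates from in-frame rates.

    A variable domain is functional when all three of its CDRs are in frame;
    assuming independence, the chain estimate is the product of the chain's
    three per-region in-frame fractions.  The scFv estimate pairs the heavy
    domain with an average light domain: heavy x mean(kappa, lambda).  All
    values in percent; a chain missing a region reports None.
    """
    pct = _as_region_map(in_frame_pct)
    out: dict[str, float | None] = {}
    for chain in Chain:
        regions = CdrRegion.for_chain(chain)
        if all(r in pct for r in regions):
            out[chain.value] = 100.0 * math.prod(pct[r] / 100.0 for r in regions)
        else:
            out[chain.value] = None
    if out["heavy"] is not None and out["kappa"] is not None and out["lambda"] is not None:
        light = (out["kappa"] + out["lambda"]) / 2.0
        out["scfv"] = out["heavy"] * light / 100.0
    else:
        out["scfv"] = None
    return out


def estimate_ptm_free_fraction(total_ptm_pct: Mapping) -> dict[str, float | None]:
    """Fraction of clones free of PTM motifs, assuming independence across CDRs.

    Per chain: product over its three regions of (1 - Total/100).  For
    assembled scFv the heavy x kappa and heavy x lambda pairings are
    reported separately, along with the complementary at-least-one-PTM
    burden.  All values in percent.
    """
    pct = _as_region_map(total_ptm_pct)
    out: dict[str, float | None] = {}
    for chain in Chain:
        regions = CdrRegion.for_chain(chain)
        if all(r in pct for r in regions):
            out[chain.value] = 100.0 * math.prod(1.0 - pct[r] / 100.0 for r in regions)
        else:
            out[chain.value] = None
    for light in (Chain.KAPPA, Chain.LAMBDA):
        key = f"heavy_{light.value}"
        if out["heavy"] is not None and out[light.value] is not None:
            out[key] = out["heavy"] * out[light.value] / 100.0
            out[f"burden_{key}"] = 100.0 - out[key]
        else:
            out[key] = None
            out[f"burden_{key}"] = None
    return out
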