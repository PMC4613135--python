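"""Non-combinatorial CDR repertoire design.

Instead of randomizing codons combinatorially, every CDR in the library is
an explicitly simulated sequence:

* CDR-H1/H2/K1/K2/K3/L1/L2 — draw a germline CDR according to its natural
  usage frequency, then mutate each position independently with the
  position's profiled total substitution rate, drawing the replacement from
  the profiled substitution distribution;
* CDR-H3 — draw a length (9-20 by default), draw the first length-3
  residues from the per-length positional frequencies, then draw the
  terminal 3 residues as one unit from the terminal-unit table;
* light-chain CDR3 (K3/L3) — hybrid: germline-based head (all but the last
  2-3 residues) plus a tail drawn per position from the tail profile.

Candidates carrying any PTM liability motif (scanned with framework
junction flanks) are rejected and redrawn, so the requested totals are
exact and the delivered repertoire is motif-free by construction.  The
designed sequences are then partitioned into synthesis pools of bounded
size and emitted as framework-flanked oligonucleotides.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .codons import reverse_translate
from .io import DesignedRepertoire, FrameworkScaffold
from .profiler import H3Profile, L3TailProfile, ShmProfile
from .ptm import DEFAULT_POLICY, PtmPolicy, scan_ptm
from .regions import CdrRegion, Chain

#: Per-region design totals ("Total" of the design table).
DEFAULT_TARGETS: dict[CdrRegion, int] = {
    CdrRegion.H1: 1500, CdrRegion.H2: 1500, CdrRegion.H3: 7836,
    CdrRegion.K1: 1500, CdrRegion.K2: 1000, CdrRegion.K3: 1500,
    CdrRegion.L1: 1500, CdrRegion.L2: 1000, CdrRegion.L3: 1500,
}

#: Maximum oligonucleotides synthesizable per array pool.
DEFAULT_POOL_CAPACITY = 3918

DEFAULT_LINKER = "GGGGSGGGGSGGGGS"


@dataclass(frozen=True)
class DesignConfig:
    targets: Mapping[CdrRegion, int] = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    h3_length_range: tuple[int, int] = (9, 20)
    pool_capacity: int = DEFAULT_POOL_CAPACITY
    seed: int = 0
    ptm: PtmPolicy = DEFAULT_POLICY
    max_attempts_factor: int = 1000  # attempt budget = factor * target

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.targets.values()):
            raise ValueError("design targets must be positive")
        if self.pool_capacity <= 0:
            raise ValueError("pool capacity must be positive")


@dataclass
class ProfileBundle:
    """Everything the designer samples from, keyed by region."""

    shm: dict[CdrRegion, ShmProfile] = field(default_factory=dict)
    h3: H3Profile | None = None
    l3_tails: dict[CdrRegion, L3TailProfile] = field(default_factory=dict)


@dataclass
class OligoPool:
    pool_id: int
    records: list[tuple[str, str]]  # (cdr protein, flanked oligonucleotide)
    capacity: int = DEFAULT_POOL_CAPACITY

    def __post_init__(self) -> None:
        if len(self.records) > self.capacity:
            raise ValueError(f"pool {self.pool_id} exceeds capacity {self.capacity}")


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _weighted_sampler(freqs: Mapping, rng: random.Random):
    items = sorted(freqs.items())
    values = [v for v, _ in items]
    weights = [w for _, w in items]
    return lambda: rng.choices(values, weights=weights, k=1)[0]


def simulate_germline_based_cdr(profile: ShmProfile, rng: random.Random) -> str:
    """One germline-usage + SHM-spectrum draw."""
    if not profile.usage:
        raise ValueError("profile has empty germline usage")
    names = sorted(profile.usage)
    g = rng.choices(names, weights=[profile.usage[n] for n in names], k=1)[0]
    return _mutate_prefix(profile, g, None, rng)


def _mutate_prefix(profile: ShmProfile, germline_name: str, upto: int | None,
                   rng: random.Random) -> str:
    germ = profile.germline_sequences[germline_name]
    cols = profile.spectrum[germline_name]
    end = len(germ) if upto is None else upto
    out = []
    for p in range(end):
        col = cols[p]
        rate = sum(col.values())
        if rate > 0 and rng.random() < rate:
            residues = sorted(col)
            out.append(rng.choices(residues, weights=[col[r] for r in residues], k=1)[0])
        else:
            out.append(germ[p])
    return "".join(out)


def simulate_h3(profile: H3Profile, rng: random.Random) -> str:
    """One positional-model + terminal-unit draw of CDR-H3."""
    lengths = sorted(profile.length_dist)
    L = rng.choices(lengths, weights=[profile.length_dist[x] for x in lengths], k=1)[0]
    if L not in profile.positional:
        raise ValueError(f"drawn length {L} has no positional table")
    out = []
    for col in profile.positional[L]:
        residues = sorted(col)
        out.append(rng.choices(residues, weights=[col[r] for r in residues], k=1)[0])
    if profile.terminal_len:
        units = sorted(profile.terminal_units)
        out.append(rng.choices(units, weights=[profile.terminal_units[u] for u in units], k=1)[0])
    return "".join(out)


def simulate_l3(profile: ShmProfile, tail: L3TailProfile, rng: random.Random) -> str:
    """One hybrid light-CDR3 draw: SHM-mutated germline head + profiled tail."""
    if not profile.usage:
        raise ValueError("profile has empty germline usage")
    names = sorted(profile.usage)
    g = rng.choices(names, weights=[profile.usage[n] for n in names], k=1)[0]
    L = len(profile.germline_sequences[g])
    if L not in tail.tail_len:
        raise ValueError(f"no tail table for light CDR3 length {L}")
    t = tail.tail_len[L]
    head = _mutate_prefix(profile, g, L - t, rng)
    tail_res = []
    for col in tail.tail_positional[L]:
        residues = sorted(col)
        tail_res.append(rng.choices(residues, weights=[col[r] for r in residues], k=1)[0])
    return head + "".join(tail_res)


def make_simulator(region: CdrRegion, profiles: ProfileBundle):
    """Pick the region's simulator: positional model for H3, hybrid for light
    CDR3, germline/SHM for everything else."""
    if region is CdrRegion.H3:
        if profiles.h3 is None:
            raise ValueError("no H3 profile provided")
        return lambda rng: simulate_h3(profiles.h3, rng)
    if region.is_light_cdr3:
        if region not in profiles.shm or region not in profiles.l3_tails:
            raise ValueError(f"hybrid CDR3 design for {region} needs both an SHM and a tail profile")
        return lambda rng: simulate_l3(profiles.shm[region], profiles.l3_tails[region], rng)
    if region not in profiles.shm:
        raise ValueError(f"no SHM profile for region {region}")
    return lambda rng: simulate_germline_based_cdr(profiles.shm[region], rng)


# ---------------------------------------------------------------------------
# Design with PTM rejection
# ---------------------------------------------------------------------------

class DesignError(RuntimeError):
    pass


def design_repertoire(region: CdrRegion, config: DesignConfig, profiles: ProfileBundle,
                      scaffold: FrameworkScaffold, rng: random.Random | None = None
                      ) -> DesignedRepertoire:
    """Draw candidates until the region's target total is reached.

    Every candidate is scanned for PTM motifs together with
    ``config.ptm.junction_flank`` framework residues on each side; any hit
    rejects the candidate.  Accepted draws keep redundancy, so the total is
    exact and the unique count is emergent.  Deterministic under the config
    seed (per-region seeds are derived from it).
    """
    if scaffold.chain is not region.chain:
        raise ValueError(f"scaffold chain {scaffold.chain} does not match region {region}")
    target = config.targets.get(region)
    if target is None:
        raise ValueError(f"no target total configured for {region}")
    if rng is None:
        # stable per-region stream derived from the config seed
        rng = random.Random((config.seed * 100 + list(CdrRegion).index(region)) & 0x7FFFFFFF)
    simulate = make_simulator(region, profiles)
    left, right = scaffold.protein_flanks(region, config.ptm.junction_flank)

    accepted: list[str] = []
    attempts = 0
    budget = config.max_attempts_factor * target
    while len(accepted) < target:
        if attempts >= budget:
            raise DesignError(
                f"{region}: accepted {len(accepted)}/{target} after {attempts} attempts; "
                "the profile may be incompatible with the PTM policy")
        attempts += 1
        cand = simulate(rng)
        if not scan_ptm(cand, region, config.ptm, left, right):
            accepted.append(cand)
    return DesignedRepertoire(region, accepted)


def design_library(config: DesignConfig, profiles: ProfileBundle,
                   scaffolds: Mapping[Chain, FrameworkScaffold]
                   ) -> dict[CdrRegion, DesignedRepertoire]:
    """Design every region with a configured target, in label order."""
    out = {}
    for region in sorted(config.targets, key=lambda r: r.label):
        out[region] = design_repertoire(region, config, profiles, scaffolds[region.chain])
    return out


# ---------------------------------------------------------------------------
# Pools, oligos, scFv assembly
# ---------------------------------------------------------------------------

def partition_pools(rep: DesignedRepertoire, capacity: int = DEFAULT_POOL_CAPACITY
                    ) -> list[list[str]]:
    """Split a designed repertoire into ceil(total/capacity) ordered chunks.

    Concatenating the chunks reconstitutes the repertoire exactly.
    """
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    seqs = rep.sequences
    return [seqs[i:i + capacity] for i in range(0, len(seqs), capacity)]


def emit_oligo_pool(pool_id: int, sequences: Sequence[str], scaffold: FrameworkScaffold,
                    region: CdrRegion, flank_nt: int,
                    codon_table: Mapping[str, str] | None = None,
                    capacity: int = DEFAULT_POOL_CAPACITY) -> OligoPool:
    """Reverse-translate a pool chunk and attach framework nucleotide flanks.

    Each oligo is: last ``flank_nt`` nucleotides of the upstream FR +
    CDR codons + first ``flank_nt`` nucleotides of the downstream FR.
    Translating the central segment recovers the CDR.
    """
    left, right = scaffold.nucleotide_flanks(region, flank_nt)
    records = [(s, left + reverse_translate(s, codon_table) + right) for s in sequences]
    return OligoPool(pool_id, records, capacity=capacity)


def assemble_scfv(heavy_cdrs: Sequence[str], light_cdrs: Sequence[str],
                  heavy_scaffold: FrameworkScaffold, light_scaffold: FrameworkScaffold,
                  linker: str = DEFAULT_LINKER) -> str:
    """Graft three heavy and three light CDRs into the scaffold frameworks.

    Returns FR1+CDR1+FR2+CDR2+FR3+CDR3+FR4 (heavy) + linker + the same for
    the light chain, at protein level.
    """
    if len(heavy_cdrs) != 3 or len(light_cdrs) != 3:
        raise ValueError("exactly three CDRs per chain are required")
    if any(not c for c in (*heavy_cdrs, *light_cdrs)):
        raise ValueError("empty CDR")

    def domain(frs: Sequence[str], cdrs: Sequence[str]) -> str:
        return frs[0] + cdrs[0] + frs[1] + cdrs[1] + frs[2] + cdrs[2] + frs[3]

    return (domain(heavy_scaffold.fr_protein, heavy_cdrs) + linker
            + domain(light_scaffold.fr_protein, light_cdrs))


def extract_cdrs(domain: str, scaffold: FrameworkScaffold) -> list[str]:
    """Inverse of one chain of :func:`assemble_scfv` for exact FR matches."""
    frs = scaffold.fr_protein
    cdrs = []
    pos = 0
    for i in range(3):
        start = domain.index(frs[i], pos) + len(frs[i])
        end = domain.index(frs[i + 1], start)
        cdrs.append(domain[start:end])
        pos = end
    return cdrs
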