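# cdrforge

Design of **non-combinatorial synthetic antibody CDR repertoires** and NGS
QC of the libraries built from them.

Synthetic antibody libraries usually diversify the complementarity
determining regions (CDRs) by random combinatorial synthesis of mono- or
trinucleotide units. That is cheap diversity, but it inevitably produces
clones with un-natural sequences and with post-translational-modification
(PTM) liability motifs — glycosylation sequons, deamidation/isomerization
dipeptides, oxidation-prone residues — that hurt developability. `cdrforge`
implements the alternative: every CDR in the library is an explicitly
simulated, individually vetted sequence, so the whole repertoire is
enumerable, nature-like, and motif-free *by construction*. The package is
for antibody engineers building phage/yeast-display libraries and for
bioinformaticians QC-ing them from sequencing data.

## The method

**Profiling.** Natural CDR sequences are compared with germline CDRs of the
same length; the germline with the fewest mismatches is taken as the
ancestor. From the assignments the profiler estimates the germline *usage*
frequencies and the somatic-hypermutation (SHM) *spectrum*: for germline
*g*, position *p* and residue *a* ≠ *g(p)*,

    spectrum[g][p][a] = #(sequences assigned to g with a at p) / #(assigned to g)

so that Σₐ spectrum[g][p][a] is the total mutation rate at that position.
CDR-H3, where V(D)J junctional diversity makes ancestors unidentifiable, is
modelled positionally instead: per-length per-position amino-acid
frequencies for the first *L*−3 residues plus a frequency table of the
terminal 3-residue units (the Kabat 100–102 tail inherited from the J
segment, Phe/Met–Asp–Tyr/Val consensus). Light-chain CDR3 is a hybrid:
germline/SHM head plus a per-position profile of the last 2–3 (J-derived)
residues.

**Design.** Candidates are drawn from those models — germline by usage,
then independent per-position substitutions; or length, positional columns
and a terminal unit for H3 — and every candidate is scanned, together with
two flanking framework residues per side, for N-X-S/T (X≠P), DG, NG, DP,
Cys and Met (Met allowed at Kabat H34 and H100, where it is common in
nature). Any hit rejects the candidate and a fresh one is drawn, so the
requested totals (7,836 CDR-H3; 1,000–1,500 per other region by default)
are exact. Germline CDRs that themselves carry DG/NG (common in CDR-H2)
are first sanitized to SG. The designed sequences are partitioned into
array-synthesis pools (≤3,918 oligos each), reverse-translated and flanked
with framework nucleotides, and six CDRs can be grafted into heavy + light
scaffolds to form an scFv.

**QC.** Merged reads of the constructed library are translated in all three
frames; the 5-residue terminal windows of FR1–FR4 serve as anchors (one
point mutation tolerated per window), and the inter-anchor segments are the
CDRs. Each CDR is classified in-frame → designed-length → designed-sequence,
feeding the library summary (per-region percentages, design coverage),
mutation statistics against germline, PTM motif percentages,
designed-vs-observed frequency agreement (r²), redundancy spectra, and the
functional-fraction and PTM-free estimators.

A synthetic-data module generates every input with known ground truth
(germline sets, natural repertoires, error-bearing reads), so the whole
pipeline is testable offline.

## Worked example

```python
import cdrforge as cf
from cdrforge.regions import CdrRegion, Chain

germlines = cf.sanitize_germline(cf.germline_fixture())
scaffolds = cf.scaffold_fixture()

rep = cf.generate_natural_repertoire(
    cf.make_repertoire_spec(CdrRegion.H2, germlines, n=5000, seed=1), germlines)
profile = cf.build_shm_profile(rep, germlines)

bundle = cf.ProfileBundle(shm={CdrRegion.H2: profile})
config = cf.DesignConfig(targets={CdrRegion.H2: 1500}, seed=1)
design = cf.design_repertoire(CdrRegion.H2, config, bundle, scaffolds[Chain.HEAVY])
print(design.total, design.unique_count)
```

prints `1500 941`: 1,500 drawn CDR-H2 sequences of which 941 are unique —
the redundancy is emergent, mirroring how heavily each germline/position is
used in nature. Longer narratives live in `examples/` (profile → design →
pools/scFv → simulated reads → QC → desk estimators); running
`examples/05_desk_estimators.py` prints, from the published per-region QC
rates of a constructed library of this design,

```
functional scFv (heavy x mean light): 53.3%
PTM-free clones, heavy+kappa pairing:  79.7%
PTM-free clones, heavy+lambda pairing: 70.2%
```

i.e. about half of assembled clones display a full-length stop-free scFv
and 70–80% carry no PTM motif in any CDR.

A thin CLI mirrors the library:
`cdrforge profile|design|pools|assemble|simulate|qc` (see `--help`); every
subcommand writes a `run_manifest.json` with its seed and parameters.

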