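# Methods

## Scope and model

`cdrforge` treats an antibody variable domain as four fixed framework
regions (FR1–FR4) interleaved with three CDRs, with a single scaffold per
chain (heavy, kappa, lambda). Diversity is non-combinatorial: the library
is a finite, enumerated list of designed CDR sequences per region, not a
randomization scheme.

### Germline assignment

An observed CDR is compared only with germline CDRs of equal length and
assigned to the one at minimal Hamming distance; ties break
lexicographically by germline name (a determinism choice — natural data
rarely ties when germlines are well separated). Sequences with no
equal-length germline are "unassigned" and excluded from usage/spectrum
estimation; their count is reported. Coordinates are 0-based internally;
reports use Kabat-style labels (the CDR-H3 tail is 100–102).

### SHM model

Mutation is modelled at amino-acid level as an independent per-position
categorical substitution: position *p* of germline *g* mutates with the
profiled total rate Σₐ spectrum[g][p][a], and the replacement residue is
drawn from the normalized column. This reproduces exactly the positional
mutation frequencies that the profiler measures, which is the design target;
it deliberately ignores nucleotide-level mechanism (hotspot motifs,
transition bias, codon structure) and within-sequence mutation correlation.
Spectra are conditioned per germline; a pooled mode (shared across
germlines of equal length) is available on `build_shm_profile`.

### CDR-H3

Junctional (V(D)J) diversity makes germline ancestry of CDR-H3 impractical,
so H3 is modelled positionally per length (default range 9–20): independent
per-position frequencies over the first *L*−3 residues, and the last three
residues drawn jointly as one unit from a pooled terminal-3-mer table
(pooling across lengths is a modelling choice; the tail derives from the J
segment and is largely length-independent). Light-chain CDR3 uses the
hybrid scheme: SHM head over the first *L*−t residues, per-position tail
profile for the last *t*; *t* = 2 for CDRs of length ≤ 9, else 3
(configurable via `split_rule`).

### PTM policy

Liability motifs: N-X-S/T with X≠P (N-glycosylation), DG (isomerization),
NG (deamidation), DP (acid-labile cleavage), and the oxidation-prone
residues C and M. Met is exempt at Kabat H34 (4th residue of the 5-residue
CDR-H1) and H100 (first residue of the H3 terminal unit), where it is
common or predominant in natural antibodies. Design-time scanning includes
`junction_flank = 2` framework residues on each side of the CDR, enough for
any dipeptide or the 3-residue sequon to straddle the junction; hits lying
entirely in the flank are ignored. Germline CDRs containing DG/NG are
sanitized to SG *before* simulation (profiles, by contrast, are estimated
against the unsanitized germlines: SHM spectra describe nature, sanitization
is a design choice). Rejected candidates are redrawn until the target total
is reached, so totals are exact and unique counts emergent; an attempt
budget (1000 × target) guards against infeasible profile/policy
combinations.

### Pools, oligos, scFv

Designed repertoires are chunked in order into ⌈total/3,918⌉ pools
(3,918 = per-pool synthesis capacity); concatenating pools reconstitutes
the repertoire. Oligos are built with a single preferred codon per residue
(E. coli-biased, configurable) so reverse translation is deterministic and
round-trip safe; codon-usage optimization and thermodynamic QC (hairpins,
Tm) are out of scope. scFv assembly is plain concatenation
FR1·CDR1·FR2·CDR2·FR3·CDR3·FR4 + (G₄S)₃ linker + light domain.

### Read annotation

Reads are translated in all three frames. The six anchors (5-residue
terminal windows of the FRs) are searched left-to-right with order
enforced in nucleotide coordinates; per anchor the best hit is the fewest
mismatches (≤1 per window by default, "point mutations allowed"), ties to
the earliest position. Searching all frames per anchor keeps CDRs
downstream of a frameshift recoverable. A CDR is *in frame* iff its
inter-anchor nucleotide length is positive, ≡0 (mod 3) and stop-free;
*designed length* and *designed sequence* are membership tests against the
designed repertoire, giving the invariant hierarchy
designed_sequence ⇒ designed_length ⇒ in_frame. A read with <2 anchors gets
frame `None` and false flags, never an exception. Framework mutation rates
are counted over the FR segments that are unambiguously recoverable
(bounded by found anchors, or extending a terminal anchor by the reference
FR length), which slightly undercounts FRs disrupted by indels.

### Estimators

Per-region percentages are computed over reads where the region was
resolvable; never-resolved regions report `None`, not zero. The
functional-domain estimate per chain is the product of its three in-frame
fractions (independence assumption); functional scFv = heavy × mean(kappa,
lambda). PTM-free per chain = Π(1 − Total/100) over its regions, reported
separately for heavy×kappa and heavy×lambda; chain-level functional rates
are also measured directly read-wise (all CDRs in frame, no stop), since
the product and the direct measurement can differ when region failures are
correlated within reads. Designed-vs-observed agreement is the squared
Pearson correlation of linear relative frequencies over designed sequences
actually observed (≥3 shared sequences required, else undefined).
Selected-vs-unselected rate comparisons use a two-sided two-proportion
z-test (`statsmodels`); the choice of test is a convention, not dictated by
the design.

## Synthetic data: what it emulates and what it does not

The generator produces (i) natural repertoires — usage-drawn germline with
independent per-position substitutions from an explicit truth table, at
default sizes 8,846 heavy / 3,110 kappa / 2,440 lambda sequences; (ii)
CDR-H3 repertoires from a positional truth model (lengths 9–20 peaked at
12–13, Gly/Tyr/Ser/Asp/Arg-rich composition with per-position jitter,
terminal units headed by FDY/MDV); and (iii) merged reads of assembled
scFv clones with substitution/insertion/deletion errors applied within the
CDR nucleotide spans (array-synthesized oligos are where synthesis errors
live; PCR-amplified framework segments are taken as faithful) plus optional
per-read stop injection. A `proofread` flag discards reads with any
out-of-frame or stop-containing CDR, emulating the outcome of one round of
anti-tag display panning; because longer CDRs accumulate more indels,
length-biased depletion of long CDRs emerges without being programmed.

Default per-position substitution rates (H1 0.16, H2 0.13, K1 0.06,
K2/K3 0.07, L1 0.075, L2/L3 0.09) put the expected mutations/CDR in the
0.5–2.5 range typical of mature repertoires. Fixture germline CDRs and
frameworks are hand-written human-like synthetic stand-ins (no claim of
matching real V-gene database entries); equal-length germlines are kept at
pairwise Hamming ≥3 (≥4 for the 5-residue CDR-H1) so closest-ancestor
assignment of mutated offspring is near-unambiguous — real germline
families satisfy this at their lengths, and without it assignment
misattribution, not estimation error, dominates short-CDR spectra.

Passing tests therefore demonstrate internal consistency — the profiler
recovers generator truths, the designer is motif-free and nature-like under
its own profiles, the annotator is calibrated against the injected error
rates — not agreement with any particular organism's repertoire. Real IMGT
/ V-Base inputs have features the generator omits: indel SHM, allelic
variation, sequencing chimeras, clonal lineage structure, and
non-independent mutation.

## Numerical and scaling choices

All sampling uses Python's `random.Random` with explicit seeds; per-region
design streams derive deterministically from the config seed, so every
stochastic output is byte-reproducible. Profile frequency invariants are
enforced at 1e-9. Test problem sizes (n = 3,000–10,000 repertoires, read
depths 150–5,000) keep the full suite under a minute while leaving binomial
standard errors small against the asserted tolerances; recovery assertions
target usage for all germlines plus per-position rates of the dominant
germline(s), where counts make the 3-SE binomial model sound, rather than
hundreds of small-count cells at once.

## Known limitations

- Amino-acid-level SHM only; no nucleotide hotspots, no indel SHM, no VDJ
  junction reconstruction.
- Kabat CDR extraction is assumed done upstream for profiling inputs (the
  loaders take already-extracted region strings); the annotator's CDR
  boundaries are anchor-defined, not a full numbering engine.
- Read QC expects merged reads (pair merging, quality trimming and chimera
  detection are upstream); near-duplicate clustering is not performed.
- Independence assumptions in the functional and PTM-free estimators ignore
  within-read correlation of failures; the direct read-level functional
  measurement is reported alongside for that reason.
- The unassigned fraction of a repertoire contributes nothing to usage or
  spectra; with sparse germline sets this can bias profiles toward
  well-covered lengths.
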