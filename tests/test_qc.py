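"""Read annotation, library summaries, PTM/mutation statistics and estimators."""

import random

import pytest

import cdrforge as cf
from cdrforge.codons import reverse_translate
from cdrforge.datasets import LIBRARY_IN_FRAME_PCT, LIBRARY_TOTAL_PTM_PCT
from cdrforge.qc import CdrCall, ReadAnnotation
from cdrforge.regions import CdrRegion, Chain


def _scfv_read(designs, scaffolds, light=Chain.KAPPA, seed=0):
    rng = random.Random(seed)
    regions = (*CdrRegion.for_chain(Chain.HEAVY), *CdrRegion.for_chain(light))
    cdrs = {r: rng.choice(designs[r].sequences) for r in regions}
    h, l = scaffolds[Chain.HEAVY].fr_nucleotide, scaffolds[light].fr_nucleotide
    hr, lr = CdrRegion.for_chain(Chain.HEAVY), CdrRegion.for_chain(light)
    nt = {r: reverse_translate(cdrs[r]) for r in regions}
    read = (h[0] + nt[hr[0]] + h[1] + nt[hr[1]] + h[2] + nt[hr[2]] + h[3]
            + reverse_translate(cf.DEFAULT_LINKER)
            + l[0] + nt[lr[0]] + l[1] + nt[lr[1]] + l[2] + nt[lr[2]] + l[3])
    return read, cdrs


def _cdr_span(read, scaffolds, designs, region, light=Chain.KAPPA):
    """Locate a CDR's nt span in an error-free assembled read."""
    ann = cf.annotate_read(read, scaffolds[region.chain], designs)
    aa = ann.cdrs[region].sequence
    nt = reverse_translate(aa)
    start = read.index(nt)
    return start, start + len(nt)


class TestAnnotateRead:
    def test_error_free_read_fully_designed(self, designs, scaffolds):
        read, cdrs = _scfv_read(designs, scaffolds)
        for chain in (Chain.HEAVY, Chain.KAPPA):
            ann = cf.annotate_read(read, scaffolds[chain], designs)
            assert ann.frame is not None and not ann.has_stop
            for region in CdrRegion.for_chain(chain):
                call = ann.cdrs[region]
                assert call.in_frame and call.designed_length and call.designed_sequence
                assert call.sequence == cdrs[region]
            assert ann.fr_mismatches == 0 and ann.fr_residues > 0

    def test_single_deletion_breaks_frame_of_that_cdr_only(self, designs, scaffolds):
        read, _ = _scfv_read(designs, scaffolds, seed=1)
        s, e = _cdr_span(read, scaffolds, designs, CdrRegion.H2)
        mutated = read[:s + 3] + read[s + 4:]  # one nt deleted inside CDR-H2
        ann = cf.annotate_read(mutated, scaffolds[Chain.HEAVY], designs)
        assert not ann.cdrs[CdrRegion.H2].in_frame
        assert ann.cdrs[CdrRegion.H1].designed_sequence
        assert ann.cdrs[CdrRegion.H3].designed_sequence  # recovered in shifted frame

    def test_stop_codon_inside_cdr3(self, designs, scaffolds):
        read, _ = _scfv_read(designs, scaffolds, seed=2)
        s, e = _cdr_span(read, scaffolds, designs, CdrRegion.H3)
        mutated = read[:s + 3] + "TAG" + read[s + 6:]
        ann = cf.annotate_read(mutated, scaffolds[Chain.HEAVY], designs)
        assert ann.has_stop
        assert not ann.cdrs[CdrRegion.H3].in_frame

    def test_point_mutation_in_anchor_tolerated(self, designs, scaffolds):
        read, cdrs = _scfv_read(designs, scaffolds, seed=3)
        sc = scaffolds[Chain.HEAVY]
        # mutate one residue inside the fr2_start anchor window
        anchor_nt = sc.fr_nucleotide[1][:15]
        i = read.index(anchor_nt)
        mutated = read[:i] + "GCA" + read[i + 3:]  # first anchor codon -> Ala
        ann = cf.annotate_read(mutated, sc, designs)
        assert ann.cdrs[CdrRegion.H1].designed_sequence
        assert ann.fr_mismatches >= 1

    def test_unrelated_read_reports_no_frame(self, scaffolds):
        ann = cf.annotate_read("ACGT" * 100, scaffolds[Chain.HEAVY])
        assert ann.frame is None
        assert all(not c.resolved for c in ann.cdrs.values())

    def test_flag_hierarchy_under_errors(self, designs, scaffolds):
        spec = cf.ReadSimSpec(designs=designs, light_chain=Chain.LAMBDA, depth=300,
                              substitution_rate=0.003, deletion_rate=0.002,
                              insertion_rate=0.001, stop_inject_rate=0.05, seed=8)
        reads = cf.generate_library_reads(spec, scaffolds)
        for chain in (Chain.HEAVY, Chain.LAMBDA):
            for ann in cf.annotate_reads(reads, scaffolds[chain], designs):
                for call in ann.cdrs.values():
                    assert call.designed_sequence <= call.designed_length <= call.in_frame


class TestSummarizeLibrary:
    def _toy_annotations(self, n_total, n_in_frame):
        anns = []
        for i in range(n_total):
            ok = i < n_in_frame
            call = CdrCall(resolved=True, sequence="SYAMS" if ok else None,
                           nt_length=15, in_frame=ok, designed_length=ok,
                           designed_sequence=ok)
            anns.append(ReadAnnotation(f"r{i}", Chain.HEAVY, 0, {CdrRegion.H1: call}))
        return anns

    def test_in_frame_percentage(self):
        report = cf.summarize_library(self._toy_annotations(10, 9))
        assert report.regions[CdrRegion.H1].in_frame_pct == 90.0

    def test_design_coverage(self):
        anns = self._toy_annotations(10, 10)
        design = cf.DesignedRepertoire(
            CdrRegion.H1, ["SYAMS", "DYYMH", "NAWMS", "SYWIG", "TYAVH"])
        report = cf.summarize_library(anns, {CdrRegion.H1: design})
        # 1 of 5 unique designed sequences observed
        assert report.regions[CdrRegion.H1].design_coverage_pct == 20.0

    def test_all_designed_reads_give_100(self, designs, scaffolds):
        spec = cf.ReadSimSpec(designs=designs, light_chain=Chain.KAPPA, depth=150, seed=4)
        reads = cf.generate_library_reads(spec, scaffolds)
        anns = (cf.annotate_reads(reads, scaffolds[Chain.HEAVY], designs)
                + cf.annotate_reads(reads, scaffolds[Chain.KAPPA], designs))
        report = cf.summarize_library(anns, designs)
        for region in (*CdrRegion.for_chain(Chain.HEAVY), *CdrRegion.for_chain(Chain.KAPPA)):
            st = report.regions[region]
            assert st.in_frame_pct == st.designed_length_pct == st.designed_sequence_pct == 100.0
        assert report.chains[Chain.HEAVY].functional_pct == 100.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            cf.summarize_library([])


class TestMutationStatistics:
    def test_arithmetic_mean(self, germlines):
        g = germlines.for_region(CdrRegion.K2)[0].sequence  # motif-free germline
        variants = [g, g[:1] + "W" + g[2:], "W" + g[1:3] + "W" + g[4:], g[:1] + "W" + g[2:]]
        stats = cf.mutation_statistics({CdrRegion.K2: variants}, germlines)
        assert stats.mean_by_region[CdrRegion.K2] == 1.0
        assert stats.rate_by_region[CdrRegion.K2] == pytest.approx(4 / (4 * 7))

    def test_region_without_germlines_skipped(self, germlines):
        stats = cf.mutation_statistics({CdrRegion.H3: ["ARDYGGFDY"]}, germlines)
        assert CdrRegion.H3 not in stats.mean_by_region

    def test_fr_rate_zero_on_error_free_reads(self, designs, scaffolds, germlines):
        spec = cf.ReadSimSpec(designs=designs, light_chain=Chain.KAPPA, depth=50, seed=5)
        reads = cf.generate_library_reads(spec, scaffolds)
        anns = cf.annotate_reads(reads, scaffolds[Chain.HEAVY], designs)
        stats = cf.mutation_statistics({}, germlines, annotations=anns)
        assert stats.fr_rate_by_chain[Chain.HEAVY] == 0.0


class TestPtmStatistics:
    def test_direct_percentages(self):
        seqs = ["AASSLQS", "AADGLQS", "AASSLQS", "AASSLQS"]
        table = cf.ptm_statistics({CdrRegion.K2: seqs})
        assert table.loc["DG", "K2"] == 25.0
        assert table.loc["Total", "K2"] == 25.0

    def test_multi_motif_sequence_counts_once_in_total(self):
        seqs = ["AADGMQS", "AASSLQS"]  # DG and Met in the same sequence
        table = cf.ptm_statistics({CdrRegion.K2: seqs})
        assert table.loc["DG", "K2"] == 50.0
        assert table.loc["Met", "K2"] == 50.0
        assert table.loc["Total", "K2"] == 50.0

    def test_designed_repertoires_are_motif_free(self, designs):
        table = cf.ptm_statistics({r: d.sequences for r, d in designs.items()})
        assert (table.fillna(0.0) == 0.0).all().all()

    def test_total_subadditive(self, germlines):
        # natural (unfiltered) repertoires carry motifs; Total <= sum of rows
        seqs_by_region = {}
        for lbl in ("H2", "K1", "L3"):
            region = CdrRegion.from_label(lbl)
            spec = cf.make_repertoire_spec(region, germlines, n=2000, seed=13)
            seqs_by_region[region] = cf.generate_natural_repertoire(spec, germlines).sequences
        table = cf.ptm_statistics(seqs_by_region)
        motif_sum = table.drop(index="Total").sum()
        assert (table.loc["Total"] <= motif_sum + 1e-9).all()
        assert (table.loc["Total"] > 0).any()


class TestCompareDesign:
    def _annotations_from_counts(self, counts):
        anns = []
        i = 0
        for seq, c in counts.items():
            for _ in range(c):
                call = CdrCall(resolved=True, sequence=seq, nt_length=3 * len(seq),
                               in_frame=True, designed_length=True, designed_sequence=True)
                anns.append(ReadAnnotation(f"r{i}", Chain.HEAVY, 0, {CdrRegion.H1: call}))
                i += 1
        return anns

    def test_proportional_frequencies_give_r2_of_1(self):
        design = cf.DesignedRepertoire(
            CdrRegion.H1, ["SYAMS"] * 4 + ["DYYMH"] * 2 + ["NAWMS"])
        anns = self._annotations_from_counts({"SYAMS": 8, "DYYMH": 4, "NAWMS": 2})
        comp = cf.compare_design(anns, CdrRegion.H1, design)
        assert comp.r_squared == pytest.approx(1.0)

    def test_shuffled_counts_give_near_zero_r2(self, bundle, scaffolds):
        # H1 designs are highly redundant, so designed frequencies vary;
        # observed counts drawn independently of them should not correlate
        config = cf.DesignConfig(targets={CdrRegion.H1: 1000}, seed=21)
        design = cf.design_repertoire(CdrRegion.H1, config, bundle, scaffolds[Chain.HEAVY])
        rng = random.Random(0)
        uniq = sorted(design.unique_sequences())
        counts = {s: rng.randint(1, 20) for s in uniq}
        anns = self._annotations_from_counts(counts)
        # relabel the calls onto H1's region key
        comp = cf.compare_design(anns, CdrRegion.H1, design)
        assert comp.r_squared is not None and comp.r_squared < 0.05

    def test_all_distinct_reads_pile_at_n1(self):
        design = cf.DesignedRepertoire(CdrRegion.H1, ["SYAMS", "DYYMH", "NAWMS"])
        anns = self._annotations_from_counts({"SYAMS": 1, "DYYMH": 1, "NAWMS": 1})
        comp = cf.compare_design(anns, CdrRegion.H1, design)
        assert comp.redundancy_spectrum == {1: 3}

    def test_too_few_shared_sequences_undefined(self):
        design = cf.DesignedRepertoire(CdrRegion.H1, ["SYAMS", "DYYMH"])
        anns = self._annotations_from_counts({"SYAMS": 5, "DYYMH": 3})
        comp = cf.compare_design(anns, CdrRegion.H1, design)
        assert comp.r_squared is None

    def test_two_proportion_test_detects_difference(self):
        stat, p_diff = cf.proportion_comparison(80, 100, 50, 100)
        _, p_same = cf.proportion_comparison(52, 100, 50, 100)
        assert p_diff < 0.01 < p_same


class TestEstimators:
    def test_heavy_functional_from_published_in_frame_rates(self):
        out = cf.estimate_functional_fractions(LIBRARY_IN_FRAME_PCT)
        assert out["heavy"] == pytest.approx(91.3 * 89.7 * 90.3 / 1e4, abs=0.05)
        assert 73.5 < out["heavy"] < 74.5

    def test_all_100_gives_100(self):
        out = cf.estimate_functional_fractions({r: 100.0 for r in CdrRegion})
        assert out["scfv"] == pytest.approx(100.0)

    def test_missing_region_is_undefined(self):
        vals = {r: 90.0 for r in CdrRegion if r is not CdrRegion.L2}
        out = cf.estimate_functional_fractions(vals)
        assert out["lambda"] is None and out["scfv"] is None

    def test_ptm_free_products(self):
        out = cf.estimate_ptm_free_fraction(LIBRARY_TOTAL_PTM_PCT)
        assert out["heavy_kappa"] == pytest.approx(79.7, abs=0.1)
        assert out["heavy_lambda"] == pytest.approx(70.2, abs=0.1)

    def test_zero_totals_give_fully_free(self):
        out = cf.estimate_ptm_free_fraction({r: 0.0 for r in CdrRegion})
        assert out["heavy_kappa"] == 100.0 and out["burden_heavy_kappa"] == 0.0

    def test_saturated_region_gives_zero_free(self):
        vals = {r: 0.0 for r in CdrRegion}
        vals[CdrRegion.H3] = 100.0
        out = cf.estimate_ptm_free_fraction(vals)
        assert out["heavy_kappa"] == 0.0
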