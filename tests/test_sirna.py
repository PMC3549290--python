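"""smallrna_profiling: filtering, nat-siRNA assignment, bias, density, context."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cisnat import (
    AnnotationSet,
    CisNatPair,
    GenomeInterval,
    SmallRnaRead,
    TranscriptModel,
    ValidationError,
    assign_nat_sirnas,
    classify_strand_bias,
    filter_small_rnas,
    overlap_exclusivity,
    sequence_stats,
    sirna_density,
)
from cisnat.sirna import build_profile, classify_genomic_context, flank_intervals


def tx(tid, strand, exons, biotype="ncRNA", chrom="chr1", locus=None):
    return TranscriptModel(
        tid, locus or tid, chrom, strand,
        [GenomeInterval(chrom, s, e, strand) for s, e in exons], biotype,
    )


def read(rid, start, end, strand="+", chrom="chr1", copies=1, first_nt="A"):
    return SmallRnaRead(
        rid, GenomeInterval(chrom, start, end, strand), copies, first_nt
    )


def simple_pair(overlap=((150, 200),), plus="P", minus="M"):
    return CisNatPair(
        plus_transcript=plus,
        minus_transcript=minus,
        chrom="chr1",
        overlap_intervals=tuple(overlap),
        overlap_length=sum(e - s for s, e in overlap),
        orientation="enclosed",
    )


class TestFilter:
    def test_length_boundaries(self):
        reads = [
            read("r17", 0, 17), read("r18", 100, 118),
            read("r34", 200, 234), read("r35", 300, 335),
        ]
        kept = {r.read_id for r in filter_small_rnas(reads)}
        assert kept == {"r18", "r34"}

    def test_read_inside_rrna_feature_is_removed(self):
        ann = AnnotationSet([tx("R", "+", [(100, 300)], "rRNA")])
        reads = [read("in", 150, 171), read("out", 400, 421)]
        kept = {r.read_id for r in filter_small_rnas(reads, ann)}
        assert kept == {"out"}

    def test_organelle_reads_are_removed(self):
        reads = [read("mito", 0, 21, chrom="chrM"), read("nuc", 0, 21, chrom="chr1")]
        kept = {r.read_id for r in filter_small_rnas(reads)}
        assert kept == {"nuc"}

    def test_planted_filter_counts(self):
        # 100 reads: 10 in excluded features, 5 out of range -> 85 survive
        ann = AnnotationSet([tx("R", "+", [(5000, 5400)], "tRNA")])
        reads = [read(f"ok{i}", 10 * i, 10 * i + 21) for i in range(85)]
        reads += [read(f"ex{i}", 5000 + 20 * i, 5021 + 20 * i) for i in range(10)]
        reads += [read(f"sh{i}", 9000 + 20 * i, 9016 + 20 * i) for i in range(5)]
        assert len(reads) == 100
        assert len(filter_small_rnas(reads, ann)) == 85


class TestAssignNatSirnas:
    def test_contained_read_is_assigned(self):
        plus, minus = assign_nat_sirnas([read("r", 160, 184)], simple_pair())
        assert [r.read_id for r in plus] == ["r"]
        assert minus == []

    def test_boundary_straddling_read_is_not_assigned(self):
        plus, minus = assign_nat_sirnas([read("r", 140, 164)], simple_pair())
        assert plus == minus == []

    def test_read_bridging_two_blocks_is_not_assigned(self):
        pair = simple_pair(overlap=((50, 100), (200, 250)))
        plus, minus = assign_nat_sirnas([read("r", 90, 210)], pair)
        assert plus == minus == []

    def test_strand_decides_attribution(self):
        plus, minus = assign_nat_sirnas(
            [read("p", 160, 184, "+"), read("m", 160, 184, "-")], simple_pair()
        )
        assert [r.read_id for r in plus] == ["p"]
        assert [r.read_id for r in minus] == ["m"]

    def test_agreement_with_per_base_containment_oracle(self):
        rng = np.random.default_rng(20240902)
        for _ in range(1000):
            n_blocks = int(rng.integers(1, 4))
            blocks, cursor = [], int(rng.integers(0, 50))
            for _ in range(n_blocks):
                w = int(rng.integers(26, 120))
                blocks.append((cursor, cursor + w))
                cursor += w + int(rng.integers(2, 60))
            pair = simple_pair(overlap=tuple(blocks))
            s = int(rng.integers(0, cursor + 40))
            r = read("r", s, s + int(rng.integers(18, 35)))
            plus, _ = assign_nat_sirnas([r], pair)
            block_bases = {p for bs, be in blocks for p in range(bs, be)}
            oracle = all(
                p in block_bases for p in range(r.interval.start, r.interval.end)
            )
            assert (len(plus) == 1) == oracle


class TestStrandBias:
    def test_zero_minus_count_is_one_strand_plus(self):
        assert classify_strand_bias(10, 0) == "one-strand-plus"
        assert classify_strand_bias(0, 10) == "one-strand-minus"

    def test_fivefold_threshold_arithmetic(self):
        assert classify_strand_bias(10, 2, fold=5) == "plus-biased"
        assert classify_strand_bias(10, 2, fold=2) == "plus-biased"
        assert classify_strand_bias(9, 2, fold=5) == "balanced"

    def test_twofold_threshold(self):
        assert classify_strand_bias(4, 8, fold=2) == "minus-biased"

    def test_both_zero_is_balanced(self):
        assert classify_strand_bias(0, 0) == "balanced"

    def test_negative_fold_is_a_contract_violation(self):
        with pytest.raises(ValidationError):
            classify_strand_bias(1, 1, fold=-1)

    def test_negative_counts_are_rejected(self):
        with pytest.raises(ValidationError):
            classify_strand_bias(-1, 0)


class TestDensity:
    def _fixture(self):
        # plus member [0,1500), minus [500,1000): overlap 500, flank 1000+500
        ann = AnnotationSet([
            tx("P", "+", [(0, 1500)]), tx("M", "-", [(500, 1000)]),
        ])
        pair = CisNatPair("P", "M", "chr1", ((500, 1000),), 500, "enclosed")
        return ann, pair

    def test_overlap_density_is_reads_per_kb(self):
        ann, pair = self._fixture()
        reads = [read(f"r{i}", 510 + 20 * i, 531 + 20 * i) for i in range(10)]
        d_ov, d_fl, ratio, enriched = sirna_density(pair, reads, ann)
        assert d_ov == pytest.approx(20.0)  # 10 reads / 0.5 kb
        assert d_fl == 0.0 and math.isinf(ratio) and enriched

    def test_enrichment_ratio_and_flag(self):
        ann, pair = self._fixture()
        overlap_reads = [read(f"o{i}", 510 + 20 * i, 531 + 20 * i) for i in range(10)]
        flank_reads = [read(f"f{i}", 10 + 30 * i, 31 + 30 * i) for i in range(4)]
        d_ov, d_fl, ratio, enriched = sirna_density(
            pair, overlap_reads + flank_reads, ann
        )
        assert d_ov == pytest.approx(20.0)
        assert d_fl == pytest.approx(4.0)  # 4 reads / 1.0 kb of flank
        assert ratio == pytest.approx(5.0)
        assert not enriched  # strictly greater than the threshold is required

    def test_no_flank_reads_gives_infinite_ratio_and_enriched(self):
        ann, pair = self._fixture()
        reads = [read("o", 510, 531)]
        _, _, ratio, enriched = sirna_density(pair, reads, ann)
        assert math.isinf(ratio) and enriched

    def test_flank_is_exon_union_minus_overlap(self):
        ann, pair = self._fixture()
        assert flank_intervals(pair, ann) == [(0, 500), (1000, 1500)]


class TestExclusivity:
    def _fixture(self):
        ann = AnnotationSet([
            tx("P", "+", [(0, 1500)]), tx("M", "-", [(500, 1000)]),
        ])
        pair = CisNatPair("P", "M", "chr1", ((500, 1000),), 500, "enclosed")
        return ann, pair

    def test_six_reads_all_in_overlap_is_exclusive(self):
        ann, pair = self._fixture()
        reads = [read(f"r{i}", 510 + 20 * i, 531 + 20 * i) for i in range(6)]
        assert overlap_exclusivity(pair, reads, ann)

    def test_one_flank_read_breaks_exclusivity(self):
        ann, pair = self._fixture()
        reads = [read(f"r{i}", 510 + 20 * i, 531 + 20 * i) for i in range(10)]
        reads.append(read("fl", 100, 121))
        assert not overlap_exclusivity(pair, reads, ann)

    def test_five_reads_is_below_the_strict_threshold(self):
        ann, pair = self._fixture()
        reads = [read(f"r{i}", 510 + 20 * i, 531 + 20 * i) for i in range(5)]
        assert not overlap_exclusivity(pair, reads, ann)

    def test_reads_elsewhere_in_the_genome_are_ignored(self):
        ann, pair = self._fixture()
        reads = [read(f"r{i}", 510 + 20 * i, 531 + 20 * i) for i in range(6)]
        reads.append(read("far", 9000, 9021))
        reads.append(read("other", 100, 121, chrom="chr2"))
        assert overlap_exclusivity(pair, reads, ann)


class TestSequenceStats:
    def test_length_histogram(self):
        reads = [read("a", 0, 21), read("b", 0, 24), read("c", 0, 24)]
        hist, _ = sequence_stats(reads)
        assert hist == {21: 1, 24: 2}

    def test_first_nucleotide_frequencies(self):
        reads = [
            read("a", 0, 21, first_nt="A"),
            read("b", 0, 21, first_nt="A"),
            read("c", 0, 21, first_nt="G"),
        ]
        _, freqs = sequence_stats(reads)
        assert freqs["A"] == pytest.approx(2 / 3)
        assert freqs["G"] == pytest.approx(1 / 3)
        assert freqs["C"] == freqs["T"] == 0.0

    def test_unknown_first_nucleotide_excluded_from_denominator(self):
        reads = [read("a", 0, 21, first_nt="A"), read("n", 0, 21, first_nt="N")]
        _, freqs = sequence_stats(reads)
        assert freqs["A"] == pytest.approx(1.0)

    def test_empty_input_reports_zero_frequencies(self):
        hist, freqs = sequence_stats([])
        assert hist == {}
        assert set(freqs.values()) == {0.0}


class TestGenomicContext:
    def _ann(self):
        return AnnotationSet([
            tx("TE", "+", [(1000, 2000)], "transposon"),
            tx("G", "+", [(5000, 5200), (5400, 5600)], "CDS-p"),
            tx("H", "-", [(9000, 9500)], "CDS-n"),
        ])

    def test_transposon_takes_precedence(self):
        assert classify_genomic_context(read("r", 1100, 1121), self._ann()) == "transposon"

    def test_exon_and_intron(self):
        ann = self._ann()
        assert classify_genomic_context(read("r", 5050, 5071), ann) == "exon"
        assert classify_genomic_context(read("r", 5250, 5271), ann) == "intron"

    def test_upstream_is_strand_aware(self):
        ann = self._ann()
        # 200 bp 5' of + strand gene G
        assert classify_genomic_context(read("r", 4800, 4821), ann) == "upstream"
        # 3' of G is downstream
        assert classify_genomic_context(read("r", 5700, 5721), ann) == "downstream"
        # 5' of - strand gene H lies to its right
        assert classify_genomic_context(read("r", 9600, 9621), ann) == "upstream"

    def test_far_from_everything_is_intergenic(self):
        assert classify_genomic_context(read("r", 50000, 50021), self._ann()) == "intergenic"


class TestProfileInvariants:
    def test_counts_conserve_and_contain(self, run_result):
        pair_by_id = {p.pair_id: p for p in run_result.representatives}
        for (pid, _cond), prof in run_result.profiles.items():
            assert prof.plus_unique >= 0 and prof.minus_unique >= 0
            assert prof.plus_total >= prof.plus_unique
            assert prof.minus_total >= prof.minus_unique
            assert prof.n_unique == prof.plus_unique + prof.minus_unique
            assert prof.density_overlap >= 0 and prof.density_flank >= 0
            assert pid in pair_by_id

    def test_exclusive_profiles_have_all_reads_in_overlap(self, run_result, bundle):
        from cisnat import io as cio

        ann = cio.read_gff3(bundle["paths"]["annotation"])
        cond = bundle["config"].conditions[0]
        reads = filter_small_rnas(
            cio.read_smallrna_bed(bundle["paths"][f"smallrna_{cond}"]), ann
        )
        pair_by_id = {p.pair_id: p for p in run_result.representatives}
        checked = 0
        for (pid, c), prof in run_result.profiles.items():
            if c != cond or not prof.exclusive:
                continue
            pair = pair_by_id[pid]
            exons = [
                (e.start, e.end)
                for tid in (pair.plus_transcript, pair.minus_transcript)
                for e in ann[tid].exons
            ]
            for r in reads:
                iv = r.interval
                if iv.chrom != pair.chrom:
                    continue
                touches = any(s < iv.end and iv.start < e for s, e in exons)
                if touches:
                    assert pair.contains_interval(iv.start, iv.end)
            checked += 1
        assert checked > 0

    def test_planted_bias_classes_recover_on_default_fixture(self, run_result, bundle):
        # stochastic step: >= 95% aggregate recovery is the documented property
        truth = bundle["truth"]["pairs"]
        n = ok = 0
        for (pid, _cond), prof in run_result.profiles.items():
            planted = truth.get(pid, {}).get("bias_class")
            if not planted:
                continue
            n += 1
            ok += prof.bias_class == planted
        assert n >= 200
        assert ok / n >= 0.95

    def test_build_profile_matches_component_functions(self, bundle, run_result):
        from cisnat import io as cio

        ann = cio.read_gff3(bundle["paths"]["annotation"])
        cond = bundle["config"].conditions[0]
        reads = filter_small_rnas(
            cio.read_smallrna_bed(bundle["paths"][f"smallrna_{cond}"]), ann
        )
        pair = run_result.representatives[0]
        prof = build_profile(pair, reads, cond, ann)
        plus, minus = assign_nat_sirnas(reads, pair)
        assert prof.plus_unique == len(plus)
        assert prof.minus_unique == len(minus)
        assert prof.bias_class == classify_strand_bias(len(plus), len(minus))
        assert prof.exclusive == overlap_exclusivity(pair, reads, ann)
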