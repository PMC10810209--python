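import random

import pytest

from oracles import (
    brute_force_covered_bp,
    brute_force_merge,
    brute_force_overlap_flags,
    brute_force_region_hits,
)

from maecall.annotate import (
    GeneModel,
    LoopSet,
    PeakSet,
    Transcript,
    annotate_feature,
    annotate_features,
    classify_accessibility,
    classify_known_novel,
    distance_to_tss,
    extend_peaks,
    merge_intervals,
    overlap_any,
    overlap_fraction_threshold,
    overlap_loop_anchors,
)
from maecall.formats import GenomicInterval as GI


class TestExtendPeaks:
    def test_clamp_at_zero(self):
        ps = PeakSet("H3K4me1", [GI("chr1", 100, 125)])
        (iv,) = extend_peaks(ps, 2500).intervals
        assert (iv.start, iv.end) == (0, 2625)

    def test_pad_zero_identity(self):
        ivs = [GI("chr1", 10, 20), GI("chr1", 100, 200)]
        assert extend_peaks(PeakSet("x", ivs), 0).intervals == ivs

    def test_nearby_peaks_merge(self):
        ps = PeakSet("x", [GI("chr1", 10_000, 10_100), GI("chr1", 14_100, 14_200)])
        merged = extend_peaks(ps, 2500).intervals
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (7500, 16700)

    def test_merge_matches_brute_force(self, random_intervals):
        ivs = random_intervals(60)
        expected = brute_force_merge(ivs)
        got = [(iv.chrom, iv.start, iv.end) for iv in merge_intervals(ivs)]
        assert sorted(got) == sorted(expected)


class TestOverlapAny:
    def test_one_bp_overlap(self):
        flags, _ = overlap_any([GI("chr1", 100, 125)], [GI("chr1", 124, 200)])
        assert flags == [True]

    def test_half_open_adjacency(self):
        flags, _ = overlap_any([GI("chr1", 100, 125)], [GI("chr1", 125, 200)])
        assert flags == [False]

    def test_matches_all_pairs_scan(self, random_intervals):
        loci = random_intervals(100)
        regions = random_intervals(20)
        flags, summary = overlap_any(loci, regions)
        assert flags == brute_force_overlap_flags(loci, regions)
        hits = brute_force_region_hits(loci, regions)
        assert summary.frac_loci_hit == pytest.approx(sum(flags) / len(loci))
        assert summary.frac_regions_hit == pytest.approx(sum(hits) / len(regions))

    def test_large_instance_against_oracle(self, random_intervals):
        loci = random_intervals(1000)
        regions = random_intervals(1000)
        flags, _ = overlap_any(loci, regions)
        assert flags == brute_force_overlap_flags(loci, regions)

    def test_padding_monotonicity(self, random_intervals):
        loci = random_intervals(50)
        ps = PeakSet("x", random_intervals(10))
        fracs = []
        for pad in (0, 500, 2500):
            _, summary = overlap_any(loci, ps.padded_intervals(pad))
            fracs.append(summary.frac_loci_hit)
        assert fracs == sorted(fracs)


class TestOverlapFractionThreshold:
    def test_30_percent_arithmetic(self):
        locus = GI("chr1", 100, 125)
        regions = [GI("chr1", 117, 200)]  # 8 bp of 25 = 0.32
        assert overlap_fraction_threshold([locus], regions, 0.3) == [True]
        assert overlap_fraction_threshold([locus], regions, 0.9) == [False]

    def test_full_containment(self):
        locus = GI("chr1", 100, 125)
        assert overlap_fraction_threshold([locus], [GI("chr1", 0, 1000)], 1.0) == [True]

    def test_union_not_double_counted(self):
        locus = GI("chr1", 100, 125)
        # two stacked copies of the same 8-bp region still cover only 8 bp
        regions = [GI("chr1", 117, 125), GI("chr1", 117, 125)]
        assert overlap_fraction_threshold([locus], regions, 0.5) == [False]

    def test_covered_bp_matches_per_base_oracle(self, random_intervals):
        loci = random_intervals(30, max_pos=2000, max_len=60)
        regions = random_intervals(15, max_pos=2000, max_len=120)
        for threshold in (0.1, 0.3, 0.9):
            got = overlap_fraction_threshold(loci, regions, threshold)
            expected = [
                brute_force_covered_bp(l, regions) / l.length >= threshold for l in loci
            ]
            assert got == expected

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            overlap_fraction_threshold([], [], 0.0)


class TestKnownNovel:
    def test_direct_hit_is_known(self):
        atlas = PeakSet("EnhancerAtlas", [GI("chr1", 0, 1000)])
        labels, _ = classify_known_novel([GI("chr1", 100, 125)], [atlas])
        assert labels == ["known"]

    def test_padded_hit_is_known(self):
        k4 = PeakSet("H3K4me1", [GI("chr1", 10_000, 10_500)], pad=2500)
        locus = GI("chr1", 10_500 + 2400, 10_500 + 2425)  # 2400 bp past the edge
        labels, per_dataset = classify_known_novel([locus], [k4])
        assert labels == ["known"]
        assert per_dataset["H3K4me1"] == [True]

    def test_no_overlap_is_novel(self):
        k4 = PeakSet("H3K4me1", [GI("chr2", 0, 100)])
        labels, _ = classify_known_novel([GI("chr1", 0, 25)], [k4])
        assert labels == ["novel"]

    def test_partition_property(self, random_intervals):
        loci = random_intervals(200)
        datasets = [
            PeakSet("a", random_intervals(10), pad=2500),
            PeakSet("b", random_intervals(10)),
        ]
        labels, _ = classify_known_novel(loci, datasets)
        assert all(lab in ("known", "novel") for lab in labels)
        assert len(labels) == len(loci)

    def test_requires_evidence(self):
        with pytest.raises(ValueError):
            classify_known_novel([GI("chr1", 0, 25)], [])


class TestAccessibility:
    def test_dhs_hit_open(self):
        dhs = PeakSet("DNase", [GI("chr1", 0, 1000)])
        atac = PeakSet("ATAC", [])
        assert classify_accessibility([GI("chr1", 10, 35)], dhs, atac) == ["open"]

    def test_no_hit_closed(self):
        dhs = PeakSet("DNase", [GI("chr2", 0, 100)])
        assert classify_accessibility([GI("chr1", 10, 35)], dhs=dhs) == ["closed"]

    def test_atac_only_union(self):
        dhs = PeakSet("DNase", [GI("chr2", 0, 100)])
        atac = PeakSet("ATAC", [GI("chr1", 0, 100)])
        assert classify_accessibility([GI("chr1", 10, 35)], dhs, atac) == ["open"]


def _transcript_plus():
    # + strand transcript chr1:1000-5000, exons [1000,1500), [3000,5000),
    # CDS (thick) 1200-4500: 5'UTR [1000,1200), 3'UTR [4500,5000)
    return Transcript(
        chrom="chr1",
        strand="+",
        start=1000,
        end=5000,
        exons=(GI("chr1", 1000, 1500), GI("chr1", 3000, 5000)),
        thick_start=1200,
        thick_end=4500,
        name="tx1",
    )


class TestFeatureAnnotation:
    model = GeneModel([_transcript_plus()])

    def test_tts_window_plus_strand(self):
        # 50 bp downstream of the + strand transcript end
        assert annotate_feature(GI("chr1", 5050, 5075), self.model) == "TTS"
        # just inside the -100 edge
        assert annotate_feature(GI("chr1", 4901, 4926), self.model) == "TTS"

    def test_tts_window_minus_strand(self):
        minus = Transcript(
            chrom="chr1", strand="-", start=1000, end=5000,
            exons=(GI("chr1", 1000, 5000),), thick_start=1000, thick_end=5000,
        )
        model = GeneModel([minus])
        # TTS of a - strand transcript is its start; window extends 1 kb left
        assert annotate_feature(GI("chr1", 400, 425), model) == "TTS"
        assert annotate_feature(GI("chr1", 2000, 2025), model) == "exon"

    def test_utr_categories(self):
        assert annotate_feature(GI("chr1", 1050, 1075), self.model) == "5UTR"
        assert annotate_feature(GI("chr1", 4600, 4625), self.model) == "3UTR"

    def test_exon_and_intron(self):
        assert annotate_feature(GI("chr1", 3500, 3525), self.model) == "exon"
        assert annotate_feature(GI("chr1", 2000, 2025), self.model) == "intron"

    def test_intergenic(self):
        assert annotate_feature(GI("chr1", 50_000, 50_025), self.model) == "intergenic"
        assert annotate_feature(GI("chr2", 1000, 1025), self.model) == "intergenic"

    def test_priority_exon_over_intron(self):
        # second transcript whose exon covers the first transcript's intron
        other = Transcript(
            chrom="chr1", strand="+", start=1800, end=2600,
            exons=(GI("chr1", 1800, 2600),), thick_start=1800, thick_end=2600,
        )
        model = GeneModel([_transcript_plus(), other])
        assert annotate_feature(GI("chr1", 2000, 2025), model) == "exon"

    def test_every_locus_gets_exactly_one_category(self, random_intervals):
        loci = random_intervals(100, max_pos=8000)
        cats = annotate_features(loci, self.model)
        assert len(cats) == len(loci)
        assert set(cats) <= {"TTS", "5UTR", "3UTR", "exon", "intron", "intergenic"}

    def test_empty_model_all_intergenic(self):
        cats = annotate_features([GI("chr1", 0, 25), GI("chr2", 5, 30)], GeneModel([]))
        assert cats == ["intergenic", "intergenic"]


class TestBed12:
    def test_parse(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t1000\t5000\ttx1\t0\t+\t1200\t4500\t0\t2\t500,2000,\t0,2000,\n"
        )
        model = GeneModel.from_bed12(p)
        (t,) = model.transcripts
        assert t.tss == 1000 and t.tts == 5000
        assert [(e.start, e.end) for e in t.exons] == [(1000, 1500), (3000, 5000)]
        assert [(u.start, u.end) for u in t.utr5()] == [(1000, 1200)]
        assert [(u.start, u.end) for u in t.utr3()] == [(4500, 5000)]
        assert [(i.start, i.end) for i in t.introns()] == [(1500, 3000)]


class TestDistanceToTss:
    model = GeneModel(
        [
            _transcript_plus(),
            Transcript(
                chrom="chr1", strand="-", start=9000, end=12_000,
                exons=(GI("chr1", 9000, 12_000),), thick_start=9000, thick_end=12_000,
            ),
        ]
    )

    def test_midpoint_at_tss(self):
        # locus [988, 1013) midpoint 1000 == tx1 TSS
        assert distance_to_tss(GI("chr1", 988, 1013), self.model) == 0

    def test_simple_distance(self):
        assert distance_to_tss(GI("chr1", 0, 24), self.model) == 988  # mid 12 → 1000

    def test_nearest_of_several(self):
        # midpoint 7000: TSS candidates 1000 (+) and 12000 (-) → 5000 wins
        assert distance_to_tss(GI("chr1", 6988, 7013), self.model) == 5000

    def test_unannotated_chromosome(self):
        assert distance_to_tss(GI("chrX", 0, 25), self.model) is None

    def test_matches_brute_force_scan(self, rng):
        tss_positions = [t.tss for t in self.model.transcripts]
        for _ in range(50):
            start = rng.randrange(0, 20_000)
            locus = GI("chr1", start, start + 25)
            expected = min(abs(locus.midpoint() - p) for p in tss_positions)
            assert distance_to_tss(locus, self.model) == expected


class TestLoopAnchors:
    loops = LoopSet(
        [
            (GI("chr1", 1000, 2000), GI("chr1", 50_000, 51_000)),
            (GI("chr2", 0, 500), GI("chr2", 9000, 9500)),
        ]
    )

    def test_hit_first_anchor(self):
        hits = overlap_loop_anchors([GI("chr1", 1500, 1525)], self.loops)
        assert hits.flags == [True]
        assert hits.n_flagged == 1
        assert hits.spans[0] == [49_000]  # midpoint distance 50500 - 1500

    def test_between_anchors_not_flagged(self):
        hits = overlap_loop_anchors([GI("chr1", 10_000, 10_025)], self.loops)
        assert hits.flags == [False]

    def test_matches_all_pairs_scan(self, random_intervals, rng):
        loci = random_intervals(50)
        loops = LoopSet(
            [
                (
                    GI("chr1", rng.randrange(0, 9000), rng.randrange(9000, 10_000)),
                    GI("chr1", rng.randrange(10_000, 19_000), rng.randrange(19_000, 20_000)),
                )
                for _ in range(10)
            ]
        )
        hits = overlap_loop_anchors(loci, loops)
        anchors = [iv for pair in loops.loops for iv in pair]
        assert hits.flags == brute_force_overlap_flags(loci, anchors)
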