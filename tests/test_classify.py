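"""Strand inference from TSS evidence and category assignment rules."""

import numpy as np
import pytest

from ripcall import (
    AMBIGUOUS,
    Feature,
    FeatureKind,
    GenomeAnnotation,
    Peak,
    PeakCategory,
    PipelineConfig,
    SimulationConfig,
    TssRecord,
    call_peaks,
    classify_peak,
    classify_peaks,
    compute_coverage,
    generate_annotation,
    infer_strand,
    simulate_reads,
    summarize_categories,
)


class TestInferStrand:
    def test_single_upstream_plus_tss(self, config):
        peak = Peak(id="p", start=1000, end=1200)
        assert infer_strand(peak, [TssRecord(900, "+")], config) == "+"

    def test_single_downstream_minus_tss(self, config):
        peak = Peak(id="p", start=1000, end=1200)
        assert infer_strand(peak, [TssRecord(1500, "-")], config) == "-"

    def test_no_tss_in_window_is_ambiguous(self, config):
        peak = Peak(id="p", start=1000, end=1200)
        tss = [TssRecord(400, "+"), TssRecord(1800, "-")]
        assert infer_strand(peak, tss, config) == AMBIGUOUS

    def test_outward_oriented_tss_do_not_vote(self, config):
        peak = Peak(id="p", start=1000, end=1200)
        # '-' TSS upstream of the peak points away from it, as does a '+'
        # TSS downstream of the peak end
        tss = [TssRecord(900, "-"), TssRecord(1300, "+")]
        assert infer_strand(peak, tss, config) == AMBIGUOUS

    def test_both_strands_supported_is_ambiguous(self, config):
        peak = Peak(id="p", start=1000, end=1200)
        tss = [TssRecord(900, "+"), TssRecord(1500, "-")]
        assert infer_strand(peak, tss, config) == AMBIGUOUS

    def test_truth_strand_recovered_on_synthetic_genomes(self):
        """Pooled over seeds, >=90% of enriched truth regions with a TSS
        get their true strand back."""

        def jaccard(a, b):
            inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
            return inter / ((a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter)

        pc = PipelineConfig()
        correct = total = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            ann, tss, truth = generate_annotation(cfg)
            ip, _ = simulate_reads(ann, truth, cfg)
            peaks = call_peaks(compute_coverage(ip, cfg.genome_length), pc)
            for r in truth.enriched():
                hits = [
                    p for p in peaks
                    if jaccard((r.start, r.end), (p.start, p.end)) >= 0.5
                ]
                if hits:
                    total += 1
                    if infer_strand(hits[0], tss, pc) == r.strand:
                        correct += 1
        assert total >= 80
        assert correct / total >= 0.9


class TestClassifyPeak:
    def test_housekeeping_beats_every_other_overlap(self, toy_annotation, config):
        peak = Peak(id="p", start=560, end=700)  # overlaps tRNA end
        assert (
            classify_peak(peak, toy_annotation, "+", config)
            is PeakCategory.TRNA_RRNA
        )

    def test_annotated_srna_feature(self, config):
        ann = GenomeAnnotation(
            "chr", 2_000_000,
            [Feature("FsrA", FeatureKind.SRNA, 1483560, 1483632, "-")],
        )
        peak = Peak(id="p", start=1483560, end=1483632)
        assert classify_peak(peak, ann, "-", config) is PeakCategory.SRNA

    def test_full_orf_coverage(self, toy_annotation, config):
        peak = Peak(id="p", start=1950, end=2650)  # contains cdsA entirely
        assert classify_peak(peak, toy_annotation, "+", config) is PeakCategory.ORF_FULL

    def test_start_codon_overlap_plus_strand(self, toy_annotation, config):
        peak = Peak(id="p", start=1940, end=2003)  # covers bases 2001-2003 only
        assert (
            classify_peak(peak, toy_annotation, "+", config) is PeakCategory.ORF_START
        )

    def test_start_codon_overlap_minus_strand(self, toy_annotation, config):
        # cdsB is on '-', so its start codon is 6298-6300
        peak = Peak(id="p", start=6298, end=6400)
        assert (
            classify_peak(peak, toy_annotation, "-", config) is PeakCategory.ORF_START
        )

    def test_stop_codon_overlap(self, toy_annotation, config):
        peak = Peak(id="p", start=2560, end=2700)  # covers cdsA stop 2598-2600
        assert (
            classify_peak(peak, toy_annotation, "+", config) is PeakCategory.ORF_STOP
        )

    def test_internal_fragment(self, toy_annotation, config):
        peak = Peak(id="p", start=2100, end=2400)
        assert (
            classify_peak(peak, toy_annotation, "+", config)
            is PeakCategory.ORF_INTERNAL
        )

    def test_both_codons_without_containment_is_unknown(self, config):
        ann = GenomeAnnotation(
            "chr", 10_000, [Feature("c", FeatureKind.CDS, 1000, 1299, "+")]
        )
        peak = Peak(id="p", start=1001, end=1299)  # misses base 1000 only
        assert classify_peak(peak, ann, "+", config) is PeakCategory.UNKNOWN

    def test_strand_mismatched_cds_is_ignored(self, toy_annotation, config):
        peak = Peak(id="p", start=2100, end=2400)  # inside cdsA, a '+' gene
        assert classify_peak(peak, toy_annotation, "-", config) is PeakCategory.UNKNOWN

    def test_ambiguous_strand_still_gets_orf_category(self, toy_annotation, config):
        peak = Peak(id="p", start=2100, end=2400)
        assert (
            classify_peak(peak, toy_annotation, AMBIGUOUS, config)
            is PeakCategory.ORF_INTERNAL
        )

    def test_intergenic_peak_without_tss_support_is_unknown(
        self, toy_annotation, config
    ):
        peak = Peak(id="p", start=3000, end=3200)
        assert (
            classify_peak(peak, toy_annotation, AMBIGUOUS, config)
            is PeakCategory.UNKNOWN
        )


class TestLeaderRule:
    def test_plus_strand_leader(self, toy_annotation, toy_tss, config):
        # TSS 1801 '+', cdsA starts 2001: leader spans 1801-2000
        peak = Peak(id="p", start=1820, end=1980)
        got = classify_peak(peak, toy_annotation, "+", config, tss=toy_tss)
        assert got is PeakCategory.LEADER

    def test_minus_strand_leader(self, toy_annotation, toy_tss, config):
        # TSS 6550 '-', cdsB ends 6300: leader spans 6301-6550
        peak = Peak(id="p", start=6330, end=6500)
        got = classify_peak(peak, toy_annotation, "-", config, tss=toy_tss)
        assert got is PeakCategory.LEADER

    def test_peak_past_start_codon_is_not_a_leader(
        self, toy_annotation, toy_tss, config
    ):
        peak = Peak(id="p", start=1900, end=2050)  # runs into cdsA
        got = classify_peak(peak, toy_annotation, "+", config, tss=toy_tss)
        assert got is not PeakCategory.LEADER

    def test_distant_tss_beyond_leader_max_is_rejected(
        self, toy_annotation, config
    ):
        tss = [TssRecord(1400, "+")]  # 601 bp upstream of cdsA start
        peak = Peak(id="p", start=1450, end=1600)
        got = classify_peak(peak, toy_annotation, "+", config, tss=tss)
        assert got is not PeakCategory.LEADER


class TestSummarize:
    def _peaks(self, categories, ratios):
        return [
            Peak(
                id=f"p{i}", start=100 * i + 1, end=100 * i + 60,
                rpkm_ratio=r, category=c,
            )
            for i, (c, r) in enumerate(zip(categories, ratios))
        ]

    def test_single_category_has_unit_proportion(self):
        peaks = self._peaks([PeakCategory.SRNA] * 4, [3, 4, 5, 6])
        table = summarize_categories(peaks).by_category
        assert list(table["category"]) == ["srna"]
        assert table["proportion"].iloc[0] == 1.0
        assert table["count"].iloc[0] == 4

    def test_counts_conserved_and_proportions_sum_to_one(self):
        rng = np.random.default_rng(31)
        cats = list(PeakCategory)
        peaks = self._peaks(
            [cats[i % len(cats)] for i in range(23)], rng.uniform(0, 50, 23)
        )
        table = summarize_categories(peaks).by_category
        assert int(table["count"].sum()) == 23
        assert table["proportion"].sum() == pytest.approx(1.0)

    def test_median_matches_sort_based_oracle(self, config):
        rng = np.random.default_rng(37)
        ratios = rng.uniform(0, 40, 15)
        peaks = self._peaks([PeakCategory.SRNA] * 15, ratios)
        summary = summarize_categories(peaks, config)
        srt = np.sort(ratios)
        assert summary.by_category["median_rpkm_ratio"].iloc[0] == pytest.approx(
            srt[7]
        )
        enriched = np.sort(ratios[ratios >= 2])
        mid = enriched[len(enriched) // 2] if len(enriched) % 2 else (
            enriched[len(enriched) // 2 - 1] + enriched[len(enriched) // 2]
        ) / 2
        assert summary.enriched_median_ratio == pytest.approx(mid)

    def test_empty_input_gives_empty_summary(self):
        summary = summarize_categories([])
        assert summary.by_category.empty


def test_category_recovery_on_synthetic_truth():
    """>=90% of called-and-enriched truth regions get their true category,
    pooled over seeds; conflicts would indicate rule-priority errors."""
    from ripcall import filter_enriched, score_peaks, union_peaks

    def jaccard(a, b):
        inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
        return inter / ((a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter)

    pc = PipelineConfig()
    ok = total = 0
    for seed in range(3):
        cfg = SimulationConfig(seed=seed)
        ann, tss, truth = generate_annotation(cfg)
        ip, ctrl = simulate_reads(ann, truth, cfg)
        peaks = union_peaks(
            call_peaks(compute_coverage(ip, cfg.genome_length), pc),
            call_peaks(compute_coverage(ctrl, cfg.genome_length), pc),
        )
        score_peaks(peaks, ip, ctrl, pc)
        enriched, _ = filter_enriched(peaks, pc)
        classify_peaks(enriched, ann, tss, pc)
        for r in truth.enriched():
            hits = [
                p for p in enriched
                if jaccard((r.start, r.end), (p.start, p.end)) >= 0.5
            ]
            if hits and hits[0].strand != AMBIGUOUS:
                total += 1
                if hits[0].category.value == r.category:
                    ok += 1
    assert total >= 40
    assert ok / total >= 0.9
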