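import numpy as np
import pandas as pd
import pytest

from acrkit import genome_model as gm
from acrkit.peaks import PeakSet

from helpers_oracles import paint_feature_classes, paint_proximal


def write_gtf(tmp_path, text):
    p = tmp_path / "genes.gtf"
    p.write_text(text)
    return p


class TestReadGeneModels:
    def test_exonic_length_is_union_not_sum(self, tmp_path):
        gtf = write_gtf(
            tmp_path,
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t141\t200\t.\t+\t.\tgene_id "g1";\n',
        )
        models = gm.read_gene_models(gtf, gm.ChromSizes({"chr1": 1000}))
        g = models["g1"]
        assert (g.interval.start, g.interval.end) == (100, 200)
        assert g.exonic_length == 100  # overlapping exons collapse

    def test_minus_strand_tss_is_last_base(self, tmp_path):
        gtf = write_gtf(
            tmp_path,
            'chr1\tsrc\tgene\t101\t200\t.\t-\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t101\t200\t.\t-\t.\tgene_id "g1";\n',
        )
        g = gm.read_gene_models(gtf, gm.ChromSizes({"chr1": 1000}))["g1"]
        assert g.tss == 199
        assert g.tes == 100

    def test_empty_gtf_yields_empty_set(self, tmp_path):
        gtf = write_gtf(tmp_path, "")
        assert len(gm.read_gene_models(gtf, gm.ChromSizes({"chr1": 1000}))) == 0

    def test_unknown_chromosome_rejected_with_record(self, tmp_path):
        gtf = write_gtf(
            tmp_path,
            'chrX\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "g9";\n'
            'chrX\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g9";\n',
        )
        with pytest.raises(ValueError, match="g9"):
            gm.read_gene_models(gtf, gm.ChromSizes({"chr1": 1000}))

    def test_gene_without_exons_rejected(self, tmp_path):
        gtf = write_gtf(tmp_path, 'chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(ValueError, match="no exon"):
            gm.read_gene_models(gtf, gm.ChromSizes({"chr1": 1000}))


class TestPromoterWindow:
    def test_plus_strand_inclusive_endpoints(self, small_models):
        g = small_models["geneA"]  # tss = 10_000
        w = gm.promoter_window(g, 2000, 100, small_models.chrom_sizes)
        assert (w.start, w.end) == (8000, 10_101)

    def test_minus_strand_mirrored(self, small_models):
        g = small_models["geneB"]  # tss = 47_999
        w = gm.promoter_window(g, 2000, 100, small_models.chrom_sizes)
        assert (w.start, w.end) == (47_899, 50_000)

    def test_clipped_at_chromosome_start(self):
        cs = gm.ChromSizes({"c": 1_000_000})
        g = gm.GeneModel(
            "g", gm.GenomicInterval("c", 10, 500, "+"),
            (gm.GenomicInterval("c", 10, 500, "+"),),
        )
        w = gm.promoter_window(g, 2000, 100, cs)
        assert w.start == 0 and w.end == 111

    def test_length_when_unclipped(self, small_models):
        g = small_models["geneA"]
        w = gm.promoter_window(g, 2000, 100, small_models.chrom_sizes)
        assert len(w) == 2000 + 100 + 1

    def test_negative_extent_rejected(self, small_models):
        with pytest.raises(ValueError):
            gm.promoter_window(small_models["geneA"], -1, 100)


class TestClassify:
    def test_promoter_beats_exon_of_other_gene(self, small_chrom_sizes):
        mk = gm.GenomicInterval
        # geneY's promoter window covers geneX's exon
        gene_x = gm.GeneModel("gx", mk("chr1", 1000, 3000, "+"), (mk("chr1", 1000, 3000, "+"),))
        gene_y = gm.GeneModel("gy", mk("chr1", 3500, 6000, "+"), (mk("chr1", 3500, 6000, "+"),))
        models = gm.GeneModelSet([gene_x, gene_y], small_chrom_sizes)
        fc = gm.classify_interval(mk("chr1", 2000, 2002), models)
        assert fc.value == gm.FeatureLabel.PROMOTER

    def test_gene_body_outside_exons_is_intron(self, small_models):
        fc = gm.classify_interval(gm.GenomicInterval("chr1", 12_400, 12_420), small_models)
        assert fc.value == gm.FeatureLabel.INTRON

    def test_far_from_genes_is_intergenic(self, small_models):
        fc = gm.classify_interval(gm.GenomicInterval("chr1", 90_000, 90_100), small_models)
        assert fc.value == gm.FeatureLabel.INTERGENIC

    def test_geneless_genome_all_intergenic(self, small_chrom_sizes):
        models = gm.GeneModelSet([], small_chrom_sizes)
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = int(rng.integers(0, 40_000))
            fc = gm.classify_interval(gm.GenomicInterval("chr1", s, s + 50), models)
            assert fc.value == gm.FeatureLabel.INTERGENIC

    def test_agrees_with_per_base_painting_oracle(self):
        from conftest import random_toy_genome

        rng = np.random.default_rng(11)
        windows = gm.DEFAULT_WINDOWS
        for _ in range(10):
            cs, models = random_toy_genome(rng)
            chrom_len = cs["chrT"]
            labels = paint_feature_classes(models, windows, "chrT", chrom_len)
            ann = gm.GenomeAnnotator(models, windows)
            pos = rng.integers(0, chrom_len, size=300)
            got = ann.classify_positions("chrT", pos)
            assert np.array_equal(got, labels[pos])
            prox = paint_proximal(models, windows, "chrT", chrom_len)
            assert np.array_equal(ann.proximal_flags("chrT", pos), prox[pos])


class TestAnnotatePeaks:
    def test_percentages_sum_to_100(self, small_models):
        rng = np.random.default_rng(1)
        rows = [
            {"chrom": "chr1", "start": int(s), "end": int(s) + 200}
            for s in rng.integers(0, 99_000, size=40)
        ]
        ann = gm.annotate_peaks(PeakSet(pd.DataFrame(rows)), small_models)
        summary = gm.feature_class_summary(ann)
        assert summary["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert summary["count"].sum() == 40

    def test_nearest_gene_tie_prefers_smaller_id(self):
        cs = gm.ChromSizes({"chr1": 100_000})
        mk = gm.GenomicInterval
        # two TSSs equidistant (both +) from midpoint 5000
        g1 = gm.GeneModel("gA", mk("chr1", 4000, 4500, "+"), (mk("chr1", 4000, 4500, "+"),))
        g2 = gm.GeneModel("gB", mk("chr1", 6000, 6500, "+"), (mk("chr1", 6000, 6500, "+"),))
        models = gm.GeneModelSet([g1, g2], cs)
        ann = gm.annotate_peaks(
            PeakSet(pd.DataFrame([{"chrom": "chr1", "start": 4900, "end": 5100}])), models
        )
        assert ann.loc[0, "nearest_gene"] == "gA"
        assert ann.loc[0, "tss_distance"] == 1000  # downstream of gA

    def test_signed_distance_orientation_on_minus_strand(self, small_models):
        # geneB tss = 47_999 (-); a peak upstream means beyond the TSS
        ann = gm.annotate_peaks(
            PeakSet(pd.DataFrame([{"chrom": "chr1", "start": 48_900, "end": 49_100}])),
            small_models,
        )
        assert ann.loc[0, "nearest_gene"] == "geneB"
        assert ann.loc[0, "tss_distance"] == -(49_000 - 47_999)

    def test_empty_peak_set(self, small_models):
        ann = gm.annotate_peaks(PeakSet(pd.DataFrame(columns=["chrom", "start", "end"])), small_models)
        assert ann.empty

    def test_order_invariance(self, small_models):
        rows = [
            {"chrom": "chr1", "start": 8000, "end": 8400, "name": "p1"},
            {"chrom": "chr2", "start": 19_500, "end": 19_900, "name": "p2"},
            {"chrom": "chr1", "start": 70_000, "end": 70_300, "name": "p3"},
        ]
        a = gm.annotate_peaks(PeakSet(pd.DataFrame(rows)), small_models)
        b = gm.annotate_peaks(PeakSet(pd.DataFrame(rows[::-1])), small_models)
        a = a.set_index("peak_id").sort_index()
        b = b.set_index("peak_id").sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_planted_promoter_peaks_all_promoter(self, noisy_bundle):
        from conftest import truth_peakset

        b = noisy_bundle
        prom_ids = [p for g, ps in b.truth.promoter_map.items() for p in ps]
        cs = gm.read_chrom_sizes(b.chrom_sizes)
        models = gm.read_gene_models(b.gtf, cs)
        ann = gm.annotate_peaks(truth_peakset(b, prom_ids), models)
        assert (ann["feature_class"] == "promoter").all()
        assert ann["proximal_promoter"].all()
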