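import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from acrkit import genome_model as gm
from acrkit import integrate as integ
from acrkit.peaks import PeakSet

from helpers_oracles import hypergeom_upper_tail_exact


class TestPromoterAcrMap:
    def test_gene_with_two_promoter_acrs(self, small_models):
        # geneA tss = 10_000 (+): proximal window [9000, 10_101)
        peaks = PeakSet(pd.DataFrame([
            {"chrom": "chr1", "start": 9000, "end": 9400, "name": "p1"},
            {"chrom": "chr1", "start": 9500, "end": 10_050, "name": "p2"},
            {"chrom": "chr1", "start": 70_000, "end": 70_200, "name": "p3"},
        ]))
        ann = gm.annotate_peaks(peaks, small_models)
        pmap = integ.map_promoter_acrs(ann, small_models)
        assert sorted(p for p, _ in pmap.genes["geneA"]) == ["p1", "p2"]
        assert pmap.count_distribution().to_dict() == {"one_acr": 0, "multi_acr": 1}

    def test_gene_without_promoter_acr_absent(self, small_models):
        peaks = PeakSet(pd.DataFrame([
            {"chrom": "chr1", "start": 70_000, "end": 70_200, "name": "p1"},
        ]))
        ann = gm.annotate_peaks(peaks, small_models)
        assert integ.map_promoter_acrs(ann, small_models).genes == {}

    def test_generator_truth_map_recovered(self, noisy_bundle):
        from conftest import truth_peakset

        b = noisy_bundle
        cs = gm.read_chrom_sizes(b.chrom_sizes)
        models = gm.read_gene_models(b.gtf, cs)
        all_ids = list(b.truth.peaks)
        ann = gm.annotate_peaks(truth_peakset(b, all_ids), models)
        pmap = integ.map_promoter_acrs(ann, models)
        got = {g: sorted(p for p, _ in v) for g, v in pmap.genes.items()}
        assert got == b.truth.promoter_map


class TestLengthGroups:
    def test_90_distinct_lengths_split_30_30_30(self):
        lengths = {f"g{i:03d}": 100 + i for i in range(90)}
        assign = integ.assign_length_groups(lengths)
        assert assign.sizes() == {"bottom": 30, "middle": 30, "top": 30}
        # shortest genes are in the bottom group
        assert assign.groups["g000"] == "bottom"
        assert assign.groups["g089"] == "top"

    def test_tie_run_moves_to_majority_side(self):
        # ranks 29-31 (1-based) share a length: 2 start in the bottom
        # group, 1 in the middle -> all 3 go to bottom: 31/29/30
        lengths = {}
        for i in range(28):
            lengths[f"g{i:03d}"] = 100 + i
        for i in range(28, 31):
            lengths[f"g{i:03d}"] = 150
        for i in range(31, 90):
            lengths[f"g{i:03d}"] = 200 + i
        assign = integ.assign_length_groups(lengths)
        assert assign.sizes() == {"bottom": 31, "middle": 29, "top": 30}

    def test_fifty_fifty_run_goes_to_lower_group(self):
        # 30 in bottom + tie run of 2 straddling the cut equally
        lengths = {f"a{i:02d}": i for i in range(29)}
        lengths["t1"] = 50
        lengths["t2"] = 50
        lengths.update({f"z{i:02d}": 100 + i for i in range(59)})
        assign = integ.assign_length_groups(lengths)
        assert assign.groups["t1"] == "bottom" and assign.groups["t2"] == "bottom"
        assert assign.sizes() == {"bottom": 31, "middle": 29, "top": 30}

    def test_all_equal_degenerate_single_group(self):
        assign = integ.assign_length_groups({f"g{i}": 7 for i in range(9)})
        sizes = assign.sizes()
        assert sum(sizes.values()) == 9
        assert sorted(sizes.values()) == [0, 0, 9]

    def test_partition_total_and_order_invariant(self):
        rng = np.random.default_rng(0)
        lengths = {f"g{i:03d}": int(v) for i, v in enumerate(rng.integers(100, 200, 100))}
        a = integ.assign_length_groups(lengths)
        shuffled = dict(sorted(lengths.items(), key=lambda kv: hash(kv[0])))
        b = integ.assign_length_groups(shuffled)
        pd.testing.assert_series_equal(a.groups, b.groups)
        assert sum(a.sizes().values()) == 100

    def test_monotone_relabel_invariance(self):
        rng = np.random.default_rng(1)
        lengths = {f"g{i:03d}": int(v) for i, v in enumerate(rng.integers(100, 140, 60))}
        a = integ.assign_length_groups(lengths)
        transformed = {k: v * 13 + 5 for k, v in lengths.items()}
        b = integ.assign_length_groups(transformed)
        pd.testing.assert_series_equal(a.groups, b.groups)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            integ.assign_length_groups({"a": 1, "b": 2})


class TestExpressionBins:
    @pytest.mark.parametrize(
        "value,bin_", [(0.0, "B1"), (1.99, "B1"), (2.0, "B2"), (4.99, "B2"),
                       (5.0, "B3"), (10.0, "B4"), (29.99, "B4"), (30.0, "B5"), (31.0, "B5")]
    )
    def test_boundaries_left_closed(self, value, bin_):
        out = integ.bin_expression(pd.Series({"g": value}))
        assert out["g"] == bin_

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            integ.bin_expression(pd.Series({"g": -1.0}))


class TestGroupBinTable:
    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(90)]
        groups = pd.Series(rng.choice(["top", "middle", "bottom"], 90), index=genes)
        bins = pd.Series(rng.choice(["B1", "B2", "B3", "B4", "B5"], 90), index=genes)
        table = integ.group_bin_table(groups, bins)
        assert table.sum(axis=1).to_numpy() == pytest.approx([100.0] * 3, abs=1e-9)

    def test_concentrated_group(self):
        genes = ["a", "b", "c"]
        groups = pd.Series(["top"] * 3, index=genes)
        bins = pd.Series(["B5"] * 3, index=genes)
        with pytest.warns(UserWarning):
            table = integ.group_bin_table(groups, bins)
        assert table.loc["top"].tolist() == [0, 0, 0, 0, 100.0]

    def test_planted_length_expression_trend(self, noisy_bundle):
        from conftest import truth_peakset

        b = noisy_bundle
        cs = gm.read_chrom_sizes(b.chrom_sizes)
        models = gm.read_gene_models(b.gtf, cs)
        common_ids = b.truth.common
        ann = gm.annotate_peaks(truth_peakset(b, common_ids), models)
        pmap = integ.map_promoter_acrs(ann, models)
        lengths = pmap.lengths("single")
        assign = integ.assign_length_groups(lengths)
        fpkm = pd.Series({g: b.truth.gene_fpkm[g][0] for g in lengths.index})
        table = integ.group_bin_table(assign.groups, integ.bin_expression(fpkm))
        assert table.loc["top", "B5"] > table.loc["bottom", "B5"]


class TestIntensityExpressionCorrelation:
    def test_linear_relation_gives_r_one(self):
        cols = [f"s{i}" for i in range(12)]
        x = pd.DataFrame([np.arange(12.0)], index=["peak1"], columns=cols)
        y = pd.DataFrame([2 * np.arange(12.0)], index=["gene1"], columns=cols)
        r = integ.intensity_expression_correlation(x, y, {"gene1": "peak1"})
        assert r["gene1"] == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        cols = [f"s{i}" for i in range(6)]
        x = pd.DataFrame([[5.0] * 6], index=["p"], columns=cols)
        y = pd.DataFrame([np.arange(6.0)], index=["g"], columns=cols)
        r = integ.intensity_expression_correlation(x, y, {"g": "p"})
        assert np.isnan(r["g"])

    def test_null_pairs_mean_r_near_zero(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(12)]
        n = 500
        x = pd.DataFrame(rng.normal(size=(n, 12)), index=[f"p{i}" for i in range(n)], columns=cols)
        y = pd.DataFrame(rng.normal(size=(n, 12)), index=[f"g{i}" for i in range(n)], columns=cols)
        r = integ.intensity_expression_correlation(x, y, {f"g{i}": f"p{i}" for i in range(n)})
        assert abs(r.mean()) < 0.05

    def test_mismatched_samples_rejected(self):
        x = pd.DataFrame([[1.0, 2.0]], index=["p"], columns=["s1", "s2"])
        y = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s3"])
        with pytest.raises(ValueError):
            integ.intensity_expression_correlation(x, y, {"g": "p"})


class TestClusterDegs:
    @staticmethod
    def archetype_fpkm(rng, n_per=25):
        archetypes = [(1, 1, 8), (1, 3, 9), (9, 3, 1), (8, 1, 1), (1, 8, 2), (8, 1, 4)]
        cols = [f"{s}_r{r}" for s in ("S1", "S2", "S3") for r in range(4)]
        stage_map = pd.Series({c: c.split("_")[0] for c in cols})
        rows, labels = [], []
        for ci, arch in enumerate(archetypes):
            for g in range(n_per):
                base = rng.lognormal(np.log(5), 0.3)
                prof = np.repeat(np.array(arch, dtype=float) * base, 4)
                rows.append(prof * rng.lognormal(0, 0.1, 12))
                labels.append(ci)
        idx = [f"g{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx, columns=cols), stage_map, pd.Series(labels, index=idx)

    def test_recovers_planted_archetypes(self):
        rng = np.random.default_rng(0)
        fpkm, stage_map, truth = self.archetype_fpkm(rng)
        assign = integ.cluster_degs(fpkm, stage_map, k=6, seed=0)
        assert adjusted_rand_score(truth, assign.labels) > 0.9

    def test_labels_numbered_by_descending_size(self):
        rng = np.random.default_rng(1)
        fpkm, stage_map, _ = self.archetype_fpkm(rng)
        assign = integ.cluster_degs(fpkm, stage_map, k=6, seed=0)
        sizes = assign.labels.value_counts().sort_index()
        assert (np.diff(sizes.to_numpy()) <= 0).all()

    def test_k_below_two_rejected(self):
        rng = np.random.default_rng(2)
        fpkm, stage_map, _ = self.archetype_fpkm(rng, n_per=2)
        with pytest.raises(ValueError):
            integ.cluster_degs(fpkm, stage_map, k=1)

    def test_fewer_genes_than_k_rejected(self):
        cols = [f"{s}_r{r}" for s in ("S1", "S2", "S3") for r in range(4)]
        stage_map = pd.Series({c: c.split("_")[0] for c in cols})
        fpkm = pd.DataFrame(np.ones((3, 12)), index=list("abc"), columns=cols)
        with pytest.raises(ValueError):
            integ.cluster_degs(fpkm, stage_map, k=6)

    def test_duplicated_gene_rows_cluster_together(self):
        rng = np.random.default_rng(3)
        fpkm, stage_map, _ = self.archetype_fpkm(rng)
        fpkm.loc["dup1"] = fpkm.iloc[0]
        fpkm.loc["dup2"] = fpkm.iloc[0]
        assign = integ.cluster_degs(fpkm, stage_map, k=6, seed=0)
        assert assign.labels["dup1"] == assign.labels["dup2"] == assign.labels[fpkm.index[0]]


class TestOverlapSignificance:
    def test_exact_small_case_1_over_252(self):
        universe = [f"u{i}" for i in range(10)]
        a = universe[:5]
        res = integ.overlap_significance(a, a, universe)
        assert res.p == pytest.approx(1 / 252)
        assert res.p == pytest.approx(
            hypergeom_upper_tail_exact(10, 5, 5, 5), rel=1e-12
        )

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(5, 20))
            universe = [f"u{i}" for i in range(m)]
            ka, kb = int(rng.integers(1, m)), int(rng.integers(1, m))
            a = list(rng.choice(universe, ka, replace=False))
            b = list(rng.choice(universe, kb, replace=False))
            res = integ.overlap_significance(a, b, universe)
            expect = hypergeom_upper_tail_exact(m, ka, kb, len(set(a) & set(b)))
            assert res.p == pytest.approx(expect, rel=1e-9)

    def test_empty_overlap_big_universe_p_near_one(self):
        universe = [f"u{i}" for i in range(1000)]
        res = integ.overlap_significance(universe[:3], universe[-3:], universe)
        assert res.p > 0.9

    def test_full_overlap_of_universe_p_one(self):
        universe = ["a", "b", "c"]
        res = integ.overlap_significance(universe, universe, universe)
        assert res.p == pytest.approx(1.0)

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError):
            integ.overlap_significance(["x"], ["a"], ["a", "b"])
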