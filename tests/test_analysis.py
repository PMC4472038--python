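"""Barcode bins, clustering, within-class correlation, stage partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import keygenes as kg
from keygenes.analysis import _bin_of, BIN_LABELS
from oracles import complete_linkage_heights, high_genes_bruteforce


def _cpm(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return kg.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "cpm")


class TestBarcodeBins:
    @pytest.mark.parametrize("value,expected", [
        (0.0, "<50"), (49.99, "<50"),
        (50.0, "50-100"), (75.0, "50-100"), (100.0, "50-100"),
        (100.01, "100-1000"), (1000.0, "100-1000"),
        (1000.01, ">1000"), (1500.0, ">1000"),
    ])
    def test_bin_edges(self, value, expected):
        assert _bin_of(value) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1e7, allow_nan=False))
    def test_bins_partition_the_nonnegative_line(self, value):
        bin_label = _bin_of(value)
        assert bin_label in BIN_LABELS
        # interval membership is consistent with the documented edges
        lower = {"<50": 0, "50-100": 50, "100-1000": 100, ">1000": 1000}
        upper = {"<50": 50, "50-100": 100, "100-1000": 1000, ">1000": np.inf}
        assert lower[bin_label] <= value or value == 0
        assert value <= upper[bin_label] or bin_label == ">1000"

    def test_mean_cpm_per_class(self):
        m = _cpm([[60, 90, 10, 10], [2000, 1000, 5, 5]],
                 genes=["A", "B"], samples=["s1", "s2", "s3", "s4"])
        labels = kg.LabelTable.from_mapping(
            {"s1": "x", "s2": "x", "s3": "y", "s4": "y"})
        table = kg.barcode_bins(m, labels, ["A", "B"])
        row = table[(table.gene == "A") & (table["class"] == "x")].iloc[0]
        assert row.mean_cpm == 75.0 and row.bin == "50-100"
        row = table[(table.gene == "B") & (table["class"] == "x")].iloc[0]
        assert row.bin == ">1000"

    def test_classifier_flag(self):
        m = _cpm([[60, 60]], genes=["A"], samples=["s1", "s2"])
        labels = kg.LabelTable.from_mapping({"s1": "x", "s2": "y"})
        table = kg.barcode_bins(m, labels, ["A"], classifier_classes={"A": ["x"]})
        flags = dict(zip(table["class"], table["in_classifying_tissue"]))
        assert flags == {"x": True, "y": False}


class TestClusterSamples:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(3, 1, 30)
        m = _cpm(np.column_stack([col, col, rng.lognormal(3, 1, 30)]))
        d = kg.cluster_samples(m, m.gene_ids)
        assert d.heights()[0] == pytest.approx(0.0, abs=1e-12)

    def test_pearson_distance_scale_invariant(self):
        rng = np.random.default_rng(1)
        col = rng.lognormal(3, 1, 30)
        m = _cpm(np.column_stack([col, 2 * col]))
        dist = kg.pearson_distance_matrix(m, m.gene_ids)
        assert dist.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_heights_match_naive_agglomeration(self):
        rng = np.random.default_rng(2)
        m = _cpm(rng.lognormal(3, 1, size=(40, 6)))
        d = kg.cluster_samples(m, m.gene_ids)
        dist = kg.pearson_distance_matrix(m, m.gene_ids).to_numpy()
        expected = complete_linkage_heights(dist)
        np.testing.assert_allclose(np.sort(d.heights()), np.sort(expected),
                                   atol=1e-12)

    def test_heights_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        m = _cpm(rng.lognormal(3, 1, size=(25, 8)))
        d = kg.cluster_samples(m, m.gene_ids)
        h = d.heights()
        assert np.all(np.diff(h) >= -1e-12)
        dist = kg.pearson_distance_matrix(m, m.gene_ids).to_numpy()
        assert dist.min() >= -1e-12 and dist.max() <= 2 + 1e-12

    def test_zero_variance_sample_named(self):
        m = _cpm([[5, 1], [5, 2], [5, 3]], samples=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            kg.cluster_samples(m, m.gene_ids)

    def test_newick_export_contains_all_samples(self):
        rng = np.random.default_rng(4)
        m = _cpm(rng.lognormal(3, 1, size=(20, 4)))
        nwk = kg.cluster_samples(m, m.gene_ids).to_newick()
        assert nwk.endswith(";")
        for s in m.sample_ids:
            assert s in nwk


class TestMeanGroupCorrelation:
    def test_identical_samples_have_r_one_sd_zero(self):
        col = np.arange(1.0, 21.0)
        m = _cpm(np.column_stack([col, col, col]))
        labels = kg.LabelTable.from_mapping({s: "x" for s in m.sample_ids})
        out = kg.mean_group_correlation(m, labels, m.gene_ids)
        row = out[out.group == "x"].iloc[0]
        assert row.mean_r == pytest.approx(1.0)
        assert row.sd_r == pytest.approx(0.0)

    def test_hand_computed_pairs(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 5.0])
        c = np.array([4.0, 3.0, 2.0, 1.0])
        d = np.array([1.0, 3.0, 2.0, 4.0])
        m = _cpm(np.column_stack([a, b, c, d]), samples=["a", "b", "c", "d"])
        labels = kg.LabelTable.from_mapping(
            {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        out = kg.mean_group_correlation(m, labels, m.gene_ids)
        r_ab = np.corrcoef(a, b)[0, 1]
        r_cd = np.corrcoef(c, d)[0, 1]
        assert out[out.group == "g1"].iloc[0].mean_r == pytest.approx(r_ab)
        assert out[out.group == "g2"].iloc[0].mean_r == pytest.approx(r_cd)
        overall = out[out.group == "__overall__"].iloc[0]
        assert overall.mean_r == pytest.approx((r_ab + r_cd) / 2)

    def test_single_sample_group_skipped(self, caplog):
        m = _cpm(np.random.default_rng(5).lognormal(3, 1, (10, 3)),
                 samples=["a", "b", "c"])
        labels = kg.LabelTable.from_mapping({"a": "x", "b": "x", "c": "lonely"})
        with caplog.at_level("WARNING"):
            out = kg.mean_group_correlation(m, labels, m.gene_ids)
        assert "lonely" not in set(out.group)

    def test_marker_genes_raise_within_class_correlation(self, truth, atlas):
        counts, labels = atlas
        c = kg.cpm(counts)
        markers = sorted(truth.marker_union())
        rng = np.random.default_rng(6)
        random_genes = list(rng.choice(
            [g for g in c.gene_ids if g not in set(markers)], size=len(markers),
            replace=False))
        r_markers = kg.mean_group_correlation(c, labels, markers)
        r_random = kg.mean_group_correlation(c, labels, random_genes)
        assert r_markers[r_markers.group == "__overall__"].iloc[0].mean_r > \
            r_random[r_random.group == "__overall__"].iloc[0].mean_r

    def test_stage_grouping_splits_classes(self, atlas):
        counts, labels = atlas
        c = kg.cpm(counts.select_samples(labels.sample_ids[:10]))
        out = kg.mean_group_correlation(
            c, labels, c.gene_ids, grouping="by_class_and_stage")
        assert any(g.endswith("_1T") or g.endswith("_2T") for g in out.group)


class TestStageSpecificGenes:
    def _stage_dataset(self, high_genes, organ_samples, other_samples, seed):
        # organ enrichment must exceed 10x the dataset-wide gene mean, so
        # the organ stays a small fraction of the dataset
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        vals = rng.uniform(10, 20, size=(30, len(organ_samples) + len(other_samples)))
        for g in high_genes:
            vals[genes.index(g), : len(organ_samples)] = 5000.0
        samples = organ_samples + other_samples
        m = _cpm(vals, genes=genes, samples=samples)
        labels = kg.LabelTable.from_mapping(
            {s: ("X" if s in organ_samples else "other") for s in samples})
        return m, labels

    def test_unique_and_common_assignment(self):
        others_a = [f"a{i}" for i in range(3, 30)]
        others_b = [f"b{i}" for i in range(3, 30)]
        m1, l1 = self._stage_dataset(["g0", "g1"], ["a1", "a2"], others_a, 0)
        m2, l2 = self._stage_dataset(["g1", "g2"], ["b1", "b2"], others_b, 1)
        part = kg.stage_specific_genes([("1T", m1, l1), ("2T", m2, l2)], "X")
        assert "g0" in part.unique_to("1T")
        assert "g2" in part.unique_to("2T")
        assert "g1" in part.common_to_all()
        # partition is disjoint and covers the union
        all_genes = sorted(g for genes in part.parts.values() for g in genes)
        assert len(all_genes) == len(set(all_genes))

    def test_uniform_gene_in_no_high_set(self):
        m1, l1 = self._stage_dataset([], ["a1", "a2"], ["a3", "a4", "a5"], 2)
        m2, l2 = self._stage_dataset([], ["b1", "b2"], ["b3", "b4", "b5"], 3)
        part = kg.stage_specific_genes([("1T", m1, l1), ("2T", m2, l2)], "X")
        assert part.union() == set()

    def test_matches_bruteforce_oracle(self, atlas):
        counts, labels = atlas
        c = kg.cpm(counts)
        samples_1 = [s for s in c.sample_ids if labels.stage_of(s) == "1T"]
        samples_2 = [s for s in c.sample_ids if labels.stage_of(s) == "2T"]
        d1 = kg.ExpressionMatrix(c.data[samples_1], "cpm")
        d2 = kg.ExpressionMatrix(c.data[samples_2], "cpm")
        part = kg.stage_specific_genes(
            [("1T", d1, labels), ("2T", d2, labels)], "liver")
        for stage, d in [("1T", d1), ("2T", d2)]:
            organ_samples = [s for s in d.sample_ids
                             if labels.class_of(s) == "liver"]
            expected = high_genes_bruteforce(d.data, organ_samples, 10.0)
            got = set().union(*(genes for key, genes in part.parts.items()
                                if stage in key))
            assert got == expected

    def test_organ_missing_from_all_but_one_dataset_errors(self):
        m1, l1 = self._stage_dataset(["g0"], ["a1", "a2"], ["a3"], 4)
        m2, l2 = self._stage_dataset(["g0"], ["b1", "b2"], ["b3"], 5)
        l2_no_x = kg.LabelTable.from_mapping(
            {s: "other" for s in m2.sample_ids})
        with pytest.raises(ValueError, match="fewer than two"):
            kg.stage_specific_genes([("1T", m1, l1), ("2T", m2, l2_no_x)], "X")
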