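"""Clustering, PCA and chromosome summaries."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xplatde import io_formats as io
from xplatde import structure as st
from xplatde.preprocess import RatioMatrix


def frame(values, index=None):
    values = np.asarray(values, dtype=float)
    index = index or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=index,
                        columns=[f"s{j}" for j in range(values.shape[1])])


def annotation(gene_to_chrom: dict) -> io.GeneAnnotation:
    return io.GeneAnnotation(
        "p",
        pd.DataFrame(
            {
                "probe_id": [f"p{g}" for g in gene_to_chrom],
                "gene_id": list(gene_to_chrom),
                "symbol": [f"G{g}" for g in gene_to_chrom],
                "chromosome": list(gene_to_chrom.values()),
            }
        ),
    )


class TestHierarchical:
    def test_identical_rows_merge_first_at_zero(self):
        f = frame([[1.0, 2.0], [1.0, 2.0], [8.0, 9.0]])
        dend = st.hierarchical_cluster(f)
        assert dend.linkage[0, 2] == 0.0
        assert set(dend.linkage[0, :2].astype(int)) == {0, 1}

    def test_three_point_hand_example(self):
        # points 0, 1, 5 on a line: merge {0,1} at 1, then with 5 at (5+4)/2
        f = frame([[0.0], [1.0], [5.0]])
        dend = st.hierarchical_cluster(f)
        np.testing.assert_allclose(dend.heights, [1.0, 4.5])

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        f = frame(rng.normal(size=(25, 6)))
        dend = st.hierarchical_cluster(f)
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_single_item_rejected(self):
        with pytest.raises(io.ValidationError, match="two items"):
            st.hierarchical_cluster(frame([[1.0, 2.0]]))

    def test_newick_export_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(1)
        f = frame(rng.normal(size=(8, 4)))
        dend = st.hierarchical_cluster(f)
        tree = dendropy.Tree.get(data=st.to_newick(dend), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(dend.labels)

    def test_samples_axis_clusters_columns(self):
        f = frame([[0.0, 0.0, 10.0], [0.0, 0.1, 10.0]])
        dend = st.hierarchical_cluster(f, axis="samples")
        assert dend.labels == ["s0", "s1", "s2"]
        assert set(dend.linkage[0, :2].astype(int)) == {0, 1}


class TestKMeans:
    def test_k1_centroid_is_columnwise_mean(self):
        rng = np.random.default_rng(2)
        f = frame(rng.normal(size=(20, 3)))
        result = st.kmeans_cluster(f, k=1, seed=0)
        np.testing.assert_allclose(result.centroids[0],
                                   f.to_numpy().mean(axis=0), atol=1e-12)
        assert (result.assignments == 0).all()

    def test_two_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(30, 4))
        b = rng.normal(20, 1, size=(30, 4))
        f = frame(np.vstack([a, b]))
        result = st.kmeans_cluster(f, k=2, seed=0)
        first, second = result.assignments[:30], result.assignments[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_inertia_beats_random_assignment(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 5))
        result = st.kmeans_cluster(frame(x), k=4, seed=0)
        labels = rng.integers(0, 4, size=40)
        inertia_random = sum(
            ((x[labels == c] - x[labels == c].mean(axis=0)) ** 2).sum()
            for c in range(4) if (labels == c).any()
        )
        assert result.inertia <= inertia_random + 1e-9

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        f = frame(rng.normal(size=(30, 4)))
        r1 = st.kmeans_cluster(f, k=3, seed=11)
        r2 = st.kmeans_cluster(f, k=3, seed=11)
        np.testing.assert_array_equal(r1.assignments, r2.assignments)
        np.testing.assert_array_equal(r1.centroids, r2.centroids)

    def test_k_exceeding_items_rejected(self):
        with pytest.raises(io.ValidationError, match="exceeds"):
            st.kmeans_cluster(frame([[1.0], [2.0]]), k=3)


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        res = st.pca(frame(rng.normal(size=(20, 5))))
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_matrix_single_component(self):
        u = np.arange(1.0, 11.0)[:, None]
        v = np.array([[1.0, 2.0, 3.0]])
        res = st.pca(frame(u @ v))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 4))
        res = st.pca(frame(x))
        centered = x - x.mean(axis=0)
        reconstructed = res.scores @ res.components
        np.testing.assert_allclose(reconstructed, centered, atol=1e-9)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(8)
        res = st.pca(frame(rng.normal(size=(12, 5))))
        gram = res.components @ res.components.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(io.ValidationError, match="constant"):
            st.pca(frame(np.full((5, 3), 2.0)))


class TestChromosomeSummaries:
    def test_distribution_fractions(self):
        ann = annotation({g: "1" if g <= 10 else "2" for g in range(1, 21)})
        dist = st.chromosome_distribution(range(1, 21), ann)
        assert dist.loc["1", "count"] == 10
        assert dist.loc["1", "fraction"] == 0.5
        assert dist["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_flagged_undefined(self):
        ann = annotation({1: "1"})
        dist = st.chromosome_distribution([], ann)
        assert (dist["count"] == 0).all()
        assert dist["fraction"].isna().all()

    def test_unannotated_gene_listed_in_error(self):
        ann = annotation({1: "1"})
        with pytest.raises(io.ValidationError, match="7"):
            st.chromosome_distribution([1, 7], ann)

    def test_random_assignment_matches_brute_force(self):
        rng = np.random.default_rng(9)
        chroms = rng.choice(["1", "2", "X"], size=100)
        ann = annotation({g + 1: c for g, c in enumerate(chroms)})
        genes = rng.choice(np.arange(1, 101), size=40, replace=False)
        dist = st.chromosome_distribution(genes, ann)
        for label in ("1", "2", "X"):
            brute = sum(chroms[g - 1] == label for g in genes)
            assert dist.loc[label, "count"] == brute

    def test_mean_expression_hand_example(self):
        ann = annotation({1: "3", 2: "3", 3: "7"})
        ratios = RatioMatrix(gene_ids=[1, 2, 3],
                             log2_ratios=np.array([[1.0], [1.0], [-2.0]]),
                             sample_ids=["t0"])
        means = st.chromosome_mean_expression(
            ratios, ann, {"up": {1, 2}, "down": {3}})
        assert means.loc["3", "up"] == 1.0
        assert means.loc["7", "down"] == -2.0
        assert np.isnan(means.loc["5", "up"])  # chromosome with no members

    def test_mean_expression_matches_brute_force(self):
        rng = np.random.default_rng(10)
        chroms = rng.choice(["1", "2"], size=30)
        ann = annotation({g + 1: c for g, c in enumerate(chroms)})
        values = rng.normal(size=(30, 4))
        ratios = RatioMatrix(gene_ids=list(range(1, 31)), log2_ratios=values,
                             sample_ids=[f"t{j}" for j in range(4)])
        up = set(range(1, 16))
        means = st.chromosome_mean_expression(ratios, ann, {"up": up})
        for label in ("1", "2"):
            member_rows = [g - 1 for g in up if chroms[g - 1] == label]
            brute = values[member_rows].mean()
            assert means.loc[label, "up"] == pytest.approx(brute, abs=1e-12)


class TestCorrelationMaps:
    def _setup(self, rng, n_genes=10, n_samples=5):
        ann = annotation({g: "4" for g in range(1, n_genes + 1)})
        values = rng.normal(size=(n_genes, n_samples))
        ratios = RatioMatrix(gene_ids=list(range(1, n_genes + 1)),
                             log2_ratios=values,
                             sample_ids=[f"t{j}" for j in range(n_samples)])
        return ann, ratios, values

    def test_unit_diagonal_and_symmetry(self):
        ann, ratios, _ = self._setup(np.random.default_rng(11))
        cmap = st.chromosome_correlation_map(ratios, ann, "4")
        m = cmap.matrix.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-12)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert (np.abs(m) <= 1 + 1e-12).all()

    def test_negated_sample_gives_minus_one(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=10)
        values = np.column_stack([base, -base, rng.normal(size=10)])
        ann = annotation({g: "4" for g in range(1, 11)})
        ratios = RatioMatrix(gene_ids=list(range(1, 11)), log2_ratios=values,
                             sample_ids=["t0", "t1", "t2"])
        cmap = st.chromosome_correlation_map(ratios, ann, "4")
        assert cmap.matrix.loc["t0", "t1"] == pytest.approx(-1.0, abs=1e-12)

    def test_pearson_matches_brute_force(self):
        ann, ratios, values = self._setup(np.random.default_rng(13))
        cmap = st.chromosome_correlation_map(ratios, ann, "4")
        for i in range(5):
            for j in range(5):
                r = np.corrcoef(values[:, i], values[:, j])[0, 1]
                assert cmap.matrix.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_spearman_equals_pearson_on_ranks(self):
        from scipy.stats import rankdata

        ann, ratios, values = self._setup(np.random.default_rng(14))
        spearman = st.chromosome_correlation_map(ratios, ann, "4",
                                                 method="spearman")
        ranked = rankdata(values, axis=0)
        expected = np.corrcoef(ranked, rowvar=False)
        np.testing.assert_allclose(spearman.matrix.to_numpy(), expected,
                                   atol=1e-12)

    def test_too_few_genes_rejected(self):
        ann = annotation({1: "9", 2: "9"})
        ratios = RatioMatrix(gene_ids=[1, 2],
                             log2_ratios=np.ones((2, 4)),
                             sample_ids=[f"t{j}" for j in range(4)])
        with pytest.raises(io.ValidationError, match="need >= 3"):
            st.chromosome_correlation_map(ratios, ann, "9")
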