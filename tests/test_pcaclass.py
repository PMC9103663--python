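"""PCA, contribution decomposition and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

from hubsig.pcaclass import (
    FeatureMatrix,
    build_feature_matrix,
    gene_contributions,
    hierarchical_cluster,
    run_pca,
)


def fm(values, index, columns, classes):
    return FeatureMatrix(
        values=pd.DataFrame(values, index=index, columns=columns),
        row_classes=pd.Series(classes),
    )


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(8)
    types = ["T1", "T2", "T3", "T4", "T5", "T6"]
    classes = dict(zip(types, ["H", "H", "H", "L", "L", "L"]))
    genes = [f"g{i:02d}" for i in range(50)]
    return fm(rng.random((6, 50)) * 10, types, genes, classes)


class TestBuildFeatureMatrix:
    def test_absent_gene_cell_is_zero(self):
        stats = pd.DataFrame(
            [("g1", "T1", 2, 0.5, 10, 5.0), ("g1", "T2", 0, 0.0, 10, 0.0),
             ("g2", "T1", 1, 0.25, 4, 1.0)],
            columns=["gene", "group", "n", "norm_count", "degree",
                     "norm_connections"],
        )
        m = build_feature_matrix(stats, ["g1", "g2"],
                                 {"T1": "H", "T2": "L"})
        assert m.values.loc["T2", "g1"] == 0.0
        assert m.values.loc["T2", "g2"] == 0.0  # missing row entirely
        assert m.values.loc["T1", "g1"] == 5.0
        assert list(m.values.columns) == ["g1", "g2"]

    def test_empty_selection_rejected(self):
        stats = pd.DataFrame(
            columns=["gene", "group", "n", "norm_count", "degree",
                     "norm_connections"]
        )
        with pytest.raises(ValueError):
            build_feature_matrix(stats, [], {})


class TestRunPCA:
    def test_matches_covariance_eigendecomposition(self, random_matrix):
        """Variance proportions equal eigenvalue shares of the brute-force
        covariance eigendecomposition."""
        res = run_pca(random_matrix)
        X = random_matrix.values.to_numpy()
        Xc = X - X.mean(axis=0)
        eig = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))[::-1]
        eig = eig[: len(res.proportions)]
        np.testing.assert_allclose(
            res.proportions, eig / np.linalg.eigvalsh(
                np.cov(Xc, rowvar=False)).sum(), atol=1e-10
        )
        np.testing.assert_allclose(
            res.sdev**2,
            eig,
            rtol=1e-10,
        )

    def test_proportions_sum_to_one_and_cumulative_monotone(self, random_matrix):
        res = run_pca(random_matrix)
        assert res.proportions.sum() == pytest.approx(1.0)
        assert (np.diff(res.cumulative) >= -1e-12).all()

    def test_rank_one_matrix_loads_everything_on_pc1(self):
        base = np.outer([1, 2, 3, 4], [1.0, 0.5, 2.0])
        m = fm(base, list("abcd"), ["g1", "g2", "g3"],
               {"a": "H", "b": "H", "c": "L", "d": "L"})
        res = run_pca(m)
        assert res.proportions[0] == pytest.approx(1.0)

    def test_constant_matrix_flagged_degenerate(self):
        m = fm(np.full((3, 4), 2.0), list("abc"), list("wxyz"),
               {"a": "H", "b": "L", "c": "L"})
        res = run_pca(m)
        assert res.degenerate
        assert (res.proportions == 0).all()

    def test_reconstruction_at_full_rank(self, random_matrix):
        res = run_pca(random_matrix)
        X = random_matrix.values.to_numpy()
        Xc = X - X.mean(axis=0)
        approx = res.coords.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(approx, Xc, atol=1e-8)

    def test_sign_convention_is_deterministic(self, random_matrix):
        a = run_pca(random_matrix)
        b = run_pca(random_matrix)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for pc in a.loadings.columns:
            col = a.loadings[pc]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


class TestGeneContributions:
    def test_single_dominant_gene(self):
        base = np.zeros((3, 2))
        base[:, 0] = [1.0, 2.0, 3.0]
        m = fm(base, list("abc"), ["g1", "g2"],
               {"a": "H", "b": "L", "c": "L"})
        res = run_pca(m)
        table = gene_contributions(res, retained=1)
        assert table.loc["g1", "PC1"] == pytest.approx(100.0)

    def test_contributions_sum_to_100_per_component(self, random_matrix):
        res = run_pca(random_matrix)
        table = gene_contributions(res, retained=3)
        pcs = [c for c in table.columns if c.startswith("PC")]
        np.testing.assert_allclose(table[pcs].sum(axis=0), 100.0, atol=1e-9)

    def test_total_share_worked_rule(self):
        """A gene at 50% of a component holding 70% of variance carries 35%
        of total variance."""
        loadings = pd.DataFrame(
            {"PC1": [np.sqrt(0.5), np.sqrt(0.5)], "PC2": [1.0, 0.0]},
            index=["g1", "g2"],
        )
        from hubsig.pcaclass import PCAResult

        res = PCAResult(
            sdev=np.array([1.0, 1.0]),
            proportions=np.array([0.7, 0.3]),
            cumulative=np.array([0.7, 1.0]),
            loadings=loadings,
            coords=pd.DataFrame(np.zeros((2, 2)), columns=["PC1", "PC2"]),
            row_classes=pd.Series({}),
        )
        table = gene_contributions(res, retained=1)
        assert table.loc["g1", "PC1"] == pytest.approx(50.0)
        # 50% of PC1 x 70% of variance = 35% of total
        retained_part = table.loc["g1", "PC1"] / 100 * 0.7 * 100
        assert retained_part == pytest.approx(35.0)
        assert table.loc["g1", "captured_share"] == pytest.approx(35.0 / 0.7)

    def test_total_share_identity(self, random_matrix):
        """total share of g = sum_k contribution(g,k) x proportion(k)."""
        res = run_pca(random_matrix)
        table = gene_contributions(res, retained=3)
        pcs = [f"PC{i + 1}" for i in range(len(res.proportions))]
        manual = (table[pcs].to_numpy() * res.proportions).sum(axis=1)
        np.testing.assert_allclose(table["total_share"], manual, atol=1e-10)

    def test_retained_bounds(self, random_matrix):
        res = run_pca(random_matrix)
        with pytest.raises(ValueError):
            gene_contributions(res, retained=0)
        with pytest.raises(ValueError):
            gene_contributions(res, retained=99)


class TestHierarchicalCluster:
    def test_manhattan_distance_arithmetic(self):
        m = fm([[0.0, 0.0], [3.0, 4.0]], ["a", "b"], ["g1", "g2"],
               {"a": "H", "b": "L"})
        tree = hierarchical_cluster(m)
        assert tree.linkage[0, 2] == pytest.approx(7.0)  # |3| + |4|

    def test_duplicate_rows_merge_first_at_zero(self):
        m = fm([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], list("abc"),
               ["g1", "g2"], {"a": "H", "b": "H", "c": "L"})
        tree = hierarchical_cluster(m)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_separated_classes_pure_cut(self):
        rng = np.random.default_rng(3)
        rows = np.vstack([rng.random((3, 10)), rng.random((3, 10)) + 50])
        classes = dict(zip("abcdef", ["H"] * 3 + ["L"] * 3))
        m = fm(rows, list("abcdef"), [f"g{i}" for i in range(10)], classes)
        tree = hierarchical_cluster(m)
        assert tree.purity == 1.0
        assert tree.separates_classes

    def test_clustering_on_pc_coordinates(self, random_matrix):
        res = run_pca(random_matrix)
        tree = hierarchical_cluster(random_matrix, on="pcs", result=res,
                                    retained=3)
        assert len(tree.labels) == 6

    def test_newick_export_contains_all_leaves(self, random_matrix):
        tree = hierarchical_cluster(random_matrix)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for label in tree.labels:
            assert label in nwk


def test_planted_class_separation_rate(interactome500, pathways8):
    """With hub enrichment planted in H, one of the first three PCs splits H
    from L rows with a margin in >= 95% of seeded replicates."""
    from hubsig.score import class_norm_counts, norm_connections
    from hubsig.synthcohort import default_design, generate_cohort

    groups = (("T1", "H", 20), ("T2", "H", 20), ("T3", "H", 20),
              ("T4", "L", 20), ("T5", "L", 20), ("T6", "L", 20))
    classes = {t: c for t, c, _ in groups}
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        design = default_design(interactome500, pathways8, seed=100 + rep,
                                groups=groups)
        profiles, _ = generate_cohort(design, interactome500)
        stats = norm_connections(
            class_norm_counts(profiles, group_by="cancer_type"),
            interactome500)
        genes = sorted(set(stats["gene"]))
        m = build_feature_matrix(stats, genes, classes)
        res = run_pca(m)
        for pc in res.coords.columns[:3]:
            coord = res.coords[pc]
            h_vals = coord[[t for t, c in classes.items() if c == "H"]]
            l_vals = coord[[t for t, c in classes.items() if c == "L"]]
            mid = (coord.max() + coord.min()) / 2
            if (h_vals > mid).all() and (l_vals < mid).all() or (
                (h_vals < mid).all() and (l_vals > mid).all()
            ):
                hits += 1
                break
    assert hits / n_rep >= 0.95
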