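import json

import numpy as np
import pytest

import sigvecta as sv


def _matrix(values, row_prefix="g", col_prefix="s"):
    values = np.asarray(values, float)
    return sv.AggregateMatrix(
        [f"{row_prefix}{i}" for i in range(values.shape[0])],
        [f"{col_prefix}{j}" for j in range(values.shape[1])],
        values,
    )


class TestBuildGeneMatrix:
    def test_outer_join_with_zero_fill(self):
        s1 = sv.GeneSignature("s1", {"A": 0.6, "B": -0.8})
        s2 = sv.GeneSignature("s2", {"C": 1.0})
        matrix = sv.build_gene_matrix(sv.SignatureCollection("t", [s1, s2]))
        frame = matrix.to_frame()
        assert list(frame.index) == ["A", "B", "C"]
        assert frame.loc["A", "s1"] == 0.6
        assert frame.loc["C", "s1"] == 0.0
        assert frame.loc["A", "s2"] == 0.0
        assert frame.loc["C", "s2"] == 1.0

    def test_conservation_of_coefficients(self, small_collection):
        collection, _ = small_collection
        frame = sv.build_gene_matrix(collection).to_frame()
        for sig in collection:
            for g, c in sig.gene_coeffs.items():
                assert frame.loc[g, sig.id] == c

    def test_column_count_equals_signatures(self, small_collection):
        collection, _ = small_collection
        assert sv.build_gene_matrix(collection).shape[1] == len(collection)


class TestFilterRows:
    def test_sum_change_keeps_both_tails(self):
        m = _matrix([[5, 0], [1, 0], [-4, 0]])
        kept = sv.filter_rows(m, "sum_change", top_n_per_tail=1)
        assert kept.row_labels == ["g0", "g2"]

    def test_sum_change_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = _matrix(rng.normal(size=(30, 4)))
            k = int(rng.integers(1, 10))
            kept = sv.filter_rows(m, "sum_change", top_n_per_tail=k)
            sums = {lbl: s for lbl, s in zip(m.row_labels, m.values.sum(1))}
            by = sorted(m.row_labels, key=lambda l: (-sums[l], l))
            expected = set(by[:k]) | set(sorted(m.row_labels, key=lambda l: (sums[l], l))[:k])
            assert set(kept.row_labels) == expected

    def test_variance_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(25, 5)))
        kept = sv.filter_rows(m, "variance", top_n=10)
        variances = dict(zip(m.row_labels, m.values.var(1)))
        expected = set(sorted(m.row_labels, key=lambda l: (-variances[l], l))[:10])
        assert set(kept.row_labels) == expected

    def test_constant_row_never_beats_varying_rows(self):
        m = _matrix([[1, 1, 1], [0, 2, 5], [3, -1, 0], [2, 2, 2]])
        kept = sv.filter_rows(m, "variance", top_n=2)
        assert set(kept.row_labels) == {"g1", "g2"}

    def test_excess_request_keeps_all_with_warning(self):
        m = _matrix([[1, 2], [3, 4]])
        with pytest.warns(UserWarning, match="keeping all"):
            kept = sv.filter_rows(m, "variance", top_n=10)
        assert kept.row_labels == m.row_labels

    def test_top10_per_tail_keeps_at_most_20(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(100, 6)))
        kept = sv.filter_rows(m, "sum_change", top_n_per_tail=10)
        assert kept.shape[0] <= 20


class TestPcaSignatures:
    def test_identical_signatures_map_to_origin(self):
        m = _matrix(np.tile([[1.0], [2.0], [3.0]], (1, 4)))
        res = sv.pca_signatures(m)
        assert np.allclose(res.coordinates, 0.0)
        assert np.allclose(res.variance_explained, 0.0)

    def test_two_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 0.01, (20, 8))
        base[0, :4] += 5.0  # cluster structure along a single gene
        m = _matrix(base)
        res = sv.pca_signatures(m)
        pc1 = res.coordinates[:, 0]
        assert set(np.sign(pc1[:4])) != set(np.sign(pc1[4:]))
        assert res.variance_explained[0] > 0.9

    def test_matches_full_svd_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            g, n = int(rng.integers(5, 40)), int(rng.integers(4, 12))
            m = _matrix(rng.normal(size=(g, n)))
            res = sv.pca_signatures(m)
            X = m.values.T
            Xc = X - X.mean(0)
            U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            k = min(3, n, g)
            oracle = U[:, :k] * s[:k]
            for j in range(k):
                a, b = res.coordinates[:, j], oracle[:, j]
                assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
            ve = (s**2 / (s**2).sum())[:k]
            assert np.allclose(res.variance_explained[:k], ve, atol=1e-8)

    def test_variance_explained_sorted_and_bounded(self, small_collection):
        collection, _ = small_collection
        res = sv.pca_signatures(sv.build_gene_matrix(collection))
        ve = res.variance_explained
        assert all(a >= b for a, b in zip(ve, ve[1:]))
        assert 0 <= ve.sum() <= 1 + 1e-12

    def test_fewer_than_three_signatures_zero_padded(self):
        m = _matrix(np.random.default_rng(5).normal(size=(6, 2)))
        with pytest.warns(UserWarning, match="padded"):
            res = sv.pca_signatures(m)
        assert res.coordinates.shape == (2, 3)
        assert np.allclose(res.coordinates[:, 1:], 0.0)  # only PC1 carries signal


class TestClusterOrder:
    def test_identical_columns_adjacent(self):
        rng = np.random.default_rng(6)
        cols = rng.normal(size=(10, 4))
        cols[:, 3] = cols[:, 0]  # duplicate pair s0/s3
        m = _matrix(cols)
        order = sv.cluster_order(m, "columns")
        pos = {m.column_labels[i]: rank for rank, i in enumerate(order)}
        assert abs(pos["s0"] - pos["s3"]) == 1

    def test_permutation_invariance_of_labeled_order(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(8, 5))
        m = _matrix(values)
        perm = rng.permutation(5)
        m_perm = sv.AggregateMatrix(
            m.row_labels, [m.column_labels[j] for j in perm], values[:, perm]
        )
        labels1 = [m.column_labels[i] for i in sv.cluster_order(m, "columns")]
        labels2 = [m_perm.column_labels[i] for i in sv.cluster_order(m_perm, "columns")]
        assert labels1 == labels2

    def test_single_vector_axis_rejected(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match="at least 2"):
            sv.cluster_order(m, "rows")

    def test_zero_norm_rows_handled(self):
        m = _matrix([[0, 0, 0], [1, 2, 3], [2, 4, 6], [0, 0, 0]])
        order = sv.cluster_order(m, "rows")
        assert sorted(order.tolist()) == [0, 1, 2, 3]


@pytest.fixture(scope="module")
def bundle(small_collection, small_library, small_compound_library):
    collection, _ = small_collection
    library, _ = small_library
    compounds, _ = small_compound_library
    config = sv.ReportConfig(alpha=0.05, seed=1, n_calibration_draws=60)
    return sv.build_report(collection, library, compounds, config=config)


class TestBuildReport:
    def test_bundle_has_pca_and_three_matrices(self, bundle, small_collection):
        collection, _ = small_collection
        assert bundle.pca.coordinates.shape == (len(collection), 3)
        assert bundle.gene_matrix.shape[1] == len(collection)
        assert bundle.enrichment_matrix.shape[1] == 2 * len(collection)
        assert bundle.compound_matrix.shape[1] == len(collection)

    def test_matrices_share_signature_column_universe(self, bundle, small_collection):
        collection, _ = small_collection
        assert bundle.gene_matrix.column_labels == collection.ids
        assert bundle.compound_matrix.column_labels == collection.ids
        base = [c.rsplit("|", 1)[0] for c in bundle.enrichment_matrix.column_labels[::2]]
        assert base == collection.ids

    def test_subset_restricts_columns(self, small_collection, small_library, small_compound_library):
        collection, _ = small_collection
        library, _ = small_library
        compounds, _ = small_compound_library
        ids = collection.ids[:2]
        config = sv.ReportConfig(alpha=0.05, seed=1, n_calibration_draws=60,
                                 gene_top_n_per_tail=5)
        bundle = sv.build_report(
            collection, library, compounds, config=config, subset=ids
        )
        assert bundle.gene_matrix.column_labels == ids
        assert len(bundle.enrichment_matrix.column_labels) == 4

    def test_empty_subset_rejected(self, small_collection, small_library, small_compound_library):
        collection, _ = small_collection
        library, _ = small_library
        compounds, _ = small_compound_library
        with pytest.raises(ValueError, match="zero signatures"):
            sv.build_report(collection, library, compounds, subset=["nope"])

    def test_unknown_metadata_field_lists_available(self, small_collection, small_library, small_compound_library):
        collection, _ = small_collection
        library, _ = small_library
        compounds, _ = small_compound_library
        with pytest.raises(ValueError, match="cell_line"):
            sv.build_report(collection, library, compounds, category="not_a_field")

    def test_category_attached_to_pca_points(self, small_collection, small_library, small_compound_library):
        collection, _ = small_collection
        library, _ = small_library
        compounds, _ = small_compound_library
        config = sv.ReportConfig(alpha=0.05, seed=1, n_calibration_draws=60)
        bundle = sv.build_report(
            collection, library, compounds, config=config, category="cell_line"
        )
        assert bundle.pca.categories == [s.metadata["cell_line"] for s in collection]

    def test_written_bundle_round_trips(self, bundle, tmp_path):
        files = sv.write_report(bundle, tmp_path / "report")
        assert set(files) == {"genes", "enrichment", "compounds"}
        manifest = json.loads((tmp_path / "report" / "manifest.json").read_text())
        assert manifest["tag"] == bundle.tag
        back = sv.read_report_matrix(tmp_path / "report" / "genes.tsv")
        assert back.row_labels == bundle.gene_matrix.row_labels
        assert np.allclose(back.values, bundle.gene_matrix.values, rtol=1e-11)
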