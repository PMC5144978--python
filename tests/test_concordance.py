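"""Cross-study correlation, optimal matching, label transfer, summaries."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from crossclust import (
    ExpressionDataset,
    assign_reference_labels,
    compute_concordance,
    concordance_summary,
    cross_dataset_correlations,
    crosstab_assignments,
    flag_nonconcordant,
    match_clusters,
    pearson_correlation,
)
from crossclust.cluster import ClusterAssignment
from crossclust.sam import TScoreMatrix


def _tmat(name, scores: np.ndarray, genes=None, k=None):
    k = k or scores.shape[1]
    genes = genes or [f"g{i}" for i in range(scores.shape[0])]
    frame = pd.DataFrame(
        scores, index=genes, columns=[f"cluster_{c}" for c in range(1, k + 1)]
    )
    return TScoreMatrix(dataset_name=name, algorithm="kmeans", k=k, scores=frame, s0=[0.1] * k)


class TestPearson:
    def test_identity_and_negation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_textbook_formula_value(self):
        assert pearson_correlation([1, 2, 3, 4], [1, 2, 3, 10]) == pytest.approx(
            0.8854377448471462
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestCrossDatasetCorrelations:
    def test_self_comparison_at_k2_is_antisymmetric(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        tm = _tmat("a", np.column_stack([col, -col]))
        m = cross_dataset_correlations(tm, tm).to_numpy()
        np.testing.assert_allclose(m, [[1, -1], [-1, 1]], atol=1e-12)

    def test_column_permutation_appears_in_argmax_pattern(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(80, 3))
        ta = _tmat("a", scores)
        tb = _tmat("b", scores[:, [2, 0, 1]])
        m = cross_dataset_correlations(ta, tb).to_numpy()
        assert m.argmax(axis=1).tolist() == [1, 2, 0]

    def test_gene_order_mismatch_detected(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(10, 2))
        ta = _tmat("a", scores)
        tb = _tmat("b", scores, genes=[f"g{i}" for i in reversed(range(10))])
        with pytest.raises(ValueError, match="gene universes differ"):
            cross_dataset_correlations(ta, tb)

    def test_gene_permutation_applied_to_both_leaves_corr_unchanged(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(40, 3))
        b = rng.normal(size=(40, 3))
        m1 = cross_dataset_correlations(_tmat("a", a), _tmat("b", b)).to_numpy()
        perm = rng.permutation(40)
        genes = [f"g{i}" for i in perm]
        m2 = cross_dataset_correlations(
            _tmat("a", a[perm], genes=genes), _tmat("b", b[perm], genes=genes)
        ).to_numpy()
        np.testing.assert_allclose(m1, m2, atol=1e-12)


class TestMatchClusters:
    def test_dominant_diagonal_gives_identity(self):
        c = np.full((3, 3), 0.1)
        np.fill_diagonal(c, 0.9)
        assert match_clusters(c) == {1: 1, 2: 2, 3: 3}

    def test_permuted_dominant_matrix_recovers_permutation(self):
        c = np.full((4, 4), 0.1)
        perm = [2, 0, 3, 1]
        for i, j in enumerate(perm):
            c[i, j] = 0.9
        assert match_clusters(c) == {i + 1: j + 1 for i, j in enumerate(perm)}

    def test_equals_brute_force_on_100_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = rng.uniform(-1, 1, size=(4, 4))
            got = match_clusters(c)
            best = max(
                permutations(range(4)),
                key=lambda p: sum(c[i, p[i]] for i in range(4)),
            )
            brute = sum(c[i, best[i]] for i in range(4))
            total = sum(c[i - 1, j - 1] for i, j in got.items())
            assert total == pytest.approx(brute, abs=1e-9)

    def test_greedy_method_is_a_bijection(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(-1, 1, size=(5, 5))
        bij = match_clusters(c, method="greedy")
        assert sorted(bij) == [1, 2, 3, 4, 5]
        assert sorted(bij.values()) == [1, 2, 3, 4, 5]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            match_clusters(np.ones((2, 3)))

    def test_matching_symmetry_forward_inverse(self):
        rng = np.random.default_rng(8)
        c = rng.uniform(-1, 1, size=(4, 4))
        fwd = match_clusters(c)
        rev = match_clusters(c.T)
        assert {j: i for i, j in fwd.items()} == rev


class TestReferenceLabels:
    def test_swap_matching_transfers_swapped_labels(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=200)
        col2 = rng.normal(size=200)
        ref = _tmat("ref", np.column_stack([col, col2]))
        other = _tmat("other", np.column_stack([col2, col]))  # swapped
        labels = assign_reference_labels(
            {"ref": ref, "other": other},
            "ref",
            {1: "mesenchymal-like", 2: "proliferative-like"},
        )
        assert labels[("ref", 1)] == "mesenchymal-like"
        assert labels[("other", 1)] == "proliferative-like"
        assert labels[("other", 2)] == "mesenchymal-like"

    def test_missing_reference_rejected(self):
        tm = _tmat("a", np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError, match="missing"):
            assign_reference_labels({"a": tm}, "nope", {1: "x", 2: "y"})

    def test_incomplete_label_map_rejected(self):
        tm = _tmat("a", np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError, match="lacks clusters"):
            assign_reference_labels({"a": tm}, "a", {1: "x"})


class TestSummaryAndFlags:
    @staticmethod
    def _three_studies(seed=0, decorrelate=None):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(300, 2))
        tmats = {}
        for name in ("a", "b", "c"):
            if name == decorrelate:
                scores = rng.normal(size=(300, 2))
            else:
                scores = base + rng.normal(scale=0.4, size=base.shape)
            tmats[name] = _tmat(name, scores)
        return tmats

    def test_singleton_pair_gives_degenerate_range(self):
        tmats = {k: v for k, v in self._three_studies().items() if k in ("a", "b")}
        result = compute_concordance(tmats)
        summary = concordance_summary(result)
        assert (summary["r_min"] == summary["r_max"]).all()
        assert (summary["n_pairs"] == 1).all()

    def test_exclusion_removes_exactly_those_pairs(self):
        result = compute_concordance(self._three_studies())
        full = concordance_summary(result)
        reduced = concordance_summary(result, exclude={"c"})
        retained = reduced[reduced["block"] == "retained"]
        # excluding c drops its two pairs (a-c and b-c) from every cluster
        assert (retained["n_pairs"] == full["n_pairs"] - 2).all()
        assert set(reduced["block"]) == {"retained", "excluded:c"}

    def test_decorrelated_study_is_flagged(self):
        tmats = self._three_studies(seed=1, decorrelate="c")
        result = compute_concordance(tmats)
        assert flag_nonconcordant(result, threshold=0.3) == {"c"}
        summary = concordance_summary(result, exclude={"c"})
        retained = summary[summary["block"] == "retained"]
        excluded = summary[summary["block"] == "excluded:c"]
        assert retained["r_min"].min() > excluded["r_max"].max()


class TestCrosstab:
    @staticmethod
    def _assignment(labels: dict[str, int]):
        return ClusterAssignment(
            dataset_name="d", algorithm="kmeans", k=max(labels.values()),
            labels=pd.Series(labels, name="cluster"), seed=0, objective=0.0,
        )

    def test_identical_labelings_give_diagonal_table(self):
        asg = self._assignment({"s1": 1, "s2": 1, "s3": 2, "s4": 2})
        orig = pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        table = crosstab_assignments(asg, orig)
        assert table.loc["cluster_1", "A"] == 2
        assert table.loc["cluster_2", "B"] == 2
        assert table.to_numpy().sum() == 4
        assert table.loc["cluster_1", "B"] == 0

    def test_all_unlabeled_collapse_into_nc_na(self):
        asg = self._assignment({"s1": 1, "s2": 2, "s3": 2})
        orig = pd.Series(dtype=object)
        table = crosstab_assignments(asg, orig)
        assert list(table.columns) == ["NC/NA"]
        assert table["NC/NA"].sum() == 3

    def test_diagonal_fraction_equals_direct_accuracy(self, small_collection):
        datasets, truth = small_collection
        from crossclust import kmeans_partition, select_union_gene_set

        gene_set = select_union_gene_set(list(datasets), 50, "mad")
        ds = datasets[0]
        asg = kmeans_partition(ds, gene_set, k=3, seed=4)
        orig = truth.labels[ds.name]
        table = crosstab_assignments(asg, orig)
        # align clusters to majority original label, then diagonal fraction
        best = table.drop(columns=["NC/NA"], errors="ignore").idxmax(axis=1)
        diag = sum(table.loc[row, lab] for row, lab in best.items())
        acc = (asg.labels.map(lambda c: best[f"cluster_{c}"]) == orig).mean()
        assert diag / table.to_numpy().sum() == pytest.approx(acc)
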