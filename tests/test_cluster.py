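"""Clustering engines: k-means, KL-NMF, consensus matrices, cophenetic ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from crossclust import (
    ExpressionDataset,
    center_genes,
    consensus_matrix,
    cophenetic_profile,
    kmeans_partition,
    nmf_assign,
    nmf_factorize,
    nonnegative_fold,
)
from crossclust.cluster import _consensus_cophenetic


def _dataset(x: np.ndarray, name="d"):
    values = pd.DataFrame(
        np.asarray(x, dtype=float),
        index=[f"g{i}" for i in range(x.shape[0])],
        columns=[f"s{j}" for j in range(x.shape[1])],
    )
    return ExpressionDataset(name, values)


class TestCenterGenes:
    def test_median_center(self):
        ds = _dataset(np.array([[1, 2, 3]]))
        out = center_genes(ds, "median_center")
        assert out.values.loc["g0"].tolist() == [-1.0, 0.0, 1.0]

    def test_none_is_identity(self):
        ds = _dataset(np.array([[1, 2, 3]]))
        assert center_genes(ds, "none") is ds

    def test_zscore_flags_constant_genes(self):
        ds = _dataset(np.array([[5, 5, 5], [1, 2, 3]]))
        out = center_genes(ds, "zscore")
        assert out.values.loc["g0"].tolist() == [0.0, 0.0, 0.0]
        assert out.ingest_report["zero_sd_genes"] == ["g0"]


class TestKMeans:
    def test_separable_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, size=(5, 10))
        b = rng.normal(10.0, 0.1, size=(5, 10))
        ds = _dataset(np.hstack([a, b]))
        asg = kmeans_partition(ds, ds.genes, k=2, seed=1, center="none")
        labels = asg.labels.to_numpy()
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_samples_gives_zero_objective(self):
        rng = np.random.default_rng(1)
        ds = _dataset(rng.normal(size=(4, 5)))
        asg = kmeans_partition(ds, ds.genes, k=5, seed=0, center="none")
        assert asg.objective == pytest.approx(0.0, abs=1e-12)
        assert sorted(asg.labels) == [1, 2, 3, 4, 5]

    def test_k_above_n_samples_rejected(self):
        ds = _dataset(np.random.default_rng(2).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_partition(ds, ds.genes, k=4, seed=0)

    def test_objective_non_increasing_in_n_init(self):
        rng = np.random.default_rng(3)
        ds = _dataset(rng.normal(size=(6, 30)))
        objs = [
            kmeans_partition(ds, ds.genes, 4, n_init=n, seed=9, center="none").objective
            for n in (1, 5, 20)
        ]
        assert objs[0] >= objs[1] >= objs[2]


class TestNonnegativeFold:
    def test_signed_row_splits(self):
        out = nonnegative_fold(np.array([[1.0, -2.0, 0.0]]))
        assert out.tolist() == [[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]]

    def test_nonnegative_input_has_zero_negative_block(self):
        x = np.abs(np.random.default_rng(0).normal(size=(3, 4)))
        out = nonnegative_fold(x)
        assert np.all(out[3:] == 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64, (4, 6),
            elements=st.floats(-100, 100, allow_nan=False, width=64),
        )
    )
    def test_reconstruction_identity(self, x):
        out = nonnegative_fold(x)
        np.testing.assert_array_equal(out[:4] - out[4:], x)


def _independent_kl(v, w, h, eps=1e-12):
    wh = np.maximum(w @ h, eps)
    mask = v > 0
    return float(
        np.sum(np.where(mask, v * np.log(np.where(mask, v, 1.0) / wh), 0.0) - v + wh)
    )


class TestNMF:
    def test_rank_one_matrix_reconstructs(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([2.0, 1.0, 4.0, 0.5])
        x = np.outer(u, v)
        fit = nmf_factorize(x, k=1, seed=0, max_iter=500)
        assert fit.divergence == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(fit.W @ fit.H, x, atol=1e-3)

    def test_block_diagonal_blocks_recovered(self):
        rng = np.random.default_rng(4)
        x = np.zeros((8, 10))
        x[:4, :5] = rng.uniform(1, 2, size=(4, 5))
        x[4:, 5:] = rng.uniform(1, 2, size=(4, 5))
        fit = nmf_factorize(x, k=2, seed=1)
        labels = nmf_assign(fit.H)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_divergence_trace_monotone_and_independently_recomputed(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 3, size=(6, 8))
        fit = nmf_factorize(x, k=2, seed=3, max_iter=200)
        trace = np.array(fit.divergence_trace)
        # monotone non-increasing up to numerical tolerance
        assert np.all(np.diff(trace) <= 1e-8 * np.maximum(1.0, trace[:-1]))
        # final divergence agrees with an independent KL evaluation
        assert fit.divergence == pytest.approx(
            _independent_kl(x, fit.W, fit.H), rel=1e-10
        )

    def test_matches_reference_mu_solver_quality(self):
        # an established MU/KL implementation should reach a comparable
        # divergence on the same matrix — guards against a broken update rule
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(5)
        x = rng.uniform(0.0, 2.0, size=(20, 15))
        ours = nmf_factorize(x, k=3, seed=2, max_iter=1000)
        ref = NMF(
            n_components=3, solver="mu", beta_loss="kullback-leibler",
            init="random", random_state=0, max_iter=2000, tol=1e-8,
        )
        w = ref.fit_transform(x)
        ref_div = _independent_kl(x, w, ref.components_)
        assert ours.divergence <= ref_div * 1.1 + 1e-6

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nmf_factorize(np.array([[1.0, -1.0]]), k=1)

    def test_k_beyond_rank_bound_rejected(self):
        with pytest.raises(ValueError, match="rank bound"):
            nmf_factorize(np.ones((3, 4)), k=4)


class TestNMFAssign:
    def test_argmax_and_tie_rule(self):
        h = np.array([[0.1, 0.5, 1.0], [0.9, 0.5, 0.0]])
        assert nmf_assign(h).tolist() == [2, 1, 1]

    def test_identity_like_assignment(self):
        assert nmf_assign(np.eye(3)).tolist() == [1, 2, 3]

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            nmf_assign(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestConsensusCophenetic:
    def test_perfect_two_block_consensus_is_exactly_one(self):
        c = np.ones((6, 6)) * 0.0
        c[:3, :3] = 1.0
        c[3:, 3:] = 1.0
        coph, _ = _consensus_cophenetic(c.copy())
        assert coph == pytest.approx(1.0)

    def test_constant_consensus_is_undefined(self):
        coph, _ = _consensus_cophenetic(np.ones((5, 5)))
        assert coph is None

    def test_hand_built_four_point_instance_matches_enumeration(self):
        c = np.array(
            [[1.0, 0.9, 0.1, 0.1],
             [0.9, 1.0, 0.1, 0.1],
             [0.1, 0.1, 1.0, 0.8],
             [0.1, 0.1, 0.8, 1.0]]
        )
        # brute-force average linkage on d = 1 - c:
        #   merge {1,2} at 0.1, merge {3,4} at 0.2,
        #   merge the two pairs at mean(0.9 x4) = 0.9
        # cophenetic distances: (1,2)=0.1, (3,4)=0.2, all cross pairs 0.9
        d = np.array([0.1, 0.9, 0.9, 0.9, 0.9, 0.2])
        t = np.array([0.1, 0.9, 0.9, 0.9, 0.9, 0.2])
        expected = np.corrcoef(d, t)[0, 1]
        coph, _ = _consensus_cophenetic(c.copy())
        assert coph == pytest.approx(expected, abs=1e-12)

    def test_consensus_entries_symmetry_and_grid(self, small_collection):
        datasets, _ = small_collection
        ds = datasets[0]
        genes = ds.genes[:80]
        res = consensus_matrix(ds, genes, k=3, n_runs=4, seed=2, max_iter=120)
        c = res.consensus.to_numpy()
        np.testing.assert_array_equal(c, c.T)
        np.testing.assert_array_equal(np.diag(c), np.ones(ds.n_samples))
        np.testing.assert_array_equal(c * 4, np.round(c * 4))
        assert res.cophenetic is None or -1.0 <= res.cophenetic <= 1.0

    def test_profile_reports_per_k_and_best(self, small_collection):
        datasets, _ = small_collection
        ds = datasets[0]
        genes = ds.genes[:80]
        profile = cophenetic_profile(ds, genes, (2, 3), n_runs=3, seed=5, max_iter=120)
        assert set(profile.values) == {2, 3}
        assert profile.best_k in (2, 3, None)
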