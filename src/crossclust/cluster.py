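"""Clustering engines: best-of-N k-means, KL-divergence NMF, and NMF consensus
clustering with cophenetic rank diagnostics.

Each study is clustered independently.  k-means runs on the gene-centered,
union-gene-restricted matrix with samples as observations, keeping the best
of ``n_init`` random restarts by within-cluster sum of squares.  NMF follows
the multiplicative-update algorithm for the generalized Kullback-Leibler
divergence on a nonnegative fold of the centered matrix (positive and
negative parts stacked as separate rows); samples are assigned to the
metagene with the largest coefficient.  Repeated NMF runs are aggregated into
a consensus (co-clustering frequency) matrix whose cophenetic correlation —
agreement between 1 - consensus distances and the merge heights of an
average-linkage tree — serves as the rank-selection diagnostic over k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .datasets import ExpressionDataset
from .features import GeneSet

__all__ = [
    "ClusterAssignment",
    "ConsensusResult",
    "CopheneticProfile",
    "center_genes",
    "kmeans_partition",
    "nonnegative_fold",
    "nmf_factorize",
    "nmf_assign",
    "nmf_partition",
    "consensus_matrix",
    "cophenetic_profile",
]

CENTER_MODES = ("median_center", "zscore", "none")


@dataclass
class ClusterAssignment:
    """A partition of one dataset's samples into k non-empty clusters."""

    dataset_name: str
    algorithm: str  # "kmeans" or "nmf"
    k: int
    labels: pd.Series  # sample_id -> cluster index in 1..k
    seed: int
    objective: float  # within-cluster SS (kmeans) / KL divergence (nmf)

    def __post_init__(self) -> None:
        present = set(self.labels.unique())
        if present != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must use every cluster 1..{self.k}, got {sorted(present)}"
            )

    def cluster_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


# ------------------------------------------------------------- preprocessing

def center_genes(
    dataset: ExpressionDataset, mode: str = "median_center"
) -> ExpressionDataset:
    """Per-gene transformation within a dataset.

    ``median_center`` subtracts the gene median; ``zscore`` additionally
    divides by the gene standard deviation (zero-sd genes stay centered and
    are flagged in ``ingest_report["zero_sd_genes"]``); ``none`` is the
    identity.
    """
    if mode not in CENTER_MODES:
        raise ValueError(f"unknown center mode {mode!r}")
    if mode == "none":
        return dataset
    x = dataset.matrix()
    centered = x - np.median(x, axis=1, keepdims=True)
    flagged: list[str] = []
    if mode == "zscore":
        sd = x.std(axis=1, ddof=1, keepdims=True)
        zero = sd[:, 0] == 0
        sd[zero, :] = 1.0
        centered = centered / sd
        flagged = [g for g, z in zip(dataset.genes, zero) if z]
    out = dataset.with_values(
        pd.DataFrame(centered, index=dataset.genes, columns=dataset.samples)
    )
    if flagged:
        out.ingest_report["zero_sd_genes"] = flagged
    return out


def _clustering_matrix(
    dataset: ExpressionDataset, gene_set: GeneSet | Sequence[str], center: str
) -> np.ndarray:
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    restricted = center_genes(dataset.subset_genes(genes), center)
    return restricted.matrix()


# ------------------------------------------------------------------- k-means

def kmeans_partition(
    dataset: ExpressionDataset,
    gene_set: GeneSet | Sequence[str],
    k: int,
    n_init: int = 20,
    seed: int = 0,
    center: str = "median_center",
) -> ClusterAssignment:
    """Best-of-``n_init`` Euclidean k-means on the selected-gene space.

    Samples are the observations; each restart starts from seeded random
    centers and the run with the lowest within-cluster sum of squares wins.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > dataset.n_samples:
        raise ValueError(f"k={k} exceeds the {dataset.n_samples} samples")
    obs = _clustering_matrix(dataset, gene_set, center).T
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        init="random",
        algorithm="lloyd",
        random_state=_u32(seed),
    ).fit(obs)
    labels = pd.Series(km.labels_ + 1, index=dataset.samples, name="cluster")
    return ClusterAssignment(
        dataset_name=dataset.name,
        algorithm="kmeans",
        k=k,
        labels=labels,
        seed=seed,
        objective=float(km.inertia_),
    )


def _u32(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0])


# ----------------------------------------------------------------------- NMF

def nonnegative_fold(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Split each signed gene row g into g+ = max(x, 0) and g- = max(-x, 0).

    The output stacks all positive parts above all negative parts, doubling
    the row count; the input is recovered exactly as g+ - g-.
    """
    if isinstance(matrix, pd.DataFrame):
        pos = matrix.clip(lower=0)
        neg = (-matrix).clip(lower=0)
        pos.index = [f"{g}+" for g in matrix.index]
        neg.index = [f"{g}-" for g in matrix.index]
        return pd.concat([pos, neg], axis=0)
    x = np.asarray(matrix, dtype=float)
    return np.vstack([np.maximum(x, 0.0), np.maximum(-x, 0.0)])


@dataclass
class NMFFit:
    """Result of one multiplicative-update NMF run."""

    W: np.ndarray
    H: np.ndarray
    divergence: float
    divergence_trace: list[float] = field(repr=False)
    n_iter: int = 0
    converged: bool = False


def _kl_divergence(v: np.ndarray, wh: np.ndarray, eps: float) -> float:
    # generalized KL: sum(v*log(v/wh) - v + wh); v log v term only where v > 0
    wh = np.maximum(wh, eps)
    pos = v > 0
    term = np.where(pos, v * np.log(np.where(pos, v, 1.0) / wh), 0.0)
    return float(np.sum(term - v + wh))


def nmf_factorize(
    matrix: np.ndarray | pd.DataFrame,
    k: int,
    max_iter: int = 500,
    seed: int = 0,
    check_interval: int = 10,
    stall_checks: int = 4,
    eps: float = 1e-12,
) -> NMFFit:
    """Multiplicative-update NMF minimizing generalized KL divergence.

    Random uniform initialization from a seeded generator.  Iteration stops
    early once the sample connectivity (argmax cluster of each H column) has
    been unchanged for ``stall_checks`` consecutive checks spaced
    ``check_interval`` iterations apart, or at ``max_iter``.  The divergence
    is recorded at every iterate and is non-increasing up to numerical
    tolerance.
    """
    v = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if np.any(v < 0):
        raise ValueError("NMF input must be nonnegative")
    m, n = v.shape
    if k < 1 or k > min(m, n):
        raise ValueError(f"k={k} outside the rank bound 1..{min(m, n)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(v.mean(), eps) / k)
    w = rng.uniform(eps, 1.0, size=(m, k)) * scale
    h = rng.uniform(eps, 1.0, size=(k, n)) * scale

    trace: list[float] = [_kl_divergence(v, w @ h, eps)]
    prev_labels: np.ndarray | None = None
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wh = np.maximum(w @ h, eps)
        h *= (w.T @ (v / wh)) / np.maximum(w.sum(axis=0)[:, None], eps)
        wh = np.maximum(w @ h, eps)
        w *= ((v / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], eps)
        trace.append(_kl_divergence(v, w @ h, eps))
        if it % check_interval == 0:
            labels = h.argmax(axis=0)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                stable += 1
                if stable >= stall_checks:
                    converged = True
                    break
            else:
                stable = 0
            prev_labels = labels
    return NMFFit(
        W=w, H=h, divergence=trace[-1], divergence_trace=trace,
        n_iter=it, converged=converged,
    )


def nmf_assign(h: np.ndarray) -> np.ndarray:
    """Assign each sample (column of H) to its largest metagene coefficient.

    Ties go to the lowest cluster index; an all-zero column is unassignable.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h.max(axis=0) == 0):
        bad = int(np.argmax(h.max(axis=0) == 0))
        raise ValueError(f"sample column {bad} has all-zero coefficients")
    return h.argmax(axis=0) + 1  # np.argmax takes the first (lowest) maximum


def nmf_partition(
    dataset: ExpressionDataset,
    gene_set: GeneSet | Sequence[str],
    k: int,
    n_init: int = 100,
    seed: int = 0,
    center: str = "median_center",
    max_iter: int = 500,
) -> ClusterAssignment:
    """Best-of-``n_init`` NMF clustering (lowest final KL divergence wins)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    x = _clustering_matrix(dataset, gene_set, center)
    v = nonnegative_fold(x)
    run_seeds = np.random.SeedSequence(seed).generate_state(n_init)
    best: NMFFit | None = None
    best_any: NMFFit | None = None
    for rs in run_seeds:
        fit = nmf_factorize(v, k, max_iter=max_iter, seed=int(rs))
        if best_any is None or fit.divergence < best_any.divergence:
            best_any = fit
        # a run whose assignment leaves a metagene empty cannot yield a
        # valid k-partition; prefer the best run among fully populated ones
        populated = len(set(fit.H.argmax(axis=0))) == k
        if populated and (best is None or fit.divergence < best.divergence):
            best = fit
    if best is None:
        raise ValueError(
            f"no NMF run among {n_init} populated all {k} clusters "
            f"(best divergence {best_any.divergence:.4g})"
        )
    labels = nmf_assign(best.H)
    return ClusterAssignment(
        dataset_name=dataset.name,
        algorithm="nmf",
        k=k,
        labels=pd.Series(labels, index=dataset.samples, name="cluster"),
        seed=seed,
        objective=best.divergence,
    )


# ----------------------------------------------------------------- consensus

@dataclass
class ConsensusResult:
    """Co-clustering frequencies over repeated NMF runs, plus the cophenetic
    correlation of the induced hierarchy.

    ``cophenetic`` is ``None`` when undefined (zero variance among
    off-diagonal consensus entries, e.g. every run produced one effective
    cluster) — an explicit marker, never a silent number.
    """

    consensus: pd.DataFrame
    k: int
    n_runs: int
    cophenetic: float | None
    linkage_heights: np.ndarray | None = field(repr=False, default=None)


def _consensus_cophenetic(consensus: np.ndarray) -> tuple[float | None, np.ndarray | None]:
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if condensed.size == 0 or np.ptp(condensed) == 0:
        return None, None
    z = linkage(condensed, method="average")
    coph, _ = cophenet(z, condensed)
    if not np.isfinite(coph):
        return None, z
    return float(coph), z


def consensus_matrix(
    dataset: ExpressionDataset,
    gene_set: GeneSet | Sequence[str],
    k: int,
    n_runs: int = 10,
    seed: int = 0,
    center: str = "median_center",
    max_iter: int = 500,
) -> ConsensusResult:
    """Average connectivity over ``n_runs`` seeded NMF factorizations.

    Entry (i, j) is the fraction of runs in which samples i and j shared an
    argmax cluster; the matrix is exactly symmetric with unit diagonal.  The
    cophenetic coefficient is the Pearson correlation between the
    off-diagonal 1 - consensus distances and the cophenetic (merge-height)
    distances of the average-linkage tree built on them.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_runs < 2:
        raise ValueError("need at least two consensus runs")
    x = _clustering_matrix(dataset, gene_set, center)
    v = nonnegative_fold(x)
    n = dataset.n_samples
    counts = np.zeros((n, n), dtype=np.int64)
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    for rs in run_seeds:
        fit = nmf_factorize(v, k, max_iter=max_iter, seed=int(rs))
        labels = fit.H.argmax(axis=0)
        counts += labels[:, None] == labels[None, :]
    consensus = counts / float(n_runs)
    coph, z = _consensus_cophenetic(consensus.copy())
    frame = pd.DataFrame(consensus, index=dataset.samples, columns=dataset.samples)
    return ConsensusResult(
        consensus=frame, k=k, n_runs=n_runs, cophenetic=coph, linkage_heights=z
    )


@dataclass
class CopheneticProfile:
    """Cophenetic coefficients over a range of candidate cluster numbers."""

    results: dict[int, ConsensusResult]

    @property
    def values(self) -> dict[int, float | None]:
        return {k: r.cophenetic for k, r in sorted(self.results.items())}

    @property
    def best_k(self) -> int | None:
        defined = {k: v for k, v in self.values.items() if v is not None}
        if not defined:
            return None
        return max(defined, key=lambda k: (defined[k], -k))


def cophenetic_profile(
    dataset: ExpressionDataset,
    gene_set: GeneSet | Sequence[str],
    k_range: Sequence[int] = range(2, 9),
    n_runs: int = 10,
    seed: int = 0,
    center: str = "median_center",
    max_iter: int = 500,
) -> CopheneticProfile:
    """One :func:`consensus_matrix` per k; undefined markers propagate."""
    k_seeds = np.random.SeedSequence(seed).generate_state(len(list(k_range)))
    results = {
        int(k): consensus_matrix(
            dataset, gene_set, int(k), n_runs=n_runs, seed=int(ks),
            center=center, max_iter=max_iter,
        )
        for k, ks in zip(k_range, k_seeds)
    }
    return CopheneticProfile(results=results)
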