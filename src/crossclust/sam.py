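"""SAM moderated t-statistics summarizing each cluster against the rest.

Every cluster of a clustering is summarized as one vector over the shared
gene universe: for gene *i* the two-class unpaired statistic

    d_i = (mean_1i - mean_2i) / (s_i + s0)

where group 1 is the cluster, group 2 all remaining samples of the same
dataset, s_i the pooled standard error, and s0 the SAM "fudge factor" that
keeps low-dispersion genes from dominating.  These vectors — not gene lists
or q-values — are what the cross-study concordance stage correlates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .datasets import ExpressionDataset

__all__ = [
    "TScoreMatrix",
    "pooled_denominator",
    "estimate_s0",
    "moderated_t_matrix",
]

S0_METHODS = ("percentile_grid", "fixed_percentile")

#: Phi^{-1}(3/4): divisor making the MAD consistent for a normal sd
_NORMAL_MAD_SCALE = 0.6744897501960817


@dataclass
class TScoreMatrix:
    """genes x clusters matrix of moderated t statistics for one clustering.

    ``scores`` columns are ``cluster_1 .. cluster_k`` in cluster-index order;
    rows follow the shared gene-universe order.  ``s0`` records the fudge
    factor used for each one-vs-rest comparison.
    """

    dataset_name: str
    algorithm: str
    k: int
    scores: pd.DataFrame
    s0: list[float]

    def __post_init__(self) -> None:
        if self.scores.shape[1] != self.k:
            raise ValueError("column count must equal k")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("t-score matrix contains non-finite entries")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def column(self, cluster: int) -> np.ndarray:
        return self.scores[f"cluster_{cluster}"].to_numpy()


def pooled_denominator(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Mean difference and pooled standard error for two unpaired groups.

    s = sqrt[(1/n1 + 1/n2) * (SS1 + SS2) / (n1 + n2 - 2)] with SSg the
    within-group sum of squared deviations.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least two values")
    mean_diff = g1.mean() - g2.mean()
    ss1 = np.sum((g1 - g1.mean()) ** 2)
    ss2 = np.sum((g2 - g2.mean()) ** 2)
    n1, n2 = g1.size, g2.size
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return float(mean_diff), float(s)


def _two_class_stats(x: np.ndarray, in_group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mean differences and pooled denominators for all genes."""
    g1 = x[:, in_group]
    g2 = x[:, ~in_group]
    n1, n2 = g1.shape[1], g2.shape[1]
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    ss1 = ((g1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((g2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return m1 - m2, s


def estimate_s0(
    mean_diffs: np.ndarray,
    s_values: np.ndarray,
    method: str = "percentile_grid",
    fixed_q: float = 0.05,
    n_windows: int = 100,
) -> float:
    """Estimate the SAM fudge factor s0.

    ``percentile_grid`` is the Tusher/Chu procedure: candidate s0 values are
    the quantiles of s at 0%, 5%, ..., 100%; for each candidate the genes are
    split into ``n_windows`` equal-count windows by s, the MAD (normal scale)
    of d = r/(s + s0) is taken within each window, and the candidate
    minimizing the coefficient of variation of those window MADs is chosen
    (smallest candidate on ties).  ``fixed_percentile`` simply returns the
    ``fixed_q`` quantile of s.
    """
    r = np.asarray(mean_diffs, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if r.shape != s.shape:
        raise ValueError("mean_diffs and s_values must have equal length")
    if not np.any(s > 0):
        raise ValueError("all pooled denominators are zero")
    if method == "fixed_percentile":
        return float(np.quantile(s, fixed_q))
    if method != "percentile_grid":
        raise ValueError(f"unknown s0 method {method!r}")
    if r.size < 100:
        raise ValueError("percentile_grid needs at least 100 genes")
    if s.max() == s.min():
        # every candidate quantile coincides; any choice is equivalent
        return float(s[0])

    candidates = np.quantile(s, np.arange(0, 21) / 20.0)
    order = np.argsort(s, kind="stable")
    windows = [w for w in np.array_split(order, n_windows) if w.size]
    # all candidates at once: D[a, i] = r_i / (s_i + s0_a); the candidate
    # s0 = 0 can hit constant genes (r = s = 0), whose nan poisons that
    # candidate's cv and removes it from contention
    with np.errstate(invalid="ignore", divide="ignore"):
        d_all = r[None, :] / (s[None, :] + candidates[:, None])
    v = np.empty((candidates.size, len(windows)))
    for j, w in enumerate(windows):
        block = d_all[:, w]
        med = np.median(block, axis=1, keepdims=True)
        # MAD about the median, normal-consistent (same scaling as
        # scipy.stats.median_abs_deviation(scale="normal"))
        v[:, j] = np.median(np.abs(block - med), axis=1) / _NORMAL_MAD_SCALE
    mean_v = v.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean_v > 0, v.std(axis=1, ddof=1) / mean_v, np.inf)
    best = np.flatnonzero(np.isclose(cv, cv.min(), rtol=0, atol=1e-15))
    return float(candidates[best].min())


def moderated_t_matrix(
    dataset: ExpressionDataset,
    assignment: ClusterAssignment,
    gene_universe: Sequence[str] | None = None,
    s0_method: str = "percentile_grid",
    s0_fixed: float | None = None,
) -> TScoreMatrix:
    """One-vs-rest moderated t vectors for every cluster of an assignment.

    For each cluster c the statistic d_i = r_i / (s_i + s0) compares the
    cluster's samples against all other samples of the same dataset, gene by
    gene over ``gene_universe`` (defaults to the dataset's full gene list).
    s0 is estimated once per comparison unless ``s0_fixed`` pins it.
    Constant genes (r = 0, s = 0) score exactly 0.
    """
    ds = dataset if gene_universe is None else dataset.subset_genes(list(gene_universe))
    labels = assignment.labels.reindex(ds.samples)
    if labels.isna().any():
        raise ValueError("assignment does not cover every sample of the dataset")
    x = ds.matrix()
    k = assignment.k
    columns = {}
    s0_used: list[float] = []
    for c in range(1, k + 1):
        in_group = (labels == c).to_numpy()
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ValueError(
                f"cluster {c} or its complement has fewer than two samples"
            )
        r, s = _two_class_stats(x, in_group)
        s0 = float(s0_fixed) if s0_fixed is not None else estimate_s0(r, s, s0_method)
        denom = s + s0
        d = np.zeros_like(r)
        nz = denom > 0
        d[nz] = r[nz] / denom[nz]
        # denom == 0 only when s == s0 == 0, i.e. a constant gene: d stays 0
        columns[f"cluster_{c}"] = d
        s0_used.append(s0)
    scores = pd.DataFrame(columns, index=ds.genes)
    return TScoreMatrix(
        dataset_name=dataset.name,
        algorithm=assignment.algorithm,
        k=k,
        scores=scores,
        s0=s0_used,
    )
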