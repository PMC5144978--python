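"""Model/results front end for the cross-study subtype concordance analysis.

:class:`SubtypeConcordance` is built from a collection of study datasets and
holds the analysis settings; :meth:`SubtypeConcordance.fit` runs selection,
per-study clustering with both algorithms, moderated-t summaries and
cross-study matching, and returns a :class:`SubtypeConcordanceResults`
carrying the estimates with a ``summary()`` table of matched-correlation
ranges per k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cluster as _cluster
from .cluster import ClusterAssignment, CopheneticProfile, cophenetic_profile
from .concordance import (
    ConcordanceResult,
    compute_concordance,
    concordance_summary,
    flag_nonconcordant,
)
from .datasets import (
    ExpressionDataset,
    apply_inclusion_filter,
    intersect_gene_universe,
    load_expression_matrix,
    load_sample_annotations,
)
from .features import GeneSet, select_union_gene_set
from .sam import TScoreMatrix, moderated_t_matrix

__all__ = ["SubtypeConcordance", "SubtypeConcordanceResults"]


class SubtypeConcordance:
    """Cross-study subtype concordance model over a collection of datasets.

    Parameters
    ----------
    datasets : list of ExpressionDataset
        Studies to analyze; gene universes are intersected on construction.
    n_per_dataset : int
        Most-variable genes contributed per study to the clustering union.
    statistic : {"mad", "variance"}
        Variability statistic for gene selection.
    center : {"median_center", "zscore", "none"}
        Per-gene transform applied before clustering.
    algorithms : sequence of {"kmeans", "nmf"}
        Clustering engines to run independently per study.
    k_list : sequence of int
        Cluster numbers at which partitions and concordance are computed.
    kmeans_inits, nmf_inits, consensus_runs : int
        Restart counts (best-of-N k-means, best-of-N NMF assignment runs,
        NMF consensus runs for cophenetic profiles).
    s0_method : {"percentile_grid", "fixed_percentile"}
        SAM fudge-factor estimator.
    reference, reference_label_map
        Optional reference study whose cluster labels are propagated to all
        studies along the matching.
    exclusion_threshold : float
        Studies whose best matched correlation falls below this are flagged
        non-concordant and excluded from range summaries.
    """

    def __init__(
        self,
        datasets: Sequence[ExpressionDataset],
        *,
        n_per_dataset: int = 1500,
        statistic: str = "mad",
        center: str = "median_center",
        algorithms: Sequence[str] = ("kmeans", "nmf"),
        k_list: Sequence[int] = (2, 3, 4),
        kmeans_inits: int = 20,
        nmf_inits: int = 100,
        consensus_runs: int = 10,
        s0_method: str = "percentile_grid",
        reference: str | None = None,
        reference_label_map: Mapping[int, str] | None = None,
        exclusion_threshold: float = 0.3,
        matching: str = "optimal",
    ) -> None:
        if len(datasets) < 2:
            raise ValueError("need at least two datasets")
        self.datasets = intersect_gene_universe(list(datasets))
        self.n_per_dataset = n_per_dataset
        self.statistic = statistic
        self.center = center
        self.algorithms = tuple(algorithms)
        self.k_list = tuple(int(k) for k in k_list)
        self.kmeans_inits = kmeans_inits
        self.nmf_inits = nmf_inits
        self.consensus_runs = consensus_runs
        self.s0_method = s0_method
        self.reference = reference
        self.reference_label_map = dict(reference_label_map) if reference_label_map else None
        self.exclusion_threshold = exclusion_threshold
        self.matching = matching

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_files(
        cls,
        matrices: Mapping[str, str | Path],
        annotations: Mapping[str, str | Path] | None = None,
        keep_histologies: Sequence[str] | None = None,
        keep_grades: Sequence[str] | None = None,
        aliases: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "SubtypeConcordance":
        """Build the model from TSV matrices (and optional annotation tables).

        When inclusion sets are given, annotation tables are required and the
        filter is applied per study before the gene universes are intersected.
        """
        datasets = []
        for name, path in matrices.items():
            ds = load_expression_matrix(path, name)
            if annotations and name in annotations:
                ann = load_sample_annotations(annotations[name], aliases=aliases)
                ds = ExpressionDataset(name, ds.values, ann, ds.ingest_report)
            if keep_histologies is not None or keep_grades is not None:
                ds = apply_inclusion_filter(
                    ds,
                    keep_histologies or set(ds.annotations["histology"].dropna()),
                    keep_grades or set(ds.annotations["grade"].dropna()),
                )
            datasets.append(ds)
        return cls(datasets, **kwargs)

    # ------------------------------------------------------------------- fit
    def select_genes(self) -> GeneSet:
        return select_union_gene_set(self.datasets, self.n_per_dataset, self.statistic)

    def fit(self, seed: int = 0) -> "SubtypeConcordanceResults":
        """Run selection, clustering, t-score summaries and concordance.

        All randomness derives from ``seed`` through a counter scheme, so a
        rerun with the same settings reproduces every output bit for bit.
        """
        gene_set = self.select_genes()
        ss = np.random.SeedSequence(seed)
        n_jobs = len(self.datasets) * len(self.algorithms) * len(self.k_list)
        job_seeds = iter(ss.generate_state(n_jobs))

        assignments: dict[tuple[str, str, int], ClusterAssignment] = {}
        tmatrices: dict[tuple[str, int], dict[str, TScoreMatrix]] = {}
        for algorithm in self.algorithms:
            for k in self.k_list:
                for ds in self.datasets:
                    js = int(next(job_seeds))
                    if algorithm == "kmeans":
                        asg = _cluster.kmeans_partition(
                            ds, gene_set, k, n_init=self.kmeans_inits,
                            seed=js, center=self.center,
                        )
                    elif algorithm == "nmf":
                        asg = _cluster.nmf_partition(
                            ds, gene_set, k, n_init=self.nmf_inits,
                            seed=js, center=self.center,
                        )
                    else:
                        raise ValueError(f"unknown algorithm {algorithm!r}")
                    assignments[(ds.name, algorithm, k)] = asg
                tmatrices[(algorithm, k)] = {
                    ds.name: moderated_t_matrix(
                        ds, assignments[(ds.name, algorithm, k)],
                        s0_method=self.s0_method,
                    )
                    for ds in self.datasets
                }
        concordance = {
            key: compute_concordance(
                tmats,
                reference=self.reference,
                reference_label_map=self.reference_label_map,
                method=self.matching,
            )
            for key, tmats in tmatrices.items()
        }
        return SubtypeConcordanceResults(
            model=self,
            seed=seed,
            gene_set=gene_set,
            assignments=assignments,
            tmatrices=tmatrices,
            concordance=concordance,
        )

    def cophenetic_profiles(
        self,
        k_range: Sequence[int] = range(2, 9),
        seed: int = 0,
        max_iter: int = 500,
    ) -> dict[str, CopheneticProfile]:
        """NMF consensus cophenetic profile per study over ``k_range``."""
        gene_set = self.select_genes()
        seeds = np.random.SeedSequence(seed).generate_state(len(self.datasets))
        return {
            ds.name: cophenetic_profile(
                ds, gene_set, k_range, n_runs=self.consensus_runs,
                seed=int(s), center=self.center, max_iter=max_iter,
            )
            for ds, s in zip(self.datasets, seeds)
        }


@dataclass
class SubtypeConcordanceResults:
    """Fitted cross-study concordance: partitions, t-score matrices, matchings."""

    model: SubtypeConcordance
    seed: int
    gene_set: GeneSet
    assignments: dict[tuple[str, str, int], ClusterAssignment]
    tmatrices: dict[tuple[str, int], dict[str, TScoreMatrix]]
    concordance: dict[tuple[str, int], ConcordanceResult]
    profiles: dict[str, CopheneticProfile] = field(default_factory=dict)

    # ------------------------------------------------------------- accessors
    def assignment(self, dataset: str, algorithm: str, k: int) -> ClusterAssignment:
        return self.assignments[(dataset, algorithm, k)]

    def nonconcordant(self, algorithm: str, k: int) -> set[str]:
        return flag_nonconcordant(
            self.concordance[(algorithm, k)], self.model.exclusion_threshold
        )

    def matched_range_table(self, algorithm: str, k: int) -> pd.DataFrame:
        """Matched-correlation min-max ranges per cluster label at one k,
        with non-concordant studies split into their own block."""
        result = self.concordance[(algorithm, k)]
        exclude = self.nonconcordant(algorithm, k)
        names = {n for pair in result.dataset_pairs for n in pair}
        if len(names - exclude) < 2:
            exclude = set()
        return concordance_summary(result, exclude=exclude)

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        """Human-readable report of matched-correlation ranges per algorithm/k."""
        lines = []
        names = [ds.name for ds in self.model.datasets]
        lines.append("Cross-study subtype concordance")
        lines.append("=" * 64)
        lines.append(f"Datasets:        {', '.join(names)}")
        lines.append(
            f"Gene universe:   {self.model.datasets[0].n_genes} shared genes"
        )
        lines.append(
            f"Clustering set:  union of top {self.model.n_per_dataset} per study "
            f"({len(self.gene_set)} genes, {self.model.statistic})"
        )
        lines.append(f"Seed:            {self.seed}")
        for (algorithm, k), _ in sorted(self.concordance.items()):
            lines.append("")
            lines.append(f"--- {algorithm}, k = {k} ---")
            excl = self.nonconcordant(algorithm, k)
            if excl:
                lines.append(
                    f"non-concordant (best matched r < "
                    f"{self.model.exclusion_threshold}): {', '.join(sorted(excl))}"
                )
            table = self.matched_range_table(algorithm, k)
            for _, row in table.iterrows():
                lines.append(
                    f"  {row['block']:<18} {row['cluster_label']:<20} "
                    f"r = {row['r_min']:+.2f} .. {row['r_max']:+.2f} "
                    f"({int(row['n_pairs'])} pairs)"
                )
        return "\n".join(lines)

    # ---------------------------------------------------------------- plots
    def plot_correlation_heatmaps(self, algorithm: str, k: int, path: str | Path) -> None:
        """Grid of pairwise k x k correlation heatmaps for one algorithm/k."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        result = self.concordance[(algorithm, k)]
        pairs = result.dataset_pairs
        ncol = min(3, len(pairs))
        nrow = int(np.ceil(len(pairs) / ncol))
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False
        )
        for ax in axes.ravel():
            ax.set_visible(False)
        for ax, (a, b) in zip(axes.ravel(), pairs):
            ax.set_visible(True)
            m = result.corr[(a, b)]
            im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_title(f"{a} vs {b}", fontsize=9)
            ax.set_xticks(range(k), m.columns, rotation=45, fontsize=7)
            ax.set_yticks(range(k), m.index, fontsize=7)
        fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.7)
        fig.suptitle(f"{algorithm}, k={k}: moderated-t correlation")
        fig.savefig(path, dpi=120)
        plt.close(fig)
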