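"""Variability-based gene selection and the cross-study union gene set.

Each study contributes its ``n_per_dataset`` most variable genes (MAD or
unbiased variance); clustering then runs on the union of those per-study
lists, so that genes that separate subtypes strongly in any one population
are available to every clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .datasets import ExpressionDataset

__all__ = ["GeneSet", "gene_variability", "select_union_gene_set"]

STATISTICS = ("mad", "variance")


@dataclass
class GeneSet:
    """An ordered union gene set with per-study provenance.

    ``genes`` is the lexicographically sorted union of the provenance lists;
    ``provenance`` maps each study name to the genes that study contributed
    (its top-``n`` list).
    """

    genes: list[str]
    provenance: dict[str, list[str]]

    def __post_init__(self) -> None:
        union = sorted(set().union(*self.provenance.values())) if self.provenance else []
        if self.genes != union:
            raise ValueError("genes must equal the sorted union of provenance lists")

    def __len__(self) -> int:
        return len(self.genes)


def gene_variability(
    dataset: ExpressionDataset, statistic: str = "mad"
) -> pd.Series:
    """Per-gene variability score.

    ``mad``: median absolute deviation about the gene median, scaled by the
    normal-consistency constant 1.4826.  ``variance``: unbiased sample
    variance.  Both are computed within the dataset only.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    if dataset.n_samples < 2:
        raise ValueError("variability needs at least two samples")
    x = dataset.matrix()
    if statistic == "mad":
        scores = median_abs_deviation(x, axis=1, scale="normal")
    else:
        scores = np.var(x, axis=1, ddof=1)
    return pd.Series(scores, index=dataset.genes, name=statistic)


def _top_genes(scores: pd.Series, n: int) -> list[str]:
    # descending score, ties at the cut broken by lexicographic gene order
    frame = pd.DataFrame({"score": scores.to_numpy(), "gene": scores.index})
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return frame["gene"].head(n).tolist()


def select_union_gene_set(
    datasets: list[ExpressionDataset],
    n_per_dataset: int = 1500,
    statistic: str = "mad",
) -> GeneSet:
    """Union of each dataset's top-``n_per_dataset`` most variable genes.

    Datasets must share the same gene universe (run
    :func:`~crossclust.datasets.intersect_gene_universe` first).  The union
    size lies in ``[n_per_dataset, n_per_dataset * len(datasets)]``.
    """
    if not datasets:
        raise ValueError("no datasets")
    universe = set(datasets[0].genes)
    for ds in datasets[1:]:
        if set(ds.genes) != universe:
            raise ValueError(
                "datasets do not share a gene universe; run intersect_gene_universe first"
            )
    if n_per_dataset > len(universe):
        raise ValueError(
            f"n_per_dataset={n_per_dataset} exceeds the {len(universe)}-gene universe"
        )
    if n_per_dataset < 1:
        raise ValueError("n_per_dataset must be positive")
    provenance = {
        ds.name: _top_genes(gene_variability(ds, statistic), n_per_dataset)
        for ds in datasets
    }
    union = sorted(set().union(*provenance.values()))
    return GeneSet(genes=union, provenance=provenance)
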