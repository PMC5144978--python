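"""Cross-study cluster concordance: correlate moderated-t vectors, match
clusters one-to-one, propagate reference labels, and summarize matched
correlation ranges.

Two clusters from different studies are "analogous" when their moderated-t
vectors over the shared gene universe correlate strongly.  For every dataset
pair the k x k Pearson matrix is computed, an optimal one-to-one matching
(Hungarian assignment maximizing the summed correlation) extracts the
analogous pairs, and labels from a reference study (e.g. the TCGA subtype
names) are carried along the matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster import ClusterAssignment
from .sam import TScoreMatrix

__all__ = [
    "ConcordanceResult",
    "pearson_correlation",
    "cross_dataset_correlations",
    "match_clusters",
    "compute_concordance",
    "assign_reference_labels",
    "concordance_summary",
    "flag_nonconcordant",
    "crosstab_assignments",
]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Standard Pearson product-moment correlation of two vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise ValueError("vectors must have equal length of at least 3")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero-variance input to Pearson correlation")
    return float(np.corrcoef(xa, ya)[0, 1])


def cross_dataset_correlations(
    t_a: TScoreMatrix, t_b: TScoreMatrix
) -> pd.DataFrame:
    """k x k matrix of Pearson correlations between t-score columns.

    Entry (a, b) correlates cluster a of the first study with cluster b of
    the second.  A gene-order mismatch is an error — silent realignment
    would hide upstream universe bugs.
    """
    if t_a.genes != t_b.genes:
        raise ValueError(
            f"gene universes differ between {t_a.dataset_name} and {t_b.dataset_name}"
        )
    if t_a.k != t_b.k:
        raise ValueError("t-score matrices have different k")
    k = t_a.k
    full = np.corrcoef(t_a.scores.to_numpy().T, t_b.scores.to_numpy().T)
    corr = full[:k, k:]
    if not np.isfinite(corr).all():
        raise ValueError("zero-variance t-score column")
    return pd.DataFrame(
        corr,
        index=[f"cluster_{i}" for i in range(1, k + 1)],
        columns=[f"cluster_{j}" for j in range(1, k + 1)],
    )


def match_clusters(
    corr: pd.DataFrame | np.ndarray, method: str = "optimal"
) -> dict[int, int]:
    """One-to-one cluster matching from a square correlation matrix.

    ``optimal`` maximizes the summed selected correlations (Hungarian
    assignment); ``greedy`` repeatedly takes the largest remaining entry.
    Ties are broken toward the lexicographically smallest assignment.
    Returns a bijection {row cluster -> column cluster}, 1-based.
    """
    c = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    k = c.shape[0]
    if method == "greedy":
        remaining_rows, remaining_cols = set(range(k)), set(range(k))
        pairs: dict[int, int] = {}
        while remaining_rows:
            best = max(
                ((c[i, j], -i, -j, i, j) for i in remaining_rows for j in remaining_cols)
            )
            _, _, _, i, j = best
            pairs[i + 1] = j + 1
            remaining_rows.discard(i)
            remaining_cols.discard(j)
        return dict(sorted(pairs.items()))
    if method != "optimal":
        raise ValueError(f"unknown matching method {method!r}")
    rows, cols = linear_sum_assignment(-c)
    total = c[rows, cols].sum()
    assignment = {int(i) + 1: int(j) + 1 for i, j in zip(rows, cols)}
    if k <= 7:
        # enforce the lexicographically-smallest tie break exactly
        best_perm, best_total = None, -np.inf
        for perm in permutations(range(k)):
            t = sum(c[i, perm[i]] for i in range(k))
            if t > best_total + 1e-12:
                best_total, best_perm = t, perm
        if best_total > total - 1e-9:
            assignment = {i + 1: j + 1 for i, j in enumerate(best_perm)}
    return assignment


@dataclass
class ConcordanceResult:
    """Pairwise cross-study cluster correlations, matchings and labels at one k."""

    k: int
    dataset_pairs: list[tuple[str, str]]
    corr: dict[tuple[str, str], pd.DataFrame]
    matching: dict[tuple[str, str], dict[int, int]]
    matched_correlations: dict[tuple[str, str], list[float]]
    reference_labels: dict[tuple[str, int], str] = field(default_factory=dict)

    def matched(self, a: str, b: str) -> list[float]:
        if (a, b) in self.matched_correlations:
            return self.matched_correlations[(a, b)]
        return self.matched_correlations[(b, a)]


def compute_concordance(
    tmats: Mapping[str, TScoreMatrix],
    reference: str | None = None,
    reference_label_map: Mapping[int, str] | None = None,
    method: str = "optimal",
) -> ConcordanceResult:
    """Full pairwise concordance across a set of per-study t-score matrices."""
    names = list(tmats)
    if len(names) < 2:
        raise ValueError("need at least two datasets")
    ks = {t.k for t in tmats.values()}
    if len(ks) != 1:
        raise ValueError("all t-score matrices must share the same k")
    k = ks.pop()
    corr, matching, matched = {}, {}, {}
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        m = cross_dataset_correlations(tmats[a], tmats[b])
        bij = match_clusters(m, method=method)
        corr[(a, b)] = m
        matching[(a, b)] = bij
        matched[(a, b)] = [float(m.iloc[i - 1, j - 1]) for i, j in bij.items()]
    labels: dict[tuple[str, int], str] = {}
    if reference is not None:
        if reference_label_map is None:
            reference_label_map = {c: f"cluster_{c}" for c in range(1, k + 1)}
        labels = assign_reference_labels(
            tmats, reference, reference_label_map, method=method
        )
    return ConcordanceResult(
        k=k,
        dataset_pairs=pairs,
        corr=corr,
        matching=matching,
        matched_correlations=matched,
        reference_labels=labels,
    )


def assign_reference_labels(
    tmats: Mapping[str, TScoreMatrix],
    reference_dataset: str,
    reference_label_map: Mapping[int, str],
    method: str = "optimal",
) -> dict[tuple[str, int], str]:
    """Carry reference cluster labels to every study along the matching.

    The reference study keeps its own labels; each other study's clusters
    take the label of the reference cluster they match.
    """
    if reference_dataset not in tmats:
        raise ValueError(f"reference dataset {reference_dataset!r} missing")
    k = tmats[reference_dataset].k
    missing = [c for c in range(1, k + 1) if c not in reference_label_map]
    if missing:
        raise ValueError(f"reference label map lacks clusters {missing}")
    labels = {
        (reference_dataset, c): reference_label_map[c] for c in range(1, k + 1)
    }
    for name, tm in tmats.items():
        if name == reference_dataset:
            continue
        m = cross_dataset_correlations(tmats[reference_dataset], tm)
        bij = match_clusters(m, method=method)  # reference cluster -> this study
        for ref_c, this_c in bij.items():
            labels[(name, this_c)] = reference_label_map[ref_c]
    return labels


def flag_nonconcordant(
    result: ConcordanceResult, threshold: float = 0.3
) -> set[str]:
    """Datasets whose best matched correlation stays below ``threshold``.

    Mirrors the handling of a study whose clusters fail to correlate with
    every other population: such a study is excluded from range summaries
    and reported separately.
    """
    best: dict[str, float] = {}
    for (a, b), values in result.matched_correlations.items():
        top = max(values)
        for name in (a, b):
            best[name] = max(best.get(name, -np.inf), top)
    return {name for name, v in best.items() if v < threshold}


def concordance_summary(
    result: ConcordanceResult, exclude: Iterable[str] = ()
) -> pd.DataFrame:
    """Min-max ranges of matched correlations per cluster label.

    Rows cover every cluster label; the ``block`` column separates the
    retained-study ranges from, per excluded study, that study's own ranges
    against the retained set (the two-block layout of a cross-population
    correlation table).
    """
    exclude = set(exclude)
    all_names = sorted({n for pair in result.dataset_pairs for n in pair})
    retained = [n for n in all_names if n not in exclude]
    if len(retained) < 2:
        raise ValueError("need at least two retained datasets")

    labels_map = dict(result.reference_labels)
    if not labels_map:
        # no reference study: anchor labels on the first retained dataset and
        # propagate them along the pairwise matchings
        anchor = retained[0]
        for c in range(1, result.k + 1):
            labels_map[(anchor, c)] = f"cluster_{c}"
        for name in all_names:
            if name == anchor:
                continue
            if (anchor, name) in result.matching:
                bij = result.matching[(anchor, name)]
                for c_anchor, c_other in bij.items():
                    labels_map[(name, c_other)] = f"cluster_{c_anchor}"
            else:
                bij = result.matching[(name, anchor)]
                for c_other, c_anchor in bij.items():
                    labels_map[(name, c_other)] = f"cluster_{c_anchor}"

    def label_of(dataset: str, cluster: int) -> str:
        return labels_map.get((dataset, cluster), f"cluster_{cluster}")

    rows = []
    per_label: dict[str, list[float]] = {}
    excluded_vals: dict[tuple[str, str], list[float]] = {}
    for (a, b), bij in result.matching.items():
        m = result.corr[(a, b)]
        for ca, cb in bij.items():
            r = float(m.iloc[ca - 1, cb - 1])
            in_a, in_b = a in exclude, b in exclude
            if not in_a and not in_b:
                per_label.setdefault(label_of(a, ca), []).append(r)
            elif in_a != in_b:
                # label the pair by its retained side
                excl, lab = (a, label_of(b, cb)) if in_a else (b, label_of(a, ca))
                excluded_vals.setdefault((excl, lab), []).append(r)
    for lab in sorted(per_label):
        vals = per_label[lab]
        rows.append(
            {"block": "retained", "cluster_label": lab,
             "r_min": min(vals), "r_max": max(vals), "n_pairs": len(vals)}
        )
    for (excl, lab) in sorted(excluded_vals):
        vals = excluded_vals[(excl, lab)]
        rows.append(
            {"block": f"excluded:{excl}", "cluster_label": lab,
             "r_min": min(vals), "r_max": max(vals), "n_pairs": len(vals)}
        )
    return pd.DataFrame(rows, columns=["block", "cluster_label", "r_min", "r_max", "n_pairs"])


def crosstab_assignments(
    assignment: ClusterAssignment,
    original_labels: pd.Series,
    na_label: str = "NC/NA",
) -> pd.DataFrame:
    """Contingency table of this clustering against originally published labels.

    Rows are this analysis' clusters 1..k; columns are the original subtype
    labels plus a trailing ``NC/NA`` column for samples the original study
    did not cluster or assess.
    """
    labels = original_labels.reindex(assignment.labels.index)
    labels = labels.where(labels.notna() & (labels.astype(str).str.len() > 0), na_label)
    table = pd.crosstab(assignment.labels, labels)
    table.index.name = "cluster"
    table.columns.name = "original_label"
    cols = [c for c in table.columns if c != na_label]
    if na_label in table.columns:
        cols.append(na_label)
    table = table[cols]
    table.index = [f"cluster_{c}" for c in table.index]
    return table
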