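"""Expression dataset containers, TSV ingest, inclusion filtering and gene-universe
restriction.

A study enters the pipeline as a genes x samples matrix of log-scale expression
values (tab-separated text, gene symbols as row keys, sample identifiers as
column keys) together with a per-sample annotation table carrying histology,
grade, stage and — when the study published its own subtyping — the original
subtype label.  Every downstream stage consumes :class:`ExpressionDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "load_expression_matrix",
    "write_expression_matrix",
    "load_sample_annotations",
    "apply_inclusion_filter",
    "intersect_gene_universe",
]

#: annotation columns required for inclusion filtering
REQUIRED_ANNOTATION_COLUMNS = ("histology", "grade")


class IngestError(ValueError):
    """Raised when an input file cannot be turned into a valid dataset."""


@dataclass
class ExpressionDataset:
    """A named genes x samples expression matrix with per-sample annotations.

    Parameters
    ----------
    name : str
        Study identifier, e.g. ``"tcga"``.
    values : pandas.DataFrame
        Complete (no missing values) real matrix; index = gene symbols,
        columns = sample identifiers, both unique.
    annotations : pandas.DataFrame, optional
        Indexed by sample identifier; columns typically include
        ``histology``, ``grade``, ``stage`` and ``original_subtype_label``.
    ingest_report : dict
        Bookkeeping from ingest/filtering (drop counts and such); not part of
        equality.
    """

    name: str
    values: pd.DataFrame
    annotations: pd.DataFrame | None = None
    ingest_report: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise IngestError(f"{self.name}: duplicate gene identifiers")
        if not self.values.columns.is_unique:
            raise IngestError(f"{self.name}: duplicate sample identifiers")
        if self.values.isna().to_numpy().any():
            raise IngestError(f"{self.name}: missing values in expression matrix")
        if self.annotations is not None:
            missing = set(self.values.columns) - set(self.annotations.index)
            if missing:
                raise IngestError(
                    f"{self.name}: {len(missing)} samples lack annotations"
                )
            # keep annotations aligned and restricted to the matrix samples
            self.annotations = self.annotations.loc[self.values.columns]

    # ------------------------------------------------------------------ views
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        """The expression values as a float ndarray (genes x samples)."""
        return self.values.to_numpy(dtype=float)

    # -------------------------------------------------------------- restrict
    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"{self.name}: {len(missing)} genes absent, e.g. {missing[:3]}")
        return ExpressionDataset(
            self.name, self.values.loc[list(genes)], self.annotations,
            dict(self.ingest_report),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"{self.name}: {len(missing)} samples absent")
        ann = self.annotations.loc[list(samples)] if self.annotations is not None else None
        return ExpressionDataset(
            self.name, self.values[list(samples)], ann, dict(self.ingest_report)
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        """Same dataset with a replaced value matrix (axes must agree)."""
        if list(values.columns) != self.samples:
            raise ValueError("sample axis changed")
        return ExpressionDataset(self.name, values, self.annotations, dict(self.ingest_report))


# ---------------------------------------------------------------------- ingest

def load_expression_matrix(path: str | Path, name: str) -> ExpressionDataset:
    """Read a tab-separated genes x samples matrix.

    First row holds sample identifiers, first column gene identifiers.  Empty
    cells are treated as missing; any gene row containing a missing value is
    dropped (and counted in ``ingest_report["n_dropped_missing"]``).  Duplicate
    gene rows are collapsed by keeping the row with the highest sample
    variance — the standard microarray probe-collapse policy — with the count
    recorded in ``ingest_report["n_dropped_duplicate"]``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (OSError, pd.errors.ParserError) as exc:
        raise IngestError(f"cannot read expression matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    bad = df.select_dtypes(exclude="number").columns
    if len(bad):
        # pinpoint the first offending cell for the error message
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            offenders = df[col][coerced.isna() & df[col].notna()]
            if len(offenders):
                raise IngestError(
                    f"{path}: non-numeric cell {offenders.iloc[0]!r} "
                    f"(gene {offenders.index[0]!r}, sample {col!r})"
                )
            df[col] = coerced

    n_before = df.shape[0]
    complete = df.dropna(axis=0)
    n_dropped_missing = n_before - complete.shape[0]

    n_dup = int(complete.index.duplicated().sum())
    if n_dup:
        variances = complete.var(axis=1, ddof=1)
        order = np.argsort(-variances.to_numpy(), kind="stable")
        complete = complete.iloc[order]
        complete = complete[~complete.index.duplicated(keep="first")]
        complete = complete.sort_index()

    if complete.shape[0] < 2 or complete.shape[1] < 2:
        raise IngestError(
            f"{path}: need at least 2 genes and 2 samples after ingest, "
            f"got {complete.shape[0]} x {complete.shape[1]}"
        )
    report = {
        "n_dropped_missing": n_dropped_missing,
        "n_dropped_duplicate": n_dup,
        "n_genes": complete.shape[0],
        "n_samples": complete.shape[1],
    }
    return ExpressionDataset(name, complete.astype(float), ingest_report=report)


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix back as tab-separated text at full float precision."""
    dataset.values.to_csv(Path(path), sep="\t")


def load_sample_annotations(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a TSV annotation table (required: sample_id, histology, grade).

    Category values are normalized to lower case; ``aliases`` maps normalized
    spellings onto a canonical vocabulary (e.g. ``{"lmp": "borderline"}``) and
    is meant to come from configuration, not code.
    """
    table = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "sample_id" not in table.columns:
        raise IngestError(f"{path}: annotation table lacks a sample_id column")
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in table.columns:
            raise IngestError(f"{path}: annotation table lacks a {col} column")
    table = table.set_index("sample_id")
    if not table.index.is_unique:
        raise IngestError(f"{path}: duplicate sample_id in annotations")
    alias_map = {k.lower(): v.lower() for k, v in (aliases or {}).items()}
    for col in ("histology", "grade", "stage"):
        if col in table.columns:
            norm = table[col].str.strip().str.lower()
            table[col] = norm.map(lambda v: alias_map.get(v, v))
    return table


# ------------------------------------------------------------------ filtering

def apply_inclusion_filter(
    dataset: ExpressionDataset,
    keep_histologies: Iterable[str],
    keep_grades: Iterable[str],
    include_missing: bool = False,
) -> ExpressionDataset:
    """Keep exactly the samples whose histology and grade are in the given sets.

    Samples with missing histology or grade are excluded unless
    ``include_missing`` is set.  Exclusion counts per reason land in
    ``ingest_report["exclusions"]``.  An empty result is an error: silently
    returning an empty dataset would let a mis-typed category pass unnoticed.
    """
    if dataset.annotations is None:
        raise IngestError(f"{dataset.name}: no annotations to filter on")
    hist = {h.lower() for h in keep_histologies}
    grade = {g.lower() for g in keep_grades}
    ann = dataset.annotations

    h = ann["histology"].str.lower() if ann["histology"].notna().all() else ann["histology"].str.lower()
    g = ann["grade"].str.lower()
    missing_mask = ann["histology"].isna() | ann["grade"].isna()
    hist_ok = h.isin(hist)
    grade_ok = g.isin(grade)
    keep = hist_ok & grade_ok
    if include_missing:
        keep = keep | missing_mask

    exclusions = {
        "histology": int((~hist_ok & ~missing_mask).sum()),
        "grade": int((hist_ok & ~grade_ok & ~missing_mask).sum()),
        "missing_annotation": 0 if include_missing else int(missing_mask.sum()),
    }
    kept = list(ann.index[keep])
    if not kept:
        raise IngestError(
            f"{dataset.name}: inclusion filter excluded every sample "
            f"(exclusions: {exclusions})"
        )
    out = dataset.subset_samples(kept)
    out.ingest_report["exclusions"] = exclusions
    out.ingest_report["n_samples_kept"] = len(kept)
    return out


def intersect_gene_universe(
    datasets: Sequence[ExpressionDataset],
) -> list[ExpressionDataset]:
    """Restrict every dataset to the shared gene universe, in sorted order.

    The shared universe is the intersection of gene sets across all datasets;
    genes are sorted lexicographically so the row order is identical
    everywhere regardless of input ordering.  Idempotent.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common: set[str] = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise IngestError("empty gene intersection across datasets")
    universe = sorted(common)
    out = []
    for ds in datasets:
        restricted = ds.subset_genes(universe)
        restricted.ingest_report["gene_universe_size"] = len(universe)
        out.append(restricted)
    return out
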