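"""End-to-end pipeline orchestration over a run directory.

A single YAML config drives ingest -> inclusion filter -> gene-universe
intersection -> union gene selection -> per-study clustering (both
algorithms, each k) -> moderated-t summaries -> cross-study concordance ->
cophenetic profiles -> optional shuffling null.  Every stage reads its
inputs from and writes its outputs to the run directory as TSV/JSON, so
stages can be re-run individually and the whole run is reproducible from
the manifest (config hash + seed + versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import ClusterAssignment, cophenetic_profile, kmeans_partition, nmf_partition
from .concordance import compute_concordance, crosstab_assignments
from .datasets import (
    ExpressionDataset,
    apply_inclusion_filter,
    intersect_gene_universe,
    load_expression_matrix,
    load_sample_annotations,
    write_expression_matrix,
)
from .features import GeneSet, gene_variability, select_union_gene_set
from .nullmodel import run_null_experiment
from .sam import moderated_t_matrix
from .simulate import SyntheticConfig, generate_multistudy

log = logging.getLogger("crossclust")

__all__ = ["PipelineConfig", "run_pipeline", "render_reports", "write_synthetic_inputs"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; loadable from YAML."""

    datasets: dict[str, dict[str, str]]  # name -> {matrix: path, annotations: path}
    output_dir: str = "run"
    keep_histologies: list[str] | None = None
    keep_grades: list[str] | None = None
    aliases: dict[str, str] = field(default_factory=dict)
    n_per_dataset: int = 1500
    statistic: str = "mad"
    center: str = "median_center"
    algorithms: list[str] = field(default_factory=lambda: ["kmeans", "nmf"])
    k_list: list[int] = field(default_factory=lambda: [2, 3, 4])
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    kmeans_inits: int = 20
    nmf_inits: int = 100
    consensus_runs: int = 10
    s0_method: str = "percentile_grid"
    reference: str | None = None
    reference_label_map: dict[int, str] | None = None
    exclusion_threshold: float = 0.3
    run_profiles: bool = True
    null_replicates: int = 0
    null_k: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("reference_label_map"):
            raw["reference_label_map"] = {
                int(k): str(v) for k, v in raw["reference_label_map"].items()
            }
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ----------------------------------------------------------------- stages

def _load_datasets(config: PipelineConfig) -> list[ExpressionDataset]:
    datasets = []
    for name, paths in config.datasets.items():
        ds = load_expression_matrix(paths["matrix"], name)
        if "annotations" in paths and paths["annotations"]:
            ann = load_sample_annotations(paths["annotations"], aliases=config.aliases)
            ds = ExpressionDataset(name, ds.values, ann, ds.ingest_report)
        datasets.append(ds)
    return datasets


def stage_ingest(config: PipelineConfig, run_dir: Path) -> list[ExpressionDataset]:
    """Load, filter and intersect; write filtered matrices and a report."""
    datasets = _load_datasets(config)
    if config.keep_histologies or config.keep_grades:
        filtered = []
        for ds in datasets:
            hist = config.keep_histologies or sorted(set(ds.annotations["histology"].dropna()))
            grd = config.keep_grades or sorted(set(ds.annotations["grade"].dropna()))
            filtered.append(apply_inclusion_filter(ds, hist, grd))
        datasets = filtered
    datasets = intersect_gene_universe(datasets)
    out = run_dir / "ingest"
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"gene_universe_size": datasets[0].n_genes}
    for ds in datasets:
        write_expression_matrix(ds, out / f"{ds.name}.tsv")
        if ds.annotations is not None:
            ds.annotations.to_csv(
                out / f"{ds.name}.annotations.tsv", sep="\t", index_label="sample_id"
            )
        report[ds.name] = {"n_samples": ds.n_samples, **ds.ingest_report}
        log.info("ingest %s: %d genes x %d samples", ds.name, ds.n_genes, ds.n_samples)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return datasets


def _read_ingested(config: PipelineConfig, run_dir: Path) -> list[ExpressionDataset]:
    out = run_dir / "ingest"
    if not out.is_dir():
        raise FileNotFoundError("run the ingest stage first")
    datasets = []
    for name in config.datasets:
        ds = load_expression_matrix(out / f"{name}.tsv", name)
        ann_path = out / f"{name}.annotations.tsv"
        if ann_path.exists():
            ann = pd.read_csv(ann_path, sep="\t", index_col=0, dtype=str)
            ds = ExpressionDataset(name, ds.values, ann, ds.ingest_report)
        datasets.append(ds)
    return datasets


def stage_select(
    config: PipelineConfig, run_dir: Path, datasets: list[ExpressionDataset]
) -> GeneSet:
    gene_set = select_union_gene_set(datasets, config.n_per_dataset, config.statistic)
    out = run_dir / "selection"
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        scores = gene_variability(ds, config.statistic).sort_values(ascending=False)
        frame = scores.rename("score").to_frame()
        frame["rank"] = np.arange(1, len(frame) + 1)
        frame.to_csv(out / f"{ds.name}.scores.tsv", sep="\t")
    (out / "gene_set.json").write_text(
        json.dumps({"genes": gene_set.genes, "provenance": gene_set.provenance}, indent=2)
    )
    log.info("selection: union of %d genes", len(gene_set))
    return gene_set


def _read_gene_set(run_dir: Path) -> GeneSet:
    path = run_dir / "selection" / "gene_set.json"
    if not path.exists():
        raise FileNotFoundError("run the select stage first")
    raw = json.loads(path.read_text())
    return GeneSet(genes=raw["genes"], provenance=raw["provenance"])


def stage_cluster(
    config: PipelineConfig,
    run_dir: Path,
    datasets: list[ExpressionDataset],
    gene_set: GeneSet,
) -> dict[tuple[str, str, int], ClusterAssignment]:
    out = run_dir / "clustering"
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    n_jobs = len(datasets) * len(config.algorithms) * len(config.k_list)
    seeds = iter(ss.generate_state(n_jobs))
    assignments = {}
    rows = []
    for algorithm in config.algorithms:
        for k in config.k_list:
            for ds in datasets:
                js = int(next(seeds))
                if algorithm == "kmeans":
                    asg = kmeans_partition(
                        ds, gene_set, k, n_init=config.kmeans_inits,
                        seed=js, center=config.center,
                    )
                else:
                    asg = nmf_partition(
                        ds, gene_set, k, n_init=config.nmf_inits,
                        seed=js, center=config.center,
                    )
                assignments[(ds.name, algorithm, k)] = asg
                for sample, cluster in asg.labels.items():
                    rows.append(
                        {"dataset": ds.name, "algorithm": algorithm, "k": k,
                         "sample_id": sample, "cluster": int(cluster)}
                    )
                log.info(
                    "cluster %s %s k=%d objective=%.4g sizes=%s",
                    ds.name, algorithm, k, asg.objective, asg.cluster_sizes(),
                )
    pd.DataFrame(rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
    return assignments


def _read_assignments(
    run_dir: Path,
) -> dict[tuple[str, str, int], ClusterAssignment]:
    path = run_dir / "clustering" / "assignments.tsv"
    if not path.exists():
        raise FileNotFoundError("run the cluster stage first")
    table = pd.read_csv(path, sep="\t")
    assignments = {}
    for (ds, alg, k), grp in table.groupby(["dataset", "algorithm", "k"]):
        labels = pd.Series(
            grp["cluster"].to_numpy(), index=grp["sample_id"].to_numpy(), name="cluster"
        )
        assignments[(ds, alg, int(k))] = ClusterAssignment(
            dataset_name=ds, algorithm=alg, k=int(k), labels=labels,
            seed=-1, objective=float("nan"),
        )
    return assignments


def stage_summarize(
    config: PipelineConfig,
    run_dir: Path,
    datasets: list[ExpressionDataset],
    assignments: Mapping[tuple[str, str, int], ClusterAssignment],
):
    out = run_dir / "tscores"
    out.mkdir(parents=True, exist_ok=True)
    by_ds = {ds.name: ds for ds in datasets}
    tmatrices: dict[tuple[str, int], dict[str, Any]] = {}
    for (name, algorithm, k), asg in assignments.items():
        tm = moderated_t_matrix(by_ds[name], asg, s0_method=config.s0_method)
        tm.scores.to_csv(out / f"{name}.{algorithm}.k{k}.tsv", sep="\t")
        tmatrices.setdefault((algorithm, k), {})[name] = tm
    return tmatrices


def stage_concord(config: PipelineConfig, run_dir: Path, tmatrices) -> None:
    out = run_dir / "concordance"
    out.mkdir(parents=True, exist_ok=True)
    from .concordance import concordance_summary, flag_nonconcordant

    for (algorithm, k), tmats in sorted(tmatrices.items()):
        result = compute_concordance(
            tmats, reference=config.reference,
            reference_label_map=config.reference_label_map,
        )
        for (a, b), m in result.corr.items():
            m.to_csv(out / f"{algorithm}.k{k}.{a}--{b}.tsv", sep="\t")
        exclude = flag_nonconcordant(result, config.exclusion_threshold)
        names = {n for pair in result.dataset_pairs for n in pair}
        if len(names - exclude) < 2:
            exclude = set()
        summary = concordance_summary(result, exclude=exclude)
        summary.to_csv(out / f"{algorithm}.k{k}.ranges.tsv", sep="\t", index=False)
        payload = {
            "k": k,
            "algorithm": algorithm,
            "nonconcordant": sorted(exclude),
            "matching": {
                f"{a}--{b}": {str(i): j for i, j in bij.items()}
                for (a, b), bij in result.matching.items()
            },
            "matched_correlations": {
                f"{a}--{b}": vals
                for (a, b), vals in result.matched_correlations.items()
            },
            "reference_labels": {
                f"{d}:{c}": lab for (d, c), lab in result.reference_labels.items()
            },
        }
        (out / f"{algorithm}.k{k}.matching.json").write_text(
            json.dumps(payload, indent=2)
        )


def stage_crosstabs(
    config: PipelineConfig,
    run_dir: Path,
    datasets: list[ExpressionDataset],
    assignments: Mapping[tuple[str, str, int], ClusterAssignment],
) -> None:
    out = run_dir / "crosstabs"
    out.mkdir(parents=True, exist_ok=True)
    by_ds = {ds.name: ds for ds in datasets}
    for (name, algorithm, k), asg in assignments.items():
        ds = by_ds[name]
        if ds.annotations is None or "original_subtype_label" not in ds.annotations:
            continue
        table = crosstab_assignments(asg, ds.annotations["original_subtype_label"])
        table.to_csv(out / f"{name}.{algorithm}.k{k}.tsv", sep="\t")


def stage_profile(
    config: PipelineConfig,
    run_dir: Path,
    datasets: list[ExpressionDataset],
    gene_set: GeneSet,
) -> None:
    out = run_dir / "profiles"
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed + 1).generate_state(len(datasets))
    profiles = {}
    for ds, s in zip(datasets, seeds):
        profile = cophenetic_profile(
            ds, gene_set, config.k_range, n_runs=config.consensus_runs,
            seed=int(s), center=config.center,
        )
        profiles[ds.name] = {str(k): v for k, v in profile.values.items()}
        for k, res in profile.results.items():
            res.consensus.to_csv(out / f"{ds.name}.k{k}.consensus.tsv", sep="\t")
        log.info("profile %s: %s best_k=%s", ds.name, profile.values, profile.best_k)
    (out / "cophenetic.json").write_text(json.dumps(profiles, indent=2))


def stage_null(
    config: PipelineConfig, run_dir: Path, datasets: list[ExpressionDataset]
) -> None:
    out = run_dir / "null"
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed + 2).generate_state(config.null_replicates)
    summary = []
    for rep, s in enumerate(seeds):
        result = run_null_experiment(
            datasets, k=config.null_k, n_per_dataset=config.n_per_dataset,
            statistic=config.statistic, seed=int(s), center=config.center,
            s0_method=config.s0_method,
        )
        summary.append(
            {
                "replicate": rep,
                "seed": int(s),
                "max_abs_matched": result.max_abs_matched,
                "matched": {
                    f"{a}--{b}": vals
                    for (a, b), vals in result.concordance.matched_correlations.items()
                },
            }
        )
        log.info("null replicate %d: max |matched r| = %.4f", rep, result.max_abs_matched)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


# -------------------------------------------------------------------- driver

def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every configured stage; returns the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    datasets = stage_ingest(config, run_dir)
    gene_set = stage_select(config, run_dir, datasets)
    assignments = stage_cluster(config, run_dir, datasets, gene_set)
    tmatrices = stage_summarize(config, run_dir, datasets, assignments)
    stage_concord(config, run_dir, tmatrices)
    stage_crosstabs(config, run_dir, datasets, assignments)
    if config.run_profiles:
        stage_profile(config, run_dir, datasets, gene_set)
    if config.null_replicates > 0:
        stage_null(config, run_dir, datasets)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "crossclust": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return run_dir


def render_reports(run_dir: str | Path) -> list[Path]:
    """Render heatmaps and line plots from a completed run's artifacts.

    Produces cross-study correlation heatmap grids per algorithm/k, consensus
    heatmaps ordered by dendrogram leaf order, and cophenetic line plots.
    Null panels are skipped cleanly when the null stage was not run.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run directory")
    figures: list[Path] = []
    out = run_dir / "figures"
    out.mkdir(exist_ok=True)

    conc = run_dir / "concordance"
    groups: dict[tuple[str, int], list[Path]] = {}
    for path in sorted(conc.glob("*.k*.*--*.tsv")):
        algorithm, kpart = path.name.split(".")[:2]
        groups.setdefault((algorithm, int(kpart[1:])), []).append(path)
    for (algorithm, k), paths in sorted(groups.items()):
        ncol = min(3, len(paths))
        nrow = int(np.ceil(len(paths) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.4 * ncol, 3.1 * nrow), squeeze=False)
        for ax in axes.ravel():
            ax.set_visible(False)
        for ax, path in zip(axes.ravel(), paths):
            ax.set_visible(True)
            m = pd.read_csv(path, sep="\t", index_col=0)
            im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_title(path.name.split(".")[2].replace("--", " vs "), fontsize=8)
            ax.set_xticks([]); ax.set_yticks([])
        fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.7)
        fig.suptitle(f"{algorithm} k={k}: cross-study moderated-t correlations")
        target = out / f"correlations.{algorithm}.k{k}.png"
        fig.savefig(target, dpi=120)
        plt.close(fig)
        figures.append(target)

    profiles_path = run_dir / "profiles" / "cophenetic.json"
    if profiles_path.exists():
        profiles = json.loads(profiles_path.read_text())
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for name, values in profiles.items():
            ks = sorted(int(k) for k in values)
            ax.plot(ks, [values[str(k)] for k in ks], marker="o", label=name)
        ax.set_xlabel("k"); ax.set_ylabel("cophenetic correlation")
        ax.legend(fontsize=7)
        fig.tight_layout()
        target = out / "cophenetic_profiles.png"
        fig.savefig(target, dpi=120)
        plt.close(fig)
        figures.append(target)
        for cons_path in sorted((run_dir / "profiles").glob("*.consensus.tsv")):
            m = pd.read_csv(cons_path, sep="\t", index_col=0)
            d = squareform(1 - m.to_numpy(), checks=False)
            if np.ptp(d) > 0:
                order = leaves_list(linkage(d, method="average"))
            else:
                order = np.arange(m.shape[0])
            fig, ax = plt.subplots(figsize=(3.5, 3.2))
            ax.imshow(m.to_numpy()[np.ix_(order, order)], vmin=0, vmax=1, cmap="viridis")
            ax.set_title(cons_path.stem, fontsize=8)
            ax.set_xticks([]); ax.set_yticks([])
            fig.tight_layout()
            target = out / (cons_path.stem + ".png")
            fig.savefig(target, dpi=110)
            plt.close(fig)
            figures.append(target)

    null_path = run_dir / "null" / "summary.json"
    if null_path.exists():
        summary = json.loads(null_path.read_text())
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(range(len(summary)), [rep["max_abs_matched"] for rep in summary])
        ax.set_xlabel("null replicate"); ax.set_ylabel("max |matched r|")
        fig.tight_layout()
        target = out / "null_summary.png"
        fig.savefig(target, dpi=120)
        plt.close(fig)
        figures.append(target)
    return figures


# ----------------------------------------------------------------- simulate

def write_synthetic_inputs(
    config: SyntheticConfig, out_dir: str | Path
) -> dict[str, dict[str, str]]:
    """Write a synthetic collection in the pipeline's input TSV format.

    Returns the ``datasets`` mapping a :class:`PipelineConfig` expects, plus
    a ``truth.json`` with labels and signatures alongside the matrices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets, truth = generate_multistudy(config)
    mapping: dict[str, dict[str, str]] = {}
    for ds in datasets:
        matrix = out / f"{ds.name}.tsv"
        ann = out / f"{ds.name}.annotations.tsv"
        write_expression_matrix(ds, matrix)
        ds.annotations.to_csv(ann, sep="\t", index_label="sample_id")
        mapping[ds.name] = {"matrix": str(matrix), "annotations": str(ann)}
    (out / "truth.json").write_text(
        json.dumps(
            {
                "labels": {n: s.to_dict() for n, s in truth.labels.items()},
                "signatures": truth.signatures,
            },
            indent=2,
        )
    )
    return mapping
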