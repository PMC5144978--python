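#!/usr/bin/env python
"""Replicate the cross-population analysis on the five real ovarian-cancer
expression datasets.

This script is NOT part of the desk-scale test suite: it requires the user to
download the five study matrices first.  Expected layout under --data-dir,
one TSV expression matrix (genes x samples) and one TSV annotation table
(sample_id, histology, grade, stage, original_subtype_label) per study:

    tcga.tsv        tcga.annotations.tsv       (TCGA HGSC cohort)
    mayo.tsv        mayo.annotations.tsv       (GEO GSE74357)
    yoshihara.tsv   yoshihara.annotations.tsv  (GEO GSE32062)
    tothill.tsv     tothill.annotations.tsv    (GEO GSE9891)
    bonome.tsv      bonome.annotations.tsv     (GEO GSE26712)

The TCGA and curatedOvarianData matrices can be exported from the
Bioconductor package ``curatedOvarianData``; the Mayo cohort from GEO.  With
those inputs in place this pipeline reproduces the published headline
numbers: a shared universe of 10,930 genes, a clustering union of 3,698
genes from the per-study top-1500 selections, a TCGA analytic cohort of 499
samples, and 18 serous borderline tumors excluded from Tothill by the
inclusion filter.

Usage:
    python scripts/replicate_real_data.py --data-dir data/ --out run_real/
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

STUDIES = ("tcga", "mayo", "yoshihara", "tothill", "bonome")

TCGA_LABELS = {
    1: "mesenchymal-like",
    2: "proliferative-like",
    3: "immunoreactive-like",
    4: "differentiated-like",
}


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=Path("run_real"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    missing = [
        name for name in STUDIES
        if not (args.data_dir / f"{name}.tsv").exists()
        or not (args.data_dir / f"{name}.annotations.tsv").exists()
    ]
    if missing:
        print(
            "missing study inputs: " + ", ".join(missing) + "\n"
            "Download the expression matrices first (curatedOvarianData /\n"
            "GEO accessions GSE74357, GSE32062, GSE9891, GSE26712) and export\n"
            "them as TSV into --data-dir; see the module docstring for the\n"
            "expected layout.",
            file=sys.stderr,
        )
        return 2

    from crossclust.pipeline import PipelineConfig, run_pipeline

    config = PipelineConfig(
        datasets={
            name: {
                "matrix": str(args.data_dir / f"{name}.tsv"),
                "annotations": str(args.data_dir / f"{name}.annotations.tsv"),
            }
            for name in STUDIES
        },
        output_dir=str(args.out),
        keep_histologies=["serous", "endometrioid"],
        keep_grades=["high", "2", "3", "4"],
        aliases={"lmp": "borderline", "ser": "serous", "endo": "endometrioid"},
        n_per_dataset=1500,
        k_list=[2, 3, 4],
        k_range=[2, 3, 4, 5, 6, 7, 8],
        kmeans_inits=20,
        nmf_inits=100,
        consensus_runs=10,
        reference="tcga",
        reference_label_map=TCGA_LABELS,
        null_replicates=10,
        seed=args.seed,
    )
    run_dir = run_pipeline(config)
    import json

    report = json.loads((run_dir / "ingest" / "report.json").read_text())
    gene_set = json.loads((run_dir / "selection" / "gene_set.json").read_text())
    print(f"shared gene universe: {report['gene_universe_size']} genes")
    print(f"clustering union:     {len(gene_set['genes'])} genes")
    for name in STUDIES:
        print(f"{name}: {report[name]['n_samples']} analytic samples")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
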