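# crossclust

Cross-study concordance analysis of molecular subtype clusterings in tumor
expression data.

## The problem

Expression-based tumor subtypes are usually discovered by clustering one
cohort.  Whether those subtypes are real biology or artifacts of one
dataset's quirks is a cross-study question: cluster each cohort
*independently*, then ask whether the clusters correspond across cohorts.
`crossclust` implements that procedure end to end for gene-expression
studies (the motivating setting is high-grade serous ovarian cancer, but
nothing is tissue-specific):

1. **Ingest** — per-study genes × samples TSV matrices plus sample
   annotations; inclusion filtering on histology/grade; restriction of all
   studies to the shared gene universe.
2. **Selection** — each study contributes its top-*n* most variable genes
   (MAD × 1.4826 or unbiased variance); clustering uses the union.
3. **Clustering** — best-of-20 Euclidean k-means and KL-divergence NMF
   (multiplicative updates on a positive/negative fold of the centered
   matrix), run independently within each study for each k; NMF consensus
   matrices over repeated runs give cophenetic-correlation profiles over
   k = 2..8 for rank selection.
4. **Signatures** — every cluster is summarized as a SAM moderated-*t*
   vector over the full shared gene universe: d = r / (s + s₀), one-vs-rest,
   with the fudge factor s₀ chosen by the percentile-grid recipe.
5. **Concordance** — Pearson correlations between t-vectors across studies;
   optimal one-to-one cluster matching (Hungarian assignment); reference
   label propagation; min–max matched-correlation range tables; contingency
   tables against previously published labels.
6. **Negative control** — independently shuffle each gene's values within
   each study and re-run everything: within-study structure persists,
   cross-study matched correlations collapse to ~2/√n_genes.
7. **Simulation** — a synthetic multi-study generator (shared subtype
   signatures, study-specific batch location/scale effects, optional
   distinct contaminant class) provides ground truth for every stage.

## Worked example

```python
from crossclust import SubtypeConcordance, SyntheticConfig, generate_multistudy

# four synthetic studies, 150 samples x 2000 genes, three planted subtypes
datasets, truth = generate_multistudy(SyntheticConfig(seed=7))

model = SubtypeConcordance(list(datasets), n_per_dataset=250,
                           k_list=(2, 3), nmf_inits=10)
results = model.fit(seed=7)
print(results.summary())
```

prints

```
Cross-study subtype concordance
================================================================
Datasets:        study_1, study_2, study_3, study_4
Gene universe:   2000 shared genes
Clustering set:  union of top 250 per study (469 genes, mad)
Seed:            7

--- kmeans, k = 2 ---
  retained           cluster_1            r = +0.47 .. +0.85 (6 pairs)
  retained           cluster_2            r = +0.47 .. +0.85 (6 pairs)

--- kmeans, k = 3 ---
  retained           cluster_1            r = +0.81 .. +0.84 (6 pairs)
  retained           cluster_2            r = +0.84 .. +0.85 (6 pairs)
  retained           cluster_3            r = +0.83 .. +0.84 (6 pairs)

--- nmf, k = 2 ---
  retained           cluster_1            r = +0.47 .. +0.85 (6 pairs)
  retained           cluster_2            r = +0.47 .. +0.85 (6 pairs)

--- nmf, k = 3 ---
  retained           cluster_1            r = +0.83 .. +0.84 (6 pairs)
  retained           cluster_2            r = +0.81 .. +0.84 (6 pairs)
  retained           cluster_3            r = +0.84 .. +0.85 (6 pairs)
```

Each line is the min–max Pearson correlation between matched ("analogous")
clusters' moderated-t vectors over all 6 study pairs.  Three subtypes were
planted, and the table shows it: at k = 3 every matched range sits at
r ≈ 0.81–0.85 for both algorithms, while forcing k = 2 merges two subtypes
and drags the weakest matched correlation down to 0.47.  The same objects
expose the pieces: `results.assignments`, `results.tmatrices`,
`results.concordance`, `results.matched_range_table("kmeans", 3)`,
`model.cophenetic_profiles()`.

## Command line

The same pipeline runs from a shell against TSV inputs, one stage per
subcommand, driven by a YAML config:

```bash
crossclust simulate --out demo/ --seed 1            # or bring your own TSVs
crossclust run-all --config demo/config.yaml
crossclust report --run-dir demo/run
```

`run-all` executes ingest → select → cluster → summarize → concord →
profile (→ null), writing TSV/JSON artifacts and a manifest (config hash,
seed, versions) sufficient to re-run byte-identically; `report` renders
heatmaps and cophenetic line plots from those artifacts.  Individual
subcommands (`ingest`, `select`, `cluster`, `summarize`, `concord`,
`profile`, `null`) re-run single stages against the same run directory.

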