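"""Synthetic multi-study expression data with planted subtype structure.

The generator emulates the statistical skeleton of a multi-population
subtyping study: a set of subtype expression signatures shared across
studies, study-specific batch location/scale effects, gene-wise Gaussian
noise, and optionally a distinct "contaminant" sample class with its own
signature — the analogue of serous borderline tumors mixed into a high-grade
serous cohort, whose presence is known to inflate support for an extra
cluster.

Generative model for gene g, sample j of dataset d:

    x_gj = mu_g + b_dg + gamma_dg * beta * 1[g in S_c(j)] + eps_gj

with mu_g ~ N(0, 1) shared across datasets, b_dg ~ N(0, batch_sd^2),
log gamma_dg ~ N(0, batch_scale_sd^2), eps ~ N(0, noise_sd^2), beta the
effect size and S_c the (disjoint) signature gene set of sample j's class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_multistudy",
    "generate_contaminated_pair",
    "CONTAMINANT_LABEL",
]

CONTAMINANT_LABEL = "contaminant"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic multi-study generator.

    Defaults describe four studies of 150 samples over 2000 genes with three
    planted subtypes of 100 signature genes each, an effect size of 1.5
    noise-sd units, unit noise, additive batch sd 0.5 and log-scale batch sd
    0.1.  ``contaminant_fraction`` adds that fraction of extra samples drawn
    from a distinct contaminant class (7% mirrors 18 borderline tumors in a
    260-sample cohort); contaminants are appended on top of
    ``samples_per_dataset``.
    """

    n_datasets: int = 4
    samples_per_dataset: int = 150
    n_genes: int = 2000
    k_true: int = 3
    signature_size: int = 100
    effect_size: float = 1.5
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    batch_scale_sd: float = 0.1
    subtype_proportions: tuple[float, ...] | None = None
    contaminant_fraction: float = 0.0
    contaminant_effect: float = 2.0
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.subtype_proportions is None:
            return np.full(self.k_true, 1.0 / self.k_true)
        p = np.asarray(self.subtype_proportions, dtype=float)
        if p.size != self.k_true or not np.isclose(p.sum(), 1.0):
            raise ValueError("subtype_proportions must have k_true entries summing to 1")
        return p

    def validate(self) -> None:
        n_classes = self.k_true + (1 if self.contaminant_fraction > 0 else 0)
        if self.signature_size * n_classes > self.n_genes:
            raise ValueError("signature sets do not fit in the gene universe")
        if self.samples_per_dataset < 4 * self.k_true:
            raise ValueError("need at least 4 samples per planted subtype")
        if not (0 <= self.contaminant_fraction < 1):
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        self.proportions()


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic collection."""

    labels: dict[str, pd.Series]  # dataset -> sample label ("subtype_i" or contaminant)
    signatures: dict[str, list[str]]  # class label -> signature genes
    batch_offsets: dict[str, pd.Series] = field(repr=False, default_factory=dict)
    batch_scales: dict[str, pd.Series] = field(repr=False, default_factory=dict)

    def n_contaminants(self, dataset: str) -> int:
        return int((self.labels[dataset] == CONTAMINANT_LABEL).sum())


def _class_names(config: SyntheticConfig) -> list[str]:
    names = [f"subtype_{c + 1}" for c in range(config.k_true)]
    if config.contaminant_fraction > 0:
        names.append(CONTAMINANT_LABEL)
    return names


def generate_multistudy(
    config: SyntheticConfig,
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Draw a collection of study datasets sharing planted subtype signatures.

    Subtype identities and signature gene sets are shared across datasets;
    batch offsets/scales are dataset-specific.  Per-dataset subtype counts
    are multinomial draws from ``subtype_proportions``; contaminant samples
    are appended on top.  Annotations carry the truth as
    ``original_subtype_label`` (empty for contaminants) and mark contaminants
    with ``histology = "borderline"`` so the inclusion filter can remove
    them.  Identical config and seed give bit-identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_global, *ss_datasets = root.spawn(1 + config.n_datasets)
    rng = np.random.default_rng(ss_global)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    mu = rng.normal(0.0, 1.0, size=config.n_genes)

    class_names = _class_names(config)
    sig_genes = rng.permutation(config.n_genes)[: config.signature_size * len(class_names)]
    signatures = {
        name: sorted(genes[i] for i in sig_genes[c * config.signature_size:(c + 1) * config.signature_size])
        for c, name in enumerate(class_names)
    }
    sig_index = {
        name: np.flatnonzero(np.isin(np.array(genes), signatures[name]))
        for name in class_names
    }

    n_cont = int(round(config.contaminant_fraction * config.samples_per_dataset))
    datasets: list[ExpressionDataset] = []
    truth = SyntheticTruth(labels={}, signatures=signatures)
    for d, ss in enumerate(ss_datasets):
        name = f"study_{d + 1}"
        rng_d = np.random.default_rng(ss)
        counts = rng_d.multinomial(config.samples_per_dataset, config.proportions())
        labels = np.repeat(
            [f"subtype_{c + 1}" for c in range(config.k_true)], counts
        ).tolist()
        labels += [CONTAMINANT_LABEL] * n_cont
        n_samples = len(labels)
        sample_ids = [f"{name}_s{j:03d}" for j in range(n_samples)]

        b = rng_d.normal(0.0, config.batch_sd, size=config.n_genes)
        gamma = np.exp(rng_d.normal(0.0, config.batch_scale_sd, size=config.n_genes))
        x = np.tile((mu + b)[:, None], (1, n_samples))
        for j, lab in enumerate(labels):
            idx = sig_index[lab]
            beta = (
                config.contaminant_effect if lab == CONTAMINANT_LABEL else config.effect_size
            )
            x[idx, j] += gamma[idx] * beta
        x += rng_d.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

        label_series = pd.Series(labels, index=sample_ids, name="label")
        is_cont = label_series == CONTAMINANT_LABEL
        annotations = pd.DataFrame(
            {
                "histology": np.where(is_cont, "borderline", "serous"),
                "grade": np.where(is_cont, "low", "high"),
                "stage": "iii",
                "original_subtype_label": label_series.where(~is_cont, "").to_numpy(),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        values = pd.DataFrame(x, index=genes, columns=sample_ids)
        datasets.append(ExpressionDataset(name, values, annotations))
        truth.labels[name] = label_series
        truth.batch_offsets[name] = pd.Series(b, index=genes)
        truth.batch_scales[name] = pd.Series(gamma, index=genes)
    return datasets, truth


def generate_contaminated_pair(
    config: SyntheticConfig,
) -> tuple[
    tuple[list[ExpressionDataset], SyntheticTruth],
    tuple[list[ExpressionDataset], SyntheticTruth],
]:
    """Paired clean/contaminated collections sharing every random draw.

    The contaminated arm is a plain :func:`generate_multistudy` draw with
    ``contaminant_fraction > 0``; the clean arm is exactly that collection
    with the contaminant samples removed, enabling a paired comparison of
    cophenetic profiles with and without the contaminant class.
    Returns ``(clean, contaminated)``.
    """
    if config.contaminant_fraction <= 0:
        raise ValueError("contaminated arm requires contaminant_fraction > 0")
    cont_datasets, cont_truth = generate_multistudy(config)
    clean_datasets: list[ExpressionDataset] = []
    clean_truth = SyntheticTruth(
        labels={},
        signatures=cont_truth.signatures,
        batch_offsets=cont_truth.batch_offsets,
        batch_scales=cont_truth.batch_scales,
    )
    for ds in cont_datasets:
        keep = [
            s for s in ds.samples
            if cont_truth.labels[ds.name].loc[s] != CONTAMINANT_LABEL
        ]
        clean_datasets.append(ds.subset_samples(keep))
        clean_truth.labels[ds.name] = cont_truth.labels[ds.name].loc[keep]
    return (clean_datasets, clean_truth), (cont_datasets, cont_truth)
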