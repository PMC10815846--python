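"""Synthetic radiogenomic cohorts with planted structure.

Generates labeled cohorts that mimic the statistical shape of an NSCLC
lymph-node-metastasis radiogenomic study: an imbalanced binary cohort
(73 non-metastasis / 20 metastasis by default), a gene-expression matrix
with block-correlated co-expression modules and a handful of
label-associated "signal" genes, a STRING-style weighted PPI edge list
that is denser inside modules than between them, and per-modality
radiomic feature tables whose per-feature discriminative AUC is
controlled analytically.

The expression model is a single-factor block model: gene g in module m
has profile

    x_g = sqrt(r) * f_m + sqrt(1 - r) * eps_g,

with f_m the module's latent factor and r the target within-module
Pearson correlation, so cor(x_g, x_h) = r for two genes sharing a
module. Signal genes receive a mean shift of d (Cohen's d, in
standardized units) in the positive class. Radiomic features follow the
binormal ROC model: a unit-variance Gaussian feature whose class-1 mean
is shifted by Delta = sqrt(2) * Phi^{-1}(A) has true AUC exactly A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_expression",
    "generate_ppi",
    "generate_radiomics",
    "generate_cohort",
    "write_cohort",
    "RADIOMIC_FEATURE_NAMES",
]

#: Printed names of PET/CT texture features (TLG, shape, and gray-level
#: run-length / zone-length / neighborhood-dependence matrix statistics);
#: used to label synthetic radiomic columns so reports read like the
#: usual LIFEx-style output.
RADIOMIC_FEATURE_NAMES: tuple[str, ...] = (
    "TLG",
    "SUVmax",
    "SUVmean",
    "SHAPE Volume (mL)",
    "SHAPE Volume (# vx)",
    "SHAPE Compacity",
    "SHAPE Sphericity",
    "HISTO Skewness",
    "HISTO Kurtosis",
    "HISTO Entropy",
    "HISTO Energy",
    "GLCM Homogeneity",
    "GLCM Energy",
    "GLCM Contrast",
    "GLCM Correlation",
    "GLCM Entropy",
    "GLCM Dissimilarity",
    "GLRLM SRE",
    "GLRLM LRE",
    "GLRLM LGRE",
    "GLRLM HGRE",
    "GLRLM SRLGE",
    "GLRLM SRHGE",
    "GLRLM LRLGE",
    "GLRLM LRHGE",
    "GLRLM GLNU",
    "GLRLM RLNU",
    "GLRLM RP",
    "NGLDM Coarseness",
    "NGLDM Contrast",
    "NGLDM Busyness",
    "GLZLM SZE",
    "GLZLM LZE",
    "GLZLM LGZE",
    "GLZLM HGZE",
    "GLZLM SZLGE",
    "GLZLM SZHGE",
    "GLZLM LZLGE",
    "GLZLM LZHGE",
    "GLZLM GLNU",
    "GLZLM ZLNU",
    "GLZLM ZP",
)


@dataclass
class SyntheticConfig:
    """Parameters of the planted cohort.

    Defaults follow the study conditions: 73 negative / 20 positive
    samples and 55 texture features per imaging modality.
    """

    n_major: int = 73
    n_minor: int = 20
    n_genes: int = 300
    module_sizes: tuple[int, ...] = (50, 50, 50)
    within_module_cor: float = 0.8
    signal_genes: int = 4
    effect_size_d: float = 1.5
    ppi_within_density: float = 0.3
    ppi_between_density: float = 0.01
    n_features_per_modality: int = 55
    feature_target_aucs: tuple[float, ...] = (0.8,) * 5
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return self.n_major + self.n_minor

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if not 0.0 <= self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be in [0, 1)")
        for name in ("ppi_within_density", "ppi_between_density"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_major < 2 or self.n_minor < 2:
            raise ValueError("need at least 2 samples per class")
        for a in self.feature_target_aucs:
            if not 0.5 <= a < 1.0:
                raise ValueError(f"target AUC {a} outside [0.5, 1)")
        if len(self.feature_target_aucs) > self.n_features_per_modality:
            raise ValueError("more target AUCs than features per modality")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth planted into it."""

    expression: pd.DataFrame  # genes x samples
    labels: pd.Series  # sample -> 0/1
    ppi_edges: pd.DataFrame  # protein1, protein2, combined_score
    radiomic_pet: pd.DataFrame  # samples x features
    radiomic_ct: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n)]


def generate_expression(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw the expression matrix, labels, and planted-truth record.

    Returns (expression genes x samples, labels, truth). Truth records
    module membership, signal genes, and the per-module latent factors.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    genes = _gene_ids(cfg.n_genes)
    samples = _sample_ids(n)
    labels = np.zeros(n, dtype=int)
    labels[cfg.n_major:] = 1

    r = cfg.within_module_cor
    x = rng.standard_normal((cfg.n_genes, n))
    membership = np.zeros(cfg.n_genes, dtype=int)  # 0 = background
    start = 0
    factors = np.empty((cfg.n_modules, n))
    for m, size in enumerate(cfg.module_sizes, start=1):
        f = rng.standard_normal(n)
        factors[m - 1] = f
        block = slice(start, start + size)
        x[block] = np.sqrt(r) * f + np.sqrt(1.0 - r) * x[block]
        membership[block] = m
        start += size

    # signal genes: one per module round-robin, shifted by d in the
    # positive class on the standardized (unit-variance) scale
    signal_idx: list[int] = []
    if cfg.signal_genes:
        offsets = np.zeros(cfg.n_modules, dtype=int)
        starts = np.cumsum((0,) + cfg.module_sizes[:-1])
        for j in range(cfg.signal_genes):
            m = j % cfg.n_modules
            signal_idx.append(int(starts[m] + offsets[m]))
            offsets[m] += 1
        x[signal_idx] += cfg.effect_size_d * labels

    expr = pd.DataFrame(x, index=genes, columns=samples)
    truth = {
        "module_membership": dict(zip(genes, membership.tolist())),
        "signal_genes": [genes[i] for i in signal_idx],
        "feature_target_aucs": list(cfg.feature_target_aucs),
    }
    return expr, pd.Series(labels, index=samples, name="metastasis"), truth


def generate_ppi(
    cfg: SyntheticConfig, truth: dict, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Bernoulli PPI edges: denser within planted modules than between.

    combined_score is uniform over [400, 999] (the STRING medium-
    confidence band). Undirected, no self-loops, no duplicates.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    genes = list(truth["module_membership"])
    member = np.array([truth["module_membership"][g] for g in genes])
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    same = (member[iu] == member[ju]) & (member[iu] > 0)
    p = np.where(same, cfg.ppi_within_density, cfg.ppi_between_density)
    keep = rng.random(p.shape) < p
    scores = rng.integers(400, 1000, size=int(keep.sum()))
    garr = np.asarray(genes)
    return pd.DataFrame(
        {
            "protein1": garr[iu[keep]],
            "protein2": garr[ju[keep]],
            "combined_score": scores,
        }
    )


def binormal_shift(target_auc: float) -> float:
    """Class-1 mean shift giving the target AUC under the binormal model."""
    return float(np.sqrt(2.0) * stats.norm.ppf(target_auc))


def generate_radiomics(
    cfg: SyntheticConfig,
    labels: np.ndarray | pd.Series,
    rng: np.random.Generator | None = None,
    modality: str = "PET",
) -> pd.DataFrame:
    """Unit-variance Gaussian features with controlled per-feature AUC.

    The first ``len(cfg.feature_target_aucs)`` columns carry the target
    AUCs via the binormal shift; remaining columns are pure noise
    (true AUC 0.5), padding the table to ``n_features_per_modality``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    y = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    n = len(y)
    k = cfg.n_features_per_modality
    x = rng.standard_normal((n, k))
    for j, a in enumerate(cfg.feature_target_aucs):
        x[:, j] += binormal_shift(a) * y
    names = [
        f"{modality} {RADIOMIC_FEATURE_NAMES[j % len(RADIOMIC_FEATURE_NAMES)]}"
        if j < len(RADIOMIC_FEATURE_NAMES)
        else f"{modality} feature {j}"
        for j in range(k)
    ]
    index = (
        labels.index if isinstance(labels, pd.Series) else _sample_ids(n)
    )
    return pd.DataFrame(x, index=index, columns=names)


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    expr, labels, truth = generate_expression(cfg, rng)
    edges = generate_ppi(cfg, truth, rng)
    pet = generate_radiomics(cfg, labels, rng, modality="PET")
    ct = generate_radiomics(cfg, labels, rng, modality="CT")
    return SyntheticCohort(
        expression=expr,
        labels=labels,
        ppi_edges=edges,
        radiomic_pet=pet,
        radiomic_ct=ct,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort in the pipeline's file dialects.

    Expression TSV (rows = genes, columns = samples), labels TSV,
    STRING-dialect edge TSV, radiomic CSVs, and a truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "ppi_edges": outdir / "ppi_edges.tsv",
        "radiomic_pet": outdir / "radiomic_pet.csv",
        "radiomic_ct": outdir / "radiomic_ct.csv",
        "truth": outdir / "truth.json",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    cohort.labels.to_frame().to_csv(paths["labels"], sep="\t", index_label="sample")
    cohort.ppi_edges.to_csv(paths["ppi_edges"], sep="\t", index=False)
    cohort.radiomic_pet.to_csv(paths["radiomic_pet"], index_label="sample")
    cohort.radiomic_ct.to_csv(paths["radiomic_ct"], index_label="sample")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1))
    return paths
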