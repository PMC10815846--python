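"""Weighted gene co-expression analysis (WGCNA-style, single block).

Soft-threshold adjacency |cor|^beta, topological overlap (TOM), module
detection by average-linkage clustering of TOM dissimilarity with a
fixed-height cut, module eigengenes, module-trait association, and
per-gene gene significance (GS = |cor(gene, trait)|).

Simplifications relative to full WGCNA: unsigned network, Pearson
correlation, fixed-height tree cut plus minimum module size in place of
dynamic tree cut, and no eigengene-based module merging. The defaults
(soft power 5, minimum module size 30) match common practice for
cohort-scale bulk expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "CoexprConfig",
    "ModuleAssignment",
    "filter_genes",
    "remove_outlier_samples",
    "adjacency_tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_stats",
    "gene_significance",
    "run_wgcna",
]


@dataclass
class CoexprConfig:
    soft_power: int = 5
    min_module_size: int = 30
    variance_filter_quantile: float = 0.0
    sample_outlier_z: float | None = None
    tree_cut_height: float = 0.99

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0.0 <= self.variance_filter_quantile < 1.0:
            raise ValueError("variance_filter_quantile must be in [0, 1)")
        if not 0.0 < self.tree_cut_height <= 1.0:
            raise ValueError("tree_cut_height must be in (0, 1]")


@dataclass
class ModuleAssignment:
    """Module labels plus per-module summaries.

    ``labels`` maps gene -> integer module label, with 0 the unassigned
    ("grey") bucket. ``eigengenes`` holds one unit-norm column per
    module (samples x modules). ``trait_stats`` has one row per module
    with point-biserial correlation and p-value against the trait.
    ``gene_significance`` is |cor(gene, trait)| per gene.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_significance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def filter_genes(expr: pd.DataFrame, cfg: CoexprConfig) -> pd.DataFrame:
    """Drop low-variability genes (median absolute deviation filter).

    Genes whose MAD falls below the ``variance_filter_quantile``
    quantile of all gene MADs are removed; gene order is preserved.
    """
    if expr.empty:
        raise ValueError("expression matrix is empty")
    if cfg.variance_filter_quantile == 0.0:
        return expr
    mad = stats.median_abs_deviation(expr.to_numpy(), axis=1)
    cutoff = np.quantile(mad, cfg.variance_filter_quantile)
    keep = mad >= cutoff
    # MAD==0 genes are uninformative for correlation networks regardless
    keep &= mad > 0
    out = expr.loc[keep]
    if out.empty:
        raise ValueError("variance filter removed all genes")
    return out


def remove_outlier_samples(expr: pd.DataFrame, cfg: CoexprConfig) -> pd.DataFrame:
    """Drop samples whose mean Euclidean distance to the rest is extreme.

    A sample is an outlier when its mean distance to all other samples
    exceeds mean + z * sd of those per-sample means. At most 20% of
    samples are removed (with a warning if the rule would take more).
    """
    if cfg.sample_outlier_z is None:
        return expr
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    x = expr.to_numpy().T  # samples x genes
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    d = np.sqrt(np.maximum(d2, 0.0))
    mean_dist = d.sum(axis=1) / (len(x) - 1)
    mu, sd = mean_dist.mean(), mean_dist.std(ddof=1)
    if sd == 0:
        return expr
    score = (mean_dist - mu) / sd
    out_mask = score > cfg.sample_outlier_z
    max_remove = int(0.2 * expr.shape[1])
    if out_mask.sum() > max_remove:
        warnings.warn(
            f"outlier rule flagged {int(out_mask.sum())} samples; capping at 20% "
            f"({max_remove})",
            stacklevel=2,
        )
        order = np.argsort(score)[::-1]
        out_mask = np.zeros_like(out_mask)
        out_mask[order[:max_remove]] = True
    return expr.loc[:, ~out_mask]


def adjacency_tom(expr: pd.DataFrame, cfg: CoexprConfig) -> pd.DataFrame:
    """TOM dissimilarity of the soft-thresholded co-expression network.

    a_ij = |pearson(x_i, x_j)|^beta (zero diagonal); the topological
    overlap is

        TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

    with connectivity k_i = sum_{u != i} a_iu, and the returned matrix
    is 1 - TOM with an exact-zero diagonal.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    x = expr.to_numpy()
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = expr.index[sd == 0][:5].tolist()
        raise ValueError(f"zero-variance genes present (filter first): {bad}")
    a = np.abs(np.corrcoef(x)) ** cfg.soft_power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    dis = 1.0 - tom
    dis = (dis + dis.T) / 2.0
    np.fill_diagonal(dis, 0.0)
    dis = np.clip(dis, 0.0, 1.0)
    return pd.DataFrame(dis, index=expr.index, columns=expr.index)


def detect_modules(dissim: pd.DataFrame, cfg: CoexprConfig) -> ModuleAssignment:
    """Average-linkage clustering with a flat cut; small clusters -> 0.

    Cluster labels are renumbered 1..M by descending module size (ties
    by first gene id); genes in clusters smaller than
    ``min_module_size`` get label 0.
    """
    d = dissim.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square symmetric")
    link = average(squareform(d, checks=False))
    raw = fcluster(link, t=cfg.tree_cut_height, criterion="distance")
    labels = np.zeros_like(raw)
    clusters = []
    for c in np.unique(raw):
        idx = np.where(raw == c)[0]
        if len(idx) >= cfg.min_module_size:
            clusters.append((len(idx), str(dissim.index[idx[0]]), idx))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for new, (_, _, idx) in enumerate(clusters, start=1):
        labels[idx] = new
    return ModuleAssignment(labels=pd.Series(labels, index=dissim.index, name="module"))


def module_eigengene(expr: pd.DataFrame, gene_ids: list[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Returned per-sample vector has unit norm and is sign-oriented to
    correlate positively with the module's mean standardized expression.
    A one-gene module degenerates to that gene's standardized profile
    (normalized).
    """
    sub = expr.loc[gene_ids].to_numpy()
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant gene in module; filter first")
    z = (sub - mu) / sd  # genes x samples
    if len(gene_ids) == 1:
        v = z[0]
    else:
        # first right singular vector of the genes x samples matrix
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
    v = v / np.linalg.norm(v)
    if np.dot(v, z.mean(axis=0)) < 0:
        v = -v
    return pd.Series(v, index=expr.columns)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def module_trait_stats(eigengenes: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Point-biserial correlation of each eigengene with a binary trait.

    Two-sided Student-t p-values. Requires both classes present.
    """
    y = trait.loc[eigengenes.index].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("trait is constant")
    rows = []
    for mod in eigengenes.columns:
        r, p = _pearson_with_p(eigengenes[mod].to_numpy(), y)
        rows.append({"module": mod, "trait_cor": r, "p_value": p})
    return pd.DataFrame(rows).set_index("module")


def gene_significance(expr: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """GS per gene: absolute Pearson correlation with the binary trait."""
    y = trait.loc[expr.columns].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("trait is constant")
    x = expr.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return pd.Series(np.abs(r), index=expr.index, name="GS")


def run_wgcna(
    expr: pd.DataFrame, trait: pd.Series, cfg: CoexprConfig | None = None
) -> ModuleAssignment:
    """Full single-block pass: filter, TOM, modules, eigengenes, stats."""
    cfg = cfg or CoexprConfig()
    expr = filter_genes(expr, cfg)
    expr = remove_outlier_samples(expr, cfg)
    trait = trait.loc[expr.columns]
    dis = adjacency_tom(expr, cfg)
    assign = detect_modules(dis, cfg)
    eg = {
        m: module_eigengene(expr, assign.genes_in(m)) for m in assign.module_ids
    }
    if eg:
        assign.eigengenes = pd.DataFrame(eg)
        assign.trait_stats = module_trait_stats(assign.eigengenes, trait)
        sizes = assign.labels.value_counts()
        assign.trait_stats.insert(0, "size", [int(sizes[m]) for m in assign.eigengenes.columns])
    assign.gene_significance = gene_significance(expr, trait)
    return assign
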