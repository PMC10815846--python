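"""Metastasis-gene filtering cascade.

Four stages, applied to the genes of trait-associated co-expression
modules: (1) a per-gene Welch two-sample t-test between metastasis and
non-metastasis samples (DEG stage), (2) hypergeometric
over-representation analysis against pathway gene sets read from a GMT
file, (3) a per-gene univariate logistic regression screen, and (4) a
final hub-gene pick by gene-significance (GS) rank.

Selection at each statistical stage is on the raw p-value at alpha
(default 0.05); Benjamini–Hochberg q-values are reported alongside for
transparency but are not used for selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "SelectionResult",
    "read_gmt",
    "deg_test",
    "ora_enrichment",
    "univariate_screen",
    "gs_rank",
]


@dataclass
class GeneSetCollection:
    """Named pathway gene sets (GMT contents)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name}")
            if any(not g for g in genes):
                raise ValueError(f"empty gene id in set: {name}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class SelectionResult:
    """Outcome of one cascade stage."""

    stage: str
    table: pd.DataFrame  # index = gene/pathway, columns include p_value, retained
    threshold: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read tab-delimited GMT: name, description, then gene ids."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{i}: GMT line needs name, description, >=1 gene")
        name = parts[0]
        sets[name] = [g for g in parts[2:] if g]
        desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def deg_test(
    expr: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> SelectionResult:
    """Per-gene Welch t-test between label groups; retain p < alpha."""
    y = labels.loc[expr.columns].to_numpy()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both classes need >= 2 samples")
    x1 = expr.loc[:, y == 1].to_numpy()
    x0 = expr.loc[:, y == 0].to_numpy()
    t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    tab = pd.DataFrame(
        {"statistic": t, "p_value": p, "q_value": _bh(p)}, index=expr.index
    )
    tab["retained"] = tab["p_value"] < alpha
    return SelectionResult(stage="deg", table=tab, threshold=alpha)


def ora_enrichment(
    query: list[str],
    background: list[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> SelectionResult:
    """Hypergeometric over-representation of each pathway in the query.

    For a pathway with K background members, a query of size n drawn
    from a background of size N, and overlap k, the p-value is the
    hypergeometric upper tail P(X >= k) — equivalent to a one-sided
    Fisher exact test on the 2x2 table.
    """
    bg = set(background)
    q = set(query)
    if not q <= bg:
        raise ValueError(f"query genes outside background: {sorted(q - bg)[:5]}")
    rows = []
    for name, genes in collection:
        members = set(genes) & bg
        overlap = sorted(q & members)
        k, big_n, big_k, n = len(overlap), len(bg), len(members), len(q)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append(
            {
                "pathway": name,
                "overlap": k,
                "set_size": big_k,
                "p_value": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    tab = pd.DataFrame(rows).set_index("pathway")
    tab["q_value"] = _bh(tab["p_value"].to_numpy())
    tab["retained"] = tab["p_value"] < alpha
    return SelectionResult(stage="ora", table=tab, threshold=alpha)


def univariate_screen(
    expr: pd.DataFrame,
    labels: pd.Series,
    genes: list[str] | None = None,
    alpha: float = 0.05,
) -> SelectionResult:
    """Per-gene univariate logistic regression of label on expression.

    Wald p-value on the slope; retain p < alpha. Perfectly separating
    genes are flagged and retained with the p=0 convention; constant
    genes are excluded with a note.
    """
    genes = list(expr.index) if genes is None else list(genes)
    missing = set(genes) - set(expr.index)
    if missing:
        raise ValueError(f"genes absent from expression: {sorted(missing)[:5]}")
    y = labels.loc[expr.columns].to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = expr.loc[g].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("gene %s constant; excluded from univariate screen", g)
            rows.append({"gene": g, "statistic": np.nan, "p_value": np.nan,
                         "note": "constant"})
            continue
        xs = (x - x.mean()) / x.std()
        design = sm.add_constant(xs)
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
                beta, p = fit.params[1], fit.pvalues[1]
                note = ""
                if not np.isfinite(p):
                    raise FloatingPointError
            except Exception:  # includes PerfectSeparationWarning raised as error
                # quasi/complete separation: infinite MLE, Wald p -> 0
                beta, p, note = np.inf * np.sign(np.corrcoef(xs, y)[0, 1]), 0.0, "separation"
                logger.warning("gene %s separates classes; retained with p=0", g)
        rows.append({"gene": g, "statistic": beta, "p_value": p, "note": note})
    tab = pd.DataFrame(rows).set_index("gene")
    ok = tab["p_value"].notna()
    q = np.full(len(tab), np.nan)
    if ok.any():
        q[ok.to_numpy()] = _bh(tab.loc[ok, "p_value"].to_numpy())
    tab["q_value"] = q
    tab["retained"] = tab["p_value"] < alpha
    return SelectionResult(stage="univariate", table=tab, threshold=alpha)


def gs_rank(gs_scores: pd.Series, k: int = 5) -> list[str]:
    """Top-k genes by gene significance; ties broken lexicographically."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(gs_scores):
        raise ValueError(f"k={k} exceeds number of genes ({len(gs_scores)})")
    order = sorted(gs_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:k]]
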