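"""Per-feature ROC/AUC screening with the Hanley–McNeil standard error.

The AUC is the Mann–Whitney estimator (ties get half credit). Its
standard error uses the Hanley & McNeil closed form

    Q1 = A / (2 - A),          Q2 = 2 A^2 / (1 + A),
    se^2 = [A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2)] / (n+ n-),

from which z = (A - 0.5) / se is compared to the standard normal to test
departure from chance. Features are selected when A >= threshold
(default 0.68, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RocStat", "auc", "hanley_mcneil", "select_features"]


@dataclass
class RocStat:
    feature: str
    auc: float
    n_pos: int
    n_neg: int
    se: float
    z: float
    p: float
    selected: bool


def auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann–Whitney AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    # rank-sum form, O((n+m) log(n+m)); ties handled by midranks
    allscores = np.concatenate([pos, neg])
    ranks = stats.rankdata(allscores)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def hanley_mcneil(a: float, n_pos: int, n_neg: int) -> tuple[float, float, float]:
    """Hanley–McNeil (se, z, p) for an AUC against the null A = 0.5.

    Degenerate AUCs of exactly 0 or 1 have zero closed-form variance and
    raise; use exact or bootstrap methods for perfectly separating
    features.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    if not 0.0 < a < 1.0:
        raise ValueError(
            f"AUC={a} is degenerate for the Hanley–McNeil formula; "
            "use an exact or resampling method"
        )
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(var))
    z = (a - 0.5) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return se, float(z), p


def select_features(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    threshold: float = 0.68,
    modality: str | None = None,
) -> pd.DataFrame:
    """Per-feature ROC statistics and inclusive-threshold selection.

    ``table`` is samples x features; rows must align with ``labels``.
    Returns a DataFrame with feature, modality, auc, n_pos, n_neg, se,
    z, p, selected (A >= threshold). Degenerate AUCs (0 or 1) are kept
    with se/z/p reported as NaN; an AUC of 1 still satisfies the
    threshold.
    """
    y = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    if len(y) != len(table):
        raise ValueError("labels do not align with feature table rows")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    rows = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        a = auc(x[y == 1], x[y == 0])
        if 0.0 < a < 1.0:
            se, z, p = hanley_mcneil(a, n_pos, n_neg)
        else:
            se = z = p = float("nan")
        rows.append(
            {
                "feature": col,
                "modality": modality or "",
                "auc": a,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "se": se,
                "z": z,
                "p": p,
                "selected": bool(a >= threshold),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
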