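"""SMOTE balancing, stratified cross-validation, and the metric battery.

The evaluation protocol mirrors the study design: the imbalanced cohort
is balanced with SMOTE (by default inside each training fold only, to
avoid leaking synthetic copies of test samples into training; a
``pre_split`` mode that balances before splitting is available and
labeled as leaky in reports), the fusion model is trained with Adam on
cross-entropy, and per-fold accuracy / precision / recall / F1 / AUC
are aggregated with normal-approximation 95% confidence intervals.
Configurations sharing fold structure are compared with a paired test
(exact sign-flip permutation for few folds, paired t otherwise).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .nn.autodiff import Adam
from .nn.model import FusionModel, FusionModelConfig, cross_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "SmoteConfig",
    "TrainConfig",
    "EvalReport",
    "smote",
    "kfold_split",
    "train_model",
    "evaluate",
    "aggregate_ci",
    "compare_configs",
    "cross_validate",
]

METRICS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    leakage_mode: str = "fold_train_only"  # or "pre_split"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.leakage_mode not in ("fold_train_only", "pre_split"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 150
    val_fraction: float = 0.2
    patience: int | None = 15  # early stop if no val improvement


@dataclass
class EvalReport:
    """Per-fold and aggregate metrics for one model configuration."""

    label: str
    fold_metrics: pd.DataFrame  # columns: repeat, fold, + METRICS
    aggregate: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.aggregate.empty and not self.fold_metrics.empty:
            rows = {}
            for m in METRICS:
                vals = self.fold_metrics[m].dropna().to_numpy()
                if vals.size and self.fold_metrics[m].isna().any():
                    logger.info("%s: %d fold(s) missing %s excluded from aggregation",
                                self.label, int(self.fold_metrics[m].isna().sum()), m)
                rows[m] = aggregate_ci(vals) if vals.size >= 2 else {
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                }
            self.aggregate = pd.DataFrame(rows).T


def smote(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling to class balance.

    Each synthetic point is x_i + lambda * (x_nn - x_i) for a random
    minority sample x_i, one of its k nearest minority neighbors x_nn
    (Euclidean), and lambda ~ U(0, 1). Returns (features, labels,
    parents) where ``parents`` has one row per output sample holding the
    two source indices into the input (real samples repeat their own
    index twice).
    """
    cfg = cfg or SmoteConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects a binary label vector")
    parents = np.stack([np.arange(len(y))] * 2, axis=1)
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    if need == 0:
        return x, y, parents
    idx_min = np.flatnonzero(y == minority)
    k = cfg.k_neighbors
    if len(idx_min) <= k:
        k = len(idx_min) - 1
        warnings.warn(
            f"minority class has {len(idx_min)} samples; reducing k_neighbors to {k}",
            stacklevel=2,
        )
    if k < 1:
        raise ValueError("minority class too small for SMOTE")
    xm = x[idx_min]
    d2 = ((xm[:, None, :] - xm[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]  # indices into idx_min
    rng = np.random.default_rng(cfg.seed)
    picks = rng.integers(0, len(idx_min), size=need)
    partners = nn[picks, rng.integers(0, k, size=need)]
    lam = rng.random((need, 1))
    synth = xm[picks] + lam * (xm[partners] - xm[picks])
    x_out = np.vstack([x, synth])
    y_out = np.concatenate([y, np.full(need, minority)])
    parents = np.vstack([parents, np.stack([idx_min[picks], idx_min[partners]], axis=1)])
    return x_out, y_out, parents


def kfold_split(
    labels: np.ndarray, k: int, seed: int, stratified: bool = True
) -> np.ndarray:
    """Fold index (0..k-1) per sample; each sample tests exactly once."""
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified:
        for c, cnt in zip(*np.unique(y, return_counts=True)):
            if cnt < k:
                raise ValueError(
                    f"class {c} has {cnt} < k={k} samples; use a smaller k"
                )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


@dataclass
class _Dataset:
    """Flat feature view of the multi-graph + image inputs."""

    graph_features: dict[str, np.ndarray]  # name -> (n, n_nodes)
    image_features: np.ndarray | None  # (n, d) or None
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.graph_order = sorted(self.graph_features)

    @property
    def n(self) -> int:
        return len(self.labels)

    def flat(self) -> np.ndarray:
        parts = [self.graph_features[g] for g in self.graph_order]
        if self.image_features is not None:
            parts.append(self.image_features)
        if not parts:
            raise ValueError("dataset has neither graphs nor image features")
        return np.hstack(parts)

    def from_flat(self, x: np.ndarray, y: np.ndarray) -> "_Dataset":
        gf = {}
        start = 0
        for g in self.graph_order:
            w = self.graph_features[g].shape[1]
            gf[g] = x[:, start:start + w]
            start += w
        img = x[:, start:] if self.image_features is not None else None
        return _Dataset(graph_features=gf, image_features=img, labels=y)

    def subset(self, idx: np.ndarray) -> "_Dataset":
        return _Dataset(
            graph_features={g: a[idx] for g, a in self.graph_features.items()},
            image_features=None if self.image_features is None else self.image_features[idx],
            labels=self.labels[idx],
        )


def _balanced_log_loss(probs: np.ndarray, labels: np.ndarray,
                       eps: float = 1e-12) -> float:
    """Cross-entropy averaged per class, then across classes.

    Checkpoint selection on an imbalanced validation slice would
    otherwise reward majority-class collapse; weighting classes equally
    keeps the selected model calibrated for balanced prediction.
    """
    y = np.asarray(labels, dtype=int)
    nll = -np.log(probs[np.arange(len(y)), y] + eps)
    return float(np.mean([nll[y == c].mean() for c in np.unique(y)]))


def stratified_holdout(labels: np.ndarray, fraction: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Boolean mask marking a stratified holdout of about ``fraction``."""
    y = np.asarray(labels)
    mask = np.zeros(len(y), dtype=bool)
    for c in np.unique(y):
        idx_c = np.flatnonzero(y == c)
        n_val = max(1, int(round(fraction * len(idx_c))))
        mask[rng.permutation(idx_c)[:n_val]] = True
    return mask


def train_model(
    model: FusionModel,
    data: _Dataset,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    val: "_Dataset | None" = None,
) -> FusionModel:
    """Adam / cross-entropy training with best-validation checkpointing.

    Checkpoint selection uses ``val`` when given; otherwise a
    stratified 10% slice of the training data is held out. The
    parameters with the lowest validation loss within the epoch budget
    are restored. Deterministic given seed. A zero-epoch budget returns
    the initial parameters.
    """
    cfg = cfg or TrainConfig()
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    if cfg.epochs == 0:
        return model
    if val is None:
        val_mask = stratified_holdout(y, cfg.val_fraction, rng)
        tr, va = data.subset(~val_mask), data.subset(val_mask)
    else:
        tr, va = data, val

    opt = Adam(model.parameters(), lr=cfg.lr)
    best_loss, best_state, stale = np.inf, model.state_dict(), 0
    for _ in range(cfg.epochs):
        probs = model.forward(tr.graph_features or None, tr.image_features,
                              training=True, rng=rng)
        loss = cross_entropy(probs, tr.labels)
        if not np.isfinite(loss.data):
            raise FloatingPointError("training diverged: loss is not finite")
        opt.zero_grad()
        loss.backward()
        opt.step()
        vprobs = model.forward(va.graph_features or None, va.image_features)
        vloss = _balanced_log_loss(vprobs.data, va.labels)
        if vloss < best_loss - 1e-9:
            best_loss, best_state, stale = vloss, model.state_dict(), 0
        else:
            stale += 1
            if cfg.patience is not None and stale >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return model


def evaluate(prob_pos: np.ndarray, pred: np.ndarray, labels: np.ndarray) -> dict:
    """Table-style metric battery on one test fold.

    Accuracy/precision/recall/F1 on hard labels, AUC on the class-1
    probability. A single-class fold leaves AUC as NaN (excluded from
    aggregation downstream).
    """
    y = np.asarray(labels)
    out = {
        "accuracy": accuracy_score(y, pred),
        "precision": precision_score(y, pred, zero_division=0),
        "recall": recall_score(y, pred, zero_division=0),
        "f1": f1_score(y, pred, zero_division=0),
    }
    if len(np.unique(y)) < 2:
        logger.warning("single-class test fold: AUC undefined, reported as NaN")
        out["auc"] = np.nan
    else:
        out["auc"] = roc_auc_score(y, prob_pos)
    return {k: float(v) for k, v in out.items()}


def aggregate_ci(values: np.ndarray) -> dict:
    """Mean with normal-approximation 95% CI over fold x repeat values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return {"mean": float(v.mean()) if v.size else np.nan,
                "ci_low": np.nan, "ci_high": np.nan}
    half = 1.96 * v.std(ddof=1) / np.sqrt(v.size)
    return {"mean": float(v.mean()), "ci_low": float(v.mean() - half),
            "ci_high": float(v.mean() + half)}


def compare_configs(
    report_a: EvalReport, report_b: EvalReport, metric: str = "accuracy"
) -> float:
    """Paired two-sided p-value between configurations on fold metrics.

    Requires matched fold structure (same repeat/fold rows). Uses an
    exact sign-flip permutation test of the mean difference when there
    are at most 20 pairs, a paired t-test otherwise.
    """
    a = report_a.fold_metrics.set_index(["repeat", "fold"])[metric]
    b = report_b.fold_metrics.set_index(["repeat", "fold"])[metric]
    if not a.index.equals(b.index):
        raise ValueError("fold structures do not match; use the same splits/seeds")
    d = (a - b).dropna().to_numpy()
    if d.size < 2:
        raise ValueError("need >= 2 matched folds")
    if np.allclose(d, 0):
        return 1.0
    if d.size <= 20:
        obs = abs(d.mean())
        count = 0
        total = 2 ** d.size
        for signs in itertools.product((1.0, -1.0), repeat=d.size):
            if abs((d * signs).mean()) >= obs - 1e-15:
                count += 1
        return count / total
    t, p = stats.ttest_rel(a.loc[b.index], b)
    return float(p)


def cross_validate(
    graph_features: dict[str, np.ndarray],
    image_features: np.ndarray | None,
    labels: np.ndarray,
    adjacencies: dict[str, np.ndarray],
    label_str: str = "",
    model_cfg: FusionModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    smote_cfg: SmoteConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of one configuration.

    SMOTE is applied according to ``smote_cfg.leakage_mode``: within
    each training fold (default, leakage-safe) or once before splitting
    (``pre_split``, replicating a balance-then-split protocol that
    leaks synthetic copies of test samples and is labeled as such).
    """
    smote_cfg = smote_cfg or SmoteConfig()
    data = _Dataset(graph_features=dict(graph_features),
                    image_features=image_features, labels=np.asarray(labels, int))
    rows = []
    for rep in range(repeats):
        rep_seed = seed + 1000 * rep
        if smote_cfg.leakage_mode == "pre_split":
            x_all, y_all, _ = smote(data.flat(), data.labels,
                                    SmoteConfig(smote_cfg.k_neighbors, rep_seed))
            full = data.from_flat(x_all, y_all)
        else:
            full = data
        folds = kfold_split(full.labels, k, seed=rep_seed)
        for f in range(k):
            test = full.subset(folds == f)
            train = full.subset(folds != f)
            val = None
            if smote_cfg.leakage_mode == "fold_train_only":
                # checkpoint validation on real samples only, then balance
                # the remaining training samples with SMOTE
                vrng = np.random.default_rng(rep_seed + f)
                vmask = stratified_holdout(
                    train.labels, (train_cfg or TrainConfig()).val_fraction, vrng)
                val = train.subset(vmask)
                train = train.subset(~vmask)
                xt, yt, _ = smote(train.flat(), train.labels,
                                  SmoteConfig(smote_cfg.k_neighbors, rep_seed + f))
                train = train.from_flat(xt, yt)
            model = FusionModel(
                adjacencies,
                0 if image_features is None else image_features.shape[1],
                model_cfg, seed=rep_seed + f,
            )
            train_model(model, train, train_cfg, seed=rep_seed + f, val=val)
            probs = model.predict_proba(test.graph_features or None,
                                        test.image_features)
            m = evaluate(probs[:, 1], probs.argmax(axis=1), test.labels)
            rows.append({"repeat": rep, "fold": f, **m})
    return EvalReport(label=label_str, fold_metrics=pd.DataFrame(rows))
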