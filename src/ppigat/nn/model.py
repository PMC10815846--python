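"""Graph-attention fusion classifier for radiogenomic prediction.

Architecture: each PPI graph's per-sample scalar node features pass
through a stack of GNN blocks (GAT layer with multi-head attention
averaged over heads, ReLU, batch normalization, dropout — three blocks
by default, weights shared across graphs), node embeddings are
max-pooled into a graph-wise embedding, and the per-graph embeddings
(in sorted graph-id order) are concatenated with the output of an image
branch (fully connected layer, ReLU, batch normalization). A two-layer
fully connected head with a softmax produces the metastasis
probability. Either branch may be absent (genes-only / images-only
ablations).

The GAT attention follows the standard formulation: per head,
e_ij = LeakyReLU(a^T [W h_i || W h_j]) for j in the neighborhood of i
(self-loops included), alpha_ij = softmax_j(e_ij) masked to the
neighborhood, and h'_i = sum_j alpha_ij W h_j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat

logger = logging.getLogger(__name__)

__all__ = ["FusionModelConfig", "GatLayer", "GnnBlock", "BatchNorm", "ImageBranch",
           "FusionModel", "graph_readout", "Adam"]


@dataclass
class FusionModelConfig:
    n_blocks: int = 3
    gat_hidden: int = 8
    heads: int = 3
    leaky_slope: float = 0.2
    dropout: float = 0.3
    image_fc_dim: int = 32
    classifier_hidden: int = 64
    n_classes: int = 2

    def __post_init__(self) -> None:
        for name in ("n_blocks", "gat_hidden", "heads", "image_fc_dim",
                     "classifier_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _as3d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None, :, :], True
    return x, False


class GatLayer:
    """Multi-head graph attention; heads combined by averaging."""

    def __init__(self, d_in: int, d_out: int, heads: int, slope: float,
                 rng: np.random.Generator):
        self.heads = heads
        self.slope = slope
        self.w = [_glorot(rng, (d_in, d_out)) for _ in range(heads)]
        self.a_src = [_glorot(rng, (d_out, 1)) for _ in range(heads)]
        self.a_dst = [_glorot(rng, (d_out, 1)) for _ in range(heads)]

    def parameters(self) -> list[Tensor]:
        return [*self.w, *self.a_src, *self.a_dst]

    def __call__(self, h: Tensor | np.ndarray, adjacency: np.ndarray) -> Tensor:
        """h: (batch, n_nodes, d_in) or (n_nodes, d_in); returns same rank."""
        squeeze = False
        if not isinstance(h, Tensor):
            arr, squeeze = _as3d(h)
            h = Tensor(arr)
        elif h.data.ndim == 2:
            h = h.reshape(1, *h.data.shape)
            squeeze = True
        adj = np.asarray(adjacency) > 0
        if not adj.diagonal().all():
            raise ValueError("adjacency must include self-loops")
        outs = None
        for w, a_s, a_d in zip(self.w, self.a_src, self.a_dst):
            z = h @ w  # (b, n, d_out)
            u = z @ a_s  # (b, n, 1): attention source term per node
            v = z @ a_d
            e = (u + v.transpose(0, 2, 1)).leaky_relu(self.slope)  # e[i,j]
            alpha = e.masked_softmax(np.broadcast_to(adj, e.shape))
            head_out = alpha @ z
            outs = head_out if outs is None else outs + head_out
        out = outs * (1.0 / self.heads)
        return out.reshape(*out.data.shape[1:]) if squeeze else out


class BatchNorm:
    """Batch normalization over all leading axes (channels last)."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        n = int(np.prod([x.data.shape[a] for a in axes]))
        if training and n > 1:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            # normalize with batch statistics, but keep them on the tape
            m = x.mean(axis=0) if x.data.ndim == 2 else x.reshape(n, x.data.shape[-1]).mean(axis=0)
            xm = x - m
            v = (xm**2).mean(axis=axes[0]) if x.data.ndim == 2 else (
                (xm**2).reshape(n, x.data.shape[-1]).mean(axis=0)
            )
            xhat = xm * ((v + self.eps) ** -0.5)
        else:
            if training and n <= 1:
                logger.warning("batch of size 1: batch norm falls back to running stats")
            xhat = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class GnnBlock:
    """GAT -> ReLU -> batch norm -> dropout (dropout in training only)."""

    def __init__(self, d_in: int, d_out: int, cfg: FusionModelConfig,
                 rng: np.random.Generator):
        self.gat = GatLayer(d_in, d_out, cfg.heads, cfg.leaky_slope, rng)
        self.bn = BatchNorm(d_out)
        self.p_drop = cfg.dropout

    def parameters(self) -> list[Tensor]:
        return self.gat.parameters() + self.bn.parameters()

    def __call__(self, h, adjacency, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        out = self.gat(h, adjacency).relu()
        out = self.bn(out, training)
        if training and self.p_drop > 0:
            if rng is None:
                raise ValueError("training forward needs an rng for dropout")
            mask = (rng.random(out.data.shape) >= self.p_drop) / (1.0 - self.p_drop)
            out = out * mask
        return out


def graph_readout(node_embeddings: Tensor | np.ndarray) -> Tensor:
    """Coordinatewise max over the node axis (second-to-last)."""
    if not isinstance(node_embeddings, Tensor):
        node_embeddings = Tensor(np.asarray(node_embeddings, dtype=np.float64))
    if node_embeddings.data.shape[-2] < 1:
        raise ValueError("empty graph has no readout")
    return node_embeddings.max(axis=-2)


class ImageBranch:
    """FC -> ReLU -> batch norm transform of the radiomic feature vector."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _glorot(rng, (d_in, d_out))
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.bn = BatchNorm(d_out)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b] + self.bn.parameters()

    def __call__(self, x: Tensor | np.ndarray, training: bool) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        return self.bn((x @ self.w + self.b).relu(), training)


class FusionModel:
    """Per-graph GNN blocks + image branch + two-FC softmax classifier.

    ``adjacencies`` maps graph id -> dense adjacency (with self-loops);
    graph embeddings are concatenated in sorted graph-id order, fixed at
    construction. GNN block weights are shared across graphs. Pass
    ``n_image_features=0`` for the genes-only ablation or no graphs for
    the images-only ablation.
    """

    def __init__(self, adjacencies: dict[str, np.ndarray], n_image_features: int,
                 cfg: FusionModelConfig | None = None, seed: int = 0):
        if not adjacencies and n_image_features == 0:
            raise ValueError("model needs at least one graph or image features")
        self.cfg = cfg or FusionModelConfig()
        self.graph_order = sorted(adjacencies)
        self.adjacencies = {k: np.asarray(adjacencies[k], dtype=np.float64)
                            for k in self.graph_order}
        self.n_image_features = n_image_features
        rng = np.random.default_rng(seed)
        self.blocks: list[GnnBlock] = []
        if self.graph_order:
            d = 1
            for _ in range(self.cfg.n_blocks):
                self.blocks.append(GnnBlock(d, self.cfg.gat_hidden, self.cfg, rng))
                d = self.cfg.gat_hidden
        self.image_branch = (
            ImageBranch(n_image_features, self.cfg.image_fc_dim, rng)
            if n_image_features else None
        )
        d_cat = len(self.graph_order) * self.cfg.gat_hidden
        if self.image_branch is not None:
            d_cat += self.cfg.image_fc_dim
        self.w1 = _glorot(rng, (d_cat, self.cfg.classifier_hidden))
        self.b1 = Tensor(np.zeros(self.cfg.classifier_hidden), requires_grad=True)
        self.w2 = _glorot(rng, (self.cfg.classifier_hidden, self.cfg.n_classes))
        self.b2 = Tensor(np.zeros(self.cfg.n_classes), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for blk in self.blocks:
            params += blk.parameters()
        if self.image_branch is not None:
            params += self.image_branch.parameters()
        params += [self.w1, self.b1, self.w2, self.b2]
        return params

    def forward(
        self,
        graph_features: dict[str, np.ndarray] | None,
        image_features: np.ndarray | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Class probabilities, shape (n_samples, n_classes).

        ``graph_features[g]`` is (n_samples, n_nodes_g) scalar node
        features for graph g; ``image_features`` is (n_samples, d).
        """
        parts: list[Tensor] = []
        if self.graph_order:
            if graph_features is None:
                raise ValueError("model was built with graphs; features missing")
            for name in self.graph_order:
                h = np.asarray(graph_features[name], dtype=np.float64)[:, :, None]
                out: Tensor | np.ndarray = h
                for blk in self.blocks:
                    out = blk(out, self.adjacencies[name], training, rng)
                parts.append(graph_readout(out))
        if self.image_branch is not None:
            if image_features is None:
                raise ValueError("model was built with an image branch; features missing")
            parts.append(self.image_branch(image_features, training))
        z = concat(parts, axis=-1) if len(parts) > 1 else parts[0]
        hidden = (z @ self.w1 + self.b1).relu()
        logits = hidden @ self.w2 + self.b2
        return logits.masked_softmax(np.ones(logits.data.shape, dtype=bool))

    def predict_proba(self, graph_features, image_features) -> np.ndarray:
        return self.forward(graph_features, image_features, training=False).data

    def state_dict(self) -> dict:
        state = {f"param_{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        bns = [blk.bn for blk in self.blocks]
        if self.image_branch is not None:
            bns.append(self.image_branch.bn)
        for i, bn in enumerate(bns):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = state[f"param_{i}"].copy()
        bns = [blk.bn for blk in self.blocks]
        if self.image_branch is not None:
            bns.append(self.image_branch.bn)
        for i, bn in enumerate(bns):
            bn.running_mean = state[f"bn_{i}_mean"].copy()
            bn.running_var = state[f"bn_{i}_var"].copy()

    def save(self, path) -> None:
        """Checkpoint: config, graph order, adjacencies, and parameters."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        payload = {
            "config": asdict(self.cfg),
            "n_image_features": self.n_image_features,
            "adjacencies": {k: a.tolist() for k, a in self.adjacencies.items()},
            "state": {k: v.tolist() for k, v in self.state_dict().items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "FusionModel":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        model = cls(
            {k: np.asarray(a) for k, a in payload["adjacencies"].items()},
            payload["n_image_features"],
            FusionModelConfig(**payload["config"]),
        )
        model.load_state_dict(
            {k: np.asarray(v) for k, v in payload["state"].items()}
        )
        return model


def cross_entropy(probs: Tensor, labels: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean negative log-probability of the true class."""
    y = np.asarray(labels, dtype=int)
    onehot = np.zeros(probs.data.shape)
    onehot[np.arange(len(y)), y] = 1.0
    return -((probs + eps).log() * onehot).sum() * (1.0 / len(y))
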