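"""Attributed PPI graphs from STRING-style edge lists.

Reads `protein1 / protein2 / combined_score` TSV exports, thresholds on
combined_score (default 400, the STRING medium-confidence floor),
induces per-gene-set subgraphs, and attaches per-sample scalar node
features (gene-standardized expression). Self-loops are added to every
node so attention always has a non-empty neighborhood; gene sets whose
induced graph has no non-loop edge are flagged as "no PPI network
formed" and excluded from modeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["PpiGraph", "load_string_edges", "induce_subgraph", "attach_features",
           "build_graphs"]


@dataclass
class PpiGraph:
    """Undirected PPI subgraph over one gene set, with node features.

    ``adjacency`` is a dense 0/1 matrix including self-loops, rows and
    columns in ``nodes`` order. ``features`` (samples x nodes), when
    attached, holds the gene-standardized expression of each node.
    """

    name: str
    nodes: list[str]
    edges: list[tuple[str, str, int]]  # non-loop edges with combined_score
    flagged_no_network: bool
    features: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def adjacency(self) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.nodes)}
        a = np.eye(len(self.nodes))
        for u, v, _ in self.edges:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.nodes)
        for u, v, s in self.edges:
            g.add_edge(u, v, combined_score=s)
        return g

    def feature_matrix(self) -> np.ndarray:
        """(samples x nodes) feature array; raises if not attached."""
        if self.features is None:
            raise ValueError(f"graph {self.name!r} has no attached features")
        return self.features.to_numpy()

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "nodes": self.nodes,
                "edges": [[u, v, int(s)] for u, v, s in self.edges],
                "flagged_no_network": self.flagged_no_network,
            }
        )


def load_string_edges(path: str | Path, score_min: int = 400) -> pd.DataFrame:
    """Load a STRING-dialect edge TSV, filter and de-duplicate.

    Keeps edges with combined_score >= score_min, drops self-pairs, and
    de-duplicates treating (a, b) == (b, a) (first occurrence wins).
    Malformed rows raise with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = scores.isna() | df["protein1"].isna() | df["protein2"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}:{line}: malformed edge row")
    df = df.assign(combined_score=scores.astype(int))
    df = df[(df["combined_score"] >= score_min) & (df["protein1"] != df["protein2"])]
    key = df.apply(
        lambda r: tuple(sorted((r["protein1"], r["protein2"]))), axis=1
    ) if len(df) else pd.Series(dtype=object)
    df = df.loc[~key.duplicated()] if len(df) else df
    return df.reset_index(drop=True)


def induce_subgraph(edges: pd.DataFrame, gene_set: list[str], name: str = "") -> PpiGraph:
    """Induced subgraph on a gene set; isolated genes kept as singletons.

    Graphs with zero non-loop edges are flagged "no PPI network formed".
    Construction is invariant to edge-list row order and endpoint order.
    """
    if not gene_set:
        raise ValueError("gene_set is empty")
    nodes = sorted(set(gene_set))
    inset = set(nodes)
    sub: dict[tuple[str, str], int] = {}
    for u, v, s in edges[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if u in inset and v in inset and u != v:
            sub.setdefault(tuple(sorted((u, v))), int(s))
    edge_list = sorted((u, v, s) for (u, v), s in sub.items())
    return PpiGraph(
        name=name or ",".join(nodes[:3]),
        nodes=nodes,
        edges=edge_list,
        flagged_no_network=len(edge_list) == 0,
    )


def attach_features(graph: PpiGraph, expr: pd.DataFrame) -> PpiGraph:
    """Attach gene-standardized expression as scalar node features.

    Node feature for sample s at gene g is (x_gs - mean_g) / sd_g across
    samples. Constant genes make the z-score undefined and raise.
    """
    missing = [g for g in graph.nodes if g not in expr.index]
    if missing:
        raise ValueError(f"genes missing from expression: {missing[:10]}")
    sub = expr.loc[graph.nodes]
    sd = sub.std(axis=1, ddof=0)
    # tolerance absorbs rounding in the mean of an exactly-constant row
    sd = sd.where(sd > 1e-12 * sub.abs().mean(axis=1).clip(lower=1.0), 0.0)
    if (sd == 0).any():
        raise ValueError(
            f"constant genes (z-score undefined): {list(sub.index[sd == 0])[:10]}"
        )
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    graph.features = z.T  # samples x nodes
    return graph


def build_graphs(
    edges: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    expr: pd.DataFrame | None = None,
) -> tuple[dict[str, PpiGraph], list[str]]:
    """Induce one graph per gene set; returns (usable graphs, flagged names).

    Usable graphs (at least one non-loop edge) get features attached
    when an expression matrix is supplied; keys are sorted for a stable
    downstream concatenation order.
    """
    usable: dict[str, PpiGraph] = {}
    flagged: list[str] = []
    for name in sorted(gene_sets):
        g = induce_subgraph(edges, gene_sets[name], name=name)
        if g.flagged_no_network:
            flagged.append(name)
            continue
        if expr is not None:
            attach_features(g, expr)
        usable[name] = g
    return usable, flagged
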