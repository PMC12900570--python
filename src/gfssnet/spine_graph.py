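"""Anatomical lumbar-spine graph and its convolutional enhancement module.

The graph has 10 nodes — background (0), vertebrae L1..L5 (1..5) and the
four interleaved discs L1/L2..L4/L5 (6..9) — with an edge wherever a
vertebra touches a neighbouring disc.  Bottleneck features are pooled and
projected to per-node embeddings, propagated through a three-layer GCN
over the symmetric-normalised adjacency, and scattered back onto the
feature map through a voxel-to-node soft assignment with a residual
connection (so the module is exactly the identity at zero weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .nn import (Conv3d, Module, Parameter, Tensor, as_tensor,
                 global_avg_pool3d)
from .nn.modules import glorot_uniform

__all__ = [
    "NODE_LABELS", "SpineGraph", "build_spine_graph", "normalize_adjacency",
    "features_to_graph", "gcn_forward", "graph_to_features", "GraphModule",
]

NODE_LABELS = ("background", "L1", "L2", "L3", "L4", "L5",
               "disc_L1_L2", "disc_L2_L3", "disc_L3_L4", "disc_L4_L5")

N_NODES = 10


def _anatomical_edges() -> list[tuple[int, int]]:
    """Each vertebra i (1..5) touches disc above (5 + i - 1, if any) and
    disc below (5 + i, if any)."""
    edges = []
    for v in range(1, 6):
        above = 5 + v - 1   # disc between v-1 and v
        below = 5 + v       # disc between v and v+1
        if above >= 6:
            edges.append((v, above))
        if below <= 9:
            edges.append((v, below))
    return sorted(set(tuple(sorted(e)) for e in edges))


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} with D the degree matrix of A + I."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    At = A + np.eye(A.shape[0])
    deg = At.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return d_inv_sqrt[:, None] * At * d_inv_sqrt[None, :]


@dataclass
class SpineGraph:
    A: np.ndarray
    A_norm: np.ndarray
    D: np.ndarray
    node_labels: tuple[str, ...] = NODE_LABELS

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.A))))
        return g


def build_spine_graph() -> SpineGraph:
    g = nx.Graph()
    g.add_nodes_from(range(N_NODES))
    g.add_edges_from(_anatomical_edges())
    A = nx.adjacency_matrix(g, nodelist=range(N_NODES)).toarray().astype(np.float64)
    At = A + np.eye(N_NODES)
    D = np.diag(At.sum(axis=1))
    return SpineGraph(A=A, A_norm=normalize_adjacency(A), D=D)


def features_to_graph(F, w_f2g, s_logits) -> tuple[Tensor, Tensor]:
    """Pool F globally, project to (B, n_nodes, H_dim) node embeddings, and
    build the voxel-to-node soft assignment S from per-voxel logits.

    ``w_f2g``: (C, n_nodes * H_dim) projection; ``s_logits``: (B, n_nodes,
    D, H, W).  Rows of S (over nodes, per voxel) sum to one.
    """
    F, w_f2g, s_logits = as_tensor(F), as_tensor(w_f2g), as_tensor(s_logits)
    B, C = F.shape[0], F.shape[1]
    h_dim = w_f2g.shape[1] // N_NODES
    pooled = global_avg_pool3d(F)               # (B, C)
    G = (pooled @ w_f2g).reshape(B, N_NODES, h_dim)
    S = s_logits.softmax(axis=1)                # (B, n_nodes, D, H, W)
    return G, S


def gcn_forward(G0, A_norm, weights) -> Tensor:
    """Three rounds of G <- ReLU(A_norm @ G @ W)."""
    if len(weights) != 3:
        raise ValueError(f"expected 3 GCN weight matrices, got {len(weights)}")
    G = as_tensor(G0)
    A = as_tensor(A_norm)
    for W in weights:
        G = (A @ G @ as_tensor(W)).relu()
    return G


def graph_to_features(G, S, F, w_g2f) -> Tensor:
    """Scatter node embeddings back per voxel through S and add residually:
    out[b, :, v] = F[b, :, v] + sum_n S[b, n, v] * (G[b, n] @ w_g2f)."""
    G, S, F, w_g2f = as_tensor(G), as_tensor(S), as_tensor(F), as_tensor(w_g2f)
    if S.shape[0] != F.shape[0] or S.shape[2:] != F.shape[2:]:
        raise ValueError(f"assignment/feature shape mismatch: "
                         f"{S.shape} vs {F.shape}")
    proj = G @ w_g2f                            # (B, n_nodes, C)
    B, n_nodes, C = proj.shape
    spatial = S.shape[2:]
    S_flat = S.reshape(B, n_nodes, -1)          # (B, n, V)
    add = proj.transpose((0, 2, 1)) @ S_flat    # (B, C, V)
    return F + add.reshape((B, C) + tuple(spatial))


class GraphModule(Module):
    """Bottleneck graph enhancement: project -> 3-layer GCN -> scatter back."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 h_dim: int = 128):
        self.spine = build_spine_graph()
        self.h_dim = h_dim
        self.w_f2g = Parameter(glorot_uniform(
            rng, (channels, N_NODES * h_dim), channels, N_NODES * h_dim))
        self.assign = Conv3d(channels, N_NODES, 1, rng)
        self.gcn_weights = [
            Parameter(glorot_uniform(rng, (h_dim, h_dim), h_dim, h_dim))
            for _ in range(3)]
        self.w_g2f = Parameter(glorot_uniform(
            rng, (h_dim, channels), h_dim, channels))

    def node_embeddings(self, F) -> tuple[Tensor, Tensor]:
        return features_to_graph(F, self.w_f2g, self.assign(as_tensor(F)))

    def forward(self, F) -> Tensor:
        F = as_tensor(F)
        G0, S = self.node_embeddings(F)
        G = gcn_forward(G0, self.spine.A_norm.astype(np.float32),
                        self.gcn_weights)
        return graph_to_features(G, S, F, self.w_g2f)
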