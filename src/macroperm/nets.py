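"""Message-passing encoder and attention primitives.

The encoder follows the bond-message formulation: a message for each directed
bond is produced from the bond feature concatenated with both endpoint node
features, messages are sum-aggregated over each node's neighbours, and bond
and node states are updated by small MLPs; after T rounds the node states are
pooled into a graph embedding.  A ``test_mode_identity`` flag replaces every
MLP by the identity on its concatenated input, which makes a single round
hand-traceable and lets tests compare against a dictionary-based brute-force
oracle exactly.

A ``directed_exclusion`` flag switches to the canonical directed variant in
which the update for bond (u, v) excludes the reverse message m_vu from the
aggregated neighbourhood sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    Parameter,
    Tensor,
    concat,
    gather_rows,
    segment_mean,
    segment_sum,
)
from .featurize import MolGraph

__all__ = [
    "MPConfig",
    "AttentionConfig",
    "MLP",
    "BatchedGraph",
    "DMPNNEncoder",
    "message_passing_round",
    "readout",
    "dmpnn_encode",
    "multi_head_attention",
    "glorot",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class MPConfig:
    rounds: int = 2
    hidden_dim: int = 32
    n_mlp_layers: int = 1          # layers per message/update MLP
    readout: str = "MEAN"          # MEAN or SUM
    test_mode_identity: bool = False
    directed_exclusion: bool = False

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.readout not in ("MEAN", "SUM"):
            raise ValueError(f"readout must be MEAN or SUM, got {self.readout!r}")


@dataclass
class AttentionConfig:
    n_heads: int = 1
    d_k: int = 8

    def __post_init__(self) -> None:
        if self.n_heads < 1 or self.d_k < 1:
            raise ValueError("n_heads and d_k must be >= 1")


class MLP:
    """Dense ReLU stack; in identity test mode it returns its input unchanged."""

    def __init__(
        self,
        rng: np.random.Generator | None,
        dims: list[int],
        identity: bool = False,
    ) -> None:
        self.identity = identity
        self.weights: list[Parameter] = []
        self.biases: list[Parameter] = []
        if not identity:
            assert rng is not None
            for a, b in zip(dims[:-1], dims[1:]):
                self.weights.append(Parameter(glorot(rng, a, b)))
                self.biases.append(Parameter(np.zeros(b)))

    def __call__(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w + b
            if i < len(self.weights) - 1:
                x = x.relu()
        return x

    def parameters(self) -> list[Parameter]:
        return [*self.weights, *self.biases]


class BatchedGraph:
    """Disjoint union of molecular graphs for vectorised message passing."""

    def __init__(self, graphs: list[MolGraph]):
        if not graphs:
            raise ValueError("empty batch")
        node_feats, edge_feats, edge_index, graph_ids = [], [], [], []
        offset = 0
        for gid, g in enumerate(graphs):
            node_feats.append(g.node_features)
            graph_ids.append(np.full(g.n_nodes, gid, dtype=np.int64))
            if g.edge_index.shape[0]:
                edge_index.append(g.edge_index + offset)
                edge_feats.append(g.edge_features)
            offset += g.n_nodes
        self.node_features = np.concatenate(node_feats, axis=0)
        self.graph_ids = np.concatenate(graph_ids)
        self.n_nodes = offset
        self.n_graphs = len(graphs)
        if edge_index:
            self.edge_index = np.concatenate(edge_index, axis=0)
            self.edge_features = np.concatenate(edge_feats, axis=0)
        else:
            self.edge_index = np.zeros((0, 2), dtype=np.int64)
            self.edge_features = np.zeros((0, graphs[0].edge_features.shape[1]))
        # bonds are stored as adjacent (u,v),(v,u) pairs -> reverse = index ^ 1
        self.reverse_index = np.arange(self.edge_index.shape[0]) ^ 1


def message_passing_round(
    x: Tensor,
    e: Tensor,
    edge_index: np.ndarray,
    n_nodes: int,
    msg_mlp: MLP,
    edge_mlp: MLP,
    node_mlp: MLP,
    reverse_index: np.ndarray | None = None,
    directed_exclusion: bool = False,
) -> tuple[Tensor, Tensor]:
    """One round: m_uv = MLP(e_uv + x_u + x_v concatenated); m_v = sum over
    incoming messages; then bond and node updates.  Returns (x', e')."""
    if edge_index.shape[0] == 0:
        # isolated nodes: zero aggregated message
        zero = Tensor(np.zeros((n_nodes, e.data.shape[1] + 2 * x.data.shape[1])))
        zero_msg = msg_mlp(zero) if not msg_mlp.identity else zero
        x_new = node_mlp(concat([x, zero_msg * 0.0], axis=1))
        return x_new, e
    src = edge_index[:, 0]
    dst = edge_index[:, 1]
    m_uv = msg_mlp(concat([e, gather_rows(x, src), gather_rows(x, dst)], axis=1))
    m_v = segment_sum(m_uv, dst, n_nodes)
    if directed_exclusion:
        assert reverse_index is not None
        # bond (u,v) sees messages into u minus its own reverse m_vu
        agg_for_edge = gather_rows(m_v, src) - gather_rows(m_uv, reverse_index)
        e_new = edge_mlp(concat([e, agg_for_edge], axis=1))
    else:
        e_new = edge_mlp(concat([e, m_uv], axis=1))
    x_new = node_mlp(concat([x, m_v], axis=1))
    return x_new, e_new


def readout(x: Tensor, graph_ids: np.ndarray, n_graphs: int, mode: str = "MEAN") -> Tensor:
    """Pool node states into per-graph embeddings (permutation invariant)."""
    if x.data.shape[0] == 0:
        raise ValueError("cannot read out an empty graph")
    if mode == "MEAN":
        return segment_mean(x, graph_ids, n_graphs)
    if mode == "SUM":
        return segment_sum(x, graph_ids, n_graphs)
    raise ValueError(f"unknown readout mode {mode!r}")


class DMPNNEncoder:
    """Input projections + T shared message-passing rounds + pooled readout."""

    def __init__(
        self,
        rng: np.random.Generator,
        d_node: int,
        d_edge: int,
        config: MPConfig,
    ) -> None:
        self.config = config
        h = config.hidden_dim
        ident = config.test_mode_identity
        self.node_in = MLP(rng, [d_node, h], identity=ident)
        self.edge_in = MLP(rng, [d_edge, h], identity=ident)
        if ident:
            self.msg_mlp = MLP(None, [], identity=True)
            self.edge_mlp = MLP(None, [], identity=True)
            self.node_mlp = MLP(None, [], identity=True)
        else:
            dims = [h] * (config.n_mlp_layers - 1)
            self.msg_mlp = MLP(rng, [3 * h, *dims, h])
            self.edge_mlp = MLP(rng, [2 * h, *dims, h])
            self.node_mlp = MLP(rng, [2 * h, *dims, h])

    def parameters(self) -> list[Parameter]:
        out = []
        for m in (self.node_in, self.edge_in, self.msg_mlp, self.edge_mlp, self.node_mlp):
            out.extend(m.parameters())
        return out

    def node_states(self, batch: BatchedGraph) -> Tensor:
        x = self.node_in(Tensor(batch.node_features))
        e = self.edge_in(Tensor(batch.edge_features))
        for _ in range(self.config.rounds):
            x, e = message_passing_round(
                x,
                e,
                batch.edge_index,
                batch.n_nodes,
                self.msg_mlp,
                self.edge_mlp,
                self.node_mlp,
                reverse_index=batch.reverse_index,
                directed_exclusion=self.config.directed_exclusion,
            )
        return x

    def __call__(self, batch: BatchedGraph) -> Tensor:
        x = self.node_states(batch)
        return readout(x, batch.graph_ids, batch.n_graphs, self.config.readout)


def dmpnn_encode(graph: MolGraph, encoder: DMPNNEncoder) -> np.ndarray:
    """Embedding of a single molecule (convenience wrapper over the batch path)."""
    return encoder(BatchedGraph([graph])).data[0]


def multi_head_attention(
    Q: Tensor,
    K: Tensor,
    V: Tensor,
    config: AttentionConfig,
    w_out: Parameter | None = None,
) -> Tensor:
    """Scaled dot-product attention, multi-head over the last dimension.

    Q is (n_q, h*d_k); K, V are (n_kv, h*d_k).  Per head the output is
    softmax(Q K^T / sqrt(d_k)) V; heads are concatenated and optionally
    projected by ``w_out``.  Every softmax row sums to 1.
    """
    h, dk = config.n_heads, config.d_k
    if Q.data.shape[1] != h * dk or K.data.shape[1] != h * dk or V.data.shape[1] != h * dk:
        raise ValueError(
            f"Q/K/V last dim must equal n_heads*d_k = {h * dk}; "
            f"got {Q.data.shape[1]}, {K.data.shape[1]}, {V.data.shape[1]}"
        )
    heads = []
    scale = 1.0 / np.sqrt(dk)
    for i in range(h):
        q = Q.slice_cols(i * dk, (i + 1) * dk)
        k = K.slice_cols(i * dk, (i + 1) * dk)
        v = V.slice_cols(i * dk, (i + 1) * dk)
        weights = (q @ k.T * scale).softmax(axis=-1)
        heads.append(weights @ v)
    out = concat(heads, axis=1) if len(heads) > 1 else heads[0]
    if w_out is not None:
        out = out @ w_out
    return out


class SelfAttentionBlock:
    """Learned Q/K/V projections + multi-head attention over a node set."""

    def __init__(self, rng: np.random.Generator, d_model: int, config: AttentionConfig):
        self.config = config
        d_inner = config.n_heads * config.d_k
        self.wq = Parameter(glorot(rng, d_model, d_inner))
        self.wk = Parameter(glorot(rng, d_model, d_inner))
        self.wv = Parameter(glorot(rng, d_model, d_inner))
        self.wo = Parameter(glorot(rng, d_inner, d_model))

    def parameters(self) -> list[Parameter]:
        return [self.wq, self.wk, self.wv, self.wo]

    def __call__(self, x: Tensor) -> Tensor:
        return multi_head_attention(
            x @ self.wq, x @ self.wk, x @ self.wv, self.config, w_out=self.wo
        )
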