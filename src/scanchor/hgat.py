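"""Hierarchical graph attention over the shared anchor graph.

Cells are the nodes; the columns of the shared anchor graph Z_s (each an
m-dimensional anchor-affinity profile) are the node features.  A stack of
masked multi-head attention layers propagates information along a kNN graph
built on those profiles, producing the high-order shared representation
Z_s' used downstream to complete the specific representations.

Attention parameters are drawn once from the run seed and kept fixed: the
layers act as a deterministic high-order propagation operator rather than a
trained network, which keeps the representation reproducible and free of an
extra training objective.  Joint training against the shared reconstruction
objective can be enabled for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .anchors import build_knn_adjacency


def _leaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, x, np.expm1(np.clip(x, None, 0.0)))


@dataclass
class AttentionState:
    """Parameters and per-layer outputs of the hierarchical attention stack.

    ``layer_weights[l][q]`` is the shared weight matrix W of head q at layer l
    (F_in x F_out); ``attn_vectors[l][q]`` the corresponding attention vector
    a of length 2*F_out.  ``graph`` is the cell-cell adjacency (with
    self-loops) defining the neighborhoods.
    """

    layer_weights: list[list[np.ndarray]]
    attn_vectors: list[list[np.ndarray]]
    graph: sparse.csr_matrix
    heads: int
    outputs: list[np.ndarray] = field(default_factory=list)


def attention_coefficients(
    Hprev: np.ndarray,
    Wk: np.ndarray,
    a: np.ndarray,
    graph: sparse.spmatrix,
) -> sparse.csr_matrix:
    """Masked attention coefficients for one head on one layer.

    For every edge (i, j) of ``graph`` the logit is
    LeakyReLU(a^T [W h_i || W h_j]) (negative slope 0.2) and coefficients are
    softmax-normalized over each node's neighborhood, so every row of the
    returned sparse matrix sums to 1 on its support.
    """
    graph = sparse.csr_matrix(graph)
    n = graph.shape[0]
    WH = np.asarray(Hprev, dtype=float) @ Wk  # n x F'
    Fp = WH.shape[1]
    a = np.asarray(a, dtype=float)
    if a.shape[0] != 2 * Fp:
        raise ValueError("attention vector length must be twice the output width")
    src_score = WH @ a[:Fp]
    dst_score = WH @ a[Fp:]
    coo = graph.tocoo()
    logits = _leaky_relu(src_score[coo.row] + dst_score[coo.col])
    # per-row softmax with max-shift for stability
    att = sparse.csr_matrix((logits, (coo.row, coo.col)), shape=(n, n))
    for i in range(n):
        lo, hi = att.indptr[i], att.indptr[i + 1]
        if hi > lo:
            e = np.exp(att.data[lo:hi] - att.data[lo:hi].max())
            att.data[lo:hi] = e / e.sum()
    return att


def gat_layer(
    Hprev: np.ndarray,
    layer_weights: list[np.ndarray],
    attn_vectors: list[np.ndarray],
    graph: sparse.spmatrix,
    final: bool = False,
) -> np.ndarray:
    """One multi-head attention layer: aggregate per head, average, activate.

    Heads are combined by averaging; the activation (ELU on hidden layers,
    identity on the final layer) is applied after the head average.
    """
    heads = len(layer_weights)
    acc = None
    for Wk, a in zip(layer_weights, attn_vectors):
        att = attention_coefficients(Hprev, Wk, a, graph)
        agg = att @ (Hprev @ Wk)
        acc = agg if acc is None else acc + agg
    out = acc / heads
    if not final:
        out = _elu(out)
    return out


def init_attention_state(
    graph: sparse.spmatrix,
    dim: int,
    layers: int,
    heads: int,
    seed: int,
    weight_noise: float = 0.1,
) -> AttentionState:
    """Seeded attention parameters; every layer maps dim -> dim.

    Shared weight matrices are identity plus scaled Glorot noise: the
    downstream Hadamard completion multiplies Z_s' entrywise with the
    specific anchor graphs, which is only meaningful if propagation keeps
    each feature dimension aligned with its anchor, so the linear maps must
    stay close to the identity.  Attention vectors are plain Glorot draws.
    """
    rng = np.random.default_rng(seed)
    limit_w = np.sqrt(6.0 / (2 * dim))
    layer_weights, attn_vectors = [], []
    for _ in range(layers):
        layer_weights.append(
            [
                np.eye(dim)
                + weight_noise * rng.uniform(-limit_w, limit_w, size=(dim, dim))
                for _ in range(heads)
            ]
        )
        attn_vectors.append(
            [rng.uniform(-limit_w, limit_w, size=2 * dim) for _ in range(heads)]
        )
    return AttentionState(
        layer_weights=layer_weights,
        attn_vectors=attn_vectors,
        graph=sparse.csr_matrix(graph),
        heads=heads,
    )


def run_hgat(
    Zs: np.ndarray,
    layers: int = 2,
    heads: int = 3,
    knn_k: int = 15,
    seed: int = 0,
    state: AttentionState | None = None,
) -> np.ndarray:
    """High-order shared representation Z_s' from stacked attention layers.

    The n cells are the nodes with the columns of ``Zs`` (m x n) as input
    features; the graph is the cosine kNN graph on those features with
    self-loops injected so no neighborhood is empty.  Returns an m x n matrix
    aligned with ``Zs``.
    """
    Zs = np.asarray(Zs, dtype=float)
    m, n = Zs.shape
    H = Zs.T  # cells as rows
    if state is None:
        A = build_knn_adjacency(H, min(knn_k, n - 1))
        A = sparse.csr_matrix(A + sparse.eye(n))
        A.data[:] = 1.0
        state = init_attention_state(A, m, layers, heads, seed)
    state.outputs = []
    out = H
    for li in range(len(state.layer_weights)):
        out = gat_layer(
            out,
            state.layer_weights[li],
            state.attn_vectors[li],
            state.graph,
            final=(li == len(state.layer_weights) - 1),
        )
        state.outputs.append(out)
    return out.T
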