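"""Attention-modulated graph message passing over gland states.

Each layer transforms node features with a shared weight matrix, weights
incoming messages by softmax attention coefficients computed from the
transformed features of the two endpoints, adds the node's own transformed
state, applies a pointwise nonlinearity, and finally renormalizes every
node feature to the unit L2 sphere so repeated rounds of message passing
cannot amplify hormone representations without bound.

Self-loops guarantee every gland attends to itself; by default they are
added to the adjacency *before* attention is computed, so the self
coefficient participates in the softmax. The alternative order (attention
on the raw adjacency, identity added afterwards) is available via
``GraphAttentionParams.self_loops = "after"``.

All operations accept either plain numpy arrays or autodiff
:class:`~endoloop.autodiff.Tensor` values (leading batch dimensions are
supported); numpy in, numpy out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["GraphAttentionParams", "AdjacencyStructure", "IsolatedNodeError",
           "attention_coefficients", "gnn_layer", "normalize_states",
           "gnn_forward", "init_graph_params"]


class IsolatedNodeError(ValueError):
    """A node has no neighbors and no self-loop: its attention row is empty."""


@dataclass
class AdjacencyStructure:
    """Base adjacency A (A[i, j] != 0 iff gland j influences gland i)."""

    base: np.ndarray

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=float)
        if self.base.ndim != 2 or self.base.shape[0] != self.base.shape[1]:
            raise ValueError("adjacency must be square")

    @property
    def n_nodes(self) -> int:
        return self.base.shape[0]

    @property
    def with_self_loops(self) -> np.ndarray:
        return np.eye(self.n_nodes) + self.base


@dataclass
class GraphAttentionParams:
    """Per-layer weight matrices W^(l), attention vectors a^(l), and the
    activation configuration shared by all layers."""

    layer_weights: list[np.ndarray]
    attention_vectors: list[np.ndarray]
    leaky_slope: float = 0.2
    activation: str = "relu"          # sigma in {relu, tanh}
    self_loops: str = "before"        # self-loop order: {before, after} attention

    def __post_init__(self):
        self.layer_weights = [np.asarray(w, dtype=float) for w in self.layer_weights]
        self.attention_vectors = [np.asarray(a, dtype=float) for a in self.attention_vectors]
        if len(self.layer_weights) < 1:
            raise ValueError("need at least one layer")
        if len(self.attention_vectors) != len(self.layer_weights):
            raise ValueError("one attention vector per layer required")
        for l, (w, a) in enumerate(zip(self.layer_weights, self.attention_vectors)):
            if a.shape != (2 * w.shape[1],):
                raise ValueError(f"layer {l}: attention vector must have length "
                                 f"{2 * w.shape[1]}, got {a.shape}")
            if l + 1 < len(self.layer_weights) and \
                    self.layer_weights[l + 1].shape[0] != w.shape[1]:
                raise ValueError(f"layer {l}->{l + 1}: dimension chain broken")
        if not 0 < self.leaky_slope < 1:
            raise ValueError("leaky_slope must lie in (0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")
        if self.self_loops not in ("before", "after"):
            raise ValueError("self_loops must be 'before' or 'after'")

    @property
    def n_layers(self) -> int:
        return len(self.layer_weights)


def init_graph_params(dims: list[int], seed: int = 42, leaky_slope: float = 0.2,
                      activation: str = "relu") -> GraphAttentionParams:
    """Xavier-uniform initialization for a chain of feature widths `dims`."""
    rng = np.random.default_rng(seed)
    weights, avecs = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
        ab = np.sqrt(6.0 / (2 * d_out + 1))
        avecs.append(rng.uniform(-ab, ab, size=2 * d_out))
    return GraphAttentionParams(weights, avecs, leaky_slope, activation)


def _apply_sigma(x: Tensor, activation: str) -> Tensor:
    return ad.relu(x) if activation == "relu" else ad.tanh(x)


def _attention_tensor(states: Tensor, adjacency: AdjacencyStructure,
                      params: GraphAttentionParams, layer: int,
                      W: Tensor | None = None, a: Tensor | None = None) -> Tensor:
    """Masked-softmax attention matrix (..., N, N) for one layer."""
    n = adjacency.n_nodes
    if states.shape[-2] != n:
        raise ValueError(f"expected {n} node rows, got {states.shape}")
    W = ad.as_tensor(params.layer_weights[layer]) if W is None else W
    a = ad.as_tensor(params.attention_vectors[layer]) if a is None else a
    if states.shape[-1] != W.shape[0]:
        raise ValueError(f"layer {layer}: states width {states.shape[-1]} "
                         f"!= weight input {W.shape[0]}")

    mask = (adjacency.with_self_loops if params.self_loops == "before"
            else adjacency.base) != 0
    empty = ~mask.any(axis=1)
    if empty.any():
        raise IsolatedNodeError(
            f"nodes {np.flatnonzero(empty).tolist()} have empty attention "
            "neighborhoods (no neighbors, no self-loop)")

    d_out = W.shape[1]
    wh = states @ W                                        # (..., N, d_out)
    s_dst = wh @ a[:d_out]                                 # (..., N)
    s_src = wh @ a[d_out:]                                 # (..., N)
    nd = len(s_dst.shape)
    logits = ad.leaky_relu(
        s_dst.reshape(*s_dst.shape, 1) + s_src.reshape(*s_src.shape[:-1], 1, n),
        params.leaky_slope)
    # numerically stable masked softmax; the shift is a detached constant
    maskf = mask.astype(float)
    shifted = logits - np.max(np.where(mask, logits.value, -np.inf),
                              axis=-1, keepdims=True)
    # zero masked entries *before* exp so off-neighborhood logits cannot overflow
    weights = ad.exp(shifted * maskf) * maskf
    alpha = weights / weights.sum(axis=-1, keepdims=True)
    if params.self_loops == "after":
        alpha = alpha + np.eye(n)
    return alpha


def _layer_tensor(states: Tensor, adjacency: AdjacencyStructure,
                  params: GraphAttentionParams, layer: int,
                  W: Tensor | None = None, a: Tensor | None = None) -> Tensor:
    W = ad.as_tensor(params.layer_weights[layer]) if W is None else W
    alpha = _attention_tensor(states, adjacency, params, layer, W, a)
    wh = states @ W
    return _apply_sigma(wh + alpha @ wh, params.activation)


def _normalize_tensor(states: Tensor) -> Tensor:
    norm_sq = (states * states).sum(axis=-1, keepdims=True)
    zero = (norm_sq.value == 0).astype(float)   # leave zero rows untouched
    return states / ((norm_sq + zero) ** 0.5)


def _dispatch(fn, states, *args, **kwargs):
    if isinstance(states, Tensor):
        return fn(states, *args, **kwargs)
    out = fn(ad.as_tensor(np.asarray(states, dtype=float)), *args, **kwargs)
    return out.value


def attention_coefficients(node_states, adjacency: AdjacencyStructure,
                           params: GraphAttentionParams, layer: int = 0):
    """Softmax attention over each node's neighborhood (self-loops included
    by default). Row i is supported on N(i) and sums to one."""
    return _dispatch(_attention_tensor, node_states, adjacency, params, layer)


def gnn_layer(node_states, adjacency: AdjacencyStructure,
              params: GraphAttentionParams, layer: int = 0):
    """One message-passing round: sigma(W h_i + sum_j alpha_ij W h_j)."""
    return _dispatch(_layer_tensor, node_states, adjacency, params, layer)


def normalize_states(node_states):
    """Project every nonzero feature row onto the unit L2 sphere."""
    return _dispatch(_normalize_tensor, node_states)


def gnn_forward(initial_states, adjacency: AdjacencyStructure,
                params: GraphAttentionParams):
    """L rounds of (attention layer -> row normalization)."""
    def run(states):
        for l in range(params.n_layers):
            states = _layer_tensor(states, adjacency, params, l)
            states = _normalize_tensor(states)
        return states
    return _dispatch(run, initial_states)
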