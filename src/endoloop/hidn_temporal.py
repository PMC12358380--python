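"""Recurrent hormone-trajectory forecasting on top of the graph stage.

Per time step the model (i) lifts each gland's scalar concentration into a
feature vector, (ii) runs attention-modulated graph message passing so each
gland's representation reflects its regulators, (iii) encodes the external
stimulus vector with a two-layer perceptron, (iv) advances one LSTM cell
per gland (weights shared across glands) on the concatenation
[graph feature || encoded stimulus], and (v) maps the stacked hidden states
through an affine readout to the predicted concentrations at the next step.

Training is teacher-forced one-step-ahead regression under the mean squared
error, with Adam, Xavier initialization, a x0.85 learning-rate decay every
10 epochs, early stopping on validation loss (patience 15), dropout on the
graph-stage outputs, and a fixed seed — the stack of defaults in
:class:`TrainingConfig`.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .endocrine_sim import InterventionSchedule, Trajectory, evaluate_intervention
from .hidn_graph import (AdjacencyStructure, GraphAttentionParams,
                         _layer_tensor, _normalize_tensor)

__all__ = ["RecurrentParams", "StimulusEncoderParams", "ReadoutParams",
           "LiftParams", "HIDNModel", "TrainingConfig", "lstm_step",
           "encode_stimulus", "forward_step", "mse_loss", "train", "rollout",
           "save_bundle", "load_bundle", "TrainingDivergence"]


class TrainingDivergence(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


# -- parameter containers ----------------------------------------------------

@dataclass
class RecurrentParams:
    """Shared-gate LSTM weights: forget/input/output gates and cell candidate."""

    W_f: np.ndarray; W_i: np.ndarray; W_o: np.ndarray; W_c: np.ndarray
    U_f: np.ndarray; U_i: np.ndarray; U_o: np.ndarray; U_c: np.ndarray
    b_f: np.ndarray; b_i: np.ndarray; b_o: np.ndarray; b_c: np.ndarray

    def __post_init__(self):
        for name in ("W_f", "W_i", "W_o", "W_c", "U_f", "U_i", "U_o", "U_c",
                     "b_f", "b_i", "b_o", "b_c"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d_in, d_h = self.W_f.shape
        for w in (self.W_i, self.W_o, self.W_c):
            if w.shape != (d_in, d_h):
                raise ValueError("input->hidden gate matrices disagree in shape")
        for u in (self.U_f, self.U_i, self.U_o, self.U_c):
            if u.shape != (d_h, d_h):
                raise ValueError("hidden->hidden gate matrices must be d_h x d_h")
        for b in (self.b_f, self.b_i, self.b_o, self.b_c):
            if b.shape != (d_h,):
                raise ValueError("gate biases must have length d_h")

    @property
    def d_hidden(self) -> int:
        return self.W_f.shape[1]

    @property
    def d_input(self) -> int:
        return self.W_f.shape[0]


@dataclass
class StimulusEncoderParams:
    """Two-layer perceptron psi: u' = sigma(W2 sigma(W1 u + b1) + b2)."""

    W1: np.ndarray; b1: np.ndarray; W2: np.ndarray; b2: np.ndarray
    activation: str = "relu"

    def __post_init__(self):
        for name in ("W1", "b1", "W2", "b2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.W1.shape[1] != self.b1.shape[0] or self.W2.shape[1] != self.b2.shape[0]:
            raise ValueError("encoder bias widths disagree with weights")
        if self.W1.shape[1] != self.W2.shape[0]:
            raise ValueError("encoder layer widths disagree")

    @property
    def d_out(self) -> int:
        return self.W2.shape[1]


@dataclass
class ReadoutParams:
    """Affine map from the stacked hidden states S(t) to h_hat(t+1)."""

    W3: np.ndarray
    b3: np.ndarray

    def __post_init__(self):
        self.W3 = np.asarray(self.W3, dtype=float)
        self.b3 = np.asarray(self.b3, dtype=float)
        if self.W3.shape[1] != self.b3.shape[0]:
            raise ValueError("readout bias width disagrees with W3")


@dataclass
class LiftParams:
    """Linear embedding of the scalar concentration into feature space."""

    weight: np.ndarray   # (1, d_embed)
    bias: np.ndarray     # (d_embed,)

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weight.shape != (1, self.bias.shape[0]):
            raise ValueError("lift weight must be 1 x d_embed")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.0005
    lr_decay: float = 0.85
    lr_decay_every: int = 10
    max_epochs: int = 150
    early_stop_patience: int = 15
    batch_size: int = 32
    dropout: float = 0.4
    seed: int = 42
    split: tuple[int, int, int] = (70, 15, 15)
    window: int = 8           # points per training window sliced from trajectories
    stride: int = 1
    clip_norm: float = 5.0

    def __post_init__(self):
        if sum(self.split) != 100:
            raise ValueError("split percentages must sum to 100")
        for name in ("learning_rate", "lr_decay", "lr_decay_every",
                     "early_stop_patience", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def _xavier(rng, d_in, d_out):
    bound = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-bound, bound, size=(d_in, d_out))


@dataclass
class HIDNModel:
    """Full forecaster: graph stage + shared-gland LSTM + encoder + readout."""

    n_glands: int
    adjacency: AdjacencyStructure
    graph: GraphAttentionParams
    lift: LiftParams
    recurrent: RecurrentParams
    encoder: StimulusEncoderParams
    readout: ReadoutParams
    dropout: float = 0.4

    def __post_init__(self):
        n, d_h = self.n_glands, self.recurrent.d_hidden
        if self.adjacency.n_nodes != n:
            raise ValueError("adjacency size disagrees with gland count")
        if self.graph.layer_weights[0].shape[0] != self.lift.bias.shape[0]:
            raise ValueError("lift width must match first graph layer input")
        d_graph = self.graph.layer_weights[-1].shape[1]
        if self.recurrent.d_input != d_graph + self.encoder.d_out:
            raise ValueError("recurrent input width must be graph width + "
                             "encoder output width")
        if self.readout.W3.shape != (n * d_h, n):
            raise ValueError(f"readout must map {n * d_h} -> {n}")

    # -- construction --------------------------------------------------------
    @classmethod
    def init(cls, n_glands: int, adjacency: AdjacencyStructure | np.ndarray,
             d_embed: int = 16, n_graph_layers: int = 2, d_stimulus: int = 8,
             encoder_hidden: int = 16, d_hidden: int = 32, dropout: float = 0.4,
             activation: str = "relu", seed: int = 42) -> "HIDNModel":
        """Xavier-initialized model with the package's desk-scale defaults."""
        if not isinstance(adjacency, AdjacencyStructure):
            adjacency = AdjacencyStructure(adjacency)
        rng = np.random.default_rng(seed)
        lift = LiftParams(_xavier(rng, 1, d_embed), np.zeros(d_embed))
        dims = [d_embed] * (n_graph_layers + 1)
        gw, ga = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            gw.append(_xavier(rng, d_in, d_out))
            ga.append(_xavier(rng, 2 * d_out, 1)[:, 0])
        graph = GraphAttentionParams(gw, ga, activation=activation)
        d_in = d_embed + d_stimulus
        rec = RecurrentParams(
            *(_xavier(rng, d_in, d_hidden) for _ in range(4)),
            *(_xavier(rng, d_hidden, d_hidden) for _ in range(4)),
            np.ones(d_hidden),                    # forget bias 1: standard warm start
            *(np.zeros(d_hidden) for _ in range(3)))
        enc = StimulusEncoderParams(_xavier(rng, n_glands, encoder_hidden),
                                    np.zeros(encoder_hidden),
                                    _xavier(rng, encoder_hidden, d_stimulus),
                                    np.zeros(d_stimulus), activation)
        readout = ReadoutParams(_xavier(rng, n_glands * d_hidden, n_glands),
                                np.zeros(n_glands))
        return cls(n_glands, adjacency, graph, lift, rec, enc, readout, dropout)

    # -- flat parameter view (for the optimizer and for serialization) -------
    def param_dict(self) -> dict[str, np.ndarray]:
        p = {"lift.weight": self.lift.weight, "lift.bias": self.lift.bias,
             "readout.W3": self.readout.W3, "readout.b3": self.readout.b3}
        for l, (w, a) in enumerate(zip(self.graph.layer_weights,
                                       self.graph.attention_vectors)):
            p[f"graph.W{l}"] = w
            p[f"graph.a{l}"] = a
        for name in ("W_f", "W_i", "W_o", "W_c", "U_f", "U_i", "U_o", "U_c",
                     "b_f", "b_i", "b_o", "b_c"):
            p[f"recurrent.{name}"] = getattr(self.recurrent, name)
        for name in ("W1", "b1", "W2", "b2"):
            p[f"encoder.{name}"] = getattr(self.encoder, name)
        return p

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.lift.weight = params["lift.weight"]
        self.lift.bias = params["lift.bias"]
        self.readout.W3 = params["readout.W3"]
        self.readout.b3 = params["readout.b3"]
        for l in range(self.graph.n_layers):
            self.graph.layer_weights[l] = params[f"graph.W{l}"]
            self.graph.attention_vectors[l] = params[f"graph.a{l}"]
        for name in ("W_f", "W_i", "W_o", "W_c", "U_f", "U_i", "U_o", "U_c",
                     "b_f", "b_i", "b_o", "b_c"):
            setattr(self.recurrent, name, params[f"recurrent.{name}"])
        for name in ("W1", "b1", "W2", "b2"):
            setattr(self.encoder, name, params[f"encoder.{name}"])

    def init_carry(self, batch_shape: tuple = ()) -> tuple[np.ndarray, np.ndarray]:
        shape = (*batch_shape, self.n_glands, self.recurrent.d_hidden)
        return np.zeros(shape), np.zeros(shape)


# -- core operations ---------------------------------------------------------

def _sigma(x: Tensor, activation: str) -> Tensor:
    return ad.relu(x) if activation == "relu" else ad.tanh(x)


def _lstm_tensor(x, s_prev, c_prev, P: dict) -> tuple[Tensor, Tensor]:
    f = ad.sigmoid(x @ P["W_f"] + s_prev @ P["U_f"] + P["b_f"])
    i = ad.sigmoid(x @ P["W_i"] + s_prev @ P["U_i"] + P["b_i"])
    o = ad.sigmoid(x @ P["W_o"] + s_prev @ P["U_o"] + P["b_o"])
    c_tilde = ad.tanh(x @ P["W_c"] + s_prev @ P["U_c"] + P["b_c"])
    c = f * c_prev + i * c_tilde
    s = o * ad.tanh(c)
    return s, c


def lstm_step(input_state, hidden_prev, cell_prev,
              params: RecurrentParams) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update: gates, cell blend, gated tanh output."""
    x = np.asarray(input_state, dtype=float)
    s = np.asarray(hidden_prev, dtype=float)
    c = np.asarray(cell_prev, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(s)) and np.all(np.isfinite(c))):
        raise ValueError("lstm_step requires finite inputs")
    P = {k: ad.as_tensor(getattr(params, k))
         for k in ("W_f", "W_i", "W_o", "W_c", "U_f", "U_i", "U_o", "U_c",
                   "b_f", "b_i", "b_o", "b_c")}
    s_new, c_new = _lstm_tensor(ad.as_tensor(x), ad.as_tensor(s), ad.as_tensor(c), P)
    return s_new.value, c_new.value


def _encode_tensor(u, P: dict, activation: str) -> Tensor:
    return _sigma(_sigma(u @ P["W1"] + P["b1"], activation) @ P["W2"] + P["b2"],
                  activation)


def encode_stimulus(inputs, params: StimulusEncoderParams) -> np.ndarray:
    """Two-layer perceptron encoding of the raw stimulus vector."""
    u = np.asarray(inputs, dtype=float)
    if u.shape[-1] != params.W1.shape[0]:
        raise ValueError(f"stimulus width {u.shape[-1]} != encoder input "
                         f"{params.W1.shape[0]}")
    P = {k: ad.as_tensor(getattr(params, k)) for k in ("W1", "b1", "W2", "b2")}
    return _encode_tensor(ad.as_tensor(u), P, params.activation).value


def _model_tensors(model: HIDNModel, requires_grad: bool) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=requires_grad)
            for k, v in model.param_dict().items()}


def _graph_stage(model: HIDNModel, P: dict, obs: Tensor,
                 drop_mask: np.ndarray | None) -> Tensor:
    """Lift scalars to features, run the graph stack, optional dropout."""
    x = obs.reshape(*obs.shape, 1) @ P["lift.weight"] + P["lift.bias"]
    for l in range(model.graph.n_layers):
        x = _layer_tensor(x, model.adjacency, model.graph, l,
                          W=P[f"graph.W{l}"], a=P[f"graph.a{l}"])
        x = _normalize_tensor(x)
    if drop_mask is not None:
        x = x * drop_mask
    return x


def _forward_step_tensor(model: HIDNModel, P: dict, obs: Tensor, u: Tensor,
                         carry: tuple[Tensor, Tensor],
                         drop_mask: np.ndarray | None = None
                         ) -> tuple[Tensor, tuple[Tensor, Tensor]]:
    """Single forward step on (..., N) observations and (..., M) stimuli."""
    n = model.n_glands
    g = _graph_stage(model, P, obs, drop_mask)                  # (..., N, dG)
    rec = {k: P[f"recurrent.{k}"] for k in
           ("W_f", "W_i", "W_o", "W_c", "U_f", "U_i", "U_o", "U_c",
            "b_f", "b_i", "b_o", "b_c")}
    enc = {k: P[f"encoder.{k}"] for k in ("W1", "b1", "W2", "b2")}
    u_enc = _encode_tensor(u, enc, model.encoder.activation)    # (..., dU)
    # broadcast the shared stimulus encoding to every gland
    u_g = u_enc.reshape(*u_enc.shape[:-1], 1, u_enc.shape[-1]) \
        * np.ones((n, 1))
    x_in = ad.concatenate([g, u_g], axis=-1)
    s, c = _lstm_tensor(x_in, carry[0], carry[1], rec)          # (..., N, dH)
    S = s.reshape(*s.shape[:-2], n * model.recurrent.d_hidden)
    pred = S @ P["readout.W3"] + P["readout.b3"]
    return pred, (s, c)


def forward_step(model: HIDNModel, observed_state, inputs, carry
                 ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """One prediction step h_hat(t+1) from observed h(t), u(t) and the
    per-gland recurrent carry; pure function of its arguments."""
    obs = np.asarray(observed_state, dtype=float)
    u = np.asarray(inputs, dtype=float)
    P = _model_tensors(model, requires_grad=False)
    pred, (s, c) = _forward_step_tensor(
        model, P, ad.as_tensor(obs), ad.as_tensor(u),
        (ad.as_tensor(carry[0]), ad.as_tensor(carry[1])))
    return pred.value, (s.value, c.value)


def mse_loss(predictions, observations) -> float:
    """Mean squared error averaged over all time steps and glands."""
    a = np.asarray(predictions, dtype=float)
    b = np.asarray(observations, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _sequence_loss(model: HIDNModel, P: dict, states: np.ndarray,
                   inputs: np.ndarray, drop_masks=None) -> Tensor:
    """Teacher-forced one-step-ahead MSE over a (B, T, N) batch."""
    B, T, n = states.shape
    carry = tuple(ad.as_tensor(c) for c in model.init_carry((B,)))
    preds = []
    for t in range(T - 1):
        mask = None if drop_masks is None else drop_masks[t]
        pred, carry = _forward_step_tensor(
            model, P, ad.as_tensor(states[:, t]), ad.as_tensor(inputs[:, t]),
            carry, drop_mask=mask)
        preds.append(pred)
    stacked = ad.stack(preds, axis=1)                           # (B, T-1, N)
    diff = stacked - states[:, 1:]
    return (diff * diff).mean()


def _windows(trajs: list[Trajectory], window: int, stride: int
             ) -> tuple[np.ndarray, np.ndarray]:
    xs, us = [], []
    for tr in trajs:
        T = tr.n_steps
        w = min(window, T)
        for start in range(0, T - w + 1, stride):
            xs.append(tr.states[start:start + w])
            us.append(tr.inputs[start:start + w])
    return np.stack(xs), np.stack(us)


def evaluate_loss(model: HIDNModel, trajs: list[Trajectory]) -> float:
    """One-step teacher-forced MSE over full trajectories (no dropout)."""
    P = _model_tensors(model, requires_grad=False)
    states = np.stack([t.states for t in trajs])
    inputs = np.stack([t.inputs for t in trajs])
    return _sequence_loss(model, P, states, inputs).item()


def split_dataset(dataset: list[Trajectory], config: TrainingConfig
                  ) -> tuple[list[Trajectory], list[Trajectory], list[Trajectory]]:
    """Seeded 70/15/15 (by default) train/validation/test split."""
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n = len(dataset)
    n_train = max(1, int(np.floor(n * config.split[0] / 100)))
    n_val = max(1, int(np.floor(n * config.split[1] / 100)))
    train_idx = order[:n_train]
    val_idx = order[n_train:n_train + n_val]
    test_idx = order[n_train + n_val:]
    pick = lambda idx: [dataset[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def train(model: HIDNModel, dataset: list[Trajectory], config: TrainingConfig
          ) -> tuple[HIDNModel, dict[str, list[float]]]:
    """Teacher-forced Adam training of the one-step-ahead MSE objective.

    Deterministic given ``config.seed``; returns the best-validation model
    and per-epoch train/validation loss histories.
    """
    if not dataset:
        raise ValueError("training requires a non-empty dataset")
    if len(dataset) < 2:
        raise ValueError("need at least 2 trajectories for a train/val split")
    model = copy.deepcopy(model)
    history: dict[str, list[float]] = {"train": [], "val": []}
    if config.max_epochs == 0:
        return model, history

    train_set, val_set, _ = split_dataset(dataset, config)
    X, U = _windows(train_set, config.window, config.stride)
    n_win = X.shape[0]
    rng = np.random.default_rng(config.seed + 1)

    params = {k: v.copy() for k, v in model.param_dict().items()}
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    stale = 0
    dG = model.graph.layer_weights[-1].shape[1]

    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)
        order = rng.permutation(n_win)
        epoch_losses = []
        for b0 in range(0, n_win, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            xb, ub = X[idx], U[idx]
            model.set_params(params)
            P = _model_tensors(model, requires_grad=True)
            masks = None
            if config.dropout > 0:
                keep = 1.0 - config.dropout
                masks = [(rng.random((len(idx), model.n_glands, dG)) < keep)
                         / keep for _ in range(xb.shape[1] - 1)]
            loss = _sequence_loss(model, P, xb, ub, drop_masks=masks)
            if not np.isfinite(loss.item()):
                raise TrainingDivergence(epoch)
            loss.backward()
            grads = {k: (P[k].grad if P[k].grad is not None
                         else np.zeros_like(params[k])) for k in params}
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if gnorm > config.clip_norm:
                scale = config.clip_norm / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            step += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)
            epoch_losses.append(loss.item())

        model.set_params(params)
        val_loss = evaluate_loss(model, val_set)
        history["train"].append(float(np.mean(epoch_losses)))
        history["val"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break

    model.set_params(best_params)
    return model, history


def rollout(model: HIDNModel, initial_state, schedule: InterventionSchedule | None,
            steps: int, dt: float = 0.1, t0: float = 0.0) -> Trajectory:
    """Closed-loop multi-step forecast: each prediction feeds the next step."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    n = model.n_glands
    if schedule is None:
        schedule = InterventionSchedule.empty(n)
    h = np.asarray(initial_state, dtype=float)
    carry = model.init_carry()
    times = t0 + dt * np.arange(steps + 1)
    states = np.empty((steps + 1, n))
    inputs = np.empty((steps + 1, n))
    states[0] = h
    inputs[0] = evaluate_intervention(schedule, times[0], n)
    for k in range(steps):
        u = evaluate_intervention(schedule, times[k], n)
        pred, carry = forward_step(model, h, u, carry)
        h = np.maximum(pred, 0.0)      # concentrations live in R+
        states[k + 1] = h
        inputs[k + 1] = evaluate_intervention(schedule, times[k + 1], n)
    return Trajectory(times, states, inputs)


# -- model bundles -----------------------------------------------------------

def save_bundle(model: HIDNModel, path) -> None:
    """Named-array archive with a JSON manifest describing the architecture."""
    manifest = {
        "n_glands": model.n_glands,
        "n_graph_layers": model.graph.n_layers,
        "leaky_slope": model.graph.leaky_slope,
        "activation": model.graph.activation,
        "self_loops": model.graph.self_loops,
        "encoder_activation": model.encoder.activation,
        "dropout": model.dropout,
    }
    arrays = {k.replace(".", "__"): v for k, v in model.param_dict().items()}
    arrays["adjacency"] = model.adjacency.base
    buf = io.BytesIO()
    np.savez(buf, manifest=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_bundle(path) -> HIDNModel:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        arrays = {k.replace("__", "."): data[k] for k in data.files
                  if k not in ("manifest", "adjacency")}
        adjacency = AdjacencyStructure(data["adjacency"])
    n, L = manifest["n_glands"], manifest["n_graph_layers"]
    graph = GraphAttentionParams(
        [arrays[f"graph.W{l}"] for l in range(L)],
        [arrays[f"graph.a{l}"] for l in range(L)],
        leaky_slope=manifest["leaky_slope"], activation=manifest["activation"],
        self_loops=manifest["self_loops"])
    lift = LiftParams(arrays["lift.weight"], arrays["lift.bias"])
    rec = RecurrentParams(*(arrays[f"recurrent.{k}"] for k in
                            ("W_f", "W_i", "W_o", "W_c", "U_f", "U_i", "U_o",
                             "U_c", "b_f", "b_i", "b_o", "b_c")))
    enc = StimulusEncoderParams(arrays["encoder.W1"], arrays["encoder.b1"],
                                arrays["encoder.W2"], arrays["encoder.b2"],
                                manifest["encoder_activation"])
    readout = ReadoutParams(arrays["readout.W3"], arrays["readout.b3"])
    return HIDNModel(n, adjacency, graph, lift, rec, enc, readout,
                     manifest["dropout"])
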