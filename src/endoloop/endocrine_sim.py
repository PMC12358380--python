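"""Mechanistic gland-network ODE simulator.

The endocrine system is modelled as a directed graph of glands. Hormone
concentration h_i(t) of gland i evolves as

    dh_i/dt = sum_j beta_ij * g_j(h_j) - gamma_i * h_i + u_i(t)

where beta_ij is the (signed) coupling strength of gland j on gland i —
negative entries encode negative feedback such as the T3 -> TRH edge of the
hypothalamic-pituitary-thyroid axis — gamma_i >= 0 is the natural
degradation rate, g_j is a secretion-response function (identity, logistic
sigmoid, or Hill), and u(t) collects external interventions (rectangular
dose pulses).

The simulator doubles as the synthetic-data generator: trajectories are
integrated with fixed-step classical Runge-Kutta (RK4), observation noise
is additive Gaussian, and concentrations are clamped at zero to respect
h in R+.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SecretionResponse", "RESPONSE_REGISTRY", "identity", "sigmoid_response",
    "hill_response", "GlandNetwork", "InterventionSchedule", "Trajectory",
    "SyntheticDatasetSpec", "IntegrationError", "derivative",
    "evaluate_intervention", "integrate", "generate_dataset",
    "read_trajectory_csv", "write_trajectory_csv",
]

OVERFLOW_GUARD = 1e12


class IntegrationError(RuntimeError):
    """Raised when the RK4 solution blows up; carries the time of failure."""

    def __init__(self, t: float):
        self.time = t
        super().__init__(f"integration diverged (|h| > {OVERFLOW_GUARD:g}) at t = {t:.6g}")


# -- secretion-response registry ---------------------------------------------

@dataclass(frozen=True)
class SecretionResponse:
    """Named secretion-response shape g(.) applied to the source hormone."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x):
        return self.fn(x)


def identity() -> SecretionResponse:
    return SecretionResponse("identity", lambda x: x)


def sigmoid_response() -> SecretionResponse:
    return SecretionResponse("sigmoid", lambda x: 1.0 / (1.0 + np.exp(-x)))


def hill_response(K: float, n: float) -> SecretionResponse:
    """Hill saturation x^n / (K^n + x^n); K > 0, n >= 1."""
    if not K > 0:
        raise ValueError(f"hill K must be > 0, got {K}")
    if not n >= 1:
        raise ValueError(f"hill n must be >= 1, got {n}")
    Kn = K ** n

    def fn(x):
        xn = np.maximum(x, 0.0) ** n
        return xn / (Kn + xn)

    return SecretionResponse(f"hill(K={K:g},n={n:g})", fn)


RESPONSE_REGISTRY: dict[str, Callable[..., SecretionResponse]] = {
    "identity": identity,
    "sigmoid": sigmoid_response,
    "hill": hill_response,
}


def make_response(name: str, **kwargs) -> SecretionResponse:
    if name not in RESPONSE_REGISTRY:
        raise ValueError(f"unknown secretion response {name!r}; "
                         f"known: {sorted(RESPONSE_REGISTRY)}")
    return RESPONSE_REGISTRY[name](**kwargs)


# -- domain types ------------------------------------------------------------

@dataclass
class GlandNetwork:
    """Directed gland graph with signed couplings and degradation rates.

    ``coupling[i, j]`` is the strength with which gland j drives gland i;
    ``responses`` maps an edge ``(i, j)`` to the secretion-response applied
    to h_j on that edge (default: identity everywhere). Because the response
    physiologically belongs to the source gland, :meth:`with_source_responses`
    assigns one response per source gland across all its outgoing edges.
    """

    gland_names: list[str]
    coupling: np.ndarray
    degradation: np.ndarray
    responses: dict[tuple[int, int], SecretionResponse] = field(default_factory=dict)

    def __post_init__(self):
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.degradation = np.asarray(self.degradation, dtype=float)
        n = len(self.gland_names)
        if len(set(self.gland_names)) != n or any(not s for s in self.gland_names):
            raise ValueError("gland names must be unique and nonempty")
        if self.coupling.shape != (n, n):
            raise ValueError(f"coupling must be {n}x{n}, got {self.coupling.shape}")
        if self.degradation.shape != (n,):
            raise ValueError(f"degradation must have length {n}")
        if np.any(self.degradation < 0):
            raise ValueError("degradation rates must be non-negative")
        for (i, j) in self.responses:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"response edge ({i},{j}) out of range")

    @property
    def n_glands(self) -> int:
        return len(self.gland_names)

    def with_source_responses(self, per_source: Sequence[SecretionResponse]) -> "GlandNetwork":
        """Assign one g_j per source gland j on every outgoing edge."""
        if len(per_source) != self.n_glands:
            raise ValueError("need one response per gland")
        responses = {}
        for i in range(self.n_glands):
            for j in range(self.n_glands):
                if self.coupling[i, j] != 0:
                    responses[(i, j)] = per_source[j]
        return GlandNetwork(self.gland_names, self.coupling, self.degradation, responses)

    def is_linear(self) -> bool:
        """True when every active edge uses the identity response."""
        return all(r.name == "identity"
                   for (i, j), r in self.responses.items() if self.coupling[i, j] != 0)

    def adjacency(self) -> np.ndarray:
        """Binary adjacency: A[i, j] = 1 iff gland j influences gland i."""
        return (self.coupling != 0).astype(float)


@dataclass
class InterventionSchedule:
    """Rectangular dose pulses: dose mu applied to one gland over [t1, t2]."""

    pulses: list[tuple[int, float, tuple[float, float]]] = field(default_factory=list)
    n_channels: int | None = None

    def __post_init__(self):
        for target, dose, (t1, t2) in self.pulses:
            if dose < 0:
                raise ValueError("dose must be non-negative")
            if t1 > t2:
                raise ValueError(f"pulse window [{t1}, {t2}] has t1 > t2")
            if self.n_channels is not None and not (0 <= target < self.n_channels):
                raise ValueError(f"pulse target {target} out of range")

    @classmethod
    def empty(cls, n_channels: int | None = None) -> "InterventionSchedule":
        return cls([], n_channels)


@dataclass
class Trajectory:
    """Time grid, hormone-state matrix and applied-input matrix."""

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.inputs = np.asarray(self.inputs, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states must be finite")
        if np.any(self.states < 0):
            raise ValueError("states must be non-negative")
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states and times disagree in length")
        if self.inputs.shape[0] != self.times.shape[0]:
            raise ValueError("inputs and times disagree in length")

    @property
    def n_steps(self) -> int:
        return len(self.times)


@dataclass
class SyntheticDatasetSpec:
    """How to sample a synthetic trajectory collection from a network."""

    n_trajectories: int
    horizon: float
    step: float
    init_ranges: list[tuple[float, float]]
    noise_sd: float = 0.0
    seed: int = 42

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.init_ranges:
            raise ValueError("init_ranges must be non-empty")
        for lo, hi in self.init_ranges:
            if lo > hi or lo < 0:
                raise ValueError(f"bad init range ({lo}, {hi})")


# -- operations --------------------------------------------------------------

def derivative(state: np.ndarray, inputs: np.ndarray, network: GlandNetwork) -> np.ndarray:
    """Right-hand side F(h, u): coupled secretion, degradation and stimuli."""
    state = np.asarray(state, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    n = network.n_glands
    if state.shape != (n,):
        raise ValueError(f"state must have length {n}, got shape {state.shape}")
    if inputs.shape != (n,):
        raise ValueError(f"inputs must have length {n}, got shape {inputs.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")

    if network.responses:
        g = np.tile(state, (n, 1))                 # g[i, j] = g_ij(h_j)
        for (i, j), resp in network.responses.items():
            g[i, j] = resp(state[j])
        drive = np.einsum("ij,ij->i", network.coupling, g)
    else:
        drive = network.coupling @ state           # identity responses
    return drive - network.degradation * state + inputs


def evaluate_intervention(schedule: InterventionSchedule, t: float,
                          n_channels: int | None = None) -> np.ndarray:
    """Stimulus vector at time t; closed interval, overlapping pulses sum."""
    if n_channels is None:
        n_channels = schedule.n_channels
        if n_channels is None:
            n_channels = 1 + max((p[0] for p in schedule.pulses), default=0)
    u = np.zeros(n_channels)
    for target, dose, (t1, t2) in schedule.pulses:
        if t1 <= t <= t2:
            u[target] += dose
    return u


def _rk4_step(h: np.ndarray, t: float, dt: float, network: GlandNetwork,
              schedule: InterventionSchedule) -> np.ndarray:
    n = network.n_glands
    u0 = evaluate_intervention(schedule, t, n)
    um = evaluate_intervention(schedule, t + dt / 2, n)
    u1 = evaluate_intervention(schedule, t + dt, n)
    k1 = derivative(h, u0, network)
    k2 = derivative(h + dt / 2 * k1, um, network)
    k3 = derivative(h + dt / 2 * k2, um, network)
    k4 = derivative(h + dt * k3, u1, network)
    return h + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate(network: GlandNetwork, h0: np.ndarray,
              schedule: InterventionSchedule | None = None,
              horizon: float = 1.0, step: float = 0.01,
              t0: float = 0.0) -> Trajectory:
    """Fixed-step RK4 over [t0, t0 + horizon], sampled every `step`.

    Concentrations are clamped at zero after each step; blow-up beyond the
    overflow guard raises :class:`IntegrationError` naming the time.
    """
    h0 = np.asarray(h0, dtype=float)
    if np.any(h0 < 0):
        raise ValueError("initial state must be non-negative")
    if step <= 0:
        raise ValueError("step must be positive")
    if horizon < step:
        raise ValueError("horizon must be at least one step")
    if schedule is None:
        schedule = InterventionSchedule.empty(network.n_glands)

    n_out = int(round(horizon / step))
    times = t0 + step * np.arange(n_out + 1)
    states = np.empty((n_out + 1, network.n_glands))
    inputs = np.empty_like(states)
    h = h0.copy()
    states[0] = h
    inputs[0] = evaluate_intervention(schedule, times[0], network.n_glands)
    for k in range(n_out):
        h = _rk4_step(h, times[k], step, network, schedule)
        if not np.all(np.isfinite(h)) or np.any(np.abs(h) > OVERFLOW_GUARD):
            raise IntegrationError(times[k + 1])
        h = np.maximum(h, 0.0)
        states[k + 1] = h
        inputs[k + 1] = evaluate_intervention(schedule, times[k + 1], network.n_glands)
    return Trajectory(times, states, inputs)


def generate_dataset(network: GlandNetwork, spec: SyntheticDatasetSpec,
                     schedule: InterventionSchedule | None = None) -> list[Trajectory]:
    """Sample trajectories: uniform h(0) from init_ranges, additive Gaussian
    observation noise of sd `noise_sd` (clamped at zero), seed-deterministic."""
    if len(spec.init_ranges) != network.n_glands:
        raise ValueError("init_ranges must give one interval per gland")
    rng = np.random.default_rng(spec.seed)
    lo = np.array([r[0] for r in spec.init_ranges])
    hi = np.array([r[1] for r in spec.init_ranges])
    out = []
    for _ in range(spec.n_trajectories):
        h0 = rng.uniform(lo, hi)
        traj = integrate(network, h0, schedule, spec.horizon, spec.step)
        states = traj.states
        if spec.noise_sd > 0:
            states = states + rng.normal(0.0, spec.noise_sd, size=states.shape)
            states = np.maximum(states, 0.0)
        out.append(Trajectory(traj.times, states, traj.inputs))
    return out


# -- tabular I/O -------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path, gland_names: Sequence[str]) -> None:
    """CSV with header time,<gland...>[,u_<gland>...]; 12 significant digits."""
    cols = {"time": traj.times}
    for k, name in enumerate(gland_names):
        cols[name] = traj.states[:, k]
    if traj.inputs.size and np.any(traj.inputs != 0):
        for k, name in enumerate(gland_names):
            cols[f"u_{name}"] = traj.inputs[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path, gland_names: Sequence[str] | None = None) -> Trajectory:
    df = pd.read_csv(path)
    if gland_names is None:
        gland_names = [c for c in df.columns if c != "time" and not c.startswith("u_")]
    states = df[list(gland_names)].to_numpy()
    u_cols = [f"u_{g}" for g in gland_names]
    if all(c in df.columns for c in u_cols):
        inputs = df[u_cols].to_numpy()
    else:
        inputs = np.zeros_like(states)
    return Trajectory(df["time"].to_numpy(), states, inputs)
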