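"""Configuration loading/validation, fixture networks, and run manifests.

Config files are YAML; each schema is a strict pydantic model (unknown keys
rejected, defaults filled) plus a ``build()`` method producing the domain
object. The fixture suite supplies three deterministic toy systems used
throughout the tests and examples:

``hpt_axis``
    Three-gland hypothalamic-pituitary-thyroid chain: TRH stimulates TSH,
    TSH stimulates T3, and T3 feeds back negatively on TRH with strength
    k_TRH — the canonical endocrine negative-feedback loop.
``linear_2g``
    A two-gland linear cross-stimulation system with strictly dissipative
    symmetric part, so unforced trajectories decay monotonically in norm.
``random_3g``
    A seeded random three-gland network with sigmoid secretion responses
    (bounded drive, hence bounded trajectories), the workhorse for
    forecaster training experiments.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .ahrs_control import ControlConfig
from .endocrine_sim import (GlandNetwork, InterventionSchedule,
                            SyntheticDatasetSpec, make_response)
from .hidn_temporal import TrainingConfig

__all__ = ["load_config", "fixture_suite", "RunManifest", "ConfigError",
           "NetworkConfig", "ScheduleConfig", "DatasetConfig",
           "TrainConfigFile", "ControlConfigFile", "FIXTURE_NAMES"]


class ConfigError(ValueError):
    """Schema violation in a configuration file, naming the offending path."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ResponseSpec(_Strict):
    type: str = "identity"
    K: float | None = None
    n: float | None = None

    def build(self):
        kwargs = {}
        if self.type == "hill":
            kwargs = {"K": self.K if self.K is not None else 1.0,
                      "n": self.n if self.n is not None else 1.0}
        return make_response(self.type, **kwargs)


class NetworkConfig(_Strict):
    glands: list[str]
    coupling: list[list[float]]
    degradation: list[float]
    responses: dict[str, ResponseSpec] = {}
    initial: list[float] | None = None
    step: float = 0.01          # default integration output interval

    @field_validator("glands")
    @classmethod
    def _unique(cls, v):
        if len(set(v)) != len(v):
            raise ValueError("gland names must be unique")
        return v

    def build(self) -> GlandNetwork:
        net = GlandNetwork(self.glands, np.array(self.coupling),
                           np.array(self.degradation))
        if self.responses:
            per_source = []
            for g in self.glands:
                spec = self.responses.get(g)
                per_source.append(spec.build() if spec else make_response("identity"))
            net = net.with_source_responses(per_source)
        return net

    def initial_state(self) -> np.ndarray:
        if self.initial is not None:
            return np.asarray(self.initial, dtype=float)
        return np.ones(len(self.glands))


class PulseSpec(_Strict):
    target: int | str
    dose: float
    window: tuple[float, float]


class ScheduleConfig(_Strict):
    pulses: list[PulseSpec] = []

    def build(self, network: GlandNetwork) -> InterventionSchedule:
        pulses = []
        for p in self.pulses:
            if isinstance(p.target, str):
                if p.target not in network.gland_names:
                    raise ConfigError(f"pulse target {p.target!r} is not a gland")
                idx = network.gland_names.index(p.target)
            else:
                idx = p.target
            pulses.append((idx, p.dose, (p.window[0], p.window[1])))
        return InterventionSchedule(pulses, network.n_glands)


class DatasetConfig(_Strict):
    network: str                   # path to a network config
    n_trajectories: int
    horizon: float
    step: float = 0.1
    init_ranges: list[tuple[float, float]]
    noise_sd: float = 0.0
    seed: int = 42

    def build_spec(self) -> SyntheticDatasetSpec:
        return SyntheticDatasetSpec(self.n_trajectories, self.horizon, self.step,
                                    [tuple(r) for r in self.init_ranges],
                                    self.noise_sd, self.seed)


class TrainConfigFile(_Strict):
    learning_rate: float = 0.0005
    lr_decay: float = 0.85
    lr_decay_every: int = 10
    max_epochs: int = 150
    early_stop_patience: int = 15
    batch_size: int = 32
    dropout: float = 0.4
    seed: int = 42
    split: tuple[int, int, int] = (70, 15, 15)
    window: int = 8
    stride: int = 1
    d_embed: int = 16
    n_graph_layers: int = 2
    d_stimulus: int = 8
    d_hidden: int = 32

    def build(self) -> TrainingConfig:
        return TrainingConfig(self.learning_rate, self.lr_decay,
                              self.lr_decay_every, self.max_epochs,
                              self.early_stop_patience, self.batch_size,
                              self.dropout, self.seed, tuple(self.split),
                              self.window, self.stride)


class ControlConfigFile(_Strict):
    targets: list[float]
    weights: list[float] | None = None
    risk_weight: float = 0.0
    interaction_risk: list[list[float]] | None = None
    intervention_lr: float = 0.5
    decay: float = 0.0
    risk_threshold: float | None = None
    penalty: float = 1e4
    max_iters: int = 1
    convergence_tol: float = 1e-10
    dt: float = 0.1

    def build(self) -> ControlConfig:
        n = len(self.targets)
        return ControlConfig(
            np.array(self.targets),
            np.array(self.weights) if self.weights is not None else np.ones(n),
            self.risk_weight,
            np.array(self.interaction_risk) if self.interaction_risk is not None
            else None,
            self.intervention_lr, self.decay,
            np.inf if self.risk_threshold is None else self.risk_threshold,
            self.penalty, self.max_iters, self.convergence_tol)


_SCHEMAS = {"network": NetworkConfig, "schedule": ScheduleConfig,
            "dataset": DatasetConfig, "train": TrainConfigFile,
            "control": ControlConfigFile}


def load_config(path, schema: str):
    """Load and validate a YAML config against a named schema.

    Unknown keys, missing required keys and wrong types raise
    :class:`ConfigError` naming the offending location.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(_SCHEMAS)}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return _SCHEMAS[schema].model_validate(raw)
    except ValidationError as err:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in err.errors()]
        raise ConfigError(f"invalid {schema} config {path}: " + "; ".join(lines)) \
            from err


def dump_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(cfg.model_dump_json(exclude_none=True)), fh)


# -- fixture suite -----------------------------------------------------------

FIXTURE_NAMES = ("hpt_axis", "linear_2g", "random_3g")


def fixture_suite(name: str, seed: int = 42
                  ) -> tuple[GlandNetwork, SyntheticDatasetSpec]:
    """Deterministic toy gland networks with matching dataset recipes."""
    if name == "hpt_axis":
        k_trh = 0.5
        net = GlandNetwork(
            ["TRH", "TSH", "T3"],
            np.array([[0.0, 0.0, -k_trh],      # T3 inhibits TRH
                      [0.8, 0.0, 0.0],         # TRH stimulates TSH
                      [0.0, 0.7, 0.0]]),       # TSH stimulates T3
            np.array([0.3, 0.4, 0.5]))
        spec = SyntheticDatasetSpec(100, 2.0, 0.1, [(0.2, 1.5)] * 3,
                                    noise_sd=0.02, seed=seed)
    elif name == "linear_2g":
        net = GlandNetwork(
            ["A", "B"],
            np.array([[0.0, 0.3],
                      [0.4, 0.0]]),
            np.array([0.6, 0.9]))
        spec = SyntheticDatasetSpec(100, 2.0, 0.1, [(0.2, 1.5)] * 2,
                                    noise_sd=0.02, seed=seed)
    elif name == "random_3g":
        rng = np.random.default_rng(seed)
        coupling = rng.uniform(-0.5, 0.5, size=(3, 3))
        np.fill_diagonal(coupling, 0.0)
        degradation = rng.uniform(0.5, 1.0, size=3)
        net = GlandNetwork(["G1", "G2", "G3"], coupling, degradation)
        net = net.with_source_responses([make_response("sigmoid")] * 3)
        spec = SyntheticDatasetSpec(200, 2.0, 0.1, [(0.2, 1.5)] * 3,
                                    noise_sd=0.02, seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return net, spec


# -- run manifests -----------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None = None
    version: str = "0.1.0"
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def start(self):
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def record_input(self, path):
        self.inputs[str(path)] = _digest(path)

    def record_output(self, path):
        self.outputs[str(path)] = _digest(path)

    def finish(self, path):
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
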