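"""Closed-loop hormonal intervention design.

The controller couples a predictor (either a one-step model of the gland
network or a trained forecaster) to the simulated plant. Each control step
it observes hormone levels, predicts the response to the current
intervention, descends the multi-objective loss

    L_multi(u) = sum_i w_i (h_i(u) - h_i^target)^2 + lambda_risk * R(u)

with respect to the intervention vector u, enforces the safety constraint
C(u) <= epsilon through a hinge penalty (plus a radial feasibility
projection, since C is monotone along rays from the origin), decays the
intervention learning rate with the total deviation from targets, applies
u to the plant, and logs deviations, losses and the stability index (the
ratio of consecutive prediction-error norms).

Patient personalization maintains a Gaussian distribution over
physiological parameters (couplings, degradation rates): exact conjugate
updates when the observation model is linear in the parameters, otherwise
gradient ascent on the log posterior with a Laplace covariance
approximation at the mode.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .endocrine_sim import GlandNetwork, Trajectory, derivative, integrate
from .hidn_temporal import HIDNModel, _forward_step_tensor, _model_tensors

__all__ = [
    "ControlConfig", "PatientPosterior", "ControlLog", "PlantPredictor",
    "HIDNPredictor", "DirectObservationModel", "TrajectoryObservationModel",
    "StabilityUndefinedError", "NumericalConditioningError",
    "deviation", "feedback_loss", "update_intervention", "stability_index",
    "risk", "multi_objective_loss", "total_deviation", "adapt_learning_rate",
    "constrained_objective", "posterior_update", "closed_loop_run",
]

FD_STEP = 1e-5


class StabilityUndefinedError(ZeroDivisionError):
    """Previous deviation is exactly zero: the ratio is undefined."""


class NumericalConditioningError(RuntimeError):
    """Posterior covariance lost positive definiteness."""


# -- configuration and state -------------------------------------------------

@dataclass
class ControlConfig:
    """Targets, clinical weights, risk couplings and optimizer settings."""

    targets: np.ndarray
    weights: np.ndarray
    risk_weight: float = 0.0          # lambda_risk
    interaction_risk: np.ndarray | None = None   # rho, zero diagonal
    intervention_lr: float = 0.5      # eta
    decay: float = 0.0                # kappa
    risk_threshold: float = np.inf    # epsilon
    penalty: float = 1e4              # lambda of the hinge
    max_iters: int = 1                # inner gradient steps per control step
    convergence_tol: float = 1e-10
    u_min: float | None = None        # optional dosage box
    u_max: float | None = None
    stability_flag_threshold: float = 1.5

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.targets.shape[0]
        if self.weights.shape != (n,):
            raise ValueError("weights must match targets in length")
        if np.any(self.weights < 0) or self.risk_weight < 0:
            raise ValueError("weights and risk_weight must be non-negative")
        if self.interaction_risk is None:
            self.interaction_risk = np.zeros((n, n))
        self.interaction_risk = np.asarray(self.interaction_risk, dtype=float)
        if self.interaction_risk.shape != (n, n):
            raise ValueError("interaction_risk must be N x N")
        if np.any(np.diag(self.interaction_risk) != 0):
            raise ValueError("interaction_risk must have a zero diagonal")
        if np.any(self.interaction_risk < 0):
            raise ValueError("interaction_risk must be non-negative")
        if self.intervention_lr <= 0:
            raise ValueError("intervention_lr must be positive")
        if self.decay < 0 or self.risk_threshold < 0 or self.penalty < 0:
            raise ValueError("decay, risk_threshold and penalty must be >= 0")

    @property
    def n(self) -> int:
        return self.targets.shape[0]


@dataclass
class PatientPosterior:
    """Gaussian state of belief over patient-specific parameters."""

    param_names: list
    mean: np.ndarray
    cov: np.ndarray
    prior_mean: np.ndarray
    prior_cov: np.ndarray
    noise_sd: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.prior_mean = np.asarray(self.prior_mean, dtype=float)
        self.prior_cov = np.asarray(self.prior_cov, dtype=float)
        for c in (self.cov, self.prior_cov):
            if not np.allclose(c, c.T):
                raise ValueError("covariance must be symmetric")
            try:
                np.linalg.cholesky(c)
            except np.linalg.LinAlgError as err:
                raise NumericalConditioningError(
                    "covariance is not positive definite") from err
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @classmethod
    def from_prior(cls, param_names, prior_mean, prior_cov, noise_sd):
        prior_mean = np.asarray(prior_mean, dtype=float)
        prior_cov = np.asarray(prior_cov, dtype=float)
        return cls(list(param_names), prior_mean.copy(), prior_cov.copy(),
                   prior_mean, prior_cov, noise_sd)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class ControlLog:
    """Per-iteration records of a closed-loop run."""

    u: list = field(default_factory=list)
    h_obs: list = field(default_factory=list)
    h_pred: list = field(default_factory=list)
    dev: list = field(default_factory=list)
    feedback_loss: list = field(default_factory=list)
    stability_index: list = field(default_factory=list)   # nan where undefined
    converged: list = field(default_factory=list)
    total_dev: list = field(default_factory=list)
    eta: list = field(default_factory=list)
    constraint: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.u[0]) if self.u else 0
        rows = {"iter": np.arange(len(self.u))}
        for k in range(n):
            rows[f"u_{k}"] = [u[k] for u in self.u]
        for k in range(n):
            rows[f"hobs_{k}"] = [h[k] for h in self.h_obs]
        for k in range(n):
            rows[f"hpred_{k}"] = [h[k] for h in self.h_pred]
        rows["feedback_loss"] = self.feedback_loss
        rows["stability_index"] = self.stability_index
        rows["D"] = self.total_dev
        rows["eta"] = self.eta
        rows["C_u"] = self.constraint
        return pd.DataFrame(rows)


# -- predictors --------------------------------------------------------------

class PlantPredictor:
    """One-step forward-Euler model of a gland network.

    Deliberately coarser than the RK4 plant so the prediction deviation is
    a nonzero, informative signal. The Euler map is exactly linear in u,
    which makes the intervention gradient available in closed form through
    the autodiff path.
    """

    def __init__(self, network: GlandNetwork, dt: float = 0.1):
        self.network = network
        self.dt = dt

    def predict(self, h_obs: np.ndarray, u: np.ndarray) -> np.ndarray:
        return h_obs + self.dt * derivative(h_obs, u, self.network)

    def predict_tensor(self, h_obs: np.ndarray, u: Tensor) -> Tensor:
        base = h_obs + self.dt * derivative(h_obs, np.zeros_like(h_obs),
                                            self.network)
        return u * self.dt + base

    def observe(self, h_obs, u):     # stateless
        pass

    def with_network(self, network: GlandNetwork) -> "PlantPredictor":
        return PlantPredictor(network, self.dt)


class HIDNPredictor:
    """Trained forecaster as the controller's predictive model.

    Maintains the per-gland recurrent carry; ``observe`` commits a step so
    the hidden state tracks the monitored patient.
    """

    def __init__(self, model: HIDNModel):
        self.model = model
        self.carry = model.init_carry()

    def predict(self, h_obs: np.ndarray, u: np.ndarray) -> np.ndarray:
        return self.predict_tensor(h_obs, ad.as_tensor(u)).value

    def predict_tensor(self, h_obs: np.ndarray, u: Tensor) -> Tensor:
        P = _model_tensors(self.model, requires_grad=False)
        pred, _ = _forward_step_tensor(
            self.model, P, ad.as_tensor(np.asarray(h_obs, dtype=float)), u,
            (ad.as_tensor(self.carry[0]), ad.as_tensor(self.carry[1])))
        return pred

    def observe(self, h_obs, u):
        P = _model_tensors(self.model, requires_grad=False)
        _, carry = _forward_step_tensor(
            self.model, P, ad.as_tensor(np.asarray(h_obs, dtype=float)),
            ad.as_tensor(np.asarray(u, dtype=float)),
            (ad.as_tensor(self.carry[0]), ad.as_tensor(self.carry[1])))
        self.carry = (carry[0].value, carry[1].value)


# -- elementary quantities ---------------------------------------------------

def deviation(predicted, observed) -> np.ndarray:
    """Prediction error h_hat - h_obs."""
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(observed, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def feedback_loss(dev) -> float:
    """Squared Euclidean norm of the deviation."""
    dev = np.asarray(dev, dtype=float)
    return float(np.dot(dev, dev))


def stability_index(dev_next, dev_prev) -> float:
    """Ratio of consecutive deviation norms; ~1 means steady tracking."""
    prev = float(np.linalg.norm(np.asarray(dev_prev, dtype=float)))
    if prev == 0.0:
        raise StabilityUndefinedError("previous deviation is zero")
    return float(np.linalg.norm(np.asarray(dev_next, dtype=float))) / prev


def risk(u, interaction_risk) -> float:
    """Intervention risk: squared intensity plus pairwise-conflict terms."""
    u = np.asarray(u, dtype=float)
    rho = np.asarray(interaction_risk, dtype=float)
    pairwise = np.abs(u[:, None] - u[None, :])
    return float(np.dot(u, u) + np.sum(rho * pairwise))


def _risk_tensor(u: Tensor, rho: np.ndarray) -> Tensor:
    n = u.shape[0]
    diff = u.reshape(n, 1) - u.reshape(1, n)
    return (u * u).sum() + (ad.absolute(diff) * rho).sum()


def multi_objective_loss(h, u, config: ControlConfig) -> float:
    """Weighted squared target mismatch plus lambda_risk * R(u)."""
    h = np.asarray(h, dtype=float)
    u = np.asarray(u, dtype=float)
    obj = float(np.sum(config.weights * (h - config.targets) ** 2))
    return obj + config.risk_weight * risk(u, config.interaction_risk)


def total_deviation(h, targets) -> float:
    """Sum of squared distances from the target levels."""
    h = np.asarray(h, dtype=float)
    targets = np.asarray(targets, dtype=float)
    return float(np.sum((h - targets) ** 2))


def adapt_learning_rate(eta: float, total_dev: float, decay: float) -> float:
    """Exponential learning-rate decay with the total deviation."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    if total_dev < 0:
        raise ValueError("total deviation must be non-negative")
    return eta * np.exp(-decay * total_dev)


def constrained_objective(h, u, config: ControlConfig) -> float:
    """Multi-objective loss plus the hinge penalty on C(u) - epsilon."""
    c = risk(u, config.interaction_risk)
    return multi_objective_loss(h, u, config) + \
        config.penalty * max(0.0, c - config.risk_threshold)


# -- intervention optimization -----------------------------------------------

def _objective_tensor(u: Tensor, predictor, observed, config: ControlConfig,
                      objective: str, penalized: bool) -> Tensor:
    pred = predictor.predict_tensor(observed, u)
    if objective == "feedback":
        diff = pred - observed
        loss = (diff * diff).sum()
    elif objective == "multi":
        diff = pred - config.targets
        loss = (ad.as_tensor(config.weights) * diff * diff).sum()
        if config.risk_weight > 0:
            loss = loss + config.risk_weight * \
                _risk_tensor(u, config.interaction_risk)
    else:
        raise ValueError("objective must be 'feedback' or 'multi'")
    if penalized and np.isfinite(config.risk_threshold) and config.penalty > 0:
        loss = loss + config.penalty * ad.maximum0(
            _risk_tensor(u, config.interaction_risk) - config.risk_threshold)
    return loss


def _objective_scalar(u: np.ndarray, predictor, observed, config, objective,
                      penalized) -> float:
    pred = predictor.predict(observed, u)
    if objective == "feedback":
        loss = feedback_loss(deviation(pred, observed))
    else:
        loss = multi_objective_loss(pred, u, config)
    if penalized and np.isfinite(config.risk_threshold) and config.penalty > 0:
        loss += config.penalty * max(
            0.0, risk(u, config.interaction_risk) - config.risk_threshold)
    return loss


def intervention_gradient(u, predictor, observed, config: ControlConfig,
                          objective: str = "feedback",
                          penalized: bool = False,
                          method: str = "auto") -> np.ndarray:
    """Gradient of the chosen loss with respect to u.

    ``auto`` uses the autodiff path when the predictor exposes
    ``predict_tensor`` and falls back to central finite differences
    (step 1e-5) otherwise.
    """
    u = np.asarray(u, dtype=float)
    observed = np.asarray(observed, dtype=float)
    use_ad = method == "ad" or (method == "auto"
                                and hasattr(predictor, "predict_tensor"))
    if use_ad:
        ut = Tensor(u, requires_grad=True)
        loss = _objective_tensor(ut, predictor, observed, config, objective,
                                 penalized)
        loss.backward()
        grad = ut.grad if ut.grad is not None else np.zeros_like(u)
    else:
        grad = np.empty_like(u)
        for k in range(u.size):
            up, um = u.copy(), u.copy()
            up[k] += FD_STEP
            um[k] -= FD_STEP
            grad[k] = (_objective_scalar(up, predictor, observed, config,
                                         objective, penalized)
                       - _objective_scalar(um, predictor, observed, config,
                                           objective, penalized)) / (2 * FD_STEP)
    if not np.all(np.isfinite(grad)):
        raise RuntimeError("non-finite intervention gradient")
    return grad


def update_intervention(u, predictor, observed, config: ControlConfig,
                        objective: str = "feedback", eta: float | None = None,
                        penalized: bool = False,
                        method: str = "auto") -> np.ndarray:
    """One gradient step u' = u - eta * grad_u(loss)."""
    u = np.asarray(u, dtype=float)
    eta = config.intervention_lr if eta is None else eta
    if eta == 0:
        return u.copy()
    grad = intervention_gradient(u, predictor, observed, config, objective,
                                 penalized, method)
    u_new = u - eta * grad
    if config.u_min is not None or config.u_max is not None:
        u_new = np.clip(u_new,
                        -np.inf if config.u_min is None else config.u_min,
                        np.inf if config.u_max is None else config.u_max)
    return u_new


def project_feasible(u, config: ControlConfig, tol: float = 1e-9) -> np.ndarray:
    """Radial projection onto {C(u) <= epsilon}.

    C(s*u) is continuous and nondecreasing in s >= 0, so bisection on the
    scale factor lands on the constraint boundary.
    """
    u = np.asarray(u, dtype=float)
    eps = config.risk_threshold
    if not np.isfinite(eps) or risk(u, config.interaction_risk) <= eps:
        return u
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if risk(mid * u, config.interaction_risk) <= eps:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return lo * u


# -- Bayesian personalization ------------------------------------------------

class DirectObservationModel:
    """Observations are a known linear map of the parameters: y = X p + noise."""

    def __init__(self, design_matrix):
        self.design_matrix = np.asarray(design_matrix, dtype=float)

    def predict(self, params) -> np.ndarray:
        return self.design_matrix @ np.asarray(params, dtype=float)

    def target(self, traj: Trajectory) -> np.ndarray:
        return traj.states.ravel()


class TrajectoryObservationModel:
    """Observations are a simulated trajectory of a gland network whose
    selected parameters are replaced by the inferred vector.

    ``param_spec`` entries: ("degradation", i) or ("coupling", i, j).
    Predictions cover rows 1..T-1 (the initial state carries no information
    about the parameters).
    """

    design_matrix = None

    def __init__(self, network: GlandNetwork, param_spec: list, h0, times):
        self.network = network
        self.param_spec = list(param_spec)
        self.h0 = np.asarray(h0, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.step = float(self.times[1] - self.times[0])
        self.horizon = float(self.times[-1] - self.times[0])

    def apply_params(self, params) -> GlandNetwork:
        net = copy.deepcopy(self.network)
        for spec, value in zip(self.param_spec, np.asarray(params, dtype=float)):
            if spec[0] == "degradation":
                net.degradation[spec[1]] = max(value, 0.0)
            elif spec[0] == "coupling":
                net.coupling[spec[1], spec[2]] = value
            else:
                raise ValueError(f"unknown parameter kind {spec[0]!r}")
        return net

    def predict(self, params) -> np.ndarray:
        net = self.apply_params(params)
        traj = integrate(net, self.h0, None, self.horizon, self.step,
                         t0=self.times[0])
        return traj.states[1:].ravel()

    def target(self, traj: Trajectory) -> np.ndarray:
        return traj.states[1:].ravel()


def _log_posterior(params, y, model, posterior: PatientPosterior) -> float:
    diff_prior = params - posterior.prior_mean
    prior_prec = np.linalg.inv(posterior.prior_cov)
    lp = -0.5 * diff_prior @ prior_prec @ diff_prior
    try:
        resid = y - model.predict(params)
    except (RuntimeError, ValueError):
        # parameter proposals where the plant diverges have no support
        return -np.inf
    return lp - 0.5 * float(resid @ resid) / posterior.noise_sd ** 2


def posterior_update(posterior: PatientPosterior, observations: Trajectory | None,
                     predictor, lr: float = 0.05, max_steps: int = 200,
                     tol: float = 1e-10) -> PatientPosterior:
    """Bayesian refinement of patient parameters.

    Linear observation models get the exact conjugate Gaussian posterior;
    otherwise gradient ascent on the log posterior (with backtracking on
    the step size) followed by a Laplace covariance approximation at the
    mode. With no observations the posterior equals the prior.
    """
    if observations is None or observations.states.size == 0:
        return PatientPosterior(posterior.param_names,
                                posterior.prior_mean.copy(),
                                posterior.prior_cov.copy(),
                                posterior.prior_mean, posterior.prior_cov,
                                posterior.noise_sd)
    y = predictor.target(observations)
    sigma2 = posterior.noise_sd ** 2
    prior_prec = np.linalg.inv(posterior.prior_cov)

    if getattr(predictor, "design_matrix", None) is not None:
        X = predictor.design_matrix
        post_prec = prior_prec + X.T @ X / sigma2
        cov = np.linalg.inv(post_prec)
        mean = cov @ (prior_prec @ posterior.prior_mean + X.T @ y / sigma2)
        cov = 0.5 * (cov + cov.T)
        return PatientPosterior(posterior.param_names, mean, cov,
                                posterior.prior_mean, posterior.prior_cov,
                                posterior.noise_sd)

    # gradient ascent on log p(p | D) with central-difference gradients
    params = posterior.mean.copy()
    k = params.size
    logp = _log_posterior(params, y, predictor, posterior)
    step = lr
    for _ in range(max_steps):
        grad = np.empty(k)
        for j in range(k):
            pp, pm = params.copy(), params.copy()
            pp[j] += FD_STEP
            pm[j] -= FD_STEP
            grad[j] = (_log_posterior(pp, y, predictor, posterior)
                       - _log_posterior(pm, y, predictor, posterior)) / (2 * FD_STEP)
        if not np.all(np.isfinite(grad)) or np.linalg.norm(grad) < tol:
            break
        # backtracking ascent step
        improved = False
        while step > 1e-12:
            cand = params + step * grad
            cand_lp = _log_posterior(cand, y, predictor, posterior)
            if cand_lp > logp:
                params, logp = cand, cand_lp
                improved = True
                step = min(step * 2.0, lr * 100)
                break
            step *= 0.5
        if not improved:
            break

    # Laplace covariance: negative Hessian of log posterior at the mode
    hess = np.empty((k, k))
    h = 1e-4
    for a in range(k):
        for b in range(a, k):
            pp = params.copy(); pp[a] += h; pp[b] += h
            pm = params.copy(); pm[a] += h; pm[b] -= h
            mp = params.copy(); mp[a] -= h; mp[b] += h
            mm = params.copy(); mm[a] -= h; mm[b] -= h
            val = (_log_posterior(pp, y, predictor, posterior)
                   - _log_posterior(pm, y, predictor, posterior)
                   - _log_posterior(mp, y, predictor, posterior)
                   + _log_posterior(mm, y, predictor, posterior)) / (4 * h * h)
            hess[a, b] = hess[b, a] = val
    prec = -hess
    try:
        cov = np.linalg.inv(prec)
        cov = 0.5 * (cov + cov.T)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise NumericalConditioningError(
            "Laplace covariance is not positive definite") from err
    return PatientPosterior(posterior.param_names, params, cov,
                            posterior.prior_mean, posterior.prior_cov,
                            posterior.noise_sd)


# -- the closed loop ---------------------------------------------------------

def _advance_plant(network: GlandNetwork, h: np.ndarray, u: np.ndarray,
                   dt: float, substeps: int = 5) -> np.ndarray:
    """RK4 advance of the plant under a constant intervention vector."""
    sub = dt / substeps
    for _ in range(substeps):
        k1 = derivative(h, u, network)
        k2 = derivative(h + sub / 2 * k1, u, network)
        k3 = derivative(h + sub / 2 * k2, u, network)
        k4 = derivative(h + sub * k3, u, network)
        h = h + sub / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(h)) or np.any(np.abs(h) > 1e12):
            raise RuntimeError("plant state diverged during control")
        h = np.maximum(h, 0.0)
    return h


def closed_loop_run(plant: GlandNetwork, predictor, config: ControlConfig,
                    h0, horizon: int = 100, dt: float = 0.1,
                    u0: np.ndarray | None = None,
                    posterior: PatientPosterior | None = None,
                    objective: str = "multi") -> ControlLog:
    """Run the full monitor -> predict -> optimize -> actuate loop.

    Per step: observe the plant, predict the response to the current u,
    take ``config.max_iters`` penalized gradient steps on the intervention,
    project onto the feasibility set, decay the learning rate with the
    total target deviation, apply u to the plant and log everything.
    """
    n = plant.n_glands
    h = np.asarray(h0, dtype=float).copy()
    u = np.zeros(n) if u0 is None else np.asarray(u0, dtype=float).copy()
    if posterior is not None and isinstance(predictor, PlantPredictor):
        # personalize the predictive model with the inferred parameter means
        net = copy.deepcopy(predictor.network)
        for spec, value in zip(posterior.param_names, posterior.mean):
            if spec[0] == "degradation":
                net.degradation[spec[1]] = max(float(value), 0.0)
            elif spec[0] == "coupling":
                net.coupling[spec[1], spec[2]] = float(value)
        predictor = predictor.with_network(net)
    eta = config.intervention_lr
    log = ControlLog()
    prev_pred: np.ndarray | None = None
    prev_dev_norm: float | None = None

    for step in range(horizon):
        h_obs = h.copy()
        # deviation of the prediction made at the previous step
        if prev_pred is not None:
            dev = deviation(prev_pred, h_obs)
        else:
            dev = np.zeros(n)
        fb = feedback_loss(dev)
        dev_norm = float(np.linalg.norm(dev))
        # the index needs two consecutive genuine deviations (steps >= 2)
        converged = False
        if prev_dev_norm is not None:
            if prev_dev_norm == 0.0:
                si, converged = np.nan, True
            else:
                si = dev_norm / prev_dev_norm
        else:
            si = np.nan

        # intervention optimization (penalized when a threshold is active)
        penalized = np.isfinite(config.risk_threshold) and config.penalty > 0
        for _ in range(max(config.max_iters, 0)):
            if eta == 0:
                break
            u_new = update_intervention(u, predictor, h_obs, config,
                                        objective=objective, eta=eta,
                                        penalized=penalized)
            moved = float(np.linalg.norm(u_new - u))
            u = u_new
            if moved < config.convergence_tol:
                break
        if penalized:
            u = project_feasible(u, config)

        pred = predictor.predict(h_obs, u)
        c_u = risk(u, config.interaction_risk)
        d_t = total_deviation(h_obs, config.targets)

        log.u.append(u.copy())
        log.h_obs.append(h_obs)
        log.h_pred.append(np.asarray(pred, dtype=float).copy())
        log.dev.append(dev)
        log.feedback_loss.append(fb)
        log.stability_index.append(si)
        log.converged.append(bool(converged))
        log.total_dev.append(d_t)
        log.eta.append(eta)
        log.constraint.append(c_u)

        eta = adapt_learning_rate(eta, d_t, config.decay)
        if hasattr(predictor, "observe"):
            predictor.observe(h_obs, u)
        try:
            h = _advance_plant(plant, h, u, dt)
        except RuntimeError as err:
            raise RuntimeError(f"{err} (control step {step})") from err
        prev_pred = np.asarray(pred, dtype=float)
        if step >= 1:      # step 0 has no genuine prediction deviation
            prev_dev_norm = dev_norm
    return log
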