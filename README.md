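# endoloop

Simulation, forecasting and closed-loop control of endocrine gland
networks, for computational endocrinologists and control/ML researchers
who need a fully synthetic, reproducible testbed for hormone-regulation
methods.

The package has three layers that mirror how such a system is studied:

1. **Mechanistic simulator** (`endoloop.endocrine_sim`). A directed gland
   network where hormone concentrations evolve as

   ```
   dh_i/dt = Σ_j β_ij g_j(h_j) − γ_i h_i + u_i(t)
   ```

   with signed coupling strengths β_ij (negative entries encode negative
   feedback, e.g. T3 → TRH in the hypothalamic–pituitary–thyroid axis),
   degradation rates γ_i ≥ 0, secretion responses g_j ∈ {identity,
   logistic, Hill}, and rectangular dose pulses u(t). Integration is
   fixed-step classical RK4 with concentrations clamped to ℝ₊; the same
   machinery generates all synthetic datasets (uniform initial states,
   additive Gaussian observation noise, seed-deterministic).

2. **Neural forecaster** (`endoloop.hidn_graph`, `endoloop.hidn_temporal`).
   Per time step, gland states are lifted to feature vectors, mixed by
   attention-modulated graph message passing
   (α_ij = softmax_j LeakyReLU(aᵀ[W h_i ‖ W h_j]), with self-loops and
   unit-L2 row normalization), combined with a two-layer encoding of the
   external stimulus, advanced by a per-gland LSTM with shared gates, and
   read out affinely to ĥ(t+1). Training minimizes one-step-ahead MSE
   with Adam (lr 5·10⁻⁴, ×0.85 decay every 10 epochs, batch 32, dropout
   0.4, early stopping with patience 15, Xavier init, seed 42). Because
   no GPU autodiff framework is assumed, gradients come from the
   package's own reverse-mode engine (`endoloop.autodiff`), verified
   against central finite differences.

3. **Closed-loop controller** (`endoloop.ahrs_control`). Each step:
   observe the plant, predict the response to the intervention u, descend
   the multi-objective loss
   `Σ w_i (h_i − h_i*)² + λ_risk (‖u‖² + Σ_{i≠j} ρ_ij |u_i − u_j|)`,
   enforce the safety constraint C(u) ≤ ε via a hinge penalty plus radial
   projection, decay the learning rate as η ← η·exp(−κ D) with the total
   target deviation D, and log prediction deviations and their ratio (the
   stability index). Patient personalization is Gaussian-Bayesian:
   conjugate updates for linear observation models, gradient ascent on
   the log posterior with a Laplace covariance otherwise.

## Worked example

```python
import numpy as np
from endoloop import (fixture_suite, generate_dataset, HIDNModel,
                      TrainingConfig, train, ControlConfig, PlantPredictor,
                      closed_loop_run)
from endoloop.hidn_temporal import evaluate_loss, split_dataset

# 1. simulate a three-gland network and train the forecaster
net, spec = fixture_suite("random_3g", seed=42)
data = generate_dataset(net, spec)              # 200 noisy trajectories
cfg = TrainingConfig(max_epochs=50, seed=42)
model, history = train(HIDNModel.init(3, net.adjacency(), seed=42), data, cfg)
_, _, test = split_dataset(data, cfg)
print(f"held-out one-step MSE: {evaluate_loss(model, test):.4f}")
print(f"held-out state variance: {np.var(np.concatenate([t.states for t in test])):.4f}")

# 2. drive a linear two-gland plant to clinical targets
plant, _ = fixture_suite("linear_2g")
control = ControlConfig(targets=np.array([0.8, 0.6]), weights=np.ones(2),
                        intervention_lr=0.08)
log = closed_loop_run(plant, PlantPredictor(plant, dt=0.1), control,
                      h0=np.array([1.4, 0.3]), horizon=100, dt=0.1)
print(f"deviation D: {log.total_dev[0]:.3f} -> {log.total_dev[-1]:.2e}")
```

prints

```
held-out one-step MSE: 0.0034
held-out state variance: 0.0686
deviation D: 0.450 -> 6.66e-04
```

i.e. the trained forecaster's one-step error is about 5% of the held-out
state variance (an untrained model sits near 100× that), and the
controller removes 99.85% of the initial squared distance to the hormone
targets within 100 steps.

A command-line interface mirrors the library:

```
endoloop fixtures --name linear_2g --out fix/
endoloop simulate --network fix/network.yaml --horizon 2 --out traj.csv
endoloop make-dataset --spec fix/dataset.yaml --out data/
endoloop train --data data/ --network fix/network.yaml --out model.bundle
endoloop forecast --model model.bundle --init traj.csv --steps 20 --out pred.csv
endoloop control --plant fix/network.yaml --analytic --config control.yaml --out log.csv
```

Every command writes a JSON run manifest (seed, config echo, input/output
digests) next to its output.

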