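# Methods

This note documents the models implemented in `endoloop`, the default
parameters and why they were chosen, the numerical choices that matter,
and what the synthetic experiments do and do not demonstrate.

## Gland-network ODE model

The endocrine system is a directed graph of N glands. The concentration
h_i(t) ∈ ℝ₊ of the hormone secreted by gland i obeys

    dh_i/dt = Σ_j β_ij g_j(h_j) − γ_i h_i + u_i(t).

* **β_ij** (per unit time) is the signed influence of gland j on gland i.
  Positive entries are stimulation, negative entries negative feedback;
  a single signed matrix carries both, so the classic
  hypothalamic–pituitary–thyroid loop (TRH → TSH → T3, T3 ⊣ TRH with
  sensitivity k_TRH) is one coupling matrix with exactly one negative
  entry.
* **g_j** is the secretion response of the source gland, chosen from a
  registry: identity (linear transfer, used wherever a closed-form
  solution is wanted), logistic sigmoid (bounded drive, saturating
  response), and Hill x^n/(K^n + x^n) with K > 0, n ≥ 1 (cooperative
  saturation). The response belongs physiologically to the source gland;
  the container also allows a per-edge assignment as a generalization.
* **γ_i ≥ 0** (per unit time) is first-order hormonal clearance.
* **u(t)** is one stimulus channel per gland; dose pulses are
  rectangular, `μ` on the closed interval [t1, t2] and 0 outside, and
  overlapping pulses on one gland add. Hormone and intervention values
  share arbitrary concentration units.

**Integration.** Fixed-step classical RK4, default output step 0.01 time
units. After each step concentrations are clamped at 0 from below, which
enforces the ℝ₊ state space; all closed-form comparison tests are run in
regimes where the clamp is provably inactive. Any state magnitude above
10¹² raises an integration-failure error naming the blow-up time. The
choice of a fixed-step explicit method keeps runs bit-reproducible and
makes the convergence order measurable (the suite verifies a log–log
error slope in [3.5, 4.5]).

**Synthetic data.** Initial states are drawn uniformly from per-gland
intervals; observation noise is additive i.i.d. Gaussian (sd
`noise_sd`), clamped at 0, applied after integration. A Gaussian
observation model is the simplest one whose scale is recoverable, and
the suite checks the empirical sd to within 5%. Everything is driven by
one `numpy` Generator per dataset, so identical seeds give bitwise
identical datasets. The generator emulates *densely sampled, regularly
spaced, mildly noisy* hormone panels; it does not emulate the sparse
and irregular sampling, assay-specific error structure, circadian
forcing or inter-individual covariates of real clinical series, so
passing results bound method behaviour only under these idealized
conditions.

## Forecaster

Per time step the model composes four stages (graph first, recurrence
second; the stimulus enters the recurrent stage):

1. **Lift.** Scalar concentrations are embedded by a learned linear map
   into d-dimensional node features (default d = 16). The message-passing
   equations act on feature vectors, while the physical state is scalar
   per gland; the lift reconciles the two.
2. **Graph attention.** L layers (default 2) of
   h_i′ = σ(W h_i + Σ_{j∈N(i)} α_ij W h_j) with
   α_ij = softmax over N(i) of LeakyReLU(aᵀ[W h_i ‖ W h_j]),
   negative slope 0.2 (the conventional value for this attention form)
   and σ = ReLU by default (tanh available). The neighborhood of gland i
   is the set of glands that appear as sources in the coupling matrix.
   Self-loops are added to the adjacency *before* attention, so α_ii is
   produced by the softmax itself; adding the identity *after* attention
   is implemented behind a switch (`self_loops="after"`) since both
   orders are defensible readings of a self-loop-augmented attention
   adjacency. The attention logits use the *transformed* features W h —
   the attention vector a then has the fixed length 2·d_out per layer,
   keeping the parameter dimensions consistent across layers; a is
   per-layer, matching the per-layer W. After every layer each nonzero
   feature row is renormalized to unit L2 norm, which prevents repeated
   message passing from amplifying representations; zero rows pass
   through unchanged (the normalization is undefined at 0 and a silent
   NaN would be worse). Normalization is applied within the graph stage
   only, not between the graph and recurrent stages.
3. **Stimulus encoding.** u′ = σ(W2 σ(W1 u + b1) + b2), a two-layer
   perceptron shared by all glands (default hidden 16, output 8).
4. **Recurrence + readout.** One LSTM cell per gland with weights shared
   across glands (hidden width 32 by default) consumes
   [graph feature ‖ u′]; gates are logistic, the cell state blends the
   previous cell and the tanh candidate, and the hidden state is the
   output gate times tanh of the cell. Sharing the gate weights across
   glands matches the single printed weight set of the gate equations and
   curbs overfitting at the problem sizes used here. The stacked hidden
   states are mapped to ĥ(t+1) by an affine readout; an affine map is
   the simplest readout whose behaviour the layer oracles can pin down
   exactly, and nothing in the experiments required more capacity there.

**Training.** Teacher-forced one-step-ahead mean squared error,
averaged over time steps and glands. Defaults: Adam with initial
learning rate 5·10⁻⁴ decayed ×0.85 every 10 epochs, batch size 32, up to
150 epochs with early stopping after 15 non-improving validation epochs
(best-validation weights restored), dropout 0.4 on the graph-stage
outputs (the one stage whose width makes co-adaptation likely), Xavier
uniform initialization, 70/15/15 train/validation/test split by
trajectory, seed 42 everywhere. Trajectories are sliced into
fixed-length windows (default 8 points, stride 1) and batches are drawn
over windows; windowed slicing is the standard way to turn a trajectory
collection into enough optimizer updates at small dataset sizes.
Gradients are clipped at global norm 5 as divergence insurance.
Training is bitwise deterministic given the seed. Gradients come from
the package's reverse-mode autodiff engine; the suite checks every
parameter group against central finite differences (relative error
< 10⁻⁴ at perturbation 10⁻⁵), with the check evaluated at a generically
perturbed parameter point because zero-initialized biases put ReLU
pre-activations exactly on their kink, where a finite difference does
not estimate a derivative.

**Rollout.** Multi-step forecasts feed each prediction back as the next
input (with the recurrent carry propagated); predictions are clamped at
0 when assembled into a trajectory.

## Controller

The closed loop alternates observation, prediction, intervention
optimization and actuation.

* **Predictors.** Either a trained forecaster or a one-step
  forward-Euler model of the gland network. The Euler predictor is
  deliberately coarser than the RK4 plant: the resulting model–plant
  mismatch keeps the prediction deviation Δh = ĥ − h_obs a nonzero,
  decaying signal, so the stability index ‖Δh(t+1)‖/‖Δh(t)‖ is
  informative on converging runs (it sits below 1 while the loop
  converges and is logged as "converged" when the denominator is exactly
  zero). Indices above a flag threshold (default 1.5) are only logged,
  not acted on.
* **Objectives.** The feedback objective is ‖ĥ − h_obs‖²; the
  multi-objective loss is Σ w_i (ĥ_i(u) − h_i*)² + λ_risk R(u) with
  R(u) = ‖u‖² + Σ_{i≠j} ρ_ij |u_i − u_j|. The ‖u‖² term is the *squared*
  L2 norm, matching the squared-norm convention of the feedback loss —
  stated explicitly because the bare notation is ambiguous. The
  subgradient of |u_i − u_j| at ties is taken as 0 (standard convention;
  keeps updates finite).
* **Gradients.** ∇_u is computed by autodiff through the predictor
  (exact for the Euler predictor, whose map is affine in u, and for the
  neural forecaster); central finite differences (step 10⁻⁵) are both
  the fallback for predictors without an autodiff path and the
  independent oracle in the tests.
* **Constraint handling.** The safety set is C(u) ≤ ε with C structurally
  identical to R. Each control step takes `max_iters` gradient steps on
  the hinge-penalized objective (penalty weight λ, default 10⁴); because
  a penalty method alone can terminate marginally outside the feasible
  set, the final intervention is radially rescaled onto the boundary
  whenever C(u) > ε — C(s·u) is continuous and nondecreasing in s ≥ 0,
  so bisection on the scale is an exact projection along the ray. With
  λ = 10⁴ every logged intervention satisfies C(u) ≤ ε + 10⁻⁶.
* **Learning-rate decay.** η ← η·exp(−κ D) with D the summed squared
  target deviation; κ = 0 disables it.
* **Standard demonstration setting.** On the linear two-gland fixture
  the loop runs with dt = 0.1, one gradient step per control step and
  η = 0.08. This gain was chosen to put the closed loop in an
  overdamped regime: the deviation then decays geometrically through
  the whole run (stability index < 1 throughout the final quarter)
  while still removing over 99% of the initial deviation within 100
  steps. Larger gains converge faster but ring, which makes consecutive
  deviation ratios oscillate around 1.
* **Re-observation.** The plant is re-observed every step, so prediction
  chains have length 1; multi-step autoregressive forecasting between
  observations is available through the forecaster's `rollout`, but the
  controller itself always resets on the fresh observation.

## Bayesian personalization

Patient-specific parameters (a chosen subset of couplings and
degradation rates) carry a Gaussian prior. When observations are an
explicitly linear function of the parameters, the posterior is the exact
conjugate Gaussian (precision additivity; the scalar case with prior
N(0,1), one unit-noise direct observation y = 2, gives N(1, 0.5)).
Otherwise the posterior mode is found by gradient ascent on the log
posterior (Gaussian prior plus Gaussian likelihood through the simulated
trajectory) with backtracking on the step size, and the covariance is
the Laplace approximation — the inverse negative Hessian at the mode,
computed by finite differences; a non-positive-definite result raises a
conditioning error rather than returning garbage. Parameter proposals
where the plant diverges are assigned zero posterior support. Restricting
to Gaussian families is a deliberate scope choice: it gives closed-form
or near-closed-form updates whose calibration can actually be tested
(the suite simulates a 20-patient cohort and checks that the truth lies
within 2 posterior sd for at least 16 of 20). The closed loop consumes a
posterior by building its predictor from the posterior means; posterior
refinement itself runs offline between episodes rather than inside the
per-step loop.

## Problem sizes and runtime

All experiments run on one CPU in minutes: the forecaster study uses 200
trajectories of the three-gland fixture (horizon 2.0, step 0.1, noise sd
0.02), trained for up to 50 epochs (~1 min); the control study runs 100
steps; the cohort study 20 patients. These sizes were chosen as the
smallest at which the measured quantities are stable across seeds.

## Known limitations

* The simulator is deterministic first-order kinetics: no delays,
  stochastic secretion, or circadian forcing.
* The forecaster's skill bounds are established on simulator output
  only; nothing here certifies behaviour on clinical data.
* The controller assumes the intervention acts additively on every
  gland's rate and that a dose may be any real number unless a box
  constraint is set; pharmacokinetics are out of scope.
* The personalization machinery is Gaussian-only and approximates
  non-conjugate posteriors by their Laplace expansion at the mode.
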