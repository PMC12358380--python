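"""Forecaster: LSTM cell, stimulus encoder, forward pipeline, training."""

import numpy as np
import pytest

from endoloop.endocrine_sim import (GlandNetwork, SyntheticDatasetSpec,
                                    generate_dataset, integrate)
from endoloop.hidn_graph import gnn_forward
from endoloop.hidn_temporal import (HIDNModel, ReadoutParams, RecurrentParams,
                                    StimulusEncoderParams, TrainingConfig,
                                    encode_stimulus, evaluate_loss,
                                    forward_step, lstm_step, mse_loss, rollout,
                                    save_bundle, load_bundle, train)


def zero_recurrent(d_in, d_h):
    z = lambda *s: np.zeros(s)
    return RecurrentParams(*(z(d_in, d_h) for _ in range(4)),
                           *(z(d_h, d_h) for _ in range(4)),
                           *(z(d_h) for _ in range(4)))


def lstm_oracle(x, s_prev, c_prev, p):
    """Element-by-element scalar-loop evaluation of the gate equations."""
    sig = lambda z: 1 / (1 + np.exp(-z))
    d_h = p.b_f.shape[0]
    s_new, c_new = np.zeros(d_h), np.zeros(d_h)
    for k in range(d_h):
        f = sig(x @ p.W_f[:, k] + s_prev @ p.U_f[:, k] + p.b_f[k])
        i = sig(x @ p.W_i[:, k] + s_prev @ p.U_i[:, k] + p.b_i[k])
        o = sig(x @ p.W_o[:, k] + s_prev @ p.U_o[:, k] + p.b_o[k])
        ct = np.tanh(x @ p.W_c[:, k] + s_prev @ p.U_c[:, k] + p.b_c[k])
        c_new[k] = f * c_prev[k] + i * ct
        s_new[k] = o * np.tanh(c_new[k])
    return s_new, c_new


class TestLSTMStep:
    def test_all_zero_everything(self):
        p = zero_recurrent(2, 3)
        s, c = lstm_step(np.zeros(2), np.zeros(3), np.zeros(3), p)
        np.testing.assert_array_equal(s, 0)
        np.testing.assert_array_equal(c, 0)

    def test_zero_params_halve_previous_cell(self):
        """sigma(0)=1/2 so the cell halves and the output gates tanh."""
        p = zero_recurrent(2, 1)
        s, c = lstm_step(np.zeros(2), np.zeros(1), np.array([2.0]), p)
        assert c[0] == pytest.approx(1.0)
        assert s[0] == pytest.approx(0.5 * np.tanh(1.0), abs=1e-12)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            d_in, d_h = int(rng.integers(1, 4)), int(rng.integers(1, 5))
            p = RecurrentParams(*(rng.normal(size=(d_in, d_h)) for _ in range(4)),
                                *(rng.normal(size=(d_h, d_h)) for _ in range(4)),
                                *(rng.normal(size=d_h) for _ in range(4)))
            x, s0, c0 = (rng.normal(size=d_in), rng.normal(size=d_h),
                         rng.normal(size=d_h))
            s, c = lstm_step(x, s0, c0, p)
            se, ce = lstm_oracle(x, s0, c0, p)
            np.testing.assert_allclose(s, se, atol=1e-12)
            np.testing.assert_allclose(c, ce, atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self):
        """Gate activations stay in (0,1) however extreme the inputs."""
        rng = np.random.default_rng(17)
        p = RecurrentParams(*(rng.normal(size=(2, 3)) * 10 for _ in range(4)),
                            *(rng.normal(size=(3, 3)) * 10 for _ in range(4)),
                            *(rng.normal(size=3) * 10 for _ in range(4)))
        x = np.array([50.0, -80.0])
        s, c = lstm_step(x, np.full(3, 30.0), np.full(3, 5.0), p)
        # |s| = |o * tanh(c)| <= 1, |c| <= f*|c_prev| + i <= |c_prev| + 1
        # (strict in real arithmetic; saturation makes it non-strict in float)
        assert np.all(np.abs(s) <= 1.0)
        assert np.all(np.abs(c) <= 6.0)

    def test_rejects_non_finite(self):
        p = zero_recurrent(1, 1)
        with pytest.raises(ValueError):
            lstm_step(np.array([np.inf]), np.zeros(1), np.zeros(1), p)


class TestStimulusEncoder:
    def test_zero_params_zero_output(self):
        p = StimulusEncoderParams(np.zeros((2, 3)), np.zeros(3),
                                  np.zeros((3, 2)), np.zeros(2))
        np.testing.assert_array_equal(encode_stimulus(np.ones(2), p), 0)

    def test_identity_on_nonnegative(self):
        p = StimulusEncoderParams(np.eye(2), np.zeros(2), np.eye(2), np.zeros(2))
        u = np.array([0.5, 2.0])
        np.testing.assert_array_equal(encode_stimulus(u, p), u)

    def test_matches_composition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = StimulusEncoderParams(rng.normal(size=(3, 4)), rng.normal(size=4),
                                      rng.normal(size=(4, 2)), rng.normal(size=2))
            u = rng.normal(size=3)
            expected = np.maximum(
                np.maximum(u @ p.W1 + p.b1, 0) @ p.W2 + p.b2, 0)
            np.testing.assert_allclose(encode_stimulus(u, p), expected,
                                       atol=1e-12)

    def test_width_mismatch_rejected(self):
        p = StimulusEncoderParams(np.eye(2), np.zeros(2), np.eye(2), np.zeros(2))
        with pytest.raises(ValueError):
            encode_stimulus(np.ones(3), p)


class TestForwardStep:
    @pytest.fixture
    def tiny_model(self):
        return HIDNModel.init(2, np.array([[0, 1], [1, 0]], float), d_embed=2,
                              n_graph_layers=1, d_stimulus=2, encoder_hidden=2,
                              d_hidden=3, dropout=0.0, seed=99)

    def test_constant_readout(self, tiny_model):
        tiny_model.readout = ReadoutParams(np.zeros((6, 2)), np.array([3.0, 7.0]))
        pred, _ = forward_step(tiny_model, np.array([1.0, 2.0]), np.zeros(2),
                               tiny_model.init_carry())
        np.testing.assert_array_equal(pred, [3.0, 7.0])

    def test_pure_function(self, tiny_model):
        args = (np.array([0.5, 1.5]), np.array([0.2, 0.0]),
                tiny_model.init_carry())
        p1, c1 = forward_step(tiny_model, *args)
        p2, c2 = forward_step(tiny_model, *args)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(c1[0], c2[0])

    def test_stage_by_stage_replay(self, tiny_model):
        """Manual lift -> graph -> encode -> lstm -> readout composition."""
        m = tiny_model
        h = np.array([0.8, 0.3])
        u = np.array([0.1, 0.4])
        feats = h[:, None] @ m.lift.weight + m.lift.bias
        feats = gnn_forward(feats, m.adjacency, m.graph)
        u_enc = encode_stimulus(u, m.encoder)
        s_rows, c_rows = [], []
        for i in range(2):
            x_in = np.concatenate([feats[i], u_enc])
            s_i, c_i = lstm_step(x_in, np.zeros(3), np.zeros(3), m.recurrent)
            s_rows.append(s_i)
            c_rows.append(c_i)
        S = np.concatenate(s_rows)
        expected = S @ m.readout.W3 + m.readout.b3
        pred, carry = forward_step(m, h, u, m.init_carry())
        np.testing.assert_allclose(pred, expected, atol=1e-10)
        np.testing.assert_allclose(carry[0], np.stack(s_rows), atol=1e-10)


class TestMSELoss:
    def test_perfect_fit(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        assert mse_loss(x, x) == 0.0

    def test_single_term(self):
        assert mse_loss(np.array([[3.0]]), np.array([[1.0]])) == 4.0

    def test_two_by_two(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert mse_loss(a, np.zeros((2, 2))) == 0.5

    def test_symmetry_and_shape_contract(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        assert mse_loss(a, b) == mse_loss(b, a)
        with pytest.raises(ValueError):
            mse_loss(a, b[:2])


class TestGradients:
    def test_training_gradients_match_finite_differences(self):
        """Backprop through the full pipeline vs central differences, every
        parameter group, on a 2-gland toy model."""
        from endoloop import autodiff as ad
        from endoloop.hidn_temporal import (_model_tensors, _sequence_loss)

        model = HIDNModel.init(2, np.array([[0, 1], [1, 0]], float), d_embed=3,
                               n_graph_layers=1, d_stimulus=2,
                               encoder_hidden=2, d_hidden=3, dropout=0.0,
                               seed=5)
        rng = np.random.default_rng(6)
        # generic parameter point: zero biases sit exactly on relu kinks,
        # where central differences do not estimate a gradient
        model.set_params({k: v + rng.normal(0, 0.05, v.shape)
                          for k, v in model.param_dict().items()})
        states = rng.uniform(0.2, 1.2, size=(2, 4, 2))
        inputs = rng.uniform(0.0, 0.5, size=(2, 4, 2))

        P = _model_tensors(model, requires_grad=True)
        loss = _sequence_loss(model, P, states, inputs)
        loss.backward()

        def loss_at(name, flat):
            params = model.param_dict()
            params = {k: v.copy() for k, v in params.items()}
            params[name] = flat.reshape(params[name].shape)
            probe = HIDNModel.init(2, np.array([[0, 1], [1, 0]], float),
                                   d_embed=3, n_graph_layers=1, d_stimulus=2,
                                   encoder_hidden=2, d_hidden=3, dropout=0.0,
                                   seed=5)
            probe.set_params(params)
            Pp = _model_tensors(probe, requires_grad=False)
            return _sequence_loss(probe, Pp, states, inputs).item()

        eps = 1e-5
        for name, tensor in P.items():
            analytic = tensor.grad
            if analytic is None:
                analytic = np.zeros_like(tensor.value)
            flat = tensor.value.ravel().copy()
            num = np.zeros_like(flat)
            for j in range(flat.size):
                up, dn = flat.copy(), flat.copy()
                up[j] += eps
                dn[j] -= eps
                num[j] = (loss_at(name, up) - loss_at(name, dn)) / (2 * eps)
            denom = max(np.linalg.norm(num), 1e-8)
            rel = np.linalg.norm(analytic.ravel() - num) / denom
            assert rel < 1e-4, f"gradient mismatch for {name}: rel={rel:.2e}"


@pytest.fixture(scope="module")
def overfit_run():
    """Small model fit to one noiseless decay trajectory (duplicated for the
    train/val split)."""
    net = GlandNetwork(["G"], np.zeros((1, 1)), np.array([1.0]))
    traj = integrate(net, np.array([1.5]), None, horizon=5.0, step=0.01)
    config = TrainingConfig(learning_rate=0.03, max_epochs=60, dropout=0.0,
                            window=12, stride=5, split=(50, 25, 25), seed=0,
                            early_stop_patience=60, lr_decay_every=30)
    model = HIDNModel.init(1, np.zeros((1, 1)), d_embed=4, n_graph_layers=1,
                           d_stimulus=2, encoder_hidden=2, d_hidden=8,
                           dropout=0.0, seed=0)
    fitted, history = train(model, [traj, traj, traj, traj], config)
    return net, traj, fitted, history


class TestTrain:
    def test_zero_epochs_is_noop(self):
        model = HIDNModel.init(1, np.zeros((1, 1)), d_embed=2,
                               n_graph_layers=1, d_stimulus=2,
                               encoder_hidden=2, d_hidden=2, seed=1)
        net = GlandNetwork(["G"], np.zeros((1, 1)), np.array([0.5]))
        trajs = generate_dataset(net, SyntheticDatasetSpec(
            4, 1.0, 0.1, [(0.5, 1.0)], 0.0, 3))
        fitted, history = train(model, trajs, TrainingConfig(max_epochs=0))
        for k, v in model.param_dict().items():
            np.testing.assert_array_equal(fitted.param_dict()[k], v)
        assert history == {"train": [], "val": []}

    def test_same_seed_identical_histories(self):
        net = GlandNetwork(["G"], np.zeros((1, 1)), np.array([0.5]))
        trajs = generate_dataset(net, SyntheticDatasetSpec(
            6, 1.0, 0.1, [(0.5, 1.0)], 0.01, 3))
        model = HIDNModel.init(1, np.zeros((1, 1)), d_embed=2,
                               n_graph_layers=1, d_stimulus=2,
                               encoder_hidden=2, d_hidden=2, seed=1)
        cfg = TrainingConfig(max_epochs=3, seed=42)
        _, h1 = train(model, trajs, cfg)
        _, h2 = train(model, trajs, cfg)
        assert h1 == h2

    def test_overfits_noiseless_decay(self, overfit_run):
        _, _, _, history = overfit_run
        assert history["train"][-1] < 1e-3

    def test_empty_dataset_rejected(self):
        model = HIDNModel.init(1, np.zeros((1, 1)), d_embed=2,
                               n_graph_layers=1, d_stimulus=2,
                               encoder_hidden=2, d_hidden=2, seed=1)
        with pytest.raises(ValueError):
            train(model, [], TrainingConfig())


class TestRollout:
    def test_one_step_equals_forward_step(self, ):
        model = HIDNModel.init(2, np.array([[0, 1], [1, 0]], float), d_embed=2,
                               n_graph_layers=1, d_stimulus=2,
                               encoder_hidden=2, d_hidden=2, seed=2)
        h0 = np.array([0.7, 0.9])
        pred, _ = forward_step(model, h0, np.zeros(2), model.init_carry())
        traj = rollout(model, h0, None, steps=1)
        np.testing.assert_allclose(traj.states[1], np.maximum(pred, 0.0),
                                   atol=1e-14)

    def test_constant_readout_fixed_point(self):
        model = HIDNModel.init(2, np.array([[0, 1], [1, 0]], float), d_embed=2,
                               n_graph_layers=1, d_stimulus=2,
                               encoder_hidden=2, d_hidden=2, seed=2)
        model.readout = ReadoutParams(np.zeros((4, 2)), np.array([0.4, 0.2]))
        traj = rollout(model, np.array([1.0, 1.0]), None, steps=5)
        np.testing.assert_array_equal(traj.states[1:],
                                      np.tile([0.4, 0.2], (5, 1)))

    def test_forecast_tracks_decay_dynamics(self, overfit_run):
        """Autoregressive rollout of the fitted model stays within 10% of
        the ODE solution over 20 steps."""
        net, traj, fitted, _ = overfit_run
        steps = 20
        pred = rollout(fitted, traj.states[0], None, steps=steps, dt=0.01)
        truth = traj.states[:steps + 1, 0]
        rel = np.abs(pred.states[:, 0] - truth) / truth
        assert rel.max() < 0.10


class TestBundles:
    def test_save_load_round_trip_idempotent(self, tmp_path):
        model = HIDNModel.init(3, np.ones((3, 3)) - np.eye(3), seed=4)
        p1 = tmp_path / "m1.bundle"
        p2 = tmp_path / "m2.bundle"
        save_bundle(model, p1)
        loaded = load_bundle(p1)
        save_bundle(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for k, v in model.param_dict().items():
            np.testing.assert_array_equal(loaded.param_dict()[k], v)
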