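import dataclasses

import numpy as np
import pytest

from cpgdrnn import (
    DRNNParams,
    TrainingConfig,
    TrainingPattern,
    backward_adjoint,
    cost,
    forward,
    init_params,
    load_params,
    predict,
    save_params,
    train,
    train_restarts,
)
from cpgdrnn.drnn_core import from_net_range, to_net_range
from cpgdrnn.errors import (
    CheckpointFormatError,
    InvalidConfigError,
    StabilityError,
)

DT = 0.01


def _zero_net(n_hidden=1, T=1.0):
    n = 12 + n_hidden
    return DRNNParams(w=np.zeros((n, n)), T=np.full(n, T), I=np.zeros(n), n_hidden=n_hidden)


def _random_net(n_hidden, seed):
    return init_params(n_hidden, np.random.default_rng(seed), TrainingConfig(dt=DT))


def _sine_pattern(n_steps=200, f=1.0, amp=0.8, seed=0):
    t = np.arange(n_steps) * DT
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, 6)
    inputs = np.column_stack([np.sin(2 * np.pi * f * k * t) for k in (1, 1, 2, 2, 3, 3)])
    inputs[:, 1::2] *= -1
    targets = amp * np.column_stack([np.sin(2 * np.pi * f * t + p) for p in phases])
    return TrainingPattern(inputs=inputs, targets=targets, Tc=1.0 / f)


class TestForward:
    def test_relaxation_to_sigmoid_midpoint(self):
        params = _zero_net(T=1.0)
        Y = forward(params, np.zeros((400, 6)), dt=DT, y0=1.0)
        assert np.all(np.diff(Y[:, 0]) <= 1e-12)  # monotone decay
        assert Y[-1, 0] == pytest.approx(0.5, abs=0.03)

    def test_decoupled_units_relax_to_bias_plus_half(self):
        params = _zero_net(T=0.5)
        params.I[:] = 0.3
        Y = forward(params, np.zeros((600, 6)), dt=DT, y0=0.0)
        # fixed point of dy/dt = -y + F(0) + I is 0.8 (input units get drive 0 too)
        np.testing.assert_allclose(Y[-1], 0.8, atol=1e-3)

    def test_grid_refinement_consistency(self):
        """Euler trajectories at dt and dt/10 agree to O(dt)."""
        params = _random_net(2, seed=5)
        t_end = 0.5
        inputs = np.zeros((int(t_end / DT), 6))
        coarse = forward(params, inputs, dt=DT)
        fine = forward(params, np.zeros((int(t_end / 0.001), 6)), dt=0.001)
        err = np.max(np.abs(coarse[-1] - fine[-1]))
        assert err < 5 * DT

    def test_stability_guard(self):
        params = _zero_net(T=0.005)
        with pytest.raises(StabilityError):
            forward(params, np.zeros((10, 6)), dt=DT)


class TestCost:
    def test_perfect_fit_zero(self):
        x = np.random.default_rng(0).normal(size=(50, 6))
        assert cost(x, x, DT) == 0.0

    def test_constant_offset_closed_form(self):
        n = int(1.0 / DT)
        out = np.zeros((n, 6))
        tgt = np.zeros((n, 6))
        out[:, 2] = 0.3
        assert cost(out, tgt, DT) == pytest.approx(0.5 * 0.3**2, rel=1e-9)

    def test_matches_brute_force(self, rng):
        out = rng.normal(size=(40, 6))
        tgt = rng.normal(size=(40, 6))
        brute = sum(
            0.5 * (out[t, i] - tgt[t, i]) ** 2 * DT for t in range(40) for i in range(6)
        )
        assert cost(out, tgt, DT) == pytest.approx(brute, rel=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(InvalidConfigError):
            cost(np.zeros((10, 6)), np.zeros((11, 6)), DT)


class TestAdjoint:
    def test_zero_error_gives_zero_gradients(self):
        params = _zero_net(T=1.0)
        inputs = np.zeros((50, 6))
        Y = forward(params, inputs, dt=DT, y0=0.5)
        targets = Y[:-1, -6:].copy()  # outputs themselves -> e == 0
        adj = backward_adjoint(params, Y, targets, dt=DT, inputs=inputs)
        assert adj.E == 0.0
        np.testing.assert_array_equal(adj.p, 0.0)
        np.testing.assert_array_equal(adj.grad_w, 0.0)
        np.testing.assert_array_equal(adj.grad_T, 0.0)

    def test_boundary_condition(self):
        params = _random_net(1, seed=0)
        inputs = np.random.default_rng(0).normal(size=(30, 6))
        Y = forward(params, inputs, dt=DT)
        adj = backward_adjoint(params, Y, np.zeros((30, 6)), dt=DT, inputs=inputs)
        np.testing.assert_array_equal(adj.p[-1], 0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_central_finite_differences(self, seed):
        r = np.random.default_rng(seed)
        params = _random_net(int(r.integers(1, 4)), seed=seed)
        n_steps = int(r.integers(10, 40))
        t = np.arange(n_steps) * DT
        inputs = np.column_stack([np.sin(2 * np.pi * 2 * t + k) for k in range(6)])
        targets = to_net_range(0.7 * np.column_stack([np.cos(2 * np.pi * t + k) for k in range(6)]))
        Y = forward(params, inputs, dt=DT)
        adj = backward_adjoint(params, Y, targets, dt=DT, inputs=inputs)

        def total_cost(p):
            return cost(forward(p, inputs, dt=DT)[:-1, -6:], targets, DT)

        eps = 1e-5
        n = params.n_units
        for i, j in r.integers(0, n, size=(8, 2)):
            w1, w2 = params.w.copy(), params.w.copy()
            w1[i, j] += eps
            w2[i, j] -= eps
            fd = (
                total_cost(dataclasses.replace(params, w=w1))
                - total_cost(dataclasses.replace(params, w=w2))
            ) / (2 * eps)
            assert adj.grad_w[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-10)
        for i in r.integers(0, n, size=4):
            T1, T2 = params.T.copy(), params.T.copy()
            T1[i] += eps
            T2[i] -= eps
            fd = (
                total_cost(dataclasses.replace(params, T=T1))
                - total_cost(dataclasses.replace(params, T=T2))
            ) / (2 * eps)
            assert adj.grad_T[i] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_gradient_refinement(self):
        """Gradients computed at dt and dt/2 converge toward each other."""
        params = _random_net(1, seed=3)
        t1 = 0.4

        def grad_at(dt):
            n = int(t1 / dt)
            tt = np.arange(n) * dt
            inputs = np.column_stack([np.sin(2 * np.pi * tt + k) for k in range(6)])
            targets = to_net_range(0.5 * np.column_stack([np.cos(2 * np.pi * tt)] * 6))
            Y = forward(params, inputs, dt=dt)
            return backward_adjoint(params, Y, targets, dt=dt, inputs=inputs).grad_w

        g1, g2, g4 = grad_at(0.008), grad_at(0.004), grad_at(0.002)
        d12 = np.abs(g1 - g2).max()
        d24 = np.abs(g2 - g4).max()
        assert d24 < 0.75 * d12  # first-order convergence


class TestTraining:
    def test_easy_task_loss_collapse(self):
        """Passthrough task: loss drops by >= 100x within 2000 iterations."""
        pattern = _sine_pattern(n_steps=150)
        cfg = TrainingConfig(n_iterations=2000, dt=DT, seed=0)
        params, history = train([pattern], 1, cfg)
        assert np.nanmin(history) <= history[0] / 100.0

    def test_loss_trend_non_increasing_windowed(self):
        pattern = _sine_pattern(n_steps=120)
        cfg = TrainingConfig(n_iterations=900, dt=DT, seed=1)
        _, history = train([pattern], 2, cfg)
        med = [np.nanmedian(history[k : k + 300]) for k in (0, 300, 600)]
        assert med[1] <= med[0] and med[2] <= med[1]

    def test_single_pattern_equals_singleton_multipattern(self):
        pattern = _sine_pattern(n_steps=100)
        cfg = TrainingConfig(n_iterations=50, dt=DT, seed=2)
        p1, h1 = train([pattern], 2, cfg)
        p2, h2 = train([pattern], 2, cfg)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(p1.w, p2.w)

    def test_multipattern_order_invariance(self):
        """Summed gradients are pattern-order invariant, so short training
        histories coincide to floating tolerance."""
        a = _sine_pattern(n_steps=100, f=1.0, seed=0)
        b = _sine_pattern(n_steps=80, f=1.25, seed=1)
        cfg = TrainingConfig(n_iterations=30, dt=DT, seed=3, precision="float64")
        _, h_ab = train([a, b], 2, cfg)
        _, h_ba = train([b, a], 2, cfg)
        np.testing.assert_allclose(h_ab, h_ba, rtol=1e-9)

    def test_trained_parameters_finite_and_T_positive(self):
        pattern = _sine_pattern(n_steps=100)
        cfg = TrainingConfig(n_iterations=300, dt=DT, seed=4, lr_w=0.05)
        params, _ = train([pattern], 3, cfg)
        assert np.all(np.isfinite(params.w))
        assert np.all(params.T > DT)


class TestRestarts:
    def test_restart_determinism(self):
        pattern = _sine_pattern(n_steps=100)
        cfg = TrainingConfig(n_iterations=60, n_restarts=3, dt=DT, seed=7)
        b1, t1 = train_restarts([pattern], 2, cfg)
        b2, t2 = train_restarts([pattern], 2, cfg)
        np.testing.assert_array_equal(b1.w, b2.w)
        assert t1.mean_si.tolist() == t2.mean_si.tolist()

    def test_best_of_more_restarts_not_worse(self):
        pattern = _sine_pattern(n_steps=100)
        cfg = TrainingConfig(n_iterations=60, dt=DT, seed=7)
        _, t2 = train_restarts([pattern], 2, cfg, n_restarts=2)
        _, t5 = train_restarts([pattern], 2, cfg, n_restarts=5)
        assert t5.mean_si.max() >= t2.mean_si.max() - 1e-12

    def test_predict_matches_training_forward(self):
        pattern = _sine_pattern(n_steps=100)
        cfg = TrainingConfig(n_iterations=60, dt=DT, seed=5)
        params, _ = train([pattern], 2, cfg)
        p1 = predict(params, pattern.inputs, dt=DT)
        p2 = from_net_range(forward(params, pattern.inputs, dt=DT)[:-1, -6:])
        np.testing.assert_array_equal(p1, p2)

    def test_zero_input_relaxes_to_autonomous_fixed_point(self):
        params = _zero_net(T=0.2)
        out = predict(params, np.zeros((500, 6)), dt=DT)
        # y -> F(0) = 0.5 in network space -> 0 in normalized space
        np.testing.assert_allclose(out[-1], 0.0, atol=1e-6)


class TestCapacity:
    def test_median_si_non_decreasing_in_hidden_units(self):
        """More hidden units do not hurt the best-restart similarity index
        (median over generator seeds) on a fixed single-velocity task."""
        from cpgdrnn import GaitGenConfig, generate_trial
        from cpgdrnn.experiments import prepare_pattern

        medians = {}
        sis = {h: [] for h in (1, 4, 20)}
        for seed in (0, 1):
            trial = generate_trial(
                GaitGenConfig(velocity_kmh=3.0, duration_s=20.0, seed=seed)
            )
            prep = prepare_pattern(trial, variant="AM")
            prep.pattern.inputs = prep.pattern.inputs / max(prep.spec.amplitudes)
            for h in sis:
                cfg = TrainingConfig(n_iterations=800, n_restarts=2, dt=DT, seed=100 + seed)
                _, table = train_restarts([prep.pattern], h, cfg)
                sis[h].append(table.mean_si.max())
        medians = {h: float(np.median(v)) for h, v in sis.items()}
        assert medians[1] <= medians[4] <= medians[20]


class TestCheckpoint:
    def test_round_trip_byte_identical(self, tmp_path):
        params = _random_net(3, seed=8)
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        save_params(params, p1, config={"note": "unit-test"})
        back = load_params(p1)
        save_params(back, p2, config={"note": "unit-test"})
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(back.w, params.w)
        np.testing.assert_array_equal(back.T, params.T)

    def test_forward_identical_after_round_trip(self, tmp_path):
        params = _random_net(2, seed=9)
        save_params(params, tmp_path / "m.json")
        back = load_params(tmp_path / "m.json")
        inputs = np.random.default_rng(0).normal(size=(50, 6))
        np.testing.assert_array_equal(
            forward(params, inputs, dt=DT), forward(back, inputs, dt=DT)
        )

    def test_corrupted_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(CheckpointFormatError):
            load_params(bad)
        bad.write_text('{"format": "something-else"}')
        with pytest.raises(CheckpointFormatError):
            load_params(bad)


def test_target_range_round_trip(rng):
    y = rng.uniform(-1, 1, size=(20, 6))
    np.testing.assert_allclose(from_net_range(to_net_range(y)), y, atol=1e-12)
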