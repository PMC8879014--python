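"""Swarm optimizer: update rule, bookkeeping, convergence, hybrid training."""

import numpy as np
import pytest

from aquametal import metrics
from aquametal.network import decode, encode, forward, n_parameters
from aquametal.preprocessing import split_dataset
from aquametal.pso import (
    PSOConfig,
    SwarmState,
    fitness,
    init_swarm,
    optimize,
    refine,
    step,
    train,
)


def sphere(p):
    return np.sum(p**2, axis=1)


def make_state(positions, velocities, fitness_fn):
    fit = fitness_fn(positions)
    best = int(np.argmin(fit))
    return SwarmState(
        positions=positions.astype(float),
        velocities=velocities.astype(float),
        pbest_positions=positions.copy().astype(float),
        pbest_fitness=fit.copy(),
        gbest_position=positions[best].astype(float).copy(),
        gbest_fitness=float(fit[best]),
    )


class TestStep:
    def test_hand_computed_update(self):
        # X = 1, V = 0.5, inertia 1, no attraction: V_new = 0.5, X_new = 1.5
        state = make_state(np.array([[1.0]]), np.array([[0.5]]), sphere)
        cfg = PSOConfig(swarm_size=1, inertia=1.0, c_cognitive=0.0, c_social=0.0)
        new = step(state, cfg, np.random.default_rng(0), sphere)
        assert new.velocities[0, 0] == pytest.approx(0.5)
        assert new.positions[0, 0] == pytest.approx(1.5)

    def test_zero_coefficients_freeze_swarm(self):
        pos = np.array([[0.3, -0.4], [1.0, 2.0]])
        state = make_state(pos, np.zeros_like(pos), sphere)
        cfg = PSOConfig(swarm_size=2, inertia=0.0, c_cognitive=0.0, c_social=0.0)
        new = step(state, cfg, np.random.default_rng(0), sphere)
        np.testing.assert_array_equal(new.positions, pos)
        np.testing.assert_array_equal(new.velocities, np.zeros_like(pos))

    def test_single_particle_at_global_best_stays_put(self):
        state = make_state(np.array([[0.7, 0.7]]), np.zeros((1, 2)), sphere)
        cfg = PSOConfig(swarm_size=1)
        new = step(state, cfg, np.random.default_rng(1), sphere)
        np.testing.assert_array_equal(new.positions, state.positions)

    def test_velocity_clamp_and_position_bounds(self):
        state = make_state(np.array([[9.9]]), np.array([[5.0]]), sphere)
        cfg = PSOConfig(
            swarm_size=1, inertia=1.0, c_cognitive=0.0, c_social=0.0,
            velocity_clamp=1.0, position_bounds=(-10, 10),
        )
        new = step(state, cfg, np.random.default_rng(0), sphere)
        assert abs(new.velocities[0, 0]) <= 1.0
        assert new.positions[0, 0] <= 10.0

    def test_geometric_velocity_decay(self):
        # lone particle at its best with inertia < 1: v_t = w^t * v_0
        w, v0 = 0.8, 0.5
        state = make_state(np.array([[0.0, 0.0]]), np.array([[v0, 0.0]]), sphere)
        cfg = PSOConfig(swarm_size=1, inertia=w, c_cognitive=0.0, c_social=0.0)
        rng = np.random.default_rng(0)
        v = v0
        for t in range(5):
            state = step(state, cfg, rng, sphere)
            v *= w
            assert state.velocities[0, 0] == pytest.approx(v)


class TestBookkeeping:
    def test_gbest_fitness_never_increases(self):
        cfg = PSOConfig(swarm_size=8, iterations=200, seed=3)
        _, _, hist = optimize(sphere, 5, cfg)
        g = [h["gbest_fitness"] for h in hist]
        assert all(a >= b - 1e-15 for a, b in zip(g, g[1:]))

    def test_pbest_gbest_match_brute_force_history(self):
        """Replay a short run and recompute the bests from raw positions."""
        cfg = PSOConfig(swarm_size=5, iterations=20, seed=11)
        rng = np.random.default_rng(cfg.seed)
        state = init_swarm(sphere, 3, cfg, rng)
        history = [state.positions.copy()]
        for _ in range(20):
            state = step(state, cfg, rng, sphere)
            history.append(state.positions.copy())
        all_pos = np.stack(history)                   # (T+1, S, D)
        fits = np.array([sphere(p) for p in all_pos])  # (T+1, S)
        expected_pbest = fits.min(axis=0)
        np.testing.assert_allclose(state.pbest_fitness, expected_pbest, atol=1e-14)
        assert state.gbest_fitness == pytest.approx(fits.min(), abs=1e-14)

    def test_optimize_deterministic_under_seed(self):
        cfg = PSOConfig(swarm_size=6, iterations=50, seed=21)
        p1, f1, _ = optimize(sphere, 4, cfg)
        p2, f2, _ = optimize(sphere, 4, cfg)
        np.testing.assert_array_equal(p1, p2)
        assert f1 == f2


class TestConvergence:
    def test_sphere_ten_dimensional(self):
        cfg = PSOConfig(swarm_size=10, iterations=2000, seed=42)
        pos, _, _ = optimize(sphere, 10, cfg)
        assert np.linalg.norm(pos) < 1e-3


class TestFitness:
    def test_equals_mse_of_decoded_network(self, rng):
        hn = 6
        vec = rng.normal(size=n_parameters(hn))
        x = rng.uniform(-1, 1, size=(30, 4))
        y = rng.uniform(-1, 1, size=30)
        pred = forward(decode(vec, hn), x)
        assert fitness(vec, hn, x, y) == pytest.approx(
            metrics.mse(y, pred), abs=1e-12
        )

    def test_order_invariant_and_empty_rejected(self, rng):
        hn = 2
        vec = rng.normal(size=n_parameters(hn))
        x = rng.uniform(-1, 1, size=(10, 4))
        y = rng.uniform(-1, 1, size=10)
        perm = rng.permutation(10)
        assert fitness(vec, hn, x, y) == pytest.approx(
            fitness(vec, hn, x[perm], y[perm]), abs=1e-14
        )
        with pytest.raises(ValueError, match="empty"):
            fitness(vec, hn, x[:0], y[:0])


class TestTrain:
    def test_deterministic_under_seed(self, campaign):
        y = campaign["norm"]["cr"].to_numpy()
        cfg = PSOConfig(iterations=60, seed=5)
        m1 = train(campaign["x"], y, campaign["split"], 5, cfg)
        m2 = train(campaign["x"], y, campaign["split"], 5, cfg)
        np.testing.assert_array_equal(encode(m1.params), encode(m2.params))
        assert m1.best_val_mse == m2.best_val_mse

    def test_parameter_recovery_from_known_network(self, rng):
        """Data from a known 4-2-1 net (noise sd 0.01) is recovered to R >= 0.99."""
        from aquametal.network import NetworkParameters

        gen = np.random.default_rng(7)
        true = NetworkParameters(
            gen.normal(size=(2, 4)), gen.normal(size=2), gen.normal(size=2), 0.2
        )
        x = gen.uniform(-1, 1, size=(80, 4))
        y = forward(true, x) + gen.normal(0, 0.01, size=80)
        split = split_dataset(80, seed=1)
        model = train(x, y, split, 2, PSOConfig(iterations=500, seed=9))
        pred = forward(model.params, x[split.validation])
        assert metrics.pearson_r(y[split.validation], pred) >= 0.99

    def test_invalid_hidden_count_rejected(self, campaign):
        with pytest.raises(ValueError):
            train(
                campaign["x"],
                campaign["norm"]["cr"].to_numpy(),
                campaign["split"],
                31,
                PSOConfig(iterations=5),
            )


class TestRefine:
    def _toy_model(self, campaign, refine_flag):
        y = campaign["norm"]["cd"].to_numpy()
        cfg = PSOConfig(iterations=40, seed=2, refine=refine_flag)
        return train(campaign["x"], y, campaign["split"], 4, cfg), y

    def test_never_worsens_validation_error(self, campaign):
        model, y = self._toy_model(campaign, False)
        s = campaign["split"]
        out = refine(
            model,
            campaign["x"][s.train], y[s.train],
            campaign["x"][s.validation], y[s.validation],
        )
        assert out.best_val_mse <= model.best_val_mse

    def test_disabled_flag_returns_unrefined_model(self, campaign):
        model, _ = self._toy_model(campaign, False)
        assert model.refined is False

    def test_quadratic_fit_reaches_machine_precision(self, rng):
        """A linear-in-parameters target is solved exactly in a few steps."""
        from aquametal.network import NetworkParameters
        from aquametal.pso import TrainedModel

        # with w_in = 0 the model is pred = b_out: fitting the mean is the
        # closed-form optimum of this quadratic-in-b_out fitness
        x = rng.uniform(-1, 1, size=(20, 4))
        y = np.full(20, 0.37)
        start = NetworkParameters(np.zeros((1, 4)), np.zeros(1), np.zeros(1), 0.0)
        model = TrainedModel(
            params=start, hn=1, history=[], seed=0,
            final_fitness=metrics.mse(y, forward(start, x)),
            best_val_mse=metrics.mse(y, forward(start, x)),
        )
        out = refine(model, x, y, x, y)
        assert out.final_fitness < 1e-12
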