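"""Hybrid network training: particle-swarm search over the flat weight
vector, early stopping on validation error, and optional damped
Gauss-Newton (Levenberg-Marquardt-style) refinement.

The swarm minimizes the fitness E(w, b) = (1/S) * sum_k (T_k - P_k)^2 over
the S training samples — identical to the training-partition MSE for a
single-output network.  Velocity and position updates follow

    V_new = w*V + C_a*r_a*(pbest - X) + C_b*r_b*(gbest - X)
    X_new = X + V_new

with componentwise uniform r_a, r_b, velocity clamping, and position
clipping to a bounded box (bounded weights keep the tansig units out of
deep saturation).  The returned model is the global best with the lowest
validation MSE seen during the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import metrics
from .network import (
    N_INPUTS,
    NetworkParameters,
    batch_forward,
    decode,
    encode,
    forward,
    n_parameters,
)

__all__ = [
    "PSOConfig",
    "SwarmState",
    "TrainedModel",
    "fitness",
    "init_swarm",
    "step",
    "optimize",
    "train",
    "refine",
]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters.

    Defaults use the standard constriction values (inertia 0.729,
    accelerations 1.49445); iteration budget 2000 with early stopping after
    200 validation-stagnant iterations.
    """

    swarm_size: int = 10
    iterations: int = 2000
    inertia: float = 0.729
    c_cognitive: float = 1.49445
    c_social: float = 1.49445
    position_bounds: tuple[float, float] = (-10.0, 10.0)
    velocity_clamp: float = 1.0
    init_position_range: tuple[float, float] = (-1.0, 1.0)
    init_velocity_range: tuple[float, float] = (-0.1, 0.1)
    seed: int = 0
    early_stop_patience: int = 200
    refine: bool = True

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.inertia < 0 or self.c_cognitive < 0 or self.c_social < 0:
            raise ValueError("inertia and accelerations must be >= 0")


@dataclass
class SwarmState:
    """Positions, velocities, and best-so-far bookkeeping."""

    positions: np.ndarray      # (S, D)
    velocities: np.ndarray     # (S, D)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray  # (S,)
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0


@dataclass
class TrainedModel:
    """PSO-trained network plus its training history."""

    params: NetworkParameters
    hn: int
    history: list[dict]        # per-iteration gbest fitness / validation MSE
    seed: int
    final_fitness: float
    best_val_mse: float
    refined: bool = False


def fitness(vector: np.ndarray, hn: int, features: np.ndarray, targets: np.ndarray) -> float:
    """Training fitness of one flat parameter vector (mean squared error)."""
    t = np.asarray(targets, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("empty training sample set")
    pred = forward(decode(np.asarray(vector, float), hn), features)
    return metrics.mse(t, pred)


def _swarm_fitness(
    positions: np.ndarray, hn: int, features: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    t = np.asarray(targets, dtype=float).ravel()
    pred = batch_forward(positions, hn, features)
    return np.mean((pred - t[None, :]) ** 2, axis=1)


def init_swarm(
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    dim: int,
    config: PSOConfig,
    rng: np.random.Generator,
) -> SwarmState:
    lo, hi = config.init_position_range
    vlo, vhi = config.init_velocity_range
    pos = rng.uniform(lo, hi, size=(config.swarm_size, dim))
    vel = rng.uniform(vlo, vhi, size=(config.swarm_size, dim))
    fit = np.asarray(fitness_fn(pos), dtype=float)
    best = int(np.argmin(fit))
    return SwarmState(
        positions=pos,
        velocities=vel,
        pbest_positions=pos.copy(),
        pbest_fitness=fit.copy(),
        gbest_position=pos[best].copy(),
        gbest_fitness=float(fit[best]),
    )


def step(
    state: SwarmState,
    config: PSOConfig,
    rng: np.random.Generator,
    fitness_fn: Callable[[np.ndarray], np.ndarray],
) -> SwarmState:
    """One synchronous swarm update; gbest fitness never increases."""
    s, d = state.positions.shape
    r_a = rng.uniform(size=(s, d))
    r_b = rng.uniform(size=(s, d))
    vel = (
        config.inertia * state.velocities
        + config.c_cognitive * r_a * (state.pbest_positions - state.positions)
        + config.c_social * r_b * (state.gbest_position[None, :] - state.positions)
    )
    clamp = config.velocity_clamp
    vel = np.clip(vel, -clamp, clamp)
    lo, hi = config.position_bounds
    pos = np.clip(state.positions + vel, lo, hi)
    fit = np.asarray(fitness_fn(pos), dtype=float)

    improved = fit < state.pbest_fitness
    pbest_pos = np.where(improved[:, None], pos, state.pbest_positions)
    pbest_fit = np.where(improved, fit, state.pbest_fitness)
    best = int(np.argmin(pbest_fit))
    if pbest_fit[best] < state.gbest_fitness:
        gbest_pos, gbest_fit = pbest_pos[best].copy(), float(pbest_fit[best])
    else:
        gbest_pos, gbest_fit = state.gbest_position, state.gbest_fitness
    return SwarmState(
        positions=pos,
        velocities=vel,
        pbest_positions=pbest_pos,
        pbest_fitness=pbest_fit,
        gbest_position=gbest_pos,
        gbest_fitness=gbest_fit,
        iteration=state.iteration + 1,
    )


def optimize(
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    dim: int,
    config: PSOConfig,
    monitor: Callable[[SwarmState], float] | None = None,
) -> tuple[np.ndarray, float, list[dict]]:
    """Minimize an arbitrary vectorized fitness function with the swarm.

    ``monitor``, if given, maps the state to a validation-style score each
    iteration; the run stops early after ``early_stop_patience`` iterations
    without monitor improvement and the monitor-best position is recorded
    in the history.  Returns (gbest_position, gbest_fitness, history).
    """
    rng = np.random.default_rng(config.seed)
    state = init_swarm(fitness_fn, dim, config, rng)
    history: list[dict] = []
    best_score = np.inf
    best_pos = state.gbest_position.copy()
    stagnant = 0
    for _ in range(config.iterations):
        state = step(state, config, rng, fitness_fn)
        rec = {"iteration": state.iteration, "gbest_fitness": state.gbest_fitness}
        if monitor is not None:
            score = float(monitor(state))
            rec["val_mse"] = score
            if score < best_score - 1e-15:
                best_score, best_pos, stagnant = score, state.gbest_position.copy(), 0
            else:
                stagnant += 1
        history.append(rec)
        if monitor is not None and stagnant >= config.early_stop_patience:
            break
    if monitor is None:
        best_pos, best_score = state.gbest_position.copy(), state.gbest_fitness
    return best_pos, float(best_score), history


def train(
    x: np.ndarray,
    y: np.ndarray,
    split,
    hn: int,
    config: PSOConfig,
) -> TrainedModel:
    """Train one 4-hn-1 network on normalized data.

    x, y : full normalized feature matrix / target vector
    split : SplitIndices; fitness uses the training rows, early stopping
        and model selection use the validation rows.
    """
    if not 1 <= hn <= 30:
        raise ValueError("hn must be in [1, 30]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    xt, yt = x[split.train], y[split.train]
    xv, yv = x[split.validation], y[split.validation]
    if len(yt) == 0 or len(yv) == 0:
        raise ValueError("empty training or validation partition")
    dim = n_parameters(hn)

    def swarm_fit(positions: np.ndarray) -> np.ndarray:
        return _swarm_fitness(positions, hn, xt, yt)

    def monitor(state: SwarmState) -> float:
        pred = forward(decode(state.gbest_position, hn), xv)
        return metrics.mse(yv, pred)

    best_pos, best_val, history = optimize(swarm_fit, dim, config, monitor)
    model = TrainedModel(
        params=decode(best_pos, hn),
        hn=hn,
        history=history,
        seed=config.seed,
        final_fitness=fitness(best_pos, hn, xt, yt),
        best_val_mse=best_val,
    )
    if config.refine:
        model = refine(model, xt, yt, xv, yv)
    return model


def _residual_jacobian(vec: np.ndarray, hn: int, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the per-sample residuals w.r.t. the flat vector."""
    params = decode(vec, hn)
    h = np.tanh(x @ params.w_in.T + params.b_hidden)      # (n, hn)
    dtanh = 1.0 - h**2
    n = x.shape[0]
    jac = np.empty((n, n_parameters(hn)))
    k = N_INPUTS * hn
    # d pred / d w_in[h, i] = w_out[h] * (1 - h^2) * x_i
    jac[:, :k] = ((params.w_out * dtanh)[:, :, None] * x[:, None, :]).reshape(n, k)
    jac[:, k:k + hn] = params.w_out * dtanh
    jac[:, k + hn:k + 2 * hn] = h
    jac[:, -1] = 1.0
    return jac


def refine(
    model: TrainedModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    max_iter: int = 60,
    n_restarts: int = 2,
) -> TrainedModel:
    """Levenberg-Marquardt refinement of the swarm solution.

    Runs a damped Gauss-Newton descent on the training fitness from the
    swarm solution and from ``n_restarts`` deterministically jittered
    copies of it (the swarm can park in a shallow basin), monitoring
    validation MSE at every accepted step and keeping the iterate with the
    lowest validation error (training halts at the moment of lowest error).
    Never returns a model with higher validation MSE than its input.
    """
    hn = model.hn
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float).ravel()
    x_val = np.asarray(x_val, float)
    y_val = np.asarray(y_val, float).ravel()

    start = encode(model.params)
    dim = start.size
    jitter_rng = np.random.default_rng(np.random.SeedSequence([model.seed, 97]))
    starts = [start] + [
        start + jitter_rng.normal(0.0, 0.3, size=dim) for _ in range(n_restarts)
    ]
    best_vec, best_val = None, model.best_val_mse

    for vec in starts:
        vec = vec.copy()
        resid = forward(decode(vec, hn), x_train) - y_train
        sse = float(resid @ resid)
        lam = 1e-2
        for _ in range(max_iter):
            jac = _residual_jacobian(vec, hn, x_train)
            jtj = jac.T @ jac
            jtr = jac.T @ resid
            stepped = False
            for _ in range(10):  # adapt damping until the step decreases SSE
                try:
                    delta = np.linalg.solve(jtj + lam * np.eye(dim), -jtr)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                trial = vec + delta
                trial_resid = forward(decode(trial, hn), x_train) - y_train
                trial_sse = float(trial_resid @ trial_resid)
                if trial_sse < sse:
                    vec, resid, sse = trial, trial_resid, trial_sse
                    lam = max(lam / 3.0, 1e-12)
                    stepped = True
                    break
                lam *= 4.0
            if not stepped:
                break
            val_mse = metrics.mse(y_val, forward(decode(vec, hn), x_val))
            if val_mse < best_val:
                best_val, best_vec = val_mse, vec.copy()
            if sse / len(y_train) < 1e-16:
                break

    if best_vec is None:
        return model
    refined_params = decode(best_vec, hn)
    return replace(
        model,
        params=refined_params,
        final_fitness=metrics.mse(y_train, forward(refined_params, x_train)),
        best_val_mse=best_val,
        refined=True,
    )
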