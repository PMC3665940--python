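"""Dynamic recurrent neural network with trainable weights and time constants.

Continuous-time units obey ``T_i dy_i/dt = -y_i + F(x_i) + I_i`` with
``x_i = sum_j w_ij y_j`` and logistic squashing ``F``; integration is explicit
Euler on the kinematic sample grid.  Gradients of the integrated squared
output error with respect to every synaptic weight and time constant are
computed by an adjoint (backward) pass that is the exact discrete transpose
of the Euler forward pass, so they match finite differences to rounding
error and converge to the continuous adjoint equations as dt -> 0.  Training
uses per-parameter adaptive learning rates in the style of Almeida: a
parameter's rate grows geometrically while successive gradient signs agree
and collapses when they flip.  Time constants are optimized in log space,
which keeps them positive by construction.

Units are ordered [6 input, N hidden, 6 output].  Input units receive the
oscillator channels through their external input I_i(t); biases of hidden and
output units are fixed at zero.  Because unit activations relax toward the
(0, 1) range of F, targets normalized to [-1, 1] are trained against their
affine image in [0.1, 0.9] and predictions are mapped back before any
similarity or covariation analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import (
    CheckpointFormatError,
    DivergenceError,
    InvalidConfigError,
    StabilityError,
    TrainingFailedError,
)
from .harmonic_features import SineInputSet

N_IN = 6
N_OUT = 6
#: affine image of the [-1, 1] target range inside the unit activation range
OUTPUT_LOW, OUTPUT_HIGH = 0.1, 0.9
_TGT_SCALE = (OUTPUT_HIGH - OUTPUT_LOW) / 2.0  # 0.4
_TGT_OFFSET = (OUTPUT_HIGH + OUTPUT_LOW) / 2.0  # 0.5

CHECKPOINT_VERSION = 1


def to_net_range(y: np.ndarray) -> np.ndarray:
    """Map [-1, 1] targets into the trainable activation band [0.1, 0.9]."""
    return _TGT_OFFSET + _TGT_SCALE * np.asarray(y, float)


def from_net_range(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_net_range`."""
    return (np.asarray(y, float) - _TGT_OFFSET) / _TGT_SCALE


@dataclass
class DRNNParams:
    """Full parameter set: weight matrix ``w`` (w[i, j] feeds unit j's state
    into unit i), per-unit time constants ``T`` (seconds), fixed biases ``I``,
    and the input/hidden/output partition."""

    w: np.ndarray
    T: np.ndarray
    I: np.ndarray
    n_hidden: int

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        n = self.n_units
        if self.w.shape != (n, n) or self.T.shape != (n,) or self.I.shape != (n,):
            raise InvalidConfigError("inconsistent parameter shapes")
        if np.any(self.T <= 0):
            raise InvalidConfigError("time constants must be positive")
        if not (np.all(np.isfinite(self.w)) and np.all(np.isfinite(self.T))):
            raise InvalidConfigError("non-finite parameters")

    @property
    def n_units(self) -> int:
        return N_IN + self.n_hidden + N_OUT

    @property
    def input_slice(self) -> slice:
        return slice(0, N_IN)

    @property
    def output_slice(self) -> slice:
        return slice(self.n_units - N_OUT, self.n_units)

    @property
    def roles(self) -> list[str]:
        return ["input"] * N_IN + ["hidden"] * self.n_hidden + ["output"] * N_OUT


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and integration settings.

    ``dt`` is the Euler step (seconds), equal to the kinematic sample interval.
    ``lr_w`` / ``lr_T`` are initial per-parameter rates for weights and log
    time constants; ``up`` / ``down`` the Almeida rate multipliers on gradient
    sign agreement / reversal, with rates clamped to [rate_min, rate_max].
    ``T_init_range`` bounds the log-uniform time-constant initialization and
    ``T_floor_factor * dt`` is the smallest admissible time constant (explicit
    Euler needs dt / T < 1).
    """

    n_iterations: int = 5_000
    n_restarts: int = 1
    dt: float = 0.01
    lr_w: float = 0.005
    lr_T: float = 0.005
    up: float = 1.2
    down: float = 0.5
    rate_min: float = 1e-7
    rate_max: float = 0.05
    weight_scale: float = 0.5
    T_init_range: tuple[float, float] = (0.03, 0.3)
    T_floor_factor: float = 1.5
    y0: float = 0.5
    seed: int | None = None
    max_recoveries: int = 3
    #: floating precision of the training loop; single precision roughly
    #: halves the wall time of large runs, and the sign-based updates are
    #: insensitive to the extra rounding.  Gradient verification against
    #: finite differences always runs in double precision via the public
    #: forward / backward_adjoint API.
    precision: str = "float32"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidConfigError("dt must be positive")
        if np.dtype(self.precision).kind != "f":
            raise InvalidConfigError("precision must be a floating dtype")
        if not (self.up > 1.0 > self.down > 0.0):
            raise InvalidConfigError("need up factor > 1 > down factor > 0")
        if self.n_iterations < 1 or self.n_restarts < 1:
            raise InvalidConfigError("iteration and restart counts must be >= 1")


@dataclass
class TrainingPattern:
    """One input -> target pair: oscillator drive for the six input units and
    normalized ([-1, 1]) six-channel target waveforms.

    The first ``washout_steps`` input samples are a lead-in that carries no
    cost: the network is driven toward its oscillatory regime before the
    scored window begins (the similarity index is defined on the limit
    cycle, not on the cold-start transient).  ``targets`` covers only the
    scored window, so ``len(inputs) == washout_steps + len(targets)``.
    """

    inputs: np.ndarray  # (washout_steps + n_scored, 6)
    targets: np.ndarray  # (n_scored, 6), in [-1, 1]
    Tc: float  # gait-cycle period (s), used for SI-based selection
    label: str = ""
    washout_steps: int = 0

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.inputs.shape[1] != N_IN:
            raise InvalidConfigError("pattern inputs must be (n_steps, 6)")
        if self.washout_steps < 0:
            raise InvalidConfigError("washout_steps must be non-negative")
        if self.targets.ndim != 2 or self.targets.shape[1] != N_OUT:
            raise InvalidConfigError("pattern targets must be (n_scored, 6)")
        if self.targets.shape[0] + self.washout_steps != self.inputs.shape[0]:
            raise InvalidConfigError(
                "inputs must span washout_steps + len(targets) samples"
            )

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_scored(self) -> int:
        return self.targets.shape[0]


@dataclass
class AdjointState:
    """Adjoint trajectory and accumulated gradients for one forward run."""

    p: np.ndarray  # (n_steps + 1, n_units); p[-1] == 0 (boundary condition)
    e: np.ndarray  # (n_steps, n_units) cost gradient d q / d y
    E: float
    grad_w: np.ndarray  # (n, n)
    grad_T: np.ndarray  # (n,)


def init_params(
    n_hidden: int, rng: np.random.Generator, config: TrainingConfig | None = None
) -> DRNNParams:
    """Fresh network: weights i.i.d. uniform in [-scale, scale], time constants
    log-uniform in ``T_init_range``, biases zero."""
    cfg = config if config is not None else TrainingConfig()
    n = N_IN + n_hidden + N_OUT
    w = rng.uniform(-cfg.weight_scale, cfg.weight_scale, size=(n, n))
    lo, hi = cfg.T_init_range
    T = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    return DRNNParams(w=w, T=np.maximum(T, cfg.T_floor_factor * cfg.dt), I=np.zeros(n), n_hidden=n_hidden)


def _external_input(params_n: int, inputs: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """(n_steps, n_units) external drive: oscillator channels on the input
    units plus the static bias vector."""
    n_steps = inputs.shape[0]
    I = np.tile(bias, (n_steps, 1))
    I[:, :N_IN] += inputs
    return I


def forward(
    params: DRNNParams,
    inputs: SineInputSet | np.ndarray,
    dt: float = 0.01,
    horizon: int | None = None,
    y0: float = 0.5,
) -> np.ndarray:
    """Integrate the network with explicit Euler.

    Returns the full state trajectory, shape ``(n_steps + 1, n_units)``;
    ``y[t]`` is the state after ``t`` steps, ``y[0] = y0`` for every unit.
    Raises :class:`StabilityError` if ``dt >= min(T)`` and
    :class:`DivergenceError` on non-finite states.
    """
    x = inputs.data if isinstance(inputs, SineInputSet) else np.asarray(inputs, float)
    if x.ndim != 2 or x.shape[1] != N_IN:
        raise InvalidConfigError("inputs must provide 6 channels")
    n_steps = x.shape[0] if horizon is None else int(horizon)
    if n_steps > x.shape[0]:
        raise InvalidConfigError("horizon exceeds the input length")
    if dt >= params.T.min():
        raise StabilityError(
            f"dt={dt} >= min time constant {params.T.min():.4g}; Euler unstable"
        )
    I = _external_input(params.n_units, x[:n_steps], params.I)
    Y, _ = _forward_core(
        params.w[None], params.T[None], I[:, None, None, :], dt, y0, store_f=False
    )
    traj = Y[:, 0, 0, :]
    if not np.all(np.isfinite(traj)):
        raise DivergenceError("network state diverged during integration")
    return traj


def _forward_core(
    W: np.ndarray,  # (R, n, n)
    T: np.ndarray,  # (R, n)
    I: np.ndarray,  # (n_steps, 1 or R, P, n) external input
    dt: float,
    y0: float,
    store_f: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Batched Euler integration over restart (R) and pattern (P) lanes.
    Returns (Y, F) with Y of shape (n_steps+1, R, P, n); F holds the squashed
    drives F(x_t) when requested (needed by the adjoint pass)."""
    n_steps = I.shape[0]
    R, n = T.shape
    P = I.shape[2]
    a = (dt / T)[:, None, :]  # (R, 1, n)
    WT = W.transpose(0, 2, 1)
    Y = np.empty((n_steps + 1, R, P, n))
    F = np.empty((n_steps, R, P, n)) if store_f else None
    y = np.full((R, P, n), float(y0))
    Y[0] = y
    for t in range(n_steps):
        f = expit(np.matmul(y, WT))
        if store_f:
            F[t] = f
        y = y + a * (f - y + I[t])
        Y[t + 1] = y
    return Y, F


def cost(outputs: np.ndarray, targets: np.ndarray, dt: float = 0.01) -> float:
    """Integrated squared output error ``E = dt * sum_t 0.5 |y_t - d_t|^2``
    (left-endpoint quadrature of the error integral)."""
    outputs = np.asarray(outputs, float)
    targets = np.asarray(targets, float)
    if outputs.shape != targets.shape:
        raise InvalidConfigError(
            f"output grid {outputs.shape} does not match target grid {targets.shape}"
        )
    return float(0.5 * dt * np.sum((outputs - targets) ** 2))


def backward_adjoint(
    params: DRNNParams,
    trajectory: np.ndarray,
    targets: np.ndarray,
    dt: float = 0.01,
    inputs: SineInputSet | np.ndarray | None = None,
) -> AdjointState:
    """Adjoint pass for one stored forward trajectory.

    ``trajectory`` is the ``(n_steps + 1, n_units)`` array from
    :func:`forward`; ``targets`` the ``(n_steps, 6)`` desired output-unit
    states (already in network range).  The adjoint p is integrated backward
    from p(t1) = 0 and the accumulated gradients are exact for the discrete
    Euler dynamics, i.e. they match central finite differences of the cost.
    ``inputs`` must repeat the drive used in the forward pass (needed for the
    time-constant gradient); omit it only for autonomous runs.
    """
    Y = np.asarray(trajectory, float)
    if Y.ndim != 2 or Y.shape[1] != params.n_units:
        raise InvalidConfigError("trajectory has wrong shape; run forward() first")
    n_steps = Y.shape[0] - 1
    targets = np.asarray(targets, float)
    if targets.shape != (n_steps, N_OUT):
        raise InvalidConfigError("targets must be (n_steps, 6) on the forward grid")
    if inputs is None:
        drive = np.zeros((n_steps, N_IN))
    else:
        drive = inputs.data if isinstance(inputs, SineInputSet) else np.asarray(inputs, float)
        drive = drive[:n_steps]
    I = _external_input(params.n_units, drive, params.I)

    W, T = params.w, params.T
    n = params.n_units
    out = params.output_slice
    a = dt / T
    # squashed drives, recomputed in one vectorized sweep
    F = expit(Y[:-1] @ W.T)  # (n_steps, n)
    e = np.zeros((n_steps, n))
    e[:, out] = Y[:n_steps, out] - targets
    E = float(0.5 * dt * np.sum(e[:, out] ** 2))

    p = np.zeros((n_steps + 1, n))  # p[t] = dE/dy_t / dt; p[n_steps] = 0
    lam = np.zeros(n)
    grad_w = np.zeros((n, n))
    S = np.zeros(n)  # accumulates lam_{t+1} * (-y_t + F_t + I_t)
    for t in range(n_steps - 1, -1, -1):
        g = lam * a * F[t] * (1.0 - F[t])
        grad_w += np.outer(g, Y[t])
        S += lam * (F[t] - Y[t] + I[t])
        lam = e[t] * dt + lam * (1.0 - a) + g @ W
        p[t] = lam / dt
    grad_T = S * (-dt / T**2)
    return AdjointState(p=p, e=e, E=E, grad_w=grad_w, grad_T=grad_T)


def _stack_patterns(
    patterns: Sequence[TrainingPattern], bias: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad patterns to a common step count.  Returns external input
    (n_steps, 1, P, n), network-range targets (n_steps, P, 6) and a validity
    mask (n_steps, P).  Washout lead-ins and steps beyond a pattern's length
    carry zero cost weight (the latter also zero drive)."""
    if len(patterns) == 0:
        raise InvalidConfigError("need at least one training pattern")
    n = bias.size
    N = max(p.n_steps for p in patterns)
    P = len(patterns)
    I = np.tile(bias, (N, 1, P, 1))
    targets = np.zeros((N, P, N_OUT))
    mask = np.zeros((N, P))
    for k, pat in enumerate(patterns):
        I[: pat.n_steps, 0, k, :N_IN] += pat.inputs
        scored = slice(pat.washout_steps, pat.n_steps)
        targets[scored, k] = to_net_range(pat.targets)
        mask[scored, k] = 1.0
    return I, targets, mask


def _batch_losses(
    Y: np.ndarray, targets: np.ndarray, mask: np.ndarray, out: slice, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lane cost and the masked, dt-weighted error trajectories."""
    diff = Y[:-1, :, :, out] - targets[:, None]  # (N, R, P, 6)
    diff *= mask[:, None, :, None]
    E = 0.5 * dt * np.sum(diff**2, axis=(0, 2, 3))
    return E, diff


class _AlmeidaState:
    """Per-parameter adaptive step sizes with gradient-sign memory, per lane.

    Resilient sign steps: each parameter moves by its own step size against
    the sign of its gradient; the step size grows by ``up`` while successive
    gradient signs agree and shrinks by ``down`` on a reversal (with the
    gradient memory cleared after a reversal, so no step is taken in the
    iteration immediately following a flip).
    """

    def __init__(self, shape_w, shape_T, cfg: TrainingConfig, dtype=np.float64):
        self.cfg = cfg
        self.eta_w = np.full(shape_w, cfg.lr_w, dtype)
        self.eta_T = np.full(shape_T, cfg.lr_T, dtype)
        self.prev_w = np.zeros(shape_w, dtype)
        self.prev_T = np.zeros(shape_T, dtype)

    def step(self, W, logT, gw, gT):
        cfg = self.cfg
        for eta, prev, g, theta in (
            (self.eta_w, self.prev_w, gw, W),
            (self.eta_T, self.prev_T, gT, logT),
        ):
            s = prev * g
            eta *= np.where(s > 0, cfg.up, np.where(s < 0, cfg.down, 1.0))
            np.clip(eta, cfg.rate_min, cfg.rate_max, out=eta)
            g = np.where(s < 0, 0.0, g)
            theta -= eta * np.sign(g)
            prev[...] = g

    def reset_lane(self, r: int, factor: float):
        self.eta_w[r] = self.cfg.lr_w * factor
        self.eta_T[r] = self.cfg.lr_T * factor
        self.prev_w[r] = 0.0
        self.prev_T[r] = 0.0


class _WorkBuffers:
    """Preallocated per-training scratch arrays (reused across iterations)."""

    def __init__(self, n_steps: int, R: int, P: int, n: int, dtype=np.float64):
        self.Y = np.empty((n_steps + 1, R, P, n), dtype)
        self.F = np.empty((n_steps, R, P, n), dtype)
        self.G = np.empty((n_steps, R, P, n), dtype)
        self.x = np.empty((R, P, n), dtype)
        self.tmp = np.empty((R, P, n), dtype)


def _sigmoid_into(x: np.ndarray, out: np.ndarray) -> None:
    """out = 1 / (1 + exp(-x)), all in place (overflow-safe: exp -> inf -> 0)."""
    np.negative(x, out=out)
    with np.errstate(over="ignore"):
        np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)


def _run_forward(W, T, I, dt, y0, buf: _WorkBuffers) -> None:
    """In-place batched Euler sweep filling ``buf.Y`` and ``buf.F``."""
    a = (dt / T)[:, None, :].astype(buf.Y.dtype)
    WT = np.ascontiguousarray(W.transpose(0, 2, 1))
    Y, F, x, tmp = buf.Y, buf.F, buf.x, buf.tmp
    Y[0] = y0
    n_steps = F.shape[0]
    for t in range(n_steps):
        np.matmul(Y[t], WT, out=x)
        _sigmoid_into(x, F[t])
        np.subtract(F[t], Y[t], out=tmp)
        tmp += I[t]
        tmp *= a
        np.add(Y[t], tmp, out=Y[t + 1])


def _batch_gradients(W, T, I, ed, dt, out, buf: _WorkBuffers):
    """Batched discrete adjoint over restart/pattern lanes.

    ``ed`` is the masked, dt-weighted output error (n_steps, R, P, 6).
    Returns gradients w.r.t. the weights and the log time constants, summed
    over patterns.  Identical (to rounding) to summing
    :func:`backward_adjoint` gradients pattern by pattern.
    """
    R, P, n = buf.x.shape
    n_steps = buf.F.shape[0]
    dtype = buf.Y.dtype
    a = (dt / T)[:, None, :].astype(dtype)
    oma = (1.0 - a).astype(dtype)
    Y, F, G, x, tmp = buf.Y, buf.F, buf.G, buf.x, buf.tmp
    lam = np.zeros((R, P, n), dtype)
    S = np.zeros((R, n), dtype)
    for t in range(n_steps - 1, -1, -1):
        # g_t = lam_{t+1} * (dt/T) * F'(x_t), kept for the weight gradient
        g = G[t]
        np.subtract(1.0, F[t], out=g)
        g *= F[t]
        g *= lam
        g *= a
        # S accumulates lam_{t+1} * (-y_t + F_t + I_t) for the T gradient
        np.subtract(F[t], Y[t], out=tmp)
        tmp += I[t]
        tmp *= lam
        S += tmp.sum(axis=1)
        # lam_t = e_t dt + lam_{t+1} (1 - dt/T) + g_t W
        np.matmul(g, W, out=x)
        lam *= oma
        lam += x
        lam[:, :, out] += ed[t]
    # dE/dw_ij = sum_t sum_p g_t[i] y_t[j], contracted as one large GEMM
    Gf = np.ascontiguousarray(G.transpose(1, 3, 0, 2)).reshape(R, n, n_steps * P)
    Yf = np.ascontiguousarray(Y[:-1].transpose(1, 0, 2, 3)).reshape(R, n_steps * P, n)
    gw = np.matmul(Gf, Yf)
    gT = S * (-dt / T**2).astype(dtype)
    return gw, (gT * T.astype(dtype))


def _train_batch(
    patterns: Sequence[TrainingPattern],
    n_hidden: int,
    config: TrainingConfig,
    n_restarts: int,
    seed: int | None,
):
    """Train ``n_restarts`` independently initialized networks in lockstep.

    Full-batch gradients are summed over patterns each iteration; a lane whose
    loss or parameters go non-finite is re-initialized with halved initial
    rates up to ``max_recoveries`` times, then abandoned.  Returns per-lane
    best parameters (at the lowest recorded loss), best losses, the loss
    history (n_iterations, n_restarts) and the per-lane recovery counts.
    """
    n = N_IN + n_hidden + N_OUT
    dtype = np.dtype(config.precision)
    bias = np.zeros(n)
    I, targets, mask = _stack_patterns(patterns, bias)
    I = I.astype(dtype)
    targets = targets.astype(dtype)
    dt = config.dt
    out = slice(n - N_OUT, n)
    ss = np.random.SeedSequence(seed)
    lane_seeds = ss.spawn(n_restarts * (config.max_recoveries + 1))
    rngs = [np.random.default_rng(s) for s in lane_seeds]
    next_rng = n_restarts

    R = n_restarts
    W = np.empty((R, n, n), dtype)
    logT = np.empty((R, n), dtype)
    for r in range(R):
        p0 = init_params(n_hidden, rngs[r], config)
        W[r] = p0.w
        logT[r] = np.log(p0.T)
    log_T_floor = np.log(config.T_floor_factor * dt)
    np.clip(logT, log_T_floor, None, out=logT)

    alm = _AlmeidaState((R, n, n), (R, n), config, dtype)
    best_E = np.full(R, np.inf)
    best_W = W.copy()
    best_logT = logT.copy()
    retries = np.zeros(R, dtype=int)
    dead = np.zeros(R, dtype=bool)
    history = np.full((config.n_iterations, R), np.nan)

    P = len(patterns)
    n_steps = I.shape[0]
    buf = _WorkBuffers(n_steps, R, P, n, dtype)
    for it in range(config.n_iterations):
        T = np.exp(logT, dtype=np.float64)
        _run_forward(W, T, I, dt, config.y0, buf)
        E, diff = _batch_losses(buf.Y, targets, mask, out, dt)
        bad = ~np.isfinite(E)
        for r in np.flatnonzero(bad & ~dead):
            retries[r] += 1
            if retries[r] > config.max_recoveries:
                dead[r] = True
                continue
            rng = rngs[next_rng]
            next_rng += 1
            p0 = init_params(n_hidden, rng, config)
            W[r] = p0.w
            logT[r] = np.clip(np.log(p0.T), log_T_floor, None)
            alm.reset_lane(r, 0.5 ** retries[r])
        if np.any(bad):
            history[it] = np.where(bad, np.nan, E)
            continue
        history[it] = E
        improved = E < best_E
        if np.any(improved):
            best_E[improved] = E[improved]
            best_W[improved] = W[improved]
            best_logT[improved] = logT[improved]

        gw, g_logT = _batch_gradients(W, T, I, diff * dt, dt, out, buf)
        alm.step(W, logT, gw, g_logT)
        np.clip(logT, log_T_floor, None, out=logT)

    if np.all(np.isinf(best_E)):
        raise TrainingFailedError(
            f"all {R} restarts diverged after {config.max_recoveries} recoveries each"
        )
    best = [
        DRNNParams(w=best_W[r].copy(), T=np.exp(best_logT[r]), I=bias.copy(), n_hidden=n_hidden)
        if np.isfinite(best_E[r])
        else None
        for r in range(R)
    ]
    return best, best_E, history, retries


def train(
    patterns: Sequence[TrainingPattern],
    n_hidden: int,
    config: TrainingConfig | None = None,
) -> tuple[DRNNParams, np.ndarray]:
    """Train a single network on one or more patterns.

    Returns the parameters at the best recorded loss and the loss history.
    """
    cfg = config if config is not None else TrainingConfig()
    best, best_E, history, _ = _train_batch(patterns, n_hidden, cfg, 1, cfg.seed)
    if best[0] is None:
        raise TrainingFailedError("training diverged")
    return best[0], history[:, 0]


def train_restarts(
    patterns: Sequence[TrainingPattern],
    n_hidden: int,
    config: TrainingConfig | None = None,
    n_restarts: int | None = None,
) -> tuple[DRNNParams, pd.DataFrame]:
    """Train ``n_restarts`` independently seeded networks and keep the one with
    the highest mean similarity index over all patterns and output channels
    (ties broken by lower loss).

    Returns the selected parameters and a per-restart summary table
    (restart, loss, mean_si, selected).
    """
    from .evaluation import similarity_index  # local import: avoids a cycle

    cfg = config if config is not None else TrainingConfig()
    R = n_restarts if n_restarts is not None else cfg.n_restarts
    best, best_E, history, retries = _train_batch(patterns, n_hidden, cfg, R, cfg.seed)

    mean_si = np.full(R, -np.inf)
    for r, params in enumerate(best):
        if params is None:
            continue
        sis = []
        for pat in patterns:
            pred = predict(params, pat.inputs, dt=cfg.dt, y0=cfg.y0)[pat.washout_steps :]
            for c in range(N_OUT):
                sis.append(similarity_index(pat.targets[:, c], pred[:, c], pat.Tc, cfg.dt))
        mean_si[r] = float(np.mean(sis))
    order = sorted(range(R), key=lambda r: (-mean_si[r], best_E[r]))
    winner = order[0]
    if not np.isfinite(mean_si[winner]):
        raise TrainingFailedError("no restart produced a finite similarity index")
    table = pd.DataFrame(
        {
            "restart": np.arange(R),
            "loss": best_E,
            "mean_si": mean_si,
            "recoveries": retries,
            "selected": [r == winner for r in range(R)],
        }
    )
    return best[winner], table


def predict(
    params: DRNNParams,
    inputs: SineInputSet | np.ndarray,
    dt: float = 0.01,
    y0: float = 0.5,
) -> np.ndarray:
    """Pure forward pass; returns the six output-unit trajectories mapped back
    to the [-1, 1] target convention, aligned with the input grid."""
    Y = forward(params, inputs, dt=dt, y0=y0)
    return from_net_range(Y[:-1, -N_OUT:])


def save_params(params: DRNNParams, path: str | Path, config: dict | None = None) -> None:
    """Serialize parameters to a version-stamped JSON checkpoint.

    JSON float repr round-trips float64 exactly, so save -> load -> save is
    byte-identical.
    """
    doc = {
        "format": "cpgdrnn-params",
        "format_version": CHECKPOINT_VERSION,
        "n_hidden": int(params.n_hidden),
        "roles": params.roles,
        "w": params.w.tolist(),
        "T": params.T.tolist(),
        "I": params.I.tolist(),
        "config": config if config is not None else {},
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_params(path: str | Path) -> DRNNParams:
    """Load a checkpoint written by :func:`save_params`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise CheckpointFormatError(f"not a valid checkpoint: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "cpgdrnn-params":
        raise CheckpointFormatError("unrecognized checkpoint schema")
    if doc.get("format_version") != CHECKPOINT_VERSION:
        raise CheckpointFormatError(
            f"unsupported checkpoint version {doc.get('format_version')!r}"
        )
    try:
        return DRNNParams(
            w=np.array(doc["w"], dtype=float),
            T=np.array(doc["T"], dtype=float),
            I=np.array(doc["I"], dtype=float),
            n_hidden=int(doc["n_hidden"]),
        )
    except (KeyError, TypeError, ValueError, InvalidConfigError) as exc:
        raise CheckpointFormatError(f"corrupted checkpoint payload: {exc}") from exc
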