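"""Adaptive Intelligent Coney Optimization (AICO).

A bounded population metaheuristic blending two behaviours per iteration:

* **predation** (coyote-style): every individual moves toward a blend of
  the global best and the population mean, with time-varying amplitudes;
* a probabilistic switch between **deviated search** (coney foraging: a
  masked step along the offset from the population mean, a running-length
  factor, a rare unit Gaussian kick, and a velocity memory) and
  **stashing** (random hiding: a single-dimension burrow move scaled by an
  iteration-decreasing hiding parameter).

Candidate moves are clipped to the search bounds and accepted greedily
(improve-or-retain), which guarantees a monotone best-so-far trajectory.
After the population sweep, the global best is additionally refined by a
Taylor-series memory update built from its last three positions, also
accepted greedily.

The optimizer is generic (any callable d-vector objective); the
hyperparameter tuner for the classifier is a thin decoding layer on top.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np

from .ecnn import ECNNConfig

log = logging.getLogger("gbsd.aico")

Objective = Callable[[np.ndarray], float]

# Taylor-series memory coefficients of the best-solution update.
_TAYLOR = (0.5, 1.359, 0.6795)


@dataclasses.dataclass
class AICOConfig:
    """Search-space and schedule parameters.

    ``b1`` sets the amplitude of the predation coefficients r1/r2 (in
    (0, 4]); ``a`` is the base of the phase-switch probability
    ``rho_s = a**y`` with y ~ U[0, 1].
    """

    N: int = 20
    d: int = 2
    bounds: Sequence[tuple[float, float]] | tuple[float, float] = (0.0, 1.0)
    tmax: int = 100
    b1: float = 2.0
    a: float = 2.0
    seed: int = 0
    maximize: bool = False

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("population size N must be >= 4")
        if self.tmax < 1:
            raise ValueError("tmax must be >= 1")
        if not 0 < self.b1 <= 4:
            raise ValueError("b1 must be in (0, 4]")
        b = np.asarray(self.bounds, dtype=np.float64)
        if b.ndim == 1:
            b = np.tile(b, (self.d, 1))
        if b.shape != (self.d, 2) or not (b[:, 0] < b[:, 1]).all():
            raise ValueError("bounds must be per-dimension (lo, hi) with lo < hi")
        self.lo = b[:, 0]
        self.hi = b[:, 1]


@dataclasses.dataclass
class AICOState:
    """Population positions, velocities, fitness, best, 3-deep history."""

    R: np.ndarray  # (N, d) positions
    V: np.ndarray  # (N, d) velocities
    fitness: np.ndarray  # (N,)
    best_x: np.ndarray  # (d,)
    best_f: float
    history: list[np.ndarray]  # best positions at t-1, t-2, t-3
    t: int
    rng: np.random.Generator
    n_deviated: int = 0
    n_stash: int = 0

    @property
    def Rmean(self) -> np.ndarray:
        return self.R.mean(axis=0)

    @property
    def Rmin(self) -> np.ndarray:
        return self.R.min(axis=0)

    @property
    def Rmax(self) -> np.ndarray:
        return self.R.max(axis=0)


def _signed(cfg: AICOConfig, objective: Objective) -> Objective:
    if cfg.maximize:
        return lambda x: -float(objective(x))
    return lambda x: float(objective(x))


def initialize(cfg: AICOConfig, objective: Objective) -> AICOState:
    """Uniform seeded population within bounds; V = 0; history = best x3."""
    rng = np.random.default_rng(cfg.seed)
    obj = _signed(cfg, objective)
    R = rng.uniform(cfg.lo, cfg.hi, size=(cfg.N, cfg.d))
    fitness = np.array([obj(x) for x in R])
    if not np.isfinite(fitness).all():
        bad = R[~np.isfinite(fitness)][0]
        raise ValueError(f"objective is non-finite at initial point {bad}")
    ib = int(np.argmin(fitness))
    best = R[ib].copy()
    return AICOState(
        R=R,
        V=np.zeros_like(R),
        fitness=fitness,
        best_x=best,
        best_f=float(fitness[ib]),
        history=[best.copy(), best.copy(), best.copy()],
        t=0,
        rng=rng,
    )


def running_length(t: int, tmax: int, r4: float) -> float:
    """Running length L in [0, 1]: |(e - e^((t-1)/tmax)^2) sin(2 pi r4)|, clipped."""
    raw = (np.e - np.exp(((t - 1) / tmax) ** 2)) * np.sin(2 * np.pi * r4)
    return float(min(abs(raw), 1.0))


def hiding_parameter(t: int, tmax: int, r6: float) -> float:
    """Hiding parameter M = ((tmax - t + 1)/tmax) * r6, decreasing in t."""
    return (tmax - t + 1) / tmax * r6


def position_probability(Rt: np.ndarray, Rmin: np.ndarray, Rmax: np.ndarray) -> float:
    """Normalized position (Rt - Rmin)/(Rmax - Rmin), averaged over dims.

    A degenerate dimension (Rmax == Rmin) contributes 0.5.
    """
    Rt, Rmin, Rmax = map(np.atleast_1d, (Rt, Rmin, Rmax))
    span = Rmax - Rmin
    frac = np.where(span > 0, (Rt - Rmin) / np.where(span > 0, span, 1.0), 0.5)
    return float(frac.mean())


def _predation_coeffs(t: int, tmax: int, b1: float) -> tuple[float, float]:
    # amplitude shifts from the population mean toward the global best as
    # t/tmax grows; the |sin| factor anneals both ends of the run
    s = abs(np.sin(np.pi * t / tmax))
    r1 = b1 * (t / tmax) ** 2 * s
    r2 = b1 * (1 - t / tmax) ** 2 * s
    return r1, r2


def _dim_mask(rng: np.random.Generator, d: int) -> np.ndarray:
    # C: ceil(r5 * d) dimensions chosen from a random permutation
    r5 = rng.random()
    n_sel = max(1, int(np.ceil(r5 * d)))
    x = rng.permutation(d)
    C = np.zeros(d)
    C[x[:n_sel]] = 1.0
    return C


def step(state: AICOState, objective: Objective, cfg: AICOConfig) -> AICOState:
    """One AICO iteration (see module docstring); mutates and returns state."""
    obj = _signed(cfg, objective)
    state.t += 1
    t, tmax = state.t, cfg.tmax
    rng = state.rng
    r1, r2 = _predation_coeffs(t, tmax, cfg.b1)
    Rmean = state.Rmean
    Rmin, Rmax = state.Rmin, state.Rmax

    for i in range(cfg.N):
        Ri = state.R[i]
        cand = Ri + r1 * (state.best_x - Ri) + r2 * (Rmean - Ri)

        y = rng.random()
        rho_s = cfg.a**y
        if rho_s > 0.5:
            # deviated search (foraging): masked running-length move away
            # from the population mean + rare unit Gaussian kick + velocity
            state.n_deviated += 1
            L = running_length(t, tmax, rng.random())
            C = _dim_mask(rng, cfg.d)
            P = L * C
            r3 = rng.random()
            kick = round(0.5 * (0.05 + r3))  # 1 with probability 0.05
            n1 = rng.standard_normal(cfg.d)
            cand = cand + P * (Ri - Rmean) + kick * n1 + state.V[i]
            new_V = state.V[i] + rng.random() * (cand - Ri)
        else:
            # stashing (random hiding): single-dimension burrow move
            state.n_stash += 1
            rho_p = position_probability(Ri, Rmin, Rmax)
            r6 = 1.0 if rho_p > 0.5 else 0.0
            M = hiding_parameter(t, tmax, r6)
            L = running_length(t, tmax, rng.random())
            C = _dim_mask(rng, cfg.d)
            P = L * C
            xk = np.zeros(cfg.d)
            xk[rng.integers(0, cfg.d)] = 1.0
            cand = Ri + P * r6 * Ri + M * (xk * Ri - Ri)
            new_V = None

        cand = np.clip(cand, cfg.lo, cfg.hi)
        f = obj(cand)
        if not np.isfinite(f):
            log.warning("non-finite fitness at %s; candidate rejected", cand)
            continue
        if f < state.fitness[i]:  # greedy improve-or-retain
            state.R[i] = cand
            state.fitness[i] = f
            if new_V is not None:
                state.V[i] = new_V
            if f < state.best_f:
                state.best_f = f
                state.best_x = cand.copy()

    # Taylor-series memory refinement of the global best
    h1, h2, h3 = state.history
    L = running_length(t, tmax, rng.random())
    C = _dim_mask(rng, cfg.d)
    P = L * C
    rho_p = position_probability(state.best_x, state.Rmin, state.Rmax)
    r6 = 1.0 if rho_p > 0.5 else 0.0
    M = hiding_parameter(t, tmax, r6)
    xk = np.zeros(cfg.d)
    xk[rng.integers(0, cfg.d)] = 1.0
    denom = 0.5 + P * r6 + M * xk * r6 - 1.0
    safe = np.abs(denom) > 1e-9
    if safe.any():
        core = np.where(
            safe,
            (_TAYLOR[1] * h1 - h2 + _TAYLOR[2] * h3) / np.where(safe, denom, 1.0),
            state.best_x,
        )
        cand = core * (1.0 - r1 - r2) + (r1 + r2) * state.best_x
        cand = np.clip(cand, cfg.lo, cfg.hi)
        f = obj(cand)
        if np.isfinite(f) and f < state.best_f:
            state.best_f = f
            state.best_x = cand.copy()
            worst = int(np.argmax(state.fitness))
            state.R[worst] = cand
            state.fitness[worst] = f

    state.history = [state.best_x.copy(), state.history[0], state.history[1]]
    return state


@dataclasses.dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float  # on the caller's scale (maximize flag already applied)
    trace: list[float]  # best value per iteration, caller's scale
    n_deviated: int
    n_stash: int


def optimize(objective: Objective, cfg: AICOConfig) -> OptimizeResult:
    """Run initialize + tmax steps; trace records the best value per iteration."""
    state = initialize(cfg, objective)
    trace = []
    sign = -1.0 if cfg.maximize else 1.0
    for _ in range(cfg.tmax):
        state = step(state, objective, cfg)
        trace.append(sign * state.best_f)
    return OptimizeResult(
        x=state.best_x.copy(),
        fun=sign * state.best_f,
        trace=trace,
        n_deviated=state.n_deviated,
        n_stash=state.n_stash,
    )


# ---------------------------------------------------------------------------
# hyperparameter decoding for the classifier
# ---------------------------------------------------------------------------

LR_RANGE = (1e-4, 1e-1)  # log-uniform
DROPOUT_RANGE = (0.0, 0.5)
FILTER_LADDER = ((4, 8, 16), (8, 16, 32), (16, 32, 64))
BATCH_LADDER = (8, 16, 32, 64)

HYPER_DIM = 4  # learning_rate, dropout, filter ladder index, batch ladder index


def _ladder_index(u: float, n: int) -> int:
    return min(int(u * n), n - 1)


def decode_hyperparams(vector: np.ndarray, base: ECNNConfig | None = None) -> ECNNConfig:
    """Map a [0, 1]^4 vector to a classifier configuration.

    Coordinates: log-uniform learning rate, dropout rate, conv-filter ladder
    index, batch-size ladder index.  Deterministic; the remaining fields are
    copied from ``base``.
    """
    v = np.clip(np.asarray(vector, dtype=np.float64), 0.0, 1.0)
    if v.shape != (HYPER_DIM,):
        raise ValueError(f"vector must have shape ({HYPER_DIM},)")
    base = base or ECNNConfig()
    lr = float(np.exp(np.log(LR_RANGE[0]) + v[0] * (np.log(LR_RANGE[1]) - np.log(LR_RANGE[0]))))
    dropout = float(DROPOUT_RANGE[0] + v[1] * (DROPOUT_RANGE[1] - DROPOUT_RANGE[0]))
    filters = FILTER_LADDER[_ladder_index(v[2], len(FILTER_LADDER))]
    batch = BATCH_LADDER[_ladder_index(v[3], len(BATCH_LADDER))]
    return dataclasses.replace(
        base,
        learning_rate=lr,
        dropout_rate=dropout,
        conv_filters=filters,
        batch_size=batch,
    )


def encode_hyperparams(cfg: ECNNConfig) -> np.ndarray:
    """Inverse of :func:`decode_hyperparams` (ladder points map to bin centers)."""
    u_lr = (np.log(cfg.learning_rate) - np.log(LR_RANGE[0])) / (
        np.log(LR_RANGE[1]) - np.log(LR_RANGE[0])
    )
    u_do = (cfg.dropout_rate - DROPOUT_RANGE[0]) / (DROPOUT_RANGE[1] - DROPOUT_RANGE[0])
    fi = FILTER_LADDER.index(tuple(cfg.conv_filters))
    bi = BATCH_LADDER.index(cfg.batch_size)
    u_f = (fi + 0.5) / len(FILTER_LADDER)
    u_b = (bi + 0.5) / len(BATCH_LADDER)
    return np.array([u_lr, u_do, u_f, u_b])


def tune_head_weights(
    model,
    X: np.ndarray,
    y: np.ndarray,
    N: int = 8,
    tmax: int = 10,
    seed: int = 0,
    bound: float = 2.0,
) -> float:
    """Desk-scale mode: optimize the classifier's final dense layer directly.

    Flattens the softmax head's weights and bias into one vector and lets
    the population search maximize training accuracy over a [-bound, bound]
    box.  Only sensible for small heads; gradient descent remains the
    primary fitting route.  Returns the achieved accuracy and installs the
    best weights in place.
    """
    head = model.pass1.layers[-1]
    shapes = [head.W.shape, head.b.shape]
    sizes = [int(np.prod(s)) for s in shapes]

    def install(vec: np.ndarray) -> None:
        head.W[...] = vec[: sizes[0]].reshape(shapes[0])
        head.b[...] = vec[sizes[0] :].reshape(shapes[1])

    def fitness(vec: np.ndarray) -> float:
        install(vec)
        logits = model.pass1.forward(np.asarray(X), train=False)
        return float((np.argmax(logits, axis=1) == y).mean())

    cfg = AICOConfig(
        N=N, d=sum(sizes), bounds=(-bound, bound), tmax=tmax, seed=seed, maximize=True
    )
    res = optimize(fitness, cfg)
    install(res.x)
    return res.fun


def tune_hyperparams(
    fitness: Callable[[ECNNConfig], float],
    base: ECNNConfig | None = None,
    N: int = 5,
    tmax: int = 2,
    seed: int = 0,
) -> tuple[ECNNConfig, float, list[float]]:
    """AICO search over classifier hyperparameters, maximizing ``fitness``
    (typically a held-out accuracy)."""
    base = base or ECNNConfig()
    cfg = AICOConfig(N=N, d=HYPER_DIM, bounds=(0.0, 1.0), tmax=tmax, seed=seed, maximize=True)
    res = optimize(lambda v: fitness(decode_hyperparams(v, base)), cfg)
    return decode_hyperparams(res.x, base), res.fun, res.trace
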