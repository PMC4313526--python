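"""Particle swarm optimization with three coefficient regimes.

The swarm minimizes an opaque objective f(x) over a box.  Velocity updates
follow

    v <- w * v + c1 r1 (pbest - x) + c2 r2 (gbest - x),    x <- x + v,

with three variants of the coefficients:

``inertia``
    w scheduled linearly from w_i = 0.9 down to w_f = 0.4 over the run,
    constant c1 = c2.
``constriction``
    w replaced by the Clerc constriction factor
    h = 2 / |2 - a - sqrt(a^2 - 4a)|, a = c1 + c2 > 4 (damping that
    guarantees convergence), c1 = c2 = 2.05 by default.
``tvac``
    scheduled inertia plus time-varying acceleration coefficients: the
    cognitive c1 decreases linearly 2.5 -> 0.5 while the social c2
    increases 0.5 -> 2.5, shifting the swarm from exploration to
    exploitation.  This is the default for the estimation pipeline.

r1, r2 are drawn fresh per particle and per dimension, uniform on [0, 1].
Velocities are clamped to a fraction of the box width; positions leaving
the box are reflected back inside with the offending velocity component
zeroed (keeps positivity bounds intact).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

VARIANTS = ("inertia", "constriction", "tvac")


@dataclass
class SwarmConfig:
    """Swarm size, stopping rule, coefficient schedules and search box."""

    bounds: np.ndarray | None = None  # dim x 2
    n_particles: int = 150
    max_iter: int = 300
    tol: float = 1e-6
    variant: str = "tvac"
    omega_i: float = 0.9
    omega_f: float = 0.4
    c1i: float = 2.5
    c2i: float = 0.5
    c1f: float = 0.5
    c2f: float = 2.5
    c_constriction: float = 2.05  # c1 = c2 for the constriction variant
    c_inertia: float = 2.0       # c1 = c2 for the plain inertia variant
    v_max_fraction: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (0 < self.omega_f <= self.omega_i < 1):
            raise ValueError("require 0 < omega_f <= omega_i < 1")
        if self.variant == "constriction" and 2 * self.c_constriction <= 4:
            raise ValueError("constriction requires c1 + c2 > 4")
        if self.bounds is not None:
            b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
            if b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 0] >= b[:, 1]):
                raise ValueError("bounds must be dim x 2 with low < high")
            if not np.all(np.isfinite(b)):
                raise ValueError("bounds must be finite")
            self.bounds = b

    @property
    def dim(self) -> int:
        if self.bounds is None:
            raise ValueError("bounds not set")
        return self.bounds.shape[0]


def inertia_weight(k: int, cfg: SwarmConfig) -> float:
    """Linearly decreasing inertia weight at iteration k (0.9 -> 0.4)."""
    if not 0 <= k <= cfg.max_iter:
        raise ValueError(f"iteration {k} outside [0, {cfg.max_iter}]")
    return (cfg.omega_i - cfg.omega_f) * (cfg.max_iter - k) / cfg.max_iter + cfg.omega_f


def tvac_coefficients(k: int, cfg: SwarmConfig) -> tuple[float, float]:
    """Time-varying acceleration coefficients at iteration k.

    c1 falls linearly from c1i to c1f while c2 rises from c2i to c2f.
    """
    if not 0 <= k <= cfg.max_iter:
        raise ValueError(f"iteration {k} outside [0, {cfg.max_iter}]")
    frac = (cfg.max_iter - k) / cfg.max_iter
    c1 = (cfg.c1f - cfg.c1i) * (1 - frac) + cfg.c1i
    c2 = (cfg.c2f - cfg.c2i) * (1 - frac) + cfg.c2i
    return c1, c2


def constriction_factor(c1: float, c2: float) -> float:
    """Clerc constriction (damping) factor, 0 < h < 1, for a = c1 + c2 > 4."""
    a = c1 + c2
    if a <= 4:
        raise ValueError(f"constriction requires c1 + c2 > 4, got {a}")
    return 2.0 / abs(2.0 - a - math.sqrt(a * a - 4.0 * a))


def stability_ok(omega: float, c1: float, c2: float) -> bool:
    """Convergence condition omega > (c1 + c2)/2 - 1 and 0 < omega < 1."""
    return 0 < omega < 1 and omega > (c1 + c2) / 2.0 - 1.0


@dataclass
class SwarmState:
    """Positions, velocities and the swarm's memory."""

    positions: np.ndarray       # n x dim
    velocities: np.ndarray      # n x dim
    pbest_pos: np.ndarray       # n x dim
    pbest_val: np.ndarray       # n
    gbest_pos: np.ndarray       # dim
    gbest_val: float
    iteration: int = 0


def _evaluate(objective, positions: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        vals = np.asarray(objective(positions), dtype=float)
    else:
        vals = np.array([float(objective(x)) for x in positions])
    bad = ~np.isfinite(vals)
    if np.any(bad):
        logger.warning("%d particle evaluation(s) non-finite; treated as +inf", bad.sum())
        vals = np.where(bad, np.inf, vals)
    return vals


def init_swarm(objective, cfg: SwarmConfig, rng: np.random.Generator,
               vectorized: bool = False) -> SwarmState:
    """Uniform positions in the box; velocities uniform in [-Vmax, Vmax]."""
    low, high = cfg.bounds[:, 0], cfg.bounds[:, 1]
    vmax = cfg.v_max_fraction * (high - low)
    pos = rng.uniform(low, high, size=(cfg.n_particles, cfg.dim))
    vel = rng.uniform(-vmax, vmax, size=(cfg.n_particles, cfg.dim))
    vals = _evaluate(objective, pos, vectorized)
    g = int(np.argmin(vals))
    return SwarmState(
        positions=pos, velocities=vel,
        pbest_pos=pos.copy(), pbest_val=vals.copy(),
        gbest_pos=pos[g].copy(), gbest_val=float(vals[g]),
    )


def _coefficients(k: int, cfg: SwarmConfig) -> tuple[float, float, float]:
    """(weight on old velocity, c1, c2) for iteration k under cfg.variant."""
    if cfg.variant == "inertia":
        return inertia_weight(k, cfg), cfg.c_inertia, cfg.c_inertia
    if cfg.variant == "constriction":
        c = cfg.c_constriction
        h = constriction_factor(c, c)
        return h, h * c, h * c
    c1, c2 = tvac_coefficients(k, cfg)
    return inertia_weight(k, cfg), c1, c2


def pso_step(state: SwarmState, objective, k: int, cfg: SwarmConfig,
             rng: np.random.Generator, vectorized: bool = False) -> SwarmState:
    """Advance the swarm one iteration (in place) and return it."""
    low, high = cfg.bounds[:, 0], cfg.bounds[:, 1]
    vmax = cfg.v_max_fraction * (high - low)
    w, c1, c2 = _coefficients(k, cfg)

    n, dim = state.positions.shape
    r1 = rng.uniform(size=(n, dim))
    r2 = rng.uniform(size=(n, dim))
    v = (w * state.velocities
         + c1 * r1 * (state.pbest_pos - state.positions)
         + c2 * r2 * (state.gbest_pos - state.positions))
    np.clip(v, -vmax, vmax, out=v)
    x = state.positions + v

    # reflect escapees back into the box and kill their velocity component
    out_low = x < low
    out_high = x > high
    x = np.where(out_low, 2 * low - x, x)
    x = np.where(out_high, 2 * high - x, x)
    np.clip(x, low, high, out=x)  # guard against reflection overshoot
    v[out_low | out_high] = 0.0

    vals = _evaluate(objective, x, vectorized)
    improved = vals < state.pbest_val
    state.pbest_pos[improved] = x[improved]
    state.pbest_val[improved] = vals[improved]
    g = int(np.argmin(state.pbest_val))
    if state.pbest_val[g] < state.gbest_val:
        state.gbest_val = float(state.pbest_val[g])
        state.gbest_pos = state.pbest_pos[g].copy()
    state.positions = x
    state.velocities = v
    state.iteration = k + 1
    return state


def pso_minimize(objective, cfg: SwarmConfig,
                 vectorized: bool = False) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the swarm until the objective drops below tol or max_iter.

    Returns (best position, best value, per-iteration gbest history).
    Deterministic for a given cfg.seed.
    """
    if cfg.bounds is None:
        raise ValueError("cfg.bounds must be set")
    rng = np.random.default_rng(cfg.seed)
    state = init_swarm(objective, cfg, rng, vectorized)

    w0, c10, c20 = _coefficients(0, cfg)
    if cfg.variant != "constriction" and not stability_ok(w0, c10, c20):
        logger.warning(
            "initial PSO coefficients (w=%.3f, c1=%.3f, c2=%.3f) violate the "
            "convergence condition w > (c1+c2)/2 - 1", w0, c10, c20,
        )

    history = [state.gbest_val]
    for k in range(cfg.max_iter):
        if state.gbest_val <= cfg.tol:
            break
        pso_step(state, objective, k, cfg, rng, vectorized)
        history.append(state.gbest_val)
    return state.gbest_pos.copy(), state.gbest_val, np.array(history)
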