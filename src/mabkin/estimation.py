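"""Multistep PSO estimation of the 23 kinetic parameters.

A simultaneous 23-dimensional search is expensive and badly conditioned, so
the problem is split into nine subproblems P1..P9 solved sequentially.  Each
subproblem fits the parameters of a single balance equation by minimizing
the summed squared one-step-ahead Euler prediction error against the densely
interpolated measurements,

    W = sum_k ( xi(k Ts) - xihat(k Ts) )^2,
    xihat((k+1) Ts) = xihat(k Ts) + Ts * f(data(k Ts), theta),

where every state other than the fitted one is pinned to its interpolated
measured trajectory (including the viable-cell density X).  Parameters
estimated in earlier subproblems are frozen and never updated afterwards.

The subproblem -> equation mapping is forced by matching each group of free
parameters to the unique balance equation that contains exactly those
parameters given the freezing order: P1 biomass (phi7*, K_S2,7); P2 antibody
(phi8*, K_S2,8); P3 proline (phi4*, K_S3,4); P4 alanine (phi2*, K_S1,2,
K_S3,2); P5 glutamine (phi6*, K_S2,6, K_S2,9, phi9*, K_S5,6); P6 asparagine
(phi5*, K_S4,5); P7 aspartate (phi3*, K_S1,3, K_S3,3); P8 glucose (phi1*,
K_S1,1); P9 the coupled viable/dead-cell pair (mu, kd).  The lactate,
glutamate and ammonia balances are not fitted: glutamate and ammonia are
unmeasured, and every lactate parameter is already fixed by P4/P7/P8.

Glutamate, although unmeasured, appears in the Monod factors of reactions
2-4.  Summing the GLN, GLU, ASN, ASP, ALA and PRO rows of the stoichiometric
matrix cancels every reaction except biomass and antibody synthesis, so the
glutamate trajectory follows in closed form from the measured pools given
its (unmeasured) initial concentration; see :func:`reconstruct_glutamate`.

Maximum rates and half-saturation constants span many orders of magnitude,
so their search boxes are parameterized on a log10 scale; mu and kd are
searched linearly on [1e-3, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .data_io import InterpolatedTrajectory, MeasurementTable, interpolate
from .model import (
    IDX,
    N_REACTIONS,
    PARAM_NAMES,
    REACTION_SUBSTRATES,
    STATE_NAMES,
    ExperimentDesign,
    KineticParameters,
    build_network,
)
from .pso import SwarmConfig, pso_minimize

logger = logging.getLogger(__name__)

_K = build_network().K

#: Default initial glutamate concentration (mM).  Glutamate is not measured;
#: this value keeps the reconstructed trajectory positive over the batch
#: given the observed pool changes.
DEFAULT_GLU0 = 1.5

#: Search boxes: rates/half-saturation constants on a log10 scale, growth
#: and decay constants linear.
PHI_KS_BOUNDS = (1e-8, 1e7)
MU_KD_BOUNDS = (1e-3, 1.0)


@dataclass(frozen=True)
class SubproblemSpec:
    """One step of the multistep scheme."""

    id: str
    target_states: tuple[str, ...]
    free_params: tuple[str, ...]
    required_params: tuple[str, ...]
    bounds: dict[str, tuple[float, float, str]]  # name -> (low, high, scale)


_SUBPROBLEM_TABLE: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("P1", ("BM",), ("phi_star_7", "ks_2_7")),
    ("P2", ("MAb",), ("phi_star_8", "ks_2_8")),
    ("P3", ("PRO",), ("phi_star_4", "ks_3_4")),
    ("P4", ("ALA",), ("phi_star_2", "ks_1_2", "ks_3_2")),
    ("P5", ("GLN",), ("phi_star_6", "ks_2_6", "ks_2_9", "phi_star_9", "ks_5_6")),
    ("P6", ("ASN",), ("phi_star_5", "ks_4_5")),
    ("P7", ("ASP",), ("phi_star_3", "ks_1_3", "ks_3_3")),
    ("P8", ("GLC",), ("phi_star_1", "ks_1_1")),
    ("P9", ("X", "Xd"), ("mu", "kd")),
)


def _reaction_param_names(i: int) -> tuple[str, ...]:
    """All kinetic parameter names appearing in the rate law of reaction i."""
    return (f"phi_star_{i}",) + tuple(
        f"ks_{j}_{ri}" for (_, (j, ri)) in REACTION_SUBSTRATES[i]
    )


def equation_param_names(state: str) -> tuple[str, ...]:
    """Kinetic parameters appearing in the balance equation of ``state``."""
    if state in ("X", "Xd"):
        return ("mu", "kd")
    s = IDX[state]
    names: list[str] = []
    for i in range(1, N_REACTIONS + 1):
        if _K[s, i - 1] != 0:
            names.extend(_reaction_param_names(i))
    return tuple(dict.fromkeys(names))


def default_subproblems(design: ExperimentDesign | None = None) -> list[SubproblemSpec]:
    """The nine subproblems in solving order, with search boxes."""
    specs: list[SubproblemSpec] = []
    frozen: set[str] = set()
    for pid, targets, free in _SUBPROBLEM_TABLE:
        referenced: list[str] = []
        for t in targets:
            referenced.extend(equation_param_names(t))
        required = tuple(n for n in dict.fromkeys(referenced) if n not in free)
        missing = set(required) - frozen
        if missing:
            raise RuntimeError(
                f"{pid} references parameters not frozen earlier: {sorted(missing)}"
            )
        bounds = {}
        for name in free:
            if name in ("mu", "kd"):
                bounds[name] = (*MU_KD_BOUNDS, "linear")
            else:
                bounds[name] = (*PHI_KS_BOUNDS, "log10")
        specs.append(SubproblemSpec(pid, targets, tuple(free), required, bounds))
        frozen.update(free)
    assert len(frozen) == 23
    return specs


def reconstruct_glutamate(
    traj: InterpolatedTrajectory, glu0: float = DEFAULT_GLU0
) -> np.ndarray:
    """Closed-form glutamate trajectory from the measured variables.

    The summed GLN+GLU+ASN+ASP+ALA+PRO balance depends only on the biomass
    and antibody synthesis rates, which are the measured dBM/dt and dMAb/dt;
    integrating gives GLU(t) as initial value plus measured pool changes.
    Clamped at zero from below.
    """
    rows = [IDX[n] for n in ("GLN", "GLU", "ASN", "ASP", "ALA", "PRO")]
    s = _K[rows, :].sum(axis=0)
    # only the biomass (7) and antibody (8) columns survive the cancellation
    s7, s8 = s[6], s[7]
    pools = sum(traj.column(n) for n in ("GLN", "ASN", "ASP", "ALA", "PRO"))
    bm = traj.column("BM")
    mab = traj.column("MAb")
    glu = (
        glu0
        + s7 * (bm - bm[0])
        + s8 * (mab - mab[0])
        - (pools - pools[0])
    )
    return np.maximum(glu, 0.0)


@dataclass(frozen=True)
class EstimationContext:
    """Dense data arrays shared by all subproblem objectives."""

    grid: np.ndarray
    Ts: float
    values: dict[str, np.ndarray]  # state name -> (N+1,) array
    t_exp: float

    def var(self, name: str) -> np.ndarray:
        return self.values[name]


def build_context(
    traj: InterpolatedTrajectory,
    design: ExperimentDesign,
    glu0: float = DEFAULT_GLU0,
) -> EstimationContext:
    values = {v: traj.column(v) for v in traj.variables}
    if "GLU" not in values:
        values["GLU"] = reconstruct_glutamate(traj, glu0)
    ts = float(traj.grid[1] - traj.grid[0])
    return EstimationContext(grid=traj.grid, Ts=ts, values=values, t_exp=design.t_exp)


class MissingParameterError(KeyError):
    """A subproblem needed a parameter that is neither free nor frozen."""


def _sse_batch(
    spec: SubproblemSpec,
    ctx: EstimationContext,
    frozen: dict[str, float],
    theta: np.ndarray,
) -> np.ndarray:
    """Vectorized subproblem SSE for a (P, d) batch of natural-unit candidates."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    P = theta.shape[0]
    free_idx = {n: j for j, n in enumerate(spec.free_params)}

    def get(name: str, flat: bool = False):
        if name in free_idx:
            col = theta[:, free_idx[name]]
            return col if flat else col[:, None]
        try:
            return float(frozen[name])
        except KeyError:
            raise MissingParameterError(
                f"{spec.id} requires frozen parameter {name!r}"
            ) from None

    grid = ctx.grid
    Ts = ctx.Ts
    n_steps = grid.size - 1

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if spec.id == "P9" or set(spec.target_states) == {"X", "Xd"}:
            xm, xdm = ctx.var("X"), ctx.var("Xd")
            mu, kd = get("mu", flat=True), get("kd", flat=True)
            mu = np.broadcast_to(np.asarray(mu, dtype=float), (P,)).copy()
            kd = np.broadcast_to(np.asarray(kd, dtype=float), (P,)).copy()
            xh = np.full(P, xm[0])
            xdh = np.full(P, xdm[0])
            sse = np.zeros(P)
            growth = grid[:-1] < ctx.t_exp
            for k in range(n_steps):
                death = kd * xh * xdh
                dx = (mu * xh - death) if growth[k] else -death
                xh = xh + Ts * dx
                xdh = xdh + Ts * death
                sse += (xh - xm[k + 1]) ** 2 + (xdh - xdm[k + 1]) ** 2
            return np.where(np.isfinite(sse), sse, np.inf)

        target = spec.target_states[0]
        s_idx = IDX[target]
        y = ctx.var(target)
        X = ctx.var("X")

        static = np.zeros((P, grid.size))
        dynamic: list[tuple[float, np.ndarray, np.ndarray | float]] = []
        for i in range(1, N_REACTIONS + 1):
            coef = _K[s_idx, i - 1]
            if coef == 0:
                continue
            base = get(f"phi_star_{i}") * X[None, :]
            dyn_K: np.ndarray | float | None = None
            for sub_idx, (j, ri) in REACTION_SUBSTRATES[i]:
                Kv = get(f"ks_{j}_{ri}")
                if sub_idx == s_idx:
                    dyn_K = Kv.ravel() if isinstance(Kv, np.ndarray) else Kv
                else:
                    S = ctx.var(STATE_NAMES[sub_idx])[None, :]
                    base = base * (S / (Kv + S))
            if dyn_K is None:
                static += coef * base
            else:
                dynamic.append((coef, base, dyn_K))

        if not dynamic:
            # pure cumulative sum: the target does not feed back into its rates
            pred = np.empty((P, grid.size))
            pred[:, 0] = y[0]
            pred[:, 1:] = y[0] + Ts * np.cumsum(static[:, :-1], axis=1)
            err = pred[:, 1:] - y[None, 1:]
            sse = np.einsum("ij,ij->i", err, err)
            return np.where(np.isfinite(sse), sse, np.inf)

        pred = np.full(P, y[0])
        sse = np.zeros(P)
        for k in range(n_steps):
            s_eff = np.maximum(pred, 0.0)
            f = static[:, k] + 0.0
            for coef, base, dyn_K in dynamic:
                f = f + coef * base[:, k] * (s_eff / (dyn_K + s_eff))
            pred = pred + Ts * f
            d = pred - y[k + 1]
            sse += d * d
        return np.where(np.isfinite(sse), sse, np.inf)


def subproblem_objective(
    spec: SubproblemSpec,
    traj: InterpolatedTrajectory,
    frozen: dict[str, float],
    candidate: np.ndarray,
    design: ExperimentDesign,
    *,
    glu0: float = DEFAULT_GLU0,
) -> float:
    """Summed squared one-step-ahead Euler prediction error for one candidate.

    ``candidate`` holds natural-unit values for ``spec.free_params`` in
    order; every parameter in ``spec.required_params`` must be in ``frozen``.
    """
    missing = set(spec.required_params) - set(frozen)
    if missing:
        raise MissingParameterError(
            f"{spec.id} missing frozen parameter(s): {sorted(missing)}"
        )
    ctx = build_context(traj, design, glu0)
    candidate = np.asarray(candidate, dtype=float)
    if candidate.shape != (len(spec.free_params),):
        raise ValueError(
            f"candidate must have length {len(spec.free_params)} for {spec.id}"
        )
    return float(_sse_batch(spec, ctx, frozen, candidate[None, :])[0])


# ---------------------------------------------------------------------------
# the multistep driver


@dataclass(frozen=True)
class SubproblemResult:
    id: str
    params: dict[str, float]
    objective: float
    n_iter: int
    seed: int
    history: np.ndarray


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of the full multistep run."""

    subproblems: tuple[SubproblemResult, ...]
    params: KineticParameters
    total_objective: float
    seed: int
    config: dict

    def param_vector(self) -> np.ndarray:
        d = self.params.to_dict()
        return np.array([d[n] for n in PARAM_NAMES])


def _search_bounds(spec: SubproblemSpec) -> np.ndarray:
    rows = []
    for name in spec.free_params:
        low, high, scale = spec.bounds[name]
        if scale == "log10":
            rows.append((np.log10(low), np.log10(high)))
        else:
            rows.append((low, high))
    return np.array(rows)


def _to_natural(spec: SubproblemSpec, u: np.ndarray) -> np.ndarray:
    """Map search-space coordinates to natural units (10**x on log dims)."""
    u = np.atleast_2d(u)
    out = u.copy()
    for j, name in enumerate(spec.free_params):
        if spec.bounds[name][2] == "log10":
            out[:, j] = 10.0 ** u[:, j]
    return out


def _subproblem_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def multistep_estimate(
    table: MeasurementTable,
    cfg: SwarmConfig,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    *,
    glu0: float = DEFAULT_GLU0,
    restarts: int = 1,
    subproblems: list[SubproblemSpec] | None = None,
) -> EstimationResult:
    """Solve P1..P9 in order with forward parameter freezing.

    Interpolates the table once, then runs one PSO per subproblem (or
    ``restarts`` independently seeded runs, keeping the best — the
    objectives have many local minima).  Deterministic given ``seed``.
    """
    design = design or ExperimentDesign()
    specs = subproblems if subproblems is not None else default_subproblems(design)
    traj = interpolate(table, design)
    ctx = build_context(traj, design, glu0)

    frozen: dict[str, float] = {}
    results: list[SubproblemResult] = []
    for idx, spec in enumerate(specs):
        missing = set(spec.required_params) - set(frozen)
        if missing:
            raise MissingParameterError(
                f"{spec.id} missing frozen parameter(s): {sorted(missing)}"
            )

        def objective(u: np.ndarray, _spec=spec) -> np.ndarray:
            return _sse_batch(_spec, ctx, frozen, _to_natural(_spec, u))

        best = None
        for r in range(max(1, restarts)):
            run_seed = _subproblem_seed(seed, idx * 1000 + r)
            run_cfg = replace(cfg, bounds=_search_bounds(spec), seed=run_seed)
            x, val, hist = pso_minimize(objective, run_cfg, vectorized=True)
            if best is None or val < best[1]:
                best = (x, val, hist, run_seed)
        x, val, hist, run_seed = best
        natural = _to_natural(spec, x)[0]
        solution = dict(zip(spec.free_params, (float(v) for v in natural)))
        frozen.update(solution)
        results.append(
            SubproblemResult(
                id=spec.id, params=solution, objective=float(val),
                n_iter=len(hist) - 1, seed=run_seed, history=hist,
            )
        )
        logger.info(
            "%s: objective %.6g after %d iterations (%s)",
            spec.id, val, len(hist) - 1,
            ", ".join(f"{k}={v:.4g}" for k, v in solution.items()),
        )

    params = KineticParameters.from_dict(frozen)
    total = float(sum(r.objective for r in results))
    snapshot = {
        "n_particles": cfg.n_particles, "max_iter": cfg.max_iter, "tol": cfg.tol,
        "variant": cfg.variant, "v_max_fraction": cfg.v_max_fraction,
        "seed": seed, "glu0": glu0, "restarts": restarts,
        "Ts": design.Ts, "t_exp": design.t_exp, "t_final": design.t_final,
    }
    return EstimationResult(
        subproblems=tuple(results), params=params,
        total_objective=total, seed=seed, config=snapshot,
    )
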