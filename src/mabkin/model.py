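"""Batch bioreactor model of a hybridoma mAb-production culture.

The culture is described by 11 extracellular metabolite concentrations
(glucose, glutamine, glutamate, asparagine, aspartate, lactate, alanine,
proline, monoclonal antibody, biomass, ammonia) coupled through nine lumped
macroreactions, plus viable (X) and dead (Xd) cell densities.  Metabolite
balances follow dxi/dt = K @ phi(xi) with a signed 11x9 stoichiometric
matrix K and compound-Monod (saturable) reaction rates

    phi_i = phi_i* . X . prod_j  S_j / (K_Sj,i + S_j),

where phi_i* is the per-cell maximum rate of macroreaction i and K_Sj,i the
half-saturation constant of substrate j in reaction i.  Viable cells grow
exponentially until t_exp and decline afterwards:

    dX/dt  = mu X - kd X Xd   (t <  t_exp)
    dX/dt  =      - kd X Xd   (t >= t_exp)
    dXd/dt = +kd X Xd.

Units: metabolites in mM, cells in 1e6 cells/mL, time in hours.  With
phi_i* in pmol/(cell h), phi_i* . X is directly mM/h, which makes the
bundled measurement table and parameter fixtures mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Ordered extracellular species (states 1..11).
SPECIES: tuple[str, ...] = (
    "GLC", "GLN", "GLU", "ASN", "ASP", "LAC", "ALA", "PRO", "MAb", "BM", "NH3",
)
#: Cell states appended after the species (states 12, 13).
CELL_STATES: tuple[str, ...] = ("X", "Xd")
STATE_NAMES: tuple[str, ...] = SPECIES + CELL_STATES
N_SPECIES = len(SPECIES)
N_REACTIONS = 9
N_STATES = N_SPECIES + 2

IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Substrate structure of the saturable rate laws: reaction i (1-based) ->
#: list of (state index of substrate, half-saturation key (j, i)).
#: Reactions 7-9 saturate on glutamine only; the contributions of their
#: other substrates are deliberately omitted in the rate laws.
REACTION_SUBSTRATES: dict[int, tuple[tuple[int, tuple[int, int]], ...]] = {
    1: ((IDX["GLC"], (1, 1)),),
    2: ((IDX["GLC"], (1, 2)), (IDX["GLU"], (3, 2))),
    3: ((IDX["GLC"], (1, 3)), (IDX["GLU"], (3, 3))),
    4: ((IDX["GLU"], (3, 4)),),
    5: ((IDX["ASN"], (4, 5)),),
    6: ((IDX["GLN"], (2, 6)), (IDX["ASP"], (5, 6))),
    7: ((IDX["GLN"], (2, 7)),),
    8: ((IDX["GLN"], (2, 8)),),
    9: ((IDX["GLN"], (2, 9)),),
}

#: The 12 half-saturation constants of the model, keyed (substrate j, reaction i).
KS_KEYS: tuple[tuple[int, int], ...] = (
    (1, 1), (1, 2), (3, 2), (1, 3), (3, 3), (3, 4),
    (4, 5), (2, 6), (5, 6), (2, 7), (2, 8), (2, 9),
)


class ModelDomainError(ValueError):
    """Raised when states or parameters leave the model's domain."""


@dataclass(frozen=True)
class ReactionNetwork:
    """Signed stoichiometry of the nine macroreactions over the 11 species."""

    species: tuple[str, ...]
    reactions: tuple[str, ...]
    K: np.ndarray  # 11 x 9, signed

    def coefficient(self, species: str, reaction: int) -> float:
        """Signed coefficient of ``species`` in 1-based ``reaction``."""
        return float(self.K[self.species.index(species), reaction - 1])


def build_network() -> ReactionNetwork:
    """Construct the canonical 11x9 stoichiometric matrix.

    Substrates carry negative signs, products positive.  Macroreactions:

    1. GLC -> 2 LAC
    2. GLC + 2 GLU -> 2 ALA + 2 LAC
    3. GLC + 2 GLU -> 2 ASP + 2 LAC
    4. GLU -> PRO
    5. ASN -> ASP + NH3
    6. GLN + ASP -> ASN + GLU
    7. biomass synthesis (0.0508 GLC + 0.0577 GLN + ... -> BM)
    8. antibody synthesis (0.0104 GLN + ... -> MAb)
    9. GLN -> GLU + NH3
    """
    K = np.zeros((N_SPECIES, N_REACTIONS))

    def put(species: str, reaction: int, value: float) -> None:
        K[SPECIES.index(species), reaction - 1] = value

    # reaction 1: GLC -> 2 LAC
    put("GLC", 1, -1.0)
    put("LAC", 1, 2.0)
    # reaction 2: GLC + 2 GLU -> 2 ALA + 2 LAC
    put("GLC", 2, -1.0)
    put("GLU", 2, -2.0)
    put("ALA", 2, 2.0)
    put("LAC", 2, 2.0)
    # reaction 3: GLC + 2 GLU -> 2 ASP + 2 LAC
    put("GLC", 3, -1.0)
    put("GLU", 3, -2.0)
    put("ASP", 3, 2.0)
    put("LAC", 3, 2.0)
    # reaction 4: GLU -> PRO
    put("GLU", 4, -1.0)
    put("PRO", 4, 1.0)
    # reaction 5: ASN -> ASP + NH3
    put("ASN", 5, -1.0)
    put("ASP", 5, 1.0)
    put("NH3", 5, 1.0)
    # reaction 6: GLN + ASP -> ASN + GLU   (k_{2,6} = 1)
    put("GLN", 6, -1.0)
    put("ASP", 6, -1.0)
    put("ASN", 6, 1.0)
    put("GLU", 6, 1.0)
    # reaction 7: biomass synthesis
    put("GLC", 7, -0.0508)
    put("GLN", 7, -0.0577)
    put("ALA", 7, -0.0133)
    put("ASN", 7, -0.006)
    put("ASP", 7, -0.0201)
    put("GLU", 7, -0.0016)
    put("PRO", 7, -0.081)
    put("BM", 7, 1.0)
    # reaction 8: antibody synthesis
    put("GLN", 8, -0.0104)
    put("ALA", 8, -0.011)
    put("ASN", 8, -0.072)
    put("ASP", 8, -0.082)
    put("GLU", 8, -0.0107)
    put("PRO", 8, -0.0148)
    put("MAb", 8, 1.0)
    # reaction 9: GLN -> GLU + NH3
    put("GLN", 9, -1.0)
    put("GLU", 9, 1.0)
    put("NH3", 9, 1.0)

    K.setflags(write=False)
    reactions = tuple(f"R{i}" for i in range(1, N_REACTIONS + 1))
    return ReactionNetwork(species=SPECIES, reactions=reactions, K=K)


@dataclass(frozen=True)
class KineticParameters:
    """The 23 kinetic parameters of the model.

    phi_star
        Maximum reaction rates phi_i*, pmol/(cell h), length 9.
    ks
        Half-saturation constants K_Sj,i in mM, keyed by (substrate j,
        reaction i); exactly the 12 keys of :data:`KS_KEYS`.
    mu
        Specific growth rate of viable cells, 1/h.
    kd
        Decay constant, per (1e6 cells/mL) per h.
    kinetics_mode
        ``"saturable"`` for the compound-Monod laws; ``"simplified"`` for
        the linear reduction phi_i = phi_i* . X (used by the comparison
        parameter sets estimated under that assumption, where net maximum
        rates may be negative).
    """

    phi_star: np.ndarray
    ks: dict[tuple[int, int], float]
    mu: float
    kd: float
    kinetics_mode: str = "saturable"

    def __post_init__(self):
        phi = np.asarray(self.phi_star, dtype=float)
        if phi.shape != (N_REACTIONS,):
            raise ModelDomainError(f"phi_star must have length 9, got {phi.shape}")
        object.__setattr__(self, "phi_star", phi)
        if set(self.ks) != set(KS_KEYS):
            raise ModelDomainError(
                f"ks must carry exactly the 12 keys {KS_KEYS}, got {sorted(self.ks)}"
            )
        if self.kinetics_mode not in ("saturable", "simplified"):
            raise ModelDomainError(f"unknown kinetics_mode {self.kinetics_mode!r}")
        if self.mu < 0 or self.kd < 0:
            raise ModelDomainError("mu and kd must be nonnegative")
        if self.kinetics_mode == "saturable":
            if np.any(phi < 0):
                raise ModelDomainError("maximum rates must be nonnegative")
            if any(v < 0 for v in self.ks.values()):
                raise ModelDomainError("half-saturation constants must be nonnegative")

    @property
    def n_free(self) -> int:
        return len(self.phi_star) + len(self.ks) + 2  # = 23

    def to_dict(self) -> dict[str, float]:
        """Flat name -> value mapping (``phi_star_i``, ``ks_j_i``, ``mu``, ``kd``)."""
        out: dict[str, float] = {}
        for i in range(N_REACTIONS):
            out[f"phi_star_{i + 1}"] = float(self.phi_star[i])
        for (j, i) in KS_KEYS:
            out[f"ks_{j}_{i}"] = float(self.ks[(j, i)])
        out["mu"] = float(self.mu)
        out["kd"] = float(self.kd)
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float], kinetics_mode: str = "saturable") -> "KineticParameters":
        phi = np.array([d[f"phi_star_{i + 1}"] for i in range(N_REACTIONS)], dtype=float)
        ks = {(j, i): float(d[f"ks_{j}_{i}"]) for (j, i) in KS_KEYS}
        return cls(phi_star=phi, ks=ks, mu=float(d["mu"]), kd=float(d["kd"]),
                   kinetics_mode=kinetics_mode)


#: Canonical ordering of the 23 free parameters.
PARAM_NAMES: tuple[str, ...] = tuple(
    [f"phi_star_{i}" for i in range(1, N_REACTIONS + 1)]
    + [f"ks_{j}_{i}" for (j, i) in KS_KEYS]
    + ["mu", "kd"]
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Timing of the batch experiment.

    t_exp: end of the exponential growth phase (h); t_final: batch length
    (h); Ts: sampling period of discretized computations (h).
    """

    t_exp: float = 54.0
    t_final: float = 147.0
    Ts: float = 0.1

    def __post_init__(self):
        if not (0 < self.t_exp < self.t_final):
            raise ModelDomainError("require 0 < t_exp < t_final")
        if self.Ts <= 0:
            raise ModelDomainError("Ts must be positive")

    @property
    def grid(self) -> np.ndarray:
        """The dense grid 0, Ts, 2Ts, ..., t_final."""
        n = int(round(self.t_final / self.Ts))
        return np.linspace(0.0, n * self.Ts, n + 1)


_NETWORK = build_network()


def reaction_rates(
    state: np.ndarray,
    params: KineticParameters,
    *,
    clip: bool = False,
    _clip_counter: list | None = None,
) -> np.ndarray:
    """Macroreaction rates phi (mM/h) at a 13-dimensional state.

    With ``clip=True`` small negative concentrations produced by integrator
    overshoot are clamped to zero (Monod factors are undefined below zero);
    otherwise negative inputs raise :class:`ModelDomainError`.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ModelDomainError(f"state must have length {N_STATES}")
    if clip:
        if np.any(state < 0):
            if _clip_counter is not None:
                _clip_counter[0] += 1
            state = np.maximum(state, 0.0)
    elif np.any(state < 0):
        bad = STATE_NAMES[int(np.argmin(state))]
        raise ModelDomainError(f"negative concentration for {bad}")

    X = state[IDX["X"]]
    phi = params.phi_star * X
    if params.kinetics_mode == "simplified":
        return phi
    for i in range(1, N_REACTIONS + 1):
        for s_idx, key in REACTION_SUBSTRATES[i]:
            S = state[s_idx]
            K = params.ks[key]
            denom = K + S
            phi[i - 1] *= S / denom if denom > 0 else (1.0 if S > 0 else 0.0)
    return phi


def state_derivative(
    t: float,
    state: np.ndarray,
    params: KineticParameters,
    design: ExperimentDesign,
    *,
    growth: bool | None = None,
    clip: bool = False,
    _clip_counter: list | None = None,
) -> np.ndarray:
    """Right-hand side of the full 13-state model at time ``t``.

    ``growth`` overrides the phase inferred from ``t < t_exp`` (used by the
    piecewise integrator so the switch is exact).
    """
    state = np.asarray(state, dtype=float)
    phi = reaction_rates(state, params, clip=clip, _clip_counter=_clip_counter)
    d = np.empty(N_STATES)
    d[:N_SPECIES] = _NETWORK.K @ phi
    X, Xd = state[IDX["X"]], state[IDX["Xd"]]
    if clip:
        X, Xd = max(X, 0.0), max(Xd, 0.0)
    if growth is None:
        growth = t < design.t_exp
    death = params.kd * X * Xd
    d[IDX["X"]] = (params.mu * X if growth else 0.0) - death
    d[IDX["Xd"]] = death
    return d


def simulate(
    initial: np.ndarray,
    params: KineticParameters,
    design: ExperimentDesign,
    t_grid: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the batch model over ``t_grid`` (len(t_grid) x 13 array).

    The exponential/decline phase switch at ``t_exp`` is handled by
    integrating the two phases separately so the transition is exact.  LSODA
    handles the stiffness from state magnitudes spanning several orders of
    magnitude; tiny negative excursions near substrate depletion are clipped
    inside the rate function and zeroed in the output.
    """
    from scipy.integrate import solve_ivp

    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise ModelDomainError(f"initial state must have length {N_STATES}")
    if np.any(initial < 0):
        raise ModelDomainError("initial state must be nonnegative")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ModelDomainError("t_grid must be non-empty and strictly increasing")
    if t_grid[0] < 0 or t_grid[-1] > design.t_final:
        raise ModelDomainError("t_grid must lie within [0, t_final]")

    counter = [0]

    def integrate(growth: bool, a: float, b: float, y0: np.ndarray, t_eval: np.ndarray):
        """One phase on [a, b]; returns (states at t_eval, state at b)."""
        rhs = lambda t, y: state_derivative(
            t, y, params, design, growth=growth, clip=True, _clip_counter=counter
        )
        if b <= a:  # zero-length segment: nothing to integrate
            states = np.tile(y0, (t_eval.size, 1))
            return states, y0.copy()
        ts = np.unique(np.concatenate((t_eval, [b]))) if t_eval.size else np.array([a, b])
        if ts[0] > a:
            ts = np.concatenate(([a], ts))
        sol = solve_ivp(rhs, (a, b), y0, method="LSODA", t_eval=ts, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a}, {b}] h: {sol.message}")
        if np.any(~np.isfinite(sol.y)):
            raise RuntimeError(f"integration produced non-finite states on [{a}, {b}] h")
        lookup = {t: sol.y[:, k] for k, t in enumerate(sol.t)}
        states = np.array([lookup[t] for t in t_eval]) if t_eval.size else np.empty((0, N_STATES))
        return states, sol.y[:, -1]

    out = np.empty((t_grid.size, N_STATES))
    t0, t_end = t_grid[0], t_grid[-1]
    pre_mask = t_grid < design.t_exp

    if t0 >= design.t_exp:  # entirely in the decline phase
        out[:], _ = integrate(False, t0, max(t_end, t0 + 1e-12), initial, t_grid)
    elif t_end < design.t_exp:  # entirely in the growth phase
        out[:], _ = integrate(True, t0, t_end if t_end > t0 else t0 + 1e-12, initial, t_grid)
    else:
        states_pre, y_exp = integrate(True, t0, design.t_exp, initial, t_grid[pre_mask])
        out[pre_mask] = states_pre
        states_post, _ = integrate(
            False, design.t_exp, t_end, np.maximum(y_exp, 0.0), t_grid[~pre_mask]
        )
        out[~pre_mask] = states_post

    if counter[0]:
        logger.debug("rate function clipped negative states %d times", counter[0])
    return np.maximum(out, 0.0)


def simulate_two_phase(
    initial: np.ndarray,
    params_growth: KineticParameters,
    params_decline: KineticParameters,
    design: ExperimentDesign,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Simulate with phase-specific parameter blocks (exponential vs decline).

    Used for comparison parameter sets estimated separately per phase under
    the simplified kinetics phi_i = phi_i* . X.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    pre = t_grid[t_grid <= design.t_exp]
    if pre.size == 0 or pre[-1] < design.t_exp:
        pre = np.append(pre, design.t_exp)
    traj_pre = simulate(initial, params_growth, design, pre)
    out = np.empty((t_grid.size, N_STATES))
    n_pre = np.sum(t_grid <= design.t_exp)
    out[:n_pre] = traj_pre[:n_pre]
    post_times = t_grid[t_grid > design.t_exp]
    if post_times.size:
        start = np.maximum(traj_pre[-1], 0.0)
        post = np.concatenate(([design.t_exp], post_times))
        traj_post = simulate(start, params_decline, design, post)
        out[n_pre:] = traj_post[1:]
    return out


# ---------------------------------------------------------------------------
# parameter-set serialization and bundled fixtures


def save_params(params: KineticParameters, path: str | Path) -> None:
    """Write a parameter set as a flat key=value YAML file."""
    doc = params.to_dict()
    doc["kinetics_mode"] = params.kinetics_mode
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(source: str | Path) -> KineticParameters:
    """Load a parameter set from YAML, or a bundled fixture by name.

    Bundled names: ``pso`` (the multistep PSO estimates), ``gao_exp`` /
    ``gao_decl`` (the simplified-kinetics comparison set, per phase) and
    ``baughman`` (the interior-point comparison set).
    """
    from importlib.resources import files

    bundled = {"pso", "gao_exp", "gao_decl", "baughman"}
    if isinstance(source, str) and source in bundled:
        text = files("mabkin.data").joinpath(f"params_{source}.yaml").read_text()
    else:
        p = Path(source)
        if not p.exists():
            raise FileNotFoundError(
                f"no parameter file {source!r}; bundled sets: {sorted(bundled)}"
            )
        text = p.read_text()
    doc = yaml.safe_load(text)
    mode = doc.pop("kinetics_mode", "saturable")
    return KineticParameters.from_dict(doc, kinetics_mode=mode)
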