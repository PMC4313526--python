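"""Stoichiometry, rate laws, phase-switched cell dynamics and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mabkin import (
    ExperimentDesign,
    KineticParameters,
    build_network,
    load_params,
    reaction_rates,
    simulate,
    state_derivative,
)
from mabkin.model import (
    IDX,
    KS_KEYS,
    ModelDomainError,
    N_REACTIONS,
    SPECIES,
    STATE_NAMES,
)

# every named coefficient of the reaction scheme (species, reaction, signed value)
PRINTED_COEFFICIENTS = [
    ("GLC", 1, -1), ("LAC", 1, 2),
    ("GLC", 2, -1), ("GLU", 2, -2), ("ALA", 2, 2), ("LAC", 2, 2),
    ("GLC", 3, -1), ("GLU", 3, -2), ("ASP", 3, 2), ("LAC", 3, 2),
    ("GLU", 4, -1), ("PRO", 4, 1),
    ("ASN", 5, -1), ("ASP", 5, 1), ("NH3", 5, 1),
    ("GLN", 6, -1), ("ASP", 6, -1), ("ASN", 6, 1), ("GLU", 6, 1),
    ("GLC", 7, -0.0508), ("GLN", 7, -0.0577), ("ALA", 7, -0.0133),
    ("ASN", 7, -0.006), ("ASP", 7, -0.0201), ("GLU", 7, -0.0016),
    ("PRO", 7, -0.081), ("BM", 7, 1),
    ("GLN", 8, -0.0104), ("ALA", 8, -0.011), ("ASN", 8, -0.072),
    ("ASP", 8, -0.082), ("GLU", 8, -0.0107), ("PRO", 8, -0.0148), ("MAb", 8, 1),
    ("GLN", 9, -1), ("GLU", 9, 1), ("NH3", 9, 1),
]


def _params(phi=None, ks_value=1.0, mu=0.0, kd=0.0, mode="saturable"):
    phi = np.zeros(9) if phi is None else np.asarray(phi, dtype=float)
    ks = {k: ks_value for k in KS_KEYS}
    return KineticParameters(phi_star=phi, ks=ks, mu=mu, kd=kd, kinetics_mode=mode)


class TestNetwork:
    def test_shape_and_labels(self):
        net = build_network()
        assert net.K.shape == (11, 9)
        assert net.species == SPECIES

    @pytest.mark.parametrize("species,reaction,value", PRINTED_COEFFICIENTS)
    def test_printed_coefficients(self, species, reaction, value):
        net = build_network()
        assert net.coefficient(species, reaction) == pytest.approx(value, abs=0)

    def test_only_printed_entries_are_nonzero(self):
        net = build_network()
        assert np.count_nonzero(net.K) == len(PRINTED_COEFFICIENTS)

    def test_biomass_and_antibody_columns_are_dense(self):
        K = build_network().K
        assert np.count_nonzero(K[:, 6]) >= 6
        assert np.count_nonzero(K[:, 7]) >= 6


class TestReactionRates:
    def test_zero_max_rates_give_zero_vector(self):
        state = np.ones(13)
        assert np.all(reaction_rates(state, _params()) == 0)

    def test_half_saturation_point(self):
        # substrate at its half-saturation constant, all other factors saturating
        p = _params(phi=[1] + [0] * 8, ks_value=0.0)
        p = KineticParameters(
            phi_star=p.phi_star, ks={**p.ks, (1, 1): 2.0}, mu=0, kd=0
        )
        state = np.full(13, 1e9)
        state[IDX["GLC"]] = 2.0
        state[IDX["X"]] = 3.0
        assert reaction_rates(state, p)[0] == pytest.approx(0.5 * 1.0 * 3.0)

    def test_biomass_rate_from_fitted_values(self, pso_params):
        # phi7 = phi7* X S2/(K+S2) with the fitted maximum rate and K
        state = np.zeros(13)
        state[IDX["GLN"]] = 2.85
        state[IDX["X"]] = 0.09
        phi = reaction_rates(state, pso_params)
        assert phi[6] == pytest.approx(3977 * 0.09 * 2.85 / (9324 + 2.85), rel=1e-3)
        assert phi[6] == pytest.approx(0.1094, rel=1e-3)

    def test_rates_seven_to_nine_depend_only_on_glutamine(self, pso_params):
        state = np.full(13, 1.0)
        state[IDX["GLN"]] = 0.7
        state[IDX["X"]] = 0.5
        ref = reaction_rates(state, pso_params)
        other = state.copy()
        for name in ("GLC", "GLU", "ASN", "ASP"):
            other[IDX[name]] = 17.0
        got = reaction_rates(other, pso_params)
        assert np.allclose(got[6:9], ref[6:9])

    def test_simplified_mode_is_linear_in_cells(self):
        phi = np.arange(1.0, 10.0)
        p = _params(phi=phi, mode="simplified")
        state = np.zeros(13)
        state[IDX["X"]] = 0.4
        assert np.allclose(reaction_rates(state, p), phi * 0.4)

    def test_zero_half_saturation_equals_simplified(self):
        phi = np.linspace(0.5, 2.0, 9)
        sat = _params(phi=phi, ks_value=0.0)
        simp = _params(phi=phi, mode="simplified")
        state = np.abs(np.sin(np.arange(13))) + 0.1
        assert np.allclose(
            reaction_rates(state, sat), reaction_rates(state, simp)
        )

    def test_negative_concentration_rejected(self):
        state = np.ones(13)
        state[2] = -0.5
        with pytest.raises(ModelDomainError):
            reaction_rates(state, _params())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 50), min_size=13, max_size=13))
    def test_rates_nonnegative_and_bounded(self, values):
        state = np.array(values)
        phi_max = np.full(9, 2.0)
        p = _params(phi=phi_max, ks_value=0.3)
        phi = reaction_rates(state, p)
        assert np.all(phi >= 0)
        # each Monod factor is <= 1, so phi_i <= phi_i* X
        assert np.all(phi <= phi_max * state[IDX["X"]] + 1e-12)


class TestStateDerivative:
    def test_growth_phase_cell_balance(self, design):
        p = _params(mu=0.043, kd=0.067)
        state = np.zeros(13)
        state[IDX["X"]] = 0.09
        state[IDX["Xd"]] = 0.02
        d = state_derivative(0.0, state, p, design)
        assert d[IDX["X"]] == pytest.approx(0.043 * 0.09 - 0.067 * 0.09 * 0.02)
        assert d[IDX["X"]] == pytest.approx(3.7493e-3, rel=1e-4)
        assert d[IDX["Xd"]] == pytest.approx(0.067 * 0.09 * 0.02)

    def test_decline_phase_drops_growth_term(self, design):
        p = _params(mu=0.043, kd=0.067)
        state = np.zeros(13)
        state[IDX["X"]] = 0.5
        state[IDX["Xd"]] = 0.1
        d = state_derivative(60.0, state, p, design)
        assert d[IDX["X"]] == pytest.approx(-0.067 * 0.5 * 0.1)

    def test_all_zero_parameters_give_zero_derivative(self, design):
        state = np.ones(13)
        assert np.all(state_derivative(10.0, state, _params(), design) == 0)

    @pytest.mark.parametrize("t,expected_growth", [(0.0, True), (53.9, True), (54.0, False), (147.0, False)])
    def test_cell_conservation(self, design, t, expected_growth):
        # d(X + Xd)/dt equals mu X during growth and zero afterwards
        p = _params(mu=0.05, kd=0.08)
        state = np.zeros(13)
        state[IDX["X"]], state[IDX["Xd"]] = 0.6, 0.3
        d = state_derivative(t, state, p, design)
        total = d[IDX["X"]] + d[IDX["Xd"]]
        assert total == pytest.approx(0.05 * 0.6 if expected_growth else 0.0, abs=1e-15)


class TestSimulate:
    def test_zero_parameters_constant_trajectory(self, design):
        init = np.linspace(0.1, 1.3, 13)
        grid = np.linspace(0, 147, 30)
        traj = simulate(init, _params(), design, grid)
        assert np.allclose(traj, init[None, :])

    def test_fitted_parameters_reproduce_batch_shapes(self, pso_params, bundled_initial, design):
        grid = np.linspace(0, 147, 148)
        traj = simulate(bundled_initial, pso_params, design, grid)
        gln = traj[:, IDX["GLN"]]
        x = traj[:, IDX["X"]]
        assert gln[-1] < 0.05  # glutamine depletion
        assert 0.7 < x.max() < 1.0  # viable-cell peak
        assert np.argmax(x) < len(grid) - 1 and x[-1] < 0.2  # rise then decline

    def test_dead_cells_nondecreasing(self, pso_params, bundled_initial, design):
        grid = np.linspace(0, 147, 148)
        traj = simulate(bundled_initial, pso_params, design, grid)
        assert np.all(np.diff(traj[:, IDX["Xd"]]) >= -1e-9)

    def test_states_stay_nonnegative(self, pso_params, bundled_initial, design):
        traj = simulate(bundled_initial, pso_params, design, np.linspace(0, 147, 148))
        assert np.all(traj >= 0)

    def test_grid_outside_batch_rejected(self, pso_params, bundled_initial, design):
        with pytest.raises(ModelDomainError):
            simulate(bundled_initial, pso_params, design, np.array([0.0, 200.0]))

    def test_euler_oracle_equivalence(self, design):
        """Adaptive integration agrees with a fine fixed-step Euler oracle.

        Uses the identifiable preset (the fitted real-data parameter set makes
        the glutamate equation too stiff for an explicit fixed-step scheme).
        """
        from mabkin.synthetic import identifiable_preset

        spec = identifiable_preset()
        p, init = spec.true_params, spec.initial
        ts = 0.001
        y = init.copy()
        oracle = [y.copy()]
        for k in range(int(147 / ts)):
            t = k * ts
            dy = state_derivative(t, y, p, design, growth=t < design.t_exp, clip=True)
            y = np.maximum(y + ts * dy, 0.0)
            if (k + 1) % 1000 == 0:
                oracle.append(y.copy())
        oracle = np.array(oracle)
        adaptive = simulate(init, p, design, np.linspace(0, 147, 148))
        for j in range(13):
            scale = max(np.max(np.abs(oracle[:, j])), 1e-30)
            assert np.max(np.abs(oracle[:, j] - adaptive[:, j])) / scale < 1e-3


class TestKineticParameters:
    def test_parameter_count_is_23(self, pso_params):
        assert pso_params.n_free == 23
        assert len(pso_params.to_dict()) == 23

    def test_dict_round_trip(self, pso_params):
        d = pso_params.to_dict()
        back = KineticParameters.from_dict(d)
        assert back.to_dict() == d

    def test_requires_exactly_twelve_half_saturation_keys(self):
        ks = {k: 1.0 for k in KS_KEYS[:-1]}
        with pytest.raises(ModelDomainError):
            KineticParameters(phi_star=np.zeros(9), ks=ks, mu=0.0, kd=0.0)

    def test_saturable_mode_rejects_negative_rates(self):
        with pytest.raises(ModelDomainError):
            _params(phi=[-1] + [0] * 8)

    def test_simplified_mode_allows_negative_net_rates(self):
        p = _params(phi=[-0.0033] + [0.005] * 8, mode="simplified")
        assert p.phi_star[0] == -0.0033

    @pytest.mark.parametrize("name", ["pso", "gao_exp", "gao_decl", "baughman"])
    def test_bundled_fixtures_load(self, name):
        p = load_params(name)
        assert p.n_free == 23

    def test_unknown_fixture_rejected(self):
        with pytest.raises(FileNotFoundError):
            load_params("nonexistent_set")


def test_two_phase_simplified_simulation(bundled_initial, design):
    """The phase-split comparison set simulates without error and switches blocks."""
    from mabkin import simulate_two_phase

    grid = np.linspace(0, 147, 50)
    traj = simulate_two_phase(
        bundled_initial, load_params("gao_exp"), load_params("gao_decl"), design, grid
    )
    assert traj.shape == (50, 13)
    assert np.all(np.isfinite(traj))
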