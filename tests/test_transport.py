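"""Grid construction, porosity/velocity closure and the transport operators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.linalg import solve_banded

from ferriflux.transport import (
    ConfigurationError,
    PorosityProfile,
    TransportParams,
    biodiffusion_profile,
    build_grid,
    irrigation_profile,
    molecular_diffusivity,
    solute_operator,
    solute_swi_flux,
    solid_operator,
    solute_burial_flux,
    tortuosity_factor,
    transport_tendency,
)

POROSITY = PorosityProfile(0.95, 0.82, 3.6)


class TestPorosityAndGrid:
    def test_porosity_endpoints(self):
        assert POROSITY(0.0) == pytest.approx(0.95)
        assert POROSITY(100.0) == pytest.approx(0.82, abs=1e-6)

    def test_invalid_porosity_rejected(self):
        with pytest.raises(ConfigurationError):
            PorosityProfile(0.8, 0.9, 3.6)
        with pytest.raises(ConfigurationError):
            PorosityProfile(1.1, 0.8, 3.6)

    @pytest.mark.parametrize("grading", [0.0, 6.0])
    def test_steady_compaction_identities(self, grading):
        grid = build_grid(150.0, 120, POROSITY, 250.0, grading=grading)
        phi_u = grid.porosity_interfaces * grid.solute_velocity
        psi_w = (1.0 - grid.porosity_interfaces) * grid.solid_velocity
        assert np.all(np.abs(phi_u / phi_u[0] - 1.0) < 1e-10)
        assert np.all(np.abs(psi_w / psi_w[0] - 1.0) < 1e-10)
        assert grid.cell_interfaces[0] == 0.0
        assert grid.cell_interfaces[-1] == pytest.approx(150.0)
        assert np.all(np.diff(grid.cell_interfaces) > 0)

    def test_surface_velocities_match_compaction_formulas(self):
        # 0.82*250/0.95 and 0.18*250/0.05, in cm/kyr
        grid = build_grid(150.0, 200, POROSITY, 250.0)
        u0 = grid.solute_velocity[0] * 1.0e3
        w0 = grid.solid_velocity[0] * 1.0e3
        assert u0 == pytest.approx(0.82 * 250.0 / 0.95, rel=1e-12)
        assert w0 == pytest.approx(0.18 * 250.0 / 0.05, rel=1e-12)

    def test_no_compaction_gives_constant_velocities(self):
        grid = build_grid(150.0, 50, PorosityProfile(0.8, 0.8, 3.6), 100.0)
        assert np.allclose(grid.solute_velocity, 0.1)
        assert np.allclose(grid.solid_velocity, 0.1)

    def test_invalid_grid_arguments(self):
        with pytest.raises(ConfigurationError):
            build_grid(-1.0, 50, POROSITY, 100.0)
        with pytest.raises(ConfigurationError):
            build_grid(150.0, 5, POROSITY, 100.0)
        with pytest.raises(ConfigurationError):
            build_grid(150.0, 50, POROSITY, 0.0)


class TestBioturbationProfiles:
    def test_biodiffusion_zero_and_plateau(self):
        grid = build_grid(150.0, 100, POROSITY, 250.0)
        zero = biodiffusion_profile(TransportParams(), grid)
        assert np.all(zero == 0.0)
        params = TransportParams(biodiffusion_coeff=20.0, mixing_depth=10.0)
        db = biodiffusion_profile(params, grid, z=np.array([0.0, 5.0, 10.0]))
        assert np.allclose(db, 20.0)

    def test_biodiffusion_decay_scale(self):
        params = TransportParams(biodiffusion_coeff=20.0, mixing_depth=10.0)
        grid = build_grid(150.0, 100, POROSITY, 250.0)
        db = biodiffusion_profile(params, grid, z=np.array([11.0]))
        assert db[0] == pytest.approx(20.0 / np.e, rel=1e-12)

    def test_irrigation_profile_values(self):
        grid = build_grid(150.0, 100, POROSITY, 250.0)
        params = TransportParams(irrigation_coeff=183.0,
                                 irrigation_attenuation=3.0)
        a = irrigation_profile(params, grid, "SO4", z=np.array([0.0, 3.0]))
        assert a[0] == pytest.approx(183.0)
        assert a[1] == pytest.approx(183.0 / np.e)

    def test_ferrous_iron_irrigation_scaling(self):
        grid = build_grid(150.0, 100, POROSITY, 250.0)
        params = TransportParams(irrigation_coeff=290.0,
                                 irrigation_attenuation=1.4)
        a = irrigation_profile(params, grid, "Fe2", z=np.array([0.0]))
        assert a[0] == pytest.approx(0.2 * 290.0)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ConfigurationError):
            TransportParams(biodiffusion_coeff=-1.0)


class TestTransportOperator:
    def test_uniform_profile_has_zero_tendency(self):
        grid = build_grid(150.0, 80, POROSITY, 250.0)
        params = TransportParams()
        c = np.full(80, 0.28)
        # no irrigation, fixed bw equal to the field: only advection of the
        # same concentration and no gradients -> zero everywhere
        tend = transport_tendency(c, "solute", grid, params, 0.28, "O2")
        assert np.max(np.abs(tend)) < 1e-12

    def test_irrigation_relaxes_to_bottom_water(self):
        grid = build_grid(150.0, 80, POROSITY, 250.0)
        params = TransportParams(irrigation_coeff=100.0,
                                 irrigation_attenuation=50.0)
        c = np.full(80, 0.28)
        tend = transport_tendency(c, "solute", grid, params, 0.28, "O2")
        assert np.max(np.abs(tend)) < 1e-12
        # and a perturbed field is driven back toward bottom water
        c2 = c + 0.1
        tend2 = transport_tendency(c2, "solute", grid, params, 0.28, "O2")
        assert np.all(tend2[grid.cell_centres < 50.0] < 0.0)

    def test_size_mismatch_raises(self):
        grid = build_grid(150.0, 80, POROSITY, 250.0)
        with pytest.raises(ValueError, match="does not match"):
            transport_tendency(np.zeros(10), "solute", grid,
                               TransportParams(), 0.0, "O2")

    def test_steady_advection_diffusion_matches_analytic(self):
        """Constant-coefficient column with fixed concentrations at both
        ends reproduces the closed-form exponential profile."""
        L, n = 150.0, 200
        por = PorosityProfile(0.9, 0.9, 3.6)        # uniform porosity
        grid = build_grid(L, n, por, 250.0)
        d_eff = np.full(n + 1, 50.0)                # cm^2/yr
        u = grid.solute_velocity[0]
        c_top, c_bot = 1.0, 0.2
        op = solute_operator(grid, d_eff, np.zeros(n), c_top)
        # impose the bottom value through a stiff relaxation in the last cell
        kappa = 1.0e8
        diag = op.diag.copy()
        diag[-1] -= kappa
        const = op.const.copy()
        const[-1] += kappa * c_bot
        ab = np.zeros((3, n))
        ab[0, 1:], ab[1], ab[2, :-1] = op.upper[:-1], diag, op.lower[1:]
        c = solve_banded((1, 1), -ab, const)
        pe = u / 50.0
        z = grid.cell_centres
        zl = z[-1]
        analytic = c_top + (c_bot - c_top) * np.expm1(pe * z) / np.expm1(pe * zl)
        assert np.max(np.abs(c - analytic)) / c_top < 5e-3

    def test_column_mass_conservation(self):
        """Inventory change equals boundary fluxes plus irrigation exchange
        for an arbitrary non-reactive field."""
        rng = np.random.default_rng(42)
        grid = build_grid(150.0, 120, POROSITY, 250.0, grading=6.0)
        params = TransportParams(biodiffusion_coeff=10.0, mixing_depth=9.7,
                                 irrigation_coeff=50.0,
                                 irrigation_attenuation=1.4)
        c = np.abs(rng.normal(1.0, 0.3, 120))
        bw = 0.5
        d0 = molecular_diffusivity("O2", 10.0, 34.2)
        d_eff = d0 / tortuosity_factor(grid.porosity_interfaces) \
            + biodiffusion_profile(params, grid)
        alpha = irrigation_profile(params, grid, "O2")
        op = solute_operator(grid, d_eff, alpha, bw)
        tend = op.apply(c)
        inv_change = np.sum(grid.porosity_centres * tend * grid.dz_cells)
        efflux_dif, efflux_irr = solute_swi_flux(c, grid, d_eff, alpha, bw)
        burial = solute_burial_flux(c, grid)
        # influx through SWI = -(efflux); net = -(dif+irr) - burial
        balance = -(efflux_dif + efflux_irr) - burial
        # the advective influx of bottom water enters through the top too
        balance += 0.0
        assert inv_change == pytest.approx(balance, rel=1e-3)

    def test_solid_deposition_flux_enters_top_cell(self):
        grid = build_grid(150.0, 100, POROSITY, 250.0)
        op = solid_operator(grid, np.zeros(101), 10.0)
        s = np.zeros(100)
        tend = op.apply(s)
        expected = 10.0 / ((1.0 - grid.porosity_centres[0]) * grid.dz_cells[0])
        assert tend[0] == pytest.approx(expected)
        assert np.allclose(tend[1:], 0.0)

    def test_grid_convergence_of_steady_profile(self):
        """Doubling resolution changes the steady conservative profile < 1%."""
        profiles = {}
        for n in (100, 200):
            grid = build_grid(150.0, n, POROSITY, 250.0, grading=6.0)
            d_eff = np.full(n + 1, 100.0)
            alpha = irrigation_profile(
                TransportParams(irrigation_coeff=30.0,
                                irrigation_attenuation=3.0), grid, "SO4")
            op = solute_operator(grid, d_eff, alpha, 1.0)
            ab = np.zeros((3, n))
            ab[0, 1:], ab[1], ab[2, :-1] = op.upper[:-1], op.diag, op.lower[1:]
            profiles[n] = (grid.cell_centres, solve_banded((1, 1), -ab, op.const))
        z100, c100 = profiles[100]
        z200, c200 = profiles[200]
        interp = np.interp(z100, z200, c200)
        assert np.max(np.abs(c100 - interp)) / np.max(np.abs(c200)) < 0.01

    def test_unbioturbated_operator_is_bitwise_reproducible(self):
        """Zero bioturbation parameters give exactly the operator of a build
        without any bioturbation terms."""
        grid = build_grid(150.0, 80, POROSITY, 250.0)
        n = grid.n_cells
        d0 = molecular_diffusivity("Fe2", 10.0, 34.2)
        d_eff = d0 / tortuosity_factor(grid.porosity_interfaces)
        plain = solute_operator(grid, d_eff, np.zeros(n), 0.0)
        params = TransportParams(biodiffusion_coeff=0.0, irrigation_coeff=0.0)
        with_bio = solute_operator(
            grid, d_eff + biodiffusion_profile(params, grid),
            irrigation_profile(params, grid, "Fe2"), 0.0)
        assert np.array_equal(plain.diag, with_bio.diag)
        assert np.array_equal(plain.lower, with_bio.lower)
        assert np.array_equal(plain.upper, with_bio.upper)
        assert np.array_equal(plain.const, with_bio.const)


class TestIrrigationFluxQuadrature:
    def test_irrigation_flux_matches_continuous_quadrature(self):
        """Uniform excess DFe: the discrete irrigation efflux equals the
        alpha-weighted column integral evaluated by adaptive quadrature."""
        por = POROSITY
        grid = build_grid(150.0, 200, por, 250.0, grading=6.0)
        params = TransportParams(irrigation_coeff=290.0 * 0.2,
                                 irrigation_attenuation=1.4)
        alpha = irrigation_profile(params, grid, "SO4")
        c_excess = 0.05
        c = np.full(200, c_excess)
        _dif, irr = solute_swi_flux(c, grid, np.full(201, 100.0), alpha, 0.0)
        integrand = lambda z: por(z) * 0.2 * 290.0 * np.exp(-z / 1.4) * c_excess
        expected, _ = quad(integrand, 0.0, 150.0)
        assert irr == pytest.approx(expected, rel=1e-3)


@given(st.floats(0.1, 30.0), st.floats(0.0, 40.0))
def test_diffusivity_positive_and_increasing_in_temperature(t, s):
    d1 = molecular_diffusivity("O2", t, s)
    d2 = molecular_diffusivity("O2", t + 1.0, s)
    assert 0.0 < d1 < d2
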