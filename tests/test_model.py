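"""Full-model assembly: steady-state solution, flux diagnostics, isotope
closure and the HCl-extractable composite."""

import numpy as np
import pytest
from dataclasses import replace

import ferriflux as ff
from ferriflux.isotopes import IsotopeParams, delta_to_heavy
from ferriflux.model import SpeciesState, SteadyModel, UsageError, fehcl_composite
from ferriflux.reactions import FeOxideClasses, KineticParams, SorptionParams

ZERO_EPS = {k: 0.0 for k in ff.IsotopeParams().eps_eff}


class TestSteadyState:
    def test_column_iron_balance_closes(self, baseline_model):
        _model, _state, diag = baseline_model
        assert diag.fe_balance_error < 0.01
        assert diag.heavy_balance_error < 0.01

    def test_flux_burial_partition(self, baseline_model):
        """Input Fe fluxes equal benthic efflux plus all burial channels."""
        _model, _state, diag = baseline_model
        out = (diag.j_dfe + diag.b_feooh + diag.b_fes + diag.b_fes2
               + diag.b_sorbed + diag.b_dfe_porewater)
        assert out == pytest.approx(diag.fe_input, rel=0.01)

    def test_production_consumption_budget(self, baseline_model):
        """P_DFe - C_DFe = benthic efflux + burial of dissolved and sorbed
        ferrous iron."""
        _model, _state, diag = baseline_model
        lhs = diag.p_dfe - diag.c_dfe
        rhs = diag.j_dfe + diag.b_dfe_porewater + diag.b_sorbed
        assert lhs == pytest.approx(rhs, rel=0.01)

    def test_state_fields_physical(self, baseline_model):
        _model, state, _diag = baseline_model
        for name, c in state.conc.items():
            assert np.all(c >= 0.0), name
        for name, h in state.heavy.items():
            # heavy never exceeds bulk wherever the pool holds real mass
            c = state.conc[name]
            mask = c > 1e-9 * np.max(c) if np.max(c) > 0 else np.zeros_like(c, bool)
            assert np.all(h[mask] <= c[mask] * (1.0 + 1e-6)), name

    def test_benthic_flux_of_solid_is_usage_error(self, baseline_model):
        model, state, _diag = baseline_model
        with pytest.raises(UsageError):
            model.benthic_flux(state, "FeS2")

    def test_result_independent_of_initial_condition(self):
        """Two distinct starting states converge to the same flux."""
        cfg = ff.make_scenario("baseline", 120.0, n_cells=60)
        m1 = SteadyModel(cfg)
        _s1, d1 = m1.run()
        m2 = SteadyModel(cfg)
        y0 = m2._initial_bulk()
        rng = np.random.default_rng(3)
        y0 = y0 * rng.uniform(0.3, 3.0, y0.size)
        _s2, d2 = m2.run(y0=y0)
        assert d2.j_dfe == pytest.approx(d1.j_dfe, rel=1e-3)

    def test_resolution_convergence_of_flux(self):
        """Doubling the number of cells changes J_DFe by < 2%."""
        res = {}
        for n in (200, 400):
            cfg = ff.make_scenario("baseline", 120.0, n_cells=n)
            _s, d = ff.run_to_steady_state(cfg)
            res[n] = d.j_dfe
        assert res[400] == pytest.approx(res[200], rel=0.02)

    def test_conservative_column_stays_uniform(self):
        """All rate constants zero: solutes settle at bottom water, the
        benthic iron flux vanishes."""
        import math
        kin = KineticParams(
            poc_decay=(0.0, 0.0, 0.0), k_feox=0.0, k_hsox=0.0, k_s0ox=0.0,
            k_ch4ox=0.0, k_aom=0.0, k_mnox=0.0, k_fesox=0.0, k_fes2ox=0.0,
            k_fesp=0.0, k_fesd=0.0, k_pyr_hs=0.0, k_pyr_s0=0.0, k_age=0.0,
            k_age_site=0.0,
            oxide_classes=FeOxideClasses(half_life={
                "FeHR": math.inf, "FeMR": math.inf, "FePR": math.inf,
                "FeU": math.inf}),
            sorption=SorptionParams(k_ads=0.0, exchange_rate=0.0),
        )
        cfg = ff.make_scenario("baseline", 120.0, n_cells=40, kinetics=kin)
        state, diag = ff.run_to_steady_state(cfg)
        assert np.allclose(state.conc["O2"], 0.120, rtol=1e-5)
        assert abs(diag.j_dfe) < 1e-6
        assert diag.cox == 0.0


class TestIsotopeClosure:
    def test_zero_fractionation_closure(self, baseline_model):
        """With every eps = 0 the delta of every iron pool and of the
        benthic flux equals the input oxide delta within 0.01 permil."""
        model, state, _diag = baseline_model
        iso0 = IsotopeParams(eps_eff=dict(ZERO_EPS))
        heavy0 = model.solve_heavy(state.conc, isotope_params=iso0)
        cfg0 = model.config.with_overrides(isotopes=iso0)
        state0 = SpeciesState(model.grid, state.conc, heavy0, cfg0)
        j, d = SteadyModel(cfg0).benthic_flux(state0, "Fe2")
        assert d == pytest.approx(model.config.delta_feooh, abs=0.01)
        for name in ("Fe2", "FeHR", "FeS", "FeS2", "XFe"):
            prof = np.asarray(state0.delta(name), dtype=float)
            # judge where the pool holds non-negligible mass
            mask = state0.conc[name] > 1e-6 * np.max(state0.conc[name])
            assert np.all(np.abs(prof[mask]
                                 - model.config.delta_feooh) < 0.01), name

    def test_more_negative_reduction_eps_lowers_flux_delta(self, baseline_model):
        model, state, diag = baseline_model
        eps2 = dict(model.config.isotopes.eps_eff)
        eps2["reduction"] = -2.5
        iso2 = IsotopeParams(eps_eff=eps2)
        heavy2 = model.solve_heavy(state.conc, isotope_params=iso2)
        cfg2 = model.config.with_overrides(isotopes=iso2)
        state2 = SpeciesState(model.grid, state.conc, heavy2, cfg2)
        _j, d2 = SteadyModel(cfg2).benthic_flux(state2, "Fe2")
        assert d2 < diag.delta_jdfe

    def test_heavy_conservation_per_reaction(self, baseline_model):
        """Heavy iron removed from a source pool equals heavy iron added to
        its target pool (shared transfer term, opposite signs)."""
        model, state, _diag = baseline_model
        terms = model._fe_reaction_terms(state.conc)
        for src, tgt, fe_rate, alpha in terms:
            assert np.all(fe_rate >= 0.0)
            assert src != tgt


class TestFeHClComposite:
    def test_composite_reduces_to_oxide_delta_without_fes_and_sorbed(self):
        grid = ff.build_grid(150.0, 20, ff.PorosityProfile(0.9, 0.8, 3.6), 60.0)
        cfg = ff.make_scenario("baseline", 120.0, n_cells=20)
        n = 20
        conc = {"FeHR": np.full(n, 5.0), "XFe": np.zeros(n),
                "FeS": np.zeros(n), "Fe2": np.zeros(n), "FeS2": np.zeros(n)}
        heavy = {k: delta_to_heavy(v, -0.8) for k, v in conc.items()}
        state = SpeciesState(grid, conc, heavy, cfg)
        bulk, delta = fehcl_composite(state)
        assert np.allclose(bulk, 5.0)
        assert np.allclose(delta, -0.8, atol=1e-9)

    def test_two_pool_mixing_arithmetic(self):
        """Equal bulk at 0 and -1 permil mix to the heavy-weighted value
        computed independently from the 56Fe fractions."""
        grid = ff.build_grid(150.0, 10, ff.PorosityProfile(0.9, 0.8, 3.6), 60.0)
        cfg = ff.make_scenario("baseline", 120.0, n_cells=10)
        n = 10
        conc = {"FeHR": np.full(n, 1.0), "FeS": np.full(n, 1.0),
                "XFe": np.zeros(n), "Fe2": np.zeros(n), "FeS2": np.zeros(n)}
        heavy = {"FeHR": delta_to_heavy(np.full(n, 1.0), 0.0),
                 "FeS": delta_to_heavy(np.full(n, 1.0), -1.0),
                 "XFe": np.zeros(n), "Fe2": np.zeros(n), "FeS2": np.zeros(n)}
        state = SpeciesState(grid, conc, heavy, cfg)
        _bulk, delta = fehcl_composite(state)
        # independent mixing oracle on the heavy fractions
        from ferriflux.isotopes import IsotopePool, delta56
        expected = delta56(IsotopePool(
            2.0, float(delta_to_heavy(1.0, 0.0) + delta_to_heavy(1.0, -1.0))))
        assert delta[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-0.5, abs=2e-3)

    def test_igneous_reporting_offset(self):
        grid = ff.build_grid(150.0, 10, ff.PorosityProfile(0.9, 0.8, 3.6), 60.0)
        cfg = ff.make_scenario("baseline", 120.0, n_cells=10)
        conc = {"FeHR": np.full(10, 1.0), "XFe": np.zeros(10),
                "FeS": np.zeros(10), "Fe2": np.zeros(10), "FeS2": np.zeros(10)}
        heavy = {k: delta_to_heavy(v, 0.0) for k, v in conc.items()}
        state = SpeciesState(grid, conc, heavy, cfg)
        _b, delta = fehcl_composite(state, igneous_scale=True)
        assert delta[0] == pytest.approx(-0.09, abs=1e-9)
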