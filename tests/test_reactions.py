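"""Reaction network: stoichiometric conservation, the Monod partition of
organic-matter mineralization, iron-oxide reduction, the sulfide-mineral
system, aging and sorption."""

import dataclasses
import math

import numpy as np
import pytest

from ferriflux.reactions import (
    FeOxideClasses,
    KineticParams,
    SorptionParams,
    StateError,
    aging_rate,
    evaluate_rates,
    iron_oxide_reduction,
    pathway_fractions,
    poc_mineralization,
    reaction_table,
    sorption_partition,
    species_list,
    sulfide_iron_mineral_rates,
)

PHI = np.array([0.9])


def _conc(variant, **overrides):
    base = {s.name: np.array([0.0]) for s in species_list(variant)}
    for k, v in overrides.items():
        base[k] = np.array([float(v)])
    return base


class TestNetworkStructure:
    @pytest.mark.parametrize("variant", ["idealized", "site"])
    def test_every_reaction_conserves_iron_and_sulfur(self, variant):
        for rx in reaction_table(variant):
            assert rx.fe_balance() == pytest.approx(0.0, abs=1e-12), rx.id
            assert rx.s_balance() == pytest.approx(0.0, abs=1e-12), rx.id

    def test_site_network_disables_nitrogen_and_manganese(self):
        site_ids = {rx.id for rx in reaction_table("site")}
        assert not any("NO3" in i or "Mn" in i for i in site_ids)
        ideal_ids = {rx.id for rx in reaction_table("idealized")}
        # the shared chemistry is one code path: every non-N/Mn, non-oxide-
        # class-specific reaction appears in both variants
        shared = {"fe_ox", "fes_precip", "fes_diss", "pyrite_hs", "pyrite_s0",
                  "fes_ox", "fes2_ox", "hs_ox", "s0_ox", "ch4_ox", "aom",
                  "aging", "fe_ads", "fe_des"}
        assert shared <= site_ids and shared <= ideal_ids

    def test_fe_transfer_reactions_declare_source_and_target(self):
        for variant in ("idealized", "site"):
            for rx in reaction_table(variant):
                if rx.eps_key is not None:
                    assert rx.fe_source is not None and rx.fe_target is not None

    @pytest.mark.parametrize("variant", ["idealized", "site"])
    def test_zero_rate_constants_give_zero_tendency(self, variant):
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
        conc = _conc(variant, O2=0.1, SO4=28.0, Fe2=0.05, HS=0.2, CH4=0.1,
                     POC1=100.0, FeS=10.0, FeS2=10.0, S0=1.0, XFe=5.0)
        rates = evaluate_rates(conc, PHI, variant, kin)
        assert all(np.all(r == 0.0) for r in rates.values())


class TestMineralizationPartition:
    def test_fractions_sum_to_one(self):
        kin = KineticParams()
        conc = _conc("idealized", O2=0.05, NO3=0.02, SO4=20.0, MnO2=30.0,
                     FeHR=50.0)
        fracs = pathway_fractions(conc, "idealized", kin)
        assert sum(f[0] for f in fracs.values()) == pytest.approx(1.0, abs=1e-5)

    def test_abundant_oxygen_dominates(self):
        kin = KineticParams()
        conc = _conc("idealized", O2=0.3, NO3=0.03, SO4=28.0, MnO2=50.0,
                     FeHR=100.0)
        fracs = pathway_fractions(conc, "idealized", kin)
        assert fracs["O2"][0] > 0.99

    def test_no_oxidants_leaves_methanogenesis(self):
        kin = KineticParams()
        conc = _conc("idealized")
        fracs = pathway_fractions(conc, "idealized", kin)
        assert fracs["CH4"][0] == pytest.approx(1.0, abs=1e-3)

    def test_pathway_rates_sum_to_total_decay(self):
        kin = KineticParams()
        conc = _conc("idealized", O2=0.01, NO3=0.01, SO4=5.0, MnO2=20.0,
                     FeHR=80.0, POC1=50.0, POC2=100.0, POC3=300.0)
        paths = poc_mineralization(conc, PHI, "idealized", kin)
        total = sum(v[0] for v in paths.values())
        expected = sum(kin.poc_decay[j] * conc[f"POC{j + 1}"][0] * (1 - PHI[0])
                       for j in range(3))
        assert total == pytest.approx(expected, rel=1e-5)

    def test_site_variant_exposes_reduced_pathway_set(self):
        kin = KineticParams()
        paths = poc_mineralization(_conc("site", O2=0.1, POC1=10.0),
                                   PHI, "site", kin)
        assert set(paths) == {"O2", "FeOOH", "SO4", "CH4"}


class TestOxideReduction:
    def test_zero_sulfide_means_no_sulfide_reduction(self):
        kin = KineticParams()
        conc = _conc("idealized", FeHR=50.0, FeMR=50.0, FePR=50.0, FeU=50.0)
        rates = iron_oxide_reduction(conc, PHI, "idealized", kin)
        for cls in ("FeHR", "FeMR", "FePR"):
            assert rates[f"hs_red_{cls}"][0] == 0.0

    def test_rate_constants_recover_half_lives(self):
        classes = FeOxideClasses()
        # k = ln 2 / t_half at the 1 mM reference sulfide level
        assert classes.rate_constant("FeHR") == pytest.approx(
            math.log(2.0) / 0.5)
        assert classes.rate_constant("FeMR") == pytest.approx(
            math.log(2.0) / 100.0)
        ratio = classes.rate_constant("FeHR") / classes.rate_constant("FeMR")
        assert ratio == pytest.approx(200.0)
        assert classes.rate_constant("FeU") == 0.0

    def test_reactivity_ordering_with_equal_stocks(self):
        kin = KineticParams()
        conc = _conc("idealized", FeHR=50.0, FeMR=50.0, FePR=50.0, FeU=50.0,
                     HS=0.5)
        rates = iron_oxide_reduction(conc, PHI, "idealized", kin)
        assert rates["hs_red_FeHR"][0] > rates["hs_red_FeMR"][0] \
            > rates["hs_red_FePR"][0] > 0.0

    def test_unreactive_class_never_reacts(self):
        ids = {rx.id for rx in reaction_table("idealized")}
        assert not any("FeU" in i for i in ids)

    def test_input_partition_must_sum_to_one(self):
        with pytest.raises(StateError):
            FeOxideClasses(partition={"FeU": 0.5, "FeHR": 0.4})


class TestSulfideMineralSystem:
    def test_net_precipitation_vanishes_at_saturation(self):
        kin = KineticParams()
        # Omega = 1 exactly: Fe * HS = K_sp
        fe = 0.02
        hs = kin.k_fes_sat / fe
        conc = _conc("idealized", Fe2=fe, HS=hs, FeS=5.0)
        r = sulfide_iron_mineral_rates(conc, PHI, "idealized", kin)
        net = r["fes_precip"][0] - r["fes_diss"][0]
        # zero within the width of the C1 smoothing of the switch
        assert abs(net) <= kin.k_fesp * 1.0e-3

    def test_no_pyrite_without_fes(self):
        kin = KineticParams()
        conc = _conc("idealized", HS=1.0, S0=5.0)
        r = sulfide_iron_mineral_rates(conc, PHI, "idealized", kin)
        assert r["pyrite_hs"][0] == 0.0 and r["pyrite_s0"][0] == 0.0

    def test_precipitation_linear_in_ferrous_far_above_saturation(self):
        kin = KineticParams()
        c1 = _conc("idealized", Fe2=0.5, HS=1.0)
        c2 = _conc("idealized", Fe2=1.0, HS=1.0)
        r1 = sulfide_iron_mineral_rates(c1, PHI, "idealized", kin)
        r2 = sulfide_iron_mineral_rates(c2, PHI, "idealized", kin)
        assert r2["fes_precip"][0] / r1["fes_precip"][0] == pytest.approx(
            2.0, rel=1e-3)

    def test_all_oxidations_stop_without_oxygen(self):
        kin = KineticParams()
        conc = _conc("idealized", Fe2=0.1, FeS=10.0, FeS2=10.0, HS=0.5, S0=2.0)
        r = sulfide_iron_mineral_rates(conc, PHI, "idealized", kin)
        for key in ("fe_ox", "fes_ox", "fes2_ox"):
            assert r[key][0] == 0.0


class TestAging:
    def test_zero_source_zero_rate(self):
        kin = KineticParams()
        assert aging_rate(_conc("idealized"), PHI, "idealized", kin)[0] == 0.0

    def test_aging_conserves_total_oxide(self):
        for variant in ("idealized", "site"):
            rx = next(r for r in reaction_table(variant) if r.id == "aging")
            assert sum(rx.stoichiometry.values()) == pytest.approx(0.0)

    def test_first_order_in_source_pool(self):
        """A closed source pool decays with e-folding time 1/k_age."""
        kin = KineticParams()
        for c0 in (10.0, 20.0):
            conc = _conc("idealized", FeHR=c0)
            rate = aging_rate(conc, PHI, "idealized", kin)[0]
            # dC/dt = -rate/(1-phi) = -k_age * C  ->  e-folding 1/k_age
            assert rate / (1.0 - PHI[0]) == pytest.approx(kin.k_age * c0,
                                                          rel=1e-6)


class TestSorptionPartition:
    def test_zero_kads_all_dissolved(self):
        d, a = sorption_partition(1.0, SorptionParams(k_ads=0.0), 0.9)
        assert a == 0.0 and d == pytest.approx(1.0 / 0.9)

    def test_equilibrium_inventory_ratio(self):
        p = SorptionParams(k_ads=170.0)
        phi = 0.85
        d, a = sorption_partition(2.0, p, phi)
        dissolved_inv = phi * d
        adsorbed_inv = (1.0 - phi) * a
        assert adsorbed_inv == pytest.approx(170.0 * dissolved_inv, rel=1e-12)

    def test_round_trip_total(self):
        p = SorptionParams(k_ads=55.0)
        phi = np.array([0.95, 0.82])
        total = np.array([0.3, 1.7])
        d, a = sorption_partition(total, p, phi)
        back = phi * d + (1.0 - phi) * a
        assert np.allclose(back, total, rtol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(StateError):
            sorption_partition(-1.0, SorptionParams(), 0.9)

    def test_kinetic_exchange_balances_at_equilibrium(self):
        """The paired one-way exchange rates cancel exactly at the
        equilibrium partition."""
        kin = KineticParams()
        p = kin.sorption
        phi = np.array([0.88])
        d, a = sorption_partition(1.0, p, phi)
        conc = _conc("idealized", Fe2=d[0], XFe=a[0])
        rates = evaluate_rates(conc, phi, "idealized", kin)
        assert rates["fe_ads"][0] == pytest.approx(rates["fe_des"][0],
                                                   rel=1e-6)
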