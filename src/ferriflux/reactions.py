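"""Species definitions and the kinetic reaction network.

Two variants of one network are provided:

* ``idealized`` — the full C-N-O-Mn-Fe-S network with four iron-oxide
  reactivity classes (FeHR, FeMR, FePR, FeU) defined by their half-life
  toward dissolved sulfide (< 1 yr, ~100 yr, ~100 000 yr, inert).
* ``site`` — the reduced C-O-Fe-S network used for site calibration, in
  which nitrogen and manganese cycling are disabled and the highly
  reactive oxide class is split into 'fresh' and 'aged' sub-pools.

Conventions
-----------
Reaction extents are volumetric rates per cm^3 of *total* sediment per
year.  Rate laws therefore carry the phase-volume fraction of their
rate-limiting reactant (``phi`` for pore-water reactions, ``1 - phi`` for
solid-bound reactants).  The stoichiometry maps species to signed
multiples of the extent; iron-transfer reactions additionally name their
Fe source and target pools and the number of Fe atoms moved per unit
extent, which is what the isotope stage consumes.

Organic matter is a multi-G mixture: two reactive fractions plus one
refractory fraction whose decay constants are chosen so that roughly 17%
of the POC rain survives burial through a 150 cm column.  Mineralization
is partitioned over the oxidants by Monod limitation with inhibition by
every more favourable oxidant; the methanogenic pathway carries the
remainder, so the pathway fractions always sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class StateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesDef:
    name: str
    phase: str                  # "solute" | "solid"
    isotope_tracked: bool = False


_SOLUTES_IDEALIZED = ["O2", "NO3", "SO4", "Fe2", "HS", "CH4", "Mn2"]
_SOLIDS_IDEALIZED = [
    "POC1", "POC2", "POC3", "MnO2",
    "FeHR", "FeMR", "FePR", "FeU", "FeS", "FeS2", "S0", "XFe",
]
_SOLUTES_SITE = ["O2", "SO4", "Fe2", "HS", "CH4"]
_SOLIDS_SITE = ["POC1", "POC2", "POC3", "FeHRf", "FeHRa", "FeS", "FeS2", "S0", "XFe"]

_FE_SPECIES = {"Fe2", "XFe", "FeHR", "FeHRf", "FeHRa", "FeMR", "FePR", "FeU",
               "FeS", "FeS2"}


def species_list(variant: str) -> list[SpeciesDef]:
    if variant == "idealized":
        solutes, solids = _SOLUTES_IDEALIZED, _SOLIDS_IDEALIZED
    elif variant == "site":
        solutes, solids = _SOLUTES_SITE, _SOLIDS_SITE
    else:
        raise StateError(f"unknown model variant {variant!r}")
    out = [SpeciesDef(n, "solute", n in _FE_SPECIES) for n in solutes]
    out += [SpeciesDef(n, "solid", n in _FE_SPECIES) for n in solids]
    return out


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

#: reference sulfide level (1 mM == 1 umol cm^-3) at which the class
#: half-lives are defined; bimolecular constants are k = ln2 / (t_half * HS_ref)
HS_REFERENCE = 1.0


@dataclass(frozen=True)
class FeOxideClasses:
    """Iron-oxide reactivity classes: sulfide half-lives and input partition."""

    half_life: dict = field(default_factory=lambda: {
        "FeHR": 0.5, "FeMR": 100.0, "FePR": 1.0e5, "FeU": math.inf,
    })
    partition: dict = field(default_factory=lambda: {
        "FeU": 0.5, "FeHR": 1.0 / 6.0, "FeMR": 1.0 / 6.0, "FePR": 1.0 / 6.0,
    })

    def __post_init__(self) -> None:
        total = sum(self.partition.values())
        if abs(total - 1.0) > 1.0e-9:
            raise StateError(f"oxide input partition sums to {total}, not 1")

    def rate_constant(self, name: str) -> float:
        """Bimolecular sulfide-reduction constant, (umol cm^-3)^-1 yr^-1."""
        t = self.half_life[name]
        if math.isinf(t):
            return 0.0
        return math.log(2.0) / (t * HS_REFERENCE)


@dataclass(frozen=True)
class SorptionParams:
    k_ads: float = 170.0          # dimensionless, on column inventories
    eps_sorption: float = +0.4    # permil
    exchange_rate: float = 100.0  # yr^-1, relaxation toward equilibrium

    def __post_init__(self) -> None:
        if self.k_ads < 0.0:
            raise StateError("k_ads must be >= 0")


def sorption_partition(total_ferrous, params: SorptionParams, porosity):
    """Split a total ferrous inventory (umol per cm^3 of total sediment)
    into a dissolved pore-water concentration and an adsorbed solid-phase
    concentration obeying the equilibrium I_adsorbed = k_ads * I_dissolved.
    """
    total = np.asarray(total_ferrous, dtype=float)
    if np.any(total < 0.0):
        raise StateError("total ferrous inventory must be >= 0")
    phi = np.asarray(porosity, dtype=float)
    dissolved_inv = total / (1.0 + params.k_ads)
    dissolved = dissolved_inv / phi
    adsorbed = params.k_ads * dissolved_inv / (1.0 - phi)
    return dissolved, adsorbed


@dataclass
class KineticParams:
    """Rate constants and half-saturation constants.

    Solute concentrations are in umol cm^-3 of pore water (== mM), solid
    concentrations in umol cm^-3 of solid.  Bimolecular constants are per
    (umol cm^-3) per year of the named co-reactant.
    """

    # multi-G POC: input fractions and first-order decay constants (yr^-1)
    poc_fractions: tuple = (0.50, 0.33, 0.17)
    poc_decay: tuple = (24.0, 1.4, 1.0e-5)

    # Monod half-saturation / inhibition constants
    k_o2: float = 0.001       # mM
    k_no3: float = 0.005      # mM
    k_mno2: float = 50.0      # umol cm^-3 solid
    k_feoh: float = 250.0     # umol cm^-3 solid
    k_so4: float = 1.0        # mM

    # secondary redox reactions
    k_feox: float = 3.0e6     # Fe2+ + O2
    k_hsox: float = 1.0e4     # HS + O2
    k_s0ox: float = 160.0     # S0 + O2
    k_ch4ox: float = 1.0e4    # CH4 + O2
    k_aom: float = 10.0       # CH4 + SO4
    k_mnox: float = 1.0e3     # Mn2+ + O2
    k_fesox: float = 1.0e3    # FeS + O2
    k_fes2ox: float = 1.0     # FeS2 + O2

    # iron-sulfide mineral system
    k_fes_sat: float = 3.0e-4   # conditional FeS solubility, mM^2
    k_fesp: float = 1.5e3       # FeS precipitation, umol cm^-3 yr^-1 per (Omega-1)
    k_fesd: float = 1.0e-3      # FeS dissolution, yr^-1 per (1-Omega)
    k_pyr_hs: float = 1.2       # FeS + HS -> FeS2
    k_pyr_s0: float = 3.0e-4    # FeS + S0 -> FeS2

    # oxide aging
    k_age: float = 0.1          # idealized FeHR -> FeMR, yr^-1
    k_age_site: float = 0.5     # site fresh -> aged FeHR, yr^-1
    #: sulfide reactivity of aged relative to fresh highly-reactive oxides
    aged_reactivity: float = 0.05
    #: bioavailability of aged oxides to dissimilatory reduction, relative
    #: to fresh (0 = microbes use fresh oxides only)
    dir_aged_weight: float = 1.0

    oxide_classes: FeOxideClasses = field(default_factory=FeOxideClasses)
    sorption: SorptionParams = field(default_factory=SorptionParams)


# ---------------------------------------------------------------------------
# reaction definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionDef:
    """One lumped reaction: stoichiometry per unit extent plus iron-transfer
    metadata used by the isotope stage."""

    id: str
    stoichiometry: dict
    eps_key: str | None = None   # key into IsotopeParams.eps_eff, or None
    fe_source: str | None = None
    fe_target: str | None = None
    fe_per_extent: float = 0.0

    def fe_balance(self) -> float:
        return sum(c for s, c in self.stoichiometry.items() if s in _FE_SPECIES)

    def s_balance(self) -> float:
        weights = {"SO4": 1, "HS": 1, "S0": 1, "FeS": 1, "FeS2": 2}
        return sum(c * weights[s] for s, c in self.stoichiometry.items()
                   if s in weights)


def _dir_classes(variant: str) -> list[str]:
    """Oxide classes available to dissimilatory (organoclastic) reduction:
    the highly reactive pool only (both its fresh and aged sub-pools)."""
    return ["FeHR"] if variant == "idealized" else ["FeHRf", "FeHRa"]


def _dir_weights(variant: str, p: "KineticParams") -> dict:
    """Bioavailability weights of the DIR-available oxide classes."""
    if variant == "idealized":
        return {"FeHR": 1.0}
    return {"FeHRf": 1.0, "FeHRa": p.dir_aged_weight}


def _sulfide_classes(variant: str) -> list[str]:
    return (["FeHR", "FeMR", "FePR"] if variant == "idealized"
            else ["FeHRf", "FeHRa"])


def _oxidation_target(variant: str) -> str:
    return "FeHR" if variant == "idealized" else "FeHRf"


def reaction_table(variant: str) -> list[ReactionDef]:
    """Enumerate the reaction network of a variant (stoichiometry only)."""
    rx: list[ReactionDef] = []
    tgt = _oxidation_target(variant)
    pocs = ["POC1", "POC2", "POC3"]

    for poc in pocs:
        rx.append(ReactionDef(f"{poc}_O2", {poc: -1.0, "O2": -1.0}))
        if variant == "idealized":
            rx.append(ReactionDef(f"{poc}_NO3", {poc: -1.0, "NO3": -0.8}))
            rx.append(ReactionDef(
                f"{poc}_MnO2", {poc: -1.0, "MnO2": -2.0, "Mn2": +2.0}))
        for cls in _dir_classes(variant):
            rx.append(ReactionDef(
                f"{poc}_{cls}", {poc: -1.0, cls: -4.0, "Fe2": +4.0},
                eps_key="reduction", fe_source=cls, fe_target="Fe2",
                fe_per_extent=4.0))
        rx.append(ReactionDef(f"{poc}_SO4", {poc: -1.0, "SO4": -0.5, "HS": +0.5}))
        rx.append(ReactionDef(f"{poc}_CH4", {poc: -1.0, "CH4": +0.5}))

    for cls in _sulfide_classes(variant):
        rx.append(ReactionDef(
            f"hs_red_{cls}", {cls: -1.0, "Fe2": +1.0, "HS": -0.5, "S0": +0.5},
            eps_key="reduction", fe_source=cls, fe_target="Fe2",
            fe_per_extent=1.0))

    rx.append(ReactionDef(
        "fe_ox", {"Fe2": -1.0, "O2": -0.25, tgt: +1.0},
        eps_key="oxidation", fe_source="Fe2", fe_target=tgt, fe_per_extent=1.0))
    rx.append(ReactionDef(
        "fes_precip", {"Fe2": -1.0, "HS": -1.0, "FeS": +1.0},
        eps_key="fes_precipitation", fe_source="Fe2", fe_target="FeS",
        fe_per_extent=1.0))
    rx.append(ReactionDef(
        "fes_diss", {"FeS": -1.0, "Fe2": +1.0, "HS": +1.0},
        eps_key="fes_dissolution", fe_source="FeS", fe_target="Fe2",
        fe_per_extent=1.0))
    rx.append(ReactionDef(
        "pyrite_hs", {"FeS": -1.0, "HS": -1.0, "FeS2": +1.0},
        eps_key="pyrite_precipitation", fe_source="FeS", fe_target="FeS2",
        fe_per_extent=1.0))
    rx.append(ReactionDef(
        "pyrite_s0", {"FeS": -1.0, "S0": -1.0, "FeS2": +1.0},
        eps_key="pyrite_precipitation", fe_source="FeS", fe_target="FeS2",
        fe_per_extent=1.0))
    rx.append(ReactionDef(
        "fes_ox", {"FeS": -1.0, "O2": -2.25, tgt: +1.0, "SO4": +1.0},
        eps_key="oxidation", fe_source="FeS", fe_target=tgt, fe_per_extent=1.0))
    rx.append(ReactionDef(
        "fes2_ox", {"FeS2": -1.0, "O2": -3.75, tgt: +1.0, "SO4": +2.0},
        eps_key="oxidation", fe_source="FeS2", fe_target=tgt, fe_per_extent=1.0))
    rx.append(ReactionDef("hs_ox", {"HS": -1.0, "O2": -2.0, "SO4": +1.0}))
    rx.append(ReactionDef("s0_ox", {"S0": -1.0, "O2": -1.5, "SO4": +1.0}))
    rx.append(ReactionDef("ch4_ox", {"CH4": -1.0, "O2": -2.0}))
    rx.append(ReactionDef("aom", {"CH4": -1.0, "SO4": -1.0, "HS": +1.0}))
    if variant == "idealized":
        rx.append(ReactionDef("mn_ox", {"Mn2": -1.0, "O2": -0.5, "MnO2": +1.0}))
        rx.append(ReactionDef(
            "aging", {"FeHR": -1.0, "FeMR": +1.0},
            fe_source="FeHR", fe_target="FeMR", fe_per_extent=1.0))
    else:
        rx.append(ReactionDef(
            "aging", {"FeHRf": -1.0, "FeHRa": +1.0},
            fe_source="FeHRf", fe_target="FeHRa", fe_per_extent=1.0))
    rx.append(ReactionDef(
        "fe_ads", {"Fe2": -1.0, "XFe": +1.0},
        eps_key="sorption", fe_source="Fe2", fe_target="XFe",
        fe_per_extent=1.0))
    rx.append(ReactionDef(
        "fe_des", {"XFe": -1.0, "Fe2": +1.0},
        fe_source="XFe", fe_target="Fe2", fe_per_extent=1.0))
    return rx


# ---------------------------------------------------------------------------
# rate evaluation
# ---------------------------------------------------------------------------

def mineralization_pathways(variant: str) -> list[str]:
    if variant == "idealized":
        return ["O2", "NO3", "MnO2", "FeOOH", "SO4", "CH4"]
    return ["O2", "FeOOH", "SO4", "CH4"]


def pathway_fractions(conc: dict, variant: str, p: KineticParams) -> dict:
    """Monod limitation / inhibition partition of POC decay over oxidants.

    Returns a dict pathway -> fraction field; fractions sum to one at every
    depth, the methanogenic remainder closing the budget.
    """
    o2 = np.maximum(conc["O2"], 0.0)
    so4 = np.maximum(conc["SO4"], 0.0)
    weights = _dir_weights(variant, p)
    feoh = sum(w * np.maximum(conc[c], 0.0) for c, w in weights.items())

    lim_o2 = o2 / (p.k_o2 + o2)
    inh_o2 = p.k_o2 / (p.k_o2 + o2)
    out = {"O2": lim_o2}
    inhib = inh_o2
    if variant == "idealized":
        no3 = np.maximum(conc["NO3"], 0.0)
        mno2 = np.maximum(conc["MnO2"], 0.0)
        out["NO3"] = no3 / (p.k_no3 + no3) * inhib
        inhib = inhib * p.k_no3 / (p.k_no3 + no3)
        out["MnO2"] = mno2 / (p.k_mno2 + mno2) * inhib
        inhib = inhib * p.k_mno2 / (p.k_mno2 + mno2)
    out["FeOOH"] = feoh / (p.k_feoh + feoh) * inhib
    inhib = inhib * p.k_feoh / (p.k_feoh + feoh)
    out["SO4"] = so4 / (p.k_so4 + so4) * inhib
    remainder = 1.0 - sum(out.values())
    out["CH4"] = _smooth_pos(remainder, 1.0e-6)
    return out


def poc_decay_rates(conc: dict, psi, p: KineticParams) -> dict:
    """Total first-order decay of each POC fraction, per total volume."""
    return {
        f"POC{j + 1}": p.poc_decay[j] * np.maximum(conc[f"POC{j + 1}"], 0.0) * psi
        for j in range(3)
    }


def _smooth_pos(x, eps: float = 1.0e-3):
    """C1-smooth approximation of max(x, 0); exact to O(eps) away from 0."""
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def _smooth_clip(x, eps: float = 1.0e-9):
    """C1 clip that is *exactly* zero for x <= 0.

    Quadratic blend on (0, eps), linear above.  Unlike a sqrt-smoothed max,
    whose 1/|x| tail leaves spurious residual consumption in exhausted
    zones, this vanishes identically for non-positive concentrations, so
    Newton closes those residuals in one step.
    """
    x = np.asarray(x, dtype=float)
    return np.where(
        x >= eps, x - 0.5 * eps,
        np.where(x > 0.0, x * x / (2.0 * eps), 0.0),
    )


def evaluate_rates(conc: dict, phi, variant: str, p: KineticParams) -> dict:
    """Extent of every reaction (umol cm^-3 total sediment yr^-1).

    Concentrations may be clipped at zero internally; rates are always
    non-negative per the one-way formulation of every reaction.
    """
    phi = np.asarray(phi, dtype=float)
    psi = 1.0 - phi
    # smooth clip: keeps the rhs C1 when the solver probes small negatives
    c = {k: _smooth_clip(v) for k, v in conc.items()}
    rates: dict[str, np.ndarray] = {}

    fracs = pathway_fractions(c, variant, p)
    decay = poc_decay_rates(c, psi, p)
    dir_classes = _dir_classes(variant)
    weights = _dir_weights(variant, p)
    feoh_total = sum(weights[cls] * c[cls] for cls in dir_classes)
    safe_feoh = np.where(feoh_total > 0.0, feoh_total, 1.0)
    for poc, r_tot in decay.items():
        rates[f"{poc}_O2"] = r_tot * fracs["O2"]
        if variant == "idealized":
            rates[f"{poc}_NO3"] = r_tot * fracs["NO3"]
            rates[f"{poc}_MnO2"] = r_tot * fracs["MnO2"]
        for cls in dir_classes:
            share = np.where(
                feoh_total > 0.0, weights[cls] * c[cls] / safe_feoh, 0.0)
            rates[f"{poc}_{cls}"] = r_tot * fracs["FeOOH"] * share
        rates[f"{poc}_SO4"] = r_tot * fracs["SO4"]
        rates[f"{poc}_CH4"] = r_tot * fracs["CH4"]

    hs = c["HS"]
    for cls in _sulfide_classes(variant):
        if variant == "site":
            k = p.oxide_classes.rate_constant("FeHR")
            if cls == "FeHRa":
                k *= p.aged_reactivity
        else:
            k = p.oxide_classes.rate_constant(cls)
        rates[f"hs_red_{cls}"] = k * c[cls] * psi * hs

    o2 = c["O2"]
    fe2 = c["Fe2"]
    rates["fe_ox"] = p.k_feox * fe2 * o2 * phi

    # smoothed one-sided saturation terms: the C1 clip avoids a derivative
    # jump at Omega = 1 that otherwise makes Newton chatter, and is exactly
    # zero away from saturation (no phantom rates in undersaturated zones)
    omega = fe2 * hs / p.k_fes_sat
    over = _smooth_clip(omega - 1.0, 1.0e-3)
    under = _smooth_clip(1.0 - omega, 1.0e-3)
    rates["fes_precip"] = p.k_fesp * over * phi
    rates["fes_diss"] = p.k_fesd * c["FeS"] * psi * under
    rates["pyrite_hs"] = p.k_pyr_hs * c["FeS"] * psi * hs
    rates["pyrite_s0"] = p.k_pyr_s0 * c["FeS"] * psi * c["S0"]
    rates["fes_ox"] = p.k_fesox * c["FeS"] * psi * o2
    rates["fes2_ox"] = p.k_fes2ox * c["FeS2"] * psi * o2
    rates["hs_ox"] = p.k_hsox * hs * o2 * phi
    rates["s0_ox"] = p.k_s0ox * c["S0"] * psi * o2
    rates["ch4_ox"] = p.k_ch4ox * c["CH4"] * o2 * phi
    rates["aom"] = p.k_aom * c["CH4"] * c["SO4"] * phi
    if variant == "idealized":
        rates["mn_ox"] = p.k_mnox * c["Mn2"] * o2 * phi
        rates["aging"] = p.k_age * c["FeHR"] * psi
    else:
        rates["aging"] = p.k_age_site * c["FeHRf"] * psi

    # reversible sorption as paired one-way exchanges; their balance point is
    # the equilibrium I_adsorbed = k_ads * I_dissolved
    srt = p.sorption
    rates["fe_ads"] = srt.exchange_rate * srt.k_ads * phi * fe2
    rates["fe_des"] = srt.exchange_rate * psi * c["XFe"]
    return rates


# ---------------------------------------------------------------------------
# spec-level convenience operations (thin views over evaluate_rates)
# ---------------------------------------------------------------------------

def poc_mineralization(conc: dict, phi, variant: str, p: KineticParams) -> dict:
    """Per-pathway POC mineralization rates (C units, per total volume)."""
    fracs = pathway_fractions({k: np.maximum(v, 0.0) for k, v in conc.items()},
                              variant, p)
    total = sum(poc_decay_rates(conc, 1.0 - np.asarray(phi, float), p).values())
    return {path: total * f for path, f in fracs.items()}


def iron_oxide_reduction(conc: dict, phi, variant: str, p: KineticParams) -> dict:
    """Dissimilatory and sulfide-mediated oxide reduction rates (Fe units)."""
    rates = evaluate_rates(conc, phi, variant, p)
    out = {}
    for cls in _dir_classes(variant):
        out[f"dir_{cls}"] = 4.0 * sum(
            rates[f"POC{j + 1}_{cls}"] for j in range(3))
    for cls in _sulfide_classes(variant):
        out[f"hs_red_{cls}"] = rates[f"hs_red_{cls}"]
    return out


def sulfide_iron_mineral_rates(conc: dict, phi, variant: str,
                               p: KineticParams) -> dict:
    rates = evaluate_rates(conc, phi, variant, p)
    keys = ["fes_precip", "fes_diss", "pyrite_hs", "pyrite_s0",
            "fe_ox", "fes_ox", "fes2_ox"]
    return {k: rates[k] for k in keys}


def aging_rate(conc: dict, phi, variant: str, p: KineticParams):
    return evaluate_rates(conc, phi, variant, p)["aging"]
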