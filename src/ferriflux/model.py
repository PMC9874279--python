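"""Full model assembly: transport + reactions + isotopes, steady-state
integration and the benthic-flux / burial diagnostics.

The solution proceeds in two stages.  The bulk stage solves the coupled
nonlinear system for all species concentrations.  The heavy stage then
solves for the 56Fe sub-pools of the Fe-bearing species with the bulk
reaction extents frozen: every Fe-transfer reaction moves heavy iron at
the rate dictated by its source pool's isotope ratio and its effective
fractionation factor.  Freezing the bulk extents is exact at steady state
(the isotope equations do not feed back on the bulk chemistry) and makes
isotope-parameter studies cheap, because only the second stage needs
re-solving when a fractionation factor changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .isotopes import (
    IsotopeParams,
    IsotopePool,
    delta56,
    delta_to_heavy,
    eps_to_alpha,
    heavy_rate_fraction,
)
from .reactions import (
    KineticParams,
    ReactionDef,
    evaluate_rates,
    poc_decay_rates,
    reaction_table,
    species_list,
)
from .scenarios import ScenarioConfig
from .solver import steady_state_solve
from .transport import (
    Grid,
    biodiffusion_profile,
    build_grid,
    irrigation_profile,
    molecular_diffusivity,
    solid_burial_flux,
    solid_operator,
    solute_burial_flux,
    solute_operator,
    solute_swi_flux,
    tortuosity_factor,
)

__all__ = [
    "SpeciesState",
    "FluxDiagnostics",
    "SteadyModel",
    "run_to_steady_state",
    "benthic_flux",
    "integrated_rates",
    "fehcl_composite",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SpeciesState:
    """Converged concentration fields plus paired 56Fe fields."""

    grid: Grid
    conc: dict                      # species -> field (native phase units)
    heavy: dict                     # Fe species -> 56Fe field
    config: ScenarioConfig

    def delta(self, species: str, igneous_scale: bool = False):
        """delta56Fe profile of one Fe species (nan where the pool is empty)."""
        pool = IsotopePool(self.conc[species], self.heavy[species])
        return delta56(pool, self.config.isotopes, igneous_scale=igneous_scale)

    def to_dataframe(self, igneous_scale: bool = False) -> pd.DataFrame:
        out = {"depth_cm": self.grid.cell_centres}
        for name, c in self.conc.items():
            out[name] = c
        for name in self.heavy:
            out[f"d56Fe_{name}"] = self.delta(name, igneous_scale=igneous_scale)
        return pd.DataFrame(out)


@dataclass
class FluxDiagnostics:
    """Benthic fluxes, burial fluxes and depth-integrated rates.

    Fluxes are in umol m^-2 d^-1 (Cox in mmol m^-2 d^-1), deltas in permil
    vs IRMM-014, positive fluxes leave the sediment (benthic efflux) or are
    buried (burial fluxes).
    """

    j_dfe: float
    delta_jdfe: float
    cox: float
    p_dfe: float
    c_dfe: float
    b_feooh: float
    b_fes: float
    b_fes2: float
    b_sorbed: float
    b_dfe_porewater: float
    delta_burial: dict
    pyrite_burial_fraction: float
    fe_input: float
    fe_balance_error: float         # relative
    heavy_balance_error: float      # relative
    o2_penetration_depth: float     # cm

    def as_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "delta_burial"}
        for name, val in self.delta_burial.items():
            out[f"delta_{name}"] = val
        return out


class UsageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SteadyModel:
    """One configured sediment column, solvable to steady state."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.species = species_list(config.variant)
        self.names = [s.name for s in self.species]
        self.index = {n: i for i, n in enumerate(self.names)}
        self.ns = len(self.species)
        self.grid = build_grid(
            config.domain_depth, config.n_cells, config.porosity,
            config.burial_velocity, grading=config.grid_grading,
        )
        self.reactions: list[ReactionDef] = reaction_table(config.variant)
        self._build_transport()
        self._build_reaction_index()
        self._bulk_solution: dict | None = None
        self._heavy_solution: dict | None = None

    # -- set-up -------------------------------------------------------------

    def _deposition_fluxes(self) -> dict:
        """Internal deposition fluxes (umol cm^-2 yr^-1) per solid species."""
        cfg = self.config
        kin = cfg.kinetics
        dep = {s.name: 0.0 for s in self.species if s.phase == "solid"}
        for j, frac in enumerate(kin.poc_fractions):
            dep[f"POC{j + 1}"] = (
                cfg.j_poc * frac * units.MMOL_M2_D_TO_UMOL_CM2_YR)
        if cfg.variant == "idealized":
            for cls, frac in kin.oxide_classes.partition.items():
                dep[cls] = cfg.j_feooh_total * frac * units.UMOL_M2_D_TO_UMOL_CM2_YR
            dep["MnO2"] = cfg.j_mno2 * units.UMOL_M2_D_TO_UMOL_CM2_YR
        else:
            dep["FeHRf"] = cfg.j_feooh_total * units.UMOL_M2_D_TO_UMOL_CM2_YR
        dep["FeS"] = cfg.j_fes * units.UMOL_M2_D_TO_UMOL_CM2_YR
        dep["FeS2"] = cfg.j_fes2 * units.UMOL_M2_D_TO_UMOL_CM2_YR
        return dep

    def _heavy_deposition_fluxes(self, dep: dict) -> dict:
        cfg = self.config
        iso = cfg.isotopes
        out = {}
        for name, flux in dep.items():
            if name in ("FeS",):
                delta = cfg.delta_fes
            elif name in ("FeS2",):
                delta = cfg.delta_fes2
            elif name.startswith("Fe"):
                delta = cfg.delta_feooh
            else:
                continue
            out[name] = delta_to_heavy(flux, delta, iso)
        return out

    def _build_transport(self) -> None:
        cfg = self.config
        grid = self.grid
        tp = cfg.transport
        db_i = biodiffusion_profile(tp, grid)
        self._ops = {}
        self._solute_aux = {}   # solute -> (d_eff_interfaces, alpha_centres)
        dep = self._deposition_fluxes()
        self._deposition = dep
        hdep = self._heavy_deposition_fluxes(dep)
        self._heavy_deposition = hdep
        theta2 = tortuosity_factor(grid.porosity_interfaces)
        for sp in self.species:
            if sp.phase == "solute":
                d0 = tp.diffusivity_overrides.get(
                    sp.name,
                    molecular_diffusivity(sp.name, tp.temperature, tp.salinity),
                )
                d_eff = d0 / theta2 + db_i
                alpha = irrigation_profile(tp, grid, sp.name)
                bw = cfg.bottom_water.get(sp.name, 0.0)
                self._solute_aux[sp.name] = (d_eff, alpha, bw)
                self._ops[sp.name] = solute_operator(grid, d_eff, alpha, bw)
            else:
                self._ops[sp.name] = solid_operator(grid, db_i, dep[sp.name])

        # heavy-stage operators: identical coefficients, isotope boundary data
        self._heavy_ops = {}
        self.fe_names = [s.name for s in self.species if s.isotope_tracked]
        for name in self.fe_names:
            sp = self.species[self.index[name]]
            if sp.phase == "solute":
                d_eff, alpha, _ = self._solute_aux[name]
                # dissolved Fe enters with the bottom-water delta; the
                # baseline bottom water is Fe-free so this is usually zero
                bw_heavy = delta_to_heavy(
                    cfg.bottom_water.get(name, 0.0), 0.0, cfg.isotopes)
                self._heavy_ops[name] = solute_operator(
                    grid, d_eff, alpha, bw_heavy)
            else:
                self._heavy_ops[name] = solid_operator(
                    grid, db_i, hdep.get(name, 0.0))

    def _build_reaction_index(self) -> None:
        """Precompute per-reaction (species index, coefficient field) pairs."""
        phi = self.grid.porosity_centres
        psi = 1.0 - phi
        self._phase_inv = {
            s.name: (1.0 / phi if s.phase == "solute" else 1.0 / psi)
            for s in self.species
        }
        self._stoich = []
        for rx in self.reactions:
            pairs = []
            for sp_name, coef in rx.stoichiometry.items():
                pairs.append((self.index[sp_name], coef * self._phase_inv[sp_name]))
            self._stoich.append((rx.id, pairs))

    # -- bulk stage ---------------------------------------------------------

    def _reaction_tendency(self, conc: dict) -> np.ndarray:
        """Reaction contribution to d(state)/dt, shape (n, ns)."""
        rates = evaluate_rates(
            conc, self.grid.porosity_centres, self.config.variant,
            self.config.kinetics,
        )
        out = np.zeros((self.grid.n_cells, self.ns))
        for rx_id, pairs in self._stoich:
            w = rates[rx_id]
            for idx, coef in pairs:
                out[:, idx] += coef * w
        return out

    def rhs_bulk(self, y: np.ndarray) -> np.ndarray:
        n = self.grid.n_cells
        state = y.reshape(n, self.ns)
        conc = {name: state[:, i] for i, name in enumerate(self.names)}
        out = self._reaction_tendency(conc)
        for i, name in enumerate(self.names):
            out[:, i] += self._ops[name].apply(state[:, i])
        return out.ravel()

    def _jacobian_bulk(self, y: np.ndarray) -> np.ndarray:
        """Banded Jacobian: exact transport bands + FD reaction blocks."""
        n, ns = self.grid.n_cells, self.ns
        bw = ns
        ab = np.zeros((2 * bw + 1, n * ns))
        # transport bands
        for i, name in enumerate(self.names):
            op = self._ops[name]
            idx = np.arange(n) * ns + i
            ab[bw, idx] += op.diag
            ab[0, idx[1:]] += op.upper[:-1]          # J[(i,s),(i+1,s)]
            ab[2 * bw, idx[:-1]] += op.lower[1:]     # J[(i,s),(i-1,s)]
        # reaction blocks by columnwise FD
        state = y.reshape(n, ns)
        conc = {name: state[:, i] for i, name in enumerate(self.names)}
        base = self._reaction_tendency(conc)
        scales = np.maximum(np.abs(state).max(axis=0), 1.0e-6)
        for s in range(ns):
            # per-cell perturbation: reactions are strictly local, so each
            # cell can carry its own step — this keeps the sampled slope
            # local (a cell sitting at zero concentration has a flat rate
            # law there, and a global step would smear the kink)
            eps = 1.0e-6 * np.abs(state[:, s]) + 1.0e-10
            pert = dict(conc)
            pert[self.names[s]] = conc[self.names[s]] + eps
            dcol = (self._reaction_tendency(pert) - base) / eps[:, None]
            col_idx = np.arange(n) * ns + s
            for sp in range(ns):
                ab[bw + sp - s, col_idx] += dcol[:, sp]
        return ab

    def _initial_bulk(self) -> np.ndarray:
        """Initial state: bottom-water solutes; solids at the advective
        burial profile damped by a rough first-order loss scale (keeps the
        fast-decaying POC fractions from starting orders of magnitude above
        their steady profile)."""
        n = self.grid.n_cells
        kin = self.config.kinetics
        y0 = np.zeros((n, self.ns))
        w = self.grid.solid_velocity[-1]
        psi = 1.0 - self.grid.porosity_interfaces[-1]
        loss_rate = {f"POC{j + 1}": kin.poc_decay[j] for j in range(3)}
        loss_rate["FeHR"] = loss_rate["FeHRf"] = kin.k_age
        z = self.grid.cell_centres
        for i, sp in enumerate(self.species):
            if sp.phase == "solute":
                y0[:, i] = self.config.bottom_water.get(sp.name, 0.0)
            else:
                dep = self._deposition[sp.name]
                k = loss_rate.get(sp.name, 0.0)
                base = dep / max(w * psi, 1.0e-12)
                y0[:, i] = base * np.exp(-np.minimum(k * z / w, 500.0))
        return y0.ravel()

    def solve_bulk(self, tol: float = 1.0e-7, max_steps: int = 600,
                   y0: np.ndarray | None = None) -> dict:
        if self._bulk_solution is not None and y0 is None:
            return self._bulk_solution
        if y0 is None:
            y0 = self._initial_bulk()
        n = self.grid.n_cells
        floors = np.maximum(
            1.0e-4 * np.abs(y0.reshape(n, self.ns)).max(axis=0), 1.0e-3)
        # slowest physical timescale: solid residence in the column
        t_res = self.grid.domain_depth / self.grid.solid_velocity[-1] * 10.0
        y = steady_state_solve(
            self.rhs_bulk, self._jacobian_bulk, y0, self.ns, floors,
            tol=tol, t_integrate=t_res,
        )
        state = np.maximum(y.reshape(n, self.ns), 0.0)
        self._bulk_solution = {
            name: state[:, i].copy() for i, name in enumerate(self.names)
        }
        return self._bulk_solution

    # -- heavy (56Fe) stage -------------------------------------------------

    def _fe_reaction_terms(self, conc: dict) -> list:
        """(source, target, Fe-transfer rate field, alpha) per Fe reaction."""
        rates = evaluate_rates(
            conc, self.grid.porosity_centres, self.config.variant,
            self.config.kinetics,
        )
        iso = self.config.isotopes
        terms = []
        for rx in self.reactions:
            if rx.fe_source is None:
                continue
            alpha = eps_to_alpha(iso.eps_eff[rx.eps_key]) if rx.eps_key else 1.0
            fe_rate = rx.fe_per_extent * rates[rx.id]
            terms.append((rx.fe_source, rx.fe_target, fe_rate, alpha))
        return terms

    def rhs_heavy_factory(self, conc: dict, isotope_params: IsotopeParams | None = None):
        iso = isotope_params or self.config.isotopes
        # floor Fe-species bulk at the fractionation limit: where a pool is
        # fully exhausted its bulk rates vanish, yet heavy iron transported
        # into that zone still needs its first-order sink (rate R/C * h);
        # the floored rate R(C_lim) combined with the h/C_lim transfer
        # ratio reconstructs exactly that specific rate
        conc_f = {
            k: (np.maximum(v, iso.c_lim) if k in self.fe_names else v)
            for k, v in conc.items()
        }
        terms = []
        rates = evaluate_rates(
            conc_f, self.grid.porosity_centres, self.config.variant,
            self.config.kinetics,
        )
        for rx in self.reactions:
            if rx.fe_source is None:
                continue
            alpha = eps_to_alpha(iso.eps_eff[rx.eps_key]) if rx.eps_key else 1.0
            fe_rate = rx.fe_per_extent * rates[rx.id]
            terms.append((rx.fe_source, rx.fe_target, fe_rate, alpha))
        nh = len(self.fe_names)
        hidx = {name: i for i, name in enumerate(self.fe_names)}
        n = self.grid.n_cells
        inv = {name: self._phase_inv[name] for name in self.fe_names}

        def rhs(h: np.ndarray) -> np.ndarray:
            hs = h.reshape(n, nh)
            out = np.zeros((n, nh))
            for i, name in enumerate(self.fe_names):
                out[:, i] += self._heavy_ops[name].apply(hs[:, i])
            for src, tgt, fe_rate, alpha in terms:
                frac = heavy_rate_fraction(
                    conc_f[src], hs[:, hidx[src]], alpha, iso, clip=False)
                hf = fe_rate * frac
                out[:, hidx[src]] -= hf * inv[src]
                out[:, hidx[tgt]] += hf * inv[tgt]
            return out.ravel()

        return rhs

    def solve_heavy(self, conc: dict | None = None,
                    isotope_params: IsotopeParams | None = None,
                    tol: float = 1.0e-9, max_steps: int = 400) -> dict:
        if conc is None:
            conc = self.solve_bulk()
        iso = isotope_params or self.config.isotopes
        rhs = self.rhs_heavy_factory(conc, iso)
        nh = len(self.fe_names)
        n = self.grid.n_cells
        hidx = {name: i for i, name in enumerate(self.fe_names)}

        # initial guess: every pool at the deposited-oxide ratio
        h0 = np.zeros((n, nh))
        hfrac0 = delta_to_heavy(1.0, self.config.delta_feooh, iso)
        for name in self.fe_names:
            h0[:, hidx[name]] = conc[name] * hfrac0
        h0 = h0.ravel()

        def jac(h: np.ndarray) -> np.ndarray:
            bw = nh
            ab = np.zeros((2 * bw + 1, n * nh))
            for i, name in enumerate(self.fe_names):
                op = self._heavy_ops[name]
                idx = np.arange(n) * nh + i
                ab[bw, idx] += op.diag
                ab[0, idx[1:]] += op.upper[:-1]
                ab[2 * bw, idx[:-1]] += op.lower[1:]
            base = rhs(h) - self._transport_only_heavy(h)
            hs = h.reshape(n, nh)
            scales = np.maximum(np.abs(hs).max(axis=0), 1.0e-9)
            for s in range(nh):
                eps = 1.0e-6 * np.abs(hs[:, s]) + 1.0e-10
                hp = h.copy()
                hp[s::nh] += eps
                dcol = (rhs(hp) - self._transport_only_heavy(hp)) - base
                dcol = dcol.reshape(n, nh) / eps[:, None]
                col_idx = np.arange(n) * nh + s
                for sp in range(nh):
                    ab[bw + sp - s, col_idx] += dcol[:, sp]
            return ab

        floors = np.maximum(np.abs(h0.reshape(n, nh)).max(axis=0) * 1.0e-4,
                            1.0e-6)
        t_res = self.grid.domain_depth / self.grid.solid_velocity[-1] * 10.0
        h = steady_state_solve(
            rhs, jac, h0, nh, floors, tol=tol, t_integrate=t_res,
        )
        hsol = np.maximum(h.reshape(n, nh), 0.0)
        heavy = {name: hsol[:, hidx[name]].copy() for name in self.fe_names}
        if isotope_params is None:
            self._heavy_solution = heavy
        return heavy

    def _transport_only_heavy(self, h: np.ndarray) -> np.ndarray:
        nh = len(self.fe_names)
        n = self.grid.n_cells
        hs = h.reshape(n, nh)
        out = np.zeros((n, nh))
        for i, name in enumerate(self.fe_names):
            out[:, i] += self._heavy_ops[name].apply(hs[:, i])
        return out.ravel()

    # -- top level ----------------------------------------------------------

    def run(self, tol: float = 1.0e-7, max_steps: int = 600,
            y0: np.ndarray | None = None) -> tuple[SpeciesState, FluxDiagnostics]:
        conc = self.solve_bulk(tol=tol, max_steps=max_steps, y0=y0)
        heavy = self.solve_heavy(conc)
        state = SpeciesState(self.grid, conc, heavy, self.config)
        return state, self.diagnostics(state)

    # -- diagnostics --------------------------------------------------------

    def _solute_efflux(self, field: np.ndarray, solute_id: str,
                       bottom_water: float) -> float:
        d_eff, alpha, _ = self._solute_aux[solute_id]
        dif, irr = solute_swi_flux(field, self.grid, d_eff, alpha, bottom_water)
        return dif + irr

    def benthic_flux(self, state: SpeciesState, solute_id: str) -> tuple[float, float]:
        """(efflux in umol m^-2 d^-1, delta56Fe of the efflux) of a solute."""
        sp = self.species[self.index[solute_id]]
        if sp.phase != "solute":
            raise UsageError(f"{solute_id} is a solid; benthic flux undefined")
        bw = self.config.bottom_water.get(solute_id, 0.0)
        flux = self._solute_efflux(state.conc[solute_id], solute_id, bw)
        delta = float("nan")
        if solute_id in state.heavy:
            hflux = self._solute_efflux(state.heavy[solute_id], solute_id, 0.0)
            delta = delta56(IsotopePool(flux, hflux), self.config.isotopes)
        return units.flux_to_reporting(flux), delta

    def integrated_rates(self, state: SpeciesState) -> tuple[float, float, float]:
        """(Cox mmol m^-2 d^-1, P_DFe, C_DFe umol m^-2 d^-1)."""
        grid = self.grid
        dz = grid.dz_cells
        psi = 1.0 - grid.porosity_centres
        kin = self.config.kinetics
        decay = poc_decay_rates(state.conc, psi, kin)
        cox_internal = float(sum(np.sum(r * dz) for r in decay.values()))
        cox = cox_internal * units.UMOL_CM2_YR_TO_MMOL_M2_D

        p_dfe = 0.0
        c_dfe = 0.0
        for src, tgt, fe_rate, _alpha in self._fe_reaction_terms(state.conc):
            # sorption exchange is a repartitioning, not production/consumption
            if {src, tgt} == {"Fe2", "XFe"}:
                continue
            total = float(np.sum(fe_rate * dz))
            if tgt == "Fe2":
                p_dfe += total
            if src == "Fe2":
                c_dfe += total
        return (cox,
                p_dfe * units.UMOL_CM2_YR_TO_UMOL_M2_D,
                c_dfe * units.UMOL_CM2_YR_TO_UMOL_M2_D)

    def diagnostics(self, state: SpeciesState) -> FluxDiagnostics:
        cfg = self.config
        grid = self.grid
        iso = cfg.isotopes

        j_dfe, delta_jdfe = self.benthic_flux(state, "Fe2")
        cox, p_dfe, c_dfe = self.integrated_rates(state)

        oxide_classes = [n for n in self.fe_names
                         if n.startswith("Fe") and n not in
                         ("Fe2", "XFe", "FeS", "FeS2")]
        burial = {}
        burial_heavy = {}
        for name in self.fe_names:
            sp = self.species[self.index[name]]
            if sp.phase == "solid":
                burial[name] = solid_burial_flux(state.conc[name], grid)
                burial_heavy[name] = solid_burial_flux(state.heavy[name], grid)
        b_feooh = sum(burial[c] for c in oxide_classes)
        b_feooh_h = sum(burial_heavy[c] for c in oxide_classes)
        b_fes = burial.get("FeS", 0.0)
        b_fes2 = burial.get("FeS2", 0.0)
        b_sorbed = burial.get("XFe", 0.0)
        b_dfe = solute_burial_flux(state.conc["Fe2"], grid)
        b_dfe_h = solute_burial_flux(state.heavy["Fe2"], grid)

        delta_burial = {
            "b_feooh": delta56(IsotopePool(b_feooh, b_feooh_h), iso),
            "b_fes": delta56(IsotopePool(b_fes, burial_heavy.get("FeS", 0.0)), iso),
            "b_fes2": delta56(IsotopePool(b_fes2, burial_heavy.get("FeS2", 0.0)), iso),
            "b_sorbed": delta56(IsotopePool(b_sorbed, burial_heavy.get("XFe", 0.0)),
                                iso),
        }

        fe_in = (cfg.j_feooh_total + cfg.j_fes + cfg.j_fes2) \
            * units.UMOL_M2_D_TO_UMOL_CM2_YR
        j_dfe_internal = j_dfe * units.UMOL_M2_D_TO_UMOL_CM2_YR
        fe_out = j_dfe_internal + b_feooh + b_fes + b_fes2 + b_sorbed + b_dfe
        fe_err = abs(fe_out - fe_in) / max(fe_in, 1.0e-12)

        heavy_in = sum(self._heavy_deposition.values())
        hflux_out = self._solute_efflux(state.heavy["Fe2"], "Fe2", 0.0)
        heavy_out = (hflux_out + b_feooh_h + burial_heavy.get("FeS", 0.0)
                     + burial_heavy.get("FeS2", 0.0)
                     + burial_heavy.get("XFe", 0.0) + b_dfe_h)
        heavy_err = abs(heavy_out - heavy_in) / max(heavy_in, 1.0e-12)

        o2 = state.conc["O2"]
        below = np.nonzero(o2 < 1.0e-3)[0]
        opd = float(grid.cell_centres[below[0]]) if below.size else float(
            grid.domain_depth)

        denom = b_fes2 + b_feooh
        pyr_frac = float(b_fes2 / denom) if denom > 0 else 0.0

        return FluxDiagnostics(
            j_dfe=j_dfe,
            delta_jdfe=delta_jdfe,
            cox=cox,
            p_dfe=p_dfe,
            c_dfe=c_dfe,
            b_feooh=b_feooh * units.UMOL_CM2_YR_TO_UMOL_M2_D,
            b_fes=b_fes * units.UMOL_CM2_YR_TO_UMOL_M2_D,
            b_fes2=b_fes2 * units.UMOL_CM2_YR_TO_UMOL_M2_D,
            b_sorbed=b_sorbed * units.UMOL_CM2_YR_TO_UMOL_M2_D,
            b_dfe_porewater=b_dfe * units.UMOL_CM2_YR_TO_UMOL_M2_D,
            delta_burial=delta_burial,
            pyrite_burial_fraction=pyr_frac,
            fe_input=fe_in * units.UMOL_CM2_YR_TO_UMOL_M2_D,
            fe_balance_error=fe_err,
            heavy_balance_error=heavy_err,
            o2_penetration_depth=opd,
        )


# ---------------------------------------------------------------------------
# module-level convenience API
# ---------------------------------------------------------------------------

def run_grid(
    configs, tol: float = 1.0e-7, progress: bool = False,
) -> list[tuple[SpeciesState, FluxDiagnostics]]:
    """Solve a sweep of configurations, warm-starting each run from its
    predecessor's state.

    Neighbouring points of a sensitivity grid have similar steady states,
    so the Newton probe usually converges directly and the sweep runs an
    order of magnitude faster than independent cold starts.  Falls back to
    a cold start automatically whenever the warm start is unusable.
    """
    out = []
    prev = None
    for cfg in configs:
        model = SteadyModel(cfg)
        y0 = None
        if prev is not None and prev.shape == (model.grid.n_cells, model.ns):
            y0 = prev.ravel().copy()
        try:
            conc = model.solve_bulk(tol=tol, y0=y0)
        except Exception:
            if y0 is None:
                raise
            model = SteadyModel(cfg)
            conc = model.solve_bulk(tol=tol)
        heavy = model.solve_heavy(conc)
        state = SpeciesState(model.grid, conc, heavy, cfg)
        diag = model.diagnostics(state)
        out.append((state, diag))
        prev = np.column_stack([conc[name] for name in model.names])
        if progress:
            print(f"{cfg.name}: O2={cfg.bottom_water.get('O2', 0.0) * 1e3:.0f} uM "
                  f"J_POC={cfg.j_poc} -> J_DFe={diag.j_dfe:.2f}")
    return out


def run_to_steady_state(
    config: ScenarioConfig, tol: float = 1.0e-7, max_steps: int = 600,
) -> tuple[SpeciesState, FluxDiagnostics]:
    """Solve one configuration to steady state and return state + fluxes."""
    return SteadyModel(config).run(tol=tol, max_steps=max_steps)


def benthic_flux(state: SpeciesState, solute_id: str = "Fe2") -> tuple[float, float]:
    return SteadyModel(state.config).benthic_flux(state, solute_id)


def integrated_rates(state: SpeciesState) -> tuple[float, float, float]:
    return SteadyModel(state.config).integrated_rates(state)


def fehcl_composite(state: SpeciesState, igneous_scale: bool = False):
    """Bulk and delta56Fe profiles of operational HCl-extractable iron
    (oxide classes + sorbed ferrous iron + FeS), in umol cm^-3 of solid."""
    oxide = [n for n in state.heavy
             if n.startswith("Fe") and n not in ("Fe2", "XFe", "FeS", "FeS2")]
    members = oxide + ["XFe", "FeS"]
    members = [m for m in members if m in state.conc]
    bulk = sum(state.conc[m] for m in members)
    heavy = sum(state.heavy[m] for m in members)
    delta = delta56(IsotopePool(bulk, heavy), state.config.isotopes,
                    igneous_scale=igneous_scale)
    return bulk, delta
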