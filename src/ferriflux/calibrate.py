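"""Calibration of effective isotope fractionation factors against
observed delta56Fe depth profiles.

The procedure mirrors the two-stage site-calibration workflow: the bulk
concentration fields are fitted first (boundary fluxes, rate constants —
outside this module's scope), after which the effective fractionations
are found by direct search, minimizing the summed squared misfit between
modelled and observed delta56Fe of the three measurable iron pools
(pore-water DFe, HCl-extractable iron, pyrite).  Because the bulk
chemistry is independent of the fractionation factors, each candidate in
the search only re-solves the (cheap, nearly linear) heavy-isotope stage.

The search is a deterministic coarse grid followed by rounds of local
refinement; no randomness is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .isotopes import IsotopeParams, IsotopePool, delta56
from .model import SpeciesState, SteadyModel, fehcl_composite
from .scenarios import ScenarioConfig

#: observable pool id -> how to extract its delta profile from a state
OBSERVABLE_POOLS = ("DFe", "FeHCl", "FeS2")


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationResult:
    eps_fit: dict                 # reaction -> fitted eps_eff (permil)
    misfit: float                 # sum of squared residuals (permil^2)
    residuals: dict = field(default_factory=dict)  # pool -> residual array
    bounds: dict = field(default_factory=dict)


def _model_delta(state: SpeciesState, pool: str):
    if pool == "DFe":
        return state.delta("Fe2")
    if pool == "FeS2":
        return state.delta("FeS2")
    if pool == "FeHCl":
        return fehcl_composite(state)[1]
    raise CalibrationError(f"unknown observable pool {pool!r}")


def _misfit(model: SteadyModel, conc: dict, iso: IsotopeParams,
            observed: dict) -> tuple[float, dict]:
    heavy = model.solve_heavy(conc, isotope_params=iso)
    state = SpeciesState(model.grid, conc, heavy,
                         model.config.with_overrides(isotopes=iso))
    total = 0.0
    residuals = {}
    z = model.grid.cell_centres
    for pool, (depths, values) in observed.items():
        prof = np.asarray(_model_delta(state, pool), dtype=float)
        good = np.isfinite(prof)
        pred = np.interp(np.asarray(depths, float), z[good], prof[good])
        res = pred - np.asarray(values, float)
        residuals[pool] = res
        total += float(np.sum(res * res))
    return total, residuals


def calibrate_fractionation(
    observed: dict,
    search_bounds: dict,
    config: ScenarioConfig,
    coarse_points: int = 9,
    refine_rounds: int = 4,
) -> CalibrationResult:
    """Fit effective fractionation factors to observed delta56Fe profiles.

    Parameters
    ----------
    observed : pool id ("DFe" | "FeHCl" | "FeS2") -> (depths_cm, deltas)
    search_bounds : reaction key (e.g. "reduction") -> (lo, hi) in permil
    config : the site configuration whose bulk fields are already fitted

    The misfit over the fitted parameters is minimized by coordinate
    descent: a coarse grid per parameter, then halving refinements around
    the incumbent.  Deterministic for a fixed grid.
    """
    if not observed:
        raise CalibrationError("empty observation set")
    for pool in observed:
        if pool not in OBSERVABLE_POOLS:
            raise CalibrationError(f"unknown observable pool {pool!r}")
    if not search_bounds:
        raise CalibrationError("no parameters to calibrate")

    model = SteadyModel(config)
    conc = model.solve_bulk()

    eps = dict(config.isotopes.eps_eff)
    base_iso = config.isotopes

    def evaluate(eps_trial: dict) -> float:
        iso = replace(base_iso, eps_eff=eps_trial)
        return _misfit(model, conc, iso, observed)[0]

    # coordinate descent: coarse grid then halving refinement per parameter
    for _sweep in range(2 if len(search_bounds) > 1 else 1):
        for key, (lo, hi) in search_bounds.items():
            grid = np.linspace(lo, hi, coarse_points)
            scores = []
            for val in grid:
                trial = dict(eps)
                trial[key] = float(val)
                scores.append(evaluate(trial))
            best = int(np.argmin(scores))
            centre = float(grid[best])
            width = (hi - lo) / (coarse_points - 1)
            for _ in range(refine_rounds):
                width *= 0.5
                cand = np.clip([centre - width, centre, centre + width], lo, hi)
                sc = []
                for val in cand:
                    trial = dict(eps)
                    trial[key] = float(val)
                    sc.append(evaluate(trial))
                centre = float(cand[int(np.argmin(sc))])
            eps[key] = centre

    iso = replace(base_iso, eps_eff=eps)
    misfit, residuals = _misfit(model, conc, iso, observed)
    return CalibrationResult(
        eps_fit={k: eps[k] for k in search_bounds},
        misfit=misfit,
        residuals=residuals,
        bounds=dict(search_bounds),
    )


def synthetic_observations(
    config: ScenarioConfig,
    depths,
    pools=OBSERVABLE_POOLS,
) -> dict:
    """Sample delta56Fe profiles from a model run, for self-consistency
    (parameter-recovery) experiments."""
    state, _ = SteadyModel(config).run()
    z = state.grid.cell_centres
    out = {}
    for pool in pools:
        prof = np.asarray(_model_delta(state, pool), dtype=float)
        good = np.isfinite(prof)
        out[pool] = (np.asarray(depths, float),
                     np.interp(np.asarray(depths, float), z[good], prof[good]))
    return out
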