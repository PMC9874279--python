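"""Scenario configurations: baseline boundary conditions, the five
bioturbation experiments and the sensitivity grids.

The idealized shelf baseline sits at 350 m water depth with 120 uM
bottom-water oxygen, a POC rain of 10 mmol m^-2 d^-1 and a total
iron-oxide rain of 1110 umol m^-2 d^-1 (half of it unreactive, the rest
split equally over the three reactive classes).  Bioturbation intensity
scales with bottom-water oxygen through an error-function ramp
``f = 0.5 + 0.5 erf((O2 - 20)/12)`` applied to both the biodiffusion
coefficient (max 10 cm^2 yr^-1) and the irrigation coefficient
(max 290 yr^-1); the mixing depth follows from the biodiffusion
coefficient and saturates at 10 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .isotopes import IsotopeParams
from .reactions import KineticParams, StateError
from .transport import ConfigurationError, PorosityProfile, TransportParams

#: maximum bioturbation intensities (modern compilation means)
DB0_MAX = 10.0      # cm^2 yr^-1
ALPHA0_MAX = 290.0  # yr^-1

#: oxygen half-ramp parameters, uM
O2_RAMP_CENTRE = 20.0
O2_RAMP_WIDTH = 12.0

#: irrigation attenuation depth used by the idealized model, cm
XIRR_IDEALIZED = 1.4

#: mixing-depth relation z_L = 1 + 9 (1 - exp(-Db0/denom)).  The default
#: denominator 3.0 cm^2 yr^-1 reproduces the stated z_L = 9.7 cm at
#: Db0 = 10; the alternative 30.0 is retained as a selectable variant.
ZL_DENOMINATOR = 3.0
ZL_DENOMINATOR_ALT = 30.0

SCENARIO_NAMES = (
    "baseline",
    "unbioturbated",
    "always_bioturbated",
    "only_biomixing",
    "only_bioirrigation",
)


def oxygen_scaling(o2_uM: float) -> float:
    """Dimensionless bioturbation scaling f(O2) in (0, 1), increasing."""
    if o2_uM < 0.0:
        raise ConfigurationError("oxygen must be >= 0")
    return 0.5 + 0.5 * math.erf((o2_uM - O2_RAMP_CENTRE) / O2_RAMP_WIDTH)


def mixing_depth(db0: float, denominator: float = ZL_DENOMINATOR) -> float:
    """Bio-mixing depth z_L (cm) as a saturating function of D_b,0."""
    if db0 < 0.0:
        raise ConfigurationError("biodiffusion coefficient must be >= 0")
    return 1.0 + 9.0 * (1.0 - math.exp(-db0 / denominator))


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one steady-state model run."""

    name: str = "baseline"
    variant: str = "idealized"      # "idealized" | "site"
    domain_depth: float = 150.0     # cm
    n_cells: int = 200
    grid_grading: float = 6.0       # 0 = uniform; >0 refines toward the SWI
    porosity: PorosityProfile = field(
        default_factory=lambda: PorosityProfile(0.95, 0.82, 3.6))
    burial_velocity: float = 60.0   # cm kyr^-1 in compacted sediment
    temperature: float = 10.0       # degC
    salinity: float = 34.2
    bottom_water: dict = field(default_factory=dict)  # umol cm^-3 per solute
    j_poc: float = 10.0             # mmol m^-2 d^-1
    j_feooh_total: float = 1110.0   # umol m^-2 d^-1
    delta_feooh: float = 0.0        # permil vs IRMM-014
    j_fes: float = 0.0              # umol m^-2 d^-1
    delta_fes: float = 0.0
    j_fes2: float = 0.0             # umol m^-2 d^-1
    delta_fes2: float = 0.0
    j_mno2: float = 2.0             # umol m^-2 d^-1 (idealized only)
    transport: TransportParams = field(default_factory=TransportParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    isotopes: IsotopeParams = field(default_factory=IsotopeParams)

    def __post_init__(self) -> None:
        if self.variant not in ("idealized", "site"):
            raise StateError(f"unknown variant {self.variant!r}")
        for name in ("j_poc", "j_feooh_total", "j_fes", "j_fes2", "j_mno2"):
            if getattr(self, name) < 0.0:
                raise ConfigurationError(f"{name} must be >= 0")
        for sol, val in self.bottom_water.items():
            if val < 0.0:
                raise ConfigurationError(f"bottom water {sol} must be >= 0")

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


#: baseline idealized bottom water, umol cm^-3 (== mM)
BASELINE_BOTTOM_WATER = {
    "O2": 0.120,
    "NO3": 0.030,
    "SO4": 28.0,
    "Fe2": 0.0,
    "HS": 0.0,
    "CH4": 0.0,
    "Mn2": 0.0,
}


def _bioturbation_params(name: str, o2_uM: float) -> TransportParams:
    if name == "baseline":
        f = oxygen_scaling(o2_uM)
        db0, a0 = DB0_MAX * f, ALPHA0_MAX * f
    elif name == "unbioturbated":
        db0, a0 = 0.0, 0.0
    elif name == "always_bioturbated":
        db0, a0 = DB0_MAX, ALPHA0_MAX
    elif name == "only_biomixing":
        db0, a0 = DB0_MAX, 0.0
    elif name == "only_bioirrigation":
        db0, a0 = 0.0, ALPHA0_MAX
    else:
        raise StateError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    return TransportParams(
        biodiffusion_coeff=db0,
        mixing_depth=mixing_depth(db0),
        irrigation_coeff=a0,
        irrigation_attenuation=XIRR_IDEALIZED,
    )


def make_scenario(name: str, o2_uM: float = 120.0, **overrides) -> ScenarioConfig:
    """Build one of the five bioturbation-experiment configurations.

    ``o2_uM`` is the bottom-water oxygen in uM; all remaining boundary
    values default to the idealized baseline.  Keyword overrides are applied
    on top (e.g. ``j_poc=4``, ``n_cells=100``).
    """
    bw = dict(BASELINE_BOTTOM_WATER)
    bw["O2"] = o2_uM * 1.0e-3
    bw.update(overrides.pop("bottom_water", {}))
    transport = overrides.pop("transport", _bioturbation_params(name, o2_uM))
    return ScenarioConfig(
        name=name, bottom_water=bw, transport=transport, **overrides)


@dataclass(frozen=True)
class SensitivityGrid:
    """Axes of the sensitivity experiments."""

    o2_uM: tuple = (1, 2, 5, 10, 15, 25, 50, 100, 120, 200)
    j_poc: tuple = (0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16)
    j_feooh: tuple = (194, 278, 555, 1110, 1914)
    so4_mM: tuple = (0, 0.01, 0.1, 1, 28)   # unbioturbated experiment only


def enumerate_grid(
    kind: str,
    o2_levels=None,
    jpoc_levels=None,
    feooh_levels=None,
    so4_levels=None,
    n_cells: int = 200,
) -> list[ScenarioConfig]:
    """Cartesian product of sensitivity-grid axes as run configurations.

    ``kind='modern'`` applies oxygen-scaled bioturbation and holds sulfate
    at its modern value; ``kind='unbioturbated'`` zeroes bioturbation and by
    default trades the oxide-flux axis for the sulfate axis.
    """
    grid = SensitivityGrid()
    o2_levels = tuple(o2_levels) if o2_levels is not None else grid.o2_uM
    jpoc_levels = tuple(jpoc_levels) if jpoc_levels is not None else grid.j_poc
    if kind == "modern":
        scenario = "baseline"
        feooh_levels = (tuple(feooh_levels) if feooh_levels is not None
                        else grid.j_feooh)
        so4_levels = tuple(so4_levels) if so4_levels is not None else (28.0,)
    elif kind == "unbioturbated":
        scenario = "unbioturbated"
        feooh_levels = (tuple(feooh_levels) if feooh_levels is not None
                        else (1110.0,))
        so4_levels = tuple(so4_levels) if so4_levels is not None else grid.so4_mM
    else:
        raise StateError(f"unknown grid kind {kind!r}")

    configs = []
    for o2 in o2_levels:
        for jp in jpoc_levels:
            for jf in feooh_levels:
                for so4 in so4_levels:
                    bw = dict(BASELINE_BOTTOM_WATER)
                    bw["O2"] = o2 * 1.0e-3
                    bw["SO4"] = float(so4)
                    cfg = make_scenario(
                        scenario, o2_uM=float(o2), j_poc=float(jp),
                        j_feooh_total=float(jf), bottom_water=bw,
                        n_cells=n_cells,
                    )
                    configs.append(cfg)
    return configs
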