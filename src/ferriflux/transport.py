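"""Vertical grid, porosity/velocity profiles and transport operators.

The sediment column is discretized with a uniform finite-volume grid,
0-based depth coordinate (positive downward, SWI at z = 0).  Three transport
processes act on the state:

* molecular diffusion of solutes, tortuosity-corrected with the modified
  Weissberg relation ``theta^2 = 1 - 2 ln(phi)``
* biodiffusive mixing (animal particle reworking treated as diffusion),
  acting on solids and, with the same coefficient, on solutes
* non-local bio-irrigation exchange of solutes with bottom water,
  ``alpha(z) * (C_bw - C(z))``

Advection follows steady compaction: ``phi * u`` and ``(1 - phi) * w`` are
depth-invariant, anchored at the compacted-sediment burial velocity.
Solute boundary conditions are fixed bottom-water concentrations at the SWI
and zero-gradient at the base; solids receive an imposed deposition flux at
the SWI.  Benthic effluxes (sediment to water) are reported positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import CM_KYR_TO_CM_YR, CM2_S_TO_CM2_YR


class ConfigurationError(ValueError):
    """Raised for non-physical transport or porosity parameters."""


# ---------------------------------------------------------------------------
# porosity and grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PorosityProfile:
    """Exponential porosity decline between a surface and an asymptotic value.

    phi(z) = phi_deep + (phi_surface - phi_deep) * exp(-z / attenuation_depth)
    """

    phi_surface: float
    phi_deep: float
    attenuation_depth: float  # cm

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_deep <= self.phi_surface < 1.0):
            raise ConfigurationError(
                "porosity must satisfy 0 < phi_deep <= phi_surface < 1, got "
                f"phi_surface={self.phi_surface}, phi_deep={self.phi_deep}"
            )
        if self.attenuation_depth <= 0.0:
            raise ConfigurationError("porosity attenuation depth must be > 0")

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        return self.phi_deep + (self.phi_surface - self.phi_deep) * np.exp(
            -z / self.attenuation_depth
        )


@dataclass(frozen=True)
class Grid:
    """Finite-volume grid with porosity and compaction velocities.

    The grid may be uniform or graded (geometrically refined toward the
    SWI, where the oxic layer demands millimetre resolution).  Velocities
    are positive downward, in cm yr^-1, evaluated at cell interfaces
    (where fluxes live) and cell centres.
    """

    cell_centres: np.ndarray
    cell_interfaces: np.ndarray
    porosity_centres: np.ndarray
    porosity_interfaces: np.ndarray
    solute_velocity: np.ndarray  # at interfaces
    solid_velocity: np.ndarray   # at interfaces
    domain_depth: float
    dz_cells: np.ndarray = field(init=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dz_cells", np.diff(self.cell_interfaces)
        )

    @property
    def n_cells(self) -> int:
        return self.cell_centres.size

    @property
    def dz(self) -> float:
        """Representative (first-cell) spacing; exact for uniform grids."""
        return float(self.dz_cells[0])


def build_grid(
    domain_depth: float,
    n_cells: int,
    porosity: PorosityProfile,
    burial_velocity_deep: float,
    grading: float = 0.0,
) -> Grid:
    """Build the vertical grid.

    Parameters
    ----------
    domain_depth : cm
    n_cells : number of cells (>= 10)
    porosity : porosity profile
    burial_velocity_deep : burial velocity in compacted sediment, cm kyr^-1
    grading : 0 for a uniform grid; > 0 for geometric refinement toward
        the SWI (interface k at L (e^(g k/n) - 1)/(e^g - 1); g ~ 6 puts
        the first cell at a few hundred micrometres for n = 100)

    The steady-compaction closure fixes the advection fields:
    ``u(z) = phi_deep * v / phi(z)`` for solutes and
    ``w(z) = (1 - phi_deep) * v / (1 - phi(z))`` for solids,
    with ``v`` the deep burial velocity in cm yr^-1.
    """
    if domain_depth <= 0.0:
        raise ConfigurationError("domain_depth must be > 0")
    if n_cells < 10:
        raise ConfigurationError("n_cells must be >= 10")
    if burial_velocity_deep <= 0.0:
        raise ConfigurationError("burial velocity must be > 0")

    if grading > 0.0:
        k = np.arange(n_cells + 1)
        interfaces = domain_depth * np.expm1(grading * k / n_cells) \
            / np.expm1(grading)
        interfaces[0], interfaces[-1] = 0.0, domain_depth
    else:
        interfaces = np.linspace(0.0, domain_depth, n_cells + 1)
    centres = 0.5 * (interfaces[:-1] + interfaces[1:])
    phi_c = porosity(centres)
    phi_i = porosity(interfaces)
    v = burial_velocity_deep * CM_KYR_TO_CM_YR
    u_i = porosity.phi_deep * v / phi_i
    w_i = (1.0 - porosity.phi_deep) * v / (1.0 - phi_i)
    return Grid(
        cell_centres=centres,
        cell_interfaces=interfaces,
        porosity_centres=phi_c,
        porosity_interfaces=phi_i,
        solute_velocity=u_i,
        solid_velocity=w_i,
        domain_depth=float(domain_depth),
    )


# ---------------------------------------------------------------------------
# bioturbation and molecular diffusivities
# ---------------------------------------------------------------------------

#: default per-solute multipliers on the bio-irrigation coefficient;
#: ferrous iron exchanges at 20% and free sulfide at 50% of the bulk rate
#: (adsorption to burrow walls / reoxidation inside burrows).
DEFAULT_IRRIGATION_SCALING = {"Fe2": 0.2, "HS": 0.5}

#: biodiffusion attenuation e-folding below the mixing depth, cm
BIODIFFUSION_DECAY_SCALE = 1.0


@dataclass(frozen=True)
class TransportParams:
    """Bioturbation and diffusion parameters for one scenario."""

    biodiffusion_coeff: float = 0.0      # D_b,0, cm^2 yr^-1
    mixing_depth: float = 10.0           # z_L, cm
    irrigation_coeff: float = 0.0        # alpha_0, yr^-1
    irrigation_attenuation: float = 3.0  # x_irr, cm
    temperature: float = 10.0            # degC
    salinity: float = 34.2
    irrigation_scaling: dict = field(
        default_factory=lambda: dict(DEFAULT_IRRIGATION_SCALING)
    )
    diffusivity_overrides: dict = field(default_factory=dict)  # cm^2 yr^-1

    def __post_init__(self) -> None:
        for name in (
            "biodiffusion_coeff",
            "mixing_depth",
            "irrigation_coeff",
            "irrigation_attenuation",
        ):
            if getattr(self, name) < 0.0:
                raise ConfigurationError(f"{name} must be >= 0")


#: free-solution diffusivity correlations D0 = (a + b*T + c*T^2) 1e-6 cm^2/s
_D0_COEFFS = {
    "O2": (11.70, 0.344, 0.00505),
    "NO3": (9.50, 0.388, 0.0),
    "SO4": (4.88, 0.232, 0.0),
    "Fe2": (3.31, 0.150, 0.0),
    "Mn2": (3.18, 0.155, 0.0),
    "HS": (10.40, 0.273, 0.0),
    "CH4": (9.80, 0.253, 0.0),
}


def molecular_diffusivity(solute_id: str, temperature: float, salinity: float) -> float:
    """Free-solution diffusivity in cm^2 yr^-1 at ambient T (degC) and S.

    Linear/quadratic temperature correlations for infinite dilution, with a
    first-order seawater viscosity correction (about -5% at S = 35).
    """
    try:
        a, b, c = _D0_COEFFS[solute_id]
    except KeyError as exc:
        raise ConfigurationError(f"no diffusivity correlation for {solute_id!r}") from exc
    d0 = (a + b * temperature + c * temperature**2) * 1.0e-6  # cm^2/s
    d0 *= 1.0 - 0.049 * salinity / 35.0
    return d0 * CM2_S_TO_CM2_YR


def tortuosity_factor(phi):
    """theta^2 = 1 - 2 ln(phi); sediment diffusivity is D0 / theta^2."""
    return 1.0 - 2.0 * np.log(phi)


def biodiffusion_profile(params: TransportParams, grid: Grid, z=None) -> np.ndarray:
    """Biodiffusion coefficient D_b(z), cm^2 yr^-1.

    Constant at D_b,0 within the mixed layer (z <= z_L), decaying
    exponentially below with a 1 cm e-folding scale (a hard cutoff would
    introduce numerical kinks).  Evaluated at grid interfaces by default.
    """
    if z is None:
        z = grid.cell_interfaces
    z = np.asarray(z, dtype=float)
    db0 = params.biodiffusion_coeff
    if db0 == 0.0:
        return np.zeros_like(z)
    out = np.where(
        z <= params.mixing_depth,
        db0,
        db0 * np.exp(-(z - params.mixing_depth) / BIODIFFUSION_DECAY_SCALE),
    )
    return out


def irrigation_profile(
    params: TransportParams, grid: Grid, solute_id: str = "", z=None
) -> np.ndarray:
    """Non-local irrigation exchange rate alpha(z), yr^-1, at cell centres."""
    if z is None:
        z = grid.cell_centres
    z = np.asarray(z, dtype=float)
    a0 = params.irrigation_coeff
    if a0 == 0.0:
        return np.zeros_like(z)
    scaling = params.irrigation_scaling.get(solute_id, 1.0)
    return scaling * a0 * np.exp(-z / params.irrigation_attenuation)


# ---------------------------------------------------------------------------
# linear transport operators
# ---------------------------------------------------------------------------

@dataclass
class LinearTransport:
    """Tridiagonal transport operator: tendency = L @ C + const.

    ``lower``/``diag``/``upper`` are the three bands of L (lower[0] and
    upper[-1] unused); ``const`` carries the boundary-condition source.
    """

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    const: np.ndarray

    def apply(self, c: np.ndarray) -> np.ndarray:
        out = self.diag * c + self.const
        out[1:] += self.lower[1:] * c[:-1]
        out[:-1] += self.upper[:-1] * c[1:]
        return out


def solute_operator(
    grid: Grid,
    diffusivity_interfaces: np.ndarray,
    alpha_centres: np.ndarray,
    bottom_water_value: float,
) -> LinearTransport:
    """Finite-volume operator for a pore-water solute.

    ``diffusivity_interfaces`` is the total effective diffusivity
    (tortuosity-corrected molecular + biodiffusive) at the n+1 interfaces.
    Fixed concentration ``bottom_water_value`` at the SWI, zero-gradient at
    the base.
    """
    n = grid.n_cells
    dz = grid.dz_cells
    dc = np.diff(grid.cell_centres)     # centre-to-centre distances
    phi_i = grid.porosity_interfaces
    phi_c = grid.porosity_centres
    u = grid.solute_velocity
    d = diffusivity_interfaces

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    const = np.zeros(n)
    inv = 1.0 / (phi_c * dz)

    # interior interfaces i = 1..n-1 between cells i-1 and i
    # F_i = -phi_i d_i (C[i]-C[i-1])/dc + phi_i u_i C[i-1]   (u > 0, upwind)
    a_dif = phi_i[1:-1] * d[1:-1] / dc          # length n-1
    a_adv = phi_i[1:-1] * u[1:-1]
    # F_i depends on C[i-1] with coeff (a_dif + a_adv) and C[i] with (-a_dif);
    # cell i-1 loses F_i, cell i gains it
    coef_im1 = a_dif + a_adv
    coef_i = -a_dif
    diag[:-1] -= coef_im1 * inv[:-1]
    upper[:-1] -= coef_i * inv[:-1]
    lower[1:] += coef_im1 * inv[1:]
    diag[1:] += coef_i * inv[1:]

    # top interface: F_0 = -phi_0 d_0 (C[0]-C_bw)/zc_0 + phi_0 u_0 C_bw
    top_dif = phi_i[0] * d[0] / grid.cell_centres[0]
    diag[0] -= top_dif * inv[0]
    const[0] += (top_dif + phi_i[0] * u[0]) * bottom_water_value * inv[0]

    # bottom interface: F_n = phi_n u_n C[n-1] (zero diffusive gradient)
    diag[-1] -= phi_i[-1] * u[-1] * inv[-1]

    # non-local irrigation exchange
    diag -= alpha_centres
    const += alpha_centres * bottom_water_value
    return LinearTransport(lower, diag, upper, const)


def solid_operator(
    grid: Grid,
    biodiffusion_interfaces: np.ndarray,
    deposition_flux: float,
) -> LinearTransport:
    """Finite-volume operator for a solid species.

    ``deposition_flux`` is the imposed total flux through the SWI in
    umol cm^-2 yr^-1 (advective + biodiffusive deposition lumped).
    """
    n = grid.n_cells
    dz = grid.dz_cells
    dc = np.diff(grid.cell_centres)
    psi_i = 1.0 - grid.porosity_interfaces  # solid volume fraction
    psi_c = 1.0 - grid.porosity_centres
    w = grid.solid_velocity
    db = biodiffusion_interfaces

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    const = np.zeros(n)
    inv = 1.0 / (psi_c * dz)

    a_dif = psi_i[1:-1] * db[1:-1] / dc
    a_adv = psi_i[1:-1] * w[1:-1]
    coef_im1 = a_dif + a_adv
    coef_i = -a_dif
    diag[:-1] -= coef_im1 * inv[:-1]
    upper[:-1] -= coef_i * inv[:-1]
    lower[1:] += coef_im1 * inv[1:]
    diag[1:] += coef_i * inv[1:]

    # imposed deposition flux through the SWI
    const[0] += deposition_flux * inv[0]

    # bottom: advective burial only
    diag[-1] -= psi_i[-1] * w[-1] * inv[-1]
    return LinearTransport(lower, diag, upper, const)


def transport_tendency(
    state_field: np.ndarray,
    species_phase: str,
    grid: Grid,
    params: TransportParams,
    bottom_water_value: float,
    solute_id: str = "",
) -> np.ndarray:
    """Tendency (concentration per yr) of one species under transport only.

    For solutes ``bottom_water_value`` is the fixed SWI concentration
    (umol cm^-3); for solids it is the deposition flux (umol cm^-2 yr^-1).
    """
    state_field = np.asarray(state_field, dtype=float)
    if state_field.shape != grid.cell_centres.shape:
        raise ValueError(
            f"field of size {state_field.size} does not match grid of "
            f"{grid.n_cells} cells"
        )
    db_i = biodiffusion_profile(params, grid)
    if species_phase == "solute":
        if solute_id in params.diffusivity_overrides:
            d0 = params.diffusivity_overrides[solute_id]
        else:
            d0 = molecular_diffusivity(solute_id, params.temperature, params.salinity)
        d_eff = d0 / tortuosity_factor(grid.porosity_interfaces) + db_i
        alpha = irrigation_profile(params, grid, solute_id)
        op = solute_operator(grid, d_eff, alpha, bottom_water_value)
    elif species_phase == "solid":
        op = solid_operator(grid, db_i, bottom_water_value)
    else:
        raise ValueError(f"unknown phase {species_phase!r}")
    return op.apply(state_field)


# ---------------------------------------------------------------------------
# boundary-flux diagnostics
# ---------------------------------------------------------------------------

def solute_swi_flux(
    c: np.ndarray,
    grid: Grid,
    diffusivity_interfaces: np.ndarray,
    alpha_centres: np.ndarray,
    bottom_water_value: float,
) -> tuple[float, float]:
    """(diffusive efflux across the SWI, depth-integrated irrigation efflux).

    Both in umol cm^-2 yr^-1, positive toward the water column.  The
    diffusive term includes the (usually negligible) advective influx of
    bottom water so that the two terms plus burial close the column budget.
    """
    phi0 = grid.porosity_interfaces[0]
    dif = phi0 * diffusivity_interfaces[0] * (c[0] - bottom_water_value) \
        / grid.cell_centres[0]
    adv_in = phi0 * grid.solute_velocity[0] * bottom_water_value
    irr = float(
        np.sum(grid.porosity_centres * alpha_centres
               * (c - bottom_water_value) * grid.dz_cells)
    )
    return float(dif - adv_in), irr


def solute_burial_flux(c: np.ndarray, grid: Grid) -> float:
    """Advective pore-water burial across the base, umol cm^-2 yr^-1."""
    return float(
        grid.porosity_interfaces[-1] * grid.solute_velocity[-1] * c[-1]
    )


def solid_burial_flux(s: np.ndarray, grid: Grid) -> float:
    """Solid burial flux across the base, umol cm^-2 yr^-1."""
    return float(
        (1.0 - grid.porosity_interfaces[-1]) * grid.solid_velocity[-1] * s[-1]
    )
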