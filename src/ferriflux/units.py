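"""Unit conventions and conversion helpers.

Internal conventions (chosen once, used everywhere):

* depth ``z`` in cm, positive downward, sediment-water interface (SWI) at 0
* time in years
* pore-water solutes in umol per cm^3 of pore water (== mmol/L == mM)
* solids in umol per cm^3 of solid phase
* deposition / benthic fluxes cross module boundaries in umol m^-2 d^-1
  (POC rain in mmol m^-2 d^-1); internally the solver works in
  umol cm^-2 yr^-1
* velocities in cm yr^-1 (configs give burial velocity in cm kyr^-1)
"""

DAYS_PER_YEAR = 365.0

#: umol m^-2 d^-1 -> umol cm^-2 yr^-1
UMOL_M2_D_TO_UMOL_CM2_YR = DAYS_PER_YEAR / 1.0e4

#: umol cm^-2 yr^-1 -> umol m^-2 d^-1
UMOL_CM2_YR_TO_UMOL_M2_D = 1.0e4 / DAYS_PER_YEAR

#: mmol m^-2 d^-1 -> umol cm^-2 yr^-1  (x1000 then as above)
MMOL_M2_D_TO_UMOL_CM2_YR = 1.0e3 * UMOL_M2_D_TO_UMOL_CM2_YR

#: umol cm^-2 yr^-1 -> mmol m^-2 d^-1
UMOL_CM2_YR_TO_MMOL_M2_D = 1.0 / MMOL_M2_D_TO_UMOL_CM2_YR

#: mol m^-3 (== mM == umol cm^-3 of water) is identity for solutes
MOL_M3_TO_UMOL_CM3 = 1.0

#: cm kyr^-1 -> cm yr^-1
CM_KYR_TO_CM_YR = 1.0e-3

SECONDS_PER_YEAR = 3.15576e7

#: cm^2 s^-1 -> cm^2 yr^-1 (molecular diffusivity tables are in 1e-6 cm^2/s)
CM2_S_TO_CM2_YR = SECONDS_PER_YEAR


def flux_to_internal(flux_umol_m2_d: float) -> float:
    """Convert a deposition flux in umol m^-2 d^-1 to umol cm^-2 yr^-1."""
    return flux_umol_m2_d * UMOL_M2_D_TO_UMOL_CM2_YR


def flux_to_reporting(flux_umol_cm2_yr: float) -> float:
    """Convert an internal flux (umol cm^-2 yr^-1) to umol m^-2 d^-1."""
    return flux_umol_cm2_yr * UMOL_CM2_YR_TO_UMOL_M2_D
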