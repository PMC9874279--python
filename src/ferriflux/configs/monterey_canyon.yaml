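# Monterey Canyon: bioturbated site under a fully oxygenated water column.
# Boundary conditions follow the published site compilation; kinetic
# constants marked "calibrated" were fitted to the site's measured benthic
# DFe flux and pore-water/solid-phase iron distributions.
name: monterey_canyon
variant: site
domain_depth_cm: 150.0
n_cells: 200
grid_grading: 6.0
porosity:
  phi_surface: 0.95
  phi_deep: 0.82
  attenuation_depth_cm: 3.6
burial_velocity_cm_kyr: 250.0
temperature_degC: 10.0
salinity: 34.2
bottom_water_umol_cm3:
  O2: 0.28
  SO4: 28.0
  Fe2: 0.0
  HS: 0.0
  CH4: 0.0
deposition:
  poc_mmol_m2_d: 8.0
  feooh_total_umol_m2_d: 320.0
  feooh_delta56_permil: -0.5
  fes_umol_m2_d: 0.0
  fes_delta56_permil: 0.0
  fes2_umol_m2_d: 30.0
  fes2_delta56_permil: 0.0
  mno2_umol_m2_d: 0.0
bioturbation:
  biodiffusion_cm2_yr: 20.0
  mixing_depth_cm: 10.0
  irrigation_yr: 183.0
  irrigation_attenuation_cm: 3.0
  irrigation_scaling:
    Fe2: 0.05    # calibrated: burrow-wall oxidation strips most irrigated Fe2+
    HS: 0.5
kinetics:            # calibrated site values (see docs/methods.md)
  k_feox: 1.15e+6
  k_feoh: 20.0
  k_fes_sat: 1.0e-5
  k_pyr_s0: 0.05
  k_age_site: 0.05
  aged_reactivity: 0.01
  dir_aged_weight: 0.0
  sorption:
    k_ads: 6000.0
eps_eff_permil:
  pyrite_precipitation: -0.4
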