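# Santa Barbara Basin: unbioturbated site under a hypoxic (~10 uM O2)
# water column.  Boundary conditions follow the published site compilation;
# kinetic constants marked "calibrated" were fitted to the site's measured
# benthic DFe flux and iron distributions.
name: santa_barbara_basin
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
  O2: 0.01
  SO4: 28.0
  Fe2: 0.0
  HS: 0.0
  CH4: 0.0
deposition:
  poc_mmol_m2_d: 4.6
  feooh_total_umol_m2_d: 560.0
  feooh_delta56_permil: -1.5
  fes_umol_m2_d: 0.0
  fes_delta56_permil: 0.0
  fes2_umol_m2_d: 30.0
  fes2_delta56_permil: -0.4
  mno2_umol_m2_d: 0.0
bioturbation:
  biodiffusion_cm2_yr: 0.0
  mixing_depth_cm: 0.001
  irrigation_yr: 0.0
  irrigation_attenuation_cm: 3.0
kinetics:            # calibrated site values (see docs/methods.md)
  k_feoh: 4500.0
  k_feox: 2.5e+6
  aged_reactivity: 0.3
  sorption:
    k_ads: 30.0
eps_eff_permil:
  pyrite_precipitation: -0.7
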