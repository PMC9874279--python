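# Methods

## Governing equations

The model solves steady-state early diagenesis on a one-dimensional
sediment column, depth `z` in cm positive downward with the
sediment–water interface (SWI) at zero.  For a pore-water solute `C`
(µmol cm⁻³ of pore water) and a solid `S` (µmol cm⁻³ of solid phase):

    ∂(φC)/∂t = ∂/∂z[ φ (D₀/θ² + D_b) ∂C/∂z ] − ∂(φuC)/∂z
               + φ α(z) (C_bw − C) + Σ ν R
    ∂(ψS)/∂t = ∂/∂z[ ψ D_b ∂S/∂z ] − ∂(ψwS)/∂z + Σ ν R

with porosity `φ(z) = φ_∞ + (φ₀ − φ∞) e^(−z/x_φ)` (exponential decline, the
standard convention when only the surface value, asymptote and attenuation
scale are known), `ψ = 1 − φ`, tortuosity `θ² = 1 − 2 ln φ`, and steady
compaction fixing the advection fields: `φu` and `ψw` are depth-invariant,
anchored at the compacted-sediment burial velocity.  Reaction rates `R`
are per cm³ of total sediment.  Solutes carry fixed bottom-water
concentrations at the SWI and zero gradients at the base; solids receive
imposed deposition fluxes.  Benthic effluxes are positive toward the water
column; the benthic flux diagnostic is the diffusive flux across the SWI
plus the depth-integrated irrigation exchange (burrow flushing is
sediment–water transfer).

Bioturbation comprises biodiffusion (`D_b = D_b,0` within the mixing depth
`z_L`, decaying below with a 1 cm e-folding — a hard cutoff would put a
kink into the Jacobian) and non-local irrigation
`α(z) = s·α₀·e^(−z/x_irr)` with solute-specific multipliers `s` (1 by
default, 0.2 for Fe²⁺ and 0.5 for free sulfide in the idealized model,
reflecting oxidation at burrow walls).  Biodiffusion is applied to solids
and, with the same coefficient, to solutes; it is negligible next to
molecular diffusion but keeps the operator symmetric between phases.

Free-solution diffusivities come from linear/quadratic temperature
correlations at in-situ salinity (≈5 % seawater viscosity correction),
overridable per solute.

## Reaction network

Two variants share one code path:

* **idealized** (C–N–O–Mn–Fe–S): four iron-oxide reactivity classes
  defined by half-life toward 1 mM sulfide — highly reactive (0.5 yr),
  moderately reactive (100 yr), poorly reactive (10⁵ yr), unreactive.
  Input partition: 50 % unreactive, the rest split equally.  FeHR ages
  into FeMR (0.1 yr⁻¹).
* **site** (C–O–Fe–S): nitrogen and manganese disabled; the highly
  reactive class splits into *fresh* and *aged* sub-pools, with aging
  rate, aged sulfide-reactivity and aged bioavailability to dissimilatory
  reduction as site parameters.

Organic matter is a three-fraction multi-G mixture (50 % at 24 yr⁻¹, 33 %
at 1.4 yr⁻¹, 17 % refractory at 10⁻⁵ yr⁻¹ — fresh-phytodetritus
reactivities chosen so that a 150 cm column oxidizes ≈83 % of the POC
rain, anchoring the baseline carbon budget).  Mineralization partitions
over O₂ > NO₃⁻ > MnO₂ > FeOOH > SO₄²⁻ > methanogenesis by Monod
limitation with inhibition by all more favourable oxidants; the
methanogenic remainder closes the partition of unity.  Secondary redox
reactions (Fe²⁺, FeS, FeS₂, HS⁻, S⁰, CH₄, Mn²⁺ oxidation; AOM) are
bimolecular.  FeS precipitates above and dissolves below a conditional
solubility threshold `Ω = [Fe²⁺][HS⁻]/K`; pyrite forms from FeS via
dissolved sulfide and via elemental sulfur (produced by sulfide-driven
oxide reduction).  Sorption of Fe²⁺ is an instantaneous linear equilibrium
on column inventories (`I_ads = K_ads · I_diss`), implemented as a fast
paired one-way exchange (100 yr⁻¹) so the adsorbed pool can be transported
as a solid; the pair's balance point is exactly the stated equilibrium,
and its isotope steady state reproduces the sorption fractionation
exactly.

## Isotope bookkeeping

Bulk iron is ⁵⁴Fe + ⁵⁶Fe.  Each Fe-transfer reaction applies its effective
fractionation factor to the isotope ratio of its Fe-bearing **source**
pool (for pyritization, FeS).  Defaults (‰): reduction −1.3 (dissimilatory
and sulfide-driven alike), all oxidations +0.4, sorption +0.4, FeS
precipitation +0.5, dissolution −0.5, pyritization −0.7 (−0.4 in the
Monterey Canyon fixture, per-site calibration).  Below a bulk
concentration of 10⁻⁹ µmol cm⁻³ reactions transfer isotopes at the pool
ratio (no fractionation), applied to the reactant pool only.  δ⁵⁶Fe is
reported against IRMM-014; a reporting option subtracts 0.09 ‰ to express
values against average igneous rocks.  Undefined δ (empty pools) renders
as NaN, never ±∞.

The ratio form `α·r/(1+α·r)` is evaluated through its algebraic
continuation `α·h/(C + (α−1)h)`, identical on physical pools but smooth
and self-correcting if a solver iterate momentarily pushes the heavy
content past the bulk.  Inside the heavy stage, Fe-species bulk fields are
floored at the fractionation limit so that heavy iron transported into an
exhausted zone still meets the first-order sink `(R/C)·h` it would have in
the continuous problem.

## Numerics

Finite volumes with upwind advection and centred diffusion.  The default
grid is geometrically refined toward the SWI (first cell ≈0.1 mm at 200
cells): the oxic surface layer is millimetric under shelf conditions, and
an unrefined 0.75 cm surface cell cannot represent the reoxidation barrier
that controls the benthic iron flux (a uniform grid remains available and
is used in the transport oracle tests).

Species are interleaved within cells, so the Jacobian is banded (bandwidth
= number of species); transport enters it analytically, reactions by
per-cell finite differences whose perturbations stay local to each cell's
magnitude.  Steady states: damped Newton (RMS-norm line search) →
semi-implicit pseudo-time marching with step control on the relative state
change and periodic Newton attempts → error-controlled BDF integration as
a last resort.  Convergence demands max |dC/dt| below 10⁻⁷ of each
species' field scale per year (the finite-difference Jacobian limits
attainable Newton residuals to ≈2×10⁻⁸; 10⁻⁷ yr⁻¹ is roughly ten orders
below the active rates).  One-sided rate switches are C1-smoothed with
clips that are exactly zero on the closed side, which keeps dead zones
residual-free.  Steady-state column budgets close to ≈10⁻¹² relative.
Solved grids warm-start neighbouring configurations in parameter sweeps
(`run_grid`), which accelerates sensitivity grids by roughly an order of
magnitude.

The ⁵⁶Fe fields are solved after the bulk state with reaction extents
frozen — exact at steady state, since the isotope fields do not feed back
on bulk chemistry — so fractionation-factor studies re-solve only a small,
nearly linear system.

## Calibration

Mirroring the two-stage site procedure, bulk chemistry is fitted first and
the effective fractionations second.  The packaged site fixtures carry the
boundary conditions of the two calibration sites (Monterey Canyon:
oxygenated, bioturbated; Santa Barbara Basin: hypoxic, unbioturbated)
plus per-site kinetic constants fitted so the modelled benthic DFe fluxes
and their δ⁵⁶Fe match the published site values.  Constants not fixed by
observation (Monod constants, secondary rate constants, FeS solubility,
sorption constant, aging rates) default to standard diagenetic-model
values, with the idealized-model set additionally tuned against three
published anchors: the baseline carbon budget, the O₂-dependence of the
five bioturbation scenarios, and the variance captured by the single-
variable (Cox, O₂) transfer-function forms.  All of them are exposed in
configuration files, and `calibrate_fractionation` performs the
fractionation-factor search (deterministic coarse grid plus halving
refinement; each candidate re-solves only the isotope stage).

Noteworthy site-calibration outcomes: the hypoxic basin requires a high
half-saturation constant for dissimilatory oxide reduction (otherwise the
entire oxide rain is consumed within millimetres of the interface, and
nearly all iron escapes); the oxygenated canyon requires fast ferrous-iron
oxidation, a strong sorption sink and restriction of dissimilatory
reduction to the fresh oxide sub-pool to reproduce simultaneously its
small flux and its moderately light signature.

## Scenarios and transfer functions

The five bioturbation experiments set (D_b,0, z_L, α₀) as: oxygen-scaled
(baseline, with `f = 0.5 + 0.5 erf((O₂−20)/12)` on maxima of
10 cm² yr⁻¹ / 290 yr⁻¹), zero (unbioturbated), fixed maxima (always
bioturbated), and the two single-mode variants.  The mixing-depth relation
is `z_L = 1 + 9(1 − e^(−D_b,0/3.0))` cm: the printed form of the relation
carries a denominator of 30, which contradicts the stated z_L = 9.7 cm at
D_b,0 = 10 that the scenario definitions depend on; the 3.0 denominator
reproduces that value and the printed alternative remains selectable.
Irrigation attenuation is 1.4 cm in the idealized model and 3 cm at the
sites.

The transfer functions are: `J = 0.153·J_FeOOH·tanh(Cox/O₂)` and
`δ = 1.65·x/(2.09+x) − 1.67` with `x = Cox²/O₂` for the modern seafloor;
`J = 0.161(1 − e^(−3.67·Cox/O₂))·J_FeOOH` and
`δ = 1.60 − 1.34·e^(−3.67(Cox/O₂)²) − 1.67` for the unbioturbated one.
`fit_surface` refits any form by multi-start nonlinear least squares with
R² on the untransformed response; undefined responses (the δ of a
vanishing flux) are dropped.  Note that the two *published* flux forms
order the same way for every argument (the asymptotic form exceeds the
tanh form pointwise), so published global totals in which the modern
seafloor out-gasses the unbioturbated one are not reproducible from these
printed equations alone; the model-level statement — bioturbation raises
the flux at high O₂ — is made on actual simulations.

The Rayleigh diagnostic treats the escaping flux as a distillate of the
finite oxide input with remaining fraction `fr = (J_max − J)/J_max`
(normalized: a remaining *fraction* must be dimensionless, and this form
reaches the analytic single-step limit `δ → d₀·α + 1000(α−1)` as J → 0),
J_max = 170 µmol m⁻² d⁻¹ by default, evaluated through expm1/log1p for
stability at vanishing flux.

Global upscaling evaluates the transfer functions per grid cell using the
cell's bottom-water O₂ and its bathymetric interval's mean Cox (packaged
table: shelf 27.12×10¹² m² at 9.4, upper slope 16.01 at 3.0, lower slope
15.84 at 1.5, deep sea 302.5×10¹² m² at 0.45 mmol m⁻² d⁻¹), a globally
uniform oxide rain of 1110 µmol m⁻² d⁻¹, and flux-weighted (optionally
areal) mean δ.  No oxygen climatology is bundled; any (O₂, depth, area)
grid can be supplied.

## What the experiments do and do not show

The scenario and grid runs are the model's own study conditions, not
synthetic stand-ins for field data: baseline boundary values represent an
idealized 350 m shelf column, and sensitivity axes span 1–200 µM O₂,
0.5–16 mmol m⁻² d⁻¹ POC rain, 194–1914 µmol m⁻² d⁻¹ oxide rain and 0–28 mM
sulfate.  Reduced 5×5×2 grids (O₂ ∈ {2, 10, 25, 100, 200} µM, POC ∈
{1, 4, 8, 12, 16}, oxide ∈ {555, 1110}) stand in for the full 500-run
grids in the test suite; they span the same dynamic range at a quarter of
the cost, and grid runs use 100 cells where standalone runs default to
200 (the flux changes by <2 % on doubling).  Agreement of refitted
transfer-function coefficients is structural, not numerical: coefficients
depend on supplementary rate constants that are calibrated, not measured.

## Known limitations

* Steady state only; no transient diagenesis or time-varying bioturbation.
* Fixed organic-matter reactivity; no dependence of decay on oxygen
  exposure or mixing.
* No non-reductive oxide dissolution, siderite/vivianite, or Fe–CH₄
  coupling; single effective fractionation factors per reaction, not
  rate-dependent.
* The site fixtures reproduce flux-level observables; full pore-water
  profile shapes (e.g. the sub-surface DFe maximum of the hypoxic basin)
  are only qualitatively captured.
* ⁵⁷Fe and ⁵⁸Fe are not tracked.
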