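# Adult female muskox parameterization for the overwinter DEB-IBM.
#
# Units: energies MJ, lengths cm, volumes cm^3, masses g, time days,
# temperatures K unless noted.  Rates are quoted at the reference
# temperature TREF and Arrhenius-corrected to body temperature at run time.
#
# The rate and conversion constants below were frozen once by
# analysis/02_calibrate_parameters.py: absolute anchors (initial total
# reserves ~1307.5 MJ at 80% condition, 70 kg structural mass, reserve
# tissue at ~7 MJ/kg) reproduce the study population's overwinter reserve
# budget, and the three free rates (pAm_ref, pM_ref, kappaX) were fitted to
# the percentage-scale baseline outcomes (overwinter reserve declines of
# both thermal groups and the midwinter metabolic depression).

deb:
  pAm_ref: 8.344070e-4 # MJ d-1 cm-2 at TREF; surface-specific max assimilation
  v_ref: 0.035736087   # cm d-1 at TREF; energy conductance (pAm_ref / [Em])
  pM_ref: 2.076338e-5  # MJ d-1 cm-3 at TREF; volume-specific somatic maintenance
  kJ_ref: 0.002        # d-1 at TREF; maturity maintenance rate coefficient
  EG: 0.0078           # MJ cm-3; volume-specific cost of structure
  kappa: 0.95          # fraction of mobilized reserve to the somatic branch
  kappaR: 0.95         # reproduction efficiency
  kappaX: 0.551        # digestion efficiency (assimilation overhead in FMR)
  TAr: 8000.0          # K; Arrhenius temperature (standard DEB value)
  TREF: 293.15         # K; reference temperature (room temperature)
  EHp: 60.0            # MJ; maturity at puberty (adults frozen here)
  EHb: null            # MJ; birth maturity threshold (null: calendar birth)
  struct_density: 1.0  # g cm-3; structural tissue density
  mu_E: 0.007          # MJ g-1; reserve tissue energy density (~7 MJ/kg)
  embryo_v_scale: 2.5  # embryo energy-conductance scale (fetal growth rate)
  embryo_reserve_density: 0.25  # scaled reserve endowed to fetal structure

environment:
  snow_max_cm: 88.0        # baseline winter maximum snow depth
  tb:
    normotherm_mean: 38.2  # C; constant winter group mean
    heterotherm_mean: 37.4 # C; overwinter group mean (ramp depth solved)
    trough_frac: 1.0       # divergence trough as fraction of the window
    recovery_frac: 0.0     # fraction of the max drop recovered by 31 May

population:
  n_individuals: 25
  n_replicates: 25
  init_reserve_fraction: 0.80
  init_structural_volume: 70000.0   # cm^3 (70 kg structural mass)
  feeding_mode: tb_independent
  pregnancy: false
  embryo_mode: maternal_independent
  seed: 20201122
  scatter:
    cv_normotherm: 0.10
    cv_heterotherm: 0.15
    mode: additive
  gestation:
    arrest_end: "11-15"   # embryonic arrest ends / active gestation starts
    birth_day: "05-01"    # calendar birth

mortality:
  e50: 0.18    # e_tot at half-maximal daily risk
  b: 60.0      # logistic steepness
  pmax: 0.15   # maximal daily mortality probability
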