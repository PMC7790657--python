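# Methods

## Model overview and assumptions

`heterodeb` simulates adult female muskoxen through one high-Arctic winter
(1 October – 31 May, 243 days) with a daily explicit-Euler time step and no
sub-stepping.  Each individual carries a standard DEB state — structural
volume `V` (cm³), reserve `E` (MJ), maturity `E_H` (MJ, frozen at the
puberty threshold: simulated animals are adults and the maturation flux is
inactive) and a reproduction buffer `E_R` (MJ).  The model is spatially
implicit: one area-averaged snow series drives everyone's forage access,
and activity, ambient-temperature thermoregulation and multi-year
demography are deliberately out of scope.

The single mechanism separating the two study groups is body temperature.
Heterothermy enters only through the Arrhenius correction
`TC = exp(T_Ar/T_REF − T_Ar/T_b)` applied to exactly three rates — somatic
maintenance `[ṗM]`, maturity maintenance `k̇J` and energy conductance
`v̇` — plus, optionally, the assimilation rate `{ṗAm}` (the "TB-dependent
feeding" mode).  In the default TB-independent mode, assimilation is
corrected with the TC of the *normothermic reference trajectory*, so both
groups ingest identically and group contrasts isolate metabolic
depression.  `T_Ar = 8000 K` is the conventional DEB value; shifting it
rescales absolute outputs but largely cancels in group contrasts, which is
why the package's acceptance surface is percentage-scale.

Starvation rules: when `κ·ṗC` cannot cover somatic maintenance (true all
winter for a full-grown adult) or the `1−κ` branch cannot cover maturity
maintenance, the shortfall is paid first from the reproduction buffer,
then from reserve; structure never shrinks.  Any residual deficit is
clamped and flagged — extreme depletion is handled by the mortality model,
not by exceptions.  Mobilization is capped at `E/dt + ṗA` so a single
Euler day cannot drive the reserve negative.

## Synthetic environment

*Snow.*  A deterministic, smooth unimodal curve stands in for a multi-year
mean of reconstructed snow depth over tundra: zero on 1 October, cosine
accumulation to the configured maximum (88 cm) in mid-March, cosine melt
leaving ~25 cm on 31 May.  Because it emulates an 18-year average it
carries no interannual noise; single-winter extremes (storm deposition,
rain-on-snow crusts) are *not* represented, so passing tests say nothing
about icing events that block forage outright.

*Forage.*  `f = max(0, 1 − (0.30/88)·depth)`: linear, anchored so 88 cm
gives `f = 0.70`, no access-cutoff depth.  The linear form reproduces all
four published (depth, f) anchor pairs (88→0.70, 108→0.63, 130→0.56,
150→0.49), which is the evidence that the original mapping was linear.
Accessibility scenarios multiply the daily series by a factor and clamp to
[0, 1].

*Body temperature.*  Normotherms hold 38.2 °C.  The heterotherm group mean
starts at the normotherm level on 1 October and diverges linearly; the
ramp depth is solved in closed form so the overwinter mean equals 37.4 °C
(verified to ±0.01 °C).  The default places the trough on the final day —
divergence grows all winter, reaching ~1.6 °C — because the reported
behaviour of the modelled groups (a metabolic-rate gap that grows
consistently through winter and is still sizeable at the end of May)
is incompatible with a mid-winter trough followed by full recovery.  The
trough date and a recovery fraction are configurable for profiles that
re-converge in spring.  Note a documented tension in the source
constraints: a 0.8 °C *mean* difference cannot coexist with a 0.8 °C
*maximum* drop for any ramp starting at zero; the generator honours the
means.

*Individual scatter.*  Daily individual TB is jittered around the group
mean; heterotherms are more variable (cv 0.15 vs 0.10).  Two modes exist.
`multiplicative` applies the log-normal scatter multiplier `exp(N(0, cv))`
to TB in °C with a mean-preserving bias correction (the raw multiplier has
mean `exp(cv²/2)`).  This literal reading produces ±4–6 °C daily swings,
and because TC is convex in TB, Jensen's inequality then inflates the
*mean* metabolic rate by ~5 % (normotherms) and ~12 % (heterotherms) —
enough to cancel the ~6 % Arrhenius depression and erase the heterothermy
benefit entirely, which contradicts the phenomenon the model exists to
quantify.  The default is therefore `additive`: TB + N(0, cv) with cv read
as a standard deviation in °C (0.10/0.15 °C), matching the sub-degree
daily variability actually observed in large ungulates while preserving
the group contrast.  The log-normal multiplier itself remains available
and tested.

## Parameter provenance and calibration

The full constant set ships in `src/heterodeb/data/muskox.yaml`; every
experiment reads it rather than hard-coding values.  Three anchors fix the
absolute scale from the study population's internally consistent energy
budget: initial total reserves of ≈1307.5 MJ at the 80 % baseline
condition (reported MJ losses divided by reported fractional declines), a
70 kg structural body (`V = 7×10⁴ cm³` at 1 g cm⁻³), and reserve tissue at
≈7 MJ kg⁻¹ (mixed adipose/lean catabolism).  Together these give
`[E_m]·V ≈ 1634 MJ` and a 257 kg prewinter female losing ~50–70 kg over
winter, inside the range reported for free-ranging muskoxen.

With the anchors fixed, `analysis/02_calibrate_parameters.py` fits the
three free rates — `{ṗAm}`, `[ṗM]` and the digestion efficiency `κ_X` —
on a deterministic mean-field winter against three percentage-scale
calibration targets: the two groups' overwinter reserve declines (36.49 %
and 27.35 % of initial stores) and a 5 % heterotherm FMR depression on
1 February.  The fit is exact (residuals ~1e-13) at

| constant | value | units |
|---|---|---|
| `{ṗAm}` | 8.344×10⁻⁴ | MJ d⁻¹ cm⁻² at T_REF |
| `v̇` | 0.0357 | cm d⁻¹ at T_REF |
| `[ṗM]` | 2.076×10⁻⁵ | MJ d⁻¹ cm⁻³ at T_REF |
| `κ_X` | 0.551 | – |

with `κ = κ_R = 0.95`, `[E_G] = 7.8 kJ cm⁻³`, `k̇J = 0.002 d⁻¹`,
`E_Hp = 60 MJ` held at standard values.  The end-of-winter group
differences in body mass (+9.0 %) and total reserves (+14.4 %) are then
*emergent*, as are October mass loss, the ~10 MJ d⁻¹ winter FMR, and the
shrinking of the benefit under TB-dependent feeding — none of these were
fitted.  The calibration script re-derives the fit from scratch on every
run and asserts agreement with the shipped constants.

*Mortality.*  The logistic `p = p_max/(1+exp(b(e_tot − e50)))` is not
published; its constants (`e50 = 0.18`, `b = 60`, `p_max = 0.15`) were
chosen once under two constraints — baseline winters end with 100 %
survival in both groups (daily risk at the baseline condition minimum is
~4×10⁻¹⁰), and risk rises steeply below `e_tot ≈ 0.2` (0.002/d at 0.25,
0.035/d at 0.20, 0.13/d at 0.15) — and then held fixed across all
scenarios.  Scenario survival *percentages* therefore depend on this
choice and are treated as directional, not numeric, predictions.

*Gestation.*  Embryonic arrest until 15 November, active gestation
thereafter, birth on 1 May (an `E_Hb` maturity trigger for earlier birth is
supported but off by default, so that slowed fetal development shows up as
lighter calves rather than later identical ones).  The fetus develops
along standard DEB growth at full scaled reserve density with an
embryo-specific conductance scale (2.5, set for an ≈8 kg calf, the size
implied by the published 1.22 kg ≈ 15 % group difference), and each unit
of new structure carries a reserve endowment (scaled density 0.25).  Its
whole demand — maintenance, growth, maturation, endowment — is paid by the
mother from `κ_R·ṗR` first, then from `E_R`; when both fall short, all
fetal fluxes scale down proportionally.  Pregnant females initialize 45 %
of their stores in the reproduction buffer: with the calibrated adult
rates the `1−κ` branch alone cannot finance gestation mid-winter, which is
exactly the capital-breeding pattern — reproduction is financed from
stores, and the chosen share keeps fetal growth demand-driven (hence
identical across thermal groups when fetal homeostasis is
TB-independent) while leaving heterotherm mothers with the larger residual
buffer at calving.  In the TB-corrected mode fetal rates use the mother's
own TC and heterotherm calves are born ~1.4 kg (~17 %) lighter.

Embryo mortality uses the maternal condition as its risk proxy (an
embryo-specific proxy is a config switch away but default-off, since
nothing in the source distinguishes them).

## Numerical and design choices

- Explicit Euler at `dt = 1 d`; all rates are slow relative to a day
  (reserve turnover `L/v̇·TC` ≈ 230 d), so stiffness is not a concern.
- The population engine is vectorized over a cohort (struct of arrays);
  random draws (TB scatter, adult and embryo mortality) are made for every
  slot every day, so trajectories are bit-reproducible for a given seed
  regardless of who dies when.  Replicate seeds spawn deterministically
  from one master seed; a run manifest records them.
- Daily summaries pool individuals alive that day; endpoint tables keep
  every individual frozen at death.  Reported dispersion is the sample
  (n−1) SD of the pooled 625 records per group, not of replicate means.
- Energy books close exactly: assimilation equals the change in body
  energy (reserve + buffer + structure at `[E_G]`) plus dissipation plus
  energy exported to the embryo, to 1e-9 per day and 1e-6 over the winter
  (asserted in tests).
- Scenario sweeps at their neutral levels (initial condition 0.80,
  accessibility ×1.0) reproduce the baseline bit-exactly under shared
  seeds.  The degree-of-heterothermy scenario replaces the heterotherm
  profile by "normotherm − Δ" with Δ constant within a level and stepped
  by 0.1 °C across levels (a per-day increment would reach a
  physiologically absurd ~24 °C by May); its Δ = 0 level is therefore the
  two-normotherm control, not the baseline ramp.

## Problem sizes

The shipped experiments use the full study design — 25 individuals × 25
replicates × 2 groups × 243 days (~3×10⁵ individual-days, ~4 s on one
core); the full scenario grids (25 experiments) run in about a minute.
Property tests use a deterministic single-individual mean-field
configuration or reduced cohorts where distributional power is not needed.

## Known limitations

- Absolute kg/MJ outputs inherit the three scale anchors; only
  percentage-scale results should be compared across parameterizations.
- The synthetic environment has no interannual or day-to-day weather
  noise, no icing events, and no spatial heterogeneity in snow or forage.
- Intake quality is folded into a single scaled functional response;
  digestive constraints and diet shifts are not modelled.
- The mortality logistic is a calibration device, so scenario survival
  levels are indicative; only their orderings are robust.
- Lactation, summer recovery and multi-year carryover lie outside the
  simulated window; "fitness" here means end-of-winter condition,
  survival and birth outcomes only.
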