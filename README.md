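# heterodeb

An individual-based dynamic energy budget model (DEB-IBM) of overwinter
energetics in adult female muskoxen (*Ovibos moschatus*), built to quantify
the energetic and fitness consequences of **seasonal heterothermy** — a
modest, sustained drop in winter body temperature — against strict
normothermy.  It is aimed at ecophysiologists and population ecologists who
want a process-based estimate of what a fraction of a degree of metabolic
depression buys an Arctic capital breeder over a snow-limited winter.

## The model

Energetics follow standard DEB theory.  Assimilated energy
`ṗA = f·TC_feed·{ṗAm}·V^{2/3}` enters a reserve `E`; mobilized reserve

```
ṗC = [E] ( [EG]·TC·v̇·V^{2/3} + ṗS ) / ( [EG] + κ[E] ),   [E] = E/V
```

is split by the kappa rule: a fraction `κ` pays somatic maintenance
`ṗS = TC·[ṗM]·V` then growth; the rest pays maturity maintenance
`ṗJ = TC·k̇J·E_H` then reproduction (`ṗR`, banked in a buffer `E_R` with
efficiency `κ_R`).  Metabolic rates carry an Arrhenius temperature
correction driven by daily body temperature `T_b`:

```
TC = exp( T_Ar/T_REF − T_Ar/T_b ),    T_Ar = 8000 K, T_REF = 293.15 K
```

Normotherms hold 38.2 °C all winter; heterotherms diverge gradually to an
overwinter mean of 37.4 °C, each individual jittered daily around its group
mean.  Food intake is driven by a snow-depth proxy: the scaled functional
response falls linearly from `f = 1` on bare ground to 0.70 under the
88 cm baseline winter maximum, with no access cutoff.  Feeding can be
TB-independent (ingestion follows the normothermic reference, so both
groups eat identically) or TB-dependent (ingestion is itself
temperature-corrected).  Daily energy expenditure is reported as a field
metabolic rate,

```
FMR = ṗS + ṗJ + ṗA(1−κ_X) + ṗR(1−κ_R) + ṗDf ,
```

with `ṗDf` the dissipating fluxes of a developing embryo.  Survival is
stochastic via a logistic function of body condition
`e_tot = (E+E_R)/([E_m]V)`, and an optional gestation sub-model covers
embryonic arrest, active gestation and spring birth, with fetal
development either buffered against or slaved to maternal temperature.

Experiments pair a normotherm and a heterotherm cohort with identical
initial states (25 individuals × 25 replicates per group, pooled
mean ± SD) over 1 October – 31 May, and three scenario dials sweep the
degree of heterothermy, prewinter body condition (80 % → 50 % of maximum
reserves), and winter forage accessibility (×0.7 – ×1.3).

## Worked example

```python
import heterodeb as hd
from heterodeb.population import MortalityModel

params = hd.default_params()            # calibrated muskox constants
env = hd.baseline_environment()         # synthetic snow + TB profiles
result = hd.run_experiment(hd.PopulationConfig(), params, env,
                           MortalityModel())
print(hd.summarize(result.endpoints)[["final_mass", "final_reserves"]])
```

```
             final_mass           final_reserves
                   mean       std           mean       std
group
heterotherm  205.675065  0.196430     949.725456  1.375009
normotherm   188.623517  0.143976     830.364618  1.007829
```

Both groups enter winter at 256.7 kg with 1307.5 MJ of total reserves and
lose mass throughout; by 31 May heterotherms are ~9.0 % heavier and hold
~14.4 % more reserves, having spent 27.4 % of their initial stores against
36.5 % for normotherms — the cumulative return on a sub-degree drop in
body temperature.  All 625 females per group survive the baseline winter.

The same comparisons, the pregnancy variants, and the scenario sweeps are
scripted as a narrative pipeline:

```
python analysis/01_synthesize_environment.py   # snow, f, TB inputs
python analysis/02_calibrate_parameters.py     # derive + verify constants
python analysis/03_baseline_comparison.py      # paired winter, both feeding modes
python analysis/04_pregnancy_comparison.py     # gestational heterothermy
python analysis/05_environmental_scenarios.py  # scenario sweeps 1-3
```

Each writes its tables under `results/`.  A thin CLI wraps the same
library: `heterodeb synth|simulate|scenario|report --help`.

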