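# thawflux

Analysis pipeline for linking permafrost-thaw temperature to methane
release at a thermokarst hotspot. The package reimplements, as tested
library code, the four desk-scale computations such a study rests on:

1. **Incubation gas kinetics** — headspace CH4/CO2 mole fractions from
   closed-jar soil incubations → masses (ideal gas) → interval fluxes →
   the temperature-sensitivity coefficient
   `Q10 = (R2/R1)^(10/(T2−T1))` over all temperature pairs and sampling
   intervals.
2. **Carbon-isotope bookkeeping** — δ13C on the VPDB scale, the apparent
   fractionation factor between soil organic matter and product CH4,
   `α_tot = (δ_sub + 1000)/(δ_CH4 + 1000)`, the δ13C-CH4–temperature
   regression, and a closed-system Rayleigh estimator
   `f = exp((δ_obs − δ_init)/ε_ox)` for interpreting methanotrophic
   enrichment of the residual CH4 pool.
3. **VOC fingerprinting** — the standard reduction for GCxGC thin-film
   feature tables (replicate averaging → blank subtraction →
   autoclaved-control subtraction → zero-row removal, with floors at
   zero), presence/absence calls, max-condition binning, superclass
   counts, and presence-overlap queries between soil incubations and a
   *Methanosarcina acetivorans* culture. A 16-compound shared-compound
   presence table ships with the package.
4. **A 1D thaw-column model** — heat conduction with freeze–thaw phase
   change (apparent heat capacity), Arrhenius × Monod microbial kinetics
   (aerobic respiration, methanogenesis with O2 inhibition, CH4
   oxidation), and Millington–Quirk diffusive gas transport on a 5 m /
   1 cm column, run as a 130-day spin-up plus 60-day warming scenarios
   (0/2/4 °C), with a CH4 mass ledger that closes to machine precision.

A synthetic-data module generates incubation, isotope and VOC inputs
with known ground truth (triplicate design, lognormal replicate noise,
planted VOC signatures), so every stage is testable without instrument
data. Intended users: biogeochemists and modellers working on soil
CH4 fluxes who want the arithmetic behind Q10, α_tot and
transport-lag claims reproducible and unit-tested.

## Worked example

Fractionation factors and the δ–temperature line from the measured
end-of-incubation values (soil OM −25.60 ‰; CH4 −64.6/−50.53/−38.90 ‰
at −4/4/10 °C):

```sh
$ python analysis/03_isotope_fractionation.py
T =    -4 °C: δ13C-CH4 =  -64.60‰ → α_tot = 1.042
T =     4 °C: δ13C-CH4 =  -50.53‰ → α_tot = 1.026
T =    10 °C: δ13C-CH4 =  -38.90‰ → α_tot = 1.014
δ–T regression: slope 1.832 ‰/°C, R² = 0.9992
Rayleigh scan (fraction of −4 °C CH4 remaining to reach the 10 °C δ):
  ε_ox =   -30‰ → f = 0.425
  ...
```

α_tot shrinks from 1.042 to 1.014 as incubations warm — the CH4 pool
enriches in 13C far more than a methanogenic-pathway shift could
explain, and the Rayleigh scan shows what fraction of the cold-treatment
CH4 would have to survive oxidation to produce the warm-treatment δ.

Shared-compound overlaps between 200 cm soil incubations and the
methanogen culture, from the packaged presence table:

```sh
$ python analysis/04_voc_overlap.py
shared-compound table: 16 compounds × 10 conditions
  200 cm soils (any T) ∩ culture 37 °C: 13 compounds
  200 cm soils (any T) ∩ culture 2 °C: 10 compounds
  200 cm at −4 °C ∩ culture (any T): 6 compounds
```

The thaw-column scenarios (≈25 s on one CPU):

```sh
$ python analysis/05_thaw_column_scenarios.py
scenario 0 °C: peak flux 1.98e-06 g/day/kg on day 60; crossover day 47.0; ...
scenario 2 °C: peak flux 6.19e-06 g/day/kg on day 60; crossover day 23.0; ...
scenario 4 °C: peak flux 1.09e-05 g/day/kg on day 53; crossover day 15.0; ...
```

Under the calibrated defaults the 4 °C run peaks near
1e-5 g CH4 day⁻¹ per kg of column soil, and the 200 cm horizon starts
persistently out-accumulating the 50 cm horizon on day 15: the shallow
layer activates first but vents to the atmosphere within days, while
deep CH4 sits behind a much longer diffusion path — the transport lag
between microbial activation at depth and surface emission.

The numbered scripts under `analysis/` are thin drivers over the
library (`thawflux.incubation`, `.isotopes`, `.voc`, `.column`,
`.synthetic`); a `thawflux` CLI exposes the same operations
(`thawflux voc`, `thawflux q10 …`, `thawflux thaw`, …) with results
written as JSON/CSV plus a provenance record.

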