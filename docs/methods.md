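# Methods

This note documents the models and procedures implemented in `thawflux`,
the choices behind their defaults, and what the synthetic-data tests do
and do not demonstrate about real data.

## 1. Incubation gas kinetics and Q10 (`thawflux.incubation`)

Closed jars (60 mL, 5 mL added water, ~5 g wet soil, N2-sparged
headspace) are sampled for CH4 and CO2 mole fractions on days
0/7/15/22/60. Mole fractions convert to gas masses with the ideal-gas
law, `n = χ·pV/(RT)`, at a fixed 101325 Pa (the measurement protocol
back-fills with N2, keeping the jars at constant pressure) and a
headspace temperature equal to the incubation temperature unless
overridden. Measurement uncertainty propagates linearly because the
ppm→mass map is linear at fixed geometry.

Fluxes are forward differences between consecutive sampling days,
normalised by the as-weighed (wet) soil mass; a dry-mass correction
factor is exposed but defaults to 1 since aliquots are reported wet.
The temperature sensitivity is

    Q10 = (R2/R1)^(10/(T2−T1)),

computed for every ordered temperature pair on every interval, using
replicate-mean fluxes. The grand mean is the arithmetic mean over all
valid (interval, pair) entries — the simplest reading of an "average
across all time points"; per-interval means are reported alongside.
Jars at or below −10 °C are excluded by default (production there is
below detection, making the ratio ill-defined), and any pair involving a
non-positive flux is excluded *and reported* rather than guessed at.
`detect_plateau` flags the first sampling day after which the |slope|
stays below a threshold, for identifying saturating treatments.

## 2. Isotope bookkeeping (`thawflux.isotopes`)

δ13C values are per mil vs VPDB (13C/12C = 0.0112372). The apparent
total fractionation factor between substrate organic matter and product
CH4 uses the convention

    α_tot = R_substrate / R_product = (δ_sub + 1000)/(δ_CH4 + 1000),

which is > 1 for 13C-depleted CH4 and is independent of the standard
ratio (it cancels). The δ13C-CH4–temperature relationship is ordinary
least squares; when the δ values are identical at every temperature
(SS_tot = 0) R² is defined as 0 and the fit flagged degenerate rather
than dividing 0/0. Mixing of carbon pools defaults to the mole-weighted
linear-δ approximation (standard at natural abundance); exact-ratio
mixing is available behind a flag and differs only in the third decimal
place for natural-abundance work.

The Rayleigh estimator interprets residual-CH4 enrichment by
methanotrophy in a closed system:

    f = exp((δ_obs − δ_init)/ε_ox),   ε_ox = 1000·(1/α_ox − 1) < 0,

with ε_ox negative for residual-pool enrichment (sign enforced: an
observed δ *below* the initial value is inconsistent with oxidation and
raises). The estimator is the exact inverse of the forward model
`δ = δ0 + ε·ln f` used in the round-trip tests. It supports
interpretation only — it cannot attribute the enrichment to a specific
oxidation pathway.

## 3. VOC feature-table reduction (`thawflux.voc`)

GCxGC peak-area tables (features × samples, with RT1/RT2, compound,
KEGG id, superclass annotations and per-sample condition/role metadata)
pass through a fixed pipeline whose order is enforced by a stage
checker:

1. arithmetic mean of replicate areas per condition;
2. subtraction of the mean of the instrument-blank and media-blank
   means, floored at zero;
3. subtraction of the autoclaved-control means from the live means,
   floored at zero;
4. optional removal of every feature whose row still contains a zero.

Flooring at zero makes the zero-row rule well defined for
over-subtracted cells. Presence in a condition is called when the
background-corrected condition mean exceeds a threshold whose default is
0 — the simplest rule consistent with subtract-then-floor; the threshold
is configurable because a signal-to-blank criterion cannot be excluded.
Feature binning assigns each feature to the condition with its highest
mean area (argmax); ties go to the first condition in a documented
canonical order and are flagged. Compound identity uses the KEGG id
when present, otherwise a case-insensitive name match; RT-window
matching (±6 s RT1, ±0.2 s RT2) is reserved for unannotated features.

A 16-compound presence table of KEGG-annotated VOCs shared between
thermokarst soil incubations (50/200/400 cm at −4/5/12 °C) and
*Methanosarcina acetivorans* C2A cultures (2/37 °C) ships with the
package, along with a compound→superclass mapping file (replacing any
online chemical-taxonomy lookup; no network access is used). Overlap
queries combine condition sets with any/all semantics; "shared at
200 cm" means the union over that depth's temperature conditions, which
is the construction that reproduces the table's own counts (13 and 10
against the warm and cold cultures, 6 for the freeze-stressed condition
against the culture union). Two counts quoted in running text elsewhere
("ten overlapping compounds at 200 cm and 5 °C"; "six shared" at 400 cm
−4 °C) are not consistent with the transcribed table under any
single-condition rule; only table-consistent counts are asserted.

## 4. Thaw-column model (`thawflux.column`)

A 1D soil column (5 m, 1 cm grid, 501 nodes) couples three pieces with
operator splitting at Δt = 0.01 day:

**Heat.** Conduction with freeze–thaw phase change via the apparent
heat-capacity method: the unfrozen-water fraction θ(T) ramps linearly
from 0 at −ΔT_f to 1 at 0 °C (ΔT_f = 0.5 °C default; a power-law ramp
is available), and the latent content L·φ·s enters through
c_app = c + L·φ·s·dθ/dT. The implicit backward-Euler step evaluates
c_app with a secant over two Picard sweeps so latent heat is not skipped
when a node crosses the freezing interval within one step; an explicit
scheme with a stability guard (naming the admissible Δt) is retained for
verification. Boundary conditions are prescribed surface temperature
and a fixed bottom temperature. Verification: steady conduction matches
the linear profile to <1e-6 °C, and the freezing front under step
cooling tracks the one-phase Stefan similarity solution
X(t) = 2λ√(αt), λ e^{λ²} erf(λ) = St/√π, within 5% (typically <2%).

**Kinetics.** Aerobic respiration, methanogenesis and CH4 oxidation are
Arrhenius × Monod ("dual Arrhenius Michaelis–Menten") rate laws:

    rate = v_max · e^{−Ea/R·(1/T − 1/T_ref)} · [S]/(K_m+[S]) · f(O2) · θ(T)

with f(O2) a Monod factor for the aerobic processes and an inhibition
factor k_i/(k_i+[O2]) for methanogenesis, T_ref = 277.15 K (4 °C, the
scenario benchmarked against incubations), and θ(T) shutting activity
off in frozen soil. Methanogenesis yields 0.5 mol CH4 per mol C
(acetoclastic disproportionation); labile carbon follows
60·exp(−z/1.2 m) mol C m⁻³, the usual organic-rich-over-mineral
profile. Explicit kinetics steps carry positivity limiters that scale
consumption back to the available pool and record the amounts actually
applied.

**Transport.** Fickian diffusion of CH4 and O2 with a Millington–Quirk
effective diffusivity, D_eff = D_air·θ_air^{10/3}/φ² +
D_water·θ_w^{10/3}/φ², where ice occupancy blocks both phases; harmonic
interface means let an ice-saturated node block transport entirely.
Fixed atmospheric composition at the surface (CH4 ≈ 1.9 ppm
equivalent), zero flux at the bottom. Darcy advection and ebullition
are deliberately out of scope; the transport interface is the extension
point. The implicit step and the surface-flux diagnostic are built from
the same discrete operator, so the per-run CH4 ledger

    production − oxidation − surface efflux − Δstorage = 0

closes to machine precision (audited each run; the acceptance threshold
is 0.1%).

**Runs and diagnostics.** A run is a 130-day spin-up under a constant
(optionally sinusoidal) baseline surface temperature followed by a
60-day scenario at constant 0/2/4 °C. Diagnostics: the day CH4 at
200 cm first exceeds 50 cm and stays higher for ≥3 consecutive archive
days (the persistence filter rejects single-day excursions), and the
first day the surface flux exceeds its spin-up baseline by a margin
(emergence lag). Per-kg-soil fluxes divide the areal flux by bulk
density × column depth (1300 kg m⁻³ × 5 m), since jar fluxes are
reported per kg while the model is per m².

**Calibrated defaults.** No published parameter values exist for this
site's kinetics, so the packaged defaults are an explicitly calibrated
set (see `scripts/calibrate_column.py`), chosen once so that the 4 °C
scenario reproduces two observations: the ~15-day 200 cm-vs-50 cm
concentration crossover and a peak surface flux of order
1e-5 g CH4 day⁻¹ kg⁻¹. The emergent mechanism: the winter baseline
(−2 °C surface over a −0.5 °C base) leaves the whole column frozen, so
spin-up is quiescent; warming drives a thaw front through a low-ice,
gas-permeable profile (porosity 0.5, saturation 0.14 — a seasonally
drained, organic-rich margin), the 50 cm horizon activates early but
vents to the atmosphere within days, while the 200 cm horizon activates
when the front arrives (~day 13–15) and accumulates because its
diffusion path is an order of magnitude longer. Thermal conductivities
(10/11 W m⁻¹ K⁻¹ thawed/frozen) are *effective* values that lump
unresolved advective heat transfer; they are far above pure-conduction
values for soil and exist so the deep column responds within the
60-day window. The methanogenesis activation energy (170 kJ mol⁻¹,
Q10 ≈ 13 near 0 °C) sits inside the wide range observed for anaerobic
CH4 production in high-latitude soils and matches the upper end of the
incubation-derived sensitivities. All defaults are plain dataclass
fields and overridable.

## 5. Synthetic data (`thawflux.synthetic`)

The generators emulate the study designs so each analysis stage has a
known ground truth:

- **Flux**: cumulative CH4/CO2 mass grows linearly at a
  temperature-dependent expected flux with ratio `q10_true^{ΔT/10}`
  (defaults: Q10 = 7.9, 1e-5 g day⁻¹ kg⁻¹ at 4 °C, triplicates at
  −30/−4/4/10 °C, days 0–60, CV = 0.1); production is zeroed at or
  below −10 °C, emulating undetectable CH4 in deeply frozen jars.
  CO2 uses a milder Q10 of 2 — CO2 production varies much less across
  treatments than CH4.
- **Isotopes**: δ13C-CH4 = slope·T + intercept + N(0, σ) with the
  measured line (1.8316 ‰ °C⁻¹, −57.45 ‰) as default and a constant
  substrate δ of −25.60 ‰.
- **VOC**: planted condition-specific compounds at a signal level far
  above blank contamination, triplicate live/autoclaved/blank columns,
  and the planted presence matrix returned as ground truth.

Noise is multiplicative lognormal (unit mean, stated CV) for areas and
fluxes — positive, heteroscedastic quantities — and additive Gaussian
for δ values. One master seed feeds a named substream per generator, so
adding a generator never perturbs existing streams.

What passing these tests shows: the estimators invert the generating
models correctly at realistic noise levels (e.g. the grand-mean Q10 is
recovered within a few percent over 200 simulated triplicate
experiments at CV = 0.1). What they do not show: robustness to
structure the generators omit — drifting instrument response, RT
misalignment between runs, co-eluting features, non-lognormal outliers,
day-0 residual-oxygen transients, or real jar-to-jar biological
heterogeneity.

## 6. Numerical and degenerate-input choices

- Tridiagonal systems are solved with banded LU (`solve_banded`).
- Backward Euler for both heat and gas diffusion: unconditionally
  stable, positivity-preserving (M-matrix), first-order in time —
  adequate at Δt = 0.01 day (refining Δt and dz changes cumulative
  flux by <2%).
- Ties in feature binning: first condition in canonical order, flagged.
- R² with zero total variance: defined 0, flagged degenerate.
- Q10 with non-positive flux: a distinct `UndefinedQ10Error`, never a
  silent NaN.
- Breakpoint values in the pathway line-weight bins belong to the upper
  class (half-open intervals), so the four classes partition [0, 100].
- Report floats serialise at 6 significant digits; machine outputs can
  retain full precision.

## 7. Known limitations

- The column model is diffusion-only: no ebullition, Darcy flow, water
  table, talik geometry, or isotope-enabled transport. Its defaults are
  a calibrated illustration of the thaw→production→transport-lag
  mechanism, not a site parameterisation.
- The 60-day scenarios use constant surface temperatures; real forcing
  varies diurnally and synoptically.
- Presence/absence calls depend on a threshold the source tables do not
  document; the default (>0 after flooring) is one defensible choice.
- The Rayleigh estimator assumes a closed, well-mixed single pool with
  constant ε_ox.
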