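# Methods

`elatosim` is a deterministic, stoichiometrically closed simulator of the
green spruce aphid (*Elatobium abietinum*) feeding on managed Sitka spruce
(*Picea sitchensis*) plantations in a cool maritime climate, together with
the machinery to run temperature × CO₂ change scenarios and to classify the
resulting population-dynamic regimes from their spectra.  This note records
the model structure, the parameter choices that matter, the numerical
scheme, and the limits of what the synthetic study conditions can show.

## 1. Climate synthesis

All weather is generated from a compact seasonal parameterization of the
long-term climate at Eskdalemuir, southern Scotland (55°19′ N, 3°12′ W,
242 m a.s.l.).  For each driver the annual course of the daily maximum and
daily minimum is a **two-anchor curve**: half-cosine segments through the
driver's two seasonal extremes (value, date).  Where the two extreme dates
are antipodal this is the plain sinusoid `mean + amplitude·cos(2π(d −
d_peak)/365)`; where they are not (this climate's printed extremes are
mostly non-antipodal — e.g. rain peaks 16 January and bottoms 16 May), the
curve still attains both extremes on their stated dates, remains smooth and
365-day periodic, and keeps its annual mean at the midpoint of the two
extremes.  That midpoint property preserves the climate's wind identity
(annual + diurnal mean wind = ½(6 + 2) = 4 m s⁻¹) exactly.

Anchor values (daily statistics):

| driver | high | low |
|---|---|---|
| wind daily max / min (m s⁻¹, 50 m) | 7.5 / 2.5 on 26 Apr | 4.5 / 1.5 antipodal |
| air-T daily mean (°C) | 13.5 on 16 Jul | 1.45 on 16 Jan |
| diurnal air-T range (°C) | 5.0 on 16 May | 2.15 on 16 Dec |
| RH daily max / min | 0.91 / 0.88 on 16 Dec | 0.75 / 0.65 on 16 May |
| rain (mm d⁻¹, daily constant) | 5.65 on 16 Jan | 2.8 on 16 May |
| bright-sunshine fraction | 0.32 on 15 Jun | 0.19 on 20 Dec |

The sunshine-fraction anchors are chosen so that the Ångström regression
`j_PAR = j_extraterrestrial,PAR · (a + b·f_sun)` with a = 0.19, b = 0.62 and
a PAR:total-shortwave ratio of 0.5 reproduces the reported PAR envelope for
this site (generated: 0.68 MJ m⁻² d⁻¹ on day 355 to 8.0 MJ m⁻² d⁻¹ on day
171, a >10× annual range).  Extraterrestrial receipt uses standard solar
declination/day-length geometry with the eccentricity correction.

Diurnal shapes are piecewise cosines anchored at **dawn** (computed from
solar geometry; minimum temperature and wind, maximum RH) and **15:00**
(the opposite extreme), continuous across midnight; day-to-day parameter
drift makes midnight jumps below 1 % of the diurnal range.  Soil
temperature is the mean of the daily air extremes and diurnally constant,
as are rain and the sunshine fraction.  Daily PAR is spread over daylight
hours with a half-sine (sine-of-elevation) profile.

A scenario is a pair (ΔT, CO₂): ΔT is added to both air and soil
temperature, CO₂ replaces the ambient 350 μmol mol⁻¹.  Users may instead
supply 12 monthly station values per driver (linearly interpolated between
month mid-points, the original construction for this climate) or a complete
forcing CSV.

A 365-day climatological year is used throughout; leap days are ignored.
Day-of-year 1 is 1 January.

## 2. Stand surrogate

The host tree is a reduced-form substrate C/N stand model in the
transport-resistance tradition: big-leaf canopy photosynthesis (rectangular
hyperbola per leaf, Beer's-law canopy integral, saturating CO₂ factor
normalized at 350 μmol mol⁻¹, parabolic temperature response, end-product
inhibition by the substrate-C concentration) feeds a foliage-associated
substrate pool `C_le`; root uptake of mineral N (Michaelis in soil mineral
N, end-product inhibited by the foliage-normalized substrate-N
concentration) feeds `N_le`.  Foliage, wood and fine-root structural pools
grow from both substrates with saturating kinetics and fixed tissue N:C
ratios; foliage expansion is capped by self-shading at `LAI_max` = 8.
Maintenance respiration (Q₁₀ = 2, throttled as substrate C empties),
tissue turnover, a two-pool litter/soil decomposition chain, mineral-N
leaching scaled by rain, constant atmospheric N deposition, and a slow
substrate-N recycling flux close both element cycles.  Stem wood leaves the
system only through harvest.

The aphid reads three host signals: leaf area per stem (`LAI / n_stems`)
and the phloem substrate concentrations `C_le / C_fol` and `N_le / C_fol`
(pool per unit foliage structural C) — an intensive food-quality signal.
It writes two: the phloem C and N withdrawal rates.

Growth, turnover and N-cycle parameters were set **once** from typical
Sitka physiology (SLA 6 m² kg⁻¹ DM, needle lifespan ≈ 5.5 y, fine-root
lifespan ≈ 1 y, foliage N:C 0.025) and upland-Britain N budgets
(deposition 2.2 g N m⁻² y⁻¹), subject to two corridors that define the
intended study conditions: the no-aphid ambient rotation must close its
canopy inside two decades and yield 9–15 m³ ha⁻¹ y⁻¹ of stem wood (the
conventional Sitka yield-class band; the model gives ≈ 10 at its 60-year
repeating equilibrium), with wood volume converted at 400 kg DM m⁻³ basic
density and 0.5 kg C kg⁻¹ DM.

**Management.**  Planting at 0.25 stems m⁻² and LAI 0.003; thinnings remove
0.45, 0.40, …, 0.10 of standing stems at years 20, 25, …, 55; clear-fell at
60 years.  Each thinning runs at a constant stem-removal rate over exactly
one day starting 1 January of its year, the rate fixed from the stem count
at the event's start, so the removed total is independent of the
integration step.  Removed stems carry their proportional share of every
per-stem pool: stem wood (with its N) to the harvest ledger, foliage and
substrates to surface litter, roots to soil, and the aphids riding on them
to soil.  At clear-fell the standing stem wood joins the harvest, residues
go to litter/soil, and the next rotation replants into the inherited
litter/soil/mineral-N state.

## 3. Aphid sub-model

Ten states, aphids per stem: apterous (wingless) instars 1–4 + adult, alate
(winged) instars 1–4 + adult.  Air temperature is the only environmental
variable acting on the aphid directly.

* **Development** — degree-day kinetics per instar (base 3 °C; thermal
  constants 28, 26, 26, 30 °C·d, ≈ 110 °C·d birth→adult, ≈ 17 d at a
  constant 10 °C), linear to an optimum of 20 °C and declining to zero at a
  32 °C ceiling.
* **Feeding** — per-capita sap C throughput proportional to body C
  (40 × body C d⁻¹ at saturation — phloem feeders pass many body-equivalents
  of dilute sap and excrete the sugar surplus), saturating in phloem C
  concentration (half at 0.02) and divided by a crowding factor
  `1/(1 + ρ_leaf/600)` with ρ_leaf in aphids per m² leaf.  The N:C ratio of
  the intake equals the phloem's own N:C — food quality is a host property.
* **Reproduction** — apterous adults bear live nymphs at up to
  4 d⁻¹, saturating in their realized N intake (half at 10⁻⁸ kg N d⁻¹) with
  a unimodal temperature response (4–16–30 °C).  Births split between
  morphs by an induction rule rising with crowding (half at 400 m⁻² leaf)
  and with food shortage; alate adults feed but do not reproduce locally
  and emigrate at 0.3 d⁻¹.  A constant background immigration rate
  (transient alates depositing apterous nymphs) is available but off by
  default; when used, the emigration ledger records the *net* migration
  export so the mass audit still closes.
* **Mortality** — stage baselines (0.03 d⁻¹ nymphs, 0.05/0.08 d⁻¹
  apterous/alate adults) + a cold term quadratic in the deficit below 2 °C
  (0.055 d⁻¹ °C⁻²) + a starvation term ramping to 0.5 d⁻¹ as the realized
  intake ratio falls below one half.  The cold coefficient is the one
  deliberately *regime-setting* parameter: it was fixed so that winters
  2 °C colder than ambient extinguish the population within the rotation
  while ambient winters only bottleneck it — the empirical overwintering
  behaviour of this species.
* **Stoichiometric closure** — body C is counts × fixed per-stage masses
  (adult 10⁻⁸ kg C, instars 0.15–0.75 of that; body N:C 0.15).  Each
  instant: respiration = 0.30 × C intake; the C and N demanded by stage
  transitions and births is taken from the remainder, and if it exceeds
  what intake can pay the demographic fluxes are scaled down in proportion
  (the starvation response also slows development); honeydew C and excreted
  N are the *residuals* of intake after respiration and growth — excess
  sugar to surface litter, exactly as phloem feeders dispose of it.
  Corpses (and thinning kills) carry body C/N to soil; emigration exports
  it.  The identities `uptake_C = respiration + honeydew + growth` and
  `uptake_N = excretion + growth` therefore hold to machine precision, and
  whole-system C and N balance closes to ~10⁻¹⁵ relative over 60 years.

The inoculum is 1 apterous adult per stem applied at time zero of the
reported rotation (the value is a free choice; the crowding-capped
dynamics forget it within a few seasons).

## 4. Simulation protocol and numerics

* **Integrator** — classical fixed-step RK4 on the full coupled state
  (11 stand pools, 10 aphid stages, 10 cumulative boundary-flux ledgers).
  Default step 1/48 d; 1/24 d is the standard analysis step used in the
  verification runs and examples, where halving the step moves the headline
  observables (Y_C, C_sys, peak ρ_aph) by < 0.02 %.  Negative excursions
  smaller than 10⁻¹² (absolute) are clamped to zero; anything larger, or a
  NaN/Inf, aborts the run with a state dump.  The compiled kernel is the
  implementation; the generic `rk4_step`/`integrate_fixed` helpers expose
  the same scheme for oracle tests.
* **Events** — management events are constant removal-rate terms active
  during their one-day window, evaluated inside the RHS, not discrete
  jumps.
* **Spin-up** — each scenario starts from its own no-aphid 60-year
  repeating equilibrium: full rotations (management included) are iterated
  until the start-of-rotation state changes < 10⁻⁴ relative per pool
  (cap 50 rotations; the ambient scenario converges in ~14, limited by the
  slow soil pool).  Aphid runs then inoculate at time zero.
* **Switch-off** — with the aphid switch off the aphid code path is
  bypassed entirely; the test suite verifies bit-identical stand
  trajectories against a run that executes the aphid machinery on a zero
  population, which is the stronger form of the equivalence.
* **Mass audit** — cumulative boundary fluxes are integrated as extra
  states with the same RK4 weights, so the interval-wise audit
  `Δ(total C) = inputs − outputs` is an algebraic identity of the RHS and
  any residual measures implementation error, not scheme error.
* **Determinism** — there is no randomness anywhere in the model; identical
  configurations give byte-identical outputs.

## 5. Spectral analysis and regime taxonomy

Population series (daily ρ_aph, total aphids per stem) are analysed over
the final 32 years of a rotation: Welch periodogram, Hann taper, 8-year
segments, 50 % overlap, per-segment mean removal, frequency axis in cycles
per year.  Integrated density matches the window variance (Parseval) to
< 1 % for deterministic input; for stochastic input the estimate carries
ordinary realization variance.  Classification is rule-based and
scale-invariant:

* **extinct** — the series stays below 10⁻⁶ of its running peak through
  the final 5 years;
* **annual** — dominant line within 10 % of an integer ≥ 1 cycle y⁻¹ and
  ≥ 50 % of the power above 1/32 cycle y⁻¹ on the integer-harmonic comb
  (a non-sinusoidal annual cycle spreads power across its harmonics);
* **k-point** (k = 2–4) — dominant subharmonic nearest 1/k cycle y⁻¹
  (tolerance at least one frequency bin: an 8-year segment cannot place
  1/3 on-grid) with ≥ 50 % of power on its comb;
* **complex** — no dominant line (peak < 10 × median) or insufficient comb
  concentration; spectral flatness is indicative, not determinative, of
  chaos, so a two-trajectory divergence-rate diagnostic is provided
  separately and deliberately not used as a classifier.

Comb bands are unions (no double counting) at least ~1.6 bins wide so a
taper-spread line is captured whole.

## 6. What the synthetic conditions do and do not show

The generated weather is a smooth climatological year: no day-to-day
weather noise, no extreme events, no inter-annual variability.  Everything
the model produces — annual cycles, multi-annual structure, die-outs — is
therefore endogenous deterministic dynamics, which is precisely what the
regime analysis targets; it also means the simulated series are far more
regular than trap-catch data, and passing regime tests says nothing about
classification skill on noisy field series beyond the constructed-series
checks.  The stand surrogate has no water/transpiration sub-model (rain
only modulates leaching), no pests other than the one aphid, no predators
or parasitoids of the aphid, no sexual/egg overwintering phase, and no
spatial structure.  Aphid damage flows solely through phloem substrate
withdrawal — the model does not represent direct needle loss from feeding
injury, so yield impacts (≈ 13 % at ambient) sit at the lower end of the
field-reported 10–50 % growth depression.  The CO₂ fertilization gain is
modest (a few per cent of yield at equilibrium) because the equilibrium
stand is nitrogen-limited; the sign structure (CO₂ up ⇒ yield up, aphids
present ⇒ yield down) is robust but magnitudes are surrogate-dependent.

## 7. Degenerate inputs and tie-breaks

Zero foliage ⇒ zero leaf area, zero phloem concentration ⇒ aphids starve
(intake 0, starvation mortality maximal); zero stems ⇒ no thinning term;
all-zero aphid state is absorbing; an all-zero population series is
rejected by the normalizer.  The substrate drain saturates in the phloem
concentration, so pools cannot be driven negative by feeding; the explicit
`aphid_drain` operation additionally documents the clamp-and-report
contract for step-wise callers.  Thinning fractions must lie strictly in
(0, 1); `maxt` must divide one day; the output cadence must be a multiple
of `maxt`.
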