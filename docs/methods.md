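# Methods

This note documents the models implemented in `agroflux`, their
assumptions, the defaults and why they were chosen, what the synthetic
campaign does and does not emulate, and the numerical conventions at the
edges. Nothing here states an empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Reference evapotranspiration (`agroflux.pet`)

Daily ET₀ follows the full FAO-56 Penman–Monteith chain on the
"minimum data" route: temperature and relative-humidity extremes, wind
speed, pressure and bright-sunshine hours.

* Saturation vapour pressure is the mean of the Tetens values at tmax and
  tmin; actual vapour pressure pairs e°(tmin) with RHmax and e°(tmax) with
  RHmin. The vapour-pressure-curve slope is evaluated at the mean of tmax
  and tmin, which also feeds the aerodynamic term.
* Extraterrestrial radiation comes from latitude and day of year (the
  sunset-hour-angle argument is clipped to ±1 so polar day/night degrade
  gracefully); solar radiation uses the Angstrom formula with the FAO
  default coefficients a_s = 0.25, b_s = 0.50 unless the site's own
  calibration is supplied. Albedo defaults to the reference-grass 0.23.
* Net longwave uses the FAO cloudiness factor 1.35·Rs/Rso − 0.35 with
  Rs/Rso capped at 1, and the humidity correction 0.34 − 0.14·√ea.
* Soil heat flux is zero at the daily step. Wind is adjusted to 2 m with
  the logarithmic profile when measured at another height. Measured
  pressure is used when present; otherwise the FAO elevation formula.
* ET₀ is floored at zero: a negative Penman–Monteith numerator (possible
  on cold, calm, snow-covered days) is reported as no evaporative demand,
  keeping the downstream ET:PET ratios well defined.

Sunshine exceeding the astronomical daylength, humidity outside [0, 100],
tmax < tmin, or non-finite inputs are rejected with a named reason rather
than silently clipped.

## Chamber fluxes (`agroflux.chambers`)

The concentration ramp is fit by ordinary least squares over **all** points
(16 points at 20-s spacing in the reference deployment). No deadband is
removed and no diffusion-curvature model is fit: with a 5-minute
deployment and a 0.005 m³ headspace the linear approximation is the
method's own assumption, and the choice keeps the estimator unbiased for
the synthetic truth, which generates linear ramps.

Quality control flags — it never discards. A deployment is flagged
`low-r2` only when r² < 0.7 **and** the slope magnitude exceeds a
configurable threshold (default ~1 ppm over the deployment): a genuinely
near-zero flux produces a flat, noise-dominated trace whose low r² is not
evidence of failure. Negative slopes (uptake) are retained with sign.

Unit chain: ppm s⁻¹ → mol m⁻² s⁻¹ through the ideal-gas headspace
inventory PV/RT at deployment temperature and pressure → g element m⁻²
day⁻¹ using 12.011 (CO₂-C) or 28.014 (N₂O-N, two nitrogens per molecule).
Headspace volume is a supplied constant, not derived from the collar
cylinder, because dome-capped chambers have irregular tops.

Same-day replicate chambers within a plot are averaged before daily
interpolation (arithmetic mean). Daily values are linearly interpolated
between sampling dates only **inside** the observed span — no
extrapolation before the first or after the last deployment; the
cumulation window is clipped to the span and the clipping is reported on
the output row. Cumulative emissions are the sum of daily g m⁻² day⁻¹
values times 10 (kg element ha⁻¹).

## Water balance (`agroflux.water_balance`)

**Profile integration.** TSM (mm) over 0–90 cm uses the trapezoidal rule
on the nonuniform sensor grid, with the shallowest sensor's reading
extended to the surface (no shallower sensor exists to anchor a gradient;
for 30/60/90 cm sensors this makes TSM = 450·θ₃₀ + 300·θ₆₀ + 150·θ₉₀ in
mm). A uniform 0.38 profile therefore gives 342 mm; alternative surface
conventions change this by ~1% and are easy to swap in `profile_tsm` if a
site has shallow sensors.

**Field capacity** is the mean TSM in the 30 days preceding crop
emergence, on the argument that a humid-continental profile recharges
fully over winter; it is estimated at site level by default (one FC across
plots) and can be overridden per plot or fixed in configuration.

**Drainage.** The 0000–0400 h storage drop, during which no ET is
expected, gives an hourly drainage rate ((TSM₀₀₀₀ − TSM₀₄₀₀)/4, clamped at
zero) scaled to 24 h. Anchor readings are the nearest record within ±15
minutes of the nominal time; a missing anchor makes the day q-unavailable.

**Note on noise sensitivity.** The ×24/4 scaling makes the drainage
estimate a noise rectifier: with independent per-reading sensor noise of
σ mm on TSM, the clamp contributes a spurious loss of about
6·√2·σ/√(2π) mm day⁻¹ on truly drainage-free days, which is then
subtracted from ET. At σ ≈ 0.5 mm (i.i.d. VWC noise of 0.001) this is
~2 mm day⁻¹ — comparable to the signal. The method therefore relies on
what real profile sensors actually provide: errors dominated by a static
calibration offset that cancels in every difference the method uses.
This sensitivity is worth knowing when judging absolute ET levels from
any field application of the method.

**Screening.** A day is excluded, first matching reason recorded, when
(1) storage increased midnight-to-midnight (net gain), (2) precipitation
fell that day or in the three preceding days, or (3) TSM exceeds FC.
Included days with ET computing negative are demoted (`negative-et`) and
treated as excluded rather than reported as negative ET.

**The drainage sign.** Storage depletion net of drainage is the physical
balance: ET_j = (TSM_j − TSM_{j+1}) − Q_j. An additive convention
(`eq1_literal=True`) is provided for comparison with analyses that add Q
to the depletion; on retained days TSM ≤ FC so Q ≈ 0 and the two nearly
coincide, which is presumably why the distinction is easy to miss.

**Gap filling.** Each excluded day receives (most recent prior measured
ET/ET₀ ratio) × that day's ET₀; days before the first measured ratio use
the first one (backfill). The single-most-recent rule is the default and
deliberately simple; an averaged-recent-ratios variant would damp the
ratio's sampling noise at the cost of tracking crop phenology more slowly.
Every day in a season is thus exactly one of measured/gap-filled, with the
source and the ratio used recorded per day.

**WUE** divides plot AGB by that plot's cumulative seasonal ET. Because a
mean of per-plot ratios differs from the ratio of means, summaries report
per-plot values and leave the averaging convention to the reader (the test
suite demonstrates the difference).

## Biomass and leachate

Dry yield = fresh mass × (1 − moisture/100) / area × 10⁴ (kg ha⁻¹). Corn
AGB = dry grain / 0.545 (standard harvest index, applied after moisture
correction). Root-profile totals are always recomputed from the depth
increments — printed totals in source tables can carry rounding — and
depth fractions are increments over the recomputed total. Soil-C stock =
concentration (g kg⁻¹) × bulk density (g cm⁻³) × thickness (cm) × 0.1
(Mg C ha⁻¹).

Leachate NO₃-N: replicate samplers within a plot-date are averaged first
(mirroring chamber replicates), then groups are summarized as mean ± SE
(sd/√n); relative reduction = (mean_ref − mean_alt)/mean_ref × 100.
Below-detection values are retained at face value unless a substitution
rule is configured.

## Synthetic campaign (`agroflux.synth`)

The generator's defaults describe one study condition and are not tuning
knobs: a humid-continental site at 40.07° N, 6 plots (2 crops × 3
blocks), 3 seasons, April–September growing season with May 1 emergence.

* **Weather**: sinusoidal temperature normals (annual mean 11 °C,
  amplitude 13.8 °C, peak at DOY 196 → Apr–Sep mean ≈ 19.5 °C) with 2 °C
  synoptic noise; Bernoulli(0.3)–Gamma(1.5) precipitation with 11 mm mean
  event depth → expected growing-season total ≈ 604 mm; sunshine and
  humidity anti-correlated with rain; the `drought` preset scales
  precipitation by 0.73 (~27% below normal).
* **Soil moisture**: an hourly single-bucket profile starting at 350 mm
  against a 340 mm field capacity. The day's true ET is a crop-coefficient
  curve (bare-soil 0.25 before emergence, ramping to a crop peak of
  1.05/1.10 by mid-season with a mild late decline) applied to the FAO-56
  ET₀ of the generated weather — as in a real canopy, so the ET:PET
  gap-filling premise holds in truth. Extraction is distributed over a
  daytime sine hump with **nothing between 0000 and 0400 h**, is
  supply-limited (a dry bucket cannot transpire), and the realized daily
  values are what the truth log records. Storage above FC drains by
  first-order relaxation (0.15 h⁻¹). TSM is disaggregated to sensor-depth
  VWC with fixed weights chosen so trapezoidal re-integration reproduces
  the bucket exactly.
* **Sensor error**: a static per-sensor calibration offset (sd 0.01
  cm³ cm⁻³ — large, but it cancels in every difference the method uses),
  output quantization at the instrument's 0.001 resolution, and
  sub-resolution electronic noise (5 × 10⁻⁵). This is the error structure
  profile sensors exhibit in the field; modelling instead a large i.i.d.
  Gaussian per reading makes the drainage estimator rectify noise (see
  above) and is a different experiment — one about a failure mode, not
  about recovery.
* **Chambers**: ramps invert the ideal-gas conversion at the configured
  true flux (seasonal Gaussian-shaped CO₂ curves per crop; N₂O baseline
  plus an early-summer fertilization pulse), 16 points at 20 s, 1 ppm
  analyzer noise for CO₂ (scaled down for N₂O's ppb-scale signal).
* **Leachate**: lognormal samples around crop-depth means; the perennial's
  mean declines relative to the reference crop by 20/60/80% over the three
  stand ages.
* **Biomass**: per-plot AGB truths at the magnitudes typical of Midwest
  trials (corn ≈ 10–12 t ha⁻¹; perennial ≈ 3.8 → 16.7 → 12.4 t ha⁻¹ over
  establishment), emitted as the harvest records the pipeline actually
  ingests (machine grain at 18% moisture; fresh quadrat bundles).

Every generator is a pure function of (parameters, seed); per-plot and
per-year streams are derived with stable integer tags so generation order
does not matter.

**What passing recovery tests do and do not show.** The campaign exercises
every screening rule, gap-filling, drainage, replicate averaging and the
full unit chains, with known truth. It does **not** emulate spatially
heterogeneous soils, sensor drift within a season, runoff or lateral flow,
chamber leakage or nonlinearity, or weather-correlated flux dynamics
beyond the smooth seasonal curves — so truth recovery here validates the
estimators' arithmetic and screening logic, not their robustness to those
field realities.

**Recovery precision.** On the default scenario the per-plot cumulative
season ET carries ±15% (≈2 sd) scatter, dominated by the interaction of
the single-latest-ratio gap-fill rule with quantized sensor readings; the
campaign-mean cumulative ET recovers truth within a few percent, and the
10% recovery check in the tests and acceptance script is applied at that
campaign level — the same unit at which such trials report ET. With
perfect sensors and no precipitation, daily ET is exact (to double
precision) on every retained day, and chamber-flux/biomass recovery is
exact at zero noise by construction.

## Problem sizes

Tests generate one-season campaigns (6 plots × 183 days hourly, ≈92k
sensor readings) wherever possible; the determinism and acceptance checks
run the full 3-season default twice. The whole suite runs in well under a
minute; the acceptance script in about one.

## Known limitations

* The gap-fill ratio uses a single prior day; an exponentially-weighted
  or windowed ratio would be less noisy and is a natural extension point.
* FC from a fixed 30-day pre-emergence mean inherits any above-FC
  transients in that window (slight overestimate after a wet spring).
* The trapezoidal surface convention (extend θ₃₀ upward) is one of several
  defensible choices and changes absolute TSM by ~1%.
* Leaching is summarized as concentration only; mass flux would require
  drainage volumes the method does not observe.
* Inferential statistics (mixed models, multiple comparisons) are out of
  scope; summaries are descriptive mean ± SE.
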