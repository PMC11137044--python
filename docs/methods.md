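# Methods

This note documents the models implemented in `empen`, the conventions and
defaults they use, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Time axis and season

A breeding season runs March 1 to February 28 of the following calendar
year. Internally every instant is a continuous *day-of-year of the season's
starting year*: March 1 = day 60, February 28 = day 424 (days past 365 run
into the next calendar year; the season axis assumes a 365-day year, and
the io layer converts exactly via real calendar dates). The arrival
parameter t₀ is therefore directly interpretable as a day-of-year
(April 7 = 97).

## Windchill (colony density) model

Apparent temperature is linear in the four drivers, T_a = T + c_W·W +
c_R·R + c_H·H with T in °C, wind W in m/s, downward solar radiation R in
W/m², relative humidity H in percent (0–100). Colony density is
ρ(T_a) = ρ_max / (1 + exp((T_a − T_c)/b₀)) with ρ_max fixed at 12.8
animals/m², the hexagonal packing density of 0.3 m circles
(π/(2√3) / (π(d/2)²), rounded to three significant figures). T_c is the
apparent temperature at which density is half of ρ_max; b₀ > 0 is the
steepness of the huddling response.

Calibration is ensemble MCMC over (c_W, c_R, c_H, T_c, b₀, σ_log) with a
lognormal likelihood on density and uniform priors on wide physical boxes
(c_W ∈ [−5, 0] °C·s/m; c_R ∈ [0, 0.1] °C·m²/W; c_H ∈ [−0.5, 0.5] °C/%;
T_c ∈ [−60, 10] °C; b₀ ∈ (0, 20] °C) — wind can only cool, sunshine only
warm; the humidity sign is left free. σ_log carries a half-normal(0.5)
prior. Walkers start from the multivariate log-linear regression of ln ρ on
(T, W, R, H): in the warm tail of the sigmoid ln ρ ≈ ln ρ_max −
(T_a − T_c)/b₀, so the regression slopes identify −1/b₀ and the coefficient
ratios, and the intercept identifies T_c.

## Phenological occupancy model

Each phenological event is a colony-wide Gaussian wave of individual event
dates; the expected count of a cohort on day t is
Σ_e magnitude_e · Φ((t − μ_e)/σ_e), clipped at zero against floating-point
undershoot. Event CDFs are evaluated exactly (no truncation). The fixed
event structure, with all magnitudes in units of BP:

| event | day (mean) | sd | females | males | non-breeders | chicks |
|---|---|---|---|---|---|---|
| arrival | t₀ | Δt₀ | +1 | +1 | +NB | |
| courtship departure | t₀+m | Δt₀ | −1 | | −NB | |
| female return (hatching) | t_r = t₀+m+b | Δb | +H | | | |
| male departure | t_r + c_max | Δb | | −1 | | |
| guard trips (2/sex, alternating) | see below | Δb | ±H | ±H | | |
| emancipation | t_e | Δb | −H | −H | | +H |
| crèche trip j = 1..7 | ladder | Δb | ±q_j | ±q_j | | −(q_{j−1}−q_j) at returns |
| fledging | t_fl | Δb | −F | −F | | −F |

Conventions and constraints:

* The arrival spread Δt₀ is shared by the courtship departure (courtship is
  equally long for everyone); every later event shares the single spread
  Δb ≥ Δt₀.
* Only the H·BP pairs whose egg hatched return as feeders; failed males
  leave with the male-departure wave and never return.
* **Guarding is strict alternation.** One parent always attends the chick;
  the returning forager spends the feeding stay c_max at the colony before
  the partner departs, so every switch overlaps by c_max. The male departs
  at t_r + c_max and makes two s_max trips; the female's trips are s_fem
  then s_max, interleaved with his. Emancipation falls at
  t_e = t_r + 5·c_max + 3·s_max + s_fem. This uses c_max in exactly its
  parameter sense ("time at the colony per trip during the guarding phase")
  and keeps the egg/chick attended on the mean timeline — a per-sex
  independent ladder with a short fixed overlap would leave the chick alone
  for most of the brooding period and, empirically, destroys the
  identifiability of H from adult counts (the guard-phase adult level is
  ≈ H·BP·(1 + overlap fraction)).
* Trip counts are fixed structure (2 guarding, 7 crèching): freeing them
  creates many near-equivalent local optima (few long trips vs many short
  ones) and the fit stops converging.
* Crèche trip j interpolates linearly from (s_max, c_max) at j = 1 to
  (s_min, c_min) at j = 7, reflecting the observed shortening of foraging
  trips towards fledging.
* Attrition: the surviving-pair fraction declines linearly across the seven
  crèche returns, q_j = H − j·(H − F)/7. Departures carry q_{j−1}, returns
  q_j (abandonments happen at sea); chick losses of (q_{j−1} − q_j)·BP ride
  on the return waves. The linear allocation is the simplest monotone
  choice; the data constrain only the endpoints H and F, not the path.
* Chicks are countable only from thermal emancipation (+H·BP at t_e); by
  construction fledged + dead chicks + lost eggs = BP exactly.
* Event dates reported by the model are *central* (mean) dates. Field
  protocols record the *first occurrence* of a behaviour, which precedes
  the central date by roughly two event standard deviations; the package
  documents this offset and does not correct for it.
* A schedule whose last event falls past February 28 is rejected
  (`ValueError` when building; zero prior mass during fitting).

### Agent-based oracle

`agent_oracle` simulates n individual pairs: every event time is an
independent Gaussian draw and survival through hatching and the seven
crèche trips is one nested uniform draw per pair (a pair survives trip j
iff u < q_j), so the expected daily count equals the analytic occupancy
exactly. `oracle_standard_error` gives the exact per-day standard deviation
of the simulated counts in closed form (binomial terms plus the
participation covariances induced by the shared uniform), which is what the
equivalence tests compare against.

## Inference

Likelihood: independent lognormal count errors,
Σ_i logN(ln obs_i | ln(model(t_i) + ε), σ_log) with ε = 10⁻⁶ guarding
ln 0, and a single season-level σ_log under a half-normal(0.5) prior.
Counts vary over two orders of magnitude within a season, which makes a
multiplicative error model the natural choice and matches the geometric
error reporting. Multiple observations on one civil day are averaged before
fitting.

Priors: uniform over the parameter boxes (t₀ ∈ [50, 150], Δt₀ ∈ [4, 14],
m ∈ [28, 42], b ∈ [50, 100], Δb ∈ [0, 14], BP ∈ [2000, 15000], NB, H,
F ∈ [0, 1], c_max ∈ [1, 5] d, trips ≤ 21 d) with the ordering constraints
c_min ≤ c_max ≤ s_min, s_fem ≤ s_max, F ≤ H, Δb ≥ Δt₀ — the widest
physiologically plausible ranges, not tailored to any one colony.

Sampler: emcee's affine-invariant ensemble, 44 walkers by default, so that
the default 300 retained steps give 13,200 posterior samples. A mandatory
integer seed drives every random element (prior draws for initialisation
and the chain itself); runs are bitwise reproducible. Walkers start in a
small ball around the best of a few thousand scored prior draws.
Diagnostics (acceptance fraction, per-parameter effective sample size via
arviz) ship with every posterior; acceptance < 5 % or very low ESS triggers
a warning but samples are still returned.

**Satellite mode** fixes everything except BP and F to supplied defaults
(a representative parameter file ships with the package; users supply their
own colony means when available) and anchors arrival so that the
female-return date t₀ + m + b equals the site's first sunrise after
midwinter plus 27.4 days — an empirical latitudinal relationship. The
offset is a configurable constant. Fewer than three usable points are
refused.

### Identifiability (what adult counts can and cannot pin down)

Weekly adult counts identify BP (incubation level), t₀, m, b (wave
timings), Δt₀, Δb, and H (guard-phase level) well — parameter-recovery
tests see BP and H within ~10 % at 10 % count noise. F, however, enters the
adult curve late in the season only through the product
(pair survival) × (colony-attendance fraction c/(s+c)); with Δb ≈ 9 d the
within-trip oscillations are smeared out and F rides an almost exact ridge
with the trip-ramp endpoints (posterior corr(F, c_min) ≈ −0.8). The
posterior honestly reflects this — truth sits inside the wide credible
interval — but the flat-prior posterior *mean* of F can sit 20–40 % below
truth. The satellite mode does not suffer from this: the trip ramp is
fixed and chicks (∝ q_j) are part of the observed totals, so F is
recovered to within ~0.1 absolute from six points. Fits restricted to
post-September adult data alone leave even BP weakly identified, which is
precisely why the constrained satellite mode exists.

## Pipeline

The four-step census recipe: measure colony areas on several dates
(October–December), predict density from weather at image time (nearest
record within ±30 min; unmatched images are listed and skipped), convert to
individuals N = ρ·A with same-day averaging, and fit the satellite mode to
N(t). The conversion factor CF = BP / mean(A) is computed over a reference
window (default: the courtship–incubation span; when no images fall there —
the normal case for satellite data — all areas are used, with a warning).
Outlier exclusion is an explicit config flag (`exclude_area_dates`), never
silent.

## Synthetic data

The generator produces the three observation streams with known truth:
sinusoidal seasonal + diurnal weather with Gaussian noise (temperature
warmest mid-January; solar radiation zero in the polar winter; wind
truncated at 0; humidity clipped to [0, 100] %), counts from the occupancy
curve (or an agent-oracle realisation) with lognormal noise, and areas by
inverting the windchill model, A = N/ρ, skipping dates where ρ falls below
10⁻³ animals/m². Presets mirror the two best-studied colony regimes: a
"PG-like" season (t₀ = 97, BP = 3900, H = 0.85, F = 0.70, trips
12 → 8 d at sea, 3 → 1.5 d at colony, female absence chosen so the return
date matches the local first sunrise + 27.4 d) and an "AB-like" season
(t₀ = 117, BP = 8600, correspondingly longer absence). Default noise is
10 % lognormal on counts.

What the generator does *not* emulate: weather autocorrelation and storms,
density dependence of trip durations on sea-ice distance, inter-annual
carry-over, observation biases of real imagery (off-nadir geometry, snow
cover, mixed pixels), or chick visibility ramping up gradually after
emancipation. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not field
accuracy.

## Numerical choices

* Sunrise: a day has a sunrise when the sun's centre clears the geometric
  horizon at local solar noon (altitude > 0°, longitude/15 h time shift,
  low-precision Fourier declination clipped to ±23.45°). Inside the polar
  circle the noon sun skims the horizon, so refraction conventions move the
  first-sunrise date by several days; the geometric convention reproduces
  the documented dates at both reference colonies (day-of-year 180 and 209
  in 2018) within a day, which is the precision the anchoring rule needs.
* Emcee is seeded by assigning a `RandomState` state tuple; a bare integer
  or generator is silently ignored by emcee's setter.
* Densities/counts are floored at 10⁻⁶ before logs; negative-count
  undershoot from summed CDFs is clipped at 0.
* Degenerate inputs: constant weather columns trigger a non-identifiability
  warning; fewer than 20 windchill pairs or 5 count points are refused;
  empty input streams raise errors naming the missing stream.
* Reduced-chain settings used in the test suite (e.g. 32 walkers, a few
  hundred steps) are smoke-test configurations; the full-mode recovery
  check uses 6000 burn-in steps, after which the posterior means are
  stable to well within their standard errors across sampler seeds.

## Known limitations

* One season, one colony per fit; no hierarchical sharing across years.
* The windchill parameters are assumed constant within a season, ignoring
  body-condition drift (fat loss during incubation changes the huddling
  response).
* The 27.4-day sunrise offset and the satellite-mode defaults are
  empirical constants; both are exposed as configuration.
* F from adults-only full fits is ridge-limited (see Identifiability);
  report its credible interval, not just the mean.
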