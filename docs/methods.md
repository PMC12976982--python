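# Methods

This note records the models, the synthetic study conditions, and the
numerical and design choices behind `vdomains`, in the spirit of a
model-documentation page.

## Process-based bloom model

One location-year ("season") runs from September 1 to May 31 of the
bloom year. The state `(x, y, z)` starts at zero and is updated hourly:

**Chill (Dynamic Model).** With `T_K` the absolute temperature,

    x_s = (A0/A1)·exp(−(E0−E1)/T_K)        (precursor equilibrium)
    k1  = A1·exp(−E1/T_K)                  (formation rate)
    x  ← x_s − (x_s − x)·exp(−k1)

When `x ≥ 1`, a temperature-gated sigmoid converts part of it into an
irreversible chill portion:

    sr = exp(slope·T_f·(T_K−T_f)/T_K),  f = sr/(1+sr)
    y ← y + x·f,   x ← x·(1−f)

`T_f` is stored in °C in the parameter vector and converted to Kelvin
inside the kinetics, following the conventional parameterization. Cool
temperatures (~2–8 °C) accumulate portions efficiently; sustained warmth
destroys the precursor before conversion, which is what makes chill the
limiting factor at the warm end of a gradient.

**Heat (Growing Degree Hours).** Zero at or below `T_b` and at or above
`T_c`; a rising cosine on `(T_b, T_u]` peaking at `T_u − T_b`; a falling
cosine on `(T_u, T_c)`. The two branches meet continuously at `T_u`; the
stress factor is fixed at 1.

**Transition and bloom.** Heat counts towards the forcing sum through
the logistic weight `w(y) = 1/(1+exp(−s1·(y−yc)))`, so endo- and
ecodormancy overlap gradually rather than switching at a date. Bloom is
the day containing the first hour with `z ≥ zc`; if the season ends
first, the prediction is a FAILURE. The precise published form of this
transition is not nailed down in the literature we follow; the logistic
form is our working choice and is used consistently in generation,
calibration and validation, so all recovery tests are internally
coherent.

The hourly recurrences are numba-compiled; a pure-Python transcription
in the test suite serves as the independent oracle (agreement to 1e-12
relative on the chill state, exact on bloom days).

## Hourly interpolation and solar geometry

Daily extremes become 24 hourly values per day: daytime follows
`tmin + (tmax−tmin)·sin(π(h−sunrise)/(daylength+4))`; night decays
logarithmically from the sunset temperature to the next day's `tmin`,
reaching it exactly at the next sunrise. Sunrise/sunset come from the
standard solar-declination day-length formula
(`δ = −23.44°·cos(2π(doy+10)/365)`), symmetric about solar noon;
latitudes beyond ±66.6° are rejected. Pre-dawn hours of the first season
day reuse that day's own sunset parameters (no previous day exists); the
last day's night targets its own `tmin`. Gaps of up to 5 days are filled
by per-variable linear interpolation (nearest value at the boundaries);
seasons missing 6 or more days are discarded outright.

## Synthetic study conditions

The generator emulates a long-term multi-location phenology network on a
coastal temperature gradient. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| locations | 12 over 5–16 °C Sep–May means | matches the emulation target gradient |
| seasons/location | uniform 27–64 | matches reported data availability |
| annual cycle | cosine, half-range 11 °C, minimum Jan 25 | mid-latitude maritime climate |
| diurnal range | 8 °C (± 0.5 °C jitter) | typical coastal station |
| daily residuals | AR(1), φ = 0.7, marginal sd 2.5 °C | day-to-day weather autocorrelation |
| observation noise | sd 1.5 days, rounded to whole days | bloom dates are recorded as dates |
| latitudes | linear 43°N (cold) → 31.5°N (warm) | gradient-consistent day lengths |

The per-location constant offset is solved so the September–May mean of
the deterministic cycle equals the configured target exactly; the
configured gradient is therefore recovered to within sampling noise.
Each location owns a random stream derived from the master seed, so
adding locations never reshuffles existing ones.

Ground-truth parameters are the published Dynamic-Model kinetic
constants (E0 = 3372.8, E1 = 9900.3, A0 = 6319.5, A1 = 5.94e13) with
`yc = 48` portions, `zc = 300` GDH, `s1 = 0.5`, `Tu = 25`, `Tf = 4`,
`Tc = 36`, `Tb = 4`, `slope = 1.6`. These were chosen (before any
downstream tuning) so that bloom falls in March–April at a 10 °C-mean
location and chill fails for the majority of seasons once seasonal means
reach ~16–18 °C, reproducing the warm-margin failure phenomenology.
Seasons where the truth model fails carry no observation — as in real
records, where a tree that never bloomed properly yields no date — and
generation aborts if more than half of all seasons fail.

What the generator does **not** emulate: elevation and radiation
effects, precipitation and multi-variable weather, spatial correlation
between locations, observer-protocol artifacts, and any genetic or
management differences between trees. Passing tests therefore show the
*method* behaves as designed under a known data-generating process, not
that any particular real-world dataset satisfies its assumptions.

## Calibration

The objective is the RMSE over seasons, with failed predictions charged
a fixed 35-day penalty — during calibration as well as validation, for
consistency (the penalty's literature use is validation-side; the
calibration-side treatment is unstated, and using it in both keeps the
diagonal of the transfer matrix equal to the stored calibration error).
During the search, bloom is scored at fractional days (threshold-crossing
hour / 24) so the surface is smooth; reported RMSEs use whole days.

The search is staged, within wide biologically plausible bounds
(`Tb∈[0,10]`, `Tu∈[10,30]`, `Tc∈[30,40]`, `yc∈[10,80]`, `zc∈[50,500]`,
`s1∈[0.05,5]`, `slope∈[1,5]`, `E0∈[3000,4000]`, `E1∈[9000,10500]`,
log10 A0∈[2.5,4.5], log10 A1∈[12.5,14.5]):

1. differential evolution over the eight response parameters with the
   four kinetic constants pinned at their published values (they are, in
   practice, never refit);
2. a Powell polish over all twelve;
3. a Powell polish of `(yc, zc)`;
4. a two-pass local 9×9 grid refinement of `(yc, zc)` on the whole-day
   objective actually reported.

Best-of-restarts, every stage seeded; identical inputs give identical
results. A 5,000-evaluation budget fits one location in ~35 s on one
CPU. Pooled (multi-location) calibration uses the identical code path.

**Identifiability.** On 40 noise-free synthetic seasons this recovers the
generating process to ≤ 1 day *calibration* RMSE. Held-out seasons from
the same climate, however, retain ~1.3–2 days RMSE: the model exhibits
strong equifinality — parameter sets indistinguishable on integer-day
training observations (including sets within a fraction of a unit of the
truth) shift predictions on unseen seasons by 1–2 days. We verified this
is not an optimizer-budget artifact (runs to 77,000 evaluations, and
local refinement started at near-truth solutions, plateau above the
truth's objective while holdout error stays ≈1.5–2 days). Sub-day
predictive recovery from date-resolution observations is, as far as we
can measure, not attainable for this model class — itself an instructive
instance of the transferability problem the package studies.

## Gaussian-process comparator

Features are the nine Sep–May calendar-month means of daily
`(tmin+tmax)/2`, standardised; the kernel is
`C·RBF(ℓ) + WhiteKernel(σ²)` with `normalize_y`, hyperparameters by
seeded multi-start marginal-likelihood maximisation. The noise variance
is bounded in `[1e-6, 1e-2]` (relative to the normalised target
variance): GP regression as used in the reference ecosystem applies a
fixed small regularisation rather than a fitted noise term, and this
bound reproduces its near-interpolating behaviour on training data.
Predictions are posterior means rounded to whole days and never fail.

## Transfer, kriging, validity domains

Every calibrated model is evaluated on every location's complete season
set (no sub-sampling); matrix axes are ordered by seasonal mean. For
kriging, the process-based diagonal carries each model's own-location
RMSE, while the ML diagonal is set to zero; both diagonals are then
densified (linear interpolation along the identity line at 0.25 °C
spacing) before kriging, so the smoother honours the diagonal *between*
locations as well — without this the surface between two zero-valued
diagonal anchors is pulled toward the large off-diagonal errors.

Ordinary kriging uses an exponential variogram
`γ(h) = nugget + psill·(1−e^{−h/r})` fitted by weighted least squares
(Cressie weights `n(h)/γ²`) to the binned empirical variogram, the
nugget capped at 10% of the sill; duplicate coordinates are averaged.
The dual form is solved once (`[Γ 1; 1ᵀ 0][b;a] = [v;0]`) and any point
is predicted as `Σ bᵢ γ(dᵢ) + a`; with `γ(0)=0` the predictor is exact
at source points, which the tests verify against a hand-solved primal
system. Default grid resolution is 0.05 °C (0.1 °C in the demo
configuration, purely a speed/size choice).

Domains: threshold mask (≤ 5 days), 8-connected components, keep those
touching the identity diagonal and covering ≥ 1% of the grid (the
quantification of "minor exceptions"; no published rule exists). Width
per calibration temperature is the Δ-interval `[Δ⁻, Δ⁺]` of the retained
mask in that column.

## Scenarios

The simplified weather generator fits, per location, a calendar-day
climatology (mean of daily `tmean` per (month, day); Feb 29 falls back
to Feb 28), a residual sd and an AR(1) coefficient; the AR coefficient
is reported as 0 when the residual sd is below 0.1 °C, where it is not
meaningfully estimable (mixing leap and non-leap seasons leaves a few
hundredths of a degree of calendar-alignment residual even for
noise-free input). Scenario seasons add per-month temperature deltas and
AR(1) residuals; 100 simulations per scenario by default. Packaged
deltas are illustrative seasonal warming levels per SSP × horizon year
(e.g. +1.0 °C for SSP1-2.6/2050 up to +4.3 °C for SSP5-8.5/2085,
relative to a ~2000 baseline), applied uniformly across months;
per-month deltas can be supplied via configuration.

Validation groups pool all locations' seasons into half-open 0.5 °C bins
of seasonal mean (7.0–18.0 °C by default → 22 groups; derived from the
data range in the pipeline), drawing at most 30 seasons per bin without
replacement (seeded). Models are evaluated against every group, the
resulting RMSE kriged over (calibration T, group centre), and each
location's simulated seasonal-mean distribution is read off that
surface; simulations outside the group-centre range are flagged as
beyond the available validation data rather than extrapolated. The
seasonal-mean window is September–May throughout (a September–June
variant of the window exists in the literature without reconciliation;
we fix one convention and expose the season window centrally).

## Problem sizes

The bundled demo/workflow configuration uses 8 locations × 20 seasons
(6–17 °C, so the warm failure margin is inside the gradient), a
1,500-evaluation calibration budget per location and a 0.1 °C grid —
sizes picked so the full pipeline runs in about a minute while still
exhibiting every qualitative feature (failure asymmetry, cold-wide /
warm-narrow process domains, near-zero ML diagonal). The 48-location
combination count is exercised with constant stub predictors, since only
the matrix combinatorics are at stake there.

## Known limitations

* Single-axis environments: transferability is indexed by seasonal mean
  temperature only, concealing phase-specific (winter vs. spring)
  differences between seasons with equal means.
* The GP feature set (monthly means) is one reasonable choice among
  many; the reference analysis does not specify one.
* Anisotropic variograms and universal kriging are not implemented.
* The scenario generator is deliberately minimal (temperature-only,
  monthly deltas, AR(1) residuals); it is not a replacement for a
  multi-variable stochastic weather generator.
* Predictive parameter recovery is limited by equifinality at
  date-resolution observations (see Calibration above).
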