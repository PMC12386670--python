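# Methods

## Model overview

`slfrisk` predicts the seasonal development (phenology) and the
climate-limited potential distribution of the spotted lanternfly
(*Lycorma delicatula*), an invasive planthopper that overwinters as an
egg and completes one generation per year. Two linked submodels run on
daily minimum/maximum temperature rasters:

1. a **cohort-structured linear degree-day model** that steps each
   raster cell through the life cycle and records the day of year
   (DOY) of five phenological events — egg hatch, nymphs halfway
   developed, adult emergence, oviposition, and diapausing egg; and
2. a **climatic-suitability model** that accumulates cold and heat
   stress units and excludes cells whose annual accumulation exceeds
   moderate or severe limits.

Linear degree-days were chosen deliberately: the development-rate data
for this species are well fitted by straight lines over the relevant
temperature range, and daily Tmin/Tmax is the finest temporal
resolution available from high-quality gridded climate sources.

## Degree-days and stress units

A day's temperature trace is approximated as a triangle rising from
Tmin to Tmax and falling back over one day. Degree-days are the area
of the trace above the lower developmental threshold (LDT), with
temperatures above the upper threshold (UDT) substituted by the UDT
(horizontal cutoff). Writing s = Tmax − Tmin, the area above a level
θ is

- 0 if Tmax ≤ θ,
- (Tmin + Tmax)/2 − θ if Tmin ≥ θ,
- (Tmax − θ)² / (2s) otherwise,

and DD = area(LDT) − area(UDT), so 0 ≤ DD ≤ UDT − LDT always. A zero
diurnal range degenerates to constant temperature (DD = T − LDT,
clipped). Cold stress units are the area *below* the cold threshold
(computed via the reflection T → −T); heat stress units the area above
the heat threshold, with no second cutoff. The same triangular
geometry is used for development and stress for internal consistency;
the closed forms agree with 1-minute numeric integration of the
triangular wave to better than 10⁻⁵ °C·d (tests assert < 0.05).
Accumulation is date-ascending in double precision, so annual totals
are bitwise reproducible.

## Species parameters

All stages share LDT = 10 °C and UDT = 35 °C. Stage durations
(°C·days): overwintered egg per cohort (below), nymphal instars 1–4
("larva") 890, pre-oviposition adult ("pupa") 630, first-to-50%
oviposition ("adult") 146, first-generation egg 202, with egg-to-adult
= 202 + 890 = 1092. Event triggers within a stage: nymphs halfway at
442 DD of the larval stage, adult emergence and oviposition at 1 DD of
the pupal and adult stages (i.e. effectively at stage entry), and the
diapausing-egg event at 100 DD of the first-generation egg stage.
Cold stress: threshold −16 °C, moderate/severe limits 300/475 units.
Heat stress: threshold 37 °C, limits 115/175 units. Parameter files
are flat `key = value` text using the standard short codes
(`eggLDT`, `larvaeDD`, `distro_mean`, …).

## Cohorts

Within-population variation in overwintered-egg development is modelled
by seven cohorts. The degree-days required to complete egg development
follow a normal distribution with mean 190 and variance 15 000 °C·d²,
truncated to [135, 360]. The discretisation — the distribution's shape,
bounds, and cohort count are given; the binning rule is this package's
choice — splits the truncated range into equal-width bins, assigns each
cohort the bin midpoint as its hatch requirement, and weights it by the
bin's normal probability mass renormalised over the truncated range.
With the defaults the first requirement is 135 + (225/7)/2 ≈ 151.07
°C·d, which fixes the closed-form test value of hatch on day 11 under a
constant 25 °C year (15 DD/day). Cohorts are independent: no density
effects, no interaction.

## Life-cycle stepping

The year starts on 1 January with all cohorts in the overwintered-egg
stage. Each day a cohort accumulates DD with its current stage's
thresholds; the overwintered egg completes when cumulative DD reach the
cohort requirement (the egg-hatch event), then larval, pupal, and adult
stages complete at their durations, and the first-generation egg halts
at the diapausing-egg event (obligate diapause — a chilling requirement
prevents further development within the model year). Excess DD on a
transition day carry into the next stage, and the carry is cascaded:
a carry that already crosses the next stage's trigger (relevant for the
1-DD pupal/adult triggers) fires the event the same day. Events that
never trigger by 31 December are nodata ("insufficient accumulation").
Leap years use 366 days; DOY is 1-based throughout. Any cell missing
climate on any day is excluded from all outputs — the simplest
defensible nodata contract.

Per-event, per-cohort DOY rasters are collapsed to an
**earliest** (minimum over cohorts) or **weighted-mean** ("peak",
cohort-weighted over cohorts in which the event occurred, weights
renormalised) map.

## Climatic suitability

Stress units accumulate over the calendar year with no decay and no
recovery. Classification is: none for units ≤ max1, moderate for
max1 < units ≤ max2, severe above max2 — a total exactly equal to a
limit stays in the lower class ("exceed" is read strictly, for
determinacy). The combined category is the worse of cold and heat;
cells with combined category "none" form the year's potential
distribution, and the multi-year product counts, per cell, the years a
cell is included. Exclusion categories are presentation overlays on the
event maps; they do not kill cohorts mid-simulation. Weekly extreme
summaries (coldest-week Tmin, hottest-week Tmax) use rolling 7-day
windows at every alignment rather than calendar weeks, since an extreme
over rolling windows bounds any calendar-week value.

## Calibration procedures

- **x-intercept method**: ordinary least squares of development rate
  (1/days) on temperature; the lower threshold is the fitted line's
  x-intercept −a/b and the stage duration the reciprocal slope 1/b.
  A non-positive slope or a single temperature is an error. On
  noise-free collinear data the generating threshold and duration are
  recovered to numerical precision.
- **Cohort grid search**: candidate (xdist1, distro_mean, xdist2)
  triples (variance fixed at 15 000) are scored against observed
  earliest and peak hatch DOYs by running the engine at each
  observation site-year; a prediction later than the observation is an
  overprediction. Candidates are ranked by fewest overpredictions,
  ties broken by MAE and then |bias| (the tie-break order is this
  package's definition; the primary criterion is the method's).

## Validation machinery

First-date monitoring records are paired with the mapped event at the
nearest cell (no interpolation — cells are the model's native
resolution): egg hatch ↔ first nymphs, nymphs halfway ↔ late nymphs
(third/fourth instars), adult emergence ↔ adults, oviposition ↔ first
oviposition. Differences are pred − obs days; MAE, bias, SD and range
are reported with an OLS regression of predicted on observed and the
mean lengths of the pointwise 95% confidence and prediction intervals.

Single-encounter records only bound the event date, so they are tested
one-sidedly with a paired Wilcoxon signed-rank test: first appearances
should be predicted no later than an encounter (pred < obs), while for
overwintered eggs the *last* predicted hatch (latest cohort) should
fall after the observation (pred > obs). Zero differences are dropped;
with untied magnitudes and n ≤ 25 the exact null distribution of the
positive-rank sum is computed by the generating-polynomial recursion,
otherwise a normal approximation with continuity and tie (midrank)
corrections is used. Stage concordance compares the model's stage on
the encounter date — the cohort-weighted modal stage by default, the
earliest cohort optionally — against the observed stage in the order
OW egg < early nymph < late nymph < adult < G1 egg, splitting early
from late nymphs at the 442-DD halfway point; both the pre-oviposition
and ovipositing model stages present as "adult". A "31 June" cutoff
sometimes seen in OW/G1 egg categorisations is treated as 30 June
(calendar impossibility).

## Synthetic climate

The generator emulates a temperate continental gradient: daily mean
temperature = base − lapse·(lat − lat_ref) + amplitude·cos(2π(doy −
peak)/365) + Gaussian noise, with Tmin/Tmax half the diurnal range
below/above the mean. Defaults: 20×20 cells over 30–50 °N, base 18 °C
at the southern edge, lapse 0.8 °C per degree latitude, amplitude
12 °C, diurnal range 10 °C, noise SD 1.5 °C, peak DOY 196 (mid-July) —
values a mid-latitude eastern-North-America station record would make
familiar. It reproduces the features the model is sensitive to
(seasonal cycle, latitudinal gradient, diurnal range, day-to-day
noise) but not spatial autocorrelation of weather systems, elevation,
coastal effects, or Tmin/Tmax asymmetries; passing tests therefore
demonstrate correctness of the model mechanics, not predictive skill
on real landscapes. Fixed seeds make every grid bit-for-bit
reproducible.

## Numerical choices and degenerate inputs

- Events trigger on the first day the accumulator *reaches* the
  trigger (≥, ties at exact equality fire that day).
- tmax < tmin cells are masked to nodata with a logged count rather
  than erroring, since inverted pairs occur in real gridded products.
- Block aggregation averages the valid cells of each block; ragged
  edges are padded with nodata and the extent extended to whole
  blocks.
- distro_mean (190) is deliberately distinct from eggDD (202): the
  cohort requirement governs the overwintered egg, eggDD the
  first-generation egg.
- All rasters are float32 on disk (GeoTIFF via tifffile, EPSG:4326
  tags) with −9999 as nodata; double precision in memory.

## Problem sizes

Test and acceptance runs use 20×20-cell synthetic grids and 1–3 year
spans, which exercise every code path (gradients steep enough to span
hatch-to-no-adult regimes, stress on both sides of both limits) while
keeping full runs to seconds. The engine is vectorised over cells, so
larger rasters scale linearly in cells × days × cohorts; trajectories
(per-day stage states) are the memory-heavy product and can be
disabled (`keep_trajectory=False`) for mapping-only runs.

## Known limitations

- No host-plant, photoperiod, or chilling-requirement effects on
  development; diapause termination is implicit in the 1 January
  start.
- One generation per year by construction.
- No moisture or precipitation suitability factors; no acclimation,
  recovery, or body-size effects on stress tolerance.
- Only EPSG:4326 north-up grids; observations are matched by nearest
  cell, not interpolated.
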