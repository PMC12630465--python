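# Methods

This note documents the quantities the package computes, the assumptions and
numerical choices behind them, and what the synthetic generator does and does
not emulate.

## Scope and data model

The unit of analysis is one model/site run: an annual stand-level table
(woody carbon pool `Cwood` and its aboveground part `Cwood_AG`, kgC m⁻²;
woody growth `WBgrowth` and mortality `Cmort` fluxes, kgC m⁻² yr⁻¹; stem
density `nstem`, stems ha⁻¹; canopy area `CA`, m² ha⁻¹; crown area index
`CAI`; per-PFT shares of vegetation carbon) plus an optional size-structured
table (`nstem_size`, `cwood_size` per dbh class). Units are fixed in storage;
the 10⁴ m² ha⁻¹ factor appears only inside computations that mix the per-m²
and per-ha bases. The dbh scheme is fixed at 16 half-open classes with upper
edges 1, 5, 10, 15, 20, 30, …, 100, 150, 200 cm and an open top class;
labels are literal ("<15" means [10, 15) cm, "≥200" is closed below).

## Budget closure

A demographic run is internally consistent when the annual stock change
equals the net woody flux:

    residual(t) = Cwood(t+1) − Cwood(t) − (WBgrowth(t) − Cmort(t))

The verdict compares `max |residual| / max Cwood` against a relative
tolerance: 10⁻⁶ by default (generated data must close to rounding error),
with 10⁻² suggested for external model archives, where percent-level drift
from recruitment bookkeeping is common. Where a model separates recruitment
carbon inputs from growth, the reader must fold them into `WBgrowth`;
harvest or disturbance export terms are out of scope.

## Rates and smoothing

The fractional mortality rate is `cmort_rate = 100 · Cmort / Cwood`
(% yr⁻¹) and the woody turnover time `τ = Cwood / Cmort` (yr); the two are
reciprocal (`τ · cmort_rate = 100`), which the tests assert on every
fixture. Years with `Cwood = 0` are flagged undefined rather than dropped;
`Cmort = 0` yields an explicitly infinite τ that summary statistics exclude
with a logged count — never a large stand-in number.

For time-series work the rates are smoothed with a *left-aligned* 30-yr
rolling mean (`out[t] = mean(v[t..t+29])`, incomplete windows dropped, so n
years shrink to n − 29). Thirty years matches the repeated 30-yr climate
cycle such simulations are typically forced with, so the smoothing removes
forcing artefacts rather than dynamics; the first 30 years after spin-up
are excluded beforehand. Mature-forest comparisons use unsmoothed annual
values over an explicit equilibrium window, because the interannual spread
is itself the quantity compared against spatial variability in plots.

## Self-thinning

Mass–density points are built per year as `N = Σ nstem_size` and
`M = Σ cwood_size · 10⁴ / N` (kgC per tree) over the dbh classes with lower
edge ≥ 10 cm. The exclusion keeps suppressed saplings and fresh recruits —
which are not part of the thinning cohort — from dragging the mean
individual mass. When no size structure exists the stand totals are used
and the deviation is recorded on the result. The per-ha basis means the
intercept k is reported in kgC · (stems ha⁻¹)⁻ᵖ; the slope is basis- and
unit-invariant (asserted under log-base change and kgC→gC rescaling).

Four period-detection methods are provided. Methods 1 and 2 threshold a
rate series at its 95th percentile (linear-interpolation percentile, R
type 7, matching the convention of the usual analysis environment for such
data) and select *strictly* exceeding years; method 1 uses a dedicated
self-thinning mortality diagnostic where a model outputs one, method 2 the
total mortality rate. Method 3 selects the consecutive run of years
spanning the maximum density decline — formally, the run [i..j] maximising
`lnN(i) − lnN(j)` over i < j, ties resolved to the earliest start and then
the longest run. This operationalises "the consecutive points between the
maximum and minimum densities"; the alternative geometric reading (corner
points of the cloud in thinning space) is ambiguous without a plot
orientation and was not adopted. Method 4 is a literal, manually chosen
range, recorded as such, and always wins when supplied.

The slope is fitted by OLS of lnM on lnN (statsmodels), requiring ≥ 3
points with non-degenerate density variance, and flagged against the band
[−2.612, −1] — the steepest exponent observed in managed-stand compilations
and the theoretically shallowest one; the classical reference value −3/2
lies between. Bounds are inclusive with 10⁻⁹ numeric slack.

## Recovery phases

The four-phase classification (grass coexistence → open-canopy growth →
closed-canopy self-thinning → late-successional) is inherently qualitative;
the classifier makes it operational with configurable thresholds:

* grass share ≥ 0.10 of C_veg keeps the stand in grass coexistence;
* canopy closure at CA ≥ 10 000 m² ha⁻¹ (crowns covering the ground once
  over — the only threshold with a conventional value; CAI ≥ 1 substitutes
  when CA is absent);
* a mortality spike is ≥ 1.5× the run's own equilibrium rate, defined as
  the mean `cmort_rate` over the final 100 years; the stand has returned to
  equilibrium when the rate re-enters ±50% of that reference;
* stem-number decline/flattening is judged on 5-yr centred rolling means
  compared 4 years apart, with a 5% flatness tolerance (≈ 1.25%/yr).

Implementation choices that matter for robustness: CA and grass share are
smoothed with a 3-yr centred mean before thresholding; the trend window is
shifted (not shrunk) at the record edges so it keeps its full span; in the
first trend window the decline requirement is waived, because no backward
baseline exists and a run that begins mid-thinning shows its spike
immediately; and thinning is required *in addition to* closure (not closure
alone), which accommodates canopy schemes where an understorey forms and
thinning is not initiated at closure. The classifier is a forward-only
state machine — backward proposals (e.g. a noisy canopy dip) are
forward-filled and logged — and an open-canopy state may not jump straight
to late-successional while a mortality spike still lies ahead. The
late-successional onset is judged on rate stabilisation only; a
composition shift in the PFT shares is auxiliary evidence, not a
requirement.

The start group is a pure function of the first label: P1 = grass
coexistence, P2 = open-canopy growth, P3 = closed-canopy thinning; a run
that begins late-successional has no recovery trajectory and is an error.
Alignment shifts each run so a common phase onset sits at year 0 and
reports the shift; runs lacking the anchor phase are excluded with a log
entry.

## Envelopes and scoring

Chronosequence envelopes use half-open 20-yr age bins, median with
10th/90th percentile bounds, and drop bins with fewer than 20 records — an
occupancy rule that keeps thinly observed ages from masquerading as
constraints. The spatial bootstrap places square subplots (default 6.25 ha)
uniformly at random, fully contained in the plot (no tiling, no wrap:
placement schemes are rarely reported for such data, and random placement
is the least structured choice), with 1000 draws and a central 95% interval
by default. Small plot sets use cellwise min–max. Model runs map onto age
bins as the mean of annual values within each bin; scoring is inside/below/
above with inclusive bounds and signed distances.

## The synthetic generator

`simulate_stand` prescribes a single even-aged woody cohort through the
four phases and *derives* the fluxes from the stock trajectory, so budget
closure is exact by construction rather than approximate. Stem density is
constant before the thinning window (or saturating, for emergent
establishment), declines geometrically inside it (default: to 20% of the
initial 2000 stems ha⁻¹), and is constant after. Mean individual mass
follows allometric growth `M = a·dbhᵇ` (a = 0.15 kgC, b = 2.4; 5%/yr
relative dbh growth from a 1 cm sapling) before the window and the power
law `M_ag = k·Nᵖ` inside it, with k fixed by continuity at the window
start. Mortality is the carbon of the thinned stems plus a background
fraction (1.5%/yr of Cwood); growth is whatever closes the budget. Canopy
area ramps linearly to cross 10 000 m² ha⁻¹ exactly at the scripted closure
year and saturates at 10 800; the grass share decays exponentially with a
timescale derived from the scripted first boundary (crossing the 10% share
half a year before it), unless set explicitly. The default run is 420 yr
with boundaries (12, 48, 130) and p = −3/2; a restocked high-density run
with closure at year 0 realises the P3 (immediate-thinning) start, and a
grassless script with closure at year 48 the P2 start.

Noise is multiplicative lognormal on *observational copies only*: stem
density, canopy area, the aboveground pool, the size structure and the PFT
shares. The conserved pool/flux columns stay noise-free so the budget check
has a clean pass case, and one factor per year is shared between a
stand-level column and its size-structure counterpart, so the structure
totals stay exactly consistent even under noise.

What the generator does *not* emulate — and what passing tests therefore do
not show about real models: no physiology (no photosynthesis, allocation or
climate response), a single cohort rather than a size distribution (the
size structure has one occupied class per year), no multi-patch landscape,
no harvest or disturbance exports, no PFT succession beyond a grass/woody
share, and noise that is serially independent, unlike real climate-driven
variability. Ground-truth recovery on these runs demonstrates the
correctness of the diagnostics, not the realism of any model.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
420-yr single-cohort runs (about 50 of them for phase-recovery checks),
200-seed Monte Carlo for the noisy slope bias, 1000 short random series for
the smoothing and percentile oracles, and a 140-yr full-span thinning run
for the reference-slope recoveries. These sizes give the statistics room to
bind (e.g. 2 standard errors on Monte Carlo means) while keeping the whole
suite in the seconds-to-a-minute range on one CPU.
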