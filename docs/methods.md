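# Methods

`luxtrack` reconstructs animal positions from archival light-logger
(geolocator) records.  This note describes the model the package implements,
the choices made where the design was genuinely open, and what the simulated
validation does and does not demonstrate.

## The observation model

A tag at position **α** observes, during twilight *i*, light readings at
times τ_ij.  The geometric solar elevation θ_ij = θ(**α**, τ_ij) is computed
with a Meeus-style low-precision ephemeris (declination, equation of centre,
apparent-longitude nutation term; elevation accurate to well under 0.1°,
verified against an independently coded Astronomical Almanac algorithm and a
published high-precision reference point).  No atmospheric refraction is
applied: the irradiance template below is a function of geometric solar
angle, and refraction variability is absorbed into the observation noise.

Surface irradiance during twilight follows a fixed template

    f''(θ) = −u² − log erfc(u),   u = 21.5 · sin θ,

evaluated through the scaled complementary error function as
f'' = −log erfcx(u), which is finite and well conditioned over the whole
domain (erfc itself underflows near u ≈ 21.5).  A tag reads light linearly
on the log scale,

    log(reading)_ij = a_i + Z_i · f''(θ_ij) + ε_ij,   ε_ij ~ N(0, σ_err),

where the per-twilight intercept a_i lumps the tag offset with that
twilight's attenuation (cloud, vegetation, posture — multiplicative in
light, hence additive in logs) and Z_i is the tag's slope.  Attenuation and
offset are not separately identifiable and never need to be: position
information is carried by the slope against the known curve.  Slopes vary
twilight-to-twilight around a tag-specific lognormal,
Z_i ~ logNormal(meanlog_Z, sdlog_Z), estimated by calibration at a known
site; σ_err is the pooled residual SD.

### Quantized, doubly clipped readings

Device readings are integers clipped to [0, 64].  A stored value ℓ ∈ 1..63
therefore means the underlying log reading lies in
[log(ℓ−½), log(ℓ+½)]; a 64 means it lies above log 63.5; a 0 below
log 0.5.  Ordinary least squares on log ℓ is biased toward flat slopes: at
the clipped ends, which samples survive is a function of the noisy response
itself, and the bias varies with season and latitude because twilight
geometry changes the mix of clipped and interior samples.  In testing, that
seasonal bias displaced a calibrated-in-July tag's posterior latitude by up
to ~1.4° in other months.

The fits here therefore maximize the exact interval likelihood: every
sample contributes P(y ∈ its interval), with dark records treated as
left-censored and saturated records as right-censored.  Because samples are
independent and each interval probability is exact, no selection effect
remains.  The optimum is found by Fisher scoring — per-sample scores of the
interval probability, information from Louis' identity (complete
information 1/σ² minus the conditional variance of the missing reading) —
which converges in a handful of iterations and vectorizes over all grid
nodes at once.  Slope standard errors come from the inverse
observed-information matrix.  Calibration fits profile σ alongside
(EM-style second-moment update) and rescale the profiled σ by the
information-weighted effective sample count with the usual two-parameter
degrees-of-freedom correction — censored samples carry only a fraction of a
sample's worth of information, so the uncorrected profile estimate runs
several percent low.  The per-node fits inside the likelihood pin σ at the
calibrated σ_err.

### Twilight windows

Threshold crossings of the light series (default level 32, the mid-scale of
a 0–64 tag; low levels are never crossed at high latitudes around
midsummer) are located by linear interpolation, with short spurious
excursions cancelled in pairs.  Each event's measurement window (default
±240 min) is clipped at the twilight-period boundaries — solar noon and
midnight, where the attenuation intercept redraws — estimated directly from
the light curve as midpoints of the smoothed diel extrema plateaus.  This
stays valid when whole twilights go undetected (bright high-latitude
nights) and when shading shifts the two crossings of a night
asymmetrically.  Clipped records within ±90 min of the anchor are retained
as censored observations; dark records far from the twilight carry no
information and are dropped.

## The spatial likelihood

The state space is a quasi-regular grid of nodes ~50 km apart (equal-area
latitude bands) within a radius of the release point.  For twilight *i* and
node *k*, the interval fit yields (Ẑ_ik, σ_ik); the node's likelihood is
the overlap integral of the calibrated slope prior with that estimate,

    L_ik = ∫₀^∞ logN(Z; meanlog_Z, sdlog_Z) · N(Z; Ẑ_ik, σ_ik) dZ,

by 201-point trapezoid quadrature on a window centred on the
precision-weighted product of the two densities (the integrand decays fast,
so the fixed rule is accurate to better than 1e-6 relative — tested against
a dense oracle).  Failed fits get zero raw likelihood; the surface is then
floored at 1e-6 of its maximum (no node is ever exactly impossible, which
would let one bad twilight extinguish the particle filter) and normalized.

A single twilight constrains position only along a broad ridge aligned with
the terminator; localization comes from accumulating surfaces through the
movement model.

## The movement model

Two behavioural states per twilight-to-twilight interval: sedentary (stay,
probability 1−p) or migrating (probability p), with migratory displacement
drawn as a von Mises direction (uniform by default) and truncated-normal
step length S ~ truncN(μ, σ, a, b); defaults p = 0.1, μ = 300 km,
σ = 150 km, a = 45 km, b = 1500 km, all configurable (per time window if
needed).  Steps are uncorrelated in time.  Proposed destinations snap to
the nearest usable node; draws snapping back to the origin or falling
outside every node's cell (off the study region) are redrawn, so the walk
is exactly a Markov chain on the grid.  The matching cell-to-cell
transition matrix — truncated-normal × von Mises planar density
p_S(d)·p_Φ/d per equal-area cell, renormalized — is exact on small grids
and serves as the particle filter's oracle (one-step total-variation gap of
the sampler ~0.003).

A behavioural mask may forbid the sedentary state on specified nodes
(e.g. open water): particles may transit but any particle that *stays* on a
masked node gets zero weight.  A hard spatial mask removes nodes entirely.

## Filtering

Sequential importance resampling over twilights with 10⁶ particles by
default (the validation studies use 2×10⁴, which the oracle comparison
shows is already well converged on these grid sizes).  Per twilight:
propose movements, weight by the twilight's surface (skipped for screened
twilights), apply the behavioural mask, resample systematically.  To fight
weight degeneracy on year-long runs, the resampling weight is
exp(mean of the particle's per-step log weights over the last 90 steps)
("block" weighting, window carried along ancestry).  Positions 90 steps
behind the frontier are treated as final; per-twilight posteriors are these
fixed-lag smoothed marginals, and per-twilight transition summaries
(migration probability, distance quartiles) come from the same snapshots.
With a window of 1 the scheme reduces to a plain bootstrap filter whose
filtering marginals converge to the exact forward recursion — the
equivalence test in the suite.

If the recapture position is known (archival tags must be physically
recovered), the final 90 states are resampled with Gaussian weights on
great-circle distance to it (SD 25 km, half the node spacing).  The
validation runs use this conditioning at the known deployment site; without
it the final weeks of a run rest on one-sided information and their
fixed-lag marginals wander by a node or two.

Effective sample size below 10 at any step aborts the run with a
diagnostic naming the twilight.

### Outlier screening

Two screens handle twilights corrupted by behaviour (e.g. an animal inside
a cavity emerging late):

* **Pre-run:** each twilight maps to the longitude where the terminator
  crosses the equator — a one-number timing diagnostic that is nearly
  constant day-to-day for any fixed position.  Per twilight kind, residuals
  from a running median (window 11) beyond 4 robust SDs (1.4826 × running
  MAD, window 31 — a short-window MAD is itself too noisy and misfires on
  clean data) are flagged.
* **On the go:** with tentative positions A (filtered ensemble mean),
  B (likelihood-weighted proposal mean under the current surface) and
  C (next surface's centroid), twilight *i* is dropped when both legs
  exceed 150 km, the return leg is no longer than the outbound leg, the
  turning angle is under 100°, *and* C lands back near A.  The return
  condition is what distinguishes an out-and-back artifact from a genuine
  one-way arrival, whose surface must never be discarded.  Surface modes
  are deliberately not used as tentative positions: the mode of a
  ridge-shaped surface jumps by hundreds of km between twilights.

Screened twilights keep their place in the chain (the movement model still
propagates across them); only their surfaces are ignored.

## Summaries

Per twilight: weighted quantiles (2.5/25/50/75/97.5%) of longitude and
latitude from the smoothed marginal (midpoint-interpolated inverse CDF, so
two equal-weight nodes give a median halfway between them), migration
probability, and distance quartiles among migrating particles.  Monthly
bias/SD tables against a known truth support simulation studies.

## The threshold baseline

The classic method — longitude from the twilight midpoint (solar noon with
equation-of-time correction), latitude from day length at a sun elevation
angle calibrated as the median elevation over known-site crossings — is
included for comparison.  The day-length equation can have zero, one or two
latitude roots; roots are disambiguated against a robust reference (median
of the last 7 accepted fixes, seeded at the calibration site, updated only
by < 15°/day moves) because a bare previous-day chain flips onto the mirror
branch during equinoxes and then poisons adjacent months.  The threshold
level is chosen adaptively as the smallest of {1, 2, 4, 8, 16, 32} device
units that yields at least 10 calibration pairs — the lowest usable level
is the most informative, but bright summer nights at high latitude never
cross low levels.  Near equinoxes day length carries no latitude
information: fixes come back missing or wildly scattered.  That is the
baseline's defining failure, and the contrast the template-fit filter is
meant to show.

## The synthetic tag generator

The generator emulates a clipped archival tag from the same physical model
the estimator assumes: per twilight period (half-day between solar noon and
midnight) it draws a_i ~ N(6.14, 1.01) and Z_i ~ logN(log 0.23, 0.0435),
then per record sets log light = a_i + Z_i f''(θ) + N(0, 0.32) and stores
clip(round(exp(·)), 0, 64) at a 2-, 5- or 10-min interval.  The default
parameters are field-realistic values estimated from a real tag at a known
site, so the simulated shading distribution is realistic in scale.  What
the generator does *not* emulate: max-over-interval sampling (records are
instantaneous draws), within-twilight movement, clock drift, sensor ageing
(available as a linear option but off by default), or temporally correlated
weather — shading is independent across half-days.  Passing the validation
therefore demonstrates correctness of the inference machinery under the
stated noise model, not robustness to every artifact of real deployments;
the real-data features above (especially correlated shading) would widen
honest posteriors.

Multi-site schedules move the tag between twilight periods, never within
one, and a helper builds equal-jump migration scenarios.

## Validation studies and problem sizes

* Stationary-tag study: two year-long 2-min tags (5°N and 55°N), July
  calibration at the known site, 1000-km-radius 50-km grid (~1250 nodes),
  2×10⁴ particles, recapture conditioning at the site.  The filter's
  monthly latitude-error SD stays within ~0.2°; the threshold baseline's
  March SD reaches ~11–14°.  Monthly *bias* is below ~0.1° away from
  equinoxes; in the equinox-adjacent months at 5°N the filter can sit a
  fraction of a grid cell off (latitude is then nearly unidentifiable and
  the posterior is free to drift within the movement prior), so the bias
  there varies with the random seed at the ±0.1–0.2° level.  A related
  caveat: the smoothed posterior of a truly stationary tag concentrates
  almost entirely on one node, so reported medians live on the 0.45°
  row lattice; in weak-information months small fluctuations in the
  accumulated evidence can flip the preferred row mid-month, inflating that
  month's error SD by up to a node spacing for unlucky realizations.
* Oracle equivalence: 250-node grid, 30 twilights, bootstrap filter vs
  exact forward recursion; mean total variation ~0.02 at 10⁵ particles.
* Track recovery: three sites at 45°N joined by two 600-km eastward
  overnight flights, May–August (a season where latitude is identifiable;
  the equinox regime is covered above), 2×10⁴ particles.  Dwell positions
  recover to within ~60 km and migration mass concentrates within one
  twilight of the true flights.

Sizes were chosen so the whole validation suite runs in minutes on one
core while keeping every qualitative regime of the method exercised.

## Numerical choices

* Angles in degrees at API boundaries; UTC everywhere; no clock-drift
  correction.
* Lognormal slope priors get an sdlog floor of 1e-3 so unnaturally clean
  calibrations stay proper.
* Interval-fit scoring steps are clamped (|Δintercept| ≤ 2, |Δslope| ≤ 0.2
  per iteration) and standardized bounds clipped at ±8 so absurd candidate
  nodes cannot produce non-finite fits; σ is floored at 0.05.
* Surface floor 1e-6 of the maximum; normalization exact to 1e-12.
* Weighted quantiles use the midpoint (Hazen) convention, fixed and
  documented.
* Ties in the running medians and diel-extremum plateaus resolve to the
  plateau midpoint.
* Known limitations: longitude near high-latitude midsummer is weakly
  identified (terminator nearly parallel to parallels), as is latitude near
  equinoxes for all methods; grids touching a pole are unsupported; the
  transition-matrix oracle is limited to ≤2000 nodes.
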