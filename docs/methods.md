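# Methods

## Scope and model

`pseudotrack` implements a pseudo-absence framework for detecting
environmental (SST) selection in daily-resolution marine animal tracks.
The inference is a two-sample comparison: SST experienced along the
observed (or synthetic) presence track versus SST sampled by cohorts of
environmentally naive simulated tracks. Nothing in the framework
identifies the *mechanism* of selection; a significant result means the
track's realized SST distribution is shifted relative to what naive
movement with the same statistics would have encountered.

## Geometry

All geometry is great-circle on a sphere of radius 6371.0088 km (IUGG
mean). At basin scales the spherical-vs-ellipsoidal error is below 0.5%,
far beneath every other uncertainty in the problem. Bearings are degrees
clockwise from true north in [0, 360); turning angles are signed degrees
in (−180, 180], positive clockwise. Longitudes normalise to (−180, 180].

A subtlety worth recording: when a walk continues "straight" (zero
turning angle), the reference bearing for the next step is the *arrival*
(final) azimuth of the previous great-circle arc, not its initial
azimuth. This makes a zero-turn walk follow a geodesic and makes
simulation exactly inverse to step/angle extraction; with the ~50 km
daily arcs used here the difference from the naive convention is
hundredths of a degree, but it is the internally consistent choice.

## Movement statistics

Step lengths and turning angles are extracted from consecutive daily
fixes and pooled per calendar month (seasonal behaviour differs; monthly
pooling keeps the null models seasonally honest). Step-length moments are
computed on ln Δl because daily displacement distributions are strongly
right-skewed. Steps spanning multi-day gaps are excluded from the monthly
statistics by default (`max_dt_days=1`) since they conflate several days
of movement; this is configurable. Zero-length steps are dropped (their
bearing is undefined). A month absent from the data falls back to the
all-month pool with a logged warning.

## Null models

Per day, each model draws a bearing and a step length:

* **Brownian**: uniform bearing; step exp(N(μ_m, σ_m)) with the month's
  log moments. Sampling in log space guarantees Δl > 0 and is consistent
  with the moments being fit on log-transformed data; a truncated
  linear-Gaussian variant is available (`brownian_space="linear"`).
* **Lévy**: uniform bearing; step from the truncated power law
  p(l) = (1−μ)/(l_max^{1−μ} − l_min^{1−μ}) · l^{−μ} on [l_min, l_max]
  (the logarithmic normaliser 1/(ln l_max − ln l_min) when μ = 1),
  sampled by exact inverse-CDF. Defaults: μ = 2, l_min = 1 m,
  l_max = 3× the 99.5th percentile of observed steps; all three are
  config values and are echoed in the output metadata, since the
  truncation is what permits μ outside the classical (1, 3].
* **CRW**: turning angle and step drawn independently and uniformly from
  the month's empirical arrays.
* **JCRW**: (θ, Δl) resampled jointly as observed pairs — an exact
  empirical 2-D distribution rather than a smoothed density, which
  preserves the long-step/small-turn dependence without bandwidth
  choices.

**Monthly restart.** The source track's date span is cut at calendar
month boundaries; each segment is simulated independently from the
observed fix on the segment's first date (the deployment fix for the
first segment; the fix dated the 1st thereafter, or the earliest fix of
that month when the 1st is missing). Headings reset (uniform) at each
restart. This constrains pseudo-absences to the animal's region while
leaving them environmentally blind within each month.

**Gaps.** Brownian and Lévy steps over a Δt-day gap are rescaled by
√Δt (diffusive scaling of displacement). CRW/JCRW instead walk through
the missing days with daily draws and only record the fix dates, because
directional persistence does not compose under a √Δt rule.

**Reproducibility.** One RNG per (source track, model, month-segment),
seeded from the master seed, a CRC-32 of the track id, the model index
and the segment index. Replicates are drawn as replicate-indexed vectors
from that generator, so cohorts are bit-reproducible and independent of
track order, and the 100-replicate cohorts simulate in vectorised numpy.

## SST field and sampling

The field is a regular (time, lat, lon) grid in °C with NaN for missing
cells, read/written as NetCDF (xarray, scipy backend). An 8-day backward
rolling mean (mean of available values; missing only if all eight days
are missing) mirrors satellite compositing and is applied before any
sampling, including the biased walk's warm-cell search.

Sampling is nearest-cell ("point value"), not bilinear: it keeps
missingness semantics trivial at ~9 km resolution. Exact midpoints
resolve to the lower cell index. When a fix carries a 95% positional CI,
the sample is a Gaussian-weighted mean over cells within 3σ of the
position, σ = 0.25 × CI radius, weight exp(−d²/2σ²) with d the
great-circle distance to the cell centre; σ below half a cell degrades to
point sampling. Pseudo-absence fixes inherit the CI of their date-matched
presence fix. Fixes whose sample is missing (cloud, or the walker left
the grid) are dropped and counted — SST availability is the effective
spatial mask; no other domain constraint is imposed on pseudo-tracks.

The warm-cell search returns the bearing to the warmest non-missing cell
centre within the search radius, excluding the cell containing the
query; ties break by distance, then (lat, lon) index order, so the
search is deterministic.

## Synthetic environment

`generate_env` emulates the statistical structure the tests are
sensitive to, not ocean physics: a linear meridional gradient, a
sinusoidal seasonal cycle, an eddy field (Gaussian-smoothed white noise,
rescaled to unit variance, AR(1) in time), white observation noise, and
spatially clumped missingness obtained by thresholding a second smooth
field at the per-day quantile of the target missing fraction (which
pins the realised fraction). Smoothing with a Gaussian kernel of std s
gives a correlogram exp(−d²/4s²), so the kernel is set to half the
requested e-folding length.

Defaults ("northeast-Pacific-like"): 20–45°N × 150–115°W at 1/12°,
22 °C at the southern edge, −0.35 °C per degree latitude northward,
1.5 °C eddies at 150 km / 20 days, 2 °C seasonal amplitude, 0.2 °C
noise, 10% missingness clumped at 100 km. These are fixture choices
representative of a subtropical eastern-boundary regime.

What the generator deliberately lacks: fronts and filaments (sharp
non-Gaussian gradients), advected (travelling) eddies, realistic cloud
statistics, land. Passing tests on this field therefore demonstrate the
statistical behaviour of the method under smooth mesoscale
autocorrelation — the property that drives the false-positive inflation
— not performance on any particular satellite product.

## Biased presence walk

Synthetic presence tracks take fixed 50 km daily steps for 80 days. Each
day the turning angle is drawn from a Von Mises distribution centred on
the *relative* bearing (target bearing minus current heading) of the
warmest SST within 50 km; κ is the selection strength (κ = 0 uniform,
i.e. no selection). When the search finds no eligible cell the centre is
0° (heading persists). The first heading is uniform; positions are exact
(no CI), so matching uses point sampling. Cohort start positions are
drawn uniformly from the poleward interior of the field (60–90% of the
latitude extent, 15–85% of longitude) — the cool side of the gradient,
mirroring deployments in cool foraging grounds with warm water available
equatorward, and leaving warm-selecting tracks room to run before
meeting the domain edge. The SST sensed on day t uses day t's field (the
day the step is chosen, not the arrival day).

## Selection tests

One-sided two-sample KS tests, both directions, on presence vs pooled
absence samples. ECDFs are evaluated right-continuously on the pooled
sorted values, making ties (discretised SST) deterministic. D is floored
at 0; p = exp(−2D²mn/(m+n)) capped at 1 — the asymptotic one-sided
formula, appropriate for the hundreds-to-thousands-point samples this
framework produces (an exact small-sample computation is deliberately
out of scope and the choice is recorded in results metadata by the
sample sizes). Classification at level α: "warmer"/"colder" when exactly
one direction is significant, "both"/"none" otherwise. By default all
requested null models pool into a single absence sample per test
(per-model testing is available). Aggregation pools dated samples by
period-of-year (monthly → yearly), so seasonally varying selection can
be inspected; Bonferroni correction (α/k) is available but off by
default — the uncorrected rates are themselves a study object.

## Power harness

For each κ: simulate the presence cohort, fit monthly statistics *to
that cohort* (the nulls share the presence data's movement rules, which
is what makes the κ = 0 case a genuine null), simulate pseudo-absence
cohorts, match everything to SST, then for each aggregation size k draw
100 random k-subsets of the cohort (each track exactly once when k = 1),
pool, test both directions, classify, and tabulate fractions with
percentile-bootstrap 95% CIs. "Correct" means: warmer-only for κ > 0,
none for κ = 0. Per-test p-values are stored so significance thresholds
can be swept without re-simulation.

Problem sizes: the shipped study uses 100 tracks per κ, 100 replicates
per null model per track, and a 95-day field — the cohort sizes of the
original study design at a desk-scale field, chosen so the full analysis
runs in minutes on one CPU.

## Numerical and design notes

* Spherical trig arguments are clipped to valid domains before
  arcsin/arccos; antipodal and zero-distance cases are exact.
* Grid axes are validated regular to 1e-9° and stored ascending
  (descending input is flipped on construction).
* The Von Mises sampler delegates to numpy's generator (Best–Fisher);
  κ = 0 is exactly uniform.
* `classify_selection` accepts α ∈ {0, 1} solely so threshold sweeps can
  include the degenerate endpoints.
* Degenerate inputs: tracks need ≥ 2 fixes and strictly increasing
  dates; empty KS samples raise; an all-missing matched track raises
  rather than silently vanishing; dropped-fix counts are logged.

## Known limitations

* Input tracks are taken as given; state-space regularisation biases
  turning angles straighter and is not corrected for.
* Only one environmental covariate (SST); multi-factor selection,
  currents, memory, and step-selection formulations are out of scope.
* The asymptotic one-sided p-value is anti-conservative for very small
  samples (tens of points); per-track tests on 80-point tracks are on
  the safe side of that regime but the false-positive inflation measured
  here is dominated by spatial autocorrelation, not by the asymptotics.
* Pseudo-absence positional uncertainty uses an isotropic Gaussian; real
  ARGOS error ellipses are anisotropic.
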