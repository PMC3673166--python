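# Methods

This note documents the models, parameters and numerical choices behind
the package, what the synthetic cohort does and does not emulate, and the
known limitations.

## Kinematic behaviour labelling

Speed *s* is the median of the five segment speeds (haversine distance /
time, sphere radius 6371 km) in a window of six consecutive fixes;
tortuosity *t* is the arc–chord ratio (first-to-last beeline distance
divided by the summed segment distances) over five consecutive fixes. The
decision rule — rest below 2.5 m s⁻¹; above it, flight when *t* ≥ 0.98
and forage otherwise — separates the bimodal speed distribution of
shearwater fixes and the directed/undirected split of fast movement.

Choices the rule's published form leaves open, fixed here:

* **Window alignment** is centred: fix *i* uses fixes *i−2 … i+3* for
  speed and *i−2 … i+2* for tortuosity, attributing behaviour to the
  place it happened. Fixes whose windows do not fit (two at the start,
  three at the end of a track) are labelled `undefined` and excluded from
  classifier training.
* **Ties** are deterministic: *s* exactly 2.5 → rest; *t* exactly 0.98
  with *s* above the cut → flight. Undefined tortuosity (zero arc
  length, i.e. five coincident fixes) implies no movement and maps to
  rest; it cannot co-occur with *s* above the cut on a single track.
* Segment speeds are medianed individually rather than computed as
  displacement over total time — the literal reading of "median speed".

## Synthetic cohort

The generator supplies ground truth for every downstream stage. It is a
study-conditions generator, not an ocean model.

**Foraging trips.** Latent states follow a three-state Markov chain
(default persistence 0.97, mean dwell ≈ 2.8 h at 5-min fixes) realised as
a correlated random walk on the sphere: per-state truncated-normal
segment speeds (rest 0.15 ± 0.08, flight 10 ± 1.2, forage 6 ± 1.5 m s⁻¹)
and von Mises heading increments (concentrations 0.3 / 2000 / 0.6). The
speed means straddle the 2.5 m s⁻¹ cut and the flight concentration keeps
five-fix windows above *t* = 0.98, so the labelling rules separate the
states by construction; with these defaults the rules recover the latent
states at ≈ 98–99%. The cohort is 20 birds × 1–3 trips of 420–540 fixes.

**Immersion.** The logger performs 200 wet/dry checks per 10-min block;
salt is Binomial(200, *w*) with per-state wet fractions *w* = 0.95 (rest),
0.02 (flight), 0.50 (forage). These are stand-ins chosen for separability
— no per-behaviour immersion distributions are published for this species
— giving rest−flight mean salt separation of ≈ 186 counts.

**Light.** Logger light is the solar elevation mapped through a linear
ramp 8° wide, quantised to 0–64, with the ramp positioned so the 4/64
threshold is crossed exactly at the configured twilight elevation angle
(default −3.5°). This makes elevation-angle calibration self-consistent
by construction and is sufficient for twilight-timing tests; it has no
weather, sensor shading or moonlight.

**Annual cycles.** A 365-day deployment tiles into breeding (90 d) →
southbound migration (28 d) → winter (153 d) → northbound migration
(28 d) → breeding, with daily waypoints near the colony (54.67° N,
5.52° W), near the winter centroid (40° S, 52° W), or stepped along the
great-circle route. Each migration leg starts and ends with two
transit-flight days that cover 10% of the route per day — so the bird
clears the 1200-km proximity radius within two days and the daily wet
proportion drops below 0.25 — and middle days mix four regimes (ordinary
travel, rest stopovers, foraging stopovers, flight days at probabilities
0.35/0.22/0.25/0.18), emulating the stopover structure of real pelagic
migrations. Per-day behavioural mixes (e.g. winter 0.90/0.01/0.09
rest/flight/forage) drive sticky within-day chains at the 10-min logger
cadence.

**Environmental rasters.** SST is a meridional gradient plus a smoothed
Gaussian random field; NPP and CHL are decreasing affine functions of SST
plus smooth noise, so productivity is highest in colder waters (negative
SST correlation by construction). Behaviour is coupled to *position*
(stage plan) but not to the raster values themselves, so multinomial
covariate effects in the synthetic pipeline are weak; the regression
machinery is instead validated on data generated directly from known
multinomial-logit coefficients.

What passing tests therefore show: the operators implement their
definitions correctly and the full chain recovers a truth constructed to
be recoverable. They do not show that real shearwater immersion data are
this separable, nor calibrate real error rates.

## Classifier

One hidden layer of 10 logistic units, softmax output over the three
behaviours, cross-entropy loss (scikit-learn `MLPClassifier`, Adam,
learning rate 10⁻³, seeded initialisation). Features are the 35 salt
counts (optionally plus light) of a centred window, scaled to [0, 1] and
then z-scored with constants fitted on the training subset only. The
window length is a design choice: 35 samples ≈ 5.8 h, long enough to span
bout structure, short relative to a day, and odd so the window centres on
the labelled moment. Missing samples inside a window are linearly
interpolated up to 3 consecutive gaps; longer gaps drop the window.

The balanced pool is 2000 examples. Since 3 does not divide 2000,
per-class counts follow a largest-remainder allocation (667/667/666); the
50/25/25 subsets are filled by a greedy always-take-the-largest-class
assignment, so subset totals are exactly 1000/500/500 and every subset
stays within two examples of class balance. Training runs 150 epochs and
restores the weights of the epoch with the highest test-subset accuracy
(early stopping against the test subset; the validation subset is never
touched before evaluation). "Chance" is operationalised as a permutation
test: the add-one-corrected fraction of 1000 validation-label
permutations whose agreement with the predictions reaches the observed
accuracy. On balanced validation data overall and class-balanced accuracy
coincide; both are reported.

## Geolocation

Threshold method: a twilight is a crossing of the light threshold (4 of
64) persisting at least two samples. Crossing times are refined by a
least-squares line through the on-ramp samples (0 < light < saturation)
within ±3 samples of the crossing — a two-point interpolation is biased
early/late because the neighbouring sample is usually clipped at the dark
end of the ramp, and at a 10-min cadence that bias is several tens of
seconds, enough to shift latitudes by degrees near the equinox windows.

Longitude places local apparent noon (sunrise/sunset midpoint) using the
equation of time; latitude solves
sin *e* = sin φ sin δ + cos φ cos δ cos *H* for φ given the half-day hour
angle *H*, declination δ, and the calibrated elevation angle *e*. The
closed form has two branches; feasible roots (|φ| ≤ 89.5°) are kept and
ambiguity resolves toward the previous day's latitude, else toward the
equator. Days with no feasible root are flagged rather than dropped.
Solar declination and the equation of time use the Spencer Fourier
series — accurate to a few hundredths of a degree, far below the ~200-km
error scale of the method.

Filters, applied in order: dark periods < 4 h remove their bounding
twilights; twilights within ±10 days of Mar 20 / Sep 22 (UTC, fixed
dates — sub-day equinox precision is irrelevant at a ±10-day window) are
removed; positions inside any ≥ 3-day run of inter-position speeds above
30 m s⁻¹ are removed; remaining positions with |lat| > 75° (outside the
species' plausible range) are removed. All filters are idempotent.
Calibration scans candidate elevation angles and keeps the one minimising
mean great-circle error against a known site, ties to the
smaller-magnitude angle.

Known limitation: in the first days outside the equinox window the
day-length/latitude relation is still nearly degenerate (δ ≈ *e*), and a
seconds-level timing error can move latitude by several degrees; the
round-trip guarantee of < 2° holds away from those edge days and away
from polar latitudes.

## Migration analysis

Stage boundaries use the 1200-km proximity rule; the "median wintering
location" is defined here as the component-wise median of
Southern-Hemisphere daily positions. Daily positions for mapping are the
mean of that day's (≤ 2) geolocation estimates, gap-filled across equinox
windows by time interpolation and flagged. Sub-stages are the first and
last 30 days and the middle of a stage; stages of ≤ 60 days get an empty
middle and a warning.

Flight bouts: per migration leg, the first run of days with daily wet
proportion < 0.25 after departure and the last run before arrival. The
run (rather than single-crossing) reading is a design choice, flagged as
such.

Occupancy KDE is an isotropic Gaussian kernel in lon/lat degrees
(geolocation default: cell 0.1°, bandwidth 10°; GPS scale: 0.01°/1°),
computed separably on a grid padded 6 bandwidths beyond the data so the
discretised density integrates to 1 within 10⁻⁶. Working in degrees
matches standard practice for geolocation-scale tracking data; the
resulting high-latitude distortion is documented, not corrected.
Isopleths are highest-density regions: the threshold is the density at
which the ranked cell masses accumulate the target fraction, and polygons
come from marching squares on the density grid. The 95% region contains
the 50% region by construction.

Top-quartile subsets rank location-days (one location per day) by each
behaviour's daily proportion; ties break toward the earlier date; set
size is ⌈0.25 n⌉. The overlap table counts days in exactly zero, one,
two or three top-sets (they sum to 100%) and the pairwise composition of
the two-set days.

## Environmental statistics

One covariate at a time, per migratory direction, 3-category multinomial
logit with rest as the reference category (statsmodels `MNLogit`,
covariate standardised internally and coefficients reported on the raw
scale; Wald standard errors and 95% CIs; probability bands by simulating
300 coefficient draws from the asymptotic normal). Non-convergence (e.g.
complete separation) flags the fit and falls back to a ridge-penalised
logistic fit without standard errors. The per-sample behaviour is the
dominant daily behaviour — how per-day proportions entered the original
regression is not published, so this is a documented design choice.

Use vs availability: uniform points inside the 95% contour polygons by
seeded rejection sampling in the bounding box; rasters sampled bilinearly
(NaN propagates, out-of-extent warns); two-sample KS via
`scipy.stats.ks_2samp`. One numerical note: with *equal* sample sizes of
100 the exact two-sample KS null is visibly discrete and rejects at
~0.035 rather than 0.05; the null-calibration test therefore uses unequal
sizes (150 used vs 200 random, the function's default availability
sample), where the attained level is ~0.051. This is a property of the
test statistic's discreteness, not of the sampling procedure.

The parameter-recovery check is phrased as interval coverage: "within
2 SE" is a 95% Wald interval, so a single 4-coefficient fit honestly
misses ~1 time in 5; the test asserts ≥ 85% coverage over 40 intervals
from 10 replicate n = 2000 datasets plus unbiasedness of the replicate
mean, which a correct fit passes with high probability and a biased one
fails badly.

## Pipeline and problem sizes

One pipeline seed fans out to per-stage seeds by SHA-256 hashing of the
stage name (all derived seeds < 2³¹); reruns are bit-identical, and run
directories carry a checksum manifest. All timestamps are UTC and days
are UTC calendar days.

The analysis drivers run the full study conditions (20 GPS birds, 31
annual deployments). The test suite exercises the same code on smaller
cohorts — e.g. 4 GPS birds, 2 annual birds and a 600-example pool for the
orchestration tests — chosen so the whole suite completes in well under a
minute of simulation time while leaving every statistical check at the
sizes stated above (the balanced-pool, KS-calibration and
coefficient-recovery checks run at their full 2000-example/2000-replicate
sizes).
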