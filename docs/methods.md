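# Methods

## The model and its assumptions

`traitsync` quantifies spatial synchrony — correlated year-to-year
fluctuation of annual average trait values among populations — with a
three-parameter Gaussian correlogram

ρ(d) = ρ∞ + (ρ0 − ρ∞) · exp(−d² / 2l²),

embedded in a zero-mean multivariate normal model for each year's
cross-section of detrended, normalized trait values.  The correlation
matrix Σ has unit diagonal; off-diagonals follow ρ(d) at the pairwise
great-circle distance.  Assumptions, in decreasing order of importance:

1. **Detrended fluctuations are jointly Gaussian with unit variance.**
   Detrending (per-population OLS on calendar year) and normalization
   (dividing residuals by their sample SD, n−1 denominator) make the unit
   diagonal a modelling convention rather than an approximation; what is
   genuinely assumed is joint normality and a common correlation
   structure across years.
2. **Isotropy and stationarity in space.**  Correlation depends on
   distance only — not direction, latitude, or habitat.
3. **Independence across years.**  The total log-likelihood is the sum of
   annual log-densities; temporal autocorrelation beyond the linear trend
   is ignored.  Because laying-date-type traits respond to essentially
   uncorrelated year-to-year weather after detrending, this is mild, but
   it is untested by this package.
4. **Non-negative correlations.**  The parameter space is restricted to
   0 ≤ ρ∞ ≤ ρ0 ≤ 1; truly negative long-range correlations are outside
   the model, and estimates landing on a boundary (often ρ̂∞ = 0) are
   reported as-is.

Σ is positive semidefinite for every admissible parameter set because it
decomposes as ρ∞·J + (ρ0−ρ∞)·(Gaussian kernel) + (1−ρ0)·I.  With
great-circle rather than Euclidean distances the Gaussian kernel is not
PSD in general, but over continental-scale site layouts (tested across
random layouts spanning Europe-sized lat/lon boxes) the minimum eigenvalue
stays ≥ −1e−10; a 1e−8 diagonal ridge backs up the Cholesky factorization
in the rare numerically singular case (e.g. co-located sites with ρ0 → 1)
and logs a warning.

## Data preparation

Brood records enter as long-format CSV.  Inclusion rules, applied per
target trait: first clutches only; no experimental manipulation; the trait
recorded; for fledgling traits, at least one fledgling (excluding total
brood losses, so fledgling number reflects parental effort rather than
predation); and — re-applied after the record-level filters — at least two
broods per population-year.  Annual aggregation uses the median for laying
date (right-skewed within years) and arithmetic means otherwise; fledgling
success is the mean of per-brood fledgling/clutch ratios.  Populations
need ≥ 9 observed years (configurable) to enter the synchrony analysis,
and ≥ 3 for detrending to be defined at all.  Climate series arrive daily
or annual per site; daily series are averaged over February–May (121 days
in leap years, 120 otherwise), dropping years missing more than 10% of the
window — a tolerance added because field inputs, unlike complete gridded
products, have gaps.

Missing years are first-class: each year's likelihood term uses only the
populations observed that year, so partly overlapping series contribute
exactly the information they carry (longer overlaps contribute more terms).
Years with a single observed population add a parameter-free N(0,1) term —
equivalent to skipping them for the argmax, but keeping log-likelihoods
comparable across parameter sets.

## Estimation

The likelihood is maximized in unconstrained internal coordinates — logit
for ρ0, ρ∞ = ρ0·logit⁻¹(u) to enforce the ordering, log for l — by
L-BFGS-B with numerical gradients.  The surface can be multimodal (a flat
correlogram with moderate ρ∞ can mimic a long-scale decay), so the search
restarts from 10 deterministic Halton points spanning ρ0 ∈ [0.10, 0.95],
ρ∞/ρ0 ∈ [0.02, 0.87], and l log-uniform between 2% and 120% of the maximum
pairwise distance; the best solution wins.  l is bounded above by 5× the
maximum pairwise distance, below by 1 km: outside that range the data
cannot distinguish scale from a flat or diagonal correlogram.  Years are
grouped by availability pattern so each distinct sub-matrix is factorized
once per likelihood evaluation; one evaluation on a 31-site × 30-year
complete panel costs well under a millisecond, a full multi-start fit
about 0.15 s.

## Parametric bootstrap

Replicate panels are simulated from the fitted parameters on the observed
availability mask (year by year, MVN restricted to that year's sites) and
refitted.  Refits warm-start at the point estimate plus 3 Halton starts —
the warm start dominates in practice, and the reduced design keeps 2000
replicates tractable; replicates that fail to converge are dropped and
counted, with an error if more than 20% fail.  Reported summaries are the
replicate medians and percentile (not BCa) 2.5/97.5 intervals; the
headline estimate for a trait is the bootstrap median.  All randomness
flows from one master seed through `numpy.random.SeedSequence` spawning
(one child per replicate), so results are bit-reproducible; pipeline cells
derive their seeds from the master seed by hashing (species, trait,
climate variable).

## Climate attribution

To measure how much a climate variable accounts for synchrony, each
population's *annual average* trait values are regressed (OLS, intercept +
slope) on that population's z-scored seasonal climate means over their
jointly observed years; the residuals are normalized and refitted.  The
raw fit uses plain detrend-then-normalize residuals.  These two recipes
mirror the two-stage procedure this design follows; because the climate
regression contains no year term by default, a shared trend that climate
does not explain remains in the adjusted panel — a real property of the
procedure, visible in simulations with a trended trait and trend-free
climate.  A `include_year` switch regresses on year and climate jointly
for users who want the adjustment net of trends.  Raw and adjusted fits
always run on the identical population set and distance matrix, and the
drop in the fitted correlogram is summarized on a distance grid by pairing
bootstrap replicates by index.

## Synthetic data

The generator emulates the structure of a multi-site nest-box study: 20–35
sites uniform in a planar region (default 2000 × 2000 km, Euclidean
distances; lat/lon boxes with haversine distances are supported), decades
of annual values (default 40 years), per-population linear trends, and
year-i.i.d. MVN fields with a known correlogram.  Defaults describe a
laying-date-like trait — mean near day 22 (April 1 = 1), SD 5 days, trend
−0.17 days/year — magnitudes chosen to match long-term European tit
monitoring.  Missingness (independent thinning plus per-population
first/last-year windows) applies to the observable panel only; the latent
field stays complete for exact oracle comparisons.  With a climate driver,
the observable field is β·C + σ·e with independent MVN fields C and e, and
the returned latent panel is e — the synchrony a perfect adjustment should
recover.  What the generator does *not* emulate: temporal autocorrelation
(an AR(1) knob exists for stress-testing but defaults off), non-Gaussian
or right-skewed brood-level distributions (the brood emitter scatters
symmetric broods around annual values purely to exercise the filters),
anisotropy, and observation error in coordinates.  Passing tests therefore
demonstrate correctness of the estimator under its own assumptions, not
robustness to their violation.

## Numerical choices and problem sizes

- Distances: haversine, Earth radius 6371.0 km; planar scenarios use exact
  Euclidean km.
- Degeneracy tolerances: residual SDs below 1e−12 × series scale raise
  degenerate-population/regressor errors; the likelihood ridge is 1e−8.
- Even-count medians: mean of the two middle values; laying dates before
  April 1 are zero or negative integers.
- Validation problem sizes (chosen to exercise each regime at useful
  Monte-Carlo precision): parameter recovery uses 200 replicates of 31–35
  sites × 30 complete years per published parameter regime; bootstrap
  coverage uses 50 outer replicates of 25 sites × 30 years with B = 200
  and 2 extra refit starts; empirical-correlogram convergence checks run
  2000–5000 simulated years.

## Known limitations

- Fixed-domain asymptotics: with few site pairs inside a short scale l,
  l̂ is noisy (the short-scale fledgling regime carries the widest
  relative tolerance for exactly this reason).
- The likelihood treats the detrended-normalized values as data; the
  uncertainty from estimating each population's trend and SD is not
  propagated into the bootstrap intervals.
- One climate variable per comparison; joint multi-variable adjustment is
  out of scope.
- Gridded-climate extraction (e.g. from NetCDF products) is out of scope;
  climate must arrive as per-site daily or annual series.
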