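# Methods

`flutterpath` re-implements, as a tested library, an analysis chain for
butterfly movement along a rural–urban gradient: second-resolution DGPS
tracks of individual butterflies (recorded by an observer following the
animal) are cleaned and segmented, condensed into per-individual
mobility and tortuosity metrics, joined with landscape covariates, and
modelled with beta/lognormal mixed-effect regressions. A synthetic-data
layer generates every input the chain consumes, with known ground
truth, so each stage is verifiable without field data.

## Track processing

**Input model.** A track is an ordered sequence of fixes (t, x, y) at a
nominal 1-s resolution, at most 12 min long (longer inputs warn rather
than fail — the cap is a protocol maximum, not a physical bound).
Geographic input is projected to a local tangent plane of the WGS84
ellipsoid centred on the track centroid (meridional and prime-vertical
curvature radii); over the ≤1 km extents of these tracks the step
lengths this yields agree with true ellipsoidal geodesics to better
than one part in 10⁵, which the suite verifies against an independent
Vincenty implementation. Absolute coordinates are not reproducible
across tools that chose different national grids; all derived metrics
depend only on relative geometry.

**Gaps.** GPS dropout (e.g. under trees) appears as missing seconds.
An inter-fix interval of ≥3 s counts as a gap (configurable; at 1-s
sampling a 2-s interval is more often a single lost fix than a real
hole, and treating it as a gap would fragment segments needlessly).
Metrics never bridge a gap: path length, steps and turning angles are
computed within gap-free segments only, and gap seconds drop out of
the flying-time denominator.

**Stop consolidation.** Stops come exclusively from the field event
log (closed intervals [start, end] with an activity label), never from
positional clustering. Because the observer drifts while the animal
sits, a stop is recorded as a point cloud; all member fixes are
replaced by the cloud's geometric median — the exact Euclidean
1-median computed by Weiszfeld iteration with the Vardi–Zhang vertex
correction (tolerance 10⁻⁴ m movement per iteration, subgradient
optimality check when an iterate lands on a data point). The audit in
the acceptance suite compares it against a refined grid search of the
convex objective. Stops overlapping the first or last retained fix are
removed from all analysis views: those intervals mix tracking with the
observer's approach/retreat. Removing them does not shift the time
origin; durations use the retained span. Stops whose interval spans a
data gap keep a single shared centre for both fix subsets.

Two views result: the *mobility* view (all retained fixes, stop
members pinned to the centre, so within-stop displacement is exactly
zero) and the *tortuosity* view (only the first fix of each stop
retained, so zero-length steps cannot corrupt turning angles).

## Movement metrics

**Sinuosity.** Tortuosity is Benhamou's corrected sinuosity

    Sin = 2 · [ p · ( (1+c)/(1−c) + b² ) ]^(−1/2)

with p the mean step length (m), c the mean cosine of turning angles
and b the coefficient of variation (population SD / mean) of step
length; units m^(−1/2); Sin → 0 for straight paths. The b² term sits
inside the factor of p — this is the form the `trajr` package's
`TrajSinuosity2` computes, and the only form under which uniform
coordinate scaling by k scales Sin by k^(−1/2) (a property the suite
tests). c = 1 returns 0 as the continuity limit. Consecutive duplicate
fixes are merged before heading computation (a heading is undefined
across a zero step); population rather than sample SD in b is fixed
for determinism — at track scale the difference is negligible. Tracks
split by gaps get one sinuosity per segment (minimum 3 fixes; shorter
segments are dropped with a warning) and a track value weighted by
segment *path length*; the alternative reading of "segment length" as
duration is available via a switch, and segment weighting by length is
the default because sinuosity is a per-distance quantity.

**Flight speed** is path length flown divided by seconds spent flying
(retained seconds that are neither inside a stop interval nor lost to
a gap). Stop seconds are excluded because after consolidation the
distance inside stops is identically zero: including those seconds
would fold stopping share — modelled separately — into speed. A
`gross` switch divides by the full retained duration instead.

**Time budget.** Stopping/nectaring/resting shares are exact ratios of
second counts over the retained span; stopping is the union of all
stop intervals, with basking and oviposition counted in stopping only
(sample sizes for those activities do not support separate analysis);
an activity recorded as unknown counts toward stopping but neither
subcategory. The acceptance suite confirms the shares equal a
per-second brute-force enumeration of the event log exactly.

## Landscape covariates

Nectar-plant coverage is the arithmetic mean of per-1-m-segment
percent covers along the activity transect. Imperviousness ("sealing")
rasters typically cover only part of the domain; uncovered cells are
imputed with the mean observed sealing of their biotope class, after
which urbanization is the mean of imputed sealing over cells whose
*centres* fall within 500/1000/2000 m of the site centre. Cell-centre
membership is used instead of fractional-area weighting: with 2 m
cells against ≥500 m radii the discretization error is below 0.1%, and
the rule is deterministic. Habitat area is the planar polygon area
(holes subtracted) in hectares, via shapely. Rasters are exchanged as
ESRI ASCII grids (plain text) on a shared grid definition; vector
inputs as GeoJSON.

## Inference

Numeric predictors are centred and scaled to unit sample SD (scaling
constants retained for back-transformation). Predictor pairs are
screened by Spearman's |rs| with 0.5 as the exclusion threshold; the
default drop rule removes the member with the larger mean absolute
correlation. Responses are moved onto their family's support: speeds
and tortuosities below 10 are divided by 10 into (0, 1) for the beta
family; shares get a 10⁻¹⁰ offset to lift exact zeros; values reaching
1 are nudged to 1 − 10⁻⁶ (open support) with a warning.

**Model.** Each response is fitted as

    g(E-scale) = X β + u_habitat + u_duration + u_site,   u_g ~ N(0, σ_g²)

with a beta family (logit link, precision φ) or a lognormal family
(log y ~ Normal(η, σ²)). Random intercepts follow the field workflow
literally: *continuous* grouping variables (habitat area, track
duration) each contribute a factor whose levels are their distinct
values — for duration this is effectively an observation-level
intercept. This is a faithful-but-unusual structure (it is what the
standard mixed-model machinery does when handed a continuous variable
as a grouping factor); a `random_as_fixed` switch treats habitat area
and duration as fixed covariates instead. Habitat area and site are
perfectly confounded when area is constant within site; their variance
split is then arbitrary but their sum is identified, and the suite
tests the sum.

**Estimation** is Laplace-approximate maximum likelihood, written for
this package: an inner penalised Fisher-scoring loop finds the joint
mode of (β, u) for candidate variance/dispersion parameters; the
marginal log-likelihood is the penalised log-likelihood at the mode
minus ½ log det of the random-effect information; a Nelder–Mead outer
loop moves (log σ_g, log φ). Every grouping factor's own information
block is diagonal, so the largest factor is eliminated by a Schur
complement and each scoring step costs O(n·m²) with m a few dozen.
Wald z = β̂/SE with SEs from the fixed-effect block of the inverse
joint information conditional on the variance parameters — the
convention of lme4/glmmTMB, against which the implementation is
cross-checked in the test suite (coefficients and SEs agree to ~10⁻²
on a shared fixture; glmmTMB serves only as an oracle there). Fisher
(expected) information is used in place of the observed Hessian for
positive-definiteness; variance parameters are log-parameterised and
soft-clipped at sd = e⁻¹⁰, with near-zero variances reported as ≈0 and
flagged singular rather than failing. No multiple-testing correction
is applied; per-coefficient Wald p-values are reported as-is.

**Radius selection.** The urbanization buffer radius (500/1000/2000 m)
is chosen per response by minimum AIC, ties resolved toward the larger
radius; the full AIC table is always reported. AIC is the package's
choice of "best explained" — the candidate fits differ only in one
fixed covariate, so AIC ranking equals likelihood ranking here.

**Diagnostics** follow the DHARMa workflow: n_sim ≥ 250 unconditional
simulations from the fitted model (random intercepts redrawn), a
randomized-PIT residual per observation — (number of simulations below
the observation + U(0,1) tie randomisation)/(n_sim + 1), exactly
U(0,1) under the model — tested for uniformity by KS, and a two-sided
Monte-Carlo dispersion test comparing the observed residual variance
with its simulated distribution. Under shared random intercepts the
per-observation residuals are exchangeable but not independent, so the
KS test is mildly conservative/anticonservative depending on the ICC;
with the modest intercept SDs of the defaults the realised rejection
rate stays near nominal (verified by the calibration experiment).

**Species contrasts** use the two-sided Wilcoxon rank-sum test (exact
null for groups of ≤10 without ties, normal approximation with tie
correction otherwise), via scipy.

## Synthetic data

`simulate_track` draws a correlated random walk: headings evolve by
von Mises(0, κ) increments (chosen because the mean turning-angle
cosine has the closed form c = I₁(κ)/I₀(κ), giving analytic targets),
step lengths are gamma with mean p and CV b, and one step spans one
sampling second — so the generating (p, c, b) are exactly the
quantities the estimators target and 2[p((1+c)/(1−c)+b²)]^(−1/2) is an
analytic reference for the estimated sinuosity. Stops arrive at a
per-second landing hazard (default 2/min), last geometric-distributed
bouts (mean 20 s), carry activity labels (nectaring 0.45, resting
0.35, basking 0.15, oviposition 0.05 — nectaring and resting dominate
real logs), and are recorded as point clouds with 0.3 m isotropic
observer jitter. GPS dropout removes flight fixes with probability
0.01 each; stop fixes are spared, matching the field observation that
signal loss happened while flying through groves. Defaults mirror the
study conditions: ~336 flight seconds (the mean recorded duration),
~1 m/s. What the generator does **not** emulate: smooth within-flight
speed autocorrelation, observer lag behind the animal, or
terrain-driven heading bias — so passing tests certify the estimators
against the CRW-with-stops model, not against every artefact of real
tracking.

`simulate_study` draws per-individual responses directly from the
inference model (beta or lognormal, linear predictor with known
coefficients on row-scaled predictors plus the three random
intercepts) across 29 sites spanning 1.4–68.8% imperviousness with
nectar coverage averaging 9.2% (gamma-shaped, SD 8.3) — the observed
ranges of the study region — and emits tables in exactly the schema
the pipeline writes, for coefficient-recovery and calibration
experiments. Urbanization and habitat area are site properties;
nectar coverage varies per individual by default (one transect per
tracked butterfly, the field design), with a `np_cov_level="site"`
collapse available. The predictor level matters for inference checks:
with only ~30 sites, a normal-reference Wald test on a purely
site-level predictor is intrinsically a little anticonservative
(effective degrees of freedom follow clusters, not individuals), and
the calibration experiments reflect the mixed individual/site design. `simulate_landscape` builds a Voronoi-patch biotope map
with class-dependent sealing, observed only west of an administrative
cut (or a monocentric exponential gradient for nested-buffer checks).
All generators are pure functions of (config, seed).

## Validation experiment sizes

The experiment functions (`flutterpath.experiments`) run at: 500 CRW
tracks × 200 steps (estimator consistency); 50 point clouds against a
0.001-m grid search; 100 tracks for exact time-budget recovery; 200
replicates × 600 individuals for coefficient recovery and 200 × 300
for null calibration; 100 replicates for KS calibration and 30 for
dispersion power (4× variance inflation). These sizes put Monte-Carlo
standard errors well inside the tolerances asserted (e.g. recovery
bias tolerance ±0.02 against an MC SE of ~0.002).

## Known limitations

* The reproduction entry point (`flutterpath reproduce`) fits the
  full model roster on a deposited per-individual table; the package
  ships only a synthetic stand-in exercise for it, since any real
  deposited dataset is an external download.
* The beta family's observation-level random intercept (duration) is
  weakly identified against the precision φ; the optimiser resolves
  the trade-off by likelihood, and either component may be reported
  near zero.
* Laplace approximation (not adaptive quadrature) — with crossed
  factors this is the standard choice and matched glmmTMB to ~10⁻² on
  fixtures, but small-sample variance components are approximate.
* The report renderer emits markdown only.
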