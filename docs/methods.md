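# Methods

`rsfkit` implements a multi-scale resource-selection analysis for a
stationary, home-range-holding prey species tracked by GPS, together
with a synthetic landscape/telemetry generator that makes every stage of
the analysis testable by parameter recovery. This note documents the
models, the conventions chosen where the design was genuinely open, the
synthetic world's assumptions, and the limits of what the validation
experiments demonstrate.

## 1. The use–availability RSF model

Resource selection is estimated at two of Johnson's orders:

* **landscape level (2nd order)** — where home ranges are placed within
  the study region;
* **home-range level (3rd order)** — which patches are used within the
  home range.

Both are fitted as binomial (logit) mixed models contrasting used
points (response 1) with random available points (response 0). The
exponentiated fixed-effect linear predictor is the resource selection
function (RSF), proportional to relative selection.

**Sampling design.** The total number of random points is ten times the
average number of relocations per hour of day,
`round(10 · n_relocations / 24)` (round-half-to-even; for 211,767
relocations this gives 88,236). At the landscape level all study-region
random points are available and a seeded 10% subsample of the random
MCP points is used; at the home-range level all MCP random points are
available (per-individual counts proportional to relocation counts) and
a seeded 1/24 subsample of all relocations is used, giving the
approximate 1:10 use:available ratio throughout. The hourly analysis
splits the home-range design into 24 tables, one per local hour, each
reusing the full available set and taking every relocation of that hour
as used.

**Model structures.** Thirteen hypothesis structures combine three
covariate blocks — forage (*f*: WC + SVD + NDVI), risk (*r*: WC + ProxW
+ TRI) and their union (*fr*) — with four modulation patterns: generic
(*G*, main effects only), spatial (*S*, every covariate interacted with
the inside/outside-protected-core factor InOut), temporal (*T*,
interacted with moon illumination) and spatio-temporal (*ST*, both),
plus a woody-cover-only null model. Temporal structures require
per-row timestamps and exist only at the home-range level, so the
landscape candidate set holds the first seven structures.

Random intercepts: management area and individual at both levels; year
and season-within-year (coded as the year × season combination factor)
additionally at the home-range level. The df of a model is the number
of fixed-effect columns plus the number of variance components; this
accounting reproduces the published example table's df column exactly
(4–14 landscape, 6–22 home-range).

**Coding conventions** (the source analyses leave these unstated; they
are declared here and reported with every fit):

* continuous covariates are z-scored on the pooled used+available rows;
  back-transformed (raw-scale) coefficients are reported alongside via
  the exact affine map;
* InOut is a 0/1 indicator with *inside* as the reference level;
* Moon enters as percent illumination / 100, uncentred.

## 2. The GLMM engine

The fitter maximizes the Laplace-approximated marginal likelihood, the
same estimator the field's standard mixed-model software uses for
binomial GLMMs:

* **inner loop** — Newton (penalized IRLS) maximization of the joint
  penalized log-likelihood over fixed effects β and random-effect modes
  u; the objective is strictly concave, and step-halving guards the
  ascent. Convergence: relative objective change < 1e-10 and gradient
  norm < 1e-5 (scaled).
* **outer loop** — bounded L-BFGS-B over θ = log σ per grouping factor,
  bounds [−8, 3]; a fit at the lower bound is reported as a boundary
  (singular) variance. The marginal log-likelihood is
  `l_pen(β̂, û) − ½ log|Z'WZ + D⁻¹| − ½ log|D|`.

Crossed factors are handled by a joint sparse indicator block; with
random intercepts only, the joint Hessian is small and dense solves are
exact. Wald standard errors come from the Schur complement of the
u-block at the optimum (conditional on θ, as is conventional).
AIC = −2 logLik + 2 df.

Correctness is guarded by three independent oracles: a plain logistic
regression (zero-variance limit, agreement < 1e-4 on coefficients), a
25-node adaptive Gauss–Hermite quadrature fit written independently in
the test suite (|Δβ| < 0.02, |ΔlogLik| < 0.1 on a five-group toy), and
a repeated-simulation calibration experiment (95% Wald CI coverage of
the slopes within 93–97% over 200 refits at n = 20,000). A one-off
cross-check against R's `glmer` during development agreed to 1e-6 in
log-likelihood and 4 decimals in the variance component; the shipped
tests rely only on the in-repo oracles.

## 3. Model support: the delta-AIC ratio

Support for a named set of structures is the mean ΔAIC across all
hypothesis models divided by the mean ΔAIC within the set (> 1 means
above-average support). The null model is excluded from both means.
That exclusion is not obvious from the verbal definition; it was pinned
by brute force against the published example table — with the null
included none of the ten printed ratios reproduce, with it excluded all
ten reproduce within ±0.01 of integer-rounded inputs — and the
derivation is frozen as a regression test. Ties in the AIC ranking are
flagged and broken toward fewer df.

## 4. Cross-validation

Boyce-style k-fold validation (default k = 10): rows are stratified by
response into k folds; each held-out fold is scored by the training
fit's fixed-effect linear predictor (random effects at their population
mean of zero, since held-out groups may be unseen), scores are cut into
10 bins at the held-out *available*-score quantiles (equal-available
count; an equal-width variant sits behind a flag), and the
area-adjusted frequency per bin — held-out used share over available
share — is Spearman-correlated with bin rank. Empty or tied bins are
merged and flagged; per-fold p-values combine by Fisher's method. The
statistic is invariant to monotone transforms of the score, which is
tested directly.

## 5. Diel and lunar analyses

The selected home-range structure is refit per hourly table, and each
covariate's 24 hourly coefficients (inside = main effect; outside =
main + interaction, with the delta-method variance) are regressed by
OLS on fixed-phase raised-cosine templates:

* single (day–night): r1(h) = (1 + cos(2π(h−12)/24))/2, peak at noon;
* double (dawn–dusk): r2(h) = (1 + cos(2π(h−6)/12))/2, peaks 06:00 and
  18:00.

Phases are configuration with these defaults; the template's affine
scaling is immaterial to the F statistic (df 1, n−2), which is proved
by a test, and the two templates are orthogonal over a full cycle, so a
pure day–night signal cannot leak into the dawn–dusk test. OLS is
unweighted by default with a within-model-variance-weighted option.
Regressors are evaluated at the integer hour; evaluation at h + 0.5 is
available but off. The lunar analysis extracts a covariate × Moon
interaction from a T/ST fit and reports the predicted relative
selection over 0–100% illumination; at 0% it reduces to the main effect
by construction.

## 6. Functional response

Per individual and covariate, the selection ratio is mean covariate at
used points over mean at available points, at each level (landscape:
the individual's MCP-point share against the shared region pool;
home range: its relocations against its own MCP points). The functional
response test is the Pearson correlation of the two levels' ratios
across individuals, separately for individuals classified inside vs
outside the protected core by the majority of their used points.
Proximity to water is kept as raw distance, so ratios above 1 read
"farther from water than available". Individuals with fewer than 30
used rows at a level are excluded with a warning.

## 7. The synthetic world

The generator realizes exactly the model the design estimates, so
recovery is a sharp test of the whole pipeline rather than a loose
plausibility check.

**Landscape.** Gaussian-random-field covariates on a regular grid
(default 30 m; the scaled test world uses 60 m): percent woody cover via
a logistic squash, a smooth DEM, a 5-class land-cover map from quantile
slices of a smooth field, four seasonal NDVI layers sharing a spatial
base with small uniform seasonal offsets (±0.03/±0.08) plus seasonal
texture, and a dense network of meandering river/drainage lines (one
per ~1.7 km of extent) mirroring a fine-scale hydrography layer. TRI,
focal Shannon diversity and water proximity are derived from these
through the same covariate operations applied to real inputs. The
western 55% of the extent is the strictly protected core; three buffer
rectangles tile the east, giving the management-area random factor.

**Tracks.** Range centres are drawn with probability ∝
exp(β_landscape · z̄) of disc-mean standardized covariates. Given a
centre, hourly fixes are independent draws from a truncated-Gaussian
kernel thinned by exp(b(t) · z), with
b(t) = β_within + δ_outside·[outside core] + diel + lunar modulation;
sampling is by rejection against the kernel proposal with an exact
per-fix score bound, and an acceptance collapse raises an error naming
the offending coefficient. Independent draws (a point-process RSF, not
a step model) make likelihood-based recovery exact; a first-order
persistence switch is deliberately absent because serial correlation is
not part of the estimand.

Two generator choices matter for the estimand and were set on explicit
bias diagnostics:

* the kernel is truncated at 0.5 σ (default σ = 4.5 km, so a 2.25 km
  range radius and ~16 km² median MCP), keeping within-range use
  intensity nearly uniform: with a hard-centred kernel the omitted
  radial term attenuates every recovered coefficient under MCP-uniform
  availability;
* drainage density and the NDVI seasonal-offset size control how much
  of a covariate's variance sits *between* home ranges (or seasons)
  rather than within them. Between-stratum variance is absorbed only
  partially by shrunken random intercepts — the classic
  within/between confounding of pooled mixed models — so the generator
  keeps within-range variation dominant. At the shipped settings the
  per-covariate recovery bias is ≤ 0.04 SD.

**Temporal truth.** Coefficients are per landscape SD of each
covariate. Defaults follow the qualitative published pattern (within
ranges: avoid woody cover, prefer heterogeneous/rugged/greener patches
farther from water; outside the core: more cover, farther from water,
flatter terrain), with the spatial contrast sized by a design power
analysis so the generating structure is identifiable at the scaled
experiment size. Moon illumination is the cosine
50·(1 − cos(2π t / 29.53 d)), sampled daily and step-constant within a
date. Local solar time is UTC+3, fixed. Individual start dates are
staggered over a 14-month window so the year and season-within-year
factors have multiple levels.

**Scaled experiment sizes** (the package's standard test conditions):
8 individuals × 1,000 hourly fixes on a 12 km / 60 m landscape with
σ = 1.5 km ranges for recovery and structure identification; 24 × 4,000
on 16 km for cross-validation (the rank statistic needs a few hundred
held-out used points per fold before bin noise stops dominating);
6 × 720 for the diel experiment. Spatial parameters scale together: the
Shannon focal buffer shrinks with the ranges (330 m, preserving the
full-scale buffer-to-range-radius ratio of ~0.44) — leaving it at 1 km
would make SVD nearly constant within the scaled ranges and reintroduce
the between-range confounding described above. Full-scale defaults
(36 × 5,000, 30 m grids, 1 km buffer) match the motivating study's data
shape.

## 8. Conventions for availability rows

The source design leaves undefined what temporal covariates random
points carry. Here each home-range available point inherits a timestamp
drawn uniformly from its individual's relocation timestamps, supplying
hour, season, year and moon values whose marginal distribution matches
the used rows — the construction that makes temporal interaction terms
calibrated under a temporally uniform truth (verified by the lunar
null-recovery test). NDVI for available rows comes from the seasonal
layer of that sampled timestamp (a midpoint-of-tracking-season variant
is available behind `ndvi_season="midpoint"`, but it injects a spurious
used-vs-available NDVI contrast whenever seasonal layers differ in
level, and is not the default). Landscape-level rows have no
timestamps; they carry season-free NDVI (the mean of the seasonal
layers), and available rows are assigned individual ids proportional to
relocation counts so the individual intercept has support on all rows.
Points on polygon boundaries count as inside. Points on missing
background are dropped and counted, not resampled.

## 9. What the validation experiments do and do not show

The synthetic world is stylized: covariates are stationary Gaussian
fields, fixes are serially independent, there is no fix loss, habitat
bias in fix success, location error, behavioural state switching, or
herding. Passing recovery therefore demonstrates that the estimation
machinery is correct and calibrated *for the model it claims to fit* —
it does not show that the RSF model is adequate for any particular real
dataset, and the published real-data coefficients, correlations and F
statistics are not reproducible from this package (the study's data are
external). Known limitations: pooled GLMMs with shrunken intercepts
attenuate selection estimates when between-range availability variance
dominates (see §7) — a property of the standard design itself that
users should keep in mind with small per-individual samples; Wald
intervals condition on the variance components; and the raised-cosine
templates assume fixed peak phases rather than estimating them
(a free-phase cosinor is out of scope).
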