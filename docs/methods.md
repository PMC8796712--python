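# Methods

This note documents the models, defaults and numerical choices behind
zooscankit, and what the synthetic-data tests do and do not demonstrate
about real scanner data.

## Standardization model

Concentrations follow the standard scanner-survey bookkeeping. For a scanned
subsample of a net haul over one depth stratum:

- abundance (ind m⁻³) = (n / F) / V_N
- biovolume (mm³ m⁻³) = (ΣV / F) / V_N
- biomass (mg DM m⁻³) = (ΣDM / F) / V_N

where F is the binary split fraction of the Folsom-splitter subsample
(1 … 1/64, stored as an exact string to avoid float round-off), and
V_N = π·(d/2)²·Δz·e is the filtered volume of a vertical haul with net
diameter d, stratum thickness Δz and filtration efficiency e (default 1,
the theoretical efficiency of a slow vertical haul without flowmeter
correction).

Individual volume uses the prolate-spheroid convention on the fitted ellipse
axes, V = 4/3·π·(major/2)·(minor/2)². Individual dry mass uses DM = a·Aᵇ on
scanned body area; the regression returns µg while biomass is reported in
mg, so a ÷1000 conversion sits between the two (the two formulas are
conventionally quoted in different units without stating the conversion).
Areas outside a coefficient pair's calibrated range produce a warning, not
an error: the ranges describe the data the coefficients were fitted on, not
hard physical limits. Likewise volumes above the 90.083 mm³ "large"
size-class ceiling are accepted.

Multi-object vignettes (overlapping organisms that cannot be separated) are
counted but not measured. They contribute the mean per-individual volume and
dry mass of their taxon, computed from the same sample's measured objects;
when a sample has none, the dataset-wide mean is the fallback. Same-sample
means are the default because body size is strongly depth-structured, and a
global mean would smear that structure across strata. Non-zooplankton
categories (detritus, feces, fiber, leg, bubble, other) are always excluded;
out-of-focus objects ("bad focus") are excluded by default but can be
included via a toggle, since they are typically unidentifiable copepods and
their treatment is a judgement call.

## Morphometrics

The per-object ellipse is the moment-equivalent ellipse of the binary mask
(second-order central moments), not a bounding ellipse; scan-processing
software is ambiguous on this point and the moment convention is the one
used by the underlying image-analysis libraries. Area is the foreground
pixel count × pixel area. The detection limit is applied on equivalent
circular diameter, ECD = 2·√(area/π), with the conventional scanner range
[0.3 mm, 59 mm], both endpoints inclusive; a major-axis-based filter is
available as a config switch. Degenerate masks (single pixels, collinear
pixels) get a one-pixel floor on the moment axes so downstream volumes stay
positive.

## Vertical structure

Depth integration sums value·thickness over strata lying fully above the
integration depth (default 400 m, a stratum boundary); deeper strata are
dropped whole rather than pro-rated, matching how a deepest partial stratum
is conventionally removed for cross-season comparability. Centroid depth is
the value-weighted mean of stratum mid-depths (25, 75, 150, 250, 350, 425 m
for the standard design) and is flagged undefined for an all-zero profile.

The day/night CD contrast tabulates taxa × {day, night} with the CD values
themselves as cells and applies a Pearson chi-square test with
df = (r−1)(c−1) and no continuity correction. Treating centroid depths as
tabled counts is statistically unconventional — CDs are not frequencies —
but it is the construction available when each season has exactly one
unreplicated day and night cast; the table builder is pluggable so a
count-based construction can be substituted.

SIMPER averages, over all between-group sample pairs (j, k), the per-taxon
terms |y_ij − y_ik| / Σ_i(y_ij + y_ik). These terms sum exactly to each
pair's Bray–Curtis dissimilarity, so the mean per-taxon contributions sum to
the mean between-group dissimilarity — an identity the tests verify to
1e−12. Values enter untransformed by default (a transform hook exists); the
reported subset is the minimal descending prefix whose cumulative share
reaches the 70% cutoff. Ties in contribution are broken by the stable sort,
i.e. input column order.

Relative composition pools taxa whose share of the dataset-wide total is
strictly below 3% (configurable) into "other"; a taxon exactly at the
threshold is kept. Seasonal day/night means are plain arithmetic means,
reported unrounded with an optional round-half-to-even display mode.

## Ordination

The RDA is implemented directly (least squares + SVD) rather than delegated,
with the vegan R implementation used only as an independent oracle in the
test suite. Y is log(x+1)-transformed abundance (natural log by default),
column-centred but not standardized (covariance-based RDA); X is the
column-centred per-cast water-column means of temperature, salinity, oxygen
and log(x+1) chlorophyll-a. A per-stratum predictor scope is available as a
switch for designs where samples within one cast should see
stratum-resolved predictors. Constant or collinear predictor columns are
rejected.

Fitted values Ŷ come from `lstsq`; the constrained fraction is
trace(ŶᵀŶ)/trace(YᵀY), axis fractions are S_i²/trace(YᵀY) from the SVD of
Ŷ, site scores are U·S (linear-combination scores), species scores the right
singular vectors, and biplot scores the predictor–axis correlations. The
permutation test permutes rows of Y without restriction (no blocking
structure is assumed), recomputes pseudo-F = (SS_c/q)/(SS_res/(n−q−1)) with
q = rank(X), and reports p = (1 + #{F* ≥ F}) / (1 + n_perm) so p is never 0.
A noise-free response (zero residual) maps to F = ∞ and hence the minimal
attainable p. The default iteration count is 10,000; analyses bundled in the
CLI default to fewer for interactive latency, with the count always
recorded in the output.

## Synthetic communities

The generator emulates the observation chain: per stratum and taxon the net
count is Poisson with mean (profile × seasonal multiplier × V_N); the
scanned subsample is a binomial thinning by the stratum's split fraction.
Thinning a Poisson count gives the scanned count m ~ Poisson(λF), so the
scaled-up estimate m/F has variance λ/F and closed-form recovery standard
errors — the reason for choosing this minimal model. The split exponent per
scan is chosen to keep the expected scan load near 1,000 objects (clipped to
0..6 binary splits), emulating how dense samples are split before scanning.

The default community has 11 taxa over the 0-50-100-200-300-400-450 m
design: seven copepod groups jointly contributing 64–81% of expected
abundance in every season and diel phase (the observed dominance band for
such fjord assemblages), a strong migrator with a daytime maximum at
100–200 m and ~74% of its night population in the upper 50 m, surface-
resident small cyclopoids, and deep-resident large mysids. Abundance peaks
in spring (post-bloom) via per-taxon seasonal multipliers; size
distributions do not change with season, keeping ground truth factorized
into (vertical profile) × (seasonal scalar) × (size distribution).

Body areas are lognormal per taxon, truncated to the intersection of the
taxon's allometric calibration range and sizes above the 0.3 mm ECD
detection limit — generated organisms are all detectable, so the detection
filter exercises its code path without biasing recovery statistics. Aspect
ratios are uniform per taxon; axes follow from area and aspect assuming an
exact ellipse. A configurable fraction of objects (default 5%, always
< 10%) is flagged as unmeasurable multi-object vignette members; junk
objects (detritus etc.) are appended at a default 8% of the scan load.
`with_dvm_amplitude` interpolates night profiles toward day profiles,
providing a clean off-switch for migration in sensitivity tests.

Synthetic CTD casts have a seasonally variable surface layer over stable
deep water (surface temperature 8.6–16.7 °C across seasons, deep ≈ 11.4 °C;
brackish surface salinity over a ≈ 32.9 deep value; a spring surface
chlorophyll-a peak with < 1.8 mg m⁻³ below 25 m) plus small seeded
measurement noise.

What the generator does *not* emulate: image noise and touching-object
scenes, classifier error (taxon labels are always correct), net avoidance
and patchiness beyond Poisson variation, within-season trends, or
taxonomically faithful morphology. Passing recovery tests therefore
demonstrate the correctness of the bookkeeping (splitting, scaling,
integration) under the stated sampling model — not robustness to
misclassification or patchy field distributions.

## Problem sizes and reproducibility

Property-based checks run at sizes chosen to make their statistics stable:
ground-truth recovery uses 100 seeded events across all seasons (≈ 1,100
taxon cells, ≥ 95% required within 3 closed-form SEs); permutation-test
calibration uses 200 null datasets at 499 permutations (rejection rate
required in [0.02, 0.09] at α = 0.05); DVM detection uses 100 paired
day/night events. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; each sampling event derives its own stream, so
stages are individually reproducible.

## Known limitations

- The chi-square on centroid depths inherits the unreplicated design's
  weaknesses; with replication, a paired test on CDs would be preferable.
- The allometric registry covers coarse groups; finer taxa are mapped to
  their group's coefficients via an alias table, and unknown labels are
  rejected rather than silently given generic coefficients.
- RDA assumes linear responses to the (few) predictors and unrestricted
  exchangeability under permutation; seasonal autocorrelation is ignored.
- The moment-equivalent ellipse slightly underestimates axes of noisy or
  concave silhouettes relative to a fitted outline ellipse.
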