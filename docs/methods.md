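# Methods

## Scope and data model

`btsel` analyses repeated daily movement measurements of individually
GPS-tagged male wild turkeys monitored from 1 March to 31 July (153
days), split into three hunting stages per population-year: pre-hunt
(before the season opener), hunt (opener through closing day,
inclusive), and post-hunt (the day after closing through 31 July).
Each bird carries exactly one fate — survived, harvested or predated —
with a fate date for the two mortality classes; harvest (including
crippling loss and illegal kills, which are pooled) can only occur
during the hunt stage, predation in any stage.

Four traits are derived per bird-day:

| trait | units | construction |
|---|---|---|
| distance to hunter access | m | mean over diurnal fixes of the access-point distance surface |
| distance to open landcover | m | mean over diurnal fixes of the open-cover distance surface |
| distance to edge landcover | m | mean over diurnal fixes of the edge distance surface |
| average hourly speed | m/h | total diurnal path length / 15 h |

The diurnal window is 05:00–20:00 inclusive; the nightly (23:58:58) fix
is excluded by default (`include_night` toggles both the distance means
and the path length).  The speed divisor is fixed at 15 hours whatever
the fix schedule (hourly or 30-minute) or the number of fixes actually
received, so undersampled days underestimate speed rather than being
rescaled — matching how a fixed-schedule field dataset behaves.  The
pipeline order is fixed: DOP filter (> 7 discarded; a fix at exactly 7
is kept) → truncation strictly before the fate date → daily metrics →
stage assignment → pooled standardization.  Standardization is the only
step that mixes populations; pooling makes the population fixed effect
the between-site contrast.

## Landscape and distance surfaces

Landscapes are 30 m rasters (ESRI ASCII on disk) of cover
(forest/open) and roads (none/primary/secondary) plus access points
placed on primary-road cells.  Edge cells are forest cells (not
themselves road corridors) with at least one open or road neighbour;
the default neighbourhood is 8-connected (diagonals count), switchable
to 4.  Road cells of both classes count as open for edge adjacency —
roads are unforested corridors — and this choice is configurable
(`roads_as_open`), since the equivalent field workflows differ on it.

Distance surfaces are exact Euclidean distance transforms
(centre-to-centre, planar metres; `scipy.ndimage.distance_transform_edt`
for cell features, a KD-tree for access points).  No geodesic
correction is applied: at a study-area scale of a few kilometres the
planar error is negligible.  A GPS point takes the surface value of its
containing cell (half-open intervals `[x, x + resolution)`), not an
interpolated value, mirroring raster extraction in GIS workflows; the
tests' brute-force oracles use the same semantics.

The synthetic generator grows elliptical open patches from a lognormal
area distribution until the requested open fraction is reached (within
+20%, by construction of the patch-size cap), then lays primary road
transects and shorter secondary segments.  Site presets differ the way
the two study areas do: the Georgia-style preset has ~15% open cover
with large (>10 ha) fields, the South-Carolina-style preset ~5% open
cover in small (<2 ha) food plots.

## Synthetic cohorts: what they emulate and what they do not

`simulate` is the ground-truth oracle for the pipeline.  Per trait it
draws daily standardized values from exactly the model the analysis
later fits — y = μ + β_stage + β_pop + β_stage:pop + b_i + e — and maps
them to raw units by a trait-specific affine transform.  Defaults:

- **Fixed effects and variance components** are the fitted values of
  the two real populations (e.g. speed: V_ind = 0.44, V_e = 0.58,
  hence r ≈ 0.43; distance to edge: 0.35/0.45, r ≈ 0.44).
- **Cohort structure**: 59 Georgia + 50 South Carolina males.  The
  per-bird number of observation days is a truncated normal
  (latent mean 111, SD 30, bounds [7, 153]) capped at the days the bird
  survived; the latent mean is calibrated so the realized cohort mean is
  ~88 repeated measures once mortality truncation is applied.
- **Fates** come from competing logit-linear hazards in the behavioural
  types, p = logistic(α + Σ_t γ_t b_t), resolved as a single categorical
  draw per bird.  The intercepts α are calibrated by root finding
  against the cohort's realized scores so the expected fate frequencies
  match the observed splits (36/13/10 of 59; 29/14/7 of 50).  Default
  selection gradients γ follow the sign pattern of the estimated
  hunter/predator selection at each site, expressed on the death-hazard
  scale.
- **Raw-unit scales** (means/SDs of the back-transform) are chosen so
  that (i) distances stay positive — draws are truncated at zero with a
  warning if more than 0.1% truncate, and the defaults keep truncation
  far below that — and (ii) simulated targets stay achievable on the
  default landscape extents.
- **Season calendars** default to 1 Apr–15 May (Georgia) and
  22 Mar–30 Apr (South Carolina), typical spring seasons which also
  reproduce the observed pre/hunt/post observation shares.

GPS tracks are generated only when asked for: the day's activity centre
is the raster cell whose three distance-surface values best match the
day's target distances (cells within half a step length of the border
are excluded so fixes stay on the raster), and the diurnal fixes
shuttle between two points `centre ± (d/2)·u` on a random axis with
`d = path/steps`, so the summed path equals speed × 15 exactly and the
± symmetry cancels the first-order gradient of the distance surfaces in
the daily means.  Round-tripping tracks through the trait module
recovers distances within one cell width and speed exactly, at daily
movement rates small relative to the raster.  The generator makes no
attempt at behavioural realism (no roosting, flocking or display
movement), so passing tests demonstrate the *statistical* machinery,
not that real turkey telemetry would satisfy, e.g., the homoscedastic
Gaussian residual assumption or the independence of daily records.

## The hierarchical model and its sampler

One univariate Gaussian random-intercept model per standardized trait;
fixed effects are hunting stage (reference pre-hunt), population
(reference Georgia) and their interaction (a stage-only and an
intercept-only formula support per-population refits and testing).
Priors are flat (improper) on fixed effects and half-Student-t(df 3,
scale 2.5) on both standard deviations — the documented defaults of the
standard Bayesian regression software this mirrors.

Sampling is a conjugate Gibbs sampler.  β is drawn from its conditional
with the random effects integrated out analytically (the "collapsed"
update, y ~ N(Xβ, V_e I + V_ind ZZ')), which removes the strong
intercept–mean(u) autocorrelation a naive alternating sampler suffers;
u is then drawn given β; the variances use the Huang–Wand inverse-gamma
parameter expansion (σ²|a ~ IG(ν/2, ν/a), a ~ IG(1/2, 1/A²) ⇔ σ ~
half-t(ν, A)), so every step is a standard conjugate draw.  The default
schedule — 2 chains × 15 300 iterations, burn-in 300, thinning 15 —
retains exactly 2000 draws; `(iterations − burnin)` must divide by the
thinning interval, and retention arithmetic is asserted.  Variances are
floored at 1e−12; chains are seeded from a spawned `SeedSequence`, so
fits are reproducible bit-for-bit.

Convergence is monitored with split R-hat per parameter (variance
components on the log scale); any value ≥ 1.1 flags the fit with a
`ConvergenceWarning` and a `converged = False` field — never silently
accepted — and the CLI `fit` command exits non-zero.  Summaries report
posterior medians, equal-tailed 2.5/97.5% credible intervals (not HPD),
PD (share of draws on the median's side of zero; ties at zero count
toward the median's sign), and ROPE with a default interval of ±0.1 on
the standardized scale — a conventional default, configurable, since no
interval is published for these data.  Variance components are reported
on the variance scale with the SD scale alongside: the published
summary table labels those rows σ but its printed repeatabilities are
only consistent with variances, so both readings are emitted.

Sampler correctness is established two ways: with variances held fixed
the β posterior matches the closed-form GLS solution, and on a
3-individual dataset the posterior means of (β, V_ind, V_e) match a
brute-force 2-D quadrature over (σ_u, σ_e) — with β handled
analytically under its flat prior — within 5%.

## Selection analysis

For each trait × contrast (survived vs harvested → hunter selection;
survived vs predated → predator selection; the third fate is dropped,
not recoded), one logistic regression of binary survival on the
per-draw random-intercept values is fitted for every retained draw:
2000 GLMs per trait under the default schedule.  Fits use Newton/IRLS
batched across draws (tolerance 1e−8, max 100 iterations); a draw that
fails to converge or diverges past |slope| > 50 is treated as separated,
recorded as NaN and counted, and more than 5% failures (configurable)
is a hard error.  BLUPs come from the full-data behavioural fit by
default — all behavioural records inform them, survival subsetting
happens only in the GLM — with per-subset refits available by passing
subset-fitted draws.

Risk traits are negated before fitting (the `flip` flag) so a positive
log-odds ratio uniformly means "riskier individuals survive more"; the
flip negates every per-draw slope exactly and is recorded in the
output's sign-convention column.

The 2000 slopes are aggregated by median, equal-tailed 95% CrI and PD —
the empirical distribution of per-draw point estimates.  **This
deliberately ignores each GLM's own standard error and therefore
understates total uncertainty.**  The understatement is not small: the
spread of the per-draw slopes reflects only posterior BLUP noise, and a
linearization bounds its SD at half the slope's true sampling SD, so
under a null (no selection) the 95% CrI of the slopes excludes zero in
at least ~33% of cohorts rather than 5% — the test suite measures ~54%
at its experimental conditions and documents the discrepancy rather
than hiding it.  Point estimates are also attenuated toward zero
relative to a regression on the true behavioural types (error in the
regressor), which the recovery tests assert.  Users should read the
selection CrIs as "uncertainty given the behavioural model", not as
frequentist confidence intervals; the sign-recovery experiments show
the medians are nevertheless reliable directional estimates at study
size for moderate gradients.

## Reproducibility plumbing

A single master seed drives every stage through a counter-based
`SeedSequence` scheme (`stage_seed(master, stage)`), so stages can be
rerun independently and the full `simulate → derive → fit → select`
chain is byte-reproducible; every CLI command writes a manifest with
file SHA-256 hashes, the seed, the config hash and the package version.
Configurations round-trip losslessly through YAML.  CSV artefacts use
UTF-8, comma separators, ISO-8601 dates and `.` decimals.

## Problem sizes used in the checks

The statistical checks run at sizes chosen to make their Monte-Carlo
error small relative to their tolerances while staying desk-scale:
sampler-vs-quadrature on 3 × 8 observations with 160 000 retained
draws; repeatability recovery over 20 cohorts of 60 birds × 90 days at
a shortened schedule (2000 iterations, 400 retained draws), asserting
the mean posterior-median repeatability within ±0.05 of truth and ≥85%
CrI coverage; selection recovery over 20 study-sized cohorts (59 birds,
60 days) with a harvest gradient of −1 on the edge trait; and the null
calibration over 200 reduced cohorts (30 birds × 15 days).

## Known limitations

- The multivariate behaviour–survival model (among-individual
  correlation between behaviour and survival) is out of scope; the
  per-draw GLM approach is the implemented alternative.
- Selection CrIs understate uncertainty (see above); no Firth-type
  penalty is applied to separated draws by default.
- The movement generator is statistical, not behavioural; landscape
  generation is stylised (elliptical patches, straight roads).
- Real-data ingestion is limited to the documented CSV/ASCII-grid
  formats; cropland-data-layer and road shapefile parsing, reprojection
  and multi-year raster updates are out of scope.
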