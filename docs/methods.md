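# Methods

This note documents the statistical procedures implemented in
`traitflux`, the parameter choices that matter, and the limits of what
the synthetic-data tests demonstrate.

## Data model and preprocessing

A community is a years × taxa matrix of non-negative densities for one
monitoring area and trophic group. Missing sampling years are absent
rows, never zero rows: a zero means "sampled, none caught". Before any
index is computed:

- **Establishment filter.** A taxon is removed when its occurrence
  fraction (years with density > 0 over sampled years) does not exceed
  the threshold (default 0.05) *and* it never occurs in two
  calendar-consecutive sampled years. The boundary counts as rare:
  "once or twice in a 40-year series" includes 2/40 = 5%. The
  denominator is the number of *sampled* years.
- **Cumulative-abundance rule** (applied to zoobenthos in the pipeline):
  taxa ranked by all-years total density (ties broken by identifier);
  the smallest prefix reaching 96% of total abundance is kept. Totals
  are across all years, not per year.
- **ln(x+1) transform.** Used because zero densities occur; applied
  before every density-weighted computation (indices, CWM), switchable
  to raw weights.
- **Imputation** (change-point analysis only): an interior missing year
  takes the mean of the nearest observed value on each side (for an
  isolated gap, the average of the two neighbouring years); boundary
  gaps copy the nearest observed value. Regression and correlation use
  observed years only — no imputation.
- **Anomaly standardisation**: zero mean, unit *sample* (n−1) standard
  deviation; used for DFA inputs and cross-group correlations.

## Trait coding and Gower–Podani dissimilarity

Traits are discrete blocks of categories; each taxon's affinities within
a block sum to 1 (fuzzy coding; single-category taxa have affinity 1).
The pairwise dissimilarity averages per-trait contributions with equal
total weight per trait:

- *Fuzzy and nominal blocks*: each category column contributes
  |aᵢ − aⱼ| / (column range over the taxon pool), weighted 1/(block
  size). Zero-range columns are excluded from numerator and denominator
  (rather than contributing 0/0).
- *Ordinal blocks*: the affinities are collapsed to a weighted mean
  category score, tied-ranked across the pool, and compared with
  Podani's tie-corrected rank formula (one term, weight 1).

Ranges and ranks are pool-relative: they are recomputed on the filtered
taxon pool of each area × group, so distances are comparable within a
pool but not across pools. The result is symmetric, zero-diagonal, in
[0, 1].

## Diversity indices

Per sampled year, with ln-density weights w:

- **SRic** — count of taxa with density > 0.
- **TRic** — count of trait categories with positive summed affinity
  over present taxa (non-weighted; any positive affinity counts).
- **FEve** — computed in the principal-coordinate embedding of the
  Gower–Podani matrix. Because fuzzy-trait Gower matrices are generally
  non-Euclidean, the embedding applies a Cailliez additive correction
  (smallest constant added to off-diagonal distances making the matrix
  Euclidean) whenever a negative eigenvalue below −10⁻⁸ (relative)
  appears; the retained axes then reproduce the corrected distances.
  A minimum spanning tree is built over the present taxa; for each edge
  joining i and j, EW = dist/(wᵢ + wⱼ), PEW = EW/ΣEW, and
  FEve = (Σ min(PEW, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)). Undefined
  (NaN) for S < 3. MST ties are resolved by the deterministic order of
  the sparse-graph routine.
- **FDis** — weighted mean distance to the weighted centroid, computed
  through the signed eigen-decomposition of the dissimilarity matrix:
  squared centroid distances are (real-block) − (imaginary-block)
  squared distances, floored at 0. This honours the published
  definition of the index on non-Euclidean matrices and is invariant to
  rescaling all weights.

## CWM and functional turnover

CWM₍c₎ = Σⱼ wⱼ aⱼc / Σⱼ wⱼ over all categories jointly; the per-block
sum-to-one identity is inherited exactly whenever total weight is
positive (an algebraic identity, property-tested to 10⁻⁹). Turnover is
the Euclidean distance between the CWM vectors of *adjacent sampled*
years, computed on unstandardised CWM values; pairs straddling a missing
sampling year are reported but flagged (`spans_gap`). No imputation is
applied here.

## Dynamic factor analysis

Model: yₜ = Z xₜ + vₜ, xₜ = xₜ₋₁ + wₜ, wₜ ~ N(0, I_m), vₜ ~ N(0, R);
rows of Y are anomaly-standardised CWM series. Identifiability follows
the standard DFA convention: state noise fixed at the identity, the
upper-right triangle of Z fixed at zero, and a fixed diffuse-ish prior
x₁ ~ N(0, (κ+1)I) with κ = 5. R structures: σ²I ("diagonal-equal"),
diag ("diagonal-unequal"), and equal variance with equal off-diagonal
covariance ("equal-varcov", fitted in closed form via the eigenbasis of
the all-ones matrix).

Estimation is EM: the E-step is an exact Kalman filter/RTS smoother
(years whose whole observation vector is missing skip the measurement
update and contribute no likelihood); the M-step solves the
zero-constrained GLS problem for Z (a Kronecker system over the free
entries) and the structure-restricted closed form for R. Because only Z
and R are updated against fixed state dynamics and prior, the observed
log-likelihood is non-decreasing at every iteration (asserted in tests
to 10⁻⁶). Defaults: tolerance 10⁻⁶ on the log-likelihood change,
max 5000 iterations, 3 starts (a deterministic SVD-based initialisation
plus seeded jitters), best likelihood kept. Model selection fits all
m ∈ {1,2,3} × 3 structures and minimises AIC = 2k − 2logL with
k = nm − m(m−1)/2 free loadings plus 1/n/2 R parameters; ties break
toward fewer trends, then the simpler structure. Varimax rotation
(applied jointly to Z and trends, preserving Z·x) and a sign convention
(the largest-|loading| series loads positively) are optional
post-processing; the smoothed trends are not separately centred.

Partially missing observation vectors are rejected rather than handled
approximately: the exact M-step under a non-diagonal R with
time-varying observation subsets loses its closed form, and the data
regime this package targets (whole missing sampling years) never
produces them.

**Recovery simulation design.** The recovery experiments use 12 series
over 40 years driven by m = 2 latent random-walk trends with standard
normal loadings; each noise-free series is standardised and N(0, 0.3²)
observation noise is added on that anomaly scale (so a correctly fitted
model has R ≈ 0.09·I — observation noise sd 0.3 in the model's own
units), then rows are re-standardised. Noise specified relative to the
*unstandardised* trend mixtures would leave post-standardisation
residual variances of order 10⁻², where AIC systematically prefers an
extra trend; on the anomaly scale the criterion identifies m = 2
reliably (20/20 seeds here) with mean canonical correlation ≈ 0.99
between estimated and true trend subspaces.

## Trend tests and cross-group correlation

Each per-year index series is regressed on year by OLS and by GLS with
AR1-correlated errors, both by maximum likelihood so AICs are
comparable: AIC_OLS = 2·3 − 2logL (intercept, slope, σ²) and
AIC_GLS = 2·4 − 2logL (+φ). The AR1 likelihood profiles β and σ² out in
closed form and optimises φ ∈ (−0.98, 0.98) by bounded scalar search;
the correlation matrix uses φ^|tᵢ−tⱼ| on observed years, so gaps are
handled without imputation. The reported p-value is two-sided from the
t-distribution with n − 2 degrees of freedom using the (GLS) covariance
of the slope. A numerically perfect line short-circuits to OLS (the
degenerate zero-variance likelihood would otherwise favour the larger
model on floating-point dust); a constant series returns slope 0 with an
undefined p-value. Measured calibration at T = 40: type-I error ≈ 0.05,
AR1(φ = 0.6) model selected in ≈ 94% of replicates.

Cross-group correlations are Pearson r on anomaly-standardised
overlapping years at lags −1, 0, +1 (positive lag: the second group
lags behind the first); lag 0 is reported unless a lagged correlation
strictly improves |r|. P-values are descriptive (no multiplicity
correction).

## Change-point analysis

Greedy best-first binary segmentation on the Normal likelihood with
per-segment MLE mean and variance (variance floored at 10⁻¹²
with a warning for constant segments); a split is accepted while
2·ΔlogL exceeds the penalty and fewer than Q changes are placed.
Penalties count the p = 2 distribution parameters of a new segment plus
its location: "bic" = (p+1)·ln n and the default "mbic" = (p+2)·ln n
(Zhang–Siegmund modified BIC, the default of the standard change-point
software). The prescribed-looking 2·ln n penalty is *not* offered: the
split statistic is a maximum over ~n candidate locations, and at T = 40
that penalty flags a change on pure N(0,1) noise ≈ 47% of the time,
versus ≈ 8% for MBIC — while 5-sd mean steps are still localised within
±1 year in 100% and sd 1→3 variance steps detected in >90% of seeded
replicates. The gross change-point restricts Q to 1; the detailed run
allows Q ≤ 5 (configurable; min segment length 2 so variances are
estimable). The change year is reported as the last year of the left
segment, in calendar years. Series must be gap-free: the pipeline
applies neighbour-average imputation first.

## Synthetic generator

`generate_community` draws log-densities baseline_j + (Λ·trend)ₜ +
AR1 noise and exponentiates, so latent trends act multiplicatively on
density and densities stay positive, matching the ln-transform
convention. Defaults emulate the monitoring setting: 40 annual samples,
30 taxa, six discrete trait blocks (ordinal size and lifespan, fuzzy
feeding and reproduction, nominal mobility and habitat), two latent
trends with loading scale 0.5, log-scale noise sd 0.3, baseline log
densities N(2, 0.8²), and a 10% fraction of rare taxa. Rare taxa are
*constructed*, not sampled: their density is zeroed except in one or two
non-consecutive sampled years, so the establishment-filter property
holds deterministically. Missing years are dropped rows. One explicit
seeded generator per call; fixed seeds give bit-identical output. The
truth record (trends, loadings, baselines, step change, φ) suffices to
compute the expected noise-free CWM trajectory without re-running the
generator, which the recovery tests exploit.

What the generator does *not* emulate: real taxon identities or pool
structure, salinity/temperature covariates, observation error in trait
assignments, within-year sampling variance, or density compensation
between taxa. Passing recovery tests therefore demonstrates the
estimators work when their assumptions hold, not that those assumptions
hold in any particular field data set.

## Pipeline

`run_pipeline` executes, per area × group: establishment filter →
(zoobenthos) cumulative-abundance rule → ln transform → Gower–Podani
distances → diversity series → CWM → turnover → DFA (AIC selection,
optional rotation) → per-metric trend fits, change-points (after
imputation) and cross-group correlations. Metrics summarised: SRic,
TRic, FEve, FDis, Fturn, and the first two DFA trends T1/T2 (evaluated
at sampled years). The summary marks a direction only at p < 0.05. All
stage outputs are CSVs; a JSON-lines log records shapes, parameters and
timings per stage; reruns from the same config and seed are
byte-identical.

## Problem sizes used in validation

Simulation-based checks run at the sizes stated in their tests: DFA
recovery over 20 seeded panels (12 × 40), trend calibration over 200
replicates of T = 40, change-point recovery over 100 replicates of
T = 40, Gower properties over 200 random trait tables, and index
oracles over all community sizes 2–6 with 10 random draws each. The
pipeline determinism check uses a 16-taxon, 32-year community with a
reduced DFA candidate grid — determinism is a contract of the
orchestration, not a statistical property, so the grid size is
immaterial there.
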