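# Methods

## The problem

Co-occurrence (correlation) networks built from microbiome surveys are
routinely read as interaction networks, but correlation is neither
necessary nor sufficient for interaction: shared habitat preferences
(environmental filtering) correlate non-interacting taxa, and genuine
interactions that play out over days need not produce contemporaneous
correlation at all. With a long, dense time series a stronger notion is
available: taxon A *Granger-causes* taxon B if A's past improves the
prediction of B beyond what B's own past (and everything else's past)
already provides. `grangernet` implements this analysis for genus-level
daily abundance tables, one table per body site.

## Model

For each body site with `n` retained genera, each genus `i` is modelled as

    x_i(t) = c_i + sum_{j=1..n} sum_{k=1..L} B[i][j][k] * x_j(t-k) + e_i(t)

on the processed (relative -> standardized -> first-differenced) scale,
with `L = 20` daily lags. This is one equation of a VAR(L) system fitted
equation by equation; because the penalty is elementwise L1, the joint and
per-equation solutions coincide. Including *all* genera as conditioning
variables is what makes the causality conditional: links created by
sequential driving (A→B→C misread as A→C) or differentially delayed
driving (A→B and A→C misread as B→C) are absorbed by the conditioning set.
It also collapses the hypothesis count from one test per ordered pair
(n(n−1)/2 unordered pairs — 253 at n=23, 1326 at n=52) to one model per
genus (23 or 52), with the expected false-positive count at α=0.05
dropping proportionally (66 → 3 for n=52).

With `n*L` predictors (460 at n=23, 1040 at n=52) against ~330 usable
observations the system is overparameterized, so each equation is fitted
by LASSO:

    min_b  (1/2N) * sum_t (y_t - b0 - x_t.b)^2  +  lambda * ||b||_1

with an unpenalized intercept. A nonzero `B[i][j][k]` is read as "genus j
Granger-causes genus i at lag k, conditional on the community", in units
of response-SD per predictor-SD on the differenced scale. "Significant"
coefficient here means *retained by the LASSO after cross-validated
penalty selection*; no per-coefficient p-values are produced.

## Preprocessing

Applied per site, strictly in this order (each step recorded in a
provenance log):

1. **Prevalence filter** — keep genera detected (nonzero) on ≥ 90% of days
   (inclusive boundary).
2. **Zero imputation** — remaining zeros are treated as sub-detection
   presence and replaced by independent uniform draws on
   `[1e-5 * m, 1e-3 * m]`, `m` the genus's mean over the raw series.
   Imputation happens on the raw scale, *before* normalization, because
   the bound is defined against the series mean and is most interpretable
   there. The imputation seed is derived from the master seed.
3. **Relative abundance** — each day's column closed to sum 1.
4. **Standardization** — each genus centered and scaled by its own mean
   and *sample* (n−1) standard deviation; at T≈350 the sample/population
   distinction is immaterial but must be fixed for reproducibility.
5. **First differencing** — removes stochastic and deterministic trends.
   Differencing happens after standardization, so differenced series do
   not have unit variance; coefficients live on this scale.

Day-index gaps are permitted on input but the lag operator treats columns
as consecutive observations; a warning is emitted when gaps exist.
Interpolation is deliberately out of scope.

## Penalty selection: rolling-origin cross-validation

The usable observations (design rows, `N = T' − L` where `T'` is the
processed length) are split into thirds. The penalty grid holds 50
log-spaced values from `lambda_max` (the smallest penalty with an all-zero
solution, `max_j |<x_j, y − mean(y)>|/N`) down to `lambda_max / 1e4`,
bracketing the all-zero and near-unpenalized extremes. For every grid
value, the model is fitted on the first third and refitted as the
training window grows one observation at a time through the middle third,
scoring each one-step-ahead forecast. The penalty minimizing the mean
squared forecast error (MSFE) wins; exact ties go to the smallest penalty
(least shrinkage), a deterministic rule. The final third provides an
independent validation MSFE at the selected penalty, with the origin still
rolling but no reselection. The final coefficient vector comes from a
fresh fit on the full series at the selected penalty.

## Solver and numerical choices

The L1 problem is solved by cyclic coordinate descent on the centered Gram
system (`G = Xc'Xc`, `c = Xc'yc`), with soft-thresholding updates and the
intercept recovered from the means. Iteration stops when the largest
absolute coefficient change in a sweep falls below `1e-7` (sweep cap
10,000) for standalone fits. Working on the Gram scale makes the per-sweep
cost independent of the window length and lets the rolling CV grow its
training window by rank-one updates (`G += x x'`) instead of refitting
from raw data; solutions are warm-started across both the penalty grid and
consecutive windows. Within the CV loop the tolerance is `1e-5` with a
2000-sweep cap at the first window and a 15-sweep cap per subsequent
step: warm-started solutions move very little per added observation, and
the only slowly-converging region of the grid — the near-unpenalized end,
where columns outnumber rows — is an overfitting regime whose forecasts
lose the MSFE comparison regardless of residual inaccuracy. Predictors are
used as-is (they arrive standardized before differencing) so coefficient
units match the model statement; the intercept is reported but unused
downstream (differenced data are near-centered).

The inner loops are compiled with numba. Correctness of the solver is
pinned in the test suite against four independent oracles: ordinary least
squares at zero penalty, the closed-form soft-threshold solution for a
single orthonormalized predictor, exhaustive enumeration of all supports
and sign patterns on small designs, and scikit-learn's `Lasso` (agreement
to ~1e-9 observed).

## Strong edges, timescales, and summaries

Most retained coefficients are small, so ecological summaries focus on
**strong** coefficients: within a site, positive coefficients at or above
the 95th percentile of the positive ones, and negative coefficients at or
below the 5th percentile of the negative ones (linear interpolation
between order statistics; values tied with the cut are flagged). Lags are
grouped into **short** (1–5 days) and **long** (15–20 days) windows; an
ordered pair's window sign is positive/negative when all in-window
coefficients agree and *conflicting* (excluded from qualitative analyses)
when they mix. The middle window (6–14 days) is reported as its own
category in summaries. Per-genus mean lags are computed over edges where
the genus is the cause (the other convention, effect-side, is a one-line
switch).

## Reshuffling null and overlap filter

Each taxon's processed series is independently permuted over time,
destroying autocorrelation and all cross-lag structure while preserving
marginals — the strongest null consistent with "randomize the time
series". (A column-permutation mode preserving same-day cross-correlation
is available behind a flag.) The full pipeline is re-run on the shuffled
data and its coefficients are scored against the *actual* data's strong
thresholds, never recomputed ones. Ordered pairs strong in both runs are
suspect and removed at the pair level (every lag of a shared pair). One
reshuffled replicate is the default, matching the single-comparison
design; the replicate count is configurable.

## Correlation comparison

Pearson correlation is computed on the same processed series the causal
model consumes, so the comparison is like-for-like (callers may supply an
undifferenced standardized series instead, since the substrate choice is
not fixed by convention); tests are two-sided at α=0.05, unadjusted. Per
timescale window, every ordered interspecific pair is cross-classified as
positive/negative/insignificant under Pearson and under the Granger
timescale call (conflicting pairs excluded), giving a 3×3 table tested
for independence with the classical chi-square statistic (expected counts
from margins, dof = 4, warning when any expected count < 5). A scatter of
correlation against the dominant (largest-magnitude) Granger coefficient
for jointly significant pairs is summarized by a Spearman rank
correlation.

## Cross-site conservation

Sites are compared on shared genera only. Quantitative conservation
requires identical (cause, effect, lag) and sign; qualitative conservation
requires identical (cause, effect), window, and sign — tolerant of
day-level lag differences, as sampling times and growth rates differ
between sites. Self-edges compare by (genus, lag, sign) quantitatively and
(genus, sign) qualitatively. Conserved fractions use the union of the two
sites' in-scope interactions over shared taxa as denominator (a
Jaccard-style measure, symmetric in the sites), reported separately for
interspecific and intraspecific interactions; per-site denominators are a
switch away, since the choice is not uniquely determined by convention.

## Synthetic communities

The generator emulates the data model the analysis assumes, wrapped in the
distortions real sequencing data carries. A latent log-abundance VAR with
a sparse signed coefficient array — every taxon gets a lag-1
self-coefficient of −0.4 (strong negative self-regulation, the dominant
empirical pattern in this kind of data), plus `n_inter_edges` interspecific
edges at lags uniform on 1..L_true with magnitudes in [0.2, 0.6] and 60%
positive — is simulated with Gaussian innovations (sd 0.25) after a
200-step burn-in. Stationarity is certified by the companion-matrix
spectral radius; unstable draws have their interspecific block rescaled
geometrically until the radius drops below 1. Latent states plus per-taxon
baseline offsets (uniform on ±1 log unit, spanning a realistic abundance
range) are exponentiated, closed to proportions, sampled as multinomial
counts at depth 1e5, and counts below a detection floor are zeroed —
producing the compositional, zero-inflated count surface the preprocessing
stage expects. The innovation sd barely affects recovery (the latent VAR
is scale-free after standardization); it sets the abundance CV relative to
multinomial noise, which at depth 1e5 is negligible.

What the generator does *not* emulate: nonlinear (e.g. Lotka–Volterra)
dynamics, overdispersed counts, taxonomic mis-assignment, day-to-day depth
variation, and irregular sampling. Passing recovery tests therefore show
that the pipeline recovers linear lagged structure through the
compositional count observation layer — not that real communities are
linear.

## Problem sizes used in tests and the acceptance script

Recovery benchmarks use 10 genera over 350 days with 12 interspecific
edges of magnitude 0.3–0.6, five (recovery) to ten (null) seeds; the
rolling-CV behavior checks use a single response with three known lagged
drivers (|b| = 0.5, noise sd 0.2, T = 351) and pure-noise controls over
ten seeds. These sizes exercise every stage at full lag order (L = 20)
while keeping a complete run at desk scale. Observed outcomes at these
conditions: interspecific lag-window recall ≈ 1.0, sign accuracy ≥ 0.9,
all self-edges recovered as negative lag-1 coefficients, and reshuffled
strong-pair counts well under half the actual counts.

## Known limitations

- No compositionality correction: closure can induce spurious negative
  dependence. The heavy LASSO shrinkage and the top-5% focus blunt but do
  not remove this; the reshuffling null quantifies the overall
  false-positive burden instead. Log-ratio or SparCC-style estimators are
  deliberately out of scope because they have no straightforward
  multivariate-regression form.
- Differencing a VAR-in-levels induces a moving-average error component;
  coefficient magnitudes are biased toward zero and lag placement can
  shift by a day, which is why the recovery scorer has a ±1-day window
  mode.
- The qualitative conservation fractions depend on the denominator
  convention; both are computed, neither is canonical.
- BIOM input is not supported; tables are tab-separated text.
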