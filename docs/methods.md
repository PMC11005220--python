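# Methods

## The model

The package treats a metabolic-cage recording as a multi-channel time series
sampled every `interval_min` minutes (default 18) over a 72-h analysis window
that follows 48 h of cage acclimation, under a 12:12 photoperiod with lights
on at 07:00. A sample is the half-open interval `[t, t + interval)`; its
light/dark phase is decided by its start time. Energy expenditure, when not
exported by the instrument, is the Weir estimate
`EE [kcal/h] = (3.941·V̇O₂ + 1.106·V̇CO₂)/1000` with gas exchange in ml/h
(absolute, not body-mass-normalized — body weight enters the clock as its own
predictor). The Weir coefficients are pluggable.

The circadian structure of a channel is modeled as a single cosine,

    y(t) = M + A·cos(2π(t − φ)/τ) + ε(t),

with MESOR `M`, amplitude `A`, acrophase `φ` and period `τ`. Period detection
scans a 1-minute grid of candidate periods (default 20–28 h, covering the
≈1423-min EE cycle that does not sit on the 72-h Fourier grid); at each
candidate the series is regressed on an intercept, a *linear trend*, and a
sin/cos pair, and the periodogram ordinate is the partial R² of the harmonic
pair. Estimating the trend jointly matters: pre-detrending lets the fitted
line absorb part of a rhythm whose period does not divide the window, which
biases the recovered period by ~7 min on a 72-h window; the joint fit is
unbiased (checked by simulation). Top periods are local maxima of the power
curve, ranked by power, ties toward the shorter period.

Rhythm parameters are then the OLS cosinor fit at a fixed period: `mesor` =
intercept, `amplitude` = √(β_cos² + β_sin²), `adjphase` = fitted peak time
expressed in minutes after lights-on, wrapped to `[0, τ)`. For a noiseless
cosine the fit is exact for any window length. The phase reference
(lights-on) is a convention of this package and is configurable via the
`t0_min` offset. All animals are fitted at the cohort consensus period
(median of per-animal top-1 periods, or a fixed period such as 1423 min); a
per-mouse-period option exists because either reading of "the same optimal
circadian cycle" is defensible. The rhythm-adjusted mean (`mesor`) is
computed but not a clock feature by default — only Amplitude and Adjphase
enter the 14-predictor set.

## Features

Each animal reduces to 14 predictors: body weight; daily means of the rate
channels V̇O₂, V̇CO₂, RER, EE, Speed; daily totals of the event channels
(Z, Feed, Drink, DistD, XT+YT, SumR+SumL); and the EE cosinor Amplitude and
Adjphase. The rate/total split follows instrument semantics and is
configurable (totals-per-day was chosen over per-hour means for activity
channels; a switch exists). Channels missing ≤5% of samples are linearly
interpolated for rhythm fitting and excluded (not imputed) from daily means;
beyond 5% the channel is rejected. Light/dark-resolved means are computed for
reporting and ordination but never enter the clock feature set.

## The clock

Training uses untreated age-ladder animals only; treated arms are scored,
never trained on. The procedure is two-stage:

1. stratified 70/30 split (largest-remainder allocation per age group, so
   every age reaches the training set; `⌊0.7·n⌋` training animals — 11/6 on a
   17-animal cohort);
2. a 500-tree regression forest (mtry = ⌊p/3⌋, min leaf 5, bootstrap) on all
   14 predictors of the training split; features ranked by **IncNodePurity**,
   the total decrease in node SSE attributable to splits on the feature,
   summed over all trees — the un-normalized impurity importance, computed
   here by walking each tree's node arrays rather than using scikit-learn's
   normalized `feature_importances_`, which is a different statistic
   (ties in the ranking break by the canonical predictor-list order);
3. a sparse forest on the top 6 features, with mtry ∈ {1..6} and min leaf
   ∈ {2, 5} tuned by mean RMSE over 5 repetitions of 10-fold CV on the
   training split (RMSE selects; MAE is reported alongside), refit on the
   whole training split, evaluated on the held-out 30%.

EE age is the sparse model's prediction; group summaries are mean ± SD and
pairwise mean differences. Forest predictions are means of leaf means, so EE
age is bounded by the training age range and quantizes toward the discrete
training ages — an intervention arm with true effective age 53 weeks reads
as ≈56 weeks (the nearest training rung), so a 27-week generated shift is
recovered as a ≈24-week delta. Determinism: a single integer seed fixes the
split, every forest, and the CV folds; identical inputs give bit-identical
predictions. The sparse model serializes to versioned JSON (flat node
arrays), and a library-independent traversal reproduces its predictions
exactly.

## Ordination

Distances are Euclidean on z-scored columns (zero-variance columns dropped
with a warning); signed quantities like Adjphase make abundance-style
metrics inappropriate. PCoA is Gower double-centering + eigendecomposition;
negative eigenvalues are reported and excluded from coordinates. NMDS
minimizes Kruskal stress-1 by alternating isotonic regression (distances on
dissimilarity ranks) with Guttman majorization updates, best of 8 starts
(PCoA configuration + 7 random), a start terminating when stress stops
decreasing — so the recorded stress trajectory is non-increasing by
construction. Axis signs are fixed (first nonzero loading positive) for
bit-reproducible plots.

## Group comparisons

Per parameter: Shapiro–Wilk normality per group and Levene variance
homogeneity; one-way ANOVA (plus Sidak-adjusted pairwise t-tests for >2
groups) iff all screens pass at α = 0.05, else Kruskal–Wallis. Both screen
outcomes are always reported so borderline branch choices are auditable.
Groups with n < 3 or all-constant data yield descriptive-only entries. No
correction is applied across parameters (each metabolic parameter is tested
on its own); the reports say so.

## The synthetic cohort generator

The generator encodes the study conditions the pipeline is meant to analyze;
its defaults are fixed, not tuning knobs. Ladder ages 6, 20, 56, 64, 80
weeks; 72 h at 18-min sampling; lights on 07:00; EE period 1423 min.
Per-age anchors:

| age (wk) | EE mesor (kcal/h) | RER | amp. (frac of mesor) | acrophase (min after lights-on) | weight (g) | activity scale |
|---|---|---|---|---|---|---|
| 6  | 0.60 | 0.75 | 0.300 | 990  | 20.5 | 1.00 |
| 20 | 0.52 | 0.75 | 0.272 | 1001 | 28.0 | 0.90 |
| 56 | 0.40 | 0.75 | 0.199 | 1030 | 33.0 | 0.70 |
| 64 | 0.36 | 0.78 | 0.182 | 1037 | 34.0 | 0.60 |
| 80 | 0.30 | 0.85 | 0.150 | 1050 | 35.5 | 0.50 |

The EE ladder encodes the 50% decline from 6 to 80 weeks and the RER ladder
the 0.75→0.85 rise after 56 weeks; weights increase with age. The remaining
anchors (mesor scale ~0.3–0.6 kcal/h ≈ 7–14 kcal/day, amplitude damping
30%→15%, 60-min phase delay, activity halving, feed 4→3 g/day, drink
5→4 ml/day) are this package's choices of realistic magnitudes for an aging
C57BL/6-scale mouse, not literature-anchored values. Intermediate ages
interpolate monotonically (PCHIP). Noise: stationary AR(1) (ρ = 0.3) with
marginal sd 5% of the mesor; between-animal mesor scatter 5%; RER gets a
0.01-sd animal offset and 0.02-sd AR(1) sample noise. V̇O₂ and V̇CO₂ are
derived by inverting the Weir relation (`V̇O₂ = 1000·EE/(3.941+1.106·RER)`,
`V̇CO₂ = RER·V̇O₂`), so the three channels are exactly consistent. Activity,
feeding and drinking are Poisson event counts with a 3:1 dark:light rate
ratio (nocturnal activity), scaled by the age profile. Interventions are a
pure effective-age shift: every profile parameter is drawn at
`age − shift` while the chronological label is retained.

What the generator does **not** emulate: ultradian feeding bouts and meal
structure, torpor, weekend/handling artifacts, sensor drift and dropouts,
inter-channel noise correlation beyond the Weir identity, and body-weight–EE
allometry. Passing tests therefore demonstrate the pipeline's correctness
and statistical behavior under the encoded aging model, not instrument-level
robustness on real exports.

## Numerical choices and known limits

- Period grid 1200–1680 min at 1-min steps; local maxima require strict
  increase on the left (plateaus count once, leftmost); endpoint maxima
  qualify against their single neighbor.
- A 72-h window covers 3.04 cycles of 1423 min. At the default 5% AR(1)
  noise the period estimator is unbiased with sd ≈ 5–6 min — close to the
  Cramér–Rao bound (≈4 min once the AR(1) noise spectrum at the circadian
  frequency is accounted for), so single-trace period estimates carry an
  irreducible few-minute jitter at this window length; longer windows or
  lower noise tighten it.
- Cosinor designs with condition number > 1e10 raise a conditioning error;
  constant series return amplitude 0 with R² 0.
- Two periods both inside the 20–28-h band are unresolvable in 72 h
  (Rayleigh limit ~1/T); the periodogram reports one merged peak.
- The clock cannot extrapolate beyond the training age range, and its
  predictions quantize toward the training rungs; rejuvenation deltas are
  conservative when the shifted effective age falls between rungs.
- NMDS on strongly clustered data can reach stress ≈ 0 via degenerate
  (collapsed-cluster) configurations; the PCoA start makes this rare but
  rank-tie-rich inputs remain susceptible, as in any Kruskal-stress NMDS.

## Problem sizes

Default desk-scale runs: trajectory and ordination on 12–20 animals (seconds);
clock training on a 40-animal ladder with the full 5×10-fold CV over the
12-configuration grid (≈4–5 min on one CPU, 600 forest fits of 500 trees);
simulation-based checks use 100–200 seeds of single-animal or n=4-per-group
cohorts (seconds to ~1 min).
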