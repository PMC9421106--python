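# Methods

This note documents the modelling choices behind `malnowcast`: what each
stage assumes, the tunable parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical decisions taken where
the design was genuinely open.

## Survey reanalysis

**Z-scores.** Weight-for-height z-scores use the LMS method,
z = ((w/M)^L − 1)/(L·S), with (L, M, S) linearly interpolated between the
reference table's tabulated height keys (log-form limit at L = 0). The
reference is pluggable (CSV with columns sex, key, L, M, S); the bundled
`LmsReferenceTable.synthetic()` is a smooth synthetic stand-in — monotone
median weight, mild skewness, ~9% coefficient of variation — not the WHO
2006 standard, and is clearly labelled as such. Records arriving with a
precomputed WHZ bypass the conversion; heights outside the reference range
leave WHZ missing.

**Exclusions.** Each record receives at most one exclusion reason, in the
fixed order missing → age out of [6, 59] months → flagged outlier. The flag
rule removes records more than 5 z-units from a center that is configurable:
each survey's observed WHZ mean (the default, the convention of the SMART
toolchain) or the reference zero. Both conventions are first-class because
source descriptions of "from the mean" are genuinely ambiguous. MUAC values
are not flagged by the z-rule; optional absolute plausibility bounds
(default 80–220 mm, off by default) can be enabled. Oedema-positive records
are never excluded by the flag rule, since their case status does not depend
on anthropometry. A record with a valid MUAC but no computable WHZ stays
eligible for MUAC-based outcomes: the two case definitions are evaluated
independently, and a record is only "missing" when both indices are absent.

**Case definitions.** WFH basis: SAM = WHZ < −3 or oedema, GAM = WHZ < −2 or
oedema. MUAC basis: SAM = MUAC < 115 mm or oedema, GAM = MUAC < 125 mm or
oedema. SAM ⊆ GAM by construction; MAM = GAM and not SAM.

**Weights.** The ENA-style quality score (0 best … 0.5 worst) is rescaled
linearly to [0, 1] with 1 = best; the analysis weight is quality × sampling
coverage (the accessible fraction of the sampling frame, e.g. 10/12 ≈ 0.83).
Surveys with unknown quality default to the rescaled midpoint 0.5.

**Design-based estimation.** Survey prevalence CIs come from an
intercept-only binomial score sandwich clustered on cluster id, computed in
closed form on the logit scale with a G/(G−1) small-sample factor, and
verified in the tests against statsmodels' cluster-robust GLM. With
singleton clusters this reduces exactly to the model-based binomial
variance. Degenerate prevalences (0 or 1) fall back to Clopper–Pearson;
single-cluster surveys fall back to the unclustered variance with a warning.
Continuous outcomes (mean WHZ/MUAC) use the gaussian analogue.

## Predictor panel engineering

Variables missing for ≥ 30% of strata or ≥ 30% of months are excluded (both
fractions are reported per variable). The 30% rule is evaluated on the raw
panel, before any interpolation — the order is not asserted as the only
defensible one, and the threshold is configurable. Remaining gaps are
filled in three passes: linear interpolation with nearest-value edge fill
for slowly varying series such as humanitarian presence; the 0.7/0.3
nearest-market/mean-of-markets weighted average for price series (falling
back to the market mean when the nearest market is also missing); and
chained-equation imputation for whatever remains, via iterative normal
linear models with posterior sampling, returning a single completed dataset
deterministic in the seed (multiple-imputation stacking is deliberately not
done: one completed panel is what propagates into modelling).

Count variables become per-population rates (per 100 000 by default) using
stratum-month denominators. All time-varying variables get 3-month trailing
rolling means — trailing, never centred, so no future information enters a
now-casting feature; the first months use the shorter available window.
Price and terms-of-trade series additionally get a cubic smoothing spline
over time (roughness penalty λ, default 5.0 — "moderate" operationalised as
a mid-range penalty; splines reproduce linear series exactly for any λ and
approach the least-squares line as λ → ∞, both of which are tested).
Originals are always retained next to derived variables, and imputation
provenance (`is_imputed`) survives every stage.

**Lagged features.** A feature is the mean of a variable over months
t − end … t − start before the reference month, start ≥ 1 so the survey
month itself is never used ("previous 3 months" ≡ months 1–3 prior).
Climate variables admit only the two trimester windows (1–3, 4–6) and the
semester (1–6). A global forecast offset k shifts every window k further
months into the past, turning the now-cast into a k-month forecast — the
offset-by-3 variant equals the corresponding deeper-lag window exactly, and
is tested as such. Windows reaching before the panel start yield missing
features, which downstream stages skip and count.

## GLM track

The chronological split sorts surveys by month and sends the first
⌈0.7 N⌉ to training, extending to the whole boundary month so a month is
never split; an empty holdout raises.

Predictor representation is chosen per variable by the smallest univariate
p-value against the intercept-only null — scaled-deviance chi-square for
quasi-binomial outcomes (the deviance difference divided by the alternative
model's Pearson dispersion), an F-test for gaussian ones — searched over
candidate lags and over continuous vs categorised forms, with ties broken
toward the continuous form and then the shortest lag. Default categorisation
breakpoints are weighted quartiles of the training distribution,
overridable per variable. Under a pure-noise predictor these selection
p-values are uniform, which the suite checks with a Kolmogorov–Smirnov test
over 500 replicates.

All non-empty subsets of the selected specs are enumerated (configurable
cap and maximum model size), fitted as weighted child-level GLMs with
cluster-robust covariance (clusters = survey × cluster id, nested),
collinear columns dropped via QR with a warning, and non-convergent fits
excluded from ranking. Estimates are invariant to rescaling all weights and
to duplicating records at half weight (tested). The Pearson dispersion is
estimated and stored; the coefficient-draw covariance is the cluster
sandwich itself, *not* additionally scaled by the dispersion — the sandwich
already absorbs overdispersion, and scaling twice would double-count it.

Stratum-month prediction aggregates child-level fitted responses; since
features are constant within a stratum-month this equals the single-row
response. Intervals are percentile intervals over multivariate-normal
coefficient draws (default 10⁴; eigenvalue-clipped covariance root),
respecting the link so quasi-binomial predictions always lie in [0, 1]. A
zero covariance degenerates the interval to the point; for gaussian
intercept-only models the percentile interval matches the closed-form
normal interval (tested at 4 × 10⁴ draws).

Shortlisting keeps the best ⌈10%⌉ of rankable candidates by holdout MSE,
ties broken by fewer terms then lexicographic label. Leave-one-out
cross-validation is at survey level — refit on all other surveys' children,
predict the held-out stratum-month — and is applied to the selected model
only, because all-subsets × LOOCV is combinatorially prohibitive.
Interactions are not searched automatically; explicit interaction columns
can be supplied as features. Mixed models are out of scope by design.

## RF track

The aggregated table has one row per surveyed stratum-month (duplicate
surveys of the same stratum-month keep separate rows), the survey's
design-based point estimate as response, and the analysis weight as a case
weight that acts as a sampling weight in the bootstrap draws. Defaults:
1000 trees, mtry = ⌈p/3⌉ (the regression convention), minimum node size 5,
everything seeded. Out-of-bag error is recorded; permutation importance
permutes each feature's one-hot block jointly, with the permutation stream
seeded from the feature *name* so rankings do not depend on column order.

Prediction intervals use the infinitesimal-jackknife variance over
bootstrap inclusion counts with the Monte-Carlo bias correction
(V̂ = Σᵢ Covᵦ(Nᵢᵦ, tᵦ)² − (n/B)·Varᵦ(tᵦ)), floored at zero with a warning,
and normal-quantile 95%/80% intervals truncated to [0, 1] for prevalence
outcomes. A practical calibration note: with trees grown to near-purity at
small n, this estimator is known to run anti-conservative; interval
calibration is therefore validated on forests whose leaves hold ≥ 20
observations, where the suite verifies 95% coverage within a 3-sigma
simulation band of nominal (the band computed from the between-replicate
spread, since test points within one replicate share a training set).
Training-set error is verified to stay below out-of-sample error on every
synthetic world tried — the regime in which forests overfit relative to
GLMs.

## Synthetic-data generator

The generator defines the study conditions. Defaults: 12 strata × 36 months
(scaled down from a national multi-year crisis), populations ~80 000 per
stratum with mild drift, surveys of 30 clusters × 20 children on a random
30% of stratum-months (sparse coverage, as in settings where under a third
of districts are surveyed), oedema prevalence 0.5%, predictor AR(1)
autocorrelation 0.7, block missingness 10% (two-state Markov chain whose
stationary missing probability equals the configured rate, giving
multi-month blocks), intra-cluster correlation 0.05 (latent-threshold
sigma² = icc/(1−icc)·π²/3; a design effect near 2 at 20 children per
cluster). The ICC and missingness defaults are placeholders for quantities
the source data do not report, and are exposed in config. True prevalence is
the inverse-logit of a linear predictor on standardised lagged predictor
features plus livelihood contrasts; default intercepts put GAM-WFH near
15%, SAM-WFH near 3%, GAM-MUAC near 8% and SAM-MUAC near 1.2% — levels
typical of crisis-affected survey series — with shared slopes and nested
intercepts guaranteeing SAM ⊆ GAM.

Two numerical details keep the generator honest. The cluster random effect
is added on the logit scale with a *recentred* intercept (Gauss–Hermite
quadrature plus root finding) so that the marginal prevalence equals the
configured truth exactly — a plain additive effect would bias the marginal
by O(σ²) and break the unbiasedness property the tests assert. Oedema is
folded into the truth: oedema-negative children draw from the adjusted
probability (p − p_oed)/(1 − p_oed), so the total prevalence including the
oedema override still equals truth. WHZ and MUAC are drawn from
truncated-normal mixtures consistent with the drawn status, and raw weight
is back-computed from WHZ through the synthetic LMS reference so that the
reanalysis stage genuinely recomputes z-scores from raw anthropometry.

What the generator does **not** emulate: geographic structure (no
coordinates; the "nearest market" is a configurable mapping, by default the
next stratum), measurement error and digit preference in anthropometry,
age-dependent WHZ distributions, correlation between the WFH and MUAC case
processes within a child, seasonality in survey scheduling, and the real
countries' predictor distributions. Passing tests therefore demonstrate
correctness of the machinery and calibration under the stated data model,
not performance on real crisis data — where measurement noise and
predictor quality are known to dilute predictive accuracy substantially.

## Problem sizes used in validation

The validation suite exercises the pipeline at deliberately graduated
scales, chosen as the package's own balance between statistical resolution
and practicality: coefficient recovery and effective coverage on one
40-strata × 36-month world (432 surveys of 600 children; coverage read over
all 432 surveyed stratum-months); the model-search property over 50
replicate worlds of 8 strata × 24 months with 31 candidate models each;
jackknife calibration over 40 forest replicates of 150 rows; and the
end-to-end determinism check on a miniature world. The acceptance script
reports the full metric set from a 16-strata × 36-month run with surveys of
15 clusters × 15 children.

## Known limitations

* The quasi-binomial "best subset" search treats the holdout MSE as the
  sole ranking criterion; the manual plausibility/parsimony judgement that
  a real analysis would add on top is out of scope.
* The IJ interval is anti-conservative for deeply grown trees at small n
  (documented above); forest intervals should be read accordingly.
* Chained imputation assumes approximate joint normality of the panel
  variables; count variables are imputed on the count scale.
* The generator's predictor effects are time-constant; regime changes
  (droughts, conflict escalations) enter only through the AR(1) series.
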