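# Methods

This note documents the statistical procedures implemented in
`benefitmetrics`, the design choices made where the methodology is
genuinely open, and what the synthetic validation does and does not show.

## Matched-pair construction

Observed treatment effect is only estimable by contrasting two similar
patients with different treatment assignments. The package pairs arms
greedily: each patient of the driving arm, processed in input order (or a
seeded random order), receives the nearest available patient of the other
arm by Mahalanobis distance on the baseline covariates.

* **Covariance scope.** The Mahalanobis metric uses the sample covariance
  of the covariates pooled over both arms (denominator n−1) — the common
  default in matching software. A singular covariance (collinear
  covariates) falls back to the Moore–Penrose pseudo-inverse with a
  warning. Standardizing covariates beforehand is unnecessary: Mahalanobis
  distance is affine-invariant whenever the covariance is full-rank.
* **Replacement.** Without replacement (default) each partner is used at
  most once and the *smaller* arm drives the matching, so every one of its
  patients is paired (n_p = min of the arm sizes). With replacement —
  preferable for clearly unbalanced arms — every untreated patient is
  matched and treated patients may repeat.
* **Determinism.** Ties at equal distance go to the lowest-index candidate;
  given the record order and settings the pairing is reproducible. No
  caliper is imposed. Propensity-based, optimal (non-greedy) and 1:k
  matching are out of scope.

Matching on covariates rather than on predicted effect keeps the observed
pairwise effects identical across candidate models, which is what makes
their metric values comparable.

Pair quantities: L = J − K with J the untreated patient's predicted risk
under control and K the treated patient's predicted risk under treatment;
M = +1 when the untreated patient had the (unfavorable) event and the
treated patient did not, −1 in the mirrored case, 0 otherwise. The
embedded eight-pair worked example stores its published M column verbatim;
note that source's column arithmetic (treated-minus-untreated outcome) is
the mirror of the benefit-positive convention just stated for pairs with
unequal outcomes. All metric formulas consume the stored M values, so the
published metric values are reproduced either way; pairs built by this
package from raw outcomes always use the benefit-positive convention.

## Smoothing

The smoothed calibration values N are a loess fit of M on L: tricube
weights w = (1 − (d/d_max)³)³ over the q = ⌈span·n⌉ nearest neighbors,
local polynomial degree 2, span 0.75, Gaussian family, no robustness
iterations — the standard loess defaults. Points exactly at the window
boundary receive weight zero. Evaluation is exact at every requested point;
no interpolation surface is used. On the eight-pair worked example this
implementation agrees with the published smoothed column at all three
printed decimals.

Numerical details:

* Duplicated x-values (ubiquitous in the duplicated super-population) are
  aggregated analytically before the local solve — the tricube weight
  depends only on x, so replicates collapse to (multiplicity × weight,
  mean response) without changing the estimate. Cost drops from O(n²) to
  O(u²) in the number of unique predictions.
* If a local window holds fewer distinct x-values than the polynomial
  needs, the local degree is lowered (with a warning); a window whose
  bandwidth is zero (all mass at one point) returns the local mean.
* Tiny cohorts that cannot support the configured degree are fitted at the
  largest feasible degree; a cohort whose predictions are all identical
  gets the intercept-only fit N ≡ mean(M).
* The grid evaluator used for plot export refuses to extrapolate outside
  the observed range of L.

## Metrics

* **Calibration-in-the-large.** Two forms are reported: the signed
  mean(M) − mean(L) (positive = effect underestimated), which is the
  package default, and the absolute smoothed form |mean(M) − mean(N)| used
  by the worked example. They answer slightly different questions and need
  not agree; both appear in every report.
* **E-for-benefit.** E_avg = mean|L − N|, E_50 = median, E_90 = 0.9
  quantile with the linear-interpolation convention h = (n−1)p + 1 on the
  sorted values (the convention that reproduces the worked example's
  published 90th percentile). Zero means perfect calibration.
* **C-for-benefit.** Over all unordered pairs of matched pairs with
  unequal M, the fraction where the larger M comes with the larger L.
  Pairs with equal M are uninformative; predicted-value ties (equal L,
  unequal M) are excluded from numerator and denominator, mirroring the
  classical concordance-statistic convention. When no informative
  comparison exists the statistic is reported as undefined, never as 0.5.
  The implementation sorts the three M-classes and counts inversions in
  O(n log n); tests pin it to the exhaustive O(n²) count.
* **Overall performance.** Treating the two patients' outcomes as
  independent Bernoulli draws, the pair's class probabilities are
  p(benefit) = (1−K)·J, p(harm) = K·(1−J), p(no effect) the remainder —
  a point on the 3-simplex by construction. Cross-entropy-for-benefit is
  the mean negative natural log of the probability assigned to the
  observed class, with probabilities clipped to [1e−15, 1] so degenerate
  predictions (risks of exactly 0 or 1) stay finite. Brier-for-benefit is
  the mean squared distance to the one-hot observed class scaled by 1/2,
  which bounds it in [0, 1].
* **Quantile groups.** For calibration plots, pairs are sorted by L and
  split into near-equal groups (default 4); each group reports mean L and
  mean M (its nonparametric ATE estimate).

## Bootstrap

Confidence intervals are percentile intervals from B resamples (default
100, nominal level 0.95) of the *matched pairs* — matching is not redone
inside the bootstrap, since the observed pairwise effects are a property
of the fixed pairing. Each resample reruns the entire pipeline including
re-smoothing. Resamples on which a metric is undefined are dropped for
that metric and counted in the report; if every resample is undefined the
interval is marked unavailable. Percentile intervals may exclude the point
estimate in pathological resamples and are known to undercover mildly at
small n_p; BCa/studentized intervals are out of scope.

## Simulation harness

The harness asks a falsifiable question: do the metrics rank a model known
to be wrong below the model that generated the data?

* **Generator.** n patients (default 2,000) with 12 covariates — six
  correlated standard-normal continuous (AR(1), ρ = 0.3) and six binary
  with prevalences 0.2–0.6 — randomized 1:1, and Bernoulli outcomes from
  the logistic model logit p = β₀ + W·β_W + X·β_X + W·X·β_{W·X}. The
  packaged coefficients (β₀ = −1.0, β_W = −0.81, moderate main effects,
  nonzero interactions) are illustrative of a prevention-trial setting:
  control-arm event rate ≈ 0.33, population ATE ≈ 0.13 on the probability
  scale, per-patient effects spanning roughly −0.07 to +0.38. They are not
  a fit to any real trial.
* **Perturbations.** `ate_over`/`ate_under` multiply β_W by 2/0.5;
  `risk_het` multiplies β_X by 2; `te_het` multiplies β_{W·X} by 3. For
  the two heterogeneity perturbations an offset δ to β_W is found by
  scalar root-finding (monotone in β_W under the logistic link; solved to
  |ΔATE| < 1e−6) so the perturbed model keeps the generating model's
  population ATE — isolating the heterogeneity error. The ATE
  perturbations stay uncorrected, since mis-stating the ATE is their
  purpose. RMSE between each model's per-patient predicted effect and the
  true effect quantifies the perturbation size.
* **Super-population.** The matched pairs are duplicated R times (default
  300) and every copy's outcomes are re-simulated from the generating
  model, pairing retained. This makes metric differences between models
  systematic rather than sampling noise. Whether one should re-match
  within the super-population is an open choice; the original pairing is
  retained here, which keeps the comparison across models exact.
* **Scale used in the shipped tests.** The acceptance-style ordering test
  runs 20 seeds at n = 2,000 and R = 50 (≈48,000 super-population pairs
  per seed) and requires the generating model to be no worse than each of
  the four perturbed models on E_avg, cross-entropy- and
  Brier-for-benefit in at least 19 of 20 seeds; one internal run at these
  sizes takes under a second thanks to the duplicate-aggregating smoother.

What the synthetic validation shows: the metrics detect each perturbation
direction (mean miscalibration, risk heterogeneity, effect heterogeneity)
under a correctly specified logistic world with randomized treatment and
fully observed covariates. What it does not show: behavior under
confounding (observational data), model classes whose miscalibration is
not expressible as coefficient rescaling, informative missingness, or
survival/continuous outcomes — all outside the package's scope.

## Degenerate inputs and numerical conventions

* Treatment and outcome must be exactly 0/1; risks in [0, 1]; missing
  covariates are rejected rather than imputed (impute upstream).
* An empty cohort raises; a single-pair cohort yields defined overall
  metrics, undefined C-for-benefit, and an intercept-only smoother.
* JSON reports carry full-precision numbers; only the human-readable
  `summary()` rounds (3 decimals, matching conventional reporting).
* Local weighted least squares is solved via `numpy.linalg.lstsq`
  (minimum-norm), so rank-deficient local designs cannot crash the fit.
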