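# Methods

`hodvh` evaluates pairs of hip heterotopic-ossification (HO) prophylaxis
plans — a single 7 Gy fraction planned on a water-equivalent (IC-off)
density model and the same plan recalculated with inhomogeneity correction
(IC-on) — and quantifies what the correction changes, dosimetrically and
radiobiologically, at the cohort level.

## Dose–volume histograms

The cumulative DVH `V(D)` is the fraction of the target volume receiving at
least `D` Gy; curves start at `(0 Gy, 1)` on a strictly increasing grid and
are non-increasing. Differentiation assigns the volume lost between
consecutive grid points to a bin at the midpoint dose (a second-order
choice), with residual hot volume at the end of the grid absorbed by a
terminal bin at the last grid dose. The inverse operation places the
cumulative drop of each bin at the bin dose itself (tail-sum convention),
so a differential→cumulative→differential round trip conserves every bin
volume to 1e−9 while bin positions migrate to midpoints. Total volume is
conserved to 1e−9 in all round trips; both directions are exercised by
property tests on random curves.

`D_q%` — the minimum dose to the hottest q% of the volume — is read off the
cumulative curve by linear interpolation in dose; on flat segments the
lowest qualifying dose is used, and if the curve never falls to q% (all of
the residual volume is hotter) the maximum grid dose is returned. This
makes `D_q%` monotone in q and exactly scale-equivariant.

## Plan-quality and radiobiological indices

* HI = (D2% − D98%) / D50% (ICRU 83): 0 for a perfectly uniform target dose.
* GI = V50% / V100% (ICRU 91): ratio of the 50% to 100% prescription
  isodose volumes. These are properties of the whole dose distribution, not
  of the target DVH, so they enter through the cohort manifest per plan.
* gEUD (Niemierko): the a-th power mean `(Σ v_i D_i^a)^(1/a)`; the study
  scenario uses a = 1, the mean dose. Computed in the log domain; for
  a < 0 with a zero-dose bin the power-mean limit 0 is returned.
* LQ-EUD: the uniform dose giving the same clonogen survival as the
  inhomogeneous distribution under linear–quadratic cell kill,
  i.e. the non-negative root `E` of

      α·E + (β/n)·E² = −ln Σ_i v_i · exp(−α·D_i − β·D_i²/n),

  with `β = α/(α/β)` and `n` fractions. The survival sum is accumulated
  with log-sum-exp so large doses cannot underflow, and the root is
  evaluated as `E = 2L / (α + √(α² + 4βL/n))`, which is cancellation-free
  and returns exactly `D` for a uniform DVH at dose `D`. The closed form is
  validated against an independent Brent root-finder on 1000 random DVHs to
  1e−9. Only α/β is clinically specified (3 Gy late, 10 Gy early); the
  absolute α defaults to the conventional 0.3 Gy⁻¹ and is configurable —
  for the near-uniform DVHs of this application the result is insensitive
  to α, and in the uniform limit independent of it.
* EQD2 = D·(d + α/β)/(2 + α/β), with the dose per fraction of the
  equivalent uniform course, d = EUD/n (here n = 1, so d = EUD). EQD2 is
  computed per plan and then averaged, not applied to cohort-mean EUDs; the
  order matters at the 0.01–0.03 Gy level.

A consequence of the LQ form worth knowing: the EUD deficit relative to the
mean dose grows with β (to second order it is ½σ²·(h′² − h″)/h′ with
h(D) = αD + βD²/n), so LQ-EUD at α/β = 3 sits at or below LQ-EUD at
α/β = 10 for any within-plan dose spread.

## Cohort statistics

Per index and arm: mean, sample SD (n − 1), and a z-based 95% CI
(mean ± 1.96·SD/√n — the normal-approximation convention used in this
application area; with n = 21 it is the convention that reproduces
reference CIs such as 7.04–7.12 for 7.08 ± 0.10). Normality is assessed
with the Shapiro–Wilk test (scipy's Royston implementation) and reported
alongside the classical 5% critical-value table (0.908 at n = 21);
the decision uses p < 0.05. Skewness is the adjusted Fisher–Pearson
standardized third moment. `NormalityResult.effect_size` is √(1 − W) — a
descriptive convention of this package (the share of ordered-sample
variation unexplained by the normal-scores fit); it plays no inferential
role.

The paired IC-off/IC-on comparison is the two-sided Wilcoxon signed-rank
test: zero differences dropped, midranks for ties, statistic = smaller
rank sum. For m ≤ 25 remaining pairs the p-value is exact, from the full
null distribution of the signed-rank sum built by the count-distribution
recursion over doubled midranks (identical to enumerating all 2^m sign
assignments, which serves as the test oracle up to m = 12); above m = 25 a
normal approximation with tie-corrected variance Σr²/4 is used, without
continuity correction. Effect size r = |z|/√m. Exact p-values are reported
in full, with no display floor. No multiple-testing adjustment is applied.

## Monte Carlo resampling study

Each of the 14 indices, in each arm, is resampled as n = 10,000 independent
normal draws with the cohort (mean, SD) as location and spread — a
parametric bootstrap of the index summaries. Indices are sampled
independently (no covariance structure is available), so joint behaviour
across indices is not reproduced, only the marginal frequency
distributions. The normal family is untruncated: with the baseline SDs of
this study, negative draws are negligible. Each (index, arm) pair derives
its substream from the master seed plus a CRC-32 hash of its name, so runs
are reproducible and adding indices never perturbs existing streams.
Histogram bin width is configurable (default: 60 equal-width bins over the
sample range). `fraction_below` reports the probability mass short of a
threshold such as the 7 Gy prophylactic dose.

## Synthetic paired cohort

No patient data ship with the package; the generator emulates the study
conditions (21 paired plans) so the pipeline runs end to end.

Each DVH is a capped logistic fall-off:
`V(D) = sigmoid((μ − D)/s) / sigmoid(μ/s)` on a 0.01 Gy grid up to a
per-patient hot-spot cap, where μ is the coverage midpoint (≈D50), s the
penumbra steepness, and the cap μ + a lognormal gap (the residual hot
volume is held at the cap, which then reads out as D2). This is the
simplest two-parameter family able to represent both the tight IC-off
curves (μ ≈ 7.05 Gy, s ≈ 0.12 Gy) and the broad, left-shifted IC-on curves
(μ ≈ 6.85 Gy, s ≈ 0.21 Gy); locations are initialised analytically from
the logistic quantile relation `D_q = μ + s·ln((100 − q)/q)` fitted to the
reference per-arm means.

Per patient, both arms share a latent anatomical shift δ ~ N(0, 0.07 Gy)
with loading 1 in the IC-off arm and 2 in the IC-on arm (the density
correction amplifies the effect of the same anatomy), plus independent
arm noise (SD 0.06 / 0.127 Gy). This reproduces the per-arm D50 SDs
(≈0.10 / 0.19 Gy), keeps IC-on coverage below IC-off for most patients,
and makes the paired tests near-uniformly significant — without copying
any patient-level values. Steepness and cap scales (0.04/0.08 and
0.15 Gy) match the remaining dispersions qualitatively; exact SD matching
is not enforced because the reference SDs entangle unknown per-patient
curve shapes. V100 is lognormal (mean 250 cc, SD 80 cc — a realistic
periarticular CTV isodose volume) and GI = V50/V100 is drawn directly as
1 + lognormal matched to the per-arm GI mean and SD.

Calibration tunes (μ location, s location, cap-gap mean) per arm by
Nelder–Mead on a common-random-numbers cohort of 500 patients, minimizing
tolerance-weighted squared residuals of the cohort means of D2…D98, HI, GI
and gEUD against the reference targets. Acceptance bands: ±0.05 Gy on dose
indices, ±0.02 on HI, ±0.15 on GI; gEUD is additionally weighted as if its
band were 0.02 Gy because it is the principal endpoint of the comparison.
Failure to reach every band raises a calibration error carrying the
best-achieved residuals. Calibration typically converges in ~35 iterations
per arm (≈25 s single-core at n = 500).

What passing tests do and do not show: the generator matches the reference
cohort's marginal index summaries and the direction/significance pattern of
the paired comparison; it does not model anatomy, prosthesis artefacts,
planning-system behaviour, or inter-index correlations beyond those induced
by the shared DVH shape, so conclusions about real patient DVH shapes
cannot be drawn from it.

## Numerical choices and degenerate inputs

* Volume bookkeeping tolerance 1e−9; file reading tolerates (and flattens)
  cumulative-volume noise up to 1e−6 and rejects larger violations naming
  the offending row.
* Flat DVH segments: `D_q%` ties resolve to the lowest dose.
* Constant samples: SD 0 with a degenerate CI; Shapiro–Wilk and skewness
  raise degenerate-input errors; all-zero paired differences raise rather
  than fabricate a p-value.
* Generator redraw guards: steepness is redrawn below 0.03 Gy and the cap
  gap below 0.6·s (cap must stay above the coverage plateau), with a retry
  limit of 100 before erroring.
* All randomness flows through `numpy.random.SeedSequence` with explicit
  spawn keys; identical configuration and seed reproduce every artefact
  byte for byte (the machine-readable summary hashes the scientific
  configuration, not the output location).

## Problem sizes

Default study: 21 patients × 2 arms on 0.01 Gy grids (≈750 points per
curve), calibration cohort n = 500 per arm, Monte Carlo n = 10,000 per
index and arm. The full pipeline including calibration completes in well
under a minute on one core.

## Known limitations

* The generator constrains cohort means (and dispersions qualitatively);
  patient-level values are unidentifiable from published summaries.
* LQ-EUD requires an absolute α the application only pins down as a ratio;
  results quoted here use α = 0.3 Gy⁻¹.
* Exact Wilcoxon p-values below ~1e−6 are attainable at n = 21 only in
  the tail; published analyses that floor p-values will not match digit
  for digit (the package reports exact values).
* No DICOM-RT parsing; DVHs enter as plain-text tables.
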