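# Methods

This note documents the statistical procedures implemented in `clcounts`,
their assumptions, the defaults and the numerical choices, in the order the
analysis runs.

## 1. Data and reconstruction

The unit of analysis is one patient's count of new cortical lesions over a
fixed follow-up window, with a treatment-arm label (`data_io`).  The
built-in 1-year dataset of the four-arm RRMS cohort (untreated, s.c. IFN
beta-1a, i.m. IFN beta-1a, glatiramer acetate) is reconstructed from the
published per-arm percentage frequency tables rather than shipped as raw
data:

* **Largest-remainder (Hamilton) rounding** converts percentages to integer
  counts.  It is the only rounding scheme that guarantees the counts sum
  exactly to the arm size; ties in the fractional parts are broken toward
  lower count values, giving a deterministic result.
* **Arm-size inference.** A printed percentage constrains the arm size
  (27.5% of patients is impossible with n = 50).  For each arm the size
  n ∈ {declared−2, …, declared+3} minimising the worst-cell deviation
  between reproduced and printed percentages is used.  Two arms resolve to
  a different size than declared (untreated: 51 vs 50; i.m. IFN: 50 vs 47),
  giving a 195-patient reconstruction against 191 declared.  The
  percentages are trusted and the discrepancy is logged.  This choice
  leaves every *relative* quantity (coefficients, extra-zeros share, AIC
  ranking, predicted frequencies) essentially unchanged but shifts the
  *absolute* log-likelihood and AIC roughly in proportion to the four extra
  patients (≈ −1.25 log-likelihood units per patient); absolute values
  from a 191-patient cohort are therefore about 3.3 (log-likelihood) and
  6.6 (AIC) away from the reconstruction's, a limit of what printed
  percentages can recover.  `reconstruct_counts(..., n_override=...)`
  forces declared sizes when that trade-off is preferred.
* Counts above the largest printed value are taken as absent (each column
  sums to 100 up to rounding).

## 2. Count models and fitting

Four families (`count_models`): Poisson, NB2 (Var = μ + μ²/ϑ, reported as
inverse dispersion 1/ϑ), ZIP and ZINB.  Zero inflation is a two-component
mixture: a structural-zero probability π plus the core count distribution,
so P(0) = π + (1−π)·P_core(0).  Treatment enters only the count-component
mean through a log link (μ_arm = exp(β₀ + β_arm), reference arm 0); π is a
single shared parameter by default.  That convention means a treatment
coefficient is a log ratio of lesion *rates among lesion-prone patients* —
under shared π this equals the marginal rate ratio.  Per-arm π is available
(`zero_inflation_shared=False`) for the likelihood-ratio check of whether
sharing is tenable.

Numerics:

* Internal parameterization is fully unconstrained: β free, log(1/ϑ),
  logit(π).  Boundary optima (π → 0, 1/ϑ → 0) are then ordinary interior
  descents toward a box edge at logit/log ±12, reported at the optimizer
  value and flagged `boundary` — the tiny 1/ϑ values seen on real fits are
  boundary artifacts, reported as such without special-casing.
* Three fixed starts (moment estimates with small π; moment estimates with
  π set to the pooled zero-excess estimate; all-zeros), plus a
  near-Poisson-limit start (1/ϑ = 10⁻⁴) for the dispersion families.
  L-BFGS-B with objective tolerance 10⁻⁸, followed by a derivative-free
  Nelder-Mead polish, which matters precisely at boundary fits where the
  likelihood is nearly flat in one direction.  Fits are deterministic given
  the data.
* The NB log-pmf evaluates log Γ(k+ϑ) − log Γ(ϑ) as Σ_{j<k} log(ϑ+j) once
  ϑ > 10⁴ to avoid catastrophic cancellation near the Poisson limit; this
  keeps finite-difference Hessians accurate at boundary fits.
* Standard errors come from the inverse observed information
  (central-difference Hessian, step 10⁻⁵·(1+|x|)), delta-transformed to the
  1/ϑ and π scales.  Parameters at a boundary have one-sided curvature and
  get no SE; the information matrix is inverted on the non-boundary block.
* Degenerate data: all-zero datasets are refused for NB/ZINB (dispersion
  not identifiable) and produce a flagged boundary fit for Poisson/ZIP; an
  all-zero *arm* is fitted with a warning (its coefficient runs to the box
  edge).
* The single-arm Poisson/ZIP optima are verified in the test suite against
  a dense grid search (λ × π at 10⁻³ resolution), and the shared-π ZIP
  regression against an independent implementation (statsmodels).

## 3. Model comparison

`model_selection` ranks converged fits by AIC = −2ℓ + 2p.  Nested pairs
(Poisson⊂NB, Poisson⊂ZIP, ZIP⊂ZINB, NB⊂ZINB) get the LR chi-square test;
the mixed-vs-count pairs (Poisson–ZIP, NB–ZIP, NB–ZINB) also get the Vuong
test.  Choices made where conventions differ:

* **Uncorrected Vuong** statistic (no AIC/BIC penalty on Σmᵢ) by default,
  two-sided p; both a correction and a one-sided option are exposed.  The
  boundary-nested Poisson–ZIP pair is still given a Vuong statistic — the
  LR reference there is conservative and practitioners report Vuong for
  zero-inflation comparisons.
* The LR statistic for boundary nestings is referred to the plain χ²₁ tail
  (not the ½χ²₀+½χ²₁ mixture); this is conservative for the zero-inflation
  and dispersion tests and matches common software behaviour.
* A numerically negative LR statistic (null above alternative within
  optimizer tolerance) is clipped to zero with a warning.
* No multiple-testing adjustment is applied across the pairwise tests.

## 4. Trial simulator and sample size

`trial_design` sizes a two-arm active-controlled trial whose endpoint is
the per-patient new-CL count.  Control counts are ZIP(λ_c, π); under the
default `count_mean` mechanism a lesion-reduction effect e gives treatment
counts ZIP((1−e)λ_c, π) — the drug lowers the lesion rate of lesion-prone
patients and leaves the structural-zero fraction alone.  The alternative
`zero_inflation` mechanism instead raises π until the overall mean drops by
e, for sensitivity analyses of drugs that act by making patients
lesion-free.

* **Embedded test.** Default: two-sided Mann-Whitney (Wilcoxon rank-sum)
  with tie-corrected normal approximation.  The rank-sum test is the
  established choice in nonparametric sample-size work for MRI lesion
  counts, and with it the simulator reproduces published CL-based sample
  sizes closely (e.g. ≈72 per arm for a 1-year, 50%-effect design against
  the i.m. IFN comparator).  The model-based alternative
  (`test="wald_zip"`) — a Wald z-test on the treatment coefficient of a
  shared-π two-arm ZIP refit of each simulated trial — is more powerful
  when the ZIP form is true and needs roughly 15–20% fewer patients; the
  package reports both rather than hiding the disagreement.  A replicate
  whose arms cannot be ranked (all observations tied) or whose ZIP fit is
  degenerate (an all-zero arm) counts as a non-rejection.
* **Power** is the rejection fraction over `n_sims` simulated trials
  (default 2000, i.e. Monte-Carlo SE ≈ 0.7 points at 90% power), with every
  replicate on its own seed stream derived from (root seed, n, replicate) —
  results are exactly reproducible and power evaluations at different n are
  independent.
* **Search.** The starting point is the closed-form two-Poisson-rates n,
  (z_{1−α/2}+z_{power})²(1/λ_c+1/λ_t)/log²(λ_t/λ_c), inflated by 1/(1−π);
  doubling/halving brackets the target power, bisection then closes to
  1-patient resolution.  The returned result carries the full evaluated
  power curve and the achieved power with its MC SE.  Because the power
  estimate at each n is itself noisy, the returned n inherits a jitter of a
  few patients across seeds (well within the MC SE bands quoted above);
  raise `n_sims` for tighter grids.
* 2-year designs start from the published 2-year ZIP regression parameters
  (`PUBLISHED_TWO_YEAR_ZIP`), since a 2-year patient-level distribution
  cannot be reconstructed from printed material.

## 5. Synthetic data

`synthetic_data` draws exact samples: structural zeros by Bernoulli(π),
NB cores by the Gamma–Poisson mixture (no pmf inversion or truncation).
Each arm has its own named substream keyed by (seed, arm label), so adding
an arm never perturbs another arm's draws; patient order is shuffled on a
separate substream.  The generator emulates exactly what the models assume
— independent patients, homogeneous parameters within arm, no drop-out, no
reader/scanner noise, no correlation between time points.  Passing
recovery and selection tests therefore validates the estimation machinery,
not the adequacy of the ZIP form for any particular real cohort.

## 6. Predicted frequency tables

`predicted_frequencies` returns 100·P(Y=k) under a fitted model for any
arm.  Whole-dataset regression fits share π (and ϑ) across arms; per-arm
*separate* fits (`fit_single_arm`) let every arm choose its own parameters
and are what published per-arm predicted columns correspond to — for ZIP
the separate fit matches the arm's observed zero fraction and mean
essentially exactly, which a shared-π regression cannot do for every arm
at once.  Both routes are exposed; tables built from separate fits should
be labelled as such.

## 7. Known limitations

* Reconstruction can only be as good as printed rounding allows; the
  191-vs-195 arm-size ambiguity above is irreducible from the published
  tables, and absolute log-likelihoods inherit it.
* Each follow-up window is analysed marginally; no longitudinal correlation
  between the 12- and 24-month counts is modelled.
* Only the treatment arm enters as a covariate; the machinery is not a
  general GLM framework.
* The LR reference for boundary hypotheses is conservative (see §3).
* Sample-size results assume the ZIP generating form and no drop-out;
  the rank-sum default partially insures against misspecification of the
  form, but not against informative missingness.
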