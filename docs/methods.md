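# Methods

## The problem and the models

Polymeric nanoparticle delivery systems release their payload in a
biphasic pattern: a rapid diffusion-dominated burst followed by slow,
erosion-controlled release. Cumulative-release curves Q(t) (percent
released by time t, in hours) digitized from published assays are short —
3 to 14 observations — which rules out most asymptotic machinery and
makes the choice of an empirical release law a genuinely statistical
question.

`relkin` treats that question as linearized model selection. Each
candidate law is transformed to a form linear in its coefficients and fit
by ordinary least squares:

- **zero order** — Q = Q₀ + k₀·t. Constant release rate; the idealized
  baseline.
- **first order** — ln Q = ln Q₀ + k₁·t. Rate proportional to the
  remaining payload; fitted as the log of cumulative release against time
  with a free intercept.
- **Korsmeyer–Peppas power law** — ln Q = ln k_KP + n·ln t. The release
  exponent n encodes the transport mechanism. Because the law is
  classically valid only over the first 60% of release, it enters the
  candidate set twice: fitted to the full curve and to the inclusive
  prefix with Q ≤ 60% (`truncate_60`). Curves that blow through 60%
  within their first two points cannot support the truncated fit and are
  flagged insufficient.
- **Weibull** — ln(−ln(1 − Q/100)) = ln α + β·lnt. Release enters as a
  fraction of 100 because the double-log needs Q ∈ (0, 1); the
  computation uses `log1p` so releases within a few ulp of 0 or 100 stay
  finite. β is the curve-shape factor used later for mechanism reading.
- **hyperbolic tangent** — atanh(Q/Q∞) = β + α·√t. Q∞ is the plateau
  (total release percentage) from dataset metadata, defaulting to the
  observed maximum. Extends a diffusion-type law to the whole curve.
- **polynomials of degree 2–5** — Q = a + b·t + c·t² + …, fitted on raw
  hours with the intercept-first design [t, t², …].

Observations where a transform is undefined (Q ≤ 0 under a log, Q = 100%
for Weibull, Q ≥ Q∞ for the hyperbolic tangent, t = 0 under ln t) are
**dropped with machine-readable reasons, not clipped** — clipping would
invent data. An optional clip mode (relative 1e-6 nudge) exists for
sensitivity checks but is off by default. Every model requires at least
one residual degree of freedom (3 usable points for the two-coefficient
laws, degree + 2 for polynomials).

## Fit statistics

`fit_ols` solves the least-squares problem directly (numpy `lstsq`,
covariance from the inverse normal matrix) and reports coefficients,
standard errors, t statistics with exact t-distribution two-tailed
p-values at the residual degrees of freedom, the overall F test against
the intercept-only (or zero) null, R², adjusted R², and the
SSR/SSE/SST decomposition. Regression through the origin reports the
**uncentered** R² (SST = ΣQ²), the convention standard linear-model
summaries use for no-intercept fits, so with- and without-intercept fits
are each compared the way their own reference output would print them.

AIC and BIC use the Gaussian likelihood with the error variance counted
as a fitted parameter (k = p + 1 for p regression coefficients):

    AIC = n ln 2π + n ln(SSE/n) + n + 2(p + 1)
    BIC = n ln 2π + n ln(SSE/n) + n + ln(n)·(p + 1)

This is the convention of R's `AIC()`/`broom::glance`, and it is what the
test suite cross-checks against an independent reference implementation
(statsmodels log-likelihood) to 1e-8 on random small designs.

**Exact fits.** Saturating polynomials on tiny curves produce SSE = 0.
Rather than crash, the fit is flagged `perfect_fit`, AIC/BIC become a
−∞ sentinel (best possible), and coefficients that are numerically zero
in an exact fit (|b| ≤ 1e-10 relative) are assigned t = 0 / p = 1 — an
exact fit provides no evidence for a term whose estimate is zero, which
is precisely the "collapses to a lower degree" situation the last-term
rule must reject.

## The decision tree

Per (dataset, model): fit with intercept; if the intercept fails its
significance test, refit through the origin (**recalculated**); if the
slope — for polynomials, the highest-order term only — fails, **reject**
(a polynomial whose last term is zero is a lower-degree model);
if the overall F test fails, **reject**; otherwise **accept**. With one
predictor and an intercept the F and slope-t tests coincide exactly, and
the suite asserts that identity.

Significance is configurable: `p_value` (p ≤ α with the exact t
distribution, default α = 0.05) or `critical_1_96` (|t| ≥ 1.96, the
large-sample two-tailed cut). At the n of these curves the two can
disagree — at 3 residual degrees of freedom the 5% critical value is
3.18, not 1.96 — and the tests pin a fixture where one rule accepts the
intercept and the other refits.

Ranking over surviving models: adjusted R² primary with R² tiebreak
(fit-quality view), AIC primary with BIC tiebreak (information view).
Criteria equal to within 1e-12 — including −∞/−∞ sentinel ties — fall
back to parsimony (fewer coefficients), then registry order. The
truncated and full power law compete as distinct candidates; when a curve
never exceeds 60% they are the same fit and registry order decides.
Corpus summaries report per-model best shares (denominator: all datasets,
no-model sets included) and the criterion-agreement fraction (datasets
where both views name the same model, excluding double-none sets).

## Bootstrap

Case (pairs) resampling of the **linearized** points at the original n,
refitting the plain with-intercept OLS per replicate — no accept/reject
decisions inside the loop, and no re-deriving of exclusion sets (the
transform domain is fixed before resampling). Summaries are replicate
means of the coefficients, R² and AIC, plus 2.5/97.5 percentile
intervals; "bootstrap-corrected AIC" here means the mean replicate AIC,
the simplest scalar faithful to a per-model bootstrap table. Default
1000 replicates, seed mandatory for published runs (default 20220310),
and identical inputs reproduce summaries bit for bit.

Replicates whose resampled design has fewer distinct predictor values
than coefficients + 1 are **discarded and counted, never redrawn**
(redrawing would distort the resampling distribution). This covers the
rank-deficient all-x-equal case and also the saturated case (exactly k
distinct values), which would yield SSE = 0 and drive the mean AIC to
−∞ on every short curve; requiring a residual degree of freedom keeps
the bootstrap AIC a finite, comparable quantity. Measured on
well-specified zero-order simulations, the CI coverage is identical
under the narrower all-equal-only rule, so the stricter rule costs
nothing in interval behavior.

**Known limitation — percentile coverage at tiny n.** Percentile
intervals carry O(1/n) coverage error. On well-specified zero-order
curves with 10 observations and 2-percentage-point noise, measured
coverage of the nominal 95% slope interval is ≈ 90% (2000 simulations);
it rises to ≈ 92% at 14 observations. Bias-corrected (BCa) or
studentized intervals would repair this but are deliberately out of
scope; percentile is what this workflow reports. Consumers should read
the intervals as approximate at the corpus's typical n.

The bootstrap ranking (`bootstrap_best_model`, most negative mean AIC
wins, mean R² as the secondary view, parsimony on 1e-12 ties) needs no
significance tests, so it adjudicates 3-point curves the deterministic
pipeline cannot.

## Mechanism interpretation

Weibull β classifies curve shape: parabolic (β < 1), exponential
(β = 1 within 1e-9), sigmoidal (β > 1); the literature overlay maps
β ≤ 0.75 to Fickian diffusion, 0.75 < β < 1 to anomalous transport, and
β ≥ 1 to relaxation/erosion-controlled (case-II type) transport. β and
the release exponent n are taken from each curve's **final** fit after
the decision tree (the origin refit when applied). Across a corpus,
an OLS line β = a + b·n evaluated at reference exponents translates the
classical n thresholds into β values; the defaults are the
spherical-geometry constants n = 0.43 (Fickian) and 0.85 (case II),
surfaced in the API so users can match slabs or cylinders.

## Synthetic data

The generator evaluates a registered model on a time grid (log- or
linear-spaced within 0–504 h), adds independent Gaussian noise **on the
percent scale** (σ = 2 percentage points by default — measurement error
lives in the assay readout, and the transforms then induce exactly the
heteroscedasticity the linearized fits face), clips to [0, 100], and by
default enforces monotone non-decreasing release with a running maximum
(cumulative release is physical; the clamp is a toggle for stress
tests). When noise pushes observations past an intended plateau the
dataset plateau widens to keep Q∞ ≥ max(Q) valid. Ground truth travels
in metadata under reserved `sim_*` keys.

`corpus_like_batch` draws observation counts from the empirical 3–14
distribution of published corpora (mode at 6 points), spans log-uniform
in [3, 504] h, plateaus uniform in [30, 100]%, and models from a mixture
weighted toward the hyperbolic tangent and Weibull shapes that dominate
biphasic release data. Parameters are solved so each curve reaches its
plateau at the end of its span. What passing tests on these curves do
**not** show: real digitized curves have correlated digitization error,
occasional non-monotone jitter, and model misspecification that no
registry member captures; the generator emulates shape and noise scale,
not provenance.

`recover_parameters` repeats simulate → refit → rank and reports bias
and RMSE of the slope-level parameter (k₀, k₁, n, Weibull β, tanh α) and
how often each ranking view picks the generator.

## Numerical choices and scales

- Times in hours, release in percent throughout; model transforms
  convert internally (Weibull divides by 100, the tanh model by Q∞).
- Test and acceptance problem sizes: 200 random designs for the OLS
  oracle, 10-point noise-free curves for recovery, 500 simulations ×
  1000 replicates for CI coverage, 40-curve synthetic corpora with full
  bootstrap for the workflow run — all chosen to give stable Monte-Carlo
  estimates in seconds on one CPU.
- Polynomial designs in raw hours are ill-conditioned at high degree on
  long spans; noise-free recovery fixtures use day-scale grids, and
  recovery there is asserted on curve reproduction (1e-8) plus relative
  coefficients (1e-5), versus 1e-8 absolute for the kinetic laws.
- Degenerate inputs: all-equal predictors raise `DegenerateDesign`; too
  few usable points raise `InsufficientData` and surface as the ID cell
  in decision matrices; an all-zero response through the origin fits
  slope 0 with SSE 0 rather than erroring.
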