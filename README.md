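# relkin — statistical comparison of drug-release kinetics models

`relkin` is a toolkit for deciding which empirical release law best
describes a cumulative drug-release curve, aimed at formulation scientists
working with polymeric nanoparticle delivery systems (e.g. PLGA
nanoparticles made by nanoprecipitation), where digitized dissolution
curves are short (3–14 points) and noisy.

Given curves of cumulative percent released Q(t) over time (hours), the
package:

1. **fits ten candidate models by linearized least squares** —

   | model | linear form |
   |---|---|
   | zero order | Q(t) = Q₀ + k₀·t |
   | first order | ln Q(t) = ln Q₀ + k₁·t |
   | Korsmeyer–Peppas (power law) | ln Q(t) = ln k_KP + n·ln t |
   | Weibull | ln(−ln(1 − Q(t)/100)) = ln α + β·ln t |
   | hyperbolic tangent | atanh(Q(t)/Q∞) = β + α·√t |
   | polynomials (2nd–5th) | Q(t) = a + b·t + c·t² + … |

   The power law is fitted both to the full curve and to the prefix with
   Q ≤ 60% (its classical validity region); the hyperbolic tangent model
   normalizes by the plateau Q∞.

2. **applies significance-based accept/recalculate/reject rules** — a
   non-significant intercept triggers a refit through the origin
   ("recalculated"); a non-significant slope (or highest polynomial term)
   or overall F test rejects the model. Both the exact t-distribution
   p-value rule and the large-sample |t| ≥ 1.96 cut are available.

3. **ranks the survivors** by adjusted R² (R² tiebreak) and by AIC (BIC
   tiebreak), where AIC/BIC use the Gaussian likelihood with the error
   variance counted as a parameter.

4. **bootstraps small curves** — case resampling of the linearized points,
   1000 replicates by default, with percentile 95% confidence intervals
   and bootstrap-averaged R²/AIC, so even 3-point curves can be ranked.

5. **reads transport mechanism off the shape parameters** — Weibull β
   (parabolic < 1, exponential = 1, sigmoidal > 1; Fickian diffusion for
   β ≤ 0.75) and the Korsmeyer–Peppas release exponent n, including a
   corpus-level β-versus-n calibration line.

A seeded synthetic-data generator produces corpus-like curves (burst +
sustained shapes, 3–504 h spans, 30–100% plateaus, percent-scale Gaussian
noise) for testing and parameter-recovery experiments.

## Worked example

```python
import numpy as np
import relkin as rk

ds = rk.ReleaseDataset(
    id="demo",
    times=np.array([1.0, 2.0, 4.0, 8.0, 16.0, 24.0]),     # hours
    release=np.array([12.0, 20.0, 33.0, 48.0, 62.0, 70.0]),  # cumulative %
)
print(rk.validate(ds))

outcomes = next(iter(rk.evaluate_all([ds]).values()))
for o in outcomes:
    if o.final_fit:
        print(f"{o.model_name:22s} {o.cell():2s} "
              f"r2_adj={o.final_fit.r2_adj: .4f} aic={o.final_fit.aic: .2f}")
v = rk.rank_models(outcomes)
print("best by R2a:", v.best_by_r2, "| best by AIC:", v.best_by_ic)
```

prints

```
['n = 6 < 8 observations; statistical conclusions are weak']
zero_order             A  r2_adj= 0.8680 aic= 46.14
first_order            A  r2_adj= 0.6738 aic= 9.39
korsmeyer_peppas_100   A  r2_adj= 0.9701 aic=-4.95
korsmeyer_peppas_60    A  r2_adj= 0.9927 aic=-9.15
weibull                A  r2_adj= 0.9910 aic=-9.35
hyperbolic_tangent     A  r2_adj= 0.9918 aic=-13.46
poly2                  RC r2_adj= 0.9807 aic= 42.83
poly3                  RC r2_adj= 0.9977 aic= 30.23
poly4                  RC r2_adj= 0.9997 aic= 17.26
poly5                  ID
best by R2a: poly4 | best by AIC: hyperbolic_tangent
```

Cells read A = accepted, RC = intercept recalculated to zero then
accepted, X = rejected, ID = insufficient data. The high-degree
polynomials chase the six points (inflated adjusted R²) but pay for their
coefficients under AIC; the hyperbolic tangent law wins the
information-criterion view. Mechanism interpretation and a bootstrap of
the winning fit:

```python
rep = rk.mechanism_report(ds)
# beta 0.709 parabolic fickian n 0.556
b = rk.bootstrap_fit(ds, "hyperbolic_tangent", n_boot=1000, seed=20220310)
# alpha 0.402, 95% CI [0.3392, 0.449], R2_boot 0.9963, AIC_boot -19.23
```

A Weibull β of 0.71 (parabolic, β ≤ 0.75) together with n ≈ 0.56 points
to diffusion-dominated release.

## Command line

```sh
relkin simulate --n 40 --seed 1 --out curves.csv          # synthetic corpus
relkin fit --input curves.csv --metadata curves.meta.csv \
    --bootstrap --seed 1 --out results/                   # full workflow
relkin mechanism --input curves.csv --out mechanism.csv
```

`fit` writes per-model fit records, the dataset × model decision matrix,
best-model verdicts, bootstrap tables, a mechanism report, a corpus
summary, and a provenance log (config hash, seed, versions, timings).

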