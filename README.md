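# slabspline

Dose–response regression for **semicontinuous exposures** — variables with a
point mass at exactly zero (non-users) and a continuous distribution over
positive values, such as a filled opioid dose in morphine milligram
equivalents (MME). The package is aimed at biostatisticians and
pharmacoepidemiologists who need to estimate

```
Δ(x) = E[Y | X = x] − E[Y | X = 0]
```

without the **safe-dose assumption**: any model whose exposure terms all
vanish at zero (a plain linear term, an ordinary spline) forces
Δ̂(x) → 0 and SE(Δ̂(x)) → 0 as x → 0 — for the simple linear model,
Var(Δ̂(x)) = x²·Var(β̂₁) exactly. That combination can manufacture an
apparently safe, precisely estimated low-dose range where none exists.

Two remedies are provided as ordinary design-matrix columns:

* **spike-at-zero** — the indicator 1(x > 0) gives exposed observations
  their own intercept, so E[Y|X=x] = β₀ + β₁1(x>0) + β₂x yields
  Δ(x) = β₁ + β₂x and Var(Δ̂(x)) → Var(β̂₁) > 0 as x → 0;
* **slab-and-spline** — a natural cubic spline whose span is constrained to
  first derivative zero at (and left of) the lower boundary knot, so the
  exposed-group curve is a constant "slab" below the first knot that joins
  the spline with a continuous derivative. Paired with the spike it spends
  one fewer degree of freedom than spike + spline, useful when the low-dose
  range is sparsely populated.

All nine modeling strategies compared in the accompanying Monte-Carlo study
(linear/quadratic/categorical/spline, with and without spike, slab-and-
spline, and zero-dose exclusion) are available as declarative specs, fitted
by OLS with Huber-White (optionally cluster-robust) sandwich covariance and
delta-method pointwise confidence bands.

## Worked example

Run a small Monte-Carlo comparison (dose scenario 1: doses are 0 with
probability 0.25, otherwise 2·Beta(1, 5); outcome
Y = 10 + 0.5·1(X>0) − 2.4X + 4.8X² + N(0, 1.5²)):

```python
import numpy as np
import slabspline as ss

cfg = ss.scenario_config(1, spike=True, N=1000, M=200, seed=42)
specs = [s for s in ss.catalog_models() if s.strategy_id in (1, 6, 8)]
res = ss.run_scenario(cfg, specs, grid=np.array([0.025, 0.2, 0.8]))
print(res.metrics[["strategy_id", "dose", "true_delta", "mean_estimate",
                   "empirical_se", "average_se", "coverage"]]
      .round(3).to_string(index=False))
```

```
 strategy_id  dose  true_delta  mean_estimate  empirical_se  average_se  coverage
           1 0.025       0.443          0.056         0.005       0.005     0.000
           1 0.200       0.212          0.452         0.042       0.044     0.000
           1 0.800       1.652          1.807         0.169       0.174     0.865
           6 0.025       0.443          0.416         0.136       0.139     0.960
           6 0.200       0.212          0.244         0.105       0.113     0.975
           6 0.800       1.652          1.854         0.139       0.146     0.735
           8 0.025       0.443          0.339         0.103       0.111     0.860
           8 0.200       0.212          0.339         0.103       0.111     0.770
           8 0.800       1.652          1.646         0.129       0.130     0.950
```

Reading the low-dose rows: the linear no-spike model (strategy 1) reports a
tiny effect (0.056 vs the true 0.443) with a tiny standard error (0.005) and
**zero** coverage — high confidence in the wrong answer, the safe-dose
signature. The spiked spline (strategy 6) is nearly unbiased there with an
honest SE (≈0.14) and ~95% coverage; `empirical_se` (SD of estimates across
replicates) and `average_se` (mean model-based SE) agree, indicating
calibrated uncertainty. The slab-and-spline (strategy 8) flattens the curve
below its first knot (7/16) — identical estimates at 0.025 and 0.2 — trading
some bias where the truth still moves within the slab for one fewer degree
of freedom; above the knot it tracks the truth closely (dose 0.8: estimate
1.646 vs truth 1.652, coverage 0.950).

The same machinery is exposed on the command line:

```sh
slabspline simulate --config bundled:scenario1_spike --out-dir out/   # metrics CSV
slabspline make-fixture --out fixture.csv                             # synthetic claims-like data
slabspline fit --data fixture.csv --strategy 6 --knot-scale 300 \
    --cluster-col cluster --covariates age,parity --out-dir out/      # coefficients + curve CSV
slabspline basis --kind slab --knots 0.4375,0.625,0.8125 --out basis.csv
```

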