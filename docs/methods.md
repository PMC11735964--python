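# Methods

## The estimand and the safe-dose assumption

For a semicontinuous dose X (P(X = 0) > 0, continuous on X > 0) and a
continuous outcome Y, the estimand is the dose–response difference
Δ(x) = E[Y|X=x] − E[Y|X=0]. A regression E[Y|X=x] = β₀ + f_β(x) with
f_β(x) → 0 as x → 0⁺ embeds the *safe-dose assumption*: Δ̂(x) and its
standard error are forced to 0 at the origin (for the simple linear model,
Var(Δ̂(x)) = x²Var(β̂₁) identically). When the truth has a discontinuity at
zero — filling a prescription at all changes the trajectory — such models
are biased at low doses *and* overconfident about the biased estimate.

Two design-matrix remedies avoid this:

* **Spike at zero.** Adding 1(x > 0) gives E[Y|X=x] = β₀ + β₁1(x>0) + f(x)
  with anchored f (f(0) = 0), so Δ(x) = β₁ + f(x) and
  Var(Δ̂(x)) = Var(β̂₁) + Var(f̂(x)) + 2Cov ≥ 0 with limit Var(β̂₁) at 0⁺.
  (The delta-method expansion for the linear case is
  Var(β̂₁) + x²Var(β̂₂) + 2x·Cov(β̂₁, β̂₂).)
* **Slab and spline.** For sparse low-dose regions, the natural-spline span
  is restricted to members with f′(t₁) = 0 at the lower boundary knot t₁.
  Since a natural spline is linear left of t₁, members are constant
  ("slab") on [0, t₁) and join the interior curve with a continuous first
  derivative. The model pairs this basis with the spike indicator, so the
  zero-dose group keeps its own intercept while all exposed low-dose
  observations share one level: one fewer degree of freedom than
  spike + unconstrained spline. Without the spike, the slab would absorb
  the zero-dose group and re-impose Δ̂ ≡ 0 below t₁ — precisely the
  pathology being avoided — so the spike is part of the slab model here.

## Basis constructions

**Natural cubic spline (`basis.ncs_basis`).** Built from interpolating
cardinal splines: column j is the natural cubic spline interpolant of the
j-th unit vector at the knots (computed with a standard natural-boundary
cubic-spline routine), continued *linearly* beyond the boundary knots
(natural boundaries zero the second derivative there, so the continuation is
C²). The cardinal functions sum to 1, so dropping one leaves K−1 columns
that, with the intercept, span the K-dimensional natural-spline space. Any
basis with the same span yields identical fits; the test suite verifies span
equivalence against an independent truncated-power construction
(projection residual < 1e−8 on random knot sets).

**Anchoring.** Every spline column has its value at dose 0 subtracted. This
is an affine reparametrization — fitted curves and all Δ̂ contrasts are
unchanged (verified by a dual-route test) — but it makes zero-dose rows
intercept-only, so alongside a spike the spike coefficient is directly the
limiting effect of an infinitesimally small dose, and β̂₀ equals the
zero-dose outcome mean exactly (separability, tested to 1e−10).

**Slab basis (`basis.slab_spline_basis`).** The row vector of analytic
column derivatives at t₁ is computed from the cardinal-spline derivative;
the NCS columns are multiplied by an orthonormal basis of its null space.
This is convention-independent and testable: the resulting fit equals
equality-constrained least squares (KKT solve) with the single constraint
f′(t₁) = 0, to 1e−8 in residual norm. K knots give K−2 columns.

**Categories (`basis.dose_categories`).** Dose 0 is its own category;
positive doses fall in left-open right-closed bins, the last open above the
top break. Category boundaries follow the printed convention (0, 1/3],
(1/3, 2/3], > 2/3 for the study's categorical model.

**Knot placement.** The catalog's knots/breaks (1/8, 1/2, 7/8; 1/3, 1/2,
2/3; 7/16, 5/8, 13/16; breaks 1/3, 2/3) are absolute dose values. A
`knot_scale` multiplier lets callers express them as fractions of their
dose scale instead (used, e.g., when fitting MME-scale data).

## Estimation

OLS via QR least squares. Uncertainty uses the Huber-White sandwich
(X′X)⁻¹M(X′X)⁻¹ with per-observation meat X′diag(e²)X, or within-cluster
score sums for cluster-robust inference. Default small-sample factor is
HC1's n/(n−p) (clusters: G/(G−1)·(n−1)/(n−p)); HC0 is selectable. At the
study's n = 1000 the choice is immaterial. Rank deficiency is detected by
pivoted QR and reported naming the offending columns; empty dose categories
are dropped from the design (with occupancy counts kept) rather than
aborting, and grid doses needing a dropped level are flagged missing.

Δ̂(x) is the linear contrast c′β̂ with c = (design row at x) − (design row at
the reference); covariate entries cancel, so covariate values never enter
the curve. SE(Δ̂(x)) = √(c′Vc); bands use normal quantiles (1.96 at 95%,
configurable level). The reference is dose 0 except for the zero-excluding
strategy, whose reference is the minimum observed positive dose (a different
estimand; grid points below it are reported missing, and in the simulation
its truth is shifted by Δ(x_ref) per replicate).

## Data-generating mechanisms

Doses: 0 with probability p₀ = 0.25, else γ_X·Beta(α_X, β_X). Scenario 1:
α_X = 1, β_X = 5, γ_X = 2 (dense low-dose range); scenario 2: α_X = 6,
β_X = 5, γ_X = 1 (sparse low-dose range). Outcomes:
Y = 10 + β₁1(X>0) − 2.4X + 4.8X² + ε, ε ~ N(0, 1.5²), with spike effect
β₁ = 0.5 (spike present) or 0 (no spike). Beta draws that underflow to
exactly 0 are redrawn so 1(X>0) stays exact. Default sample size N = 1000
per replicate.

The synthetic claims-like fixture (`simgen.generate_applied_fixture`)
emulates only the *shape* of a pharmacy-claims analysis — 45% zero mass,
gamma-distributed positive MME doses, a semicontinuous outcome, repeated
cluster ids, two covariates. It exercises the fit/cluster/covariate code
paths end to end; it does not reproduce any real cohort's moments, so
passing fixture tests demonstrates plumbing, not real-data validity.
Likewise the simulation's Gaussian, homoskedastic errors and exact quadratic
truth mean that "correct-model" results here do not speak to robustness
under real-data misspecification beyond the shapes studied.

## Monte-Carlo engine

Per scenario, M replicates (default M = 500 for desk-scale runs — the MC SE
of a coverage estimate near 0.95 is then ≈ 0.0097 — with M = 5000 feasible
via config). Each replicate draws a sample from an independent RNG
substream spawned from the master seed, fits every requested strategy, and
evaluates Δ̂ and its SE on the grid; per-model failures are recorded with a
reason code, never aborting. Aggregation is streaming (Welford one-pass
mean/SD), so no per-replicate storage is needed; results are independent of
execution order. Reported per model × dose: truth, mean estimate, bias,
empirical SE (SD of estimates), average SE (mean model SE), coverage of
estimate ± 1.96·SE against the truth, and the contributing replicate count
(cells where a model failed or a point was unrepresentable are excluded
from the denominator).

Evaluation grid: {0.01, 0.025, 0.05} ∪ 19 evenly spaced points on
[0.05·γ_X, 0.95·γ_X]. The fixed low points probe the region where the
safe-dose assumption bites; the spread covers the support. The grid is a
package default and fully overridable.

## Numerical choices

* C¹ verification of the slab join uses central differences with step 1e−5
  and tolerance 1e−6 — well above double-precision noise.
* Basis span comparisons use QR projection residuals (< 1e−8 relative).
* The sandwich is symmetrized ((V+V′)/2) and the HC1 factor applied to the
  final product so HC1 = factor·HC0 holds bit-exactly.
* CSVs are written with shortest-round-trip float formatting; exact re-read
  requires a round-trip float parser (`float_precision="round_trip"` in
  pandas), which the round-trip test uses.
* Seeds: a master integer seed spawns per-replicate substreams
  (`SeedSequence.spawn`); identical seeds give bit-identical outputs.

## Known limitations

* **Sandwich SEs at extrapolated doses.** Under scenario 1, P(X > 1.5) ≈
  7·10⁻⁴, so grid doses ≳ 1.2 rest on quadratic extrapolation from a
  handful of high-leverage observations. There the HC0/HC1 sandwich is
  biased downward (high-leverage residuals are shrunk): measured true
  coverage of nominal 95% intervals from the *correctly specified* model is
  ≈ 0.937 at doses 1.2–1.9 (M = 3000), versus 0.950 for classical
  homoskedastic intervals, which are exact under this mechanism. Coverage
  summaries over the full default grid therefore dip a little below 0.95 at
  the extreme tail; within the data-supported range (doses ≤ 0.9) coverage
  is at nominal. Leverage-adjusted variants (HC2/HC3) would mitigate this
  but are outside the estimator family studied.
* The slab model is deliberately stiff below its first knot: when the true
  curve moves within [0, t₁), the slab trades bias for stability — visible
  in the worked example at dose 0.2.
* Only continuous outcomes and OLS are supported; GLMs, survival outcomes,
  multiple imputation, and confounding-adjustment machinery (weighting,
  propensity methods) are out of scope.
* The categorical model's inference ignores the data-driven possibility of
  empty categories (cells are simply dropped and counted).
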