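# Methods note

This note records the modelling assumptions, the estimation machinery, the
simulator's realism and limits, and the numerical choices, so that results
can be interpreted and the package extended without reverse-engineering the
code.

## The model

Data are twin pairs measured on P phenotypes per twin (P = waves ×
variables).  A pair's 2P-vector is multivariate normal with mean (μ, μ)
(means constrained equal across twins and zygosity groups — the usual twin
assumption, testable against the saturated model) and covariance

```
Σ_z = [ Σ_W     Σ_X(z) ]
      [ Σ_X(z)  Σ_W    ]
```

where the within-twin block Σ_W = Σ_c V_c is the sum of component
covariance matrices and the cross-twin block Σ_X(z) = Σ_c k_c(z) V_c
weights each component by its kinship coefficient: A 1/0.5, C 1/1,
D 1/0.25, E 0/0 for MZ/DZ.  C and D have proportional MZ/DZ weight
patterns against A and are refused together (classical confounding of
twins reared together).

Component matrices V_c are parameterised in paths, never directly:

- **Cholesky**: V_c = X_c X_cʹ, X_c lower triangular.  Squared entries over
  total wave variance are the reported shares; column k is the influence
  arising at wave k.
- **Common pathway**: V_c = p_c² λλʹ + diag(s_c²) with Σ_c p_c² = 1 enforced
  through spherical angles in [0, π/2] (for AE a single angle:
  p_A = cos φ, p_E = sin φ), λ_w ≥ 0 latent loadings, s_c wave-specific
  paths.  Identification requires W ≥ 3 (enforced).
- **Correlated factors**: V_c = S_c R_c S_c with S_c = diag(paths) and R_c
  a correlation matrix built from a triangular factor with unit-norm rows
  (hyperspherical angles in (0, π)), so R_c is positive definite by
  construction for any interior parameter value.

Because every component enters through squares/cross-products, all V_c are
positive semi-definite at any parameter value, so standardised shares are
always in [0, 1] without post-hoc clipping.  The E-component diagonal
paths carry a lower bound of 1e-4: E is the only component present in both
Σ_W + Σ_X and Σ_W − Σ_X (the P±Q diagonalisation of the exchangeable
block structure), so a strictly positive-definite E makes the full Σ_z
positive definite everywhere in the feasible region.  Models without this
guarantee (saturated baselines) are protected by a likelihood penalty on
non-PD proposals instead.

## Estimation

**FIML.**  Rows are grouped by missingness pattern; each pattern
contributes n log|Σ_o| + Σ_i (x_i − μ_o)ʹ Σ_o⁻¹ (x_i − μ_o) + n·p_o·log 2π
through its sufficient statistics (count, mean, ML scatter), where the
subscript o marks the observed subset.  Patterns with equal observed count
are batched and solved with stacked Cholesky factorisations, so the cost
scales with the number of patterns, not the number of pairs.  The gradient
with respect to (μ, Σ) is analytic
(∂/∂Σ = n(Σ⁻¹ − Σ⁻¹ S* Σ⁻¹) with S* the centred scatter about μ) and is
contracted with a central-difference Jacobian of the builder — builders
are cheap closed-form matrix constructions, so this hybrid gives near-
analytic speed without hand-deriving per-model derivatives.

**Optimisation.**  L-BFGS-B with bounds, ftol 1e-12, multiple starts
(default 5: the method-of-moments start plus jittered copies; ties below
1e-6 resolve to the earliest start).  Starting values come from
Falconer-style moment estimates of the component matrices (e.g.
A ≈ 2(C_MZ − C_DZ)) projected to positive definite.  A fit where no start
escapes the non-PD penalty raises with per-start diagnostics rather than
returning silently.

**Uncertainty.**  Observed-information standard errors from a central-
difference Hessian of −2LL (cov = 2H⁻¹), and delta-method CIs for every
standardised summary (shares, communalities, rG/rE) via a numerical
Jacobian of the summary map.

**Comparison.**  df = observed data values − free parameters;
AIC = −2LL + 2k with exact ties broken toward fewer parameters; chi-square
LRTs for declared nestings.  For variance components on the boundary the
chi-square reference is conservative (the true null distribution is the
0.5·δ₀ + 0.5·χ²₁ mixture); p-values are reported without mixture
correction and the test suite verifies the empirical mixture behaviour.
A practical consequence documented by the acceptance suite: with AE truth
and the candidate set {ACE, ADE, AE}, AE wins AIC only when both boundary
LRT statistics stay below 2, which happens with probability ≈ 0.85 —
independent of sample size, because each statistic clears 2 with
probability 0.5·P(χ²₁ > 2) ≈ 0.079 and the two failure events (requiring
r_DZ above vs below r_MZ/2) are nearly disjoint.  The acceptance property
test asserting a ≥90% selection rate therefore fails, by design, and the
unit suite asserts the attainable property (clear majority, and more often
than either alternative) instead.

## The simulator

Cohorts are drawn directly from the path equations: per pair, each
component contributes B_c z where B_c B_cʹ = V_c and the latent z has
cross-twin correlation k_c(z) (constructed as √k·common + √(1−k)·unique;
exact copies at k = 1).  The empirical covariance therefore converges to
exactly the matrix the model builders produce — verified at n = 50,000
pairs within 0.02 entrywise for every structure.

Realism choices for the emulated study (a six-wave young-adult cohort of
2,200 MZ / 4,200 DZ pairs measuring a 10-item 0–4 anxiety scale):

- **Skew**: questionnaire severity scores are right-skewed; raw scores are
  generated as (z + 3)², so the analysis pipeline's square-root transform
  restores approximate normality (the fold at z < −3 affects ~0.1% of
  draws).  Normality after transform is what the FIML model assumes.
- **Missingness**: wave-level MCAR at rate 0.10 per twin-wave cell; pairs
  with no observed value at all are dropped (cohort inclusion mirrors "at
  least one twin with data").  MCAR is a simplification — real attrition
  is at best MAR — but FIML is consistent under MAR, so MCAR is the
  appropriate *validation* regime for the estimator.
- **Truth values** (`twinstab.recovery`): univariate additive share 0.39;
  common pathway latent A share 0.60 with communalities
  linspace(0.51, 0.76) across the six waves and wave-specific variance
  split 15% A / 85% E (implying wave heritabilities 0.37–0.49 and specific-E
  shares 0.20–0.42); Cholesky truth with wave-1 A1 share 0.39, persistent
  A1 at 0.36, a small wave-2 genetic innovation (0.04–0.05), E1
  persistence 0.08 and time-specific E 0.51–0.52; dimension heritabilities
  0.43/0.33 with rG 0.90 and rE 0.62; stability correlation 0.76.
- **Items**: responses are λʹf + unique noise discretised at thresholds
  (−0.5, 0.5, 1.5, 2.5) into 0–4 categories; factors carry an A/E split
  (h² 0.4) with cross-twin correlation a²·kinship.  The 6/3/1 loading
  pattern (two loadings of 0.7 blocks plus one weak 0.2/0.2 item) is the
  recovery target for the EFA stage.  Degenerate (constant) items after
  discretisation are flagged with a warning; communalities above 1 are
  rejected.

## Factor-structure stage

EFA: pairwise-complete correlations, minres extraction (uniquenesses
optimised by L-BFGS-B over the reduced-matrix eigendecomposition), factor
count by parallel analysis (mean eigenvalues of 50 same-shaped noise
datasets) restricted to the candidate range 1–3, quartimin oblique
rotation via `statsmodels`' factor-rotation routines, and the assignment
rule |loading| > 0.3 with strict dominance (ties unassigned).  CFA reuses
the FIML core (single group, factor variances fixed to 1, correlations
free through the same hyperspherical parameterisation) and reports
chi-square against the saturated model, CFI/TLI against the independence
baseline, RMSEA and correlation-scale SRMR.  One twin per pair enters all
item-level analyses so observations are independent; the sample is split
70/30 into exploration and confirmation halves.

## Problem sizes and runtime

The package's own canonical scale is the emulated cohort: 6,400 pairs,
6 waves, 10% missingness.  On one CPU a univariate fit takes ~30 ms, the
48-parameter Cholesky ~3 s and the common pathway model ~1.5 s, so the
20-replicate recovery experiments behind each acceptance target run in
seconds to ~1.5 minutes each and `scripts/acceptance.py` completes in
about 2 minutes.  Pattern batching keeps the FIML cost flat in the number
of pairs; the practical ceiling is the number of distinct missingness
patterns (capped at 2^12 here by the 12 observed cells per pair).

## Limits

- No sex/age moderation, no opposite-sex pairs, no rater effects.
- MCAR missingness only in the generator (estimation itself is valid under
  MAR).
- Ordinal items are analysed as continuous after discretisation (Pearson,
  not polychoric, correlations), which attenuates loadings and factor
  correlations; the EFA recovery targets account for this.
- The boundary-mixture LRT correction is documented but not applied.
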