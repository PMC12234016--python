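# twinstab

Longitudinal twin models of phenotypic stability: a two-group FIML
structured-covariance engine with the classical biometric model families,
plus the phenotypic and psychometric stages that surround them in a real
twin study, and a ground-truthed cohort simulator to validate all of it.

## The science

Repeatedly measuring the same trait in monozygotic (MZ) and dizygotic (DZ)
twin pairs makes it possible to ask not just *how heritable* a trait is,
but *why it is stable*: do the same genetic influences persist across
occasions, or is stability environmentally maintained?  The package
implements the full modelling ladder used for this question:

- **Univariate ACE/ADE/AE/CE/E models** per occasion: cross-twin
  covariances weighted by kinship coefficients (A: 1/0.5, C: 1/1,
  D: 1/0.25, E: 0/0 for MZ/DZ) decompose phenotypic variance into additive
  genetic (A), shared environmental (C), dominance (D) and non-shared
  environmental (E) parts.  C and D are not jointly identifiable in twins
  reared together and are refused together.
- **Cholesky decomposition** across waves: each component's covariance is a
  lower-triangular path matrix times its transpose, so factor k's loadings
  on waves k..W quantify continuity of influences arising at wave k and the
  diagonal quantifies innovation.
- **Common pathway model**: a single latent stability factor (its unit
  variance split between A and E) loads on every wave; occasion-specific
  residuals carry their own A/E split.  The latent factor's A share is the
  heritability *of stability itself*.
- **Correlated-factor model** for multiple symptom dimensions: per-variable
  A/E variances with genetic (rG) and environmental (rE) correlations
  between dimensions.
- **Phenotypic stage**: square-root transform for right-skewed severity
  scores, one-twin-per-pair stability correlations with Fisher confidence
  intervals, double-entered cross-twin correlations, Cronbach's alpha, and
  split-sample EFA (minres extraction, parallel analysis, quartimin
  rotation) with confirmatory factor analysis fitted by the same FIML core.

Everything is estimated by full-information maximum likelihood on the raw
(incomplete) data: each missingness pattern contributes its own
marginalised multivariate-normal likelihood, so pairs with any observed
wave stay in the analysis.  Model comparison uses AIC with likelihood-ratio
tests for declared nestings, against saturated and constrained-saturated
baselines.

## Worked example

Simulate a six-wave cohort under a common pathway truth with latent
heritability 0.60 and wave communalities rising from 0.51 to 0.76
(right-skewed raw scores, 10% wave-level missingness), then fit the model:

```python
from twinstab import models
from twinstab.biometric import build_common_pathway, standardize
from twinstab.data import sqrt_transform
from twinstab.recovery import cpm_truth
from twinstab.simulate import simulate

data, truth = simulate(cpm_truth(seed=20240901))   # 2,200 MZ + 4,200 DZ pairs
groups = sqrt_transform(data).group_arrays()        # [MZ, DZ] pair arrays
res = models.fit(build_common_pathway(6, data=groups), groups, n_starts=2)
est = standardize(res)
print(round(est.latent_heritability, 3))
print([round(c, 3) for c in est.communalities])
```

```
0.604
[0.513, 0.565, 0.62, 0.664, 0.714, 0.758]
```

The latent A share and the communality gradient recover the generating
truth.  The same cohort through the numbered drivers (see below) gives the
per-wave Cholesky picture — a persistent first genetic factor next to
largely time-specific environment:

```
 wave  A1_share  A_total  E1_share  E_specific
    1  0.353953 0.353953  0.646047    0.646047
    2  0.296383 0.408176  0.074506    0.517319
    ...
    6  0.367132 0.489820  0.107226    0.266694
```

The same models are available from the command line:

```bash
twinstab simulate --config sim.yaml --out cohort.csv
twinstab fit-cpm cohort.csv --family AE --out cpm.json
twinstab run-study --config study.yaml --outdir results/run
```

## Repository layout

- `src/twinstab/` — the library; all computation lives here.
  - `fiml.py` pattern-wise FIML likelihood core with analytic gradients
  - `models.py` model specs, multistart L-BFGS-B fitting, saturated baselines
  - `biometric.py` Cholesky / common pathway / correlated-factor builders
  - `data.py` dataset container, CSV I/O, transforms, twin correlations
  - `simulate.py` ground-truthed cohort and item-level simulators
  - `selection.py` AIC comparison and likelihood-ratio tests
  - `factors.py` EFA (minres, parallel analysis, quartimin) and FIML CFA
  - `pipeline.py` / `cli.py` end-to-end study driver and `twinstab` CLI
- `analysis/` — numbered thin drivers (`01_simulate_cohort.py` …
  `07_correlated_factors.py`) that run the study sequence and write tables
  under `results/`.
- `tests/` — unit, property (hypothesis, derandomised) and acceptance
  tests.
- `scripts/acceptance.py` — recomputes every recovery target from scratch.
- `docs/methods.md` — modelling and numerical methods note.

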