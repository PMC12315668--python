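# clpnet — cross-lagged panel networks for executive function and psychopathology

`clpnet` implements a cross-lagged panel network (CLPN) analysis of the
dynamic interplay between executive functions (working memory,
inhibitory control) and broad-band psychopathology (internalizing,
externalizing symptoms) across three adolescent assessment waves
(mean ages ≈ 10.2, 13.5, 18.2 years). Because the cohort it emulates is
licensed and cannot be redistributed, the package ships a calibrated
synthetic-cohort generator as a first-class, tested component: every
downstream stage can be exercised — and validated against known
ground truth — without any data download.

## The model

For each wave transition *t* → *t+1*, every node
*y<sub>j</sub><sup>(t+1)</sup>* (internalizing, externalizing,
working-memory aggregate, inverted go/no-go RT, inverted commission
errors; all z-scored within wave) is regressed on **all** nodes at wave
*t* plus predictor-only covariates (age, optionally gender):

  y⁽ᵗ⁺¹⁾ⱼ = β₀ⱼ + Σᵢ βᵢⱼ yᵢ⁽ᵗ⁾ + γⱼ·age⁽ᵗ⁾ + ε,

with the LASSO penalty λΣ|β| and λ chosen per node by 10-fold
cross-validation (CV-minimum rule by default, one-SE rule as an
option). The solver is a from-scratch cyclic coordinate descent with
soft-thresholding, verified against closed forms, KKT conditions, and an
exact sign-pattern enumeration oracle. The βᵢⱼ assemble into a directed
source × target matrix: off-diagonal entries are cross-lagged edges,
the diagonal carries autoregressive effects, and covariates have no
incoming edges. Edge-weight accuracy is assessed by a nonparametric
participant bootstrap (CV re-selection inside every replicate), and each
(EF, symptom) pair is classified from the presence of its two directed
edges: EF → symptom only = *risk factor*, symptom → EF only =
*consequence*, both = *both*.

The synthetic generator evolves five latent constructs under a known
sparse lag matrix per wave pair (spectral radius < 1), observes them
through a measurement layer (two span indicators correlating r = 0.46,
binomial commission errors out of 25 no-go trials, Gaussian RT, CBCL- or
ABCL-scaled symptom sums with the ABCL at age ≥ 18), oversamples a
high-risk stratum (60.89%), and applies monotone informative dropout
calibrated to 35.14% whose probability *decreases* with wave-1
internalizing.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_fit_networks.py
```

prints (cohort of n = 1,992, seed 11):

```
simulated 1992 participants (seed 11)
  high-risk fraction: 0.6225 (target 0.6089)
  attrition rate:     0.3524 (target 0.3514)
  digit/corsi r at wave 1: 0.442 (target 0.46)
  observed per wave: {1: 1992, 2: 1638, 3: 1290}
wave pair (1, 2): 1992 -> 1635 complete cases; 4 outlier cells removed; 3270 node-table rows
wave pair (2, 3): 1992 -> 1288 complete cases; 4 outlier cells removed; 2576 node-table rows
waves 1->2: n=1635, density 0.72 (18/25 nonzero lagged edges)
waves 2->3: n=1288, density 0.92 (23/25 nonzero lagged edges)
support overlap (Jaccard): 0.71; weight correlation: 0.82
```

The calibration lines show the generator hitting its cohort-composition
targets at sampling precision. The density lines count nonzero entries
of the 5×5 lagged coefficient matrix (autoregressive diagonal included,
covariate edges excluded): the middle-adolescence network is denser and
more reciprocal than the early one. `04_bootstrap_stability.py`
(b = 1,000 participant resamples) adds per-edge percentile intervals and
inclusion proportions, `05_classify_accounts.py` prints the
risk-factor/consequence table, and `06_recovery_experiment.py` scores
estimated supports against generator truth over a sample-size grid.
Small summary artifacts land in `results/`; bulky regenerable panels in
`scratch/`.

Library use mirrors the scripts:

```python
from clpnet import default_config, simulate_cohort, build_node_table, fit_clpn

panel = simulate_cohort(default_config(2000, seed=1))
table, report = build_node_table(panel, wave_pair=(1, 2))
net = fit_clpn(table, (1, 2), covariates=("age",), k=10, seed=2)
print(net.to_matrix_frame().round(2))
```

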