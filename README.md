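# panelweight

Case-mix–weighted primary care panel sizes from routinely collected EHR
encounter data.

Raw panel counts treat every empaneled patient as equal work, but patients
differ enormously in the primary care effort they demand. `panelweight`
implements an EHR-derived weighting method for health systems that empanel
patients to primary care physicians (PCPs): it phenotypes each patient from
two years of encounter counts, consolidates the phenotypes into work
clusters, and solves population-conserving cluster weights so that a
provider's *weighted* panel size reflects the case mix they actually carry.
It is written for health-system analysts and population-health researchers;
a synthetic EHR generator makes the whole pipeline runnable and testable
without any protected data.

## The method

For each patient and 12-month window a **visit vector** of annual encounter
counts is built over ~12 encounter categories (PCP office visits, missed
appointments, urgent care, telephone encounters, ED visits, emergent and
elective hospitalizations, specialty visits, infusion, transfusion,
radiology/procedures, and secure messages by direction), with two
adjustments:

- **Effective PCP visits** — each office visit is weighted by the active
  medication count at that visit: weight 1 for ≤ 5 medications, 1.5 for
  6–10, 1.75 for > 10; the effective count is the sum of weights.
- **Specialty capping** — per specialty, annual counts are truncated at
  `mean + 2·SD` among that specialty's users before summing, so
  high-frequency specialties (e.g. weekly dermatology treatments) do not
  dominate. With caps of 15.8 (dermatology) and 6.7 (cardiology), a patient
  with 20 dermatology and 2 cardiology visits contributes 17.8.

**Utilization phenotypes A–G.** Decision rules first: patients with raw PCP
counts more than 6 SD above the population mean are *high outliers* (G);
patients with ≤ 1 PCP visit, 0 ED visits, 0 hospitalizations, ≤ 4 specialty
visits, ≤ 2 telephone encounters and ≤ 6 messages received are *minimally
active* (A); those with no activity at all (missed appointments excluded)
are *inactive*. Everyone else is clustered by k-means (k = 4, 5 random
restarts, ≤ 10 iterations, raw visits/year, deliberately unstandardised —
capping is the only scale control) on all categories except messaging; the
lowest-ranked cluster (by median raw PCP visits) is split in two by a second
k-means. The five clustered groups are labelled B–F in ascending order of
median raw PCP visits.

**Work clusters and weights.** Phenotypes collapse into intermediate groups
X/Y/Z (default {A,B}→X, {C,D}→Y, {E,F,G}→Z, configurable). A message
escalation rule promotes, by one group, patients who sent more than
1.5 SD of messages above their group's mean or received more than 24;
groups then become the final **low / medium / high** clusters, minimally
active patients join *low*, and *inactive* stays separate. Weights are
anchored on cluster medians of effective PCP visits,

```
ratio_c = median_c / median_low,          c ∈ {low, medium, high}
w       = (N_total − N_inactive·0.05) / Σ_c N_c·ratio_c
weight_c = w·ratio_c,                     weight_inactive = 0.05
```

so that the total weighted population exactly equals the unweighted one. A
provider's weighted panel size is `Σ_c n_c·weight_c` over their empaneled
patients.

**Validation.** The phenotypes are validated as predictors: log-linear
models (OLS on `log(y+1)`) forecast each patient's year-2 primary care
encounters (PCP + telephone) from 12 age-sex bins, payer, and either the
7 phenotypes or a *naive phenotype* (septile rank of total year-1 in-person
encounters), comparing out-of-sample adjusted R² and AIC across the seven
predictor combinations. A Poisson variant on raw counts is available.

## Worked example

```python
from panelweight import PanelWeightModel, generate_population

pop = generate_population(n_patients=5000, seed=1)   # synthetic 2-year EHR
model = PanelWeightModel(pop.encounters, pop.patients)
results = model.fit(seed=1)
print(results.summary())
```

```
Panel weighting results
============================================================
patients: 5000   train/test: 2957/1267   seed: 1

Utilization phenotypes (full population, concurrent year):
  inactive:871  A:1352  B:484  C:591  D:1213  E:399  F:80  G:10

Work clusters, medians and weights (scaling factor w = 0.3459):
  cluster          n   median eff. PCP    weight  weighted n
  inactive       871                 -     0.050        43.6
  low           1689              1.00     0.346       584.2
  medium        1767              3.25     1.124      1986.3
  high           673             10.25     3.545      2386.0
  total weighted size: 5000.000 (unweighted 5000)

Providers with panels > 150: 20 (excluded 4); mean panel change +1.1%

Next-year utilization prediction (log-linear, test-set R2):
  age_sex                      adjR2(test)=0.059  AIC=6681
  payer                        adjR2(test)=0.069  AIC=6591
  naive_phenotype              adjR2(test)=0.382  AIC=5605
  utilization_phenotype        adjR2(test)=0.597  AIC=4107 *
  age_sex_payer                adjR2(test)=0.116  AIC=6452
  age_sex_payer_naive          adjR2(test)=0.400  AIC=5517
  age_sex_payer_utilization    adjR2(test)=0.594  AIC=4111
```

Reading the output: each patient lands in exactly one phenotype
(A = minimally active … G = high outlier) and one work cluster; a *high*
patient counts 3.5 low-cluster patients' worth of work, an *inactive* one
0.05, and the weighted total reproduces the empaneled population exactly
(the conservation constraint). The model comparison shows the qualitative
pattern the method is built on: utilization phenotypes out-predict both the
naive encounter-count septiles and demographics alone, with the lowest AIC
(`*`).

`results.save(outdir)` writes every stage's artifact (visit vectors,
phenotypes, work clusters, `weights.json`, per-provider and per-clinic panel
summaries, model comparison) as CSV/JSON with provenance headers, and
`results.plot_panel_change()` draws the distribution of relative panel-size
change across providers.

The same pipeline is available from the shell:

```bash
panelweight simulate --n 5000 --seed 1 --out data/
panelweight run --in data/ --out out/ --seed 1
# or stage by stage: features -> phenotype -> weight -> validate -> report
```

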