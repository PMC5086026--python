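# Methods

This note records the modelling choices behind `panelweight`: the weighting
algorithm itself, the constants it depends on, what the synthetic EHR
generator does and does not emulate, and the numerical conventions adopted
where the design was genuinely open.

## The weighting algorithm

The unit of analysis is the empaneled adult patient (ages 18–115) observed
over two consecutive 12-month windows, half-open `[start, end)`. All
behaviour is driven by annual encounter *counts*, never by diagnoses: the
premise is that observed service activity is a usable proxy for primary
care work effort, which also means the method cannot distinguish necessary
from induced utilization (see Limitations).

### Visit vectors

Each patient-window becomes a vector of per-category counts. Two components
are derived rather than raw:

- **Effective PCP visits** = Σ per-visit weights, where a visit's weight is
  a step function of the active-medication count at that visit:
  1.0 (≤ 5 meds), 1.5 (6–10), 1.75 (> 10). The bands approximate the extra
  reconciliation effort of polypharmacy visits and are configurable
  (`MedWeightBands`).
- **Capped specialty total** = Σ_s min(count_s, cap_s), with
  cap_s = mean + 2·sample SD of annual visits among patients who saw
  specialty *s* at least once (zero-visit patients excluded from the
  denominator). Caps are estimated once, system-wide, over the full
  collection period (both windows pooled) and then frozen; a specialty seen
  by a single patient gets that patient's count as its cap (no variance
  information, so the conservative choice is no truncation headroom).

Patients active for less than a full window are *not* annualised: 2 visits
in 3 months count as 2, not 8. Annualising short exposures was tried in the
original development of this method and produced inflated vectors for
briefly active patients.

### Rules, then clustering

Rule order matters and is: high outlier → minimally active → inactive.

- High outlier: raw PCP visits > mean + 6·SD, where mean/SD are computed on
  the training population restricted to patients with at least one
  encounter of any kind (the statistic would otherwise be diluted by the
  empaneled-but-absent). These patients never enter k-means.
- Minimally active: ≤ 1 PCP visit, 0 ED visits, 0 hospitalizations
  (emergent + elective), ≤ 4 specialty visits (capped total), ≤ 2 telephone
  encounters, ≤ 6 secure messages *received*. The message criterion is read
  as clinician→patient messages; both directions are tracked separately
  throughout because the escalation rule later needs both.
- Inactive: zero across *all* vector components except missed
  appointments. This is deliberately stricter than "zero in the
  minimally-active screen categories": a patient whose only activity is
  urgent care or sent messages is active, not inactive.

Remaining patients are clustered on all vector components except the two
message counts, in raw visits/year, unstandardised — the per-specialty
capping is the only scale control, which keeps the cluster centers directly
interpretable as visit profiles. k-means is run with k = 4, 5 random
initialisations, at most 10 Lloyd iterations, keeping the restart with the
lowest within-cluster sum of squares. The contract is "minimise WSS under
those restart/iteration limits", not a particular update schedule; Lloyd
(via scikit-learn) satisfies it, and empty clusters are re-seeded by
scikit-learn's relocation rule. The lowest-ranked cluster — clusters are
ranked by median raw PCP visits, ties broken by mean, then by cluster index
(the ranking must be deterministic; the tie-break is otherwise arbitrary) —
is split in two by a second k-means with identical settings. The five
clustered groups are labelled B–F ascending by the same (median, mean)
key; minimally active is A and high outlier G. `wss_curve` exposes the
elbow diagnostic that motivates k = 4, but k is fixed, not auto-selected.

### Work clusters, escalation, weights

Phenotypes collapse to intermediate groups X/Y/Z through a configurable
map, default {A,B}→X, {C,D}→Y, {E,F,G}→Z. The published record never
prints the exact membership of the collapse; this default is the inferred
one (it reproduces the published cluster-share pattern most closely) and is
a configuration value precisely because it is inferred.

The escalation rule is applied once, after collapse, with no cascading:
a patient moves up one group if they *sent* more messages than
mean + 1.5·SD of their originally assigned group (statistics computed on
the full original groups, at assignment time) or *received* more than 24.
The top group cannot move; minimally active patients are exempt and join
*low* at the end regardless, which resolves the ordering ambiguity between
"escalate" and "A is added to low" in favour of the final placement rule.
X/Y/Z then become low/medium/high; inactive is the fourth, untouched
cluster.

Weights: medians of effective PCP visits per active cluster, ratios to the
low median, inactive fixed at 0.05 (empaneled but dormant — a nominal
future-activity reservation, excluded from scaling), and the conservation
solve

    w = (N_total − N_inactive·0.05) / Σ_{c∈{low,med,high}} N_c·ratio_c.

Conservation holds to floating-point precision by construction; the
invariant is asserted at 10⁻⁶ relative tolerance. Weighted sizes are kept
as reals and rounded only for display. Because weights are normalised
within the system, they are not comparable across health systems.

### Validation models

Year-2 primary care encounters (PCP visits + telephone, or PCP only) are
predicted from 12 age-sex bins (age groups 18-34/35-49/50-64/65-69/70-84/
85-115; missing sex coded female to keep those patients in the sample),
payer (3-level commercial / Medicare-Medicaid / other by default, 4-level
as a config switch), and either the 7 phenotypes (the phenotypes, not the
3 work clusters, because they carry finer distinctions) or the naive
septile phenotype. The naive phenotype ranks patients by total in-person
encounters (no telephone, no messages, no missed appointments) and cuts
the ranks into 7 bins; ties share the lower septile via minimum ranks
(`ceil(rank·7/n)`), so septile sizes differ only by the number of ties.

The outcome is modelled as OLS on log(y + 1); the offset is needed because
many patients have zero year-2 visits, and +1 is the conventional choice
(configurable). Adjusted R² and AIC come from the Gaussian likelihood on
the log scale. Out-of-sample scoring applies frozen training coefficients
to the test split; test R² is 1 − SSE/SST on the log scale, adjusted with
the test n and the training model's parameter count (the adjustment's
degrees of freedom are not uniquely defined for frozen-coefficient scoring;
this is the package's convention). The 70/30 split uses a nearest-integer
training size — round(0.7·n), so 34,748 patients split 24,324/10,424 — and
a seeded permutation. A Poisson GLM with canonical log link on raw counts
is provided as the non-log alternative; the zero-inflated variant is out of
scope.

## The synthetic EHR generator

`generate_population` emulates the study conditions: a mixture of
utilization archetypes whose per-category annual rates, medication-count
means, mixture weights, age distributions, sex ratios and payer mixes
follow the published training-set profiles of the eight groups (inactive
plus A–G) — e.g. the minimally active archetype averages 0.7 PCP visits and
2.3 medications, the high-outlier archetype 33 PCP visits and 16
medications, with mixture weights equal to the published group sizes over
24,324 patients.

Counts are Poisson by default (the minimal count law; the published record
describes no generative model), with two deliberate departures:

- An optional negative-binomial dispersion (gamma-Poisson mixture) for
  overdispersed categories.
- A per-archetype Bernoulli law for categories whose published profile is
  *underdispersed*: phenotype A's PCP visits print mean 0.7 with SD 0.5,
  which no Poisson can produce (Poisson SD would be 0.84). Bernoulli(0.7)
  matches both moments almost exactly and reflects what the numbers imply —
  most minimally active patients make exactly 0 or 1 visit. Under a Poisson
  law the low work cluster frequently ends up with a zero median of
  effective PCP visits, which makes the weight solve degenerate; the real
  system evidently had a positive low median (its published low weight is
  0.659), so the Bernoulli law is the more faithful emulation, not a
  convenience.

Year-2 coupling: rate₂ = (1 − ρ)·base + ρ·(year-1 count), ρ = 0.6 per
archetype by default — a moderate persistence chosen once so that next-year
prediction is neither trivial nor impossible; the published record implies
persistence (phenotypes predict next-year use) but quantifies no ρ.
Demographics are drawn per archetype (truncated-normal ages, Bernoulli sex
with a small missing-sex rate, categorical payer with the pooled
Medicare-Medicaid mass split 60/40 so the 4-level payer scheme is
populated). Providers receive a complexity tilt so clinic case mix varies
across panels, emulating the real spread from women's-health to geriatric
clinics; with tilt 0 all panels converge to the population mix and every
relative panel change is ≈ 0.

What the generator does **not** emulate: within-patient correlation between
categories beyond what the archetype mixture induces (the published record
gives only marginal means/SDs, so any joint dependence would be invented),
diagnoses, free text, billing minutes, seasonal structure, or enrolment
churn. Passing tests therefore demonstrate that the algorithm recovers
planted structure and satisfies its arithmetic contracts — not that the
phenotypes of any particular real system will look like Tables of this
package's defaults.

## Numerical conventions and degenerate inputs

- Medians: midpoint of the two central order statistics for even n.
- Sample SDs use n−1 throughout (caps, outlier rule, escalation).
- Windows half-open, dates ISO-8601, no time zones.
- k-means restart seeds derive from a `SeedSequence` of the stage seed;
  identical config + seed ⇒ byte-identical outputs end to end.
- Records outside a window are ignored, not errors; records for unknown
  specialties (no cap) are errors.
- Empty active clusters, a zero low-cluster median, n < k, or a split of
  fewer than 2 patients reject with explicit messages rather than producing
  silently meaningless weights.
- Problem sizes used by the shipped checks: the conservation check runs the
  full pipeline at the study's population size (52,368); phenotype-count
  and recovery checks use 10,000 and 20×2,500 patients respectively —
  large enough for every regime (high outlier mass ≈ 0.16%) to be
  populated, small enough for a desk run.

## Known limitations

- Activity-as-effort: the method inherits the gaming and induced-demand
  caveats of any utilization-based measure.
- The collapse map and several rule constants are inferred or conventional
  rather than printed; all are configuration values.
- Out-of-sample "adjusted" R² for frozen coefficients has no canonical
  definition; a different df convention shifts values slightly.
- The pediatric population is out of scope; rule thresholds are calibrated
  to adults.
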