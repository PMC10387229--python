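# ictrans — latent transitions of intrinsic capacity in older adults

Intrinsic capacity (IC) is the composite of an older person's physical and
mental capacities, conventionally split into six domains: locomotion,
nutrition, vision, hearing, cognition and psychological.  Epidemiologists
studying ageing in the 10/66 surveys (population-based cohorts of adults 65+
in Latin America, the Caribbean and China) want to know *which combinations*
of domain impairments occur together, how people move between those
combinations over a 4–5 year follow-up, and whether the combinations predict
hard outcomes.  `ictrans` is a complete, reusable implementation of that
analysis for two-wave binary impairment data:

* deterministic coding of the six impairments and outcomes from raw
  measures (`ictrans.coding`);
* a **latent transition model** fitted by EM (`ictrans.lta`);
* status-count selection, canonical severity ordering and transition
  summaries (`ictrans.selection`);
* concurrent/predictive validity: adjusted logistic models with
  covariate-standardised probabilities, a generalized ordered logit for
  self-rated health, Cox mortality models with Harrell's C and
  proportional-hazards diagnostics (`ictrans.validity`);
* a calibrated synthetic cohort generator (`ictrans.cohort`) and a
  deterministic end-to-end pipeline (`ictrans.pipeline`).

Because the source data are restricted, the package ships a generator whose
parameters transcribe the published estimates (status prevalences
43/17/22/18%, the printed transition probabilities, per-status impairment
frequencies, and the published effect sizes).  Fitting the model to its own
synthetic cohorts and recovering those numbers is the package's end-to-end
correctness check; `docs/methods.md` records the provenance of every
constant and what the checks do and do not demonstrate.

## The model

Subject *i* has covariates *x_i*, a latent baseline status *a* ∈ {1..S} and
follow-up status *b*.  With membership δ_a(x) (multinomial logit on age, sex
and education), transitions τ_ab, and measurement-invariant item-response
probabilities ρ_aj = P(domain *j* impaired | status *a*), the observed-data
likelihood is

    L_i = Σ_a Σ_b δ_a(x_i) τ_ab Π_j ρ_aj^{y_ij1} (1−ρ_aj)^{1−y_ij1}
                               Π_j ρ_bj^{y_ij2} (1−ρ_bj)^{1−y_ij2}

with missing indicators marginalised factor-by-factor (a fully missing
second wave — death or dropout — marginalises *b* out).  EM maximises this
with closed-form ρ/τ updates and a Newton step for δ; statuses are reported
in canonical severity order (ascending Σ_j ρ_aj, cognition breaking the top
tie).  Four statuses emerge: high IC, low deterioration (mainly locomotion),
and high deterioration without / with cognitive impairment.

## Worked example

```python
from ictrans.cohort import paper_replication_config, generate
from ictrans.lta import IndicatorPanel, fit, e_step, assign_modal
from ictrans.selection import summarise_transitions

cfg = paper_replication_config()
cohort = generate(cfg, seed=1066, n=20_000)
panel = IndicatorPanel.from_dataframes(cohort.indicators, cohort.covariates)
fr = fit(panel, S=4, n_starts=20, seed=2067, tol=1e-9, max_iter=3000)
print(fr.params.initial_probabilities(panel.x).mean(axis=0))  # ~ (0.45, 0.16, 0.22, 0.17)
post = e_step(panel, fr.params)
s1, s2 = assign_modal(post)
print(summarise_transitions(s1, s2, both_observed=panel.wave2_observed).fractions)
```

The same analysis as a narrative sequence lives under `analysis/`
(`01_simulate_cohort.py` … `06_full_pipeline.py`); each script prints what
it found and writes its tables under `results/`.  Output actually printed by
`analysis/03_fit_and_select.py` and `analysis/04_transitions.py` on the
seed-1066 cohort:

```
 S         loglik  n_params           AIC           BIC  entropy
 3 -106097.273798        32 212258.547596 212511.459197 0.743749
 4 -105071.422246        48 210238.844493 210618.211895 0.644123
 5 -105062.793074        66 210257.586148 210779.216327 0.605818
BIC selects S = 4

baseline prevalences (healthiest first): [44.6 15.9 22.4 17.1]
transition matrix:
[[0.356 0.584 0.06  0.   ]
 [0.004 0.754 0.009 0.233]
 [0.    0.125 0.863 0.012]
 [0.018 0.    0.    0.982]]

flows among subjects observed at both waves:
  worsened  37.1%
  stable    59.9%
  improved  3.0%
```

Read against the generating truth (prevalences 43/17/22/18; transitions
0.60 / 0.27 / 0.12 in the marked cells; flows 61% stable, 3% improved):
the fit recovers the structure, with the known mild attenuation of the
high-IC→low-det entry discussed in `docs/methods.md`.  The validity models
(`analysis/05_validity.py`) recover the published effect sizes — e.g.
mortality HR 4.54 (95% CI 4.08–5.04) against a generating 4.60 — at the
published per-outcome sample sizes.

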