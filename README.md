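# rxpersist

Medication **persistence** and **adherence** analysis of prescription-claims
data, built for pharmacoepidemiologists studying oral antidiabetic therapy —
specifically new users of sodium-glucose co-transporter 2 inhibitors
(SGLT2i, ATC `A10P`) among type-2-diabetes patients in a Japanese
employment-based claims database — and for anyone who wants a tested,
reproducible implementation of the standard new-user / permissible-gap /
PDC toolkit.

The package covers the whole pipeline:

- **Claims model** — four flat CSV tables (enrollment, prescriptions with
  ATC code and days of supply, ICD-10 diagnoses with suspected-diagnosis
  flags, outpatient-visit claims), with the month-resolution date
  convention (`YYYYMM` → day 15) handled on parse.
- **Cohort builder** — new-user design: index date at the first SGLT2i
  fill, 180-day antidiabetic washout, enrollment spanning
  `[index − 180, index + 365)`, and an auditable exclusion cascade
  (single fill, combination at index, fixed-dose combination, < 2
  pre-index visits) with conserved flow counts.
- **Exposure engine** — gap-based persistence: the first fill-to-fill gap
  strictly exceeding the permissible gap *g* (90 days primary, 30 days
  sensitivity) dates a discontinuation at `min(prev fill + supply, 365)`;
  switching to another antidiabetic ends monotherapy at that fill's date;
  restarts after gap events are flagged. Adherence is the proportion of
  days covered,

  `PDC = |union of [fill, fill + supply) intersected with [0, 365)| / 365`,

  overlapping supply counted once, with `PDC >= 0.80` defining adherent.
- **Covariates** — calendar year, age, sex, visit count and mean
  inter-visit interval, concomitant cardiometabolic drug classes
  (C09/C07/C08/C03/C10), six ICD-10 comorbidity flags and the Charlson
  comorbidity index (Quan-2005 mapping, original weights).
- **Statistics** — Kaplan–Meier persistence
  `S(t) = prod_{t_i <= t} (1 − d_i/n_i)`, incidence per 1000 person-years,
  crude (univariate) and adjusted (joint) logistic odds ratios with Wald
  95% CIs, VIF multicollinearity screening, and OLS slopes of PDC /
  follow-up on age and visit interval.
- **Synthetic generator** — populations with planted covariate effects on
  the one-year non-persistence log-odds, refill jitter, missed refills,
  switches, restarts and every exclusion branch, so each stage can be
  validated against a known truth (see `docs/methods.md`).

## Worked example

```python
import rxpersist as rp
from rxpersist.synthetic import SimulationConfig, generate
from rxpersist.exposure import GapPolicy
from rxpersist.stats import km_estimate, incidence

bundle, truth = generate(SimulationConfig(n_patients=2000, seed=11))
cohort, flow = rp.build_cohort(bundle)
print(flow.to_frame().to_string(index=False))

exp = rp.compute_exposure(cohort, bundle, GapPolicy(90))
km = km_estimate(exp["persistence_days"], exp["discontinued"])
print(f"persistence at 365 d : {100 * km.survival_at(365):.1f}%")
print(f"mean PDC             : {100 * exp['pdc'].mean():.1f}%")
print(f"adherent (PDC >= 80%): {100 * exp['adherent'].mean():.1f}%")
print(f"incidence            : {incidence(exp).rate_per_1000py:.1f} per 1000 person-years")
```

which prints

```
               stage  n_remaining  n_excluded
      total_patients         2000           0
 new_user_candidates         1296         704
     missing_rx_date         1296           0
    single_sglt2i_rx         1196         100
combination_at_index         1128          68
        fdc_at_index         1089          39
      lt2_pre_visits         1054          35
        final_cohort         1054           0
persistence at 365 d : 60.1%
mean PDC             : 79.6%
adherent (PDC >= 80%): 64.2%
incidence            : 517.8 per 1000 person-years
```

Reading the funnel: of 2,000 simulated patients, 1,296 are new users with
a clean washout and full observation windows; staged exclusions leave a
1,054-patient analytic cohort. About 60% of the cohort is still on
monotherapy at one year under the 90-day gap rule, and the mean share of
follow-up days with drug supply on hand is ~80%.

The same stages are available from the shell:

```bash
rxpersist synth --seed 11 --n 2000 --out data/
rxpersist cohort --in data/ --out cohort.csv --flow flow.csv
rxpersist exposure --cohort cohort.csv --in data/ --gap 90 --out exposure.csv
rxpersist covariates --cohort cohort.csv --in data/ --out covariates.csv
rxpersist analyze --exposure exposure.csv --covariates covariates.csv --out results/
# or everything at once, from a YAML config:
rxpersist run --synthetic sim.yaml --out results/
```

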