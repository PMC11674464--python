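# Default parameter bundle: provenance

Generated from `hbocsim/_defaults.py` (`hbocsim export-defaults` reproduces it).
Two classes of values:

**Observed clinical-service estimates, encoded verbatim**

- `config.yaml: referral_model` — referral odds model for breast and ovarian
  cancer (constant plus odds-ratio terms) from Australian familial cancer
  service observations and expert opinion.
- `config.yaml: testing_uptake` — diagnostic-testing uptake (0.96 breast,
  0.95 ovarian) from Australian series.
- `predictive_uptake.csv` and `config.yaml: male_predictive_rate_ratio` —
  annual cascade-testing probabilities by degree, age band and time since the
  family variant was identified; male rate ratio 0.422; zero under 18.

**Literature-anchored stand-ins (synthetic, overridable)**

These emulate surfaces whose primary sources are not redistributable here.
Each is generated from a small number of published anchors and calibrated
once against population-level validation targets (mean family size ~22.3 for
probands 50-54, ~30% never-screeners, ~14.5% of non-carrier probands with an
affected first-degree relative, ~12% female lifetime breast-cancer risk).

- `hazards.csv` — annual hazards, ages 0-100. Non-carrier baseline follows
  the Australian registry age profile, scaled to cumulative risk to age 80 of
  12.8% (breast; ~1 in 7 to 85) and 1.2% (ovary). Carrier penetrance uses
  smooth gene-specific shapes scaled to cohort-literature lifetime risks
  (e.g. breast to 80: BRCA1 0.72, BRCA2 0.69, PALB2 0.53; ovary: BRCA1 0.44,
  BRCA2 0.17, RAD51C 0.11, RAD51D 0.13, BRIP1 0.058).
- `gene_prevalence.csv` — population carrier frequencies in women,
  anchored to population-cohort estimates (totals ~1.5%).
- `lifetable.csv` — Gompertz-Makeham annual death probabilities tuned to
  Australian-like survival (female e0 ~86, male ~80); the female table is
  used as net of breast/ovarian cancer mortality.
- `parity_cdf.csv` / `maternal_age.csv` — completed-parity distribution
  (mean 2.67) with age-specific CDFs derived by binomial thinning against a
  discretised normal maternal-age-at-birth distribution (mean 27.5, sd 5.5).
- `screening_performance.csv` / `screening_start.csv` — mammography
  sensitivity/specificity by age and MRI performance from screening-programme
  and surveillance literature; population start-age distribution carrying 30%
  never-participation mass; high-risk start-delay distribution.
- `surgery_uptake.csv` — BRRM/RRSO annual uptake by gene and age band with
  the stated gene equivalences (PALB2 at BRCA2 rates; ATM/CHEK2 at half;
  RRSO windows from 45 for RAD51C/D, 50 for PALB2, 60 for BRIP1).
- `survival.csv` + multipliers — annual excess mortality by organ, stage and
  age band, with subtype/histology multipliers, matching registry-like 5-year
  relative survival.
- `config.yaml: tumour_models` — categorical distributions for breast
  subtype/grade/size/nodes/metastasis and ovarian histology/grade/stage
  (serous shifted toward distant stage; "other" histotypes partly
  reclassified to serous at ages 70+).
- `config.yaml: sojourn_dist` — lognormal preclinical sojourn, mean ~2.7
  years (shorter for BRCA1).

All values are plain text and overridable through a user config.
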