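# Methods

## Model overview

`hbocsim` is a discrete-time (annual-cycle), individual-based microsimulation
of hereditary breast and ovarian cancer (HBOC) genetic testing in
family-structured populations. Each simulated unit is a family built around a
female proband who is cancer-free at entry and aged 20-59. The family
contains her first- and second-degree relatives — two parents and four
grandparents always, with siblings, aunts/uncles (piblings), children,
nieces/nephews (niblings) and grandchildren drawn from parity distributions.
Married-in co-parents are generated where needed so that descendants have two
genetic parents; they transmit genotypes and participate in pedigree logic
but are excluded from family-size and outcome metrics.

Everyone's life is simulated from birth on one timeline: entry is year 0, so
"baseline history" (cancers, deaths, screening before entry) is simply the
years up to 0, during which population breast screening operates but no
genetic testing exists. The main simulation runs years 1..horizon (default
160, maximum 160) until each person dies or exits at age 100. The population
can be dynamic (children born during the simulation enter at birth, provided
the mother is alive) or static.

## Genotypes

Monogenic risk is a single pathogenic/likely-pathogenic (P/LP) variant in one
of eight genes: BRCA1, BRCA2, PALB2, CHEK2 (1100delC only, as a single allele
class), ATM, RAD51C, RAD51D, BRIP1. Founders (grandparents, married-ins)
carry a variant with the population prevalences in the bundle; descendants
inherit Mendelianly with transmission probability 1/2 and no de novo events;
a person carries at most one variant.

Polygenic risk is a pair of organ-specific standard-normal scores
(breast, ovary) following the infinitesimal model: founders draw N(0,1),
children take the midparent mean plus segregation noise of variance 1/2,
preserving unit marginal variance in every generation. The two organ scores
are independent by default (`polygenic_correlation` exposes a joint draw).
The hazard multiplier for score z is HR^z / exp(ln(HR)^2 / 2), where HR is
the published hazard ratio per SD (defaults 1.60 breast, 1.32 ovary); the
divisor makes the population-mean multiplier exactly 1 so that calibrated
population incidence is preserved. A small "frailty gap" remains in
*cumulative* probabilities (Jensen's inequality, well under 1% absolute at
these parameters); the incidence-recovery test allows for it.

## Natural history

Hazards are annual piecewise-constant rates on integer ages 0-100. A
person's onset hazard is the genotype curve (carrier penetrance or
non-carrier baseline) times the polygenic multiplier, times any surgery
multiplier. Event times are drawn by inverting the cumulative hazard against
a stored unit-exponential draw. This is exact for the yearly-cycle model and
lets a mid-life hazard change (risk-reducing surgery) re-plan future events
without disturbing any other random draw.

Breast cancer onset is preclinical (screen-detectable) disease; subtype
(triple-negative / HER2 / hormone-receptor-positive) and grade are drawn
conditional on genotype; the sojourn time is lognormal (default mean ~2.7
years, shorter for BRCA1). The tumour is diagnosed symptomatically when the
sojourn expires unless a screen detects it or surgery removes it first. At
detection, size, nodal status and metastasis are drawn conditional on the
detection mode and fixed thereafter; stage is derived (metastasis > distant,
nodes > regional, else local). Contralateral disease is a second course
whose hazard accrues only after the first diagnosis and is abolished by
contralateral or bilateral mastectomy; a second primary sets the bilateral
flag used by testing eligibility.

Ovarian cancer has no preclinical phase and no screening. Carriers diagnosed
after age 25 have high-grade serous disease; otherwise histology is
age-conditional, grade histology-conditional, and stage grade-conditional
with a shift toward distant stage for serous tumours (also reflecting the
intentional reclassification of "other" histotypes toward serous at 70+).

Mortality combines a sex-specific lifetable (the female table is treated as
net of breast/ovarian cancer deaths) with per-tumour annual excess mortality
by organ, stage and age band (subtype/histology multipliers), active for 15
years after diagnosis; the earliest event wins, and within a year the fixed
cycle order resolves ties (other-cause death precedes diagnosis; cancer death
follows all clinical events). Male relatives carry no cancer risk.

## Screening and prevention

Population pathway: start age drawn from a distribution over 40-64 carrying
30% "never" mass; two-yearly mammography with a geometric adherence delay,
to age 74; screening stops at a breast-cancer diagnosis or BRRM. A screen
detects an existing preclinical tumour with the combined sensitivity of the
attended modalities (1 - prod(1-sens)). Women identified as carriers move to
annual surveillance: mammography 25-64 plus MRI 25-59 for BRCA1/2/PALB2,
mammography 35-59 for the moderate-risk genes, with the age at first
high-risk screen drawn as an uptake delay from eligibility and moderate-risk
women delayed a further ten years.

Risk-reducing surgery requires known carrier status: BRRM for unaffected
BRCA1/2/PALB2 carriers (ATM and CHEK2 at half the BRCA2 rate, others
ineligible); RRSO by gene-specific windows (BRCA1 from 35, BRCA2 from 40,
PALB2 from 50, RAD51C/D from 45, BRIP1 from 60). Uptake is an annual
Bernoulli with age- and gene-specific rates. Surgery multiplies the organ's
hazard thereafter (defaults: BRRM x0.10 on breast, RRSO x0.05 on ovary; the
RRSO effect on breast risk defaults to none and is switchable). CRRM is
decided in the year of a unilateral breast-cancer diagnosis (uptake 0.45 for
known carriers, 0.05 otherwise) and removes contralateral risk only.
Surgeries are absorbing.

## Genetic services

Referral happens only in a diagnosis year (re-referral at each new primary):
odds = constant x applicable odds ratios (tumour type, age, grade, subtype
or histology, survival under 12 months, prior breast cancer), probability
odds/(1+odds). "High grade" means grade 3 for breast and grade >= 2 for
ovary (both configurable). Funded-testing eligibility: triple-negative
breast cancer at <= 50 (or any age with an affected relative), >= 3 affected
first/second-degree relatives (counted on both lineage sides), bilateral
breast cancer, grade 2/3 serous ovarian cancer at any age, or non-mucinous
grade 2/3 ovarian cancer under 70. Diagnostic testing is a full panel
(high-risk: BRCA1/2, PALB2; the extended panel exists but is excluded from
the policy scenarios) with uptake 0.96 (breast) / 0.95 (ovary); the assay is
error-free. The first positive creates the family-variant knowledge and the
cascade begins the same year.

Predictive testing: each year, every eligible relative (alive, never
panel- or predictive-tested, not an obligate non-carrier) tests with the
annual probability from the uptake table by degree of relation to the index
carrier (clipped at second degree), age band and time since identification
(identification year = "<1", years 1-3 = "1-3", later = ">3"); males take
rate ratio 0.422 and under-18s never test. Obligate non-carriers are
computed by lineage constraint propagation: the variant entered through a
single founder, so a person can carry it only if some founder origin reaches
them through a descent path avoiding observed negatives while reaching every
observed positive. A positive maternal grandfather therefore removes the
paternal side. An exhaustive single-origin enumerator (the test oracle)
verifies this algorithm on small pedigrees. A woman who tested negative
predictively remains panel-eligible if she later develops cancer.

## Scenarios

1. `no_testing` — all genetic testing and high-risk management off.
2. `current_practice` — referral model + eligibility + uptake, high-risk panel.
3. `optimised_referral` — referral probability 1 for eligibility-meeting cases.
4. `test_all_breast` — additionally, testing offered to all breast cancers
   diagnosed before 80.

Interventions apply to all individuals, not only probands, so a family
variant can first surface in a relative; background testing progressively
removes carriers from the newly-diagnosed proband pool (prevalence
dilution). Sensitivity toggles reproduce the comparison design of earlier
models: `disable_relative_diagnostic_testing` and
`force_full_predictive_uptake` (every eligible adult relative tests once
identified). A study toggle `force_index_identification` identifies the
variant with certainty at a carrier proband's diagnosis, used by the
predictive-uptake validation study.

## Randomness and reproducibility

Every draw comes from a named substream keyed by (master seed, family,
attempt, person, purpose) — with the year added for annually evaluated gates
(screen detection, referral, testing and surgery uptake). Runs are
byte-identical for identical seed/config/parameters, and different scenarios
are common-random-number paired: the same woman experiences the same
natural-history draws everywhere, so scenario contrasts reflect the
interventions. Because interventions feed back on incidence, set-level
nesting of tested probands across scenarios holds conditionally (identical
diagnosis histories), while detection rates and counts order unconditionally.

Entry conditioning (the proband must be alive and cancer-free at year 0) is
enforced by regenerating the family with a bumped attempt counter. Carrier
conditioned studies force the proband's genotype and propagate the variant
up a uniformly chosen grandparent-parent path, reproducing the conditional
pedigree distribution given a carrier proband at ~100x the efficiency of
rejection sampling.

## Default parameters and calibration

The referral odds model, testing uptake and the predictive-uptake table are
encoded verbatim from their published values. Everything else ships as
literature-anchored stand-ins (see `data/default/PROVENANCE.md`): hazard
shapes scaled so cumulative risks hit published lifetime-risk anchors
(baseline breast 12.8% to 80, ~1-in-7 to 85; BRCA1 72%, BRCA2 69%, PALB2 53%
breast to 80; BRCA1 44%, BRCA2 17% ovary, etc.), Gompertz-Makeham lifetables
matched to national survival, a completed-parity distribution (mean 2.67)
thinned by a maternal-age distribution (mean 27.5, sd 5.5) for age-specific
parity, and registry-like screening performance, survival and tumour tables.

The stand-ins were calibrated once, at design time, against the population
validation targets: mean family size ~22.3 for probands aged 50-54 (observed
~22.5), ~30% never-screeners (0.30 by construction), and ~14.5% of
non-carrier probands with an affected first-degree relative. The last target
settles at ~13.0% under the default bundle: with a ~10% affected-mother rate
(the realistic product of incidence accrual and maternal survival) plus
~2 siblings at midlife risk, the union probability cannot reach 14.5%
without pushing parity or incidence beyond their own anchors, so the honest
value is reported rather than over-fitting one target at the expense of the
others. Five-year predictive-testing uptake among at-risk relatives
(first-degree relatives of the index carrier, the 50%-risk group) comes out
near 20% with ~1.9-2.0 relatives tested per carrier proband; relatives alive
at a carrier proband's diagnosis average ~14.8-15.1.

## What the generator does and does not emulate

The synthetic families reproduce marginal parity, maternal-age patterns,
age-specific incidence, survival and screening participation, and the
familial clustering induced by the modelled monogenic and polygenic risk.
They do not emulate calendar-time trends in fertility or incidence (one
stationary schedule serves all generations), assortative mating, shared
non-genetic family environment, consanguinity, third-degree structure, male
cancer risks, VUS reporting, or clinic-ascertainment bias. Passing the
validation targets therefore shows internal consistency with the declared
study conditions, not field accuracy for any particular registry year.

## Numerical choices and problem sizes

Hazard curves are linear interpolations of anchor points rescaled in
cumulative-hazard space; probabilities are 1-exp(-h). Sojourn times round to
whole years for scheduling (minimum 0: same-year diagnosis). Within-year
event order is fixed and documented (births, other-cause death, onset and
symptomatic diagnosis, screening, referral/diagnostic testing, predictive
testing, pathway and surgery, cancer death, exit). Validation studies run at
reduced scale chosen to keep Monte-Carlo error well inside each target's
tolerance: 1,200 carrier families for the uptake study, 10,000 families for
family size, 20,000 for family history, 3,000 carrier families for the
scenario-1 outcome, 100,000 draws for screening participation.

## Known limitations

No cost-effectiveness layer, no treatment effects (PARP inhibitors, systemic
therapy), no VUS or reclassification, no privately funded testing, no male
cancer endpoints, no ovarian screening, and carrier-probability tools
(CanRisk-style) are out of scope; eligibility is the rule-based
approximation described above. The obligate-carrier algorithm assumes a
single family variant; a second variant entering by marriage is recorded for
the individual but does not spawn a second cascade.
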