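# hbocsim

A family-structured microsimulation of genetic testing for hereditary breast
and ovarian cancer (HBOC), for modellers and health-services researchers who
need to compare testing policies while modelling relatives — and cascade
(predictive) testing within families — explicitly rather than through
average-relative assumptions.

Each simulated family is built around a cancer-free female proband with her
first- and second-degree relatives. Individuals carry a monogenic genotype
(at most one pathogenic variant in BRCA1, BRCA2, PALB2, CHEK2 1100delC, ATM,
RAD51C, RAD51D or BRIP1) and organ-specific polygenic scores z ~ N(0,1)
inherited under the infinitesimal model (child = midparent mean + noise of
variance 1/2). The annual cancer-onset hazard for a woman aged a is

    h(a) = h_gene(a) · HR^z / exp(ln²HR / 2) · m_surgery

where h_gene is the carrier penetrance (or non-carrier baseline) curve, HR is
the hazard ratio per SD of polygenic score, and the divisor keeps the
population-mean multiplier at 1. Breast cancer begins as preclinical disease
with a lognormal sojourn time and is diagnosed symptomatically, by
mammography/MRI screening, or pre-empted by surgery; ovarian cancer has no
preclinical phase. Diagnosed women are referred to genetics services with
probability odds/(1+odds) from an odds model (constant x odds ratios for
age, grade, subtype/histology, short survival, prior breast cancer), tested
subject to funding criteria and uptake, and a positive full-panel result
opens annual cascade testing of relatives at published age-, degree-, sex-
and time-dependent uptake probabilities, with obligate non-carriers excluded
by lineage constraint propagation. Identified carriers enter high-risk
surveillance and may take risk-reducing mastectomy/salpingo-oophorectomy.
Four policy scenarios are built in: no testing, current practice, optimised
referral, and testing all breast cancers under 80.

## Worked example

```python
import hbocsim
from hbocsim import engine, outcomes

p = hbocsim.default_parameters()
families = hbocsim.generate_population(300, (20, 24), p, seed=3)
log = engine.run_simulation(families, engine.build_scenario("current_practice"), p)

cohort = outcomes.select_cohort(log)          # probands with breast cancer < 80
print(len(cohort.probands), "probands in the analysis cohort")
det = outcomes.detection_rate(log, cohort, group="probands")
print(f"carrier probands identified: {det['n_identified']}/{det['n_carriers']}")
```

With seed 3 this prints:

```
35 probands in the analysis cohort
carrier probands identified: 0/1
```

i.e. of 300 probands followed from age 20-24, 35 developed breast cancer
before 80 (~11.7%, consistent with the bundled lifetime-risk calibration),
one of them carried a high-risk variant, and current-practice referral
missed her — the model's expression of the known under-ascertainment of
carriers by criteria-based testing (at scale, current practice identifies
roughly half of carrier probands at diagnosis). The same log yields life expectancy,
anchored life-years, Kaplan-Meier incidence in relatives and per-scenario
summary tables via `outcomes.life_metrics`, `outcomes.cumulative_incidence`
and `outcomes.summary_report`.

A command-line interface wraps the same pipeline:

```bash
hbocsim run -s current_practice -n 1000 --seed 1 -o log.jsonl
hbocsim export-defaults bundle/   # inspect or edit the parameter bundle
hbocsim validate -c bundle/config.yaml
```

## Parameters

The complete parameterisation ships as one YAML config referencing plain CSV
tables (`src/hbocsim/data/default/`): gene prevalences, penetrance and
baseline-incidence curves, lifetables, parity and maternal-age
distributions, screening performance and participation, surgery uptake and
risk reduction, survival, tumour-characteristic models, and the referral and
predictive-testing uptake tables. `data/default/PROVENANCE.md` records which
values are encoded verbatim from published service data and which are
literature-anchored stand-ins. Any field can be overridden from a user
config passed to `load_parameters`. See `docs/methods.md` for the model
description, assumptions and limitations.

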