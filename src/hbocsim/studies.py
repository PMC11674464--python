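"""Validation and calibration studies: self-contained routines that generate
a population, run the relevant part of the model, and measure one headline
quantity (family size, family history prevalence, never-screener fraction,
predictive-testing uptake, relatives alive at a carrier proband's diagnosis).

These are the model's internal-validation checks; the acceptance script and
the test suite both call them.
"""

from __future__ import annotations

import numpy as np

from . import engine, genetics, outcomes
from .parameters import HIGH_RISK_GENES, ParameterSet, default_parameters
from .pedigree import Family, generate_population
from .screening import sample_screening_start


def _carrier_gene_mix(p: ParameterSet, rng, genes=None) -> str:
    genes = genes or HIGH_RISK_GENES
    w = np.array([p.gene_prevalence[g] for g in genes], float)
    return genes[int(rng.choice(len(genes), p=w / w.sum()))]


def generate_carrier_families(
    n_families: int, proband_age_group, p: ParameterSet, seed: int, genes=None
) -> list[Family]:
    """Families conditioned on the proband carrying a (high-risk, by default)
    variant, with the gene mixed in proportion to population prevalence."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    gene_for = [_carrier_gene_mix(p, rng, genes) for _ in range(n_families)]
    return generate_population(
        n_families, proband_age_group, p, seed,
        force_proband_gene=lambda fid: gene_for[fid],
    )


def family_size_study(n_families: int, p: ParameterSet | None = None,
                      seed: int = 1, proband_age_group=(50, 54)) -> dict:
    """Mean family size at entry (proband + first/second-degree relatives,
    alive and deceased, married-ins excluded)."""
    p = p or default_parameters()
    fams = generate_population(n_families, proband_age_group, p, seed)
    sizes = [f.size_at_entry() for f in fams]
    return {"mean_family_size": float(np.mean(sizes)), "n": n_families}


def family_history_study(n_families: int, p: ParameterSet | None = None,
                         seed: int = 1, proband_age_group=(50, 54)) -> dict:
    """Fraction of non-carrier probands with >= 1 first-degree relative with
    a breast-cancer history at entry."""
    p = p or default_parameters()
    fams = generate_population(n_families, proband_age_group, p, seed)
    n_nc = n_hit = 0
    for f in fams:
        pr = f.proband
        if pr.genotype.plp_gene is not None:
            continue
        n_nc += 1
        for rid, deg in f.relatives_by_degree(pr.id).items():
            m = f.members[rid]
            if deg == 1 and m.in_family and any(
                t.organ == "breast" and t.age_at_diagnosis + m.birth_year <= 0
                for t in m.cancer_history
            ):
                n_hit += 1
                break
    return {"fraction_with_affected_fdr": n_hit / n_nc, "n": n_nc}


def never_screener_study(n_draws: int, p: ParameterSet | None = None, seed: int = 1) -> dict:
    """Fraction of population-pathway screening-start draws that are never."""
    p = p or default_parameters()
    rng = np.random.default_rng(seed)

    class _W:
        age_at_entry = 50

    never = sum(
        sample_screening_start(_W(), "population", p, rng) is None
        for _ in range(n_draws)
    )
    return {"never_fraction": never / n_draws, "n": n_draws}


def predictive_uptake_study(
    n_families: int, p: ParameterSet | None = None, seed: int = 1,
    proband_age_group=(20, 24), window_years: int = 5,
) -> dict:
    """Cascade-testing uptake in the first years after a family variant is
    identified at a carrier proband's cancer diagnosis, under current
    practice.

    Returns the fraction of at-risk relatives who complete a predictive test
    within ``window_years`` yearly cycles, and the mean number of predictive
    tests per identified carrier proband (all relatives) in that window.

    "At-risk relatives" is the 50%-carrier-risk group in the clinical-genetics
    sense: first-degree relatives of the index carrier who are alive,
    untested and possible carriers at identification (any age).
    """
    p = p or default_parameters()
    fams = generate_carrier_families(n_families, proband_age_group, p, seed)
    sc = engine.build_scenario("current_practice", force_index_identification=True)
    engine.run_simulation(fams, sc, p)

    eligible = tested = probands_identified = tests_total = 0
    for f in fams:
        k = f.variant_knowledge
        if k is None or k.index_carrier_id != f.proband_id:
            continue
        probands_identified += 1
        y0 = k.year_identified
        possible = genetics._possible_carriers(f, {f.proband_id: "positive"})
        degrees = f.relatives_by_degree(f.proband_id)
        for m in f.members.values():
            if m.id == f.proband_id or not m.in_family:
                continue
            if m.sim is not None and m.sim.excluded:
                continue
            if degrees.get(m.id) != 1:
                continue
            ts = m.test_state
            if not m.alive_in(y0) or m.id not in possible:
                continue
            if ts.panel_tested_year is not None and ts.panel_tested_year < y0:
                continue
            eligible += 1
            if ts.predictive_tested_year is not None and \
                    y0 <= ts.predictive_tested_year < y0 + window_years:
                tested += 1
        for m in f.members.values():
            ts = m.test_state
            if ts.predictive_tested_year is not None and \
                    y0 <= ts.predictive_tested_year < y0 + window_years:
                tests_total += 1
    return {
        "uptake_fraction": tested / eligible if eligible else float("nan"),
        "tests_per_proband": tests_total / probands_identified if probands_identified else float("nan"),
        "n_probands": probands_identified,
        "n_eligible_relatives": eligible,
    }


def carrier_relatives_study(
    n_families: int, p: ParameterSet | None = None, seed: int = 1,
    proband_age_group=(20, 24),
) -> dict:
    """Scenario 1 (no genetic testing), dynamic population: mean number of
    male and female first/second-degree relatives alive at the proband's
    breast-cancer diagnosis, among carrier probands diagnosed before 80."""
    p = p or default_parameters()
    fams = generate_carrier_families(n_families, proband_age_group, p, seed)
    sc = engine.build_scenario("no_testing")
    log = engine.run_simulation(fams, sc, p)
    cohort = outcomes.select_cohort(log)
    res = outcomes.relatives_alive_at_diagnosis(log, cohort)
    return {"mean_relatives_alive": res["mean"], "n_probands": res["n_probands"]}
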