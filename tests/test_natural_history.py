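"""Cancer onset hazards, breast courses, tumour characteristics, death."""

import math

import numpy as np
import pytest

from hbocsim.fixtures import ScriptedRNG, zero_hazard_params
from hbocsim.natural_history import (
    TumourRecord,
    annual_hazard,
    assign_breast_prognostics,
    cancer_death_age,
    first_passage_year,
    other_cause_death_age,
    person_hazard_curve,
    polygenic_multiplier,
    sample_breast_course,
    sample_death,
    sample_ovarian_cancer,
)
from hbocsim.pedigree import Genotype, Person


def _woman(gene=None, z=0.0, birth_year=-50, surgeries=None):
    w = Person(id="w", family_id=0, local_idx=0, sex="F", relation="proband",
               birth_year=birth_year)
    w.genotype = Genotype(plp_gene=gene, z_breast=z, z_ovary=z)
    w.surgeries = surgeries or {}
    return w


def test_annual_hazard_identity_for_reference_woman(params):
    w = _woman()
    for age in (30, 50, 70):
        base = params.baseline_incidence["breast"][age]
        norm = math.exp(-0.5 * math.log(params.polygenic_hr_per_sd["breast"]) ** 2)
        assert annual_hazard(w, "breast", age, params) == pytest.approx(
            1 - math.exp(-base * norm)
        )


def test_polygenic_hazard_ratio():
    assert polygenic_multiplier(1.0, 1.6) / polygenic_multiplier(0.0, 1.6) == pytest.approx(1.6)
    # normalisation: population mean multiplier is 1
    z = np.random.default_rng(0).normal(size=200000)
    mults = np.exp(np.log(1.6) * z - 0.5 * np.log(1.6) ** 2)
    assert np.mean(mults) == pytest.approx(1.0, abs=0.01)


def test_surgery_multiplier_contract(params):
    w = _woman(surgeries={"BRRM": -10})  # surgery at age 40 (year -10, born -50)
    before = _woman()
    h_after = annual_hazard(w, "breast", 45, params)
    h_before = annual_hazard(before, "breast", 45, params)
    rate_before = -math.log(1 - h_before)
    rate_after = -math.log(1 - h_after)
    assert rate_after == pytest.approx(rate_before * params.surgery["risk_reduction"]["BRRM"])
    # before the surgery age the hazard is unchanged
    assert annual_hazard(w, "breast", 35, params) == \
        pytest.approx(annual_hazard(before, "breast", 35, params))


def test_annual_hazard_age_bounds(params):
    with pytest.raises(ValueError):
        annual_hazard(_woman(), "breast", 101, params)


def test_first_passage_inverts_cumulative_hazard():
    h = np.zeros(101)
    h[40:] = 0.1
    assert first_passage_year(h, 0.05) == 40
    assert first_passage_year(h, 0.95) == 49
    assert first_passage_year(h, 1e9) is None
    # multiplier segments: zero out after age 45
    assert first_passage_year(h, 0.95, segments=[(45, 0.0)]) is None


def test_breast_course_zero_hazard_gives_no_tumour():
    p0 = zero_hazard_params()
    rng = np.random.default_rng(1)
    assert sample_breast_course(_woman(), p0, rng) is None


def test_breast_course_after_brrm_is_none(params):
    rng = np.random.default_rng(1)
    assert sample_breast_course(_woman(surgeries={"BRRM": -20}), params, rng) is None


def test_degenerate_sojourn_schedules_symptomatic_dx(params_copy):
    params_copy.sojourn_dist = {"default": {"mu": math.log(2.0), "sigma": 1e-9}}
    rng = np.random.default_rng(3)
    for _ in range(50):
        t = sample_breast_course(_woman(z=1.0), params_copy, rng)
        if t is not None:
            assert t.age_at_diagnosis == t.age_at_onset + 2
            return
    pytest.fail("no tumour sampled in 50 draws")


def test_brca1_tumours_enriched_for_triple_negative(params):
    rng = np.random.default_rng(4)
    n = 4000
    tn_brca1 = np.mean([
        t.subtype == "TN"
        for t in (sample_breast_course(_woman("BRCA1", z=1.0), params, rng) for _ in range(n))
        if t is not None
    ])
    tn_none = np.mean([
        t.subtype == "TN"
        for t in (sample_breast_course(_woman(z=1.0), params, rng) for _ in range(n))
        if t is not None
    ])
    assert tn_brca1 > 2 * tn_none


def test_prognostics_immutable(params):
    t = TumourRecord(organ="breast", age_at_onset=50, age_at_diagnosis=52,
                     subtype="HR+", grade=2)
    assign_breast_prognostics(t, "screen", params, np.random.default_rng(0))
    with pytest.raises(RuntimeError, match="immutable"):
        assign_breast_prognostics(t, "screen", params, np.random.default_rng(0))


def test_screen_detected_tumours_stochastically_smaller(params):
    rng = np.random.default_rng(5)
    order = {"<10": 0, "10-20": 1, "21-50": 2, ">50": 3}

    def mean_size(mode):
        sizes = []
        for _ in range(4000):
            t = TumourRecord(organ="breast", age_at_onset=50, age_at_diagnosis=52,
                             subtype="HR+", grade=2)
            assign_breast_prognostics(t, mode, params, rng)
            sizes.append(order[t.size_class])
        return np.mean(sizes)

    assert mean_size("screen") < mean_size("symptomatic") - 0.3


def test_degenerate_size_table(params_copy):
    for mode in params_copy.tumour_models["breast"]["size_by_mode"]:
        params_copy.tumour_models["breast"]["size_by_mode"][mode] = {
            "<10": 1.0, "10-20": 0.0, "21-50": 0.0, ">50": 0.0
        }
    rng = np.random.default_rng(0)
    t = TumourRecord(organ="breast", age_at_onset=50, age_at_diagnosis=52,
                     subtype="HR+", grade=2)
    assign_breast_prognostics(t, "symptomatic", params_copy, rng)
    assert t.size_class == "<10"


def test_carrier_ovarian_cancer_high_grade_serous(params):
    rng = np.random.default_rng(0)
    t = sample_ovarian_cancer(_woman("BRCA1"), 52, params, rng)
    assert t.histology == "serous" and t.grade == 3
    assert t.age_at_onset == t.age_at_diagnosis == 52  # no preclinical phase


def test_ovarian_stage_ordering(params):
    rng = np.random.default_rng(1)
    dist_hg_serous = np.mean([
        sample_ovarian_cancer(_woman("BRCA1"), 60, params, rng).stage == "distant"
        for _ in range(3000)
    ])
    # mucinous grade 1 directly from the stage table
    tm = params.tumour_models["ovary"]
    p_mucinous_g1_distant = tm["stage_by_grade"][1]["distant"]
    assert dist_hg_serous > p_mucinous_g1_distant + 0.2


def test_rrso_before_event_blocks_ovarian_cancer(params):
    rng = np.random.default_rng(2)
    w = _woman(surgeries={"RRSO": -10})  # RRSO at 40 (born -50)
    assert sample_ovarian_cancer(w, 35, params, rng) is None  # event pre-dates organ removal? no: 35 < 40 -> blocked


def test_other_cause_death_from_spiked_lifetable(params_copy):
    params_copy.lifetable["F"] = np.zeros(101)
    params_copy.lifetable["F"][90] = 1.0
    w = _woman()
    age, cause = sample_death(w, params_copy, np.random.default_rng(0))
    assert (age, cause) == (90, "other")


def test_zero_excess_survival_means_no_cancer_deaths(params_copy):
    params_copy.survival["excess"] = [(o, s, b, 0.0) for (o, s, b, _) in params_copy.survival["excess"]]
    params_copy.lifetable["F"] = np.zeros(101)
    params_copy.lifetable["F"][95] = 1.0
    w = _woman()
    w.cancer_history = [TumourRecord(organ="breast", age_at_onset=50, age_at_diagnosis=52,
                                     subtype="HR+", grade=2, stage="distant",
                                     node_status="positive", metastasis=True)]
    age, cause = sample_death(w, params_copy, np.random.default_rng(1))
    assert cause == "other" and age == 95


def test_five_year_survival_recovers_input_rate(params):
    """Simulated 5-year survival for a stage stratum reproduces the
    exponential implied by its input excess rate (input-recovery oracle)."""
    t = TumourRecord(organ="breast", age_at_onset=55, age_at_diagnosis=55,
                     subtype="HR+", grade=2, stage="regional")
    rate = params.survival_excess("breast", "regional", 55) * \
        params.survival["subtype_multiplier"]["HR+"]
    rng = np.random.default_rng(3)
    n = 20000
    draws = rng.exponential(size=n)
    deaths_by_5 = np.mean([
        (a is not None and a < 60) for a in (cancer_death_age(t, e, params) for e in draws)
    ])
    expected = 1 - math.exp(-5 * rate)
    assert deaths_by_5 == pytest.approx(expected, abs=3 * math.sqrt(expected * (1 - expected) / n))


def test_incidence_recovery_against_input_curve(params):
    """With the polygenic normalisation on, simulated cumulative onset by 80
    for non-carriers matches the input baseline within Monte-Carlo error plus
    the small frailty (Jensen) gap."""
    rng = np.random.default_rng(11)
    n = 30000
    h = params.baseline_incidence["breast"]
    lam = h[:80].sum()
    z = rng.normal(size=n)
    mult = np.exp(np.log(params.polygenic_hr_per_sd["breast"]) * z
                  - 0.5 * np.log(params.polygenic_hr_per_sd["breast"]) ** 2)
    e = rng.exponential(size=n)
    onset_by_80 = np.mean(e < mult * lam)
    nominal = 1 - math.exp(-lam)
    assert onset_by_80 == pytest.approx(nominal, rel=0.05)


def test_all_cause_survival_non_increasing(params):
    q = params.lifetable["F"]
    s = np.cumprod(1 - q)
    assert np.all(np.diff(s) <= 1e-15)
    assert other_cause_death_age("F", 1e9, params) is None  # age-100 cap


def test_carrier_hazard_dominates_baseline(params):
    h_c = person_hazard_curve(_woman("BRCA1"), "breast", params)
    h_n = person_hazard_curve(_woman(), "breast", params)
    sel = params.baseline_incidence["breast"] > 0
    assert np.all(h_c[sel] >= h_n[sel])
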