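"""Screening pathways, screen outcomes, and risk-reducing surgery rules."""

import numpy as np
import pytest

from hbocsim.fixtures import ScriptedRNG
from hbocsim.natural_history import TumourRecord
from hbocsim.pedigree import Genotype, Person, TestState
from hbocsim.screening import (
    SurgeryEligibilityError,
    combined_performance,
    modalities_for,
    next_interval,
    sample_screening_start,
    sample_surgery,
    screen_event,
    surgery_eligible,
    update_risk_pathway,
)


def _woman(gene=None, known=False, birth_year=-40, cancers=0, surgeries=None):
    w = Person(id="w", family_id=0, local_idx=0, sex="F", relation="sibling",
               birth_year=birth_year)
    w.genotype = Genotype(plp_gene=gene)
    w.surgeries = surgeries or {}
    if known:
        w.test_state = TestState(predictive_tested_year=0, result="positive",
                                 result_gene=gene)
    for _ in range(cancers):
        w.cancer_history.append(
            TumourRecord(organ="breast", age_at_onset=38, age_at_diagnosis=39,
                         subtype="HR+", grade=2)
        )
    return w


def test_population_start_never_fraction(params):
    rng = np.random.default_rng(0)
    w = _woman()
    draws = [sample_screening_start(w, "population", params, rng) for _ in range(20000)]
    never = np.mean([d is None for d in draws])
    assert never == pytest.approx(0.30, abs=0.012)
    started = [d for d in draws if d is not None]
    assert min(started) >= 40 and max(started) <= 64


def test_degenerate_start_distribution(params_copy):
    params_copy.screening["start_cdf"]["population"] = [(50, 1.0)]
    w = _woman()
    rng = np.random.default_rng(1)
    assert all(
        sample_screening_start(w, "population", params_copy, rng) == 50
        for _ in range(100)
    )


def test_moderate_start_is_high_risk_plus_ten(params):
    w = _woman()
    u = 0.3  # same uptake-delay draw for both pathways
    hr = sample_screening_start(w, "high_risk", params, ScriptedRNG([u]), at_age=28)
    mod = sample_screening_start(w, "moderate_risk", params, ScriptedRNG([u]), at_age=28)
    assert mod == hr + 10


def test_high_risk_start_never_mass(params):
    w = _woman()
    assert sample_screening_start(w, "high_risk", params, ScriptedRNG([0.99]), at_age=30) is None


def test_pathway_age_windows(params):
    assert modalities_for("high_risk", 30, params) == {"mammography", "MRI"}
    assert modalities_for("high_risk", 62, params) == {"mammography"}  # MRI stops at 59
    assert modalities_for("high_risk", 66, params) == set()
    assert modalities_for("moderate_risk", 34, params) == set()
    assert modalities_for("moderate_risk", 45, params) == {"mammography"}
    assert modalities_for("moderate_risk", 60, params) == set()
    assert modalities_for("population", 39, params) == set()
    assert modalities_for("population", 74, params) == {"mammography"}
    assert modalities_for("population", 75, params) == set()


def test_combined_sensitivity_dominates_single_modality(params):
    for age in (30, 45, 55, 63):
        s_m, _ = combined_performance({"mammography"}, age, params)
        s_r, _ = combined_performance({"MRI"}, age, params)
        s_both, spec_both = combined_performance({"mammography", "MRI"}, age, params)
        assert s_both >= max(s_m, s_r)
        assert spec_both <= min(1.0, *(combined_performance({m}, age, params)[1]
                                       for m in ("mammography", "MRI")))


def test_screen_event_outcomes(params_copy):
    params_copy.screening["performance"] = [("mammography", 0, 100, 1.0, 1.0)]
    w = _woman()
    rng = np.random.default_rng(0)
    assert screen_event(w, {"mammography"}, 50, params_copy, rng, True) == "true_positive"
    assert screen_event(w, {"mammography"}, 50, params_copy, rng, False) == "true_negative"
    params_copy.screening["performance"] = [("mammography", 0, 100, 0.0, 0.0)]
    assert screen_event(w, {"mammography"}, 50, params_copy, rng, True) == "false_negative"
    assert screen_event(w, {"mammography"}, 50, params_copy, rng, False) == "false_positive"


def test_update_risk_pathway(params):
    w = _woman("BRCA1", known=True, birth_year=-30)
    assert update_risk_pathway(w, "BRCA1", params).pathway == "high_risk"
    assert update_risk_pathway(w, "ATM", params).pathway == "moderate_risk"
    assert update_risk_pathway(w, None, params).pathway == "population"


def test_interval_is_target_plus_geometric_delay(params):
    rng = np.random.default_rng(2)
    pop = [next_interval("population", params, rng) for _ in range(2000)]
    hr = [next_interval("high_risk", params, rng) for _ in range(2000)]
    assert min(pop) == 2 and min(hr) == 1
    assert np.mean(pop) == pytest.approx(2 + (1 - 0.6) / 0.6, abs=0.1)


# -- surgery ----------------------------------------------------------------


def test_atm_brrm_uptake_half_of_brca2(params):
    for age in (35, 45, 55):
        assert params.surgery_uptake("BRRM", "ATM", age) == pytest.approx(
            0.5 * params.surgery_uptake("BRRM", "BRCA2", age)
        )


def test_palb2_brrm_uptake_equals_brca2(params):
    for age in (35, 45, 55):
        assert params.surgery_uptake("BRRM", "PALB2", age) == \
            params.surgery_uptake("BRRM", "BRCA2", age)


def test_rad51c_rrso_age_window(params):
    w43 = _woman("RAD51C", known=True, birth_year=-43)
    with pytest.raises(SurgeryEligibilityError):
        sample_surgery(w43, "RRSO", 43, params, ScriptedRNG([0.0]))
    w46 = _woman("RAD51C", known=True, birth_year=-46)
    assert sample_surgery(w46, "RRSO", 46, params, ScriptedRNG([0.0])) is True
    assert sample_surgery(w46, "RRSO", 46, params, ScriptedRNG([0.999])) is False


def test_brip1_rrso_from_sixty(params):
    assert not surgery_eligible(_woman("BRIP1", known=True), "RRSO", 55, params)
    assert surgery_eligible(_woman("BRIP1", known=True), "RRSO", 61, params)


def test_brrm_requires_known_carrier_status(params):
    assert not surgery_eligible(_woman("BRCA1", known=False), "BRRM", 40, params)
    assert surgery_eligible(_woman("BRCA1", known=True), "BRRM", 40, params)


def test_brrm_not_offered_to_breast_cancer_affected(params):
    w = _woman("BRCA1", known=True, cancers=1)
    assert not surgery_eligible(w, "BRRM", 45, params)


def test_rad51d_ineligible_for_brrm(params):
    assert not surgery_eligible(_woman("RAD51D", known=True), "BRRM", 40, params)


def test_surgery_absorbing(params):
    w = _woman("BRCA1", known=True, surgeries={"RRSO": -2})
    with pytest.raises(SurgeryEligibilityError):
        sample_surgery(w, "RRSO", 45, params, ScriptedRNG([0.0]))


def test_crrm_requires_unilateral_breast_cancer(params):
    assert not surgery_eligible(_woman(), "CRRM", 45, params)
    assert surgery_eligible(_woman(cancers=1), "CRRM", 45, params)
    assert not surgery_eligible(_woman(cancers=2), "CRRM", 45, params)


def test_crrm_uptake_higher_for_known_carriers(params):
    carrier = _woman("BRCA2", known=True, cancers=1)
    noncarrier = _woman(cancers=1)
    u = params.surgery["crrm_uptake"]
    assert u["carrier"] > u["noncarrier"]
    boundary = (u["noncarrier"] + u["carrier"]) / 2
    assert sample_surgery(carrier, "CRRM", 45, params, ScriptedRNG([boundary])) is True
    assert sample_surgery(noncarrier, "CRRM", 45, params, ScriptedRNG([boundary])) is False
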