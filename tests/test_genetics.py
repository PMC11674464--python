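"""Referral model, funded-testing eligibility, predictive cascade logic and
the obligate-non-carrier lineage algorithm."""

import itertools

import numpy as np
import pytest

from hbocsim.fixtures import (
    enumerate_genotype_constraints,
    oracle_possible_carriers,
    toy_three_generation,
    toy_trio,
)
from hbocsim.genetics import (
    FamilyVariantKnowledge,
    TestingError,
    degree_to_index,
    is_obligate_noncarrier,
    is_test_eligible,
    perform_test,
    predictive_eligible,
    predictive_uptake_probability,
    referral_probability,
)
from hbocsim.natural_history import TumourRecord
from hbocsim.pedigree import Genotype


def _breast(age, subtype="HR+", grade=2, course=1):
    return TumourRecord(organ="breast", age_at_onset=age - 1, age_at_diagnosis=age,
                        subtype=subtype, grade=grade, course=course,
                        prognostics_assigned=True)


def _ovary(age, histology="serous", grade=3):
    return TumourRecord(organ="ovary", age_at_onset=age, age_at_diagnosis=age,
                        histology=histology, grade=grade, prognostics_assigned=True)


# -- referral ----------------------------------------------------------------


def test_referral_breast_reference_category(params):
    t = _breast(35, subtype="TN", grade=1)
    odds = 3.23
    assert referral_probability(t, 35, False, False, params) == pytest.approx(odds / (1 + odds))


def test_referral_breast_derived_example(params):
    t = _breast(45, subtype="TN", grade=3)
    odds = 3.23 * 0.38 * 2.37
    assert referral_probability(t, 45, False, False, params) == pytest.approx(odds / (1 + odds))
    assert referral_probability(t, 45, False, False, params) == pytest.approx(0.744, abs=0.001)


def test_referral_ovarian_derived_example(params):
    t = _ovary(65, histology="serous", grade=3)
    odds = 3.09 * 0.20 * 1.06
    assert referral_probability(t, 65, False, False, params) == pytest.approx(odds / (1 + odds))
    assert referral_probability(t, 65, False, False, params) == pytest.approx(0.396, abs=0.001)


def test_referral_her2_gets_both_subtype_terms(params):
    t = _breast(45, subtype="HER2", grade=3)
    odds = 3.23 * 0.38 * 2.37 * 0.50 * 0.22
    assert referral_probability(t, 45, False, False, params) == pytest.approx(odds / (1 + odds))


def test_referral_prior_breast_multiplier(params):
    t = _ovary(55, histology="endometrioid", grade=1)
    base = referral_probability(t, 55, False, False, params)
    with_prior = referral_probability(t, 55, False, True, params)
    assert with_prior > base
    odds = 3.09 * 17.75
    assert with_prior == pytest.approx(odds / (1 + odds))


def test_referral_unknown_organ_rejected(params):
    t = TumourRecord(organ="lung", age_at_onset=50, age_at_diagnosis=50)
    with pytest.raises(ValueError):
        referral_probability(t, 50, False, False, params)


# -- eligibility --------------------------------------------------------------


def test_tn_breast_at_or_under_fifty_eligible():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.cancer_history = [_breast(48, subtype="TN", grade=3)]
    assert is_test_eligible(pro, fam, year=pro.birth_year + 48)


def test_tn_breast_over_fifty_needs_affected_relative():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.cancer_history = [_breast(55, subtype="TN", grade=3)]
    year = pro.birth_year + 55
    assert not is_test_eligible(pro, fam, year)
    fam.members["mo"].cancer_history = [_breast(60)]
    assert is_test_eligible(pro, fam, year)


def test_mucinous_low_grade_old_ovarian_ineligible():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.cancer_history = [_ovary(75, histology="mucinous", grade=1)]
    assert not is_test_eligible(pro, fam, pro.birth_year + 75)


def test_serous_high_grade_any_age_eligible():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.cancer_history = [_ovary(78, histology="serous", grade=2)]
    assert is_test_eligible(pro, fam, pro.birth_year + 78)


def test_nonmucinous_grade2_under70_eligible():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.cancer_history = [_ovary(65, histology="clear_cell", grade=2)]
    assert is_test_eligible(pro, fam, pro.birth_year + 65)
    pro.cancer_history = [_ovary(72, histology="clear_cell", grade=2)]
    assert not is_test_eligible(pro, fam, pro.birth_year + 72)


def test_three_affected_relatives_eligible():
    fam = toy_three_generation()
    pro = fam.members["pro"]
    pro.cancer_history = [_breast(60, subtype="HR+", grade=1)]
    year = pro.birth_year + 60
    assert not is_test_eligible(pro, fam, year)
    for pid in ("mo", "aunt", "mgm"):
        fam.members[pid].cancer_history = [_breast(55)]
    assert is_test_eligible(pro, fam, year)


def test_bilateral_breast_cancer_eligible():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.cancer_history = [_breast(55), _breast(58, course=2)]
    assert is_test_eligible(pro, fam, pro.birth_year + 58)


# -- predictive uptake --------------------------------------------------------


@pytest.mark.parametrize(
    "degree,age,sex,elapsed,expected",
    [
        (1, 35, "F", 0, 0.286),
        (1, 35, "F", 2, 0.098),
        (1, 35, "F", 5, 0.022),
        (2, 55, "F", 5, 0.002),
        (2, 20, "M", 4, 0.034 * 0.422),
        (1, 17, "F", 0, 0.0),
        (3, 35, "F", 0, 0.112),  # beyond second degree treated as second
    ],
)
def test_predictive_uptake_lookup(params, degree, age, sex, elapsed, expected):
    assert predictive_uptake_probability(degree, age, sex, elapsed, params) == \
        pytest.approx(expected)


# -- testing ------------------------------------------------------------------


def test_panel_scope_chek2_not_on_high_risk_panel():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.genotype = Genotype(plp_gene="CHEK2_1100delC")
    assert perform_test(pro, fam, "diagnostic", 5, panel="high_risk") == "negative"
    assert fam.variant_knowledge is None
    fam2 = toy_trio()
    pro2 = fam2.members["ch"]
    pro2.genotype = Genotype(plp_gene="CHEK2_1100delC")
    assert perform_test(pro2, fam2, "diagnostic", 5, panel="extended") == "positive"
    assert fam2.variant_knowledge.gene == "CHEK2_1100delC"


def test_double_panel_test_is_error():
    fam = toy_trio()
    pro = fam.members["ch"]
    perform_test(pro, fam, "diagnostic", 5)
    with pytest.raises(TestingError):
        perform_test(pro, fam, "diagnostic", 6)


def test_predictive_requires_known_variant():
    fam = toy_trio()
    with pytest.raises(TestingError):
        perform_test(fam.members["mo"], fam, "predictive", 5)


def test_predictive_detects_family_gene_exactly():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.genotype = Genotype(plp_gene="BRCA2")
    fam.members["mo"].genotype = Genotype(plp_gene="BRCA2")
    perform_test(pro, fam, "diagnostic", 3)
    assert fam.variant_knowledge.year_identified == 3
    assert perform_test(fam.members["mo"], fam, "predictive", 4) == "positive"
    assert perform_test(fam.members["fa"], fam, "predictive", 4) == "negative"


def test_negative_predictive_then_cancer_still_panel_testable():
    fam = toy_trio()
    pro = fam.members["ch"]
    pro.genotype = Genotype(plp_gene="BRCA1")
    perform_test(pro, fam, "diagnostic", 2)
    mo = fam.members["mo"]
    assert perform_test(mo, fam, "predictive", 3) == "negative"
    # later cancer: full panel still allowed (she might carry another gene)
    assert perform_test(mo, fam, "diagnostic", 10) == "negative"


# -- obligate non-carriers / lineage localisation -----------------------------


def test_maternal_grandfather_positive_excludes_paternal_side():
    fam = toy_three_generation()
    fam.members["mgf"].genotype = Genotype(plp_gene="BRCA1")
    fam.members["pro"].genotype = Genotype(plp_gene="BRCA1")
    perform_test(fam.members["pro"], fam, "diagnostic", 1)
    assert predictive_eligible(fam.members["pgm"], fam)  # both sides still open
    perform_test(fam.members["mgf"], fam, "predictive", 2)
    for pid in ("pgm", "pgf", "uncle"):
        assert is_obligate_noncarrier(fam.members[pid], fam)
        assert not predictive_eligible(fam.members[pid], fam)
    for pid in ("mo", "aunt", "sib"):
        assert not is_obligate_noncarrier(fam.members[pid], fam)
        assert predictive_eligible(fam.members[pid], fam)
    # the father is off the maternal lineage too
    assert is_obligate_noncarrier(fam.members["fa"], fam)


def test_both_parents_negative_child_obligate():
    fam = toy_trio()
    fam.members["ch"].genotype = Genotype(plp_gene="BRCA2")
    k = FamilyVariantKnowledge(gene="BRCA2", year_identified=0, index_carrier_id="ch")
    k.record("ch", "positive")
    fam.variant_knowledge = k
    sib_like = fam  # child of fa+mo
    k.record("mo", "negative")
    assert not is_obligate_noncarrier(fam.members["fa"], fam)
    k.record("fa", "negative")
    # now the proband's positive is inconsistent with both parents negative,
    # and nobody else can carry
    assert k.possible_carriers(fam) == set()


def test_tested_relatives_not_predictive_eligible():
    fam = toy_trio()
    fam.members["ch"].genotype = Genotype(plp_gene="BRCA1")
    perform_test(fam.members["ch"], fam, "diagnostic", 1)
    perform_test(fam.members["mo"], fam, "predictive", 2)
    assert not predictive_eligible(fam.members["mo"], fam)  # already tested
    assert not predictive_eligible(fam.members["ch"], fam)  # panel tested


def test_degree_to_index(params):
    fam = toy_three_generation()
    fam.members["pro"].genotype = Genotype(plp_gene="BRCA1")
    perform_test(fam.members["pro"], fam, "diagnostic", 1)
    assert degree_to_index(fam.members["mo"], fam) == 1
    assert degree_to_index(fam.members["aunt"], fam) == 2
    assert degree_to_index(fam.members["pgf"], fam) == 2


def test_oracle_matches_production_on_single_observations():
    fam = toy_three_generation()
    from hbocsim.genetics import _possible_carriers

    for pid in fam.members:
        for result in ("positive", "negative"):
            observed = {pid: result}
            assert _possible_carriers(fam, observed) == \
                oracle_possible_carriers(fam, observed), (pid, result)


def test_oracle_flags_impossible_observations():
    fam = toy_trio()
    observed = {"mo": "negative", "fa": "negative", "ch": "positive"}
    assert enumerate_genotype_constraints(fam, observed) == []
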