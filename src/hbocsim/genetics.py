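"""Clinical genetics services: referral after a cancer diagnosis, eligibility
for publicly funded testing, diagnostic (full-panel) testing, and predictive
cascade testing with family-knowledge propagation.

Referral is an odds model (constant x odds-ratio terms per tumour and
patient characteristics). Eligibility encodes the funding criteria: the 10%
carrier-probability threshold is assumed met for triple-negative breast
cancer at/under 50 (or any age with an affected relative), a strong family
history (>= 3 affected first/second-degree relatives), bilateral breast
cancer, grade 2/3 serous ovarian cancer at any age, and non-mucinous grade
2/3 ovarian cancer under 70.

Once a family variant is identified, relatives are eligible for predictive
testing unless they are obligate non-carriers. Obligate status is computed
by lineage constraint propagation: the variant entered the family through a
single founder (no de novo events), so a person can carry it only if some
founder origin has a descent path to them avoiding everyone who has tested
negative, with every confirmed carrier reachable from that same origin. A
positive in, say, a maternal grandfather therefore localises the variant to
the maternal lineage and removes the paternal side from eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .natural_history import TumourRecord
from .parameters import (
    EXTENDED_PANEL,
    HIGH_RISK_GENES,
    ParameterSet,
    pred_age_band,
    time_band,
)
from .pedigree import Family, Person

PANEL_GENES = {"high_risk": list(HIGH_RISK_GENES), "extended": list(EXTENDED_PANEL)}


class TestingError(RuntimeError):
    __test__ = False  # not a pytest test class despite the name


@dataclass
class FamilyVariantKnowledge:
    """What the family (and its clinicians) know about the family variant."""

    gene: str
    year_identified: int
    index_carrier_id: str
    #: observed results for the family gene: person id -> "positive"/"negative"
    observed: dict[str, str] = field(default_factory=dict)
    _possible_cache: set[str] | None = field(default=None, repr=False)

    def record(self, person_id: str, result: str) -> None:
        self.observed[person_id] = result
        self._possible_cache = None

    def possible_carriers(self, family: Family) -> set[str]:
        """Ids of members who could still carry the family variant given the
        observed results (confirmed carriers are included)."""
        if self._possible_cache is None:
            self._possible_cache = _possible_carriers(family, self.observed)
        return self._possible_cache


def _possible_carriers(family: Family, observed: dict[str, str]) -> set[str]:
    negatives = {pid for pid, r in observed.items() if r == "negative"}
    positives = {pid for pid, r in observed.items() if r == "positive"}
    possible: set[str] = set()
    for origin in family.founders():
        if origin.id in negatives:
            continue
        reach = {origin.id}
        frontier = [origin.id]
        while frontier:
            nxt = []
            for pid in frontier:
                for child in family.children_of(pid):
                    if child.id in negatives or child.id in reach:
                        continue
                    reach.add(child.id)
                    nxt.append(child.id)
            frontier = nxt
        if positives <= reach:
            possible |= reach
    return possible


def is_obligate_noncarrier(person: Person, family: Family) -> bool:
    k = family.variant_knowledge
    if k is None:
        return False
    return person.id not in k.possible_carriers(family)


# ---------------------------------------------------------------------------
# referral


def referral_probability(
    cancer: TumourRecord,
    age: int,
    survival_lt_12m: bool,
    prior_breast: bool,
    p: ParameterSet,
) -> float:
    """Probability of referral to genetics services in the diagnosis year:
    odds = constant x product of applicable odds ratios; p = odds/(1+odds)."""
    if cancer.organ == "breast":
        m = p.referral_model["breast"]
        odds = m["constant"]
        if 40 <= age <= 49:
            odds *= m["age_40_49"]
        elif 50 <= age <= 69:
            odds *= m["age_50_69"]
        elif age >= 70:
            odds *= m["age_70_plus"]
        if survival_lt_12m:
            odds *= m["survival_lt_12m"]
        if cancer.grade is not None and cancer.grade >= p.notes.get("breast_high_grade_min", 3):
            odds *= m["high_grade"]
        if cancer.subtype != "TN":
            odds *= m["non_triple_negative"]
            if cancer.subtype == "HER2":
                odds *= m["her2"]
    elif cancer.organ == "ovary":
        m = p.referral_model["ovary"]
        odds = m["constant"]
        if 60 <= age <= 74:
            odds *= m["age_60_74"]
        elif age >= 75:
            odds *= m["age_75_plus"]
        if survival_lt_12m:
            odds *= m["survival_lt_12m"]
        if cancer.grade is not None and cancer.grade >= p.notes.get("ovary_high_grade_min", 2):
            odds *= m["high_grade"]
        if prior_breast:
            odds *= m["prior_breast"]
        if cancer.histology == "mucinous":
            odds *= m["mucinous"]
        elif cancer.histology == "other":
            odds *= m["other_histotype"]
    else:
        raise ValueError(f"unknown cancer organ {cancer.organ!r}")
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# eligibility


def is_test_eligible(person: Person, family: Family, year: int) -> bool:
    """Whether a cancer-affected, referred person meets the funded-testing
    criteria, evaluated against all cancers diagnosed by ``year``."""
    tumours = [t for t in person.cancer_history
               if t.age_at_diagnosis + person.birth_year <= year]
    if not tumours:
        return False
    affected = family.affected_relative_count(person.id, year)
    if affected >= 3:
        return True
    breast = [t for t in tumours if t.organ == "breast"]
    if len(breast) >= 2:  # bilateral breast cancer
        return True
    for t in breast:
        if t.subtype == "TN" and (t.age_at_diagnosis <= 50 or affected >= 1):
            return True
    for t in tumours:
        if t.organ != "ovary" or t.grade is None or t.grade < 2:
            continue
        if t.histology == "serous":
            return True
        if t.histology != "mucinous" and t.age_at_diagnosis < 70:
            return True
    return False


def predictive_eligible(person: Person, family: Family) -> bool:
    """Eligibility for predictive (cascade) testing: a family variant is
    known, the person has had neither a full panel nor a prior predictive
    test, and they are not an obligate non-carrier."""
    k = family.variant_knowledge
    if k is None:
        return False
    ts = person.test_state
    if ts.panel_tested_year is not None or ts.predictive_tested_year is not None:
        return False
    return person.id in k.possible_carriers(family)


def predictive_uptake_probability(
    degree: int, age: int, sex: str, years_since_identified: int, p: ParameterSet
) -> float:
    """Annual probability that an eligible relative completes a predictive
    test, by degree of relation, age band and time since the family variant
    was identified; males take the rate ratio, under-18s never test."""
    if age < 18:
        return 0.0
    deg = 1 if degree <= 1 else 2
    prob = p.predictive_uptake[(deg, pred_age_band(age), time_band(years_since_identified))]
    if sex == "M":
        prob *= p.male_predictive_rate_ratio
    return prob


# ---------------------------------------------------------------------------
# testing


def perform_test(
    person: Person, family: Family, kind: str, year: int, panel: str = "high_risk"
) -> str:
    """Perform a diagnostic (full-panel) or predictive test; the assay is
    error-free. Returns "positive" or "negative", updates the person's test
    state, and creates/updates the family variant knowledge on a positive.

    A diagnostic test detects the person's variant iff its gene is on the
    chosen panel. A predictive test requires a known family variant and
    detects carrier status for that gene exactly. Testing a person twice
    with the full panel is an error.
    """
    ts = person.test_state
    k = family.variant_knowledge
    gene = person.genotype.plp_gene
    if kind == "diagnostic":
        if ts.panel_tested_year is not None:
            raise TestingError(f"{person.id} already panel tested")
        positive = gene is not None and gene in PANEL_GENES[panel]
        ts.panel_tested_year = year
        ts.panel = panel
        if positive:
            ts.result, ts.result_gene = "positive", gene
        elif ts.result != "positive":
            ts.result = "negative"
        if k is not None and k.gene in PANEL_GENES[panel]:
            k.record(person.id, "positive" if gene == k.gene else "negative")
    elif kind == "predictive":
        if k is None:
            raise TestingError("predictive testing requires a known family variant")
        if ts.panel_tested_year is not None:
            raise TestingError(f"{person.id} not predictive-eligible after panel testing")
        positive = gene == k.gene
        ts.predictive_tested_year = year
        if positive:
            ts.result, ts.result_gene = "positive", gene
        elif ts.result != "positive":
            ts.result = "negative"
        k.record(person.id, "positive" if positive else "negative")
    else:
        raise ValueError(f"unknown test kind {kind!r}")

    if positive and family.variant_knowledge is None:
        family.variant_knowledge = FamilyVariantKnowledge(
            gene=gene, year_identified=year, index_carrier_id=person.id
        )
        family.variant_knowledge.record(person.id, "positive")
    return "positive" if positive else "negative"


def degree_to_index(person: Person, family: Family) -> int:
    """Degree of relation to the index carrier for the uptake table (first
    or second; anything more distant is treated as second degree)."""
    k = family.variant_knowledge
    if k is None:
        return 2
    degs = family.relatives_by_degree(k.index_carrier_id)
    return degs.get(person.id, 2)
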