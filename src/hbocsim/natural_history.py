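"""Cancer natural history: onset hazards (monogenic x polygenic x surgery),
the preclinical breast sojourn phase, tumour characteristics, and death from
cancer or other causes.

Breast cancer onset is the start of asymptomatic but screen-detectable
disease; the tumour is diagnosed symptomatically when the sojourn time
expires unless screen-detected or removed by risk-reducing surgery first.
Ovarian cancer has no preclinical phase (onset = diagnosis), and carrier
ovarian cancers diagnosed after age 25 are high-grade serous.

All hazards are annual piecewise-constant rates on integer ages 0..100;
event ages are sampled by inverting the cumulative hazard against a unit
exponential draw, so simulated incidence reproduces the input curves by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .parameters import MAX_AGE, ParameterSet

BREAST_SUBTYPES = ["TN", "HER2", "HR+"]
SIZE_CLASSES = ["<10", "10-20", "21-50", ">50"]
OVARIAN_HISTOLOGIES = ["serous", "endometrioid", "clear_cell", "mucinous", "other"]
STAGES = ["local", "regional", "distant"]


@dataclass
class TumourRecord:
    organ: str  # "breast" | "ovary"
    age_at_onset: int
    age_at_diagnosis: int
    detection_mode: str = "symptomatic"  # "symptomatic" | "screen" | "baseline"
    # breast fields
    subtype: str | None = None
    grade: int | None = None
    size_class: str | None = None
    node_status: str | None = None  # "positive" | "negative"
    metastasis: bool | None = None
    sojourn_time: float | None = None
    course: int = 1  # 1 = first breast primary, 2 = contralateral
    # ovarian fields
    histology: str | None = None
    stage: str | None = None
    prognostics_assigned: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TumourRecord":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# hazards


def polygenic_multiplier(z: float, hr_per_sd: float) -> float:
    """Polygenic hazard multiplier, normalised so its population mean is 1
    (dividing by E[HR^Z] = exp(ln(HR)^2 / 2) for standard-normal Z)."""
    log_hr = math.log(hr_per_sd)
    return math.exp(log_hr * z - 0.5 * log_hr * log_hr)


def surgery_multiplier(person, organ: str, age: int, p: ParameterSet) -> float:
    m = 1.0
    if organ == "breast":
        if "BRRM" in person.surgeries and age >= person.surgeries["BRRM"] - person.birth_year:
            m *= p.surgery["risk_reduction"]["BRRM"]
    else:
        if "RRSO" in person.surgeries and age >= person.surgeries["RRSO"] - person.birth_year:
            m *= p.surgery["risk_reduction"]["RRSO"]
    if organ == "breast" and "RRSO" in person.surgeries \
            and age >= person.surgeries["RRSO"] - person.birth_year:
        m *= p.surgery.get("rrso_breast_multiplier", 1.0)
    return m


def annual_hazard(person, organ: str, age: int, p: ParameterSet) -> float:
    """Per-year probability of cancer onset for ``person`` at ``age``:
    1 - exp(-h) where h = base(gene, organ, age) x normalised polygenic
    multiplier x surgery multiplier."""
    if not 0 <= age <= MAX_AGE:
        raise ValueError(f"age {age} outside hazard tables (0-{MAX_AGE})")
    h = p.hazard(person.genotype.plp_gene, organ)[age]
    h *= polygenic_multiplier(person.genotype.z(organ), p.polygenic_hr_per_sd[organ])
    h *= surgery_multiplier(person, organ, age, p)
    return 1.0 - math.exp(-h)


def person_hazard_curve(person, organ: str, p: ParameterSet) -> np.ndarray:
    """Full age 0-100 annual hazard (rate, not probability) excluding surgery
    effects, which are handled as multiplier segments."""
    h = p.hazard(person.genotype.plp_gene, organ)
    return h * polygenic_multiplier(person.genotype.z(organ), p.polygenic_hr_per_sd[organ])


def first_passage_year(
    hazard: np.ndarray, exp_draw: float, segments: list[tuple[int, float]] | None = None
) -> int | None:
    """First integer age at which the accumulated hazard reaches ``exp_draw``
    (a unit-exponential draw), or None if the event never happens by age 100.

    ``segments`` is a piecewise-constant multiplier timeline as
    [(start_age, multiplier), ...] with start ages increasing; the multiplier
    of the last segment at or before an age applies.
    """
    h = np.asarray(hazard, float)
    if segments:
        mult = np.ones_like(h)
        for start, m in segments:
            mult[max(0, start):] = m
        h = h * mult
    cum = np.cumsum(h)
    idx = int(np.searchsorted(cum, exp_draw, side="left"))
    return idx if idx <= MAX_AGE else None


def _draw_categorical(rng, dist: dict) -> Any:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


# ---------------------------------------------------------------------------
# breast course


def sample_sojourn(gene: str | None, p: ParameterSet, rng) -> float:
    sp = p.sojourn_params(gene)
    return float(rng.lognormal(mean=sp["mu"], sigma=sp["sigma"]))


def draw_breast_characteristics(gene: str | None, p: ParameterSet, rng) -> tuple[str, int]:
    tm = p.tumour_models["breast"]
    subtype = _draw_categorical(rng, tm["subtype_by_gene"][gene if gene else "none"])
    grade = _draw_categorical(rng, tm["grade_by_subtype"][subtype])
    return subtype, int(grade)


def sample_breast_course(person, p: ParameterSet, rng) -> TumourRecord | None:
    """Sample a full preclinical breast course for a woman: onset age from
    the genotype-adjusted hazards, hormone-receptor subtype and grade
    conditional on genotype, and a lognormal sojourn time. The returned
    record has its symptomatic diagnosis scheduled at onset + sojourn;
    screening or surgery may pre-empt it in the simulation. Returns None if
    onset never occurs (or the woman has had a BRRM)."""
    if person.sex != "F" or "BRRM" in person.surgeries:
        return None
    h = person_hazard_curve(person, "breast", p)
    onset = first_passage_year(h, rng.exponential())
    if onset is None:
        return None
    subtype, grade = draw_breast_characteristics(person.genotype.plp_gene, p, rng)
    sojourn = sample_sojourn(person.genotype.plp_gene, p, rng)
    return TumourRecord(
        organ="breast",
        age_at_onset=onset,
        age_at_diagnosis=onset + int(round(sojourn)),
        detection_mode="symptomatic",
        subtype=subtype,
        grade=grade,
        sojourn_time=sojourn,
    )


def assign_breast_prognostics(
    t: TumourRecord, detection_mode: str, p: ParameterSet, rng
) -> TumourRecord:
    """On detection, assign tumour size, node status and metastasis
    conditional on the detection mode; the fields are fixed thereafter and a
    second call is an error."""
    if t.prognostics_assigned:
        raise RuntimeError("prognostic characteristics already assigned and are immutable")
    tm = p.tumour_models["breast"]
    t.detection_mode = detection_mode
    t.size_class = _draw_categorical(rng, tm["size_by_mode"][detection_mode])
    p_nodes = tm["node_pos_by_size"][t.size_class]
    t.node_status = "positive" if rng.random() < p_nodes else "negative"
    p_met = tm["metastasis_by_nodes"][t.node_status]
    t.metastasis = bool(rng.random() < p_met)
    t.stage = "distant" if t.metastasis else ("regional" if t.node_status == "positive" else "local")
    t.prognostics_assigned = True
    return t


# ---------------------------------------------------------------------------
# ovarian cancer


def _ovary_age_band(age: int) -> str:
    if age < 50:
        return "<50"
    if age < 70:
        return "50-69"
    return "70+"


def sample_ovarian_cancer(person, age: int, p: ParameterSet, rng) -> TumourRecord | None:
    """Characteristics of an ovarian cancer diagnosed at ``age``.

    Carriers diagnosed after age 25 get high-grade serous disease; otherwise
    histology is conditional on age, grade on histology, and stage on grade
    with an extra shift toward distant stage for serous tumours. Returns
    None if the woman has had an RRSO before ``age`` (organ removed; the
    small residual risk is handled by the hazard multiplier upstream, and a
    post-RRSO event reaching this point keeps serous/carrier rules)."""
    if person.sex != "F":
        return None
    if "RRSO" in person.surgeries and age < person.surgeries["RRSO"] - person.birth_year:
        return None
    tm = p.tumour_models["ovary"]
    carrier = person.genotype.plp_gene is not None
    if carrier and age > 25:
        histology, grade = "serous", 3
    else:
        histology = _draw_categorical(rng, tm["histology_by_age"][_ovary_age_band(age)])
        grade = int(_draw_categorical(rng, tm["grade_by_histology"][histology]))
    stage_dist = dict(tm["stage_by_grade"][grade])
    if histology == "serous":
        shift = min(tm["serous_distant_shift"], stage_dist["local"])
        stage_dist["local"] -= shift
        stage_dist["distant"] += shift
    stage = _draw_categorical(rng, stage_dist)
    return TumourRecord(
        organ="ovary",
        age_at_onset=age,
        age_at_diagnosis=age,
        detection_mode="symptomatic",
        histology=histology,
        grade=grade,
        stage=stage,
        prognostics_assigned=True,
    )


# ---------------------------------------------------------------------------
# death


def other_cause_death_age(sex: str, exp_draw: float, p: ParameterSet) -> int | None:
    """Other-cause death age from the sex-specific lifetable, or None if the
    person survives to the age-100 cap."""
    q = p.lifetable[sex]
    h = -np.log(np.clip(1.0 - q, 1e-12, 1.0))
    return first_passage_year(h, exp_draw)


def cancer_excess_rate(t: TumourRecord, age: int, p: ParameterSet) -> float:
    rate = p.survival_excess(t.organ, t.stage, age)
    if t.organ == "breast" and t.subtype is not None:
        rate *= p.survival["subtype_multiplier"][t.subtype]
    elif t.organ == "ovary" and t.histology is not None:
        rate *= p.survival["histology_multiplier"][t.histology]
    return rate


def cancer_death_age(t: TumourRecord, exp_draw: float, p: ParameterSet) -> int | None:
    """Age at cancer-specific death for a diagnosed tumour, sampled from the
    annual excess-mortality rate (active for ``excess_years`` after
    diagnosis), or None if the person outlives the excess window."""
    years = int(p.survival["excess_years"])
    h = np.zeros(MAX_AGE + 1)
    for a in range(t.age_at_diagnosis, min(MAX_AGE, t.age_at_diagnosis + years) + 1):
        h[a] = cancer_excess_rate(t, a, p)
    return first_passage_year(h, exp_draw)


def sample_death(person, p: ParameterSet, rng) -> tuple[int, str]:
    """Sample (age at death, cause) for a person given their current cancer
    history: other-cause mortality from the lifetable competes with
    cancer-specific excess mortality after each diagnosis; the earliest event
    wins, and survivors exit at the age-100 cap with cause "none"."""
    other = other_cause_death_age(person.sex, rng.exponential(), p)
    best_age = other if other is not None else MAX_AGE
    cause = "other" if other is not None else "none"
    for t in person.cancer_history:
        ca = cancer_death_age(t, rng.exponential(), p)
        if ca is not None and ca < best_age:
            best_age, cause = ca, t.organ
    return best_age, cause
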