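"""Breast screening and risk-reducing surgery.

Population screening models the national two-yearly mammography programme:
women start between ages 40 and 64 (about 30% never participate) and screen
to age 74 with calibrated inter-screen delays. Women identified as carriers
move to annual surveillance: mammography 25-64 plus MRI 25-59 for high-risk
genes (BRCA1/2, PALB2), mammography 35-59 for moderate-risk genes, with the
age at first high-risk screen drawn from an uptake-delay distribution
(moderate-risk women start ten years later).

Risk-reducing surgery (BRRM, RRSO) is limited to known carriers with
age- and gene-specific annual uptake; CRRM is available to women with
unilateral breast cancer with carrier-dependent uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import HIGH_RISK_GENES, ParameterSet
from .pedigree import Person

PATHWAYS = ["none", "population", "moderate_risk", "high_risk"]


class SurgeryEligibilityError(RuntimeError):
    pass


@dataclass
class ScreeningState:
    pathway: str = "population"
    never: bool = False
    age_first_screen: int | None = None
    last_screen_age: int | None = None
    modalities: set = field(default_factory=lambda: {"mammography"})


def _draw_start_cdf(cdf: list[tuple[int, float]], u: float) -> int | None:
    """Inverse-CDF draw; mass beyond the final cumulative value means the
    woman never starts."""
    for offset, cum in cdf:
        if u <= cum:
            return offset
    return None


def sample_screening_start(
    person: Person, pathway: str, p: ParameterSet, rng, at_age: int | None = None
) -> int | None:
    """Age at first screen on a pathway, or None for never.

    Population: an absolute start age in [40, 64] (~30% of draws are never).
    High-risk: the eligibility age (``at_age``) plus an uptake delay.
    Moderate-risk: the high-risk draw delayed a further ten years for
    mammography.
    """
    u = rng.random()
    if pathway == "population":
        return _draw_start_cdf(p.screening["start_cdf"]["population"], u)
    delay = _draw_start_cdf(p.screening["start_cdf"]["high_risk"], u)
    if delay is None:
        return None
    base = at_age if at_age is not None else person.age_at_entry
    if pathway == "high_risk":
        return max(base, p.screening["high_risk"]["mammo_age_min"]) + delay
    if pathway == "moderate_risk":
        shift = p.screening["moderate"]["start_shift"]
        return max(base + delay + shift, p.screening["moderate"]["mammo_age_min"])
    raise ValueError(f"unknown screening pathway {pathway!r}")


def modalities_for(pathway: str, age: int, p: ParameterSet) -> set[str]:
    """Screening modalities available on a pathway at a given age."""
    mods: set[str] = set()
    if pathway == "population":
        start_ages = [a for a, _ in p.screening["start_cdf"]["population"]]
        if min(start_ages) <= age <= p.screening["population"]["age_stop"]:
            mods.add("mammography")
    elif pathway == "high_risk":
        hr = p.screening["high_risk"]
        if hr["mammo_age_min"] <= age <= hr["mammo_age_max"]:
            mods.add("mammography")
        if hr["mri_age_min"] <= age <= hr["mri_age_max"]:
            mods.add("MRI")
    elif pathway == "moderate_risk":
        mr = p.screening["moderate"]
        if mr["mammo_age_min"] <= age <= mr["mammo_age_max"]:
            mods.add("mammography")
    return mods


def combined_performance(modalities, age: int, p: ParameterSet) -> tuple[float, float]:
    """Sensitivity and specificity of a modality set: a tumour is detected if
    any modality detects it; a screen is falsely positive if any modality
    recalls, so combined specificity is the product."""
    sens_miss, spec = 1.0, 1.0
    if not modalities:
        return 0.0, 1.0
    for mod in sorted(modalities):
        s, sp = p.screening_performance(mod, age)
        sens_miss *= 1.0 - s
        spec *= sp
    return 1.0 - sens_miss, spec


def screen_event(
    person: Person, modalities, age: int, p: ParameterSet, rng,
    has_preclinical_tumour: bool,
) -> str:
    """Outcome of one attended screen: one of "true_positive",
    "false_negative", "false_positive", "true_negative". Detection of a
    preclinical tumour triggers a screen-detected diagnosis upstream."""
    sens, spec = combined_performance(modalities, age, p)
    u = rng.random()
    if has_preclinical_tumour:
        return "true_positive" if u < sens else "false_negative"
    return "false_positive" if u > spec else "true_negative"


def risk_pathway_for_gene(gene: str, p: ParameterSet) -> str:
    return "high_risk" if gene in HIGH_RISK_GENES else "moderate_risk"


def update_risk_pathway(person: Person, result_gene: str | None, p: ParameterSet) -> ScreeningState:
    """Screening state after a genetic test result: positive results move the
    woman to the gene's surveillance pathway; negative results leave the
    population rules unchanged."""
    state = ScreeningState()
    if result_gene is None:
        state.pathway = "population"
    else:
        state.pathway = risk_pathway_for_gene(result_gene, p)
        state.modalities = modalities_for(state.pathway, max(25, person.age_at_entry), p)
    return state


def next_interval(pathway: str, p: ParameterSet, rng) -> int:
    """Years until the next screen: the pathway's target interval plus a
    geometric adherence delay."""
    cfg = p.screening["population" if pathway == "population" else "high_risk"]
    delay = int(rng.geometric(cfg["interval_delay_p"])) - 1
    return int(cfg["interval_target"]) + delay


# ---------------------------------------------------------------------------
# surgery


def surgery_eligible(person: Person, surgery: str, age: int, p: ParameterSet) -> bool:
    if surgery in person.surgeries:
        return False  # absorbing
    if surgery == "CRRM":
        breast_dx = [t for t in person.cancer_history if t.organ == "breast"]
        return len(breast_dx) == 1
    if not person.test_state.known_carrier:
        return False
    gene = person.test_state.result_gene
    if surgery == "BRRM" and any(t.organ == "breast" for t in person.cancer_history):
        return False
    return any(
        s == surgery and g == gene and lo <= age <= hi and up > 0
        for s, g, lo, hi, up in p.surgery["uptake"]
    )


def sample_surgery(person: Person, surgery: str, age: int, p: ParameterSet, rng) -> bool:
    """Bernoulli uptake draw for an eligible person; raises
    :class:`SurgeryEligibilityError` if the eligibility rules (known carrier
    status, gene-specific age windows, unilateral disease for CRRM,
    absorbing prior surgery) are not met."""
    if not surgery_eligible(person, surgery, age, p):
        raise SurgeryEligibilityError(
            f"{person.id} not eligible for {surgery} at age {age}"
        )
    if surgery == "CRRM":
        kind = "carrier" if person.test_state.known_carrier else "noncarrier"
        rate = p.surgery["crrm_uptake"][kind]
    else:
        rate = p.surgery_uptake(surgery, person.test_state.result_gene, age)
    return bool(rng.random() < rate)
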