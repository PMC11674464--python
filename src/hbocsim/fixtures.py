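"""Deterministic toy populations, scripted random streams and the exhaustive
genotype-constraint enumerator used as an independent oracle for the
obligate-non-carrier logic."""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np

from .parameters import MAX_AGE, ORGANS, GENES, ParameterSet, default_parameters
from .pedigree import Family, Person, generate_population


class ScriptedRNG:
    """Injectable random source yielding a scripted sequence of uniforms, so
    single stochastic branches can be forced in tests. Other draw kinds fall
    back to a seeded generator."""

    def __init__(self, uniforms, seed: int = 0):
        self._uniforms = list(uniforms)
        self._fallback = np.random.default_rng(seed)

    def random(self):
        if self._uniforms:
            return self._uniforms.pop(0)
        return self._fallback.random()

    def __getattr__(self, name):
        return getattr(self._fallback, name)


# ---------------------------------------------------------------------------
# exhaustive genotype-constraint oracle


def enumerate_genotype_constraints(
    f: Family, observed: dict[str, str]
) -> list[frozenset[str]]:
    """All Mendelian-consistent single-variant carrier sets given observed
    test results (person id -> "positive"/"negative").

    A carrier set is consistent when it descends from exactly one founder
    origin (no de novo events: every carrier with in-family parents has a
    carrier parent), contains every observed positive and no observed
    negative. The result is the exhaustive list of such sets; a person is an
    obligate non-carrier iff they appear in none of them. An empty list with
    observed positives means the observations are impossible.
    """
    ids = list(f.members)
    if len(ids) > 14:
        raise ValueError("oracle enumeration is for small pedigrees (<= 14 members)")
    positives = {pid for pid, r in observed.items() if r == "positive"}
    negatives = {pid for pid, r in observed.items() if r == "negative"}
    founders = {m.id for m in f.founders()}
    parents = {pid: [q.id for q in f.parents_of(pid)] for pid in ids}
    consistent = []
    for r in range(len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            s = set(combo)
            if not positives <= s or s & negatives:
                continue
            if s:
                if len(s & founders) != 1:
                    continue
                ok = all(
                    (not parents[pid]) or any(q in s for q in parents[pid])
                    for pid in s
                )
                if not ok:
                    continue
            elif positives:
                continue
            consistent.append(frozenset(s))
    return consistent


def oracle_possible_carriers(f: Family, observed: dict[str, str]) -> set[str]:
    """Union of the consistent carrier sets: everyone who could carry the
    variant. Complement (given an identified variant) = obligate non-carriers."""
    out: set[str] = set()
    for s in enumerate_genotype_constraints(f, observed):
        out |= s
    return out


# ---------------------------------------------------------------------------
# hand-checkable toy pedigrees


def toy_trio(results: dict[str, str] | None = None) -> Family:
    """Father, mother, child. Member ids: 'fa', 'mo', 'ch'."""
    members = {
        "fa": Person(id="fa", family_id=0, local_idx=0, sex="M", relation="father",
                     birth_year=-60),
        "mo": Person(id="mo", family_id=0, local_idx=1, sex="F", relation="mother",
                     birth_year=-58),
        "ch": Person(id="ch", family_id=0, local_idx=2, sex="F", relation="proband",
                     birth_year=-30, father_id="fa", mother_id="mo"),
    }
    return Family(family_id=0, proband_id="ch", members=members)


def toy_three_generation() -> Family:
    """Proband with parents and all four grandparents, one maternal aunt and
    one paternal uncle (10 members). Ids: mgm, mgf, pgm, pgf, mo, fa, aunt,
    uncle, pro, sib."""
    def P(pid, sex, rel, by, fa=None, mo=None):
        return Person(id=pid, family_id=0, local_idx=len(out), sex=sex, relation=rel,
                      birth_year=by, father_id=fa, mother_id=mo)

    out: dict[str, Person] = {}
    for pid, sex, rel, by, fa, mo in [
        ("mgm", "F", "grandparent", -105, None, None),
        ("mgf", "M", "grandparent", -107, None, None),
        ("pgm", "F", "grandparent", -104, None, None),
        ("pgf", "M", "grandparent", -106, None, None),
        ("mo", "F", "mother", -78, "mgf", "mgm"),
        ("aunt", "F", "pibling", -75, "mgf", "mgm"),
        ("fa", "M", "father", -80, "pgf", "pgm"),
        ("uncle", "M", "pibling", -77, "pgf", "pgm"),
        ("pro", "F", "proband", -50, "fa", "mo"),
        ("sib", "M", "sibling", -48, "fa", "mo"),
    ]:
        out[pid] = P(pid, sex, rel, by, fa, mo)
    return Family(family_id=0, proband_id="pro", members=out)


# ---------------------------------------------------------------------------
# toy populations with analytically known outcomes


def zero_hazard_params() -> ParameterSet:
    p = copy.deepcopy(default_parameters())
    for organ in ORGANS:
        p.baseline_incidence[organ] = np.zeros(MAX_AGE + 1)
    for key in list(p.penetrance):
        p.penetrance[key] = np.zeros(MAX_AGE + 1)
    return p


def spike_params(onset_age: int = 45, sojourn_years: float = 0.25) -> ParameterSet:
    """Breast cancer is certain at ``onset_age`` for everyone; zero hazard
    elsewhere; near-degenerate sojourn."""
    p = zero_hazard_params()
    spike = np.zeros(MAX_AGE + 1)
    spike[onset_age] = 50.0  # cumulative hazard >> 1: onset certain this year
    p.baseline_incidence["breast"] = spike
    for gene in GENES:
        p.penetrance[(gene, "breast")] = spike.copy()
    p.polygenic_hr_per_sd = {"breast": 1.0 + 1e-9, "ovary": 1.0 + 1e-9}
    mu = float(np.log(max(sojourn_years, 1e-6)))
    p.sojourn_dist = {"default": {"mu": mu, "sigma": 1e-6}}
    return p


@dataclass
class ToyPopulation:
    name: str
    families: list[Family]
    params: ParameterSet
    expected: dict = field(default_factory=dict)


def make_toy_population(name: str, n_families: int = 5, seed: int = 7) -> ToyPopulation:
    """Named deterministic miniature populations with known outcomes.

    - "no_cancer_world": all cancer hazards zero -> no diagnosis events ever.
    - "certain_cancer_proband": breast onset certain at 45 with ~3-month
      sojourn -> every surviving proband is diagnosed at age 45.
    - "one_carrier_family": a single family with a forced BRCA1 proband,
      certain triple-negative onset at 45 and testing uptake 1 -> under full
      referral the family variant is identified in the diagnosis year.
    """
    if name == "no_cancer_world":
        p = zero_hazard_params()
        fams = generate_population(n_families, (30, 39), p, seed)
        return ToyPopulation(name, fams, p, {"n_diagnoses": 0})
    if name == "certain_cancer_proband":
        p = spike_params(onset_age=45)
        fams = generate_population(n_families, (20, 24), p, seed)
        return ToyPopulation(name, fams, p, {"proband_dx_age": 45})
    if name == "one_carrier_family":
        p = spike_params(onset_age=45)
        p.testing_uptake = {"breast": 1.0, "ovary": 1.0}
        p.tumour_models["breast"]["subtype_by_gene"]["BRCA1"] = {
            "TN": 1.0, "HER2": 0.0, "HR+": 0.0
        }
        fams = generate_population(1, (20, 24), p, seed, force_proband_gene="BRCA1")
        return ToyPopulation(
            name, fams, p,
            {"identification_age": 45, "identified_gene": "BRCA1"},
        )
    raise KeyError(f"unknown toy population {name!r}")
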