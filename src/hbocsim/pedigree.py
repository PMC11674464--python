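"""Input-population generation: proband-centred families with first- and
second-degree relatives, ages, sexes, vital status, monogenic and polygenic
genotypes, and pre-entry (baseline) cancer histories.

Each family is generated around a female, cancer-free proband aged 20-59 at
entry (entry = simulation year 0; ages at entry are ``-birth_year``). The
proband always has two parents and four grandparents; siblings, piblings
(aunts/uncles), children, niblings (nieces/nephews) and grandchildren are
drawn from parity distributions with birth timing from a maternal-age-at-birth
distribution. Co-parents needed to give siblings/children offspring are
generated as married-in non-members: they contribute genotypes (and matter
for obligate-carrier logic) but are excluded from family-size metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np

from .parameters import GENES, ParameterSet

RELATIONS = [
    "proband", "mother", "father", "sibling", "grandparent",
    "pibling", "child", "nibling", "grandchild", "married_in",
]

FIRST_DEGREE = 1
SECOND_DEGREE = 2


@dataclass
class Genotype:
    """Monogenic (at most one P/LP variant) plus polygenic genotype."""

    plp_gene: str | None = None
    z_breast: float = 0.0
    z_ovary: float = 0.0

    def z(self, organ: str) -> float:
        return self.z_breast if organ == "breast" else self.z_ovary


@dataclass
class TestState:
    """Genetic-testing history of one person."""

    __test__ = False  # not a pytest test class despite the name

    referred_years: list[int] = field(default_factory=list)
    panel_tested_year: int | None = None
    panel: str | None = None  # "high_risk" | "extended"
    predictive_tested_year: int | None = None
    result: str = "untested"  # "untested" | "negative" | "positive"
    result_gene: str | None = None

    @property
    def known_carrier(self) -> bool:
        return self.result == "positive"

    @property
    def positive_year(self) -> int | None:
        if self.result != "positive":
            return None
        years = [y for y in (self.panel_tested_year, self.predictive_tested_year) if y is not None]
        return min(years) if years else None


@dataclass
class Person:
    id: str
    family_id: int
    local_idx: int
    sex: str  # "F" | "M"
    relation: str
    birth_year: int  # entry is year 0; negative = born before entry
    father_id: str | None = None
    mother_id: str | None = None
    in_family: bool = True  # married-in co-parents are members but not counted
    genotype: Genotype = field(default_factory=Genotype)
    cancer_history: list = field(default_factory=list)  # TumourRecord list
    test_state: TestState = field(default_factory=TestState)
    surgeries: dict[str, int] = field(default_factory=dict)  # type -> year
    death_year: int | None = None
    death_cause: str | None = None
    sim: Any = None  # per-run simulation state attached by the engine

    @property
    def age_at_entry(self) -> int:
        return -self.birth_year

    def age_in(self, year: int) -> int:
        return year - self.birth_year

    def vital_status(self, year: int = 0) -> str:
        if self.death_year is not None and self.death_year <= year:
            return "deceased"
        if self.birth_year > year:
            return "unborn"
        return "alive"

    def alive_in(self, year: int) -> bool:
        return self.vital_status(year) == "alive"

    def cancer_affected_by(self, year: int) -> bool:
        return any(t.age_at_diagnosis + self.birth_year <= year for t in self.cancer_history)


@dataclass
class Family:
    family_id: int
    proband_id: str
    members: dict[str, Person]
    variant_knowledge: Any = None  # genetics.FamilyVariantKnowledge | None
    seed_info: tuple[int, int, int] = (0, 0, 0)  # (master seed, family id, attempt)

    @property
    def proband(self) -> Person:
        return self.members[self.proband_id]

    def person(self, pid: str) -> Person:
        return self.members[pid]

    def __iter__(self) -> Iterable[Person]:
        return iter(self.members.values())

    def family_members(self) -> list[Person]:
        """Members counted in family-size metrics (excludes married-ins)."""
        return [m for m in self.members.values() if m.in_family]

    def size(self) -> int:
        return len(self.family_members())

    def size_at_entry(self) -> int:
        """Members in existence at entry (born by year 0, alive or deceased,
        excluding married-ins and never-materialised births)."""
        return sum(
            1 for m in self.family_members()
            if m.birth_year <= 0 and (m.sim is None or not m.sim.excluded)
        )

    def parents_of(self, pid: str) -> list[Person]:
        p = self.members[pid]
        return [self.members[q] for q in (p.father_id, p.mother_id)
                if q is not None and q in self.members]

    def children_of(self, pid: str) -> list[Person]:
        return [m for m in self.members.values() if pid in (m.father_id, m.mother_id)]

    def founders(self) -> list[Person]:
        return [m for m in self.members.values()
                if m.father_id is None and m.mother_id is None]

    def full_siblings_of(self, pid: str) -> list[Person]:
        p = self.members[pid]
        if p.father_id is None and p.mother_id is None:
            return []
        return [m for m in self.members.values()
                if m.id != pid and m.father_id == p.father_id
                and m.mother_id == p.mother_id
                and (m.father_id is not None or m.mother_id is not None)]

    def relatives_by_degree(self, pid: str) -> dict[str, int]:
        """First- and second-degree relatives of ``pid`` within the family
        graph: parents/children/full siblings are degree 1; grandparents,
        grandchildren, piblings, niblings and half-siblings are degree 2."""
        out: dict[str, int] = {}
        p = self.members[pid]
        parents = self.parents_of(pid)
        children = self.children_of(pid)
        sibs = self.full_siblings_of(pid)
        for m in parents + children + sibs:
            out[m.id] = 1
        # half-siblings: share exactly one parent
        for m in self.members.values():
            if m.id == pid or m.id in out:
                continue
            shared = len({m.father_id, m.mother_id} & {p.father_id, p.mother_id} - {None})
            if shared == 1:
                out[m.id] = 2
        for par in parents:
            for gp in self.parents_of(par.id):
                out.setdefault(gp.id, 2)
            for pib in self.full_siblings_of(par.id):
                out.setdefault(pib.id, 2)
        for sib in sibs:
            for nib in self.children_of(sib.id):
                out.setdefault(nib.id, 2)
        for ch in children:
            for gc in self.children_of(ch.id):
                out.setdefault(gc.id, 2)
        out.pop(pid, None)
        return out

    def affected_relative_count(self, pid: str, year: int,
                                organs: tuple[str, ...] = ("breast", "ovary")) -> int:
        """Number of first/second-degree in-family relatives with a breast or
        ovarian cancer history by ``year`` (alive or deceased)."""
        n = 0
        for rid in self.relatives_by_degree(pid):
            m = self.members[rid]
            if not m.in_family:
                continue
            if any(t.organ in organs and t.age_at_diagnosis + m.birth_year <= year
                   for t in m.cancer_history):
                n += 1
        return n


# ---------------------------------------------------------------------------
# sampling helpers


def _draw_cdf(rng, cdf: dict[int, float]) -> int:
    u = rng.random()
    for k in sorted(cdf):
        if u <= cdf[k]:
            return k
    return max(cdf)


def parity_age_group(age: int) -> str:
    if age < 20:
        return "15-19"
    if age >= 45:
        return "45+"
    lo = 5 * (age // 5)
    return f"{lo}-{lo + 4}"


def sample_parity(age: int, p: ParameterSet, rng) -> int:
    """Number of children born by ``age``, drawn from the age-group parity CDF."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if age < 15:
        return 0
    return _draw_cdf(rng, p.parity_cdf[parity_age_group(age)])


def _completed_parity(p: ParameterSet, rng, at_least_one: bool = False) -> int:
    cdf = p.parity_cdf["45+"]
    if not at_least_one:
        return _draw_cdf(rng, cdf)
    p0 = cdf[0]
    u = p0 + rng.random() * (1.0 - p0)
    for k in sorted(cdf):
        if u <= cdf[k]:
            return max(k, 1)
    return max(cdf)


def _maternal_age(p: ParameterSet, rng) -> int:
    ages = sorted(p.maternal_age_dist)
    u = rng.random()
    acc = 0.0
    for a in ages:
        acc += p.maternal_age_dist[a]
        if u <= acc:
            return a
    return ages[-1]


def _spouse_gap(rng) -> int:
    return int(np.clip(round(rng.normal(2.0, 2.5)), -5, 12))


# ---------------------------------------------------------------------------
# family structure


def _age_group_bounds(proband_age_group) -> tuple[int, int]:
    if isinstance(proband_age_group, str):
        lo, _, hi = proband_age_group.partition("-")
        return int(lo), int(hi)
    lo, hi = proband_age_group
    return int(lo), int(hi)


def generate_family(
    proband_age_group,
    p: ParameterSet,
    rng_seed: int,
    family_id: int = 0,
    attempt: int = 0,
) -> Family:
    """Generate the structure of one family (no genotypes or histories yet).

    ``proband_age_group`` is an inclusive age range, as a (lo, hi) tuple or a
    string like ``"50-54"``; the proband age is uniform within it. The result
    is deterministic given (seed, family id, attempt).
    """
    lo, hi = _age_group_bounds(proband_age_group)
    if lo < 20 or hi > 59 or lo > hi:
        raise ValueError("proband age group must lie within [20, 59]")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, family_id, attempt, 0)))

    members: dict[str, Person] = {}
    counter = [0]

    def add(sex, relation, birth_year, father=None, mother=None, in_family=True) -> Person:
        pid = f"{family_id}:{counter[0]}"
        person = Person(
            id=pid, family_id=family_id, local_idx=counter[0], sex=sex,
            relation=relation, birth_year=int(birth_year),
            father_id=father, mother_id=mother, in_family=in_family,
        )
        counter[0] += 1
        members[pid] = person
        return person

    proband_age = int(rng.integers(lo, hi + 1))

    # founders first so that parent rows precede children in the PED file
    m_gm = add("F", "grandparent", 0)
    m_gf = add("M", "grandparent", 0)
    p_gm = add("F", "grandparent", 0)
    p_gf = add("M", "grandparent", 0)
    mother = add("F", "mother", 0, father=m_gf.id, mother=m_gm.id)
    father = add("M", "father", 0, father=p_gf.id, mother=p_gm.id)
    proband = add("F", "proband", -proband_age, father=father.id, mother=mother.id)

    mother.birth_year = proband.birth_year - _maternal_age(p, rng)
    father.birth_year = mother.birth_year - _spouse_gap(rng)
    m_gm.birth_year = mother.birth_year - _maternal_age(p, rng)
    m_gf.birth_year = m_gm.birth_year - _spouse_gap(rng)
    p_gm.birth_year = father.birth_year - _maternal_age(p, rng) - p.paternal_age_shift
    p_gf.birth_year = p_gm.birth_year - _spouse_gap(rng)

    def random_sex() -> str:
        return "F" if rng.random() < 0.5 else "M"

    def add_children(parent: Person, n: int, relation: str) -> list[Person]:
        """Give ``parent`` n children with a married-in co-parent."""
        if n <= 0:
            return []
        if parent.sex == "F":
            co = add("M", "married_in", parent.birth_year - _spouse_gap(rng), in_family=False)
            mo, fa = parent, co
        else:
            co = add("F", "married_in", parent.birth_year + _spouse_gap(rng), in_family=False)
            mo, fa = co, parent
        kids = []
        for _ in range(n):
            off = _maternal_age(p, rng)
            if parent.sex == "M":
                off += p.paternal_age_shift
            kids.append(add(random_sex(), relation, parent.birth_year + off,
                            father=fa.id, mother=mo.id))
        return kids

    # siblings: mother's other children
    n_sibs = _completed_parity(p, rng, at_least_one=True) - 1
    siblings = []
    for _ in range(n_sibs):
        siblings.append(add(random_sex(), "sibling",
                            mother.birth_year + _maternal_age(p, rng),
                            father=father.id, mother=mother.id))

    # piblings: the parents' full siblings
    for gm, gf in ((m_gm, m_gf), (p_gm, p_gf)):
        for _ in range(_completed_parity(p, rng, at_least_one=True) - 1):
            add(random_sex(), "pibling", gm.birth_year + _maternal_age(p, rng),
                father=gf.id, mother=gm.id)

    # children and grandchildren of the proband
    children = add_children(proband, _completed_parity(p, rng), "child")
    for ch in children:
        add_children(ch, _completed_parity(p, rng), "grandchild")

    # niblings: children of the proband's siblings
    for sib in siblings:
        add_children(sib, _completed_parity(p, rng), "nibling")

    fam = Family(family_id=family_id, proband_id=proband.id, members=members,
                 seed_info=(rng_seed, family_id, attempt))
    return fam


# ---------------------------------------------------------------------------
# genotypes


def _draw_plp(rng, p: ParameterSet) -> str | None:
    u = rng.random()
    acc = 0.0
    for g in GENES:
        acc += p.gene_prevalence[g]
        if u < acc:
            return g
    return None


def _draw_z_pair(rng, rho: float) -> tuple[float, float]:
    a, b = rng.normal(size=2)
    return a, rho * a + np.sqrt(max(0.0, 1 - rho**2)) * b


def assign_genotypes(
    f: Family, p: ParameterSet, rng, force_proband_gene: str | None = None
) -> Family:
    """Assign monogenic variants and polygenic scores to every member.

    Founders (grandparents and married-ins) draw a variant at population
    prevalence and standard-normal polygenic scores; descendants inherit
    Mendelianly (transmission probability 1/2, no de novo events) with
    polygenic scores following the infinitesimal model: midparent mean plus
    segregation noise of variance 1/2, preserving unit marginal variance.

    ``force_proband_gene`` conditions the family on the proband carrying the
    given variant: a uniformly chosen grandparent is made the founder source
    and transmission is forced along the path to the proband (all other
    transmissions remain fair coin flips). This reproduces the conditional
    genotype distribution given a carrier proband, for efficient study of
    carrier families.
    """
    rho = p.polygenic_correlation
    forced_links: set[tuple[str, str]] = set()
    forced_founder: str | None = None
    if force_proband_gene is not None:
        if force_proband_gene not in GENES:
            raise ValueError(f"unknown gene {force_proband_gene!r}")
        proband = f.proband
        parent = f.members[proband.mother_id if rng.random() < 0.5 else proband.father_id]
        gp = f.parents_of(parent.id)
        source = gp[int(rng.random() < 0.5)] if gp else parent
        forced_founder = source.id
        forced_links = {(parent.id, proband.id), (source.id, parent.id)}

    ordered = sorted(f.members.values(), key=lambda m: (m.birth_year, m.local_idx))
    for person in ordered:
        parents = f.parents_of(person.id)
        if not parents:
            gene = _draw_plp(rng, p)
            if person.id == forced_founder:
                gene = force_proband_gene
            zb, zo = _draw_z_pair(rng, rho)
            person.genotype = Genotype(plp_gene=gene, z_breast=zb, z_ovary=zo)
        else:
            inherited = []
            for par in parents:
                g = par.genotype.plp_gene
                u = rng.random()
                if g is not None:
                    forced = (par.id, person.id) in forced_links
                    if forced or u < 0.5:
                        inherited.append(g)
            gene = inherited[0] if len(inherited) == 1 else (
                inherited[int(rng.random() < 0.5)] if inherited else None
            )
            zm = np.mean([par.genotype.z_breast for par in parents])
            zo_m = np.mean([par.genotype.z_ovary for par in parents])
            eb, eo = _draw_z_pair(rng, rho)
            person.genotype = Genotype(
                plp_gene=gene,
                z_breast=zm + eb * np.sqrt(0.5),
                z_ovary=zo_m + eo * np.sqrt(0.5),
            )
    return f


# ---------------------------------------------------------------------------
# baseline history


def assign_baseline_history(f: Family, p: ParameterSet, master_seed: int | None = None) -> Family:
    """Simulate each member's life from birth to simulation entry (year 0):
    cancer onsets and diagnoses under the natural-history model (with
    population breast screening but no genetic testing), other-cause and
    cancer deaths. Sets vital status, cancer histories and death records."""
    from . import engine  # deferred: engine imports this module's types

    seed = master_seed if master_seed is not None else f.seed_info[0]
    engine.simulate_baseline(f, p, seed)
    return f


def generate_population(
    n_families: int,
    proband_age_group,
    p: ParameterSet,
    seed: int,
    force_proband_gene=None,
) -> list[Family]:
    """Generate ``n_families`` complete families (structure, genotypes,
    baseline histories), enforcing the entry condition that the proband is
    alive and cancer-free at year 0 (families violating it are regenerated
    with a bumped attempt counter, keeping the output deterministic).

    ``force_proband_gene`` may be a gene name applied to every family, or a
    callable mapping the family index to a gene name (or None).
    """
    families = []
    for fid in range(n_families):
        gene = force_proband_gene(fid) if callable(force_proband_gene) else force_proband_gene
        for attempt in range(200):
            fam = generate_family(proband_age_group, p, seed, family_id=fid, attempt=attempt)
            rng = np.random.default_rng(np.random.SeedSequence((seed, fid, attempt, 1)))
            assign_genotypes(fam, p, rng, force_proband_gene=gene)
            assign_baseline_history(fam, p, seed)
            pr = fam.proband
            if pr.alive_in(0) and not pr.cancer_affected_by(0):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate an eligible proband in 200 attempts")
        families.append(fam)
    return families


# ---------------------------------------------------------------------------
# PED export / import


def export_pedigree(f: Family, path: str | Path) -> Path:
    """Write a PED-style text file (family, id, father, mother, sex,
    phenotype) plus a JSON sidecar (``<path>.json``) holding model-specific
    fields; the pair round-trips losslessly through :func:`import_pedigree`."""
    path = Path(path)
    lines = []
    sidecar: dict[str, Any] = {"family_id": f.family_id, "proband_id": f.proband_id,
                               "seed_info": list(f.seed_info), "persons": {}}
    for m in f.members.values():
        pheno = 2 if m.cancer_history else 1
        lines.append("\t".join([
            str(f.family_id), m.id, m.father_id or "0", m.mother_id or "0",
            "1" if m.sex == "M" else "2", str(pheno),
        ]))
        sidecar["persons"][m.id] = {
            "local_idx": m.local_idx,
            "relation": m.relation,
            "birth_year": m.birth_year,
            "in_family": m.in_family,
            "death_year": m.death_year,
            "death_cause": m.death_cause,
            "plp_gene": m.genotype.plp_gene,
            "z_breast": m.genotype.z_breast,
            "z_ovary": m.genotype.z_ovary,
            "surgeries": m.surgeries,
            "cancer_history": [t.to_dict() for t in m.cancer_history],
        }
    path.write_text("\n".join(lines) + "\n")
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def import_pedigree(path: str | Path) -> Family:
    from .natural_history import TumourRecord

    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {"persons": {}}
    members: dict[str, Person] = {}
    fam_id = sidecar.get("family_id", 0)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 PED columns, got {len(parts)}")
        _, pid, father, mother, sex_code, _pheno = parts
        if sex_code not in ("1", "2"):
            raise ValueError(f"{path}:{lineno}: invalid sex code {sex_code!r}")
        extra = sidecar["persons"].get(pid, {})
        person = Person(
            id=pid, family_id=fam_id,
            local_idx=extra.get("local_idx", lineno - 1),
            sex="M" if sex_code == "1" else "F",
            relation=extra.get("relation", "unknown"),
            birth_year=extra.get("birth_year", 0),
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            in_family=extra.get("in_family", True),
        )
        person.genotype = Genotype(
            plp_gene=extra.get("plp_gene"),
            z_breast=extra.get("z_breast", 0.0),
            z_ovary=extra.get("z_ovary", 0.0),
        )
        person.death_year = extra.get("death_year")
        person.death_cause = extra.get("death_cause")
        person.surgeries = {k: int(v) for k, v in extra.get("surgeries", {}).items()}
        person.cancer_history = [TumourRecord.from_dict(d) for d in extra.get("cancer_history", [])]
        members[pid] = person

    _validate_pedigree(members, path)
    proband_id = sidecar.get("proband_id")
    if proband_id is None:
        proband_id = next((m.id for m in members.values() if m.relation == "proband"),
                          next(iter(members)))
    fam = Family(family_id=fam_id, proband_id=proband_id, members=members,
                 seed_info=tuple(sidecar.get("seed_info", (0, 0, 0))))
    return fam


def _validate_pedigree(members: dict[str, Person], path) -> None:
    for m in members.values():
        for pid, want_sex, label in ((m.father_id, "M", "father"), (m.mother_id, "F", "mother")):
            if pid is None:
                continue
            if pid not in members:
                raise ValueError(f"{path}: {m.id} references unknown {label} {pid}")
            if members[pid].sex != want_sex:
                raise ValueError(
                    f"{path}: {m.id} has {label} {pid} of wrong sex "
                    f"(two recorded {label}s or sex mismatch)"
                )
    # acyclicity via birth-year-free DFS
    seen: dict[str, int] = {}

    def visit(pid: str, stack: set[str]):
        if pid in stack:
            raise ValueError(f"{path}: pedigree cycle involving {pid}")
        if seen.get(pid):
            return
        stack.add(pid)
        m = members[pid]
        for q in (m.father_id, m.mother_id):
            if q is not None:
                visit(q, stack)
        stack.discard(pid)
        seen[pid] = 1

    for pid in members:
        visit(pid, set())
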