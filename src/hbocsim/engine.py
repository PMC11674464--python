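"""Simulation engine: yearly cycles over family units under a scenario.

Every person's life is simulated from birth on an integer-year clock (entry
into the main simulation is year 0, so baseline history is simply the part
of the same timeline with years <= 0, during which population screening runs
but no genetic testing exists). Within each simulated year events are
applied in a fixed order:

    births -> other-cause death -> cancer onset and symptomatic diagnosis ->
    screening -> referral + diagnostic testing -> family-knowledge update +
    predictive testing -> risk-pathway update + surgery -> cancer death ->
    exit at age 100

Stochastic draws come from named substreams keyed by (master seed, family,
person, purpose[, year]); annually evaluated gates (testing uptake, surgery
uptake, screen detection) are keyed by year as well, making runs under
different scenarios common-random-number paired and every run reproducible.

Event *timing* draws (onset, death and the like) are sampled once by
inverting cumulative hazards against stored unit-exponential draws, so a
mid-life change in hazards (risk-reducing surgery) replans future events
without disturbing any other draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genetics, natural_history as nh, screening as scr
from .parameters import MAX_AGE, ParameterSet
from .pedigree import Family, Person

SCENARIOS = ["no_testing", "current_practice", "optimised_referral", "test_all_breast"]

# named random substreams per person
_P = {
    "life": 0, "breast1": 1, "breast2": 2, "ovary": 3,
    "char1": 4, "char2": 5, "prog1": 6, "prog2": 7, "ovchar": 8,
    "survb1": 9, "survb2": 10, "survov": 11,
    "screen": 12, "screen_hr": 13,
    "detect": 14, "referral": 15, "uptake": 16, "predictive": 17,
    "brrm": 18, "rrso": 19, "crrm": 20,
}


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    scenario: str = "current_practice"
    panel: str = "high_risk"
    dynamic_population: bool = True
    horizon: int = 160
    disable_relative_diagnostic_testing: bool = False
    force_full_predictive_uptake: bool = False
    #: study toggle: identify the family variant with certainty at a carrier
    #: proband's cancer diagnosis (used by the predictive-uptake validation study)
    force_index_identification: bool = False
    log_screens: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if not 1 <= self.horizon <= 160:
            raise ConfigError(f"horizon must be in [1, 160], got {self.horizon}")
        if self.panel not in genetics.PANEL_GENES:
            raise ConfigError(f"unknown panel {self.panel!r}")

    @property
    def testing_enabled(self) -> bool:
        return self.scenario != "no_testing"


def build_scenario(name: str, **overrides) -> ScenarioConfig:
    """The four policy scenarios. Extended-panel genes are excluded from all
    of them (high-risk panel only); population breast screening is active in
    all of them; scenario 1 disables all genetic testing and therefore all
    high-risk management."""
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}")
    return ScenarioConfig(scenario=name, **overrides)


class EventLog:
    """Append-only per-person event records plus a person attribute table."""

    COLUMNS = ["person", "family", "year", "age", "kind",
               "organ", "mode", "gene", "result", "extra"]

    def __init__(self, rows: list | None = None, persons: pd.DataFrame | None = None):
        self.rows = rows if rows is not None else []
        self._persons = persons
        self._frame: pd.DataFrame | None = None

    def add(self, person: Person, year: int, kind: str, organ=None, mode=None,
            gene=None, result=None, extra=None) -> None:
        self.rows.append((person.id, person.family_id, year, year - person.birth_year,
                          kind, organ, mode, gene, result, extra))
        self._frame = None

    @property
    def events(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame(self.rows, columns=self.COLUMNS)
        return self._frame

    @property
    def persons(self) -> pd.DataFrame:
        if self._persons is None:
            raise RuntimeError("person table not attached")
        return self._persons

    def to_jsonl(self, path) -> None:
        self.events.to_json(path, orient="records", lines=True)


def persons_table(families: list[Family]) -> pd.DataFrame:
    rows = []
    for fam in families:
        degs = fam.relatives_by_degree(fam.proband_id)
        for m in fam.members.values():
            rows.append((
                m.id, fam.family_id, m.sex, m.relation, m.birth_year, m.in_family,
                degs.get(m.id, 0 if m.id == fam.proband_id else 3),
                m.genotype.plp_gene, m.genotype.z_breast, m.genotype.z_ovary,
                bool(m.sim.excluded) if m.sim is not None else False,
            ))
    return pd.DataFrame(rows, columns=[
        "person", "family", "sex", "relation", "birth_year", "in_family",
        "degree", "plp_gene", "z_breast", "z_ovary", "excluded",
    ])


# ---------------------------------------------------------------------------
# per-person simulation state


class _PersonSim:
    __slots__ = (
        "active", "excluded", "dead", "exited",
        "death_other_year", "cancer_death_year", "exit_year",
        "e_breast", "e_ovary",
        "onset_year", "sympt_year", "tumour", "cancelled",
        "ovary_dx_year", "ovary_done",
        "pathway", "scr_never", "next_screen_year", "screening_stopped",
        "pathway_upgraded", "screen_rng", "contra_start_age",
    )

    def __init__(self):
        self.active = False
        self.excluded = False
        self.dead = False
        self.exited = False
        self.death_other_year: int | None = None
        self.cancer_death_year: int | None = None
        self.exit_year: int | None = None
        self.e_breast = [None, None]
        self.e_ovary: float | None = None
        self.onset_year: list[int | None] = [None, None]
        self.sympt_year: list[int | None] = [None, None]
        self.tumour: list = [None, None]
        self.cancelled = [False, False]
        self.ovary_dx_year: int | None = None
        self.ovary_done = False
        self.pathway = "population"
        self.scr_never = False
        self.next_screen_year: int | None = None
        self.screening_stopped = False
        self.pathway_upgraded = False
        self.screen_rng = None
        self.contra_start_age: int | None = None

    @property
    def terminal(self) -> bool:
        return self.dead or self.exited


def _stream(fam: Family, person: Person, purpose: str) -> np.random.Generator:
    seed, fid, attempt = fam.seed_info
    return np.random.default_rng(
        np.random.SeedSequence((seed, fid, attempt, person.local_idx, _P[purpose]))
    )


def _u01(fam: Family, person: Person, purpose: str, year: int) -> float:
    seed, fid, attempt = fam.seed_info
    ss = np.random.SeedSequence((seed, fid, attempt, person.local_idx, _P[purpose], year + 1000))
    return ss.generate_state(1)[0] / 2.0**32


# ---------------------------------------------------------------------------
# simulation


class Simulation:
    """Mutable simulation state over a list of families.

    Construct, then call :meth:`run_cycle` per year or :meth:`run` for a
    span; family objects are updated in place and all events accumulate in
    :attr:`log`.
    """

    def __init__(self, families: list[Family], sc: ScenarioConfig | None, p: ParameterSet):
        self.families = families
        self.sc = sc
        self.p = p
        self.log = EventLog()
        self._next_year: dict[int, int] = {}
        for fam in families:
            for m in fam.members.values():
                if m.sim is None:
                    m.sim = _PersonSim()
                if sc is not None and not sc.dynamic_population and m.birth_year > 0:
                    m.sim.excluded = True
            self._next_year[fam.family_id] = min(
                (m.birth_year for m in fam.members.values() if not m.sim.excluded),
                default=0,
            )

    # -- planning ----------------------------------------------------------

    def _activate(self, fam: Family, person: Person, year: int) -> None:
        s = person.sim
        mo = fam.members.get(person.mother_id) if person.mother_id else None
        if mo is not None and (not mo.sim.active or mo.sim.dead):
            s.excluded = True  # mother died (or was never born) before this birth
            return
        s.active = True
        s.exit_year = person.birth_year + MAX_AGE
        death_age = nh.other_cause_death_age(
            person.sex, _stream(fam, person, "life").exponential(), self.p
        )
        s.death_other_year = None if death_age is None else person.birth_year + death_age
        if person.sex == "F":
            s.e_breast = [
                _stream(fam, person, "breast1").exponential(),
                _stream(fam, person, "breast2").exponential(),
            ]
            s.e_ovary = _stream(fam, person, "ovary").exponential()
            self._replan_breast(fam, person, course=0)
            self._replan_ovary(fam, person)
            self._plan_population_screening(fam, person)

    def _breast_segments(self, person: Person) -> list[tuple[int, float]]:
        segs = []
        if "BRRM" in person.surgeries:
            segs.append((person.surgeries["BRRM"] - person.birth_year,
                         self.p.surgery["risk_reduction"]["BRRM"]))
        return segs

    def _ovary_segments(self, person: Person) -> list[tuple[int, float]]:
        segs = []
        if "RRSO" in person.surgeries:
            segs.append((person.surgeries["RRSO"] - person.birth_year,
                         self.p.surgery["risk_reduction"]["RRSO"]))
        return segs

    def _replan_breast(self, fam: Family, person: Person, course: int) -> None:
        s = person.sim
        if s.tumour[course] is not None or s.cancelled[course]:
            return
        segs = self._breast_segments(person)
        if course == 1:
            # contralateral risk only accrues once a first primary exists
            if s.contra_start_age is None:
                s.onset_year[course] = None
                return
            segs = [(0, 0.0), (s.contra_start_age, 1.0)] + segs
        h = nh.person_hazard_curve(person, "breast", self.p)
        onset = nh.first_passage_year(h, s.e_breast[course], segs)
        s.onset_year[course] = None if onset is None else person.birth_year + onset
        s.sympt_year[course] = None

    def _replan_ovary(self, fam: Family, person: Person) -> None:
        s = person.sim
        if s.ovary_done:
            return
        h = nh.person_hazard_curve(person, "ovary", self.p)
        dx = nh.first_passage_year(h, s.e_ovary, self._ovary_segments(person))
        s.ovary_dx_year = None if dx is None else person.birth_year + dx

    def _plan_population_screening(self, fam: Family, person: Person) -> None:
        s = person.sim
        rng = _stream(fam, person, "screen")
        start = scr.sample_screening_start(person, "population", self.p, rng)
        s.pathway = "population"
        if start is None:
            s.scr_never = True
            s.next_screen_year = None
        else:
            s.next_screen_year = person.birth_year + start
        s.screen_rng = rng

    def _screen_interval(self, person: Person) -> int:
        return scr.next_interval(person.sim.pathway, self.p, person.sim.screen_rng)

    # -- cycle -------------------------------------------------------------

    def run(self, year_from: int, year_to: int) -> None:
        for year in range(year_from, year_to + 1):
            self.run_cycle(year)

    def run_cycle(self, year: int) -> None:
        for fam in self.families:
            if self._next_year[fam.family_id] > year:
                continue
            self._family_year(fam, year)
            self._next_year[fam.family_id] = self._family_next(fam, year)

    def _family_next(self, fam: Family, year: int) -> int:
        if fam.variant_knowledge is not None:
            return year + 1
        best = year + 10**6
        for m in fam.members.values():
            s = m.sim
            if s.excluded or s.terminal:
                continue
            if not s.active:
                best = min(best, m.birth_year)
                continue
            for c in (
                s.death_other_year, s.cancer_death_year, s.exit_year,
                s.onset_year[0], s.onset_year[1],
                s.sympt_year[0], s.sympt_year[1],
                s.ovary_dx_year, s.next_screen_year,
            ):
                if c is not None and c > year:
                    best = min(best, c)
        return best

    def _family_year(self, fam: Family, year: int) -> None:
        p = self.p
        sc = self.sc
        testing = sc is not None and sc.testing_enabled and year >= 1
        diagnosed_now: list[tuple[Person, object]] = []
        members = list(fam.members.values())

        # 1. births
        for m in members:
            s = m.sim
            if not s.active and not s.excluded and m.birth_year == year:
                self._activate(fam, m, year)

        # 2. other-cause death
        for m in members:
            s = m.sim
            if s.active and not s.terminal and s.death_other_year == year:
                self._die(fam, m, year, "other")

        # 3. cancer onset, symptomatic diagnosis, ovarian diagnosis
        for m in members:
            s = m.sim
            if not s.active or s.terminal:
                continue
            for course in (0, 1):
                if s.onset_year[course] == year and not s.cancelled[course]:
                    self._breast_onset(fam, m, year, course)
            for course in (0, 1):
                t = s.tumour[course]
                if (t is not None and not s.cancelled[course]
                        and not t.prognostics_assigned and s.sympt_year[course] == year):
                    self._diagnose_breast(fam, m, year, course, "symptomatic", diagnosed_now)
            if s.ovary_dx_year == year and not s.ovary_done:
                self._diagnose_ovary(fam, m, year, diagnosed_now)

        # 4. screening
        for m in members:
            s = m.sim
            if (not s.active or s.terminal or s.screening_stopped
                    or s.next_screen_year != year):
                continue
            self._screen(fam, m, year, diagnosed_now)

        # 5. referral + diagnostic testing (+ CRRM decision at diagnosis)
        for person, tumour in diagnosed_now:
            if testing:
                self._refer_and_test(fam, person, tumour, year)
            if year >= 1 and tumour.organ == "breast":
                self._consider_crrm(fam, person, year)

        # 6. predictive testing
        if testing and fam.variant_knowledge is not None:
            k = fam.variant_knowledge
            if year >= k.year_identified:
                for m in members:
                    self._consider_predictive(fam, m, year)

        # 7. risk pathway + risk-reducing surgery
        if testing:
            for m in members:
                self._manage_carrier(fam, m, year)

        # 8. cancer death
        for m in members:
            s = m.sim
            if s.active and not s.terminal and s.cancer_death_year == year:
                cause = self._cancer_death_cause(m, year)
                self._die(fam, m, year, cause)

        # 9. exit at the age cap
        for m in members:
            s = m.sim
            if s.active and not s.terminal and s.exit_year == year:
                s.exited = True
                self.log.add(m, year, "exit")

    # -- event handlers ----------------------------------------------------

    def _die(self, fam: Family, person: Person, year: int, cause: str) -> None:
        s = person.sim
        s.dead = True
        person.death_year = year
        person.death_cause = cause
        self.log.add(person, year, "death", extra=cause)

    def _cancer_death_cause(self, person: Person, year: int) -> str:
        for t in person.cancer_history:
            if getattr(t, "_death_year", None) == year:
                return t.organ
        return person.cancer_history[-1].organ if person.cancer_history else "other"

    def _breast_onset(self, fam: Family, person: Person, year: int, course: int) -> None:
        s = person.sim
        rng = _stream(fam, person, f"char{course + 1}")
        subtype, grade = nh.draw_breast_characteristics(person.genotype.plp_gene, self.p, rng)
        sojourn = nh.sample_sojourn(person.genotype.plp_gene, self.p, rng)
        age = year - person.birth_year
        t = nh.TumourRecord(
            organ="breast", age_at_onset=age,
            age_at_diagnosis=age + int(round(sojourn)),
            subtype=subtype, grade=grade, sojourn_time=sojourn, course=course + 1,
        )
        s.tumour[course] = t
        s.sympt_year[course] = year + int(round(sojourn))

    def _diagnose_breast(self, fam: Family, person: Person, year: int, course: int,
                         mode: str, diagnosed_now: list) -> None:
        s = person.sim
        t = s.tumour[course]
        rng = _stream(fam, person, f"prog{course + 1}")
        nh.assign_breast_prognostics(t, mode, self.p, rng)
        if year <= 0:
            t.detection_mode = "baseline"
        t.age_at_diagnosis = year - person.birth_year
        person.cancer_history.append(t)
        self.log.add(person, year, "diagnosis", organ="breast", mode=t.detection_mode,
                     extra=t.subtype)
        self._schedule_cancer_death(fam, person, t, f"survb{course + 1}")
        s.screening_stopped = True  # organised screening ends at breast-cancer diagnosis
        if course == 0 and s.contra_start_age is None:
            s.contra_start_age = year - person.birth_year
            self._replan_breast(fam, person, course=1)
        diagnosed_now.append((person, t))

    def _diagnose_ovary(self, fam: Family, person: Person, year: int, diagnosed_now: list) -> None:
        s = person.sim
        s.ovary_done = True
        age = year - person.birth_year
        rng = _stream(fam, person, "ovchar")
        t = nh.sample_ovarian_cancer(person, age, self.p, rng)
        if t is None:
            return
        if year <= 0:
            t.detection_mode = "baseline"
        person.cancer_history.append(t)
        self.log.add(person, year, "diagnosis", organ="ovary", mode=t.detection_mode,
                     extra=t.histology)
        self._schedule_cancer_death(fam, person, t, "survov")
        diagnosed_now.append((person, t))

    def _schedule_cancer_death(self, fam: Family, person: Person, t, purpose: str) -> None:
        s = person.sim
        age = nh.cancer_death_age(t, _stream(fam, person, purpose).exponential(), self.p)
        if age is None:
            return
        year = person.birth_year + age
        t._death_year = year
        if s.cancer_death_year is None or year < s.cancer_death_year:
            s.cancer_death_year = year

    def _screen(self, fam: Family, person: Person, year: int, diagnosed_now: list) -> None:
        s = person.sim
        age = year - person.birth_year
        mods = scr.modalities_for(s.pathway, age, self.p)
        if not mods:
            s.next_screen_year = None
            return
        preclinical = [
            c for c in (0, 1)
            if s.tumour[c] is not None and not s.cancelled[c]
            and not s.tumour[c].prognostics_assigned
        ]
        detected = False
        if preclinical:
            sens, _ = scr.combined_performance(mods, age, self.p)
            if _u01(fam, person, "detect", year) < sens:
                self._diagnose_breast(fam, person, year, preclinical[0], "screen", diagnosed_now)
                detected = True
        if self.sc is not None and self.sc.log_screens:
            self.log.add(person, year, "screen", mode="+".join(sorted(mods)),
                         result="detected" if detected else "attended")
        if not detected:
            s.next_screen_year = year + self._screen_interval(person)

    # -- genetics ----------------------------------------------------------

    def _refer_and_test(self, fam: Family, person: Person, tumour, year: int) -> None:
        sc, p = self.sc, self.p
        ts = person.test_state
        if ts.known_carrier or ts.panel_tested_year is not None:
            return
        age = year - person.birth_year
        s = person.sim
        death = min((y for y in (s.death_other_year, s.cancer_death_year) if y is not None),
                    default=None)
        dies_fast = death is not None and death <= year
        prior_breast = any(
            t.organ == "breast" and t is not tumour
            and t.age_at_diagnosis < age
            for t in person.cancer_history
        )
        forced = (
            sc.force_index_identification
            and person.relation == "proband"
            and person.genotype.plp_gene in genetics.PANEL_GENES[sc.panel]
        )
        if sc.scenario == "current_practice" and not forced:
            pr = genetics.referral_probability(tumour, age, dies_fast, prior_breast, p)
            referred = _u01(fam, person, "referral", year) < pr
        else:
            referred = True
        if referred:
            ts.referred_years.append(year)
            self.log.add(person, year, "referral", organ=tumour.organ)
        eligible = genetics.is_test_eligible(person, fam, year)
        offer = referred and eligible
        if sc.scenario == "test_all_breast" and tumour.organ == "breast" and age < 80:
            offer = True
        if sc.disable_relative_diagnostic_testing and person.relation != "proband":
            offer = False
        if forced:
            offer = True
        if not offer:
            return
        if forced or _u01(fam, person, "uptake", year) < p.testing_uptake[tumour.organ]:
            result = genetics.perform_test(person, fam, "diagnostic", year, panel=sc.panel)
            self.log.add(person, year, "test", mode="diagnostic", gene=ts.result_gene,
                         result=result, extra=sc.panel)

    def _consider_predictive(self, fam: Family, person: Person, year: int) -> None:
        s = person.sim
        if not s.active or s.terminal:
            return
        if not genetics.predictive_eligible(person, fam):
            return
        k = fam.variant_knowledge
        age = year - person.birth_year
        if self.sc.force_full_predictive_uptake:
            prob = 1.0 if age >= 18 else 0.0
        else:
            deg = genetics.degree_to_index(person, fam)
            prob = genetics.predictive_uptake_probability(
                deg, age, person.sex, year - k.year_identified, self.p
            )
        if prob > 0 and _u01(fam, person, "predictive", year) < prob:
            result = genetics.perform_test(person, fam, "predictive", year)
            self.log.add(person, year, "test", mode="predictive", gene=k.gene,
                         result=result)

    def _consider_crrm(self, fam: Family, person: Person, year: int) -> None:
        """Contralateral mastectomy decision in the year of a breast-cancer
        diagnosis (all scenarios; uptake depends on known carrier status)."""
        s = person.sim
        if s.terminal or "CRRM" in person.surgeries or "BRRM" in person.surgeries:
            return
        diagnosed = [c for c in (0, 1) if s.tumour[c] is not None
                     and s.tumour[c].prognostics_assigned and not s.cancelled[c]]
        if len(diagnosed) != 1:
            return
        kind = "carrier" if person.test_state.known_carrier else "noncarrier"
        rate = self.p.surgery["crrm_uptake"][kind]
        if _u01(fam, person, "crrm", year) < rate:
            person.surgeries["CRRM"] = year
            other = 1 - diagnosed[0]
            s.cancelled[other] = True
            s.onset_year[other] = None
            s.sympt_year[other] = None
            self.log.add(person, year, "surgery", extra="CRRM")

    def _manage_carrier(self, fam: Family, person: Person, year: int) -> None:
        s = person.sim
        ts = person.test_state
        if (not s.active or s.terminal or person.sex != "F"
                or not ts.known_carrier or ts.positive_year is None
                or year < ts.positive_year):
            return
        p = self.p
        gene = ts.result_gene
        age = year - person.birth_year

        if not s.pathway_upgraded:
            s.pathway_upgraded = True
            if not any(t.organ == "breast" for t in person.cancer_history):
                pathway = scr.risk_pathway_for_gene(gene, p)
                rng = _stream(fam, person, "screen_hr")
                start = scr.sample_screening_start(person, pathway, p, rng, at_age=age)
                if start is not None:
                    s.pathway = pathway
                    s.screening_stopped = False
                    s.next_screen_year = max(person.birth_year + start, year + 1)
                    s.screen_rng = rng

        if scr.surgery_eligible(person, "BRRM", age, p):
            rate = p.surgery_uptake("BRRM", gene, age)
            if rate > 0 and _u01(fam, person, "brrm", year) < rate:
                person.surgeries["BRRM"] = year
                for c in (0, 1):
                    if s.tumour[c] is not None and not s.tumour[c].prognostics_assigned:
                        s.cancelled[c] = True
                        s.sympt_year[c] = None
                    elif s.tumour[c] is None:
                        self._replan_breast(fam, person, c)
                s.screening_stopped = True
                self.log.add(person, year, "surgery", extra="BRRM")

        if not s.ovary_done and scr.surgery_eligible(person, "RRSO", age, p):
            rate = p.surgery_uptake("RRSO", gene, age)
            if rate > 0 and _u01(fam, person, "rrso", year) < rate:
                person.surgeries["RRSO"] = year
                self._replan_ovary(fam, person)
                self.log.add(person, year, "surgery", extra="RRSO")


# ---------------------------------------------------------------------------
# public entry points


def simulate_baseline(fam: Family, p: ParameterSet, master_seed: int) -> None:
    """Run one family's unified timeline from the earliest birth to entry
    (year 0): population screening active, no genetic testing. Leaves each
    person's simulation state attached for the main phase and stores the
    baseline event rows on the family."""
    sim = Simulation([fam], None, p)
    first = min(m.birth_year for m in fam.members.values())
    sim.run(first, 0)
    fam._baseline_rows = sim.log.rows


def run_simulation(families: list[Family], sc: ScenarioConfig, p: ParameterSet) -> EventLog:
    """Run the main simulation (years 1..horizon) over families that already
    carry baseline state, under one scenario. Mutates the families; to
    compare scenarios, regenerate the population with the same seed (all
    random substreams are keyed, so regeneration is exact).

    Returns the complete :class:`EventLog` (baseline events included) with
    the person table attached.
    """
    sim = Simulation(families, sc, p)
    sim.run(1, sc.horizon)
    rows = []
    for fam in families:
        rows.extend(getattr(fam, "_baseline_rows", []))
    log = EventLog(rows + sim.log.rows, persons_table(families))
    return log


def run_cycle(state: Simulation, year: int, sc: ScenarioConfig | None = None,
              p: ParameterSet | None = None) -> Simulation:
    """Advance an existing simulation state by one yearly cycle."""
    state.run_cycle(year)
    return state
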