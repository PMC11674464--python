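"""Cohort selection and outcome metrics computed from event logs.

The analysis cohort mirrors the evaluation design: probands who develop
breast cancer during the simulation before age 80 (excluding probands whose
variant was detected before their diagnosis) and their first- and
second-degree relatives, with metrics anchored at the proband's diagnosis
year: test counts, carrier detection rates by mechanism, relatives alive at
diagnosis, Kaplan-Meier cumulative incidence in relatives, life expectancy
and anchored life-years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import EventLog
from .parameters import HIGH_RISK_GENES


@dataclass
class CohortSpec:
    """Proband filter for the analysis cohort."""

    max_dx_age: int = 80  # strict upper bound ("aged under 80 at diagnosis")
    exclude_pre_diagnosis_carrier_detection: bool = True
    organ: str = "breast"


@dataclass
class Cohort:
    probands: pd.DataFrame  # person, family, dx_year, dx_age
    relatives: pd.DataFrame  # person table rows for 1st/2nd-degree in-family relatives
    spec: CohortSpec = field(default_factory=CohortSpec)

    @property
    def anchor_by_family(self) -> dict[int, int]:
        return dict(zip(self.probands["family"], self.probands["dx_year"]))


def select_cohort(log: EventLog, spec: CohortSpec | None = None) -> Cohort:
    spec = spec or CohortSpec()
    ev, persons = log.events, log.persons
    probands = persons[persons["relation"] == "proband"]
    dx = ev[(ev["kind"] == "diagnosis") & (ev["organ"] == spec.organ)]
    dx = dx[dx["person"].isin(probands["person"])]
    first = dx.sort_values("year").groupby("person", as_index=False).first()
    first = first[first["age"] < spec.max_dx_age]
    if spec.exclude_pre_diagnosis_carrier_detection and not first.empty:
        pos = ev[(ev["kind"] == "test") & (ev["result"] == "positive")]
        pos_year = pos.groupby("person")["year"].min()
        dxy = first.set_index("person")["year"]
        detected_before = dxy.index[
            dxy.index.isin(pos_year.index) & (pos_year.reindex(dxy.index) < dxy)
        ]
        first = first[~first["person"].isin(detected_before)]
    probands_out = first.rename(columns={"year": "dx_year", "age": "dx_age"})[
        ["person", "family", "dx_year", "dx_age"]
    ].reset_index(drop=True)
    fams = set(probands_out["family"])
    mask = (
        persons["family"].isin(fams)
        & persons["in_family"]
        & persons["degree"].isin([1, 2])
    )
    if "excluded" in persons:  # drop never-materialised births
        mask &= ~persons["excluded"]
    rel = persons[mask].reset_index(drop=True)
    return Cohort(probands=probands_out, relatives=rel, spec=spec)


# ---------------------------------------------------------------------------
# helpers


def death_table(log: EventLog) -> pd.DataFrame:
    """Terminal event (death or exit at the age-100 cap) per person."""
    ev = log.events
    term = ev[ev["kind"].isin(["death", "exit"])]
    return term.sort_values("year").groupby("person", as_index=False).first()[
        ["person", "year", "age", "kind", "extra"]
    ].rename(columns={"year": "end_year", "age": "end_age", "kind": "end_kind",
                      "extra": "cause"})


def alive_in_year(persons: pd.DataFrame, deaths: pd.DataFrame, year_by_family) -> pd.Series:
    """Boolean mask over ``persons`` rows: alive in their family's anchor year."""
    anchor = persons["family"].map(year_by_family)
    end = persons.merge(deaths, on="person", how="left")
    died = (end["end_kind"] == "death") & (end["end_year"].to_numpy() <= anchor.to_numpy())
    born = persons["birth_year"].to_numpy() <= anchor.to_numpy()
    return pd.Series(born & ~died.to_numpy(), index=persons.index)


def cancer_free_at(log: EventLog, persons: pd.DataFrame, year_by_family) -> pd.Series:
    ev = log.events
    dx = ev[ev["kind"] == "diagnosis"].groupby("person")["year"].min()
    anchor = persons["family"].map(year_by_family)
    first_dx = persons["person"].map(dx)
    return pd.Series(
        first_dx.isna().to_numpy() | (first_dx.to_numpy() > anchor.to_numpy()),
        index=persons.index,
    )


# ---------------------------------------------------------------------------
# metrics


def relatives_alive_at_diagnosis(
    log: EventLog, cohort: Cohort, genes: list[str] | None = None
) -> dict:
    """Mean number of male and female first/second-degree relatives alive in
    the proband's diagnosis year, per carrier proband (carriers of ``genes``,
    default the high-risk panel)."""
    genes = genes if genes is not None else HIGH_RISK_GENES
    carriers = cohort.probands.merge(
        log.persons[["person", "plp_gene"]], on="person"
    )
    carriers = carriers[carriers["plp_gene"].isin(genes)]
    if carriers.empty:
        return {"mean": float("nan"), "n_probands": 0, "counts": []}
    anchors = dict(zip(carriers["family"], carriers["dx_year"]))
    rel = cohort.relatives[cohort.relatives["family"].isin(anchors)]
    deaths = death_table(log)
    alive = alive_in_year(rel, deaths, anchors)
    counts = rel[alive.to_numpy()].groupby("family").size()
    counts = counts.reindex(list(anchors), fill_value=0)
    return {
        "mean": float(counts.mean()),
        "n_probands": int(len(carriers)),
        "counts": counts.to_list(),
    }


def detection_rate(
    log: EventLog, cohort: Cohort, gene: str | None = None, group: str = "probands"
) -> dict:
    """Proportion of carriers identified through genetic testing, split by
    mechanism: diagnostic testing at/before the proband's diagnosis,
    predictive testing, or diagnostic testing after a later cancer
    ("post_cancer")."""
    persons = log.persons
    ev = log.events
    genes = [gene] if gene else list(HIGH_RISK_GENES)
    if group == "probands":
        base = cohort.probands.merge(persons[["person", "plp_gene"]], on="person")
        anchors = dict(zip(base["family"], base["dx_year"]))
    else:
        anchors = cohort.anchor_by_family
        base = cohort.relatives.copy()
    base = base[base["plp_gene"].isin(genes)]
    n = len(base)
    if n == 0:
        return {"n_carriers": 0, "n_identified": 0, "rate": float("nan"),
                "by_mechanism": {}}
    pos = ev[(ev["kind"] == "test") & (ev["result"] == "positive")
             & ev["person"].isin(base["person"])]
    pos = pos.sort_values("year").groupby("person", as_index=False).first()
    mech: dict[str, int] = {"diagnostic": 0, "predictive": 0, "post_cancer": 0}
    fam_of = dict(zip(base["person"], base["family"]))
    for r in pos.itertuples():
        anchor = anchors.get(fam_of[r.person])
        if r.mode == "predictive":
            mech["predictive"] += 1
        elif anchor is not None and r.year > anchor:
            mech["post_cancer"] += 1
        else:
            mech["diagnostic"] += 1
    identified = int(len(pos))
    return {
        "n_carriers": n,
        "n_identified": identified,
        "rate": identified / n,
        "by_mechanism": mech,
    }


def life_metrics(log: EventLog, cohort: Cohort, person_ids=None) -> dict:
    """Life expectancy (mean age at terminal event, capped at 100) and
    anchored life-years (mean years lived after the proband's diagnosis
    year), with person-level normal-approximation 95% CIs."""
    deaths = death_table(log)
    anchors = cohort.anchor_by_family
    persons = log.persons
    if person_ids is None:
        person_ids = list(cohort.probands["person"])
    sub = persons[persons["person"].isin(person_ids)].merge(deaths, on="person", how="left")
    if sub["end_year"].isna().any():
        missing = sub[sub["end_year"].isna()]["person"].iloc[0]
        raise ValueError(f"person {missing} has no terminal event in the log")
    ages = sub["end_age"].to_numpy(float)
    anchor_years = sub["family"].map(anchors).to_numpy(float)
    anchored = np.maximum(0.0, sub["end_year"].to_numpy(float) - anchor_years)

    def ci(x):
        m = float(np.mean(x))
        half = 1.96 * float(np.std(x, ddof=1)) / math.sqrt(len(x)) if len(x) > 1 else 0.0
        return {"mean": m, "ci": (m - half, m + half), "n": int(len(x))}

    return {"life_expectancy": ci(ages), "anchored_life_years": ci(anchored)}


def cumulative_incidence(
    log: EventLog,
    cohort: Cohort,
    organ: str = "breast",
    carriers_only: bool = True,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Kaplan-Meier cumulative incidence of ``organ`` cancer among female
    relatives unaffected at the proband's diagnosis, from the anchor year,
    censoring at the competing cancer, death from other causes, or exit."""
    from lifelines import KaplanMeierFitter

    genes = genes if genes is not None else HIGH_RISK_GENES
    anchors = cohort.anchor_by_family
    rel = cohort.relatives
    rel = rel[rel["sex"] == "F"]
    if carriers_only:
        rel = rel[rel["plp_gene"].isin(genes)]
    deaths = death_table(log)
    alive = alive_in_year(rel, deaths, anchors)
    unaffected = cancer_free_at(log, rel, anchors)
    rel = rel[(alive & unaffected).to_numpy()]
    if rel.empty:
        return pd.DataFrame({"time": [], "cum_incidence": []})

    ev = log.events
    dx = ev[(ev["kind"] == "diagnosis") & ev["person"].isin(rel["person"])]
    event_year = dx[dx["organ"] == organ].groupby("person")["year"].min()
    compete_year = dx[dx["organ"] != organ].groupby("person")["year"].min()
    end = deaths.set_index("person")["end_year"]

    anchor = rel["family"].map(anchors).to_numpy(float)
    e_year = rel["person"].map(event_year).to_numpy(float)
    c_year = rel["person"].map(compete_year).to_numpy(float)
    t_end = rel["person"].map(end).to_numpy(float)

    stop = np.nanmin(np.column_stack([e_year, c_year, t_end]), axis=1)
    observed = (~np.isnan(e_year)) & (e_year <= np.nan_to_num(c_year, nan=np.inf)) \
        & (e_year <= t_end)
    durations = np.maximum(stop - anchor, 0.0)
    keep = durations >= 0
    kmf = KaplanMeierFitter()
    kmf.fit(durations[keep], event_observed=observed[keep])
    sf = kmf.survival_function_
    return pd.DataFrame({
        "time": sf.index.to_numpy(float),
        "cum_incidence": 1.0 - sf.iloc[:, 0].to_numpy(float),
    })


def surgery_uptake_curve(log: EventLog, cohort: Cohort, surgery: str = "RRSO",
                         genes: list[str] | None = None) -> pd.DataFrame:
    """Cumulative uptake of a risk-reducing surgery among carrier female
    relatives unaffected at the proband's diagnosis."""
    from lifelines import KaplanMeierFitter

    genes = genes if genes is not None else HIGH_RISK_GENES
    anchors = cohort.anchor_by_family
    rel = cohort.relatives
    rel = rel[(rel["sex"] == "F") & rel["plp_gene"].isin(genes)]
    deaths = death_table(log)
    alive = alive_in_year(rel, deaths, anchors)
    unaffected = cancer_free_at(log, rel, anchors)
    rel = rel[(alive & unaffected).to_numpy()]
    if rel.empty:
        return pd.DataFrame({"time": [], "cum_uptake": []})
    ev = log.events
    surg = ev[(ev["kind"] == "surgery") & (ev["extra"] == surgery)]
    s_year = surg.groupby("person")["year"].min()
    end = deaths.set_index("person")["end_year"]
    anchor = rel["family"].map(anchors).to_numpy(float)
    e_year = rel["person"].map(s_year).to_numpy(float)
    t_end = rel["person"].map(end).to_numpy(float)
    stop = np.nanmin(np.column_stack([e_year, t_end]), axis=1)
    observed = ~np.isnan(e_year) & (e_year <= t_end)
    durations = np.maximum(stop - anchor, 0.0)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    return pd.DataFrame({
        "time": sf.index.to_numpy(float),
        "cum_uptake": 1.0 - sf.iloc[:, 0].to_numpy(float),
    })


# ---------------------------------------------------------------------------
# summary report


def _pct(num: int, den: int) -> str:
    if den == 0 or num == 0:
        return "0 (0%)"
    return f"{num} ({100.0 * num / den:.2f}%)"


def summary_report(logs: dict[str, EventLog], spec: CohortSpec | None = None) -> pd.DataFrame:
    """Per-scenario outcome table for probands diagnosed with breast cancer
    and their relatives (counts and percentages per row, one column per
    scenario)."""
    cols = {}
    for name, log in logs.items():
        cohort = select_cohort(log, spec)
        persons = log.persons
        ev = log.events
        pro = cohort.probands.merge(persons[["person", "plp_gene"]], on="person")
        n_pro = len(pro)
        carriers = pro[pro["plp_gene"].isin(HIGH_RISK_GENES)]
        tests = ev[(ev["kind"] == "test") & ev["person"].isin(pro["person"])]
        dxy = dict(zip(pro["person"], pro["dx_year"]))
        diag = tests[(tests["mode"] == "diagnostic")]
        diag_at_dx = sum(1 for r in diag.itertuples() if r.year >= dxy[r.person])
        pred = tests[tests["mode"] == "predictive"]
        # secondary ovarian cancer in carrier probands
        ov = ev[(ev["kind"] == "diagnosis") & (ev["organ"] == "ovary")
                & ev["person"].isin(carriers["person"])]
        sec_ov = sum(1 for r in ov.itertuples() if r.year > dxy.get(r.person, np.inf))

        rel_stats = relatives_alive_at_diagnosis(log, cohort)
        rel = cohort.relatives
        rel_tests = ev[(ev["kind"] == "test") & ev["person"].isin(rel["person"])]
        anchors = cohort.anchor_by_family
        deaths = death_table(log)
        fem = rel[rel["sex"] == "F"]
        alive = alive_in_year(fem, deaths, anchors)
        unaff = cancer_free_at(log, fem, anchors)
        fem_unaff = fem[(alive & unaff).to_numpy()]
        fem_unaff_carrier = fem_unaff[fem_unaff["plp_gene"].isin(HIGH_RISK_GENES)]

        col = {
            "Probands, n": n_pro,
            "Age at diagnosis, mean (sd)": (
                f"{cohort.probands['dx_age'].mean():.2f} ({cohort.probands['dx_age'].std():.2f})"
                if n_pro else "-"
            ),
            "P/LP prevalence (high-risk genes)": _pct(len(carriers), n_pro),
            "Diagnostic tests in probands": _pct(diag_at_dx, n_pro),
            "Predictive tests in probands": _pct(len(pred["person"].unique()), n_pro),
            "Secondary ovarian cancer in carrier probands": _pct(sec_ov, len(carriers)),
            "Relatives alive per carrier proband": (
                f"{rel_stats['mean']:.2f}" if rel_stats["n_probands"] else "-"
            ),
            "Diagnostic tests in relatives, n": int(
                (rel_tests["mode"] == "diagnostic").sum()
            ),
            "Predictive tests in relatives, n": int(
                (rel_tests["mode"] == "predictive").sum()
            ),
            "Unaffected female relatives per proband": (
                f"{len(fem_unaff) / n_pro:.2f}" if n_pro else "-"
            ),
            "Unaffected carrier female relatives per proband": (
                f"{len(fem_unaff_carrier) / n_pro:.2f}" if n_pro else "-"
            ),
        }
        cols[name] = col
    return pd.DataFrame(cols)


def render_markdown(table: pd.DataFrame) -> str:
    return table.to_markdown()
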