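"""Cohort selection and outcome metrics, checked against hand-built logs."""

import numpy as np
import pandas as pd
import pytest

from hbocsim import outcomes
from hbocsim.engine import EventLog


def _log(event_rows, person_rows):
    """Hand-built EventLog: events as (person, family, year, age, kind,
    organ, mode, gene, result, extra); persons as (person, family, sex,
    relation, birth_year, in_family, degree, plp_gene)."""
    persons = pd.DataFrame(
        [r + (0.0, 0.0) for r in person_rows],
        columns=["person", "family", "sex", "relation", "birth_year",
                 "in_family", "degree", "plp_gene", "z_breast", "z_ovary"],
    )
    return EventLog(list(event_rows), persons)


def _simple_population():
    persons = [
        ("p1", 1, "F", "proband", -20, True, 0, "BRCA1"),
        ("r1", 1, "F", "sibling", -22, True, 1, "BRCA1"),
        ("r2", 1, "M", "sibling", -25, True, 1, None),
        ("p2", 2, "F", "proband", -20, True, 0, None),
        ("r3", 2, "F", "mother", -50, True, 1, None),
    ]
    events = [
        # family 1: proband diagnosed at 50 (year 30), relatives alive then
        ("p1", 1, 30, 50, "diagnosis", "breast", "symptomatic", None, None, "HR+"),
        ("p1", 1, 30, 50, "test", None, "diagnostic", "BRCA1", "positive", "high_risk"),
        ("r1", 1, 31, 53, "test", None, "predictive", "BRCA1", "positive", None),
        ("p1", 1, 60, 80, "death", None, None, None, None, "other"),
        ("r1", 1, 68, 90, "death", None, None, None, None, "other"),
        ("r2", 1, 20, 45, "death", None, None, None, None, "other"),
        # family 2: proband diagnosed at 82 -> excluded from the cohort
        ("p2", 2, 62, 82, "diagnosis", "breast", "symptomatic", None, None, "HR+"),
        ("p2", 2, 70, 90, "death", None, None, None, None, "other"),
        ("r3", 2, 40, 90, "death", None, None, None, None, "other"),
    ]
    return _log(events, persons)


def test_select_cohort_age_filter():
    log = _simple_population()
    cohort = outcomes.select_cohort(log)
    assert list(cohort.probands["person"]) == ["p1"]
    assert cohort.probands["dx_age"].iloc[0] == 50
    assert set(cohort.relatives["person"]) == {"r1", "r2"}


def test_select_cohort_excludes_pre_diagnosis_detection():
    persons = [("p1", 1, "F", "proband", -20, True, 0, "BRCA1")]
    events = [
        ("p1", 1, 20, 40, "test", None, "predictive", "BRCA1", "positive", None),
        ("p1", 1, 30, 50, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p1", 1, 60, 80, "death", None, None, None, None, "other"),
    ]
    cohort = outcomes.select_cohort(_log(events, persons))
    assert cohort.probands.empty


def test_select_cohort_empty_log():
    cohort = outcomes.select_cohort(_log([], []))
    assert cohort.probands.empty and cohort.relatives.empty


def test_detection_rate_hand_counts():
    persons = [("p%d" % i, i, "F", "proband", -20, True, 0,
                "BRCA1" if i <= 3 else None) for i in range(1, 13)]
    events = []
    for i in range(1, 13):
        events.append((f"p{i}", i, 30, 50, "diagnosis", "breast", "symptomatic",
                       None, None, None))
        events.append((f"p{i}", i, 60, 80, "death", None, None, None, None, "other"))
    for i in (1, 2):  # two of the three carriers identified
        events.append((f"p{i}", i, 30, 50, "test", None, "diagnostic", "BRCA1",
                       "positive", "high_risk"))
    log = _log(events, persons)
    cohort = outcomes.select_cohort(log)
    det = outcomes.detection_rate(log, cohort, gene="BRCA1", group="probands")
    assert det["n_carriers"] == 3
    assert det["n_identified"] == 2
    assert det["rate"] == pytest.approx(2 / 3)


def test_detection_mechanisms_sum_to_total():
    log = _simple_population()
    cohort = outcomes.select_cohort(log)
    det = outcomes.detection_rate(log, cohort, group="relatives")
    assert sum(det["by_mechanism"].values()) == det["n_identified"]
    assert det["by_mechanism"]["predictive"] == 1


def test_no_testing_detection_rate_zero():
    persons = [("p1", 1, "F", "proband", -20, True, 0, "BRCA1")]
    events = [
        ("p1", 1, 30, 50, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p1", 1, 60, 80, "death", None, None, None, None, "other"),
    ]
    log = _log(events, persons)
    det = outcomes.detection_rate(log, outcomes.select_cohort(log), group="probands")
    assert det["n_identified"] == 0 and det["rate"] == 0.0


def test_life_metrics_two_person_toy():
    persons = [
        ("p1", 1, "F", "proband", -20, True, 0, None),
        ("p2", 2, "F", "proband", -20, True, 0, None),
    ]
    events = [
        ("p1", 1, 30, 50, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p2", 2, 30, 50, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p1", 1, 60, 80, "death", None, None, None, None, "other"),
        ("p2", 2, 70, 90, "death", None, None, None, None, "other"),
    ]
    log = _log(events, persons)
    cohort = outcomes.select_cohort(log)
    m = outcomes.life_metrics(log, cohort)
    assert m["life_expectancy"]["mean"] == pytest.approx(85.0)
    assert m["anchored_life_years"]["mean"] == pytest.approx(35.0)
    lo, hi = m["life_expectancy"]["ci"]
    assert lo <= 85.0 <= hi


def test_life_metrics_anchor_equals_death_year():
    persons = [("p1", 1, "F", "proband", -20, True, 0, None)]
    events = [
        ("p1", 1, 59, 79, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p1", 1, 59, 79, "death", None, None, None, None, "breast"),
    ]
    log = _log(events, persons)
    m = outcomes.life_metrics(log, outcomes.select_cohort(log))
    assert m["anchored_life_years"]["mean"] == 0.0


def test_life_metrics_requires_terminal_event():
    persons = [("p1", 1, "F", "proband", -20, True, 0, None)]
    events = [("p1", 1, 30, 50, "diagnosis", "breast", "symptomatic", None, None, None)]
    log = _log(events, persons)
    with pytest.raises(ValueError, match="terminal"):
        outcomes.life_metrics(log, outcomes.select_cohort(log))


def test_cumulative_incidence_matches_hand_km():
    # 4 carrier female relatives from anchor year 0: events at t=2, t=4;
    # censored at t=3, t=5 -> KM: S(2)=3/4, S(4)=3/4 * (1/2) = 3/8
    persons = [
        ("p1", 1, "F", "proband", -40, True, 0, "BRCA1"),
        ("a", 1, "F", "sibling", -40, True, 1, "BRCA1"),
        ("b", 1, "F", "sibling", -41, True, 1, "BRCA1"),
        ("c", 1, "F", "sibling", -42, True, 1, "BRCA1"),
        ("d", 1, "F", "sibling", -43, True, 1, "BRCA1"),
    ]
    events = [
        ("p1", 1, 0, 40, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p1", 1, 40, 80, "death", None, None, None, None, "other"),
        ("a", 1, 2, 42, "diagnosis", "breast", "symptomatic", None, None, None),
        ("a", 1, 40, 81, "death", None, None, None, None, "other"),
        ("b", 1, 3, 44, "death", None, None, None, None, "other"),
        ("c", 1, 4, 46, "diagnosis", "breast", "symptomatic", None, None, None),
        ("c", 1, 40, 82, "death", None, None, None, None, "other"),
        ("d", 1, 5, 48, "death", None, None, None, None, "other"),
    ]
    log = _log(events, persons)
    cohort = outcomes.select_cohort(log)
    ci = outcomes.cumulative_incidence(log, cohort, organ="breast")
    by_t = dict(zip(ci["time"], ci["cum_incidence"]))
    assert by_t[2.0] == pytest.approx(1 - 3 / 4)
    assert by_t[4.0] == pytest.approx(1 - 3 / 8)


def test_cumulative_incidence_no_events_flat_zero():
    persons = [
        ("p1", 1, "F", "proband", -40, True, 0, "BRCA1"),
        ("a", 1, "F", "sibling", -40, True, 1, "BRCA1"),
    ]
    events = [
        ("p1", 1, 0, 40, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p1", 1, 40, 80, "death", None, None, None, None, "other"),
        ("a", 1, 45, 85, "death", None, None, None, None, "other"),
    ]
    log = _log(events, persons)
    ci = outcomes.cumulative_incidence(log, outcomes.select_cohort(log), organ="breast")
    assert np.allclose(ci["cum_incidence"], 0.0)


def test_relatives_alive_at_diagnosis_counting():
    log = _simple_population()
    cohort = outcomes.select_cohort(log)
    res = outcomes.relatives_alive_at_diagnosis(log, cohort)
    # r1 alive in year 30, r2 died in year 20
    assert res["n_probands"] == 1
    assert res["mean"] == 1.0


def test_summary_report_scenario1_zero_rows():
    persons = [("p1", 1, "F", "proband", -20, True, 0, "BRCA1"),
               ("r1", 1, "F", "sibling", -22, True, 1, None)]
    events = [
        ("p1", 1, 30, 50, "diagnosis", "breast", "symptomatic", None, None, None),
        ("p1", 1, 60, 80, "death", None, None, None, None, "other"),
        ("r1", 1, 62, 84, "death", None, None, None, None, "other"),
    ]
    log = _log(events, persons)
    table = outcomes.summary_report({"no_testing": log})
    col = table["no_testing"]
    assert col["Diagnostic tests in probands"] == "0 (0%)"
    assert col["Predictive tests in probands"] == "0 (0%)"
    assert outcomes.render_markdown(table)


def test_summary_report_percent_self_consistency():
    log = _simple_population()
    table = outcomes.summary_report({"current_practice": log})
    cell = table["current_practice"]["Diagnostic tests in probands"]
    n, pct = cell.split(" (")
    assert float(pct.rstrip("%)")) == pytest.approx(100.0 * int(n) / 1, abs=0.01)
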