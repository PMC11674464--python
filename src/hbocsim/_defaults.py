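"""Construction of the bundled default parameter set.

The referral odds model, genetic-testing uptake and the predictive-testing
uptake table are observed Australian clinical-service estimates and are
encoded verbatim. Everything else (penetrance, baseline incidence, parity,
lifetables, screening performance, surgery uptake, survival, tumour models)
is a documented stand-in anchored to the cohort literature and Australian
registry summaries, with hazard curves rescaled so that their cumulative
risks to age 80 match the published lifetime-risk anchors. See
``data/default/PROVENANCE.md`` for sources and the methods note for the
calibration targets that discipline these choices.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import (
    GENES,
    MAX_AGE,
    ORGANS,
    PRED_AGE_BANDS,
    TIME_BANDS,
    ParameterSet,
)

# lifetime (to age 80) cumulative-risk anchors for carriers, by (gene, organ);
# high-risk breast genes from large prospective carrier cohorts, moderate
# genes from case-control relative risks applied to the population baseline
_CUM_RISK_80 = {
    ("BRCA1", "breast"): 0.72,
    ("BRCA2", "breast"): 0.69,
    ("PALB2", "breast"): 0.53,
    ("CHEK2_1100delC", "breast"): 0.27,
    ("ATM", "breast"): 0.25,
    ("RAD51C", "breast"): 0.20,
    ("RAD51D", "breast"): 0.20,
    ("BRIP1", "breast"): 0.14,
    ("BRCA1", "ovary"): 0.44,
    ("BRCA2", "ovary"): 0.17,
    ("PALB2", "ovary"): 0.05,
    ("CHEK2_1100delC", "ovary"): 0.012,
    ("ATM", "ovary"): 0.020,
    ("RAD51C", "ovary"): 0.11,
    ("RAD51D", "ovary"): 0.13,
    ("BRIP1", "ovary"): 0.058,
}

_BASELINE_CUM_80 = {"breast": 0.128, "ovary": 0.012}

# hazard *shapes* as (age, relative hazard) anchors; the absolute level is set
# by rescaling to the cumulative-risk anchor above
_SHAPES = {
    "breast_baseline": [(0, 0), (20, 0), (25, 0.01), (30, 0.055), (35, 0.13),
                        (40, 0.27), (45, 0.41), (50, 0.58), (55, 0.70),
                        (60, 0.80), (65, 1.0), (70, 0.99), (75, 0.96),
                        (80, 0.96), (85, 0.91), (90, 0.88), (100, 0.85)],
    "breast_high": [(0, 0), (18, 0), (22, 0.02), (25, 0.08), (30, 0.3),
                    (35, 0.65), (40, 0.95), (45, 1.05), (50, 1.0),
                    (55, 0.95), (60, 0.9), (70, 0.8), (80, 0.7), (100, 0.6)],
    "breast_moderate": [(0, 0), (20, 0), (25, 0.05), (30, 0.15), (35, 0.33),
                        (40, 0.58), (45, 0.8), (50, 0.9), (55, 0.97),
                        (60, 1.0), (70, 1.05), (80, 1.05), (100, 1.0)],
    "ovary_baseline": [(0, 0), (25, 0), (30, 0.05), (35, 0.1), (40, 0.2),
                       (45, 0.35), (50, 0.5), (55, 0.7), (60, 0.85),
                       (65, 0.95), (70, 1.0), (80, 1.05), (100, 1.05)],
    "ovary_brca1": [(0, 0), (30, 0), (35, 0.2), (40, 0.55), (45, 0.9),
                    (50, 1.05), (55, 1.1), (60, 1.05), (70, 0.95),
                    (80, 0.85), (100, 0.7)],
    "ovary_late": [(0, 0), (35, 0), (40, 0.05), (45, 0.25), (50, 0.6),
                   (55, 0.95), (60, 1.05), (65, 1.1), (70, 1.05),
                   (80, 0.95), (100, 0.8)],
}

_SHAPE_BY_GENE = {
    ("BRCA1", "breast"): "breast_high",
    ("BRCA2", "breast"): "breast_high",
    ("PALB2", "breast"): "breast_high",
    ("CHEK2_1100delC", "breast"): "breast_moderate",
    ("ATM", "breast"): "breast_moderate",
    ("RAD51C", "breast"): "breast_moderate",
    ("RAD51D", "breast"): "breast_moderate",
    ("BRIP1", "breast"): "breast_moderate",
    ("BRCA1", "ovary"): "ovary_brca1",
    ("BRCA2", "ovary"): "ovary_late",
    ("PALB2", "ovary"): "ovary_late",
    ("CHEK2_1100delC", "ovary"): "ovary_baseline",
    ("ATM", "ovary"): "ovary_baseline",
    ("RAD51C", "ovary"): "ovary_late",
    ("RAD51D", "ovary"): "ovary_late",
    ("BRIP1", "ovary"): "ovary_late",
}


def _curve(shape_name: str, cum_risk_80: float) -> np.ndarray:
    anchors = _SHAPES[shape_name]
    ages = np.array([a for a, _ in anchors], float)
    rel = np.array([r for _, r in anchors], float)
    h = np.interp(np.arange(MAX_AGE + 1, dtype=float), ages, rel)
    target_cum_hazard = -math.log(1.0 - cum_risk_80)
    scale = target_cum_hazard / h[:80].sum()
    return h * scale


def _lifetable(makeham: float, alpha: float, beta: float, q_infant: float) -> np.ndarray:
    ages = np.arange(MAX_AGE + 1, dtype=float)
    q = makeham + alpha * np.exp(beta * ages)
    q[0] = q_infant
    q[1:5] = np.maximum(q[1:5], 2e-4)
    return np.clip(q, 0.0, 0.7)


def _completed_parity() -> dict[int, float]:
    # completed-family parity distribution (mothers' generation stand-in);
    # mean ~2.67, conditional-on-parous mean ~2.97
    pmf = {0: 0.10, 1: 0.10, 2: 0.28, 3: 0.25, 4: 0.15, 5: 0.07, 6: 0.04, 7: 0.01}
    assert abs(sum(pmf.values()) - 1.0) < 1e-9
    return pmf


def _maternal_age_dist() -> dict[int, float]:
    ages = np.arange(16, 46)
    w = np.exp(-0.5 * ((ages - 27.5) / 5.5) ** 2)
    w /= w.sum()
    return {int(a): float(p) for a, p in zip(ages, w)}


def _age_specific_parity_cdfs(
    completed_pmf: dict[int, float], maternal: dict[int, float], max_children: int
) -> dict[str, dict[int, float]]:
    """Derive parity-by-age CDFs from the completed distribution by binomial
    thinning with the maternal-age distribution (the probability a birth has
    occurred by age a is the maternal-age CDF at a)."""
    m_ages = np.array(sorted(maternal))
    m_probs = np.array([maternal[a] for a in m_ages])
    groups = {
        "15-19": 17, "20-24": 22, "25-29": 27, "30-34": 32,
        "35-39": 37, "40-44": 42, "45+": 47,
    }
    out: dict[str, dict[int, float]] = {}
    for name, mid in groups.items():
        f_by_age = float(m_probs[m_ages <= mid].sum())
        pmf = np.zeros(max_children + 1)
        for n, pn in completed_pmf.items():
            for k in range(n + 1):
                pmf[k] += pn * math.comb(n, k) * f_by_age**k * (1 - f_by_age) ** (n - k)
        cdf = np.clip(np.cumsum(pmf), 0.0, 1.0)
        cdf[-1] = 1.0
        out[name] = {k: float(cdf[k]) for k in range(max_children + 1)}
    return out


def build_default_parameters() -> ParameterSet:
    gene_prevalence = {
        "BRCA1": 0.0020,
        "BRCA2": 0.0030,
        "PALB2": 0.0020,
        "CHEK2_1100delC": 0.0030,
        "ATM": 0.0035,
        "RAD51C": 0.0007,
        "RAD51D": 0.0005,
        "BRIP1": 0.0010,
    }

    baseline_incidence = {
        organ: _curve(f"{organ}_baseline", _BASELINE_CUM_80[organ]) for organ in ORGANS
    }
    penetrance = {
        (gene, organ): _curve(_SHAPE_BY_GENE[(gene, organ)], _CUM_RISK_80[(gene, organ)])
        for gene in GENES
        for organ in ORGANS
    }

    referral_model = {
        "breast": {
            "constant": 3.23,
            "age_40_49": 0.38,
            "age_50_69": 0.22,
            "age_70_plus": 0.10,
            "survival_lt_12m": 0.35,
            "high_grade": 2.37,
            "non_triple_negative": 0.50,
            "her2": 0.22,
        },
        "ovary": {
            "constant": 3.09,
            "age_60_74": 0.20,
            "age_75_plus": 0.08,
            "survival_lt_12m": 0.04,
            "high_grade": 1.06,
            "prior_breast": 17.75,
            "mucinous": 0.08,
            "other_histotype": 0.20,
        },
    }
    testing_uptake = {"breast": 0.96, "ovary": 0.95}

    pred_rows = {
        1: {
            "18-29": (0.259, 0.098, 0.071),
            "30-49": (0.286, 0.098, 0.022),
            "50-59": (0.146, 0.033, 0.010),
            "60+": (0.099, 0.014, 0.007),
        },
        2: {
            "18-29": (0.072, 0.045, 0.034),
            "30-49": (0.112, 0.080, 0.021),
            "50-59": (0.114, 0.034, 0.002),
            "60+": (0.039, 0.017, 0.002),
        },
    }
    predictive_uptake: dict[tuple[int, str, str], float] = {}
    for deg in (1, 2):
        for ab in PRED_AGE_BANDS:
            for i, tb in enumerate(TIME_BANDS):
                v = 0.0 if ab == "<18" else pred_rows[deg][ab][i]
                predictive_uptake[(deg, ab, tb)] = v

    max_children = 8
    completed = _completed_parity()
    maternal = _maternal_age_dist()
    parity_cdf = _age_specific_parity_cdfs(completed, maternal, max_children)

    # population screening: 30% never participate; starters begin between 40
    # and 64, concentrated around the invitation age of 50
    start_ages = np.arange(40, 65)
    w = np.where(start_ages < 50, 0.25, 1.0) * np.exp(-0.08 * np.abs(start_ages - 50.0))
    w = 0.70 * w / w.sum()
    population_start = [(int(a), float(c)) for a, c in zip(start_ages, np.cumsum(w))]
    population_start[-1] = (64, 0.70)
    # high-risk surveillance: delay (years) from eligibility to first screen
    hr_delay = [(0, 0.50), (1, 0.72), (2, 0.84), (3, 0.90), (4, 0.93), (5, 0.95)]

    screening = {
        "performance": [
            ("mammography", 0, 39, 0.62, 0.92),
            ("mammography", 40, 49, 0.70, 0.95),
            ("mammography", 50, 59, 0.80, 0.96),
            ("mammography", 60, 100, 0.85, 0.96),
            ("MRI", 0, 100, 0.90, 0.90),
        ],
        "start_cdf": {"population": population_start, "high_risk": hr_delay},
        "population": {
            "age_stop": 74,
            "interval_target": 2,
            "interval_delay_p": 0.6,
        },
        "high_risk": {
            "mammo_age_min": 25,
            "mammo_age_max": 64,
            "mri_age_min": 25,
            "mri_age_max": 59,
            "interval_target": 1,
            "interval_delay_p": 0.7,
        },
        "moderate": {"mammo_age_min": 35, "mammo_age_max": 59, "start_shift": 10},
    }

    surgery_uptake = []
    for gene, mult in (("BRCA1", 1.0), ("BRCA2", 1.0), ("PALB2", 1.0),
                       ("ATM", 0.5), ("CHEK2_1100delC", 0.5)):
        surgery_uptake += [
            ("BRRM", gene, 18, 39, 0.040 * mult),
            ("BRRM", gene, 40, 49, 0.025 * mult),
            ("BRRM", gene, 50, 69, 0.008 * mult),
        ]
    surgery_uptake += [
        ("RRSO", "BRCA1", 35, 44, 0.10), ("RRSO", "BRCA1", 45, 54, 0.13),
        ("RRSO", "BRCA1", 55, 74, 0.06),
        ("RRSO", "BRCA2", 40, 49, 0.09), ("RRSO", "BRCA2", 50, 59, 0.11),
        ("RRSO", "BRCA2", 60, 74, 0.05),
        ("RRSO", "PALB2", 50, 59, 0.10), ("RRSO", "PALB2", 60, 74, 0.05),
        ("RRSO", "RAD51C", 45, 59, 0.10), ("RRSO", "RAD51C", 60, 74, 0.05),
        ("RRSO", "RAD51D", 45, 59, 0.10), ("RRSO", "RAD51D", 60, 74, 0.05),
        ("RRSO", "BRIP1", 60, 74, 0.08),
    ]
    surgery = {
        "uptake": surgery_uptake,
        "risk_reduction": {"BRRM": 0.10, "RRSO": 0.05},
        "rrso_breast_multiplier": 1.0,
        "crrm_uptake": {"carrier": 0.45, "noncarrier": 0.05},
    }

    survival = {
        "excess": [
            ("breast", "local", "<50", 0.006), ("breast", "local", "50-69", 0.005),
            ("breast", "local", "70+", 0.009),
            ("breast", "regional", "<50", 0.028), ("breast", "regional", "50-69", 0.030),
            ("breast", "regional", "70+", 0.042),
            ("breast", "distant", "<50", 0.20), ("breast", "distant", "50-69", 0.24),
            ("breast", "distant", "70+", 0.30),
            ("ovary", "local", "<50", 0.020), ("ovary", "local", "50-69", 0.030),
            ("ovary", "local", "70+", 0.045),
            ("ovary", "regional", "<50", 0.09), ("ovary", "regional", "50-69", 0.12),
            ("ovary", "regional", "70+", 0.16),
            ("ovary", "distant", "<50", 0.25), ("ovary", "distant", "50-69", 0.30),
            ("ovary", "distant", "70+", 0.38),
        ],
        "subtype_multiplier": {"TN": 1.8, "HER2": 1.1, "HR+": 0.85},
        "histology_multiplier": {
            "serous": 1.1, "clear_cell": 1.3, "endometrioid": 0.7,
            "mucinous": 0.9, "other": 1.2,
        },
        "excess_years": 15,
    }

    lifetable = {
        # female table net of breast/ovarian cancer deaths (stand-in)
        "F": _lifetable(2.5e-4, 4.5e-6, 0.110, 3.5e-3),
        "M": _lifetable(6.0e-4, 1.37e-5, 0.1026, 4.5e-3),
    }

    tumour_models = {
        "breast": {
            "subtype_by_gene": {
                "none": {"TN": 0.11, "HER2": 0.14, "HR+": 0.75},
                "BRCA1": {"TN": 0.65, "HER2": 0.05, "HR+": 0.30},
                "BRCA2": {"TN": 0.16, "HER2": 0.07, "HR+": 0.77},
                "PALB2": {"TN": 0.30, "HER2": 0.08, "HR+": 0.62},
                "CHEK2_1100delC": {"TN": 0.05, "HER2": 0.12, "HR+": 0.83},
                "ATM": {"TN": 0.06, "HER2": 0.10, "HR+": 0.84},
                "RAD51C": {"TN": 0.30, "HER2": 0.10, "HR+": 0.60},
                "RAD51D": {"TN": 0.30, "HER2": 0.10, "HR+": 0.60},
                "BRIP1": {"TN": 0.15, "HER2": 0.12, "HR+": 0.73},
            },
            "grade_by_subtype": {
                "TN": {1: 0.03, 2: 0.20, 3: 0.77},
                "HER2": {1: 0.08, 2: 0.42, 3: 0.50},
                "HR+": {1: 0.28, 2: 0.50, 3: 0.22},
            },
            "size_by_mode": {
                "screen": {"<10": 0.34, "10-20": 0.45, "21-50": 0.18, ">50": 0.03},
                "symptomatic": {"<10": 0.09, "10-20": 0.40, "21-50": 0.41, ">50": 0.10},
                "baseline": {"<10": 0.09, "10-20": 0.40, "21-50": 0.41, ">50": 0.10},
            },
            "node_pos_by_size": {"<10": 0.08, "10-20": 0.20, "21-50": 0.42, ">50": 0.65},
            "metastasis_by_nodes": {"negative": 0.010, "positive": 0.085},
        },
        "ovary": {
            "histology_by_age": {
                "<50": {"serous": 0.35, "endometrioid": 0.25, "clear_cell": 0.15,
                        "mucinous": 0.15, "other": 0.10},
                "50-69": {"serous": 0.52, "endometrioid": 0.17, "clear_cell": 0.10,
                          "mucinous": 0.08, "other": 0.13},
                "70+": {"serous": 0.62, "endometrioid": 0.07, "clear_cell": 0.05,
                        "mucinous": 0.05, "other": 0.21},
            },
            "grade_by_histology": {
                "serous": {1: 0.05, 2: 0.15, 3: 0.80},
                "endometrioid": {1: 0.35, 2: 0.40, 3: 0.25},
                "clear_cell": {1: 0.05, 2: 0.15, 3: 0.80},
                "mucinous": {1: 0.50, 2: 0.30, 3: 0.20},
                "other": {1: 0.20, 2: 0.30, 3: 0.50},
            },
            "stage_by_grade": {
                1: {"local": 0.50, "regional": 0.30, "distant": 0.20},
                2: {"local": 0.30, "regional": 0.35, "distant": 0.35},
                3: {"local": 0.15, "regional": 0.35, "distant": 0.50},
            },
            "serous_distant_shift": 0.15,
        },
    }

    sojourn_dist = {
        # lognormal preclinical sojourn (years); BRCA1 tumours grow faster
        "default": {"mu": 0.85, "sigma": 0.55},
        "BRCA1": {"mu": 0.50, "sigma": 0.50},
        "BRCA2": {"mu": 0.70, "sigma": 0.50},
    }

    notes = {
        "family_history_counts_both_sides": True,
        "ovary_high_grade_min": 2,
        "breast_high_grade_min": 3,
    }

    return ParameterSet(
        gene_prevalence=gene_prevalence,
        penetrance=penetrance,
        baseline_incidence=baseline_incidence,
        polygenic_hr_per_sd={"breast": 1.60, "ovary": 1.32},
        polygenic_correlation=0.0,
        referral_model=referral_model,
        testing_uptake=testing_uptake,
        predictive_uptake=predictive_uptake,
        male_predictive_rate_ratio=0.422,
        parity_cdf=parity_cdf,
        maternal_age_dist=maternal,
        paternal_age_shift=2,
        max_children=max_children,
        screening=screening,
        surgery=surgery,
        survival=survival,
        lifetable=lifetable,
        tumour_models=tumour_models,
        sojourn_dist=sojourn_dist,
        notes=notes,
    )
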