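"""Model parameterisation: the :class:`ParameterSet` container, the bundled
defaults, YAML/CSV loading and saving, and validation.

The full parameterisation covers gene prevalences, age-specific hazard curves
(carrier penetrance and non-carrier baseline incidence), polygenic hazard
ratios, the referral odds model, genetic-testing uptake, predictive-testing
uptake by degree/age/time, family-structure distributions (parity, maternal
age), screening performance and participation, surgery uptake and effect,
cancer survival, lifetables, tumour characteristic models and the breast
preclinical sojourn distribution.

The parameter bundle on disk is one YAML config referencing plain CSV tables
(one per rate surface), so every number is diff-able and editable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

GENES = [
    "BRCA1",
    "BRCA2",
    "PALB2",
    "CHEK2_1100delC",
    "ATM",
    "RAD51C",
    "RAD51D",
    "BRIP1",
]
HIGH_RISK_GENES = ["BRCA1", "BRCA2", "PALB2"]
MODERATE_RISK_GENES = ["CHEK2_1100delC", "ATM", "RAD51C", "RAD51D", "BRIP1"]
EXTENDED_PANEL = list(GENES)

ORGANS = ["breast", "ovary"]
MAX_AGE = 100

#: age bands used by the predictive-testing uptake table
PRED_AGE_BANDS = ["<18", "18-29", "30-49", "50-59", "60+"]
#: time-since-identification bands (years elapsed: 0 -> "<1", 1-3 -> "1-3", >3 -> ">3")
TIME_BANDS = ["<1", "1-3", ">3"]

SURVIVAL_AGE_BANDS = ["<50", "50-69", "70+"]

_TABLE_FILES = {
    "hazards": "hazards.csv",
    "lifetable": "lifetable.csv",
    "parity_cdf": "parity_cdf.csv",
    "maternal_age": "maternal_age.csv",
    "predictive_uptake": "predictive_uptake.csv",
    "screening_performance": "screening_performance.csv",
    "screening_start": "screening_start.csv",
    "surgery_uptake": "surgery_uptake.csv",
    "survival": "survival.csv",
    "gene_prevalence": "gene_prevalence.csv",
}


class ParameterError(ValueError):
    """Raised when a parameter bundle is missing a field or fails validation."""


def pred_age_band(age: int) -> str:
    if age < 18:
        return "<18"
    if age < 30:
        return "18-29"
    if age < 50:
        return "30-49"
    if age < 60:
        return "50-59"
    return "60+"


def time_band(elapsed_years: int) -> str:
    """Map whole years since family-variant identification onto the uptake
    table's time bands: the identification year itself is "<1", years 1-3 are
    "1-3", later years ">3"."""
    if elapsed_years < 1:
        return "<1"
    if elapsed_years <= 3:
        return "1-3"
    return ">3"


def survival_age_band(age: int) -> str:
    if age < 50:
        return "<50"
    if age < 70:
        return "50-69"
    return "70+"


@dataclass
class ParameterSet:
    """Complete model parameterisation.

    Hazard curves are annual piecewise-constant hazards on integer ages
    0..100 (inclusive), stored as length-101 arrays.
    """

    gene_prevalence: dict[str, float]
    penetrance: dict[tuple[str, str], np.ndarray]  # (gene, organ) -> hazard[101]
    baseline_incidence: dict[str, np.ndarray]  # organ -> hazard[101]
    polygenic_hr_per_sd: dict[str, float]
    polygenic_correlation: float
    referral_model: dict[str, dict[str, float]]
    testing_uptake: dict[str, float]
    predictive_uptake: dict[tuple[int, str, str], float]  # (degree, age band, time band)
    male_predictive_rate_ratio: float
    parity_cdf: dict[str, dict[int, float]]  # age group -> {n children: cum prob}
    maternal_age_dist: dict[int, float]
    paternal_age_shift: int
    max_children: int
    screening: dict[str, Any]
    surgery: dict[str, Any]
    survival: dict[str, Any]
    lifetable: dict[str, np.ndarray]  # sex ("F"/"M") -> annual death prob[101]
    tumour_models: dict[str, Any]
    sojourn_dist: dict[str, dict[str, float]]
    notes: dict[str, Any] = field(default_factory=dict)

    # -- convenience -------------------------------------------------------
    def hazard(self, gene: str | None, organ: str) -> np.ndarray:
        """Annual hazard curve for a genotype: carrier penetrance for ``gene``
        or the non-carrier baseline when ``gene`` is None."""
        if gene is None:
            return self.baseline_incidence[organ]
        return self.penetrance[(gene, organ)]

    def sojourn_params(self, gene: str | None) -> dict[str, float]:
        if gene is not None and gene in self.sojourn_dist:
            return self.sojourn_dist[gene]
        return self.sojourn_dist["default"]

    def screening_performance(self, modality: str, age: int) -> tuple[float, float]:
        for row in self.screening["performance"]:
            mod, lo, hi, sens, spec = row
            if mod == modality and lo <= age <= hi:
                return float(sens), float(spec)
        raise ParameterError(f"no screening performance row for {modality} at age {age}")

    def surgery_uptake(self, surgery: str, gene: str, age: int) -> float:
        for row in self.surgery["uptake"]:
            s, g, lo, hi, p = row
            if s == surgery and g == gene and lo <= age <= hi:
                return float(p)
        return 0.0

    def survival_excess(self, organ: str, stage: str, age: int) -> float:
        band = survival_age_band(age)
        for row in self.survival["excess"]:
            o, s, b, rate = row
            if o == organ and s == stage and b == band:
                return float(rate)
        raise ParameterError(f"no survival row for {organ}/{stage}/{band}")

    def equals(self, other: "ParameterSet") -> bool:
        """Field-by-field equality with tolerant float/array comparison."""
        return not _diff(self, other)


def _diff(a: ParameterSet, b: ParameterSet) -> list[str]:
    out = []
    for f in dataclasses.fields(ParameterSet):
        va, vb = getattr(a, f.name), getattr(b, f.name)
        if not _eq(va, vb):
            out.append(f.name)
    return out


def _eq(a, b) -> bool:
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return np.allclose(np.asarray(a, float), np.asarray(b, float), rtol=1e-9, atol=1e-12)
    if isinstance(a, dict) and isinstance(b, dict):
        if set(a) != set(b):
            return False
        return all(_eq(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        if len(a) != len(b):
            return False
        return all(_eq(x, y) for x, y in zip(a, b))
    if isinstance(a, float) or isinstance(b, float):
        try:
            return math.isclose(float(a), float(b), rel_tol=1e-9, abs_tol=1e-12)
        except (TypeError, ValueError):
            return a == b
    return a == b


# ---------------------------------------------------------------------------
# defaults

_DEFAULT_CACHE: ParameterSet | None = None


def default_parameters() -> ParameterSet:
    """Return the shipped default parameterisation (cached; treat as read-only
    or copy before mutating)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        from ._defaults import build_default_parameters

        _DEFAULT_CACHE = build_default_parameters()
        report = validate_parameters(_DEFAULT_CACHE)
        if report:  # pragma: no cover - defaults are validated in tests
            raise ParameterError(f"default parameters invalid: {report[:3]}")
    return _DEFAULT_CACHE


# ---------------------------------------------------------------------------
# save / load


def save_parameters(p: ParameterSet, directory: str | Path) -> Path:
    """Write ``p`` as a YAML config plus CSV tables under ``directory``.

    Returns the path of the written config file. ``load_parameters`` on that
    path round-trips to a field-identical ParameterSet.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [(g, v) for g, v in p.gene_prevalence.items()],
        columns=["gene", "prevalence"],
    ).to_csv(directory / _TABLE_FILES["gene_prevalence"], index=False)

    rows = []
    for organ in ORGANS:
        for age in range(MAX_AGE + 1):
            rows.append((f"baseline_{organ}", age, p.baseline_incidence[organ][age]))
    for (gene, organ), h in sorted(p.penetrance.items()):
        for age in range(MAX_AGE + 1):
            rows.append((f"{gene}_{organ}", age, h[age]))
    pd.DataFrame(rows, columns=["curve", "age", "hazard"]).to_csv(
        directory / _TABLE_FILES["hazards"], index=False, float_format="%.10g"
    )

    pd.DataFrame(
        {
            "age": np.arange(MAX_AGE + 1),
            "F": p.lifetable["F"],
            "M": p.lifetable["M"],
        }
    ).to_csv(directory / _TABLE_FILES["lifetable"], index=False, float_format="%.10g")

    rows = [
        (grp, k, v)
        for grp, cdf in p.parity_cdf.items()
        for k, v in sorted(cdf.items())
    ]
    pd.DataFrame(rows, columns=["age_group", "children", "cum_prob"]).to_csv(
        directory / _TABLE_FILES["parity_cdf"], index=False, float_format="%.10g"
    )

    pd.DataFrame(
        sorted(p.maternal_age_dist.items()), columns=["age", "prob"]
    ).to_csv(directory / _TABLE_FILES["maternal_age"], index=False, float_format="%.10g")

    rows = [
        (deg, ab, tb, p.predictive_uptake[(deg, ab, tb)])
        for deg in (1, 2)
        for ab in PRED_AGE_BANDS
        for tb in TIME_BANDS
    ]
    pd.DataFrame(rows, columns=["degree", "age_band", "time_band", "probability"]).to_csv(
        directory / _TABLE_FILES["predictive_uptake"], index=False
    )

    pd.DataFrame(
        p.screening["performance"],
        columns=["modality", "age_from", "age_to", "sensitivity", "specificity"],
    ).to_csv(directory / _TABLE_FILES["screening_performance"], index=False)

    rows = [
        (pathway, off, cum)
        for pathway, cdf in p.screening["start_cdf"].items()
        for off, cum in cdf
    ]
    pd.DataFrame(rows, columns=["pathway", "offset", "cum_prob"]).to_csv(
        directory / _TABLE_FILES["screening_start"], index=False, float_format="%.10g"
    )

    pd.DataFrame(
        p.surgery["uptake"],
        columns=["surgery", "gene", "age_from", "age_to", "annual_probability"],
    ).to_csv(directory / _TABLE_FILES["surgery_uptake"], index=False)

    pd.DataFrame(
        p.survival["excess"], columns=["organ", "stage", "age_band", "annual_excess"]
    ).to_csv(directory / _TABLE_FILES["survival"], index=False)

    config = {
        "tables": dict(_TABLE_FILES),
        "polygenic_hr_per_sd": p.polygenic_hr_per_sd,
        "polygenic_correlation": p.polygenic_correlation,
        "referral_model": p.referral_model,
        "testing_uptake": p.testing_uptake,
        "male_predictive_rate_ratio": p.male_predictive_rate_ratio,
        "paternal_age_shift": p.paternal_age_shift,
        "max_children": p.max_children,
        "screening_config": {
            k: v for k, v in p.screening.items() if k not in ("performance", "start_cdf")
        },
        "surgery_config": {k: v for k, v in p.surgery.items() if k != "uptake"},
        "survival_config": {k: v for k, v in p.survival.items() if k != "excess"},
        "tumour_models": p.tumour_models,
        "sojourn_dist": p.sojourn_dist,
        "notes": p.notes,
    }
    cfg_path = directory / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(_plain(config), sort_keys=False))
    return cfg_path


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML."""
    if isinstance(obj, dict):
        return {_plain_key(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _plain_key(k):
    if isinstance(k, np.generic):
        return k.item()
    if isinstance(k, tuple):
        return "|".join(str(x) for x in k)
    return k


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load a parameter bundle from a YAML config.

    Any field absent from the config falls back to the bundled default. CSV
    table paths are resolved relative to the config file. Raises
    :class:`ParameterError` on missing tables or validation failures.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ParameterError(f"missing parameter config: {config_path}")
    raw = yaml.safe_load(config_path.read_text()) or {}
    base = config_path.parent
    d = default_parameters()

    def table(name: str) -> pd.DataFrame | None:
        fn = raw.get("tables", {}).get(name)
        if fn is None:
            return None
        path = base / fn
        if not path.exists():
            raise ParameterError(f"missing parameter table '{name}': {path}")
        try:
            return pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            raise ParameterError(f"unparseable table '{name}' ({path}): {exc}") from exc

    t = table("gene_prevalence")
    gene_prevalence = (
        dict(d.gene_prevalence)
        if t is None
        else {str(r.gene): float(r.prevalence) for r in t.itertuples()}
    )

    t = table("hazards")
    if t is None:
        baseline = {o: d.baseline_incidence[o].copy() for o in ORGANS}
        penetrance = {k: v.copy() for k, v in d.penetrance.items()}
    else:
        baseline, penetrance = {}, {}
        for curve, grp in t.groupby("curve"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if not np.array_equal(ages, np.arange(MAX_AGE + 1)):
                raise ParameterError(
                    f"hazard curve '{curve}' must cover integer ages 0-100 with no gaps"
                )
            h = grp["hazard"].to_numpy(float)
            name = str(curve)
            gene, _, organ = name.rpartition("_")
            if gene == "baseline":
                baseline[organ] = h
            else:
                penetrance[(gene, organ)] = h
        for organ in ORGANS:
            baseline.setdefault(organ, d.baseline_incidence[organ].copy())
        for key, v in d.penetrance.items():
            penetrance.setdefault(key, v.copy())

    t = table("lifetable")
    if t is None:
        lifetable = {s: d.lifetable[s].copy() for s in ("F", "M")}
    else:
        t = t.sort_values("age")
        lifetable = {"F": t["F"].to_numpy(float), "M": t["M"].to_numpy(float)}

    t = table("parity_cdf")
    if t is None:
        parity_cdf = {g: dict(c) for g, c in d.parity_cdf.items()}
    else:
        parity_cdf = {}
        for grp, rows in t.groupby("age_group"):
            parity_cdf[str(grp)] = {
                int(r.children): float(r.cum_prob) for r in rows.itertuples()
            }

    t = table("maternal_age")
    maternal = (
        dict(d.maternal_age_dist)
        if t is None
        else {int(r.age): float(r.prob) for r in t.itertuples()}
    )

    t = table("predictive_uptake")
    if t is None:
        predictive = dict(d.predictive_uptake)
    else:
        predictive = {
            (int(r.degree), str(r.age_band), str(r.time_band)): float(r.probability)
            for r in t.itertuples()
        }

    t = table("screening_performance")
    performance = (
        [tuple(r) for r in d.screening["performance"]]
        if t is None
        else [
            (str(r.modality), int(r.age_from), int(r.age_to), float(r.sensitivity), float(r.specificity))
            for r in t.itertuples()
        ]
    )

    t = table("screening_start")
    if t is None:
        start_cdf = {k: [tuple(x) for x in v] for k, v in d.screening["start_cdf"].items()}
    else:
        start_cdf = {}
        for pathway, rows in t.groupby("pathway"):
            start_cdf[str(pathway)] = [
                (int(r.offset), float(r.cum_prob)) for r in rows.itertuples()
            ]

    t = table("surgery_uptake")
    uptake = (
        [tuple(r) for r in d.surgery["uptake"]]
        if t is None
        else [
            (str(r.surgery), str(r.gene), int(r.age_from), int(r.age_to), float(r.annual_probability))
            for r in t.itertuples()
        ]
    )

    t = table("survival")
    excess = (
        [tuple(r) for r in d.survival["excess"]]
        if t is None
        else [
            (str(r.organ), str(r.stage), str(r.age_band), float(r.annual_excess))
            for r in t.itertuples()
        ]
    )

    def merged(key: str, default_val):
        user = raw.get(key)
        if user is None:
            return _copy_nested(default_val)
        if isinstance(default_val, dict) and isinstance(user, dict):
            out = _copy_nested(default_val)
            _deep_update(out, user)
            return out
        return user

    screening = merged("screening_config", {k: v for k, v in d.screening.items() if k not in ("performance", "start_cdf")})
    screening["performance"] = performance
    screening["start_cdf"] = start_cdf
    surgery = merged("surgery_config", {k: v for k, v in d.surgery.items() if k != "uptake"})
    surgery["uptake"] = uptake
    survival = merged("survival_config", {k: v for k, v in d.survival.items() if k != "excess"})
    survival["excess"] = excess

    p = ParameterSet(
        gene_prevalence=gene_prevalence,
        penetrance=penetrance,
        baseline_incidence=baseline,
        polygenic_hr_per_sd=merged("polygenic_hr_per_sd", d.polygenic_hr_per_sd),
        polygenic_correlation=float(raw.get("polygenic_correlation", d.polygenic_correlation)),
        referral_model=merged("referral_model", d.referral_model),
        testing_uptake=merged("testing_uptake", d.testing_uptake),
        predictive_uptake=predictive,
        male_predictive_rate_ratio=float(
            raw.get("male_predictive_rate_ratio", d.male_predictive_rate_ratio)
        ),
        parity_cdf=parity_cdf,
        maternal_age_dist=maternal,
        paternal_age_shift=int(raw.get("paternal_age_shift", d.paternal_age_shift)),
        max_children=int(raw.get("max_children", d.max_children)),
        screening=screening,
        surgery=surgery,
        survival=survival,
        lifetable=lifetable,
        tumour_models=merged("tumour_models", d.tumour_models),
        sojourn_dist=merged("sojourn_dist", d.sojourn_dist),
        notes=merged("notes", d.notes),
    )
    report = validate_parameters(p)
    if report:
        raise ParameterError("invalid parameter bundle: " + "; ".join(report[:5]))
    return p


def _copy_nested(obj):
    if isinstance(obj, dict):
        return {k: _copy_nested(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_copy_nested(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.copy()
    return obj


def _deep_update(base: dict, update: dict) -> None:
    for k, v in update.items():
        if k in base and isinstance(base[k], dict) and isinstance(v, dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


# ---------------------------------------------------------------------------
# validation


def _check_prob(report, value, where):
    try:
        v = float(value)
    except (TypeError, ValueError):
        report.append(f"{where}: non-numeric probability {value!r}")
        return
    if not (0.0 <= v <= 1.0):
        report.append(f"{where}: probability {v} outside [0, 1]")


def validate_parameters(p: ParameterSet) -> list[str]:
    """Report-only validation; returns a list of violations (empty if valid)."""
    report: list[str] = []

    for g, v in p.gene_prevalence.items():
        _check_prob(report, v, f"gene_prevalence[{g}]")
    if sum(p.gene_prevalence.values()) > 1.0:
        report.append("gene_prevalence: total carrier frequency exceeds 1")

    for (gene, organ), h in p.penetrance.items():
        _check_hazard(report, h, f"penetrance[{gene},{organ}]")
    for organ, h in p.baseline_incidence.items():
        _check_hazard(report, h, f"baseline_incidence[{organ}]")
    for organ in ORGANS:
        if organ not in p.baseline_incidence:
            report.append(f"baseline_incidence: missing organ {organ}")

    for organ, hr in p.polygenic_hr_per_sd.items():
        if not hr > 0:
            report.append(f"polygenic_hr_per_sd[{organ}]: must be > 0, got {hr}")
    if not (-1.0 <= p.polygenic_correlation <= 1.0):
        report.append("polygenic_correlation outside [-1, 1]")

    for organ, model in p.referral_model.items():
        for term, odds in model.items():
            if not odds > 0:
                report.append(f"referral_model[{organ}][{term}]: odds must be > 0")
    for organ, v in p.testing_uptake.items():
        _check_prob(report, v, f"testing_uptake[{organ}]")

    for (deg, ab, tb), v in p.predictive_uptake.items():
        _check_prob(report, v, f"predictive_uptake[{deg},{ab},{tb}]")
        if ab == "<18" and v != 0.0:
            report.append(f"predictive_uptake[{deg},<18,{tb}]: must be 0 for under-18s")
    for deg in (1, 2):
        for ab in PRED_AGE_BANDS:
            for tb in TIME_BANDS:
                if (deg, ab, tb) not in p.predictive_uptake:
                    report.append(f"predictive_uptake: missing cell ({deg},{ab},{tb})")
    _check_prob(report, p.male_predictive_rate_ratio, "male_predictive_rate_ratio")

    for grp, cdf in p.parity_cdf.items():
        vals = [cdf[k] for k in sorted(cdf)]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            report.append(f"parity_cdf[{grp}]: not non-decreasing")
        if vals and abs(vals[-1] - 1.0) > 1e-9:
            report.append(f"parity_cdf[{grp}]: must end at 1, ends at {vals[-1]}")
        for k, v in cdf.items():
            _check_prob(report, v, f"parity_cdf[{grp}][{k}]")

    tot = sum(p.maternal_age_dist.values())
    if abs(tot - 1.0) > 1e-6:
        report.append(f"maternal_age_dist: probabilities sum to {tot}, not 1")

    for sex in ("F", "M"):
        q = p.lifetable.get(sex)
        if q is None or len(q) != MAX_AGE + 1:
            report.append(f"lifetable[{sex}]: must cover ages 0-100")
            continue
        for age, v in enumerate(q):
            if not (0.0 <= v <= 1.0):
                report.append(f"lifetable[{sex}] age {age}: probability {v} outside [0,1]")
                break

    for row in p.screening["performance"]:
        _, lo, hi, sens, spec = row
        _check_prob(report, sens, f"screening sensitivity {row[:3]}")
        _check_prob(report, spec, f"screening specificity {row[:3]}")
    for pathway, cdf in p.screening["start_cdf"].items():
        cums = [c for _, c in cdf]
        if any(b < a - 1e-12 for a, b in zip(cums, cums[1:])):
            report.append(f"screening start_cdf[{pathway}]: not non-decreasing")
        for _, c in cdf:
            _check_prob(report, c, f"screening start_cdf[{pathway}]")
    pop_ages = [a for a, _ in p.screening["start_cdf"].get("population", [])]
    if pop_ages and (min(pop_ages) < 40 or max(pop_ages) > 64):
        report.append("screening start_cdf[population]: start ages must lie in [40, 64]")

    for row in p.surgery["uptake"]:
        _check_prob(report, row[4], f"surgery uptake {row[:4]}")
    for s, v in p.surgery["risk_reduction"].items():
        _check_prob(report, v, f"surgery risk_reduction[{s}]")
    for k, v in p.surgery["crrm_uptake"].items():
        _check_prob(report, v, f"crrm_uptake[{k}]")

    for row in p.survival["excess"]:
        if row[3] < 0:
            report.append(f"survival excess {row[:3]}: negative rate")

    _check_categoricals(report, p.tumour_models)

    for key, sp in p.sojourn_dist.items():
        if sp.get("sigma", 0) <= 0:
            report.append(f"sojourn_dist[{key}]: sigma must be > 0")

    return report


def _check_hazard(report, h, where):
    h = np.asarray(h, float)
    if h.shape != (MAX_AGE + 1,):
        report.append(f"{where}: hazard curve must cover integer ages 0-100 (length 101)")
        return
    if np.any(~np.isfinite(h)):
        report.append(f"{where}: non-finite hazard values")
        return
    bad = np.nonzero(h < 0)[0]
    if bad.size:
        report.append(f"{where}: negative hazard at age {int(bad[0])}")


def _check_categoricals(report, node, path="tumour_models"):
    """Every leaf dict of category->prob must be a distribution."""
    if isinstance(node, dict):
        vals = list(node.values())
        if vals and all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in vals):
            keys = list(node.keys())
            if all(isinstance(k, (str, int)) for k in keys) and len(vals) > 1:
                s = sum(vals)
                if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
                    report.append(f"{path}: probability outside [0,1]")
                elif path.endswith(("node_pos_by_size", "metastasis_by_nodes")) or path.endswith("_shift"):
                    pass  # per-category Bernoulli probabilities, not a distribution
                elif abs(s - 1.0) > 1e-6:
                    report.append(f"{path}: distribution sums to {s:.6f}, not 1")
            return
        for k, v in node.items():
            _check_categoricals(report, v, f"{path}.{k}")
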