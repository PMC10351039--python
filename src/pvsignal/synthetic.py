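"""FAERS-like synthetic spontaneous-report streams with known ground truth.

The generator emulates the structure of a spontaneous reporting database at
desk scale: a large background of reports suspecting other drugs, plus
target-drug report streams whose psychiatric-PT reporting rates are the
background baselines multiplied by configurable reporting-rate multipliers
(the ground-truth relative reporting rate per (drug, PT) pair). Every case
carries demographics drawn from configurable margins (defaulting to the
shipped reference cohort's printed distributions: ~70% male, ~72% North
America, hospitalisation-dominated outcomes), near-duplicate records are
injected by cloning a case and re-drawing exactly one of the four dedup key
fields, and field-level missingness is applied last.

Generation is report-level: each case is created once with its full PT set,
the way FAERS cases carry multiple reactions. A fixed seed makes the record
stream, the written file and the ground truth byte-identical across runs.

What the generator does *not* emulate: reporting dynamics over calendar time
(Weber effect, stimulated reporting), drug–drug interaction signals,
correlated missingness, or free-text narratives.
"""
from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import CohortIndex
from .descriptives import AGE_BANDS, worst_outcome
from .disproportionality import SignalResult, TOTAL_LABEL
from .records import AdrFlag, DrugRole, ICSRRecord, Outcome, Sex

DEFAULT_TARGET_CASES = {
    "sorafenib": 3000,
    "sunitinib": 3500,
    "cabozantinib": 1500,
    "lenvatinib": 800,
    "vandetanib": 150,
}

#: Baseline per-report probability that a background case lists each
#: psychiatric PT. Rates are in the 3/10,000 – 6/1,000 range typical of
#: individual psychiatric PTs in spontaneous-report databases.
DEFAULT_PT_BASELINE = {
    "confusional state": 0.004,
    "feeding disorder": 0.002,
    "hypersomnia": 0.002,
    "disorientation": 0.002,
    "mental status changes": 0.0015,
    "aphonia": 0.001,
    "mutism": 0.0005,
    "thyrotoxic crisis": 0.0003,
    "laziness": 0.0003,
    "insomnia": 0.006,
    "depression": 0.005,
    "anxiety": 0.004,
}

#: Non-psychiatric filler PTs; every case receives one so that no report has
#: an empty reaction list and the "all other events" column is populated.
FILLER_PTS = (
    "diarrhoea", "nausea", "fatigue", "hypertension", "rash",
    "headache", "vomiting", "dizziness", "pyrexia", "decreased appetite",
)

BACKGROUND_DRUGS = tuple(f"comparator-{i:02d}" for i in range(1, 21))

_REGION_COUNTRIES = {
    "North America": ("US", "CA", "MX"),
    "South America": ("BR", "AR", "CO"),
    "Europe": ("DE", "FR", "GB", "IT", "ES"),
    "Asia": ("JP", "CN", "KR", "IN"),
    "Other": ("AU", "NZ", "ZA"),
}
_OUTCOME_SETS = {
    "Death": frozenset({Outcome.DEATH}),
    "Disability": frozenset({Outcome.DISABILITY}),
    "Hospitalization": frozenset({Outcome.HOSPITALIZATION}),
    "Life-Threatening": frozenset({Outcome.LIFE_THREATENING}),
}
_INDICATION_TEXT = {
    "Renal cancer": "renal cell carcinoma",
    "Hepatic cancer": "hepatocellular carcinoma",
    "Neoplasm malignant": "neoplasm malignant",
    "Gastrointestinal stromal": "gastrointestinal stromal tumour",
    "Thyroid cancer": "thyroid cancer",
    "Lung neoplasm malignant": "lung neoplasm malignant",
    "Pancreatic carcinoma": "pancreatic carcinoma",
    "Other": "melanoma",
}
_AGE_SAMPLING = {name: (int(lo), 95 if hi == float("inf") else int(hi)) for name, lo, hi in AGE_BANDS}


def _reference_margins() -> dict[str, dict[str, float]]:
    """Pooled non-missing facet distributions from the shipped reference
    demographics (male-dominated, mostly North American, etc.)."""
    from .reference import load_demographics_reference

    df = load_demographics_reference()
    drugs = [c for c in df.columns if c not in ("facet", "level")]
    margins: dict[str, dict[str, float]] = {}
    for facet in ("sex", "age", "region", "outcome", "indication", "year"):
        sub = df[(df["facet"] == facet) & (df["level"] != "Missing")]
        counts = {row["level"]: float(sum(row[d] for d in drugs)) for _, row in sub.iterrows()}
        total = sum(counts.values())
        margins[facet] = {k: v / total for k, v in counts.items()}
    return margins


def _reference_missingness() -> dict[str, float]:
    from .reference import load_demographics_reference

    df = load_demographics_reference()
    drugs = [c for c in df.columns if c not in ("facet", "level")]
    out: dict[str, float] = {}
    for facet, fieldname in (
        ("age", "age_years"), ("sex", "sex"), ("region", "country"),
        ("outcome", "outcomes"), ("indication", "indications"),
    ):
        sub = df[df["facet"] == facet]
        total = float(sum(sub[d].sum() for d in drugs))
        miss = float(sum(sub[sub["level"] == "Missing"][d].sum() for d in drugs))
        out[fieldname] = miss / total
    out["event_date"] = 0.05
    return out


class ConfigError(ValueError):
    """An infeasible generator configuration (e.g. rate > 1)."""


@dataclass
class SyntheticConfig:
    """Generative parameters; ``seed`` fully determines the output."""

    seed: int = 0
    n_background: int = 50_000
    n_cases: Mapping[str, int] = dfield(default_factory=lambda: dict(DEFAULT_TARGET_CASES))
    pt_baseline: Mapping[str, float] = dfield(default_factory=lambda: dict(DEFAULT_PT_BASELINE))
    rr_multiplier: Mapping[tuple[str, str], float] = dfield(default_factory=dict)
    margins: Optional[Mapping[str, Mapping[str, float]]] = None
    missingness: Optional[Mapping[str, float]] = None
    duplicate_rate: float = 0.05
    adr_prob: float = 0.637

    def multiplier(self, drug: str, pt: str) -> float:
        return float(self.rr_multiplier.get((drug, pt), 1.0))

    def validate(self) -> None:
        for pt, p in self.pt_baseline.items():
            if not (0 <= p <= 1):
                raise ConfigError(f"baseline for {pt!r} outside [0, 1]")
        for (drug, pt), m in self.rr_multiplier.items():
            if m < 0:
                raise ConfigError(f"multiplier for ({drug}, {pt}) negative")
            if pt not in self.pt_baseline:
                raise ConfigError(f"multiplier refers to unknown PT {pt!r}")
            if m * self.pt_baseline[pt] > 1:
                raise ConfigError(f"rate for ({drug}, {pt}) exceeds 1")
        if not (0 <= self.duplicate_rate < 1):
            raise ConfigError("duplicate_rate must be in [0, 1)")
        if not (0 <= self.adr_prob <= 1):
            raise ConfigError("adr_prob must be in [0, 1]")
        for f, p in (self.missingness or {}).items():
            if not (0 <= p <= 1):
                raise ConfigError(f"missingness for {f!r} outside [0, 1]")

    def run_id(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "n_background": self.n_background,
                "n_cases": dict(sorted(self.n_cases.items())),
                "pt_baseline": dict(sorted(self.pt_baseline.items())),
                "rr_multiplier": sorted(
                    (f"{d}|{p}", m) for (d, p), m in self.rr_multiplier.items()
                ),
                "duplicate_rate": self.duplicate_rate,
                "adr_prob": self.adr_prob,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    """Generation-time bookkeeping for recovery checks."""

    run_id: str
    cells: dict[tuple[str, str], tuple[int, int, int, int]]
    multipliers: dict[tuple[str, str], float]
    duplicate_groups: dict[str, list[str]]  # original case_id → clone ids
    worst_outcomes: dict[str, str]          # case_id → outcome label pre-missingness

    def to_json(self, path: str | Path) -> None:
        payload = {
            "run_id": self.run_id,
            "cells": {f"{d}|{p}": list(v) for (d, p), v in sorted(self.cells.items())},
            "multipliers": {f"{d}|{p}": m for (d, p), m in sorted(self.multipliers.items())},
            "duplicate_groups": self.duplicate_groups,
            "worst_outcomes": self.worst_outcomes,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _sample_demographics(n: int, margins, rng: np.random.Generator) -> dict[str, list]:
    out: dict[str, list] = {}
    sex_levels = list(margins["sex"])
    sex_probs = np.array([margins["sex"][lv] for lv in sex_levels])
    out["sex"] = [
        {"Females": Sex.FEMALE, "Males": Sex.MALE}[sex_levels[i]]
        for i in rng.choice(len(sex_levels), size=n, p=sex_probs / sex_probs.sum())
    ]
    age_levels = list(margins["age"])
    age_probs = np.array([margins["age"][lv] for lv in age_levels])
    band_idx = rng.choice(len(age_levels), size=n, p=age_probs / age_probs.sum())
    lows = np.array([_AGE_SAMPLING[age_levels[i]][0] for i in band_idx])
    highs = np.array([_AGE_SAMPLING[age_levels[i]][1] for i in band_idx])
    out["age"] = rng.integers(lows, highs + 1).astype(float).tolist()
    region_levels = list(margins["region"])
    region_probs = np.array([margins["region"][lv] for lv in region_levels])
    region_idx = rng.choice(len(region_levels), size=n, p=region_probs / region_probs.sum())
    countries = np.empty(n, dtype=object)
    for r, level in enumerate(region_levels):
        mask = region_idx == r
        pool = _REGION_COUNTRIES[level]
        countries[mask] = rng.choice(pool, size=int(mask.sum()))
    out["country"] = countries.tolist()
    outc_levels = list(margins["outcome"])
    outc_probs = np.array([margins["outcome"][lv] for lv in outc_levels])
    out["outcomes"] = [
        _OUTCOME_SETS[outc_levels[i]]
        for i in rng.choice(len(outc_levels), size=n, p=outc_probs / outc_probs.sum())
    ]
    ind_levels = list(margins["indication"])
    ind_probs = np.array([margins["indication"][lv] for lv in ind_levels])
    out["indication"] = [
        _INDICATION_TEXT[ind_levels[i]]
        for i in rng.choice(len(ind_levels), size=n, p=ind_probs / ind_probs.sum())
    ]
    year_levels = list(margins["year"])
    year_probs = np.array([margins["year"][lv] for lv in year_levels])
    year_idx = rng.choice(len(year_levels), size=n, p=year_probs / year_probs.sum())
    years = []
    for i in year_idx:
        level = year_levels[i]
        if "-" in level:
            lo, hi = (int(x) for x in level.split("-"))
            years.append((lo, hi))
        else:
            years.append((int(level), int(level)))
    year_lo = np.array([y[0] for y in years])
    year_hi = np.array([y[1] for y in years])
    chosen_years = rng.integers(year_lo, year_hi + 1)
    day_offset = rng.integers(0, 365, size=n)
    lag = rng.integers(0, 181, size=n)
    report_dates, event_dates = [], []
    for y, off, lg in zip(chosen_years.tolist(), day_offset.tolist(), lag.tolist()):
        rd = _dt.date(int(y), 1, 1) + _dt.timedelta(days=int(off) % 365)
        report_dates.append(rd)
        event_dates.append(rd - _dt.timedelta(days=int(lg)))
    out["report_date"] = report_dates
    out["event_date"] = event_dates
    return out


def _draw_pt_sets(
    n: int, pts: Sequence[str], probs: np.ndarray, rng: np.random.Generator
) -> list[list[str]]:
    hits = rng.random((n, len(pts))) < probs[None, :]
    sets: list[list[str]] = [[] for _ in range(n)]
    for j, pt in enumerate(pts):
        for i in np.nonzero(hits[:, j])[0]:
            sets[i].append(pt)
    return sets


def generate(config: SyntheticConfig) -> tuple[list[ICSRRecord], GroundTruth]:
    """Generate the record stream and its ground truth.

    Order of operations: base cases (background then targets) → duplicate
    injection → ground-truth counting → missingness. Ground-truth cell
    counts therefore agree exactly with a cohort built from the output when
    missingness is zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    margins = config.margins or _reference_margins()
    missingness = dict(config.missingness if config.missingness is not None else _reference_missingness())

    pts = sorted(config.pt_baseline)
    baseline = np.array([config.pt_baseline[pt] for pt in pts])

    cases: list[dict] = []  # mutable pre-records

    def _add_cases(drug: str, n: int, probs: np.ndarray, prefix: str) -> None:
        if n == 0:
            return
        demo = _sample_demographics(n, margins, rng)
        pt_sets = _draw_pt_sets(n, pts, probs, rng)
        fillers = rng.choice(FILLER_PTS, size=n)
        is_background = drug == ""
        drug_names = (
            rng.choice(BACKGROUND_DRUGS, size=n) if is_background else np.array([drug] * n)
        )
        adr_draw = rng.random(n)
        for i in range(n):
            reactions = pt_sets[i] + [str(fillers[i])]
            psychiatric = bool(pt_sets[i])
            flag = AdrFlag.YES if (psychiatric and adr_draw[i] < config.adr_prob) else AdrFlag.NO
            cases.append(
                {
                    "case_id": f"{prefix}{i:06d}",
                    "report_date": demo["report_date"][i],
                    "event_date": demo["event_date"][i],
                    "age_years": demo["age"][i],
                    "sex": demo["sex"][i],
                    "country": demo["country"][i],
                    "drugs": ((str(drug_names[i]), DrugRole.PRIMARY_SUSPECT),),
                    "reactions": tuple(reactions),
                    "indications": (demo["indication"][i],),
                    "outcomes": demo["outcomes"][i],
                    "adr_flag": flag,
                }
            )

    _add_cases("", config.n_background, baseline, "bg-")
    for drug in sorted(config.n_cases):
        mult = np.array([config.multiplier(drug, pt) for pt in pts])
        _add_cases(drug, int(config.n_cases[drug]), baseline * mult, f"{drug[:3]}-")

    # duplicate injection: clone a case, re-draw exactly one key field so the
    # clone matches its original on exactly 3 of the 4 dedup key fields
    duplicate_groups: dict[str, list[str]] = {}
    if config.duplicate_rate > 0:
        n_dup = int(round(config.duplicate_rate * len(cases) / (1 - config.duplicate_rate)))
        eligible = [i for i, c in enumerate(cases) if c["event_date"] is not None]
        n_dup = min(n_dup, len(eligible))
        chosen = rng.choice(len(eligible), size=n_dup, replace=False)
        clones = []
        for k in sorted(chosen.tolist()):
            orig = cases[eligible[k]]
            clone = dict(orig)
            clone["case_id"] = orig["case_id"] + "-dup"
            which = int(rng.integers(0, 4))
            if which == 0:
                clone["event_date"] = orig["event_date"] + _dt.timedelta(days=int(rng.integers(1, 31)))
            elif which == 1:
                delta = int(rng.integers(1, 11))
                new_age = (orig["age_years"] or 50) + delta
                clone["age_years"] = float(new_age if new_age <= 100 else (orig["age_years"] - delta))
            elif which == 2:
                clone["sex"] = Sex.MALE if orig["sex"] is Sex.FEMALE else Sex.FEMALE
            else:
                pool = [c for cs in _REGION_COUNTRIES.values() for c in cs if c != orig["country"]]
                clone["country"] = str(pool[int(rng.integers(0, len(pool)))])
            clones.append(clone)
            duplicate_groups[orig["case_id"]] = [clone["case_id"]]
        cases.extend(clones)

    # ground truth from the full pre-missingness stream
    target_drugs = sorted(config.n_cases)
    universe = len(cases)
    drug_of = [c["drugs"][0][0] for c in cases]
    cells: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    multipliers: dict[tuple[str, str], float] = {}
    pt_masks = {pt: np.array([pt in c["reactions"] for c in cases]) for pt in pts}
    for drug in target_drugs:
        drug_mask = np.array([d == drug for d in drug_of])
        n_drug = int(drug_mask.sum())
        for pt in pts:
            pt_mask = pt_masks[pt]
            a = int((drug_mask & pt_mask).sum())
            b = n_drug - a
            c_ = int(pt_mask.sum()) - a
            d_ = universe - a - b - c_
            cells[(drug, pt)] = (a, b, c_, d_)
            multipliers[(drug, pt)] = config.multiplier(drug, pt)
    worst = {
        c["case_id"]: (worst_outcome(c["outcomes"]).value if c["outcomes"] else "missing")
        for c in cases
    }
    truth = GroundTruth(
        run_id=config.run_id(),
        cells=cells,
        multipliers=multipliers,
        duplicate_groups=duplicate_groups,
        worst_outcomes=worst,
    )

    # field-level missingness, applied last
    for fieldname, rate in missingness.items():
        if rate <= 0:
            continue
        mask = rng.random(len(cases)) < rate
        for i in np.nonzero(mask)[0]:
            if fieldname == "sex":
                cases[i]["sex"] = Sex.MISSING
            elif fieldname == "outcomes":
                cases[i]["outcomes"] = frozenset()
            elif fieldname == "indications":
                cases[i]["indications"] = ()
            else:
                cases[i][fieldname] = None

    records = [
        ICSRRecord(
            case_id=c["case_id"],
            report_date=c["report_date"],
            event_date=c["event_date"],
            age_years=c["age_years"],
            sex=c["sex"],
            country=c["country"],
            drugs=c["drugs"],
            reactions=c["reactions"],
            indications=c["indications"],
            outcomes=frozenset(c["outcomes"]),
            adr_flag=c["adr_flag"],
        )
        for c in cases
    ]
    return records, truth


@dataclass
class RecoveryRow:
    drug: str
    pt: str
    true_rr: float
    n: int
    ror: float
    prr: float
    ebgm: float
    signal: bool


@dataclass
class RecoveryReport:
    """True vs. estimated relative reporting rates and flag correctness."""

    rows: list[RecoveryRow]

    @property
    def null_rows(self) -> list[RecoveryRow]:
        return [r for r in self.rows if r.true_rr == 1.0]

    @property
    def elevated_rows(self) -> list[RecoveryRow]:
        return [r for r in self.rows if r.true_rr > 1.0]

    @property
    def false_signal_rate(self) -> float:
        null = self.null_rows
        if not null:
            return float("nan")
        return sum(r.signal for r in null) / len(null)

    @property
    def sensitivity(self) -> float:
        elevated = self.elevated_rows
        if not elevated:
            return float("nan")
        return sum(r.signal for r in elevated) / len(elevated)


def truth_vs_estimate(
    truth: GroundTruth,
    results: Sequence[SignalResult],
    run_id: Optional[str] = None,
) -> RecoveryReport:
    """Join scan results onto generation-time truth, per (drug, PT) cell.

    ``run_id`` (when given) must match the truth's run id — a guard against
    comparing artifacts from different runs.
    """
    if run_id is not None and run_id != truth.run_id:
        raise ValueError(f"run id mismatch: truth {truth.run_id}, results {run_id}")
    by_cell = {(r.drug, r.pt): r for r in results if r.pt != TOTAL_LABEL}
    rows = []
    for (drug, pt), mult in sorted(truth.multipliers.items()):
        res = by_cell.get((drug, pt))
        if res is None:
            continue
        rows.append(
            RecoveryRow(
                drug=drug, pt=pt, true_rr=mult, n=res.n,
                ror=res.ror, prr=res.prr, ebgm=res.ebgm, signal=res.signal,
            )
        )
    return RecoveryReport(rows=rows)
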