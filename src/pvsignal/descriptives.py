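"""Descriptive summaries of a cohort: sex, age bands, reporter region,
worst-outcome classification, indication groups and report-year bins.

Every facet is tabulated per target drug (and pooled) as count + percent of
the drug's cohort size, so each column of every facet sums to the cohort
size and every percentage is recomputable from the emitted counts.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cohort import CohortIndex
from .records import ICSRRecord, Outcome, Sex

logger = logging.getLogger("pvsignal")

#: Severity ranking used for worst-outcome classification, most severe first.
#: Death is ranked highest ("the most serious" outcome); a report listing
#: several outcome codes is classified by the most severe one.
SEVERITY_ORDER: tuple[Outcome, ...] = (
    Outcome.DEATH,
    Outcome.LIFE_THREATENING,
    Outcome.DISABILITY,
    Outcome.HOSPITALIZATION,
    Outcome.CONGENITAL_ANOMALY,
    Outcome.OTHER,
)

_SEVERITY_RANK = {o: i for i, o in enumerate(SEVERITY_ORDER)}

MISSING = "Missing"

#: Outcome facet levels as reported; congenital-anomaly and other-coded
#: worst outcomes are tabulated under Missing (no dedicated row).
OUTCOME_LEVELS = ["Death", "Disability", "Hospitalization", "Life-Threatening", MISSING]
_OUTCOME_LABEL = {
    Outcome.DEATH: "Death",
    Outcome.DISABILITY: "Disability",
    Outcome.HOSPITALIZATION: "Hospitalization",
    Outcome.LIFE_THREATENING: "Life-Threatening",
}

SEX_LEVELS = ["Females", "Males", MISSING]

#: Age bands, closed on both ends; reports below the adult range get their
#: own "<18" band rather than being merged into 18-29.
AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<18", 0, 17),
    ("18-29", 18, 29),
    ("30-49", 30, 49),
    ("50-64", 50, 64),
    ("65-74", 65, 74),
    ("75-84", 75, 84),
    (">=85", 85, float("inf")),
)
AGE_LEVELS = [name for name, _, _ in AGE_BANDS] + [MISSING]

REGION_LEVELS = ["North America", "South America", "Europe", "Asia", "Other", MISSING]

INDICATION_LEVELS = [
    "Renal cancer",
    "Hepatic cancer",
    "Neoplasm malignant",
    "Gastrointestinal stromal",
    "Thyroid cancer",
    "Lung neoplasm malignant",
    "Pancreatic carcinoma",
    "Other",
    MISSING,
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.5 % → 2.50, .005 rounds away from zero)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def worst_outcome(outcomes: Sequence[Outcome] | frozenset[Outcome]) -> Optional[Outcome]:
    """The most severe outcome of a report, or None for an empty set.

    When a single report carries several outcome codes it is classified by
    the most severe; invariant to ordering and duplicates.
    """
    members = set(outcomes)
    if not members:
        return None
    return min(members, key=_SEVERITY_RANK.__getitem__)


def age_band(age_years: Optional[float]) -> str:
    """Band label for an age; missing → "Missing"."""
    if age_years is None:
        return MISSING
    for name, lo, hi in AGE_BANDS:
        if lo <= age_years <= hi:
            return name
    return MISSING


def load_region_map(path: str | Path) -> dict[str, str]:
    """Two-column ``country<TAB>region`` table mapping ISO 3166-1 alpha-2
    codes to the reporting regions."""
    table: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:2] != ["country", "region"]:
            raise ValueError("region map must have header 'country\\tregion'")
        for line in fh:
            if line.strip():
                country, region = line.rstrip("\r\n").split("\t")[:2]
                table[country.strip().upper()] = region.strip()
    return table


def default_region_map() -> dict[str, str]:
    from .reference import packaged_path

    return load_region_map(packaged_path("country_region.tsv"))


def region_of(country: Optional[str], region_map: Optional[Mapping[str, str]] = None) -> str:
    """Continent-level reporting region; countries outside the tabulated
    regions (Oceania, Africa) map to "Other", unknown/missing to "Missing"."""
    if country is None:
        return MISSING
    if region_map is None:
        region_map = default_region_map()
    return region_map.get(country.upper(), MISSING)


# keyword → group, checked in order; first match wins
_INDICATION_RULES: tuple[tuple[str, str], ...] = (
    ("renal", "Renal cancer"),
    ("hepat", "Hepatic cancer"),
    ("liver", "Hepatic cancer"),
    ("thyroid", "Thyroid cancer"),
    ("gist", "Gastrointestinal stromal"),
    ("gastrointestinal stromal", "Gastrointestinal stromal"),
    ("lung", "Lung neoplasm malignant"),
    ("pancrea", "Pancreatic carcinoma"),
    ("neoplasm malignant", "Neoplasm malignant"),
)


def indication_group(raw: Optional[str]) -> str:
    """Keyword-based grouping of free-text indications into the reported
    categories; unmatched → "Other", empty → "Missing"."""
    if raw is None or not raw.strip():
        return MISSING
    text = " ".join(raw.casefold().split())
    for keyword, group in _INDICATION_RULES:
        if keyword in text:
            return group
    return "Other"


@dataclass
class DemographicsSummary:
    """Per-drug facet counts plus pooled column and year-bin labels."""

    drugs: list[str]
    cohort_sizes: dict[str, int]
    facets: dict[str, dict[str, Counter]]  # facet → drug → level counts
    year_levels: list[str]

    POOLED = "All"

    def counts(self, facet: str, drug: str) -> Counter:
        return self.facets[facet][drug]

    def percent(self, facet: str, drug: str, level: str, ndigits: int = 2) -> Optional[float]:
        """count/cohort-size·100, half-up rounded; None for an empty cohort."""
        size = self.cohort_sizes[drug]
        if size == 0:
            return None
        return round_half_up(100.0 * self.facets[facet][drug][level] / size, ndigits)

    def facet_levels(self, facet: str) -> list[str]:
        if facet == "sex":
            return SEX_LEVELS
        if facet == "age":
            return AGE_LEVELS
        if facet == "region":
            return REGION_LEVELS
        if facet == "outcome":
            return OUTCOME_LEVELS
        if facet == "indication":
            return INDICATION_LEVELS
        if facet == "year":
            return self.year_levels
        raise KeyError(facet)

    def to_frame(self, facet: str) -> pd.DataFrame:
        """One facet as a tidy table: level, then count/percent per drug."""
        levels = self.facet_levels(facet)
        data: dict[str, list] = {"level": levels}
        for drug in self.drugs + [self.POOLED]:
            counts = self.facets[facet][drug]
            data[f"{drug}_n"] = [counts[lv] for lv in levels]
            data[f"{drug}_pct"] = [
                "—" if self.cohort_sizes[drug] == 0 else f"{self.percent(facet, drug, lv):.2f}"
                for lv in levels
            ]
        return pd.DataFrame(data)

    def write_tables(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for facet in ("sex", "age", "region", "outcome", "indication", "year"):
            path = outdir / f"{facet}.tsv"
            self.to_frame(facet).to_csv(path, sep="\t", index=False)
            written.append(path)
        return written


def _year_bins(year_window: tuple[int, int], pooled_until: int) -> list[str]:
    start, end = year_window
    levels = [f"{start}-{pooled_until}"]
    levels += [str(y) for y in range(pooled_until + 1, end + 1)]
    return levels + [MISSING]


def _year_level(
    report_year: Optional[int], year_window: tuple[int, int], pooled_until: int
) -> str:
    if report_year is None:
        return MISSING
    start, end = year_window
    if report_year < start or report_year > end:
        logger.warning("report year %d outside window %d-%d", report_year, start, end)
        return MISSING
    if report_year <= pooled_until:
        return f"{start}-{pooled_until}"
    return str(report_year)


def summarize(
    index: CohortIndex,
    records: Sequence[ICSRRecord],
    region_map: Optional[Mapping[str, str]] = None,
    year_window: tuple[int, int] = (2006, 2022),
    pooled_until: int = 2012,
) -> DemographicsSummary:
    """Tabulate every facet for each target drug's cohort cases and pooled.

    A case is attributed to a drug when it contributes to any of that drug's
    cohort cells; a case suspecting two target drugs appears in both columns
    but once in the pooled column. Early report years are pooled into one
    ``start–pooled_until`` bin, later years are single bins.
    """
    if region_map is None:
        region_map = default_region_map()
    by_id = {rec.case_id: rec for rec in records}
    drugs = sorted(index.drug_cases)
    year_levels = _year_bins(year_window, pooled_until)
    summary = DemographicsSummary(
        drugs=drugs,
        cohort_sizes={},
        facets={f: {} for f in ("sex", "age", "region", "outcome", "indication", "year")},
        year_levels=year_levels,
    )

    pooled_cases: set[str] = set()
    for drug in drugs:
        pooled_cases |= index.cohort_cases(drug)
    columns = {drug: index.cohort_cases(drug) for drug in drugs}
    columns[DemographicsSummary.POOLED] = pooled_cases

    for column, case_ids in columns.items():
        counters = {f: Counter({lv: 0 for lv in summary.facet_levels(f) if f != "year"})
                    for f in summary.facets}
        counters["year"] = Counter({lv: 0 for lv in year_levels})
        for case_id in sorted(case_ids):
            rec = by_id[case_id]
            counters["sex"][
                {Sex.FEMALE: "Females", Sex.MALE: "Males", Sex.MISSING: MISSING}[rec.sex]
            ] += 1
            counters["age"][age_band(rec.age_years)] += 1
            counters["region"][region_of(rec.country, region_map)] += 1
            worst = worst_outcome(rec.outcomes)
            counters["outcome"][_OUTCOME_LABEL.get(worst, MISSING)] += 1
            first_ind = rec.indications[0] if rec.indications else None
            counters["indication"][indication_group(first_ind)] += 1
            year = rec.report_date.year if rec.report_date else None
            counters["year"][_year_level(year, year_window, pooled_until)] += 1
        summary.cohort_sizes[column] = len(case_ids)
        for facet, counter in counters.items():
            summary.facets[facet][column] = counter
    return summary
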