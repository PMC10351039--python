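"""Shipped reference tables and deterministic fixture expansion.

Two small reference tables travel with the package:

* ``reference_signal_rows.tsv`` — a published set of disproportionality
  statistics (per drug–PT pair and pooled rows) for five multikinase
  inhibitors against psychiatric preferred terms. Raw contingency counts
  are not published, so these rows are used to replay and cross-check the
  interval conventions (deriving the Wald SE from each ROR/ROR05 pair) and
  the criterion decisions, never as inputs to the estimators.
* ``reference_demographics.tsv`` — the matching per-drug demographic facet
  counts (sex, age bands, reporter region, worst outcome, indication group,
  report-year bins). :func:`expand_demographics` turns these marginal
  counts into a synthetic cohort of individual case records so that the
  descriptive machinery can re-aggregate them from scratch.
"""
from __future__ import annotations

import datetime as _dt
import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .records import AdrFlag, DrugRole, ICSRRecord, Outcome, Sex

logger = logging.getLogger("pvsignal")


def packaged_path(name: str) -> Path:
    """Filesystem path of a data file shipped inside the package."""
    return Path(resources.files("pvsignal") / "data" / name)


def load_signal_reference() -> pd.DataFrame:
    """Published signal statistics; columns drug, pt, n, ror, ror05, prr,
    chi2, ic, ic025, ebgm, ebgm05."""
    return pd.read_csv(packaged_path("reference_signal_rows.tsv"), sep="\t")


def load_demographics_reference() -> pd.DataFrame:
    """Published per-drug demographic counts; columns facet, level, then one
    count column per drug."""
    return pd.read_csv(packaged_path("reference_demographics.tsv"), sep="\t")


# representative concrete values used when expanding marginal counts into
# individual synthetic records
_AGE_REPRESENTATIVE = {
    "<18": 15, "18-29": 25, "30-49": 40, "50-64": 60,
    "65-74": 70, "75-84": 80, ">=85": 88, "Missing": None,
}
_REGION_REPRESENTATIVE = {
    "North America": "US", "South America": "BR", "Europe": "DE",
    "Asia": "JP", "Other": "AU", "Missing": None,
}
_SEX_REPRESENTATIVE = {"Females": Sex.FEMALE, "Males": Sex.MALE, "Missing": Sex.MISSING}
_OUTCOME_REPRESENTATIVE = {
    "Death": frozenset({Outcome.DEATH}),
    "Disability": frozenset({Outcome.DISABILITY}),
    "Hospitalization": frozenset({Outcome.HOSPITALIZATION}),
    "Life-Threatening": frozenset({Outcome.LIFE_THREATENING}),
    "Missing": frozenset(),
}
_INDICATION_REPRESENTATIVE = {
    "Renal cancer": "renal cell carcinoma",
    "Hepatic cancer": "hepatocellular carcinoma",
    "Neoplasm malignant": "neoplasm malignant",
    "Gastrointestinal stromal": "gastrointestinal stromal tumour",
    "Thyroid cancer": "thyroid cancer",
    "Lung neoplasm malignant": "lung neoplasm malignant",
    "Pancreatic carcinoma": "pancreatic carcinoma",
    "Other": "melanoma",
    "Missing": None,
}


def _year_representative(level: str) -> int:
    if "-" in level:  # pooled early bin: use its first year
        return int(level.split("-")[0])
    return int(level)


def _facet_sequence(df: pd.DataFrame, facet: str, drug: str, n: int) -> list[str]:
    """Level labels for ``n`` cases, following the marginal counts in order.

    An over-long facet column (a source-table inconsistency) is truncated at
    ``n`` with a warning; a short one is padded with "Missing".
    """
    sub = df[df["facet"] == facet]
    seq: list[str] = []
    for _, row in sub.iterrows():
        seq.extend([row["level"]] * int(row[drug]))
    if len(seq) > n:
        logger.warning(
            "facet %s for %s sums to %d > cohort size %d; truncating", facet, drug, len(seq), n
        )
        seq = seq[:n]
    elif len(seq) < n:
        seq.extend(["Missing"] * (n - len(seq)))
    return seq


def expand_demographics(
    df: pd.DataFrame | None = None,
    pt: str = "confusional state",
) -> list[ICSRRecord]:
    """Deterministically expand marginal facet counts into one synthetic
    record per cohort case.

    Each drug column becomes ``N`` cases (primary-suspect target drug, one
    psychiatric PT, ADR-flagged); within each facet the level sequence
    follows the marginal counts, with facets assigned independently — the
    joint distribution is synthetic, only the margins are meaningful.
    """
    if df is None:
        df = load_demographics_reference()
    drugs = [c for c in df.columns if c not in ("facet", "level")]
    sizes = {d: int(df[df["facet"] == "sex"][d].sum()) for d in drugs}
    records: list[ICSRRecord] = []
    for drug in drugs:
        n = sizes[drug]
        seqs = {
            facet: _facet_sequence(df, facet, drug, n)
            for facet in ("sex", "age", "region", "outcome", "indication", "year")
        }
        for i in range(n):
            year_level = seqs["year"][i]
            year = None if year_level == "Missing" else _year_representative(year_level)
            ind = _INDICATION_REPRESENTATIVE[seqs["indication"][i]]
            records.append(
                ICSRRecord(
                    case_id=f"{drug}-{i:04d}",
                    report_date=_dt.date(year, 6, 15) if year else None,
                    event_date=_dt.date(year, 5, 15) if year else None,
                    age_years=_AGE_REPRESENTATIVE[seqs["age"][i]],
                    sex=_SEX_REPRESENTATIVE[seqs["sex"][i]],
                    country=_REGION_REPRESENTATIVE[seqs["region"][i]],
                    drugs=((drug, DrugRole.PRIMARY_SUSPECT),),
                    reactions=(pt,),
                    indications=(ind,) if ind else (),
                    outcomes=_OUTCOME_REPRESENTATIVE[seqs["outcome"][i]],
                    adr_flag=AdrFlag.YES,
                )
            )
    return records
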