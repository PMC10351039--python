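"""Readers and writers for the flat ICSR table dialects.

Two dialects of the same column contract are supported:

* ``case_per_row`` — one row per case; multi-valued fields (drugs, reactions,
  indications, outcomes) are ";"-separated within their column.
* ``reaction_per_row`` — one row per (case, reaction); rows sharing a
  ``case_id`` are merged into one record.

Columns (UTF-8, tab- or comma-delimited, auto-detected from the header):
``case_id, report_date, event_date, age_years, sex, country, drug_name,
drug_role, reactions, indications, outcomes, adr_flag``.

Dates are ISO 8601 (YYYY-MM-DD) or compact YYYYMMDD; anything else becomes
missing with a logged warning — a malformed value never drops a record.
Outcome codes are the FAERS-style DE/LT/HO/DS/CA/OT; drug roles PS/SS/C/I;
sex F/M; adr_flag Y/N.
"""
from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .records import (
    AdrFlag,
    DrugRole,
    ICSRRecord,
    MedDRAMap,
    Outcome,
    Sex,
    normalize_drug_name,
    normalize_text,
)

logger = logging.getLogger("pvsignal")

COLUMNS = [
    "case_id",
    "report_date",
    "event_date",
    "age_years",
    "sex",
    "country",
    "drug_name",
    "drug_role",
    "reactions",
    "indications",
    "outcomes",
    "adr_flag",
]

_ROLE_CODES = {
    "ps": DrugRole.PRIMARY_SUSPECT,
    "ss": DrugRole.SECONDARY_SUSPECT,
    "c": DrugRole.CONCOMITANT,
    "i": DrugRole.INTERACTING,
}
_ROLE_TO_CODE = {v: k.upper() for k, v in _ROLE_CODES.items()}

_OUTCOME_CODES = {
    "de": Outcome.DEATH,
    "lt": Outcome.LIFE_THREATENING,
    "ho": Outcome.HOSPITALIZATION,
    "ds": Outcome.DISABILITY,
    "ca": Outcome.CONGENITAL_ANOMALY,
    "ot": Outcome.OTHER,
}
_OUTCOME_TO_CODE = {v: k.upper() for k, v in _OUTCOME_CODES.items()}

_SEX_CODES = {"f": Sex.FEMALE, "female": Sex.FEMALE, "m": Sex.MALE, "male": Sex.MALE}


@dataclass
class IngestionReport:
    """Field-level accounting for one file read."""

    n_rows: int = 0
    n_cases: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


class SchemaError(ValueError):
    """The input file is missing a mandatory column."""


def parse_date(raw: str) -> Optional[_dt.date]:
    raw = raw.strip()
    if not raw:
        return None
    for fmt in ("%Y-%m-%d", "%Y%m%d"):
        try:
            return _dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    return None


def _parse_age(raw: str) -> Optional[float]:
    raw = raw.strip()
    if not raw:
        return None
    try:
        age = float(raw)
    except ValueError:
        return None
    if not (0 <= age <= 150):
        return None
    return age


def _split_multi(raw: str) -> list[str]:
    return [part.strip() for part in raw.split(";") if part.strip()]


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_icsr_table(
    path: str | Path,
    dialect: str = "case_per_row",
    synonyms: Optional[Mapping[str, str]] = None,
) -> tuple[list[ICSRRecord], IngestionReport]:
    """Read an ICSR table into validated records.

    Returns ``(records, report)``: one record per distinct case_id (in first-
    appearance order) and an :class:`IngestionReport` counting rows, cases and
    field-level warnings. A value that fails validation is set to missing and
    warned about, never silently dropped; a missing mandatory column is a hard
    :class:`SchemaError`.
    """
    if dialect not in ("case_per_row", "reaction_per_row"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    report = IngestionReport()
    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            return [], report
        delim = _detect_delimiter(header_line)
        header = [h.strip() for h in header_line.rstrip("\r\n").split(delim)]
        missing_cols = [c for c in COLUMNS if c not in header]
        if missing_cols:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delim)
        raw_rows = list(reader)

    # Accumulate per-case, merging reaction_per_row rows that share a case_id.
    order: list[str] = []
    acc: dict[str, dict] = {}
    for i, row in enumerate(raw_rows, start=2):
        report.n_rows += 1
        case_id = (row.get("case_id") or "").strip()
        if not case_id:
            report.warn(f"row {i}: empty case_id, row skipped")
            continue
        if case_id not in acc:
            order.append(case_id)
            acc[case_id] = {
                "report_date": None,
                "event_date": None,
                "age_years": None,
                "sex": Sex.MISSING,
                "country": None,
                "drugs": [],
                "reactions": [],
                "indications": [],
                "outcomes": set(),
                "adr_flag": AdrFlag.MISSING,
                "_seen_scalar": False,
            }
        entry = acc[case_id]

        if not entry["_seen_scalar"]:
            entry["_seen_scalar"] = True
            for date_field in ("report_date", "event_date"):
                raw = (row.get(date_field) or "").strip()
                parsed = parse_date(raw)
                if raw and parsed is None:
                    report.warn(f"case {case_id}: unparseable {date_field} {raw!r} set to missing")
                entry[date_field] = parsed
            raw_age = (row.get("age_years") or "").strip()
            age = _parse_age(raw_age)
            if raw_age and age is None:
                report.warn(f"case {case_id}: unparseable age {raw_age!r} set to missing")
            entry["age_years"] = age
            raw_sex = normalize_text(row.get("sex") or "")
            if raw_sex:
                sex = _SEX_CODES.get(raw_sex)
                if sex is None:
                    report.warn(f"case {case_id}: unknown sex code {raw_sex!r} set to missing")
                    sex = Sex.MISSING
                entry["sex"] = sex
            raw_country = (row.get("country") or "").strip().upper()
            if raw_country:
                if len(raw_country) == 2 and raw_country.isalpha():
                    entry["country"] = raw_country
                else:
                    report.warn(f"case {case_id}: invalid country code {raw_country!r} set to missing")
            raw_flag = normalize_text(row.get("adr_flag") or "")
            if raw_flag in ("y", "yes"):
                entry["adr_flag"] = AdrFlag.YES
            elif raw_flag in ("n", "no"):
                entry["adr_flag"] = AdrFlag.NO
            elif raw_flag:
                report.warn(f"case {case_id}: unknown adr_flag {raw_flag!r} set to missing")
            for raw_out in _split_multi(row.get("outcomes") or ""):
                code = _OUTCOME_CODES.get(normalize_text(raw_out))
                if code is None:
                    report.warn(f"case {case_id}: unknown outcome code {raw_out!r} ignored")
                else:
                    entry["outcomes"].add(code)
            for raw_ind in _split_multi(row.get("indications") or ""):
                norm = normalize_text(raw_ind)
                if norm not in entry["indications"]:
                    entry["indications"].append(norm)

        raw_drugs = _split_multi(row.get("drug_name") or "")
        raw_roles = _split_multi(row.get("drug_role") or "")
        for j, raw_drug in enumerate(raw_drugs):
            role_code = normalize_text(raw_roles[j]) if j < len(raw_roles) else ""
            role = _ROLE_CODES.get(role_code)
            if role is None:
                if role_code:
                    report.warn(f"case {case_id}: unknown drug role {role_code!r}, treated as concomitant")
                role = DrugRole.CONCOMITANT
            pair = (normalize_drug_name(raw_drug, synonyms), role)
            if pair not in entry["drugs"]:
                entry["drugs"].append(pair)

        raw_reactions = _split_multi(row.get("reactions") or "")
        if dialect == "reaction_per_row" and len(raw_reactions) > 1:
            report.warn(f"case {case_id}: multiple PTs in one reaction_per_row row")
        for raw_pt in raw_reactions:
            norm = normalize_text(raw_pt)
            if norm not in entry["reactions"]:
                entry["reactions"].append(norm)

    records: list[ICSRRecord] = []
    for case_id in order:
        entry = acc[case_id]
        if not entry["drugs"]:
            report.warn(f"case {case_id}: no valid drug, case dropped")
            continue
        if not entry["reactions"]:
            report.warn(f"case {case_id}: no valid reaction, case dropped")
            continue
        records.append(
            ICSRRecord(
                case_id=case_id,
                report_date=entry["report_date"],
                event_date=entry["event_date"],
                age_years=entry["age_years"],
                sex=entry["sex"],
                country=entry["country"],
                drugs=tuple(entry["drugs"]),
                reactions=tuple(entry["reactions"]),
                indications=tuple(entry["indications"]),
                outcomes=frozenset(entry["outcomes"]),
                adr_flag=entry["adr_flag"],
            )
        )
    report.n_cases = len(records)
    return records, report


def _fmt_date(d: Optional[_dt.date]) -> str:
    return d.isoformat() if d else ""


def _fmt_age(a: Optional[float]) -> str:
    if a is None:
        return ""
    return str(int(a)) if float(a).is_integer() else repr(a)


def _scalar_fields(rec: ICSRRecord) -> dict[str, str]:
    return {
        "case_id": rec.case_id,
        "report_date": _fmt_date(rec.report_date),
        "event_date": _fmt_date(rec.event_date),
        "age_years": _fmt_age(rec.age_years),
        "sex": {"female": "F", "male": "M", "missing": ""}[rec.sex.value],
        "country": rec.country or "",
        "indications": ";".join(rec.indications),
        "outcomes": ";".join(sorted(_OUTCOME_TO_CODE[o] for o in rec.outcomes)),
        "adr_flag": {"yes": "Y", "no": "N", "missing": ""}[rec.adr_flag.value],
    }


def write_icsr_table(
    records: Sequence[ICSRRecord],
    path: str | Path,
    dialect: str = "case_per_row",
    delimiter: str = "\t",
) -> None:
    """Write records in either dialect; reading the file back yields the same
    records (round-trip contract)."""
    if dialect not in ("case_per_row", "reaction_per_row"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS, delimiter=delimiter, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            base = _scalar_fields(rec)
            base["drug_name"] = ";".join(name for name, _ in rec.drugs)
            base["drug_role"] = ";".join(_ROLE_TO_CODE[role] for _, role in rec.drugs)
            if dialect == "case_per_row":
                base["reactions"] = ";".join(rec.reactions)
                writer.writerow(base)
            else:
                for pt in rec.reactions:
                    row = dict(base)
                    row["reactions"] = pt
                    writer.writerow(row)


def read_meddra_map(path: str | Path) -> MedDRAMap:
    """Load a two-column ``pt<TAB>soc`` table into a :class:`MedDRAMap`."""
    entries: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:2] != ["pt", "soc"]:
            raise SchemaError("MedDRA map must have header 'pt\\tsoc'")
        for line in fh:
            if not line.strip():
                continue
            pt, soc = line.rstrip("\r\n").split("\t")[:2]
            entries[pt] = soc
    return MedDRAMap(entries)


def read_synonym_table(path: str | Path) -> dict[str, str]:
    """Load a two-column ``alias<TAB>canonical`` drug synonym table."""
    table: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:2] != ["alias", "canonical"]:
            raise SchemaError("synonym table must have header 'alias\\tcanonical'")
        for line in fh:
            if not line.strip():
                continue
            alias, canonical = line.rstrip("\r\n").split("\t")[:2]
            table[normalize_text(alias)] = normalize_text(canonical)
    return table
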