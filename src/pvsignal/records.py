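"""Domain types for individual case safety reports (ICSRs).

An ICSR is one spontaneous adverse-event report: one patient, one or more
suspect/concomitant drugs, one or more reactions coded as MedDRA Preferred
Terms (PTs), plus demographics, indications, outcome codes and the source
database's ADR yes/no classification.
"""
from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


def normalize_text(raw: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return " ".join(raw.casefold().split())


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    MISSING = "missing"


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class Outcome(str, enum.Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    OTHER = "other"


class AdrFlag(str, enum.Enum):
    YES = "yes"
    NO = "no"
    MISSING = "missing"


class AdrFilter(str, enum.Enum):
    ADR_ONLY = "adr_only"
    NON_ADR_ONLY = "non_adr_only"
    ALL = "all"


class RoleFilter(str, enum.Enum):
    PRIMARY_SUSPECT_ONLY = "primary_suspect_only"
    ANY_SUSPECT = "any_suspect"
    ANY = "any"


def normalize_drug_name(raw: str, synonyms: Optional[Mapping[str, str]] = None) -> str:
    """Normalize a drug name: case-fold, collapse whitespace, then apply an
    optional alias→canonical synonym table (brand → generic). Unknown names
    pass through normalized.

    Raises ValueError on an empty/blank name.
    """
    if raw is None or not raw.strip():
        raise ValueError("drug name must be non-empty")
    name = normalize_text(raw)
    if synonyms:
        name = synonyms.get(name, name)
    return name


@dataclass(frozen=True)
class ICSRRecord:
    """One spontaneous report after ingestion validation.

    ``drugs`` holds (normalized name, role) pairs; ``reactions`` holds unique
    normalized PT strings; ``outcomes`` is the set of outcome codes reported
    for the case. Missing values are ``None`` (dates, age, country) or the
    MISSING enum member (sex, adr_flag).
    """

    case_id: str
    report_date: Optional[_dt.date]
    event_date: Optional[_dt.date]
    age_years: Optional[float]
    sex: Sex
    country: Optional[str]
    drugs: tuple[tuple[str, DrugRole], ...]
    reactions: tuple[str, ...]
    indications: tuple[str, ...] = ()
    outcomes: frozenset[Outcome] = frozenset()
    adr_flag: AdrFlag = AdrFlag.MISSING

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.drugs:
            raise ValueError(f"case {self.case_id}: drugs list must be non-empty")
        if not self.reactions:
            raise ValueError(f"case {self.case_id}: reactions list must be non-empty")
        if self.age_years is not None and not (0 <= self.age_years <= 150):
            raise ValueError(f"case {self.case_id}: age {self.age_years} outside [0, 150]")
        if len({normalize_text(pt) for pt in self.reactions}) != len(self.reactions):
            raise ValueError(f"case {self.case_id}: duplicate PTs after normalization")

    def drug_names(self, role_filter: RoleFilter = RoleFilter.ANY) -> set[str]:
        """Distinct drug names whose role passes ``role_filter``."""
        if role_filter is RoleFilter.PRIMARY_SUSPECT_ONLY:
            allowed = {DrugRole.PRIMARY_SUSPECT}
        elif role_filter is RoleFilter.ANY_SUSPECT:
            allowed = {DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT}
        else:
            allowed = set(DrugRole)
        return {name for name, role in self.drugs if role in allowed}


class MedDRAMap:
    """PT → System Organ Class lookup.

    Each PT maps to exactly one SOC (the multi-axial MedDRA hierarchy is out
    of scope); lookups are case-insensitive after normalization. PTs looked
    up but not found are collected in :attr:`unknown_pts` so a pipeline run
    can report every term it could not classify.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._entries: dict[str, str] = {}
        for pt, soc in entries.items():
            key = normalize_text(pt)
            soc_n = soc.strip()
            if key in self._entries and self._entries[key] != soc_n:
                raise ValueError(f"PT {pt!r} maps to multiple SOCs")
            self._entries[key] = soc_n
        self.unknown_pts: set[str] = set()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return normalize_text(pt) in self._entries

    def get(self, pt: str) -> Optional[str]:
        """SOC for ``pt``, or None for an unknown term (recorded)."""
        soc = self._entries.get(normalize_text(pt))
        if soc is None:
            self.unknown_pts.add(normalize_text(pt))
        return soc

    def pts_in_soc(self, soc: str) -> set[str]:
        return {pt for pt, s in self._entries.items() if s == soc}


def map_pt_to_soc(pt: str, meddra: MedDRAMap) -> Optional[str]:
    """SOC for a PT; None (and a run-log entry in ``meddra.unknown_pts``)
    when the term is not in the map."""
    return meddra.get(pt)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort selection: which drugs, which SOC, ADR split, drug-role scope."""

    target_drugs: frozenset[str]
    soc_filter: str
    adr_filter: AdrFilter = AdrFilter.ALL
    role_filter: RoleFilter = RoleFilter.PRIMARY_SUSPECT_ONLY

    def __post_init__(self) -> None:
        if not self.target_drugs:
            raise ValueError("target_drugs must be non-empty")
        if not self.soc_filter:
            raise ValueError("soc_filter must be non-empty")

    @classmethod
    def create(
        cls,
        target_drugs: Iterable[str],
        soc_filter: str,
        adr_filter: AdrFilter | str = AdrFilter.ALL,
        role_filter: RoleFilter | str = RoleFilter.PRIMARY_SUSPECT_ONLY,
    ) -> "CohortSpec":
        return cls(
            target_drugs=frozenset(normalize_drug_name(d) for d in target_drugs),
            soc_filter=soc_filter.strip(),
            adr_filter=AdrFilter(adr_filter),
            role_filter=RoleFilter(role_filter),
        )
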