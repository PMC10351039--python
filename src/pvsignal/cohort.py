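"""Cohort construction: from deduplicated reports to per-(drug, PT) case sets.

The disproportionality contrast is always "target drug vs. all other drugs"
within a fixed case universe (every deduplicated report in the input), so the
index keeps three layers of bookkeeping:

* ``cells[(drug, pt)]`` — cases reporting the target event under the drug;
* ``drug_cases[drug]`` — all cases where the drug passes the role filter,
  whatever they report (the a+b margin);
* ``event_cases[pt]`` — all cases in the universe reporting the event and
  passing the SOC/ADR filters, any drug (the a+c margin).

A case reporting k cohort PTs contributes one count to each of the k
(drug, PT) cells but only once to the drug margin — the standard PT-level
2×2 convention for spontaneous-report databases.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .records import (
    AdrFilter,
    AdrFlag,
    CohortSpec,
    ICSRRecord,
    MedDRAMap,
)

logger = logging.getLogger("pvsignal")


@dataclass
class CohortIndex:
    """Case-set index backing contingency-table assembly."""

    spec: CohortSpec
    universe_size: int
    cells: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    drug_cases: dict[str, set[str]] = field(default_factory=dict)
    event_cases: dict[str, set[str]] = field(default_factory=dict)
    unknown_pts: frozenset[str] = frozenset()

    def cohort_pts(self, drug: str) -> list[str]:
        """PTs observed for a drug's cohort cells, sorted."""
        return sorted(pt for (d, pt) in self.cells if d == drug and self.cells[(d, pt)])

    def cohort_cases(self, drug: str) -> set[str]:
        """Cases contributing to any of the drug's cohort cells."""
        out: set[str] = set()
        for (d, pt), cases in self.cells.items():
            if d == drug:
                out |= cases
        return out

    def counts(self, drug: str, pt: str) -> tuple[int, int, int, int]:
        """The 2×2 margins (a, b, c, d) for one (drug, event) pair."""
        cell = self.cells.get((drug, pt), set())
        a = len(cell)
        b = len(self.drug_cases.get(drug, set())) - a
        c = len(self.event_cases.get(pt, set())) - a
        d = self.universe_size - a - b - c
        return a, b, c, d

    def pooled_counts(self, drug: str | None = None) -> tuple[int, int, int, int]:
        """Margins with all cohort PTs pooled as one composite event.

        ``drug=None`` pools across every target drug as well (grand total).
        """
        drugs = [drug] if drug is not None else sorted(self.drug_cases)
        pts = sorted({pt for (d, pt) in self.cells if drug is None or d == drug})
        event_union: set[str] = set()
        for pt in pts:
            event_union |= self.event_cases.get(pt, set())
        cell_union: set[str] = set()
        for d in drugs:
            cell_union |= self.cohort_cases(d)
        drug_union: set[str] = set()
        for d in drugs:
            drug_union |= self.drug_cases.get(d, set())
        a = len(cell_union)
        b = len(drug_union) - a
        c = len(event_union) - a
        d_ = self.universe_size - a - b - c
        return a, b, c, d_


def _adr_passes(flag: AdrFlag, adr_filter: AdrFilter) -> bool:
    if adr_filter is AdrFilter.ALL:
        return True
    if adr_filter is AdrFilter.ADR_ONLY:
        return flag is AdrFlag.YES
    # missing flags are treated as non-ADR (and logged by split_adr)
    return flag is not AdrFlag.YES


def build_cohort(
    records: Sequence[ICSRRecord],
    spec: CohortSpec,
    meddra: MedDRAMap,
) -> CohortIndex:
    """Index deduplicated records for the scan defined by ``spec``.

    A record enters cell (drug d, PT p) iff d is a target drug passing the
    role filter, p is among the record's reactions, p maps to the SOC filter,
    and the record's ADR flag passes the ADR filter. The ``event_cases``
    margin applies the same SOC and ADR filters but no drug condition, so the
    comparator column ("all other drugs") is consistent with the cells.
    """
    index = CohortIndex(spec=spec, universe_size=len(records))
    for drug in sorted(spec.target_drugs):
        index.drug_cases[drug] = set()
    seen_targets: set[str] = set()

    for rec in records:
        rec_drugs = rec.drug_names(spec.role_filter)
        rec_targets = rec_drugs & spec.target_drugs
        for d in rec_targets:
            index.drug_cases[d].add(rec.case_id)
        seen_targets |= rec_targets

        if not _adr_passes(rec.adr_flag, spec.adr_filter):
            continue
        for pt in rec.reactions:
            if meddra.get(pt) != spec.soc_filter:
                continue
            index.event_cases.setdefault(pt, set()).add(rec.case_id)
            for d in rec_targets:
                index.cells.setdefault((d, pt), set()).add(rec.case_id)

    for drug in sorted(spec.target_drugs - seen_targets):
        logger.warning("target drug %r never appears in the data; empty cell", drug)
    index.unknown_pts = frozenset(meddra.unknown_pts)
    return index


def split_adr(
    records: Sequence[ICSRRecord],
) -> tuple[list[ICSRRecord], list[ICSRRecord], int]:
    """Partition records by ADR flag.

    Returns ``(adr, non_adr, n_missing_flag)``; reports with a missing flag
    are placed in the non-ADR side and counted (and logged).
    """
    adr: list[ICSRRecord] = []
    non_adr: list[ICSRRecord] = []
    n_missing = 0
    for rec in records:
        if rec.adr_flag is AdrFlag.YES:
            adr.append(rec)
        else:
            if rec.adr_flag is AdrFlag.MISSING:
                n_missing += 1
            non_adr.append(rec)
    if n_missing:
        logger.info("split_adr: %d records with missing ADR flag placed in non-ADR", n_missing)
    return adr, non_adr, n_missing
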