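"""Disproportionality statistics for drug–event 2×2 tables.

For one (drug, event) pair the deduplicated case universe is cross-
classified as

================================  =============  ============
                                  target event   other events
================================  =============  ============
target drug                       a              b
all other drugs                   c              d
================================  =============  ============

with T = a+b+c+d and N = a (the number of co-reports). Four classical
signal-detection statistics are computed, all sharing the Wald log-scale
standard error SE = sqrt(1/a + 1/b + 1/c + 1/d):

* **ROR** (reporting odds ratio) = ad/(bc), 95% CI = ROR·e^(±1.96·SE);
  criterion ROR05 > 1 and N ≥ 2.
* **PRR** (proportional reporting ratio) = [a/(a+b)]/[c/(c+d)] with the
  uncorrected Pearson χ² = (ad−bc)²·T/[(a+b)(c+d)(a+c)(b+d)];
  criterion PRR ≥ 2, χ² ≥ 4 and N ≥ 3.
* **IC** (information component) = log2[a·T/((a+c)(a+b))], the observed/
  expected reporting ratio in bits; the lower bound is the multiplicative
  form IC025 = IC·e^(−1.96·SE), defined for IC > 0; criterion IC025 > 0.
* **EBGM** = a·T/((a+c)(a+b)) — the unshrunk observed/expected (relative
  reporting) ratio, algebraically 2^IC; lower bound EBGM05 =
  EBGM·e^(−z·SE) with z = 1.645 by default (the one-sided 95% bound that
  matches published signal tables; z = 1.96 is available via
  ``ebgm_z``); criterion EBGM05 > 2.

A pair is a **signal** when at least one criterion fires. No Bayesian
shrinkage is applied to IC or EBGM and no multiplicity adjustment is made:
the statistics are the simplified closed forms used in published
spontaneous-report analyses, not the full BCPNN posterior or the
gamma-Poisson shrinker.

Zero cells leave the affected statistics undefined (NaN) and their flags
False by default; the Haldane–Anscombe +0.5 correction to all four cells can
be requested instead (``zero_correction=True``).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cohort import CohortIndex

logger = logging.getLogger("pvsignal")

NAN = float("nan")


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts for one (drug, event) pair."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total <= 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def n(self) -> float:
        """Number of co-occurrence reports (the a cell)."""
        return self.a

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self, delta: float = 0.5) -> "ContingencyTable":
        """Haldane–Anscombe continuity correction: add ``delta`` to all cells."""
        return ContingencyTable(self.a + delta, self.b + delta, self.c + delta, self.d + delta)

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SignalResult:
    """All statistics, bounds and criterion decisions for one pair."""

    drug: str
    pt: str
    n: int
    ror: float
    ror05: float
    ror95: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_flag: bool = False
    prr_flag: bool = False
    ic_flag: bool = False
    ebgm_flag: bool = False
    signal: bool = False


def wald_se(table: ContingencyTable) -> float:
    """Log-scale Wald standard error sqrt(1/a+1/b+1/c+1/d); NaN if any cell
    is zero."""
    if table.has_zero_cell():
        return NAN
    return math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)


def interval_lower(point: float, se: float, z: float) -> float:
    """Multiplicative lower bound point·e^(−z·SE) of a positive statistic."""
    return point * math.exp(-z * se)


def interval_upper(point: float, se: float, z: float) -> float:
    return point * math.exp(z * se)


def derive_wald_se(point: float, lower: float, z: float = 1.96) -> float:
    """Invert the Wald interval: the SE implied by a (point, lower-bound)
    pair, SE = ln(point/lower)/z. Used to replay published rows whose raw
    counts are not printed."""
    return math.log(point / lower) / z


def compute_ror(table: ContingencyTable) -> tuple[float, float, float]:
    """(ROR, ROR05, ROR95); NaN triple when a zero cell makes it undefined."""
    if table.has_zero_cell():
        return NAN, NAN, NAN
    ror = (table.a * table.d) / (table.b * table.c)
    se = wald_se(table)
    return ror, interval_lower(ror, se, 1.96), interval_upper(ror, se, 1.96)


def compute_prr_chi2(table: ContingencyTable) -> tuple[float, float]:
    """(PRR, uncorrected Pearson χ²); PRR is NaN when c = 0 or a+b = 0."""
    a, b, c, d = table.a, table.b, table.c, table.d
    T = table.total
    if a + b == 0 or c + d == 0 or c == 0:
        prr = NAN
    else:
        prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = NAN if denom == 0 else (a * d - b * c) ** 2 * T / denom
    return prr, chi2


def compute_ic(table: ContingencyTable) -> tuple[float, float]:
    """(IC, IC025) in bits; the lower bound is the multiplicative form and is
    only defined for IC > 0 (otherwise NaN, flag False)."""
    a = table.a
    T = table.total
    if a == 0 or (table.a + table.c) == 0 or (table.a + table.b) == 0:
        return NAN, NAN
    ic = math.log2(a * T / ((table.a + table.c) * (table.a + table.b)))
    se = wald_se(table)
    ic025 = interval_lower(ic, se, 1.96) if ic > 0 and not math.isnan(se) else NAN
    return ic, ic025


def compute_ebgm(table: ContingencyTable, z: float = 1.645) -> tuple[float, float]:
    """(EBGM, EBGM05) where EBGM = a·T/((a+c)(a+b)) is the unshrunk
    observed/expected ratio and EBGM05 its multiplicative lower bound with
    multiplier ``z`` (one-sided 95% by default)."""
    a = table.a
    T = table.total
    if a == 0 or (table.a + table.c) == 0 or (table.a + table.b) == 0:
        return NAN, NAN
    ebgm = a * T / ((table.a + table.c) * (table.a + table.b))
    se = wald_se(table)
    ebgm05 = interval_lower(ebgm, se, z) if not math.isnan(se) else NAN
    return ebgm, ebgm05


def _ge(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x >= threshold


def _gt(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x > threshold


def evaluate_criteria(result: SignalResult) -> SignalResult:
    """Apply the four signal criteria; an undefined statistic never fires.

    ROR: ROR05 > 1 and N ≥ 2 · PRR: PRR ≥ 2, χ² ≥ 4 and N ≥ 3 ·
    BCPNN: IC025 > 0 · MGPS: EBGM05 > 2 (any N). A pair is a signal when
    at least one criterion fires.
    """
    ror_flag = _gt(result.ror05, 1.0) and result.n >= 2
    prr_flag = _ge(result.prr, 2.0) and _ge(result.chi2, 4.0) and result.n >= 3
    ic_flag = _gt(result.ic025, 0.0)
    ebgm_flag = _gt(result.ebgm05, 2.0)
    return replace(
        result,
        ror_flag=ror_flag,
        prr_flag=prr_flag,
        ic_flag=ic_flag,
        ebgm_flag=ebgm_flag,
        signal=ror_flag or prr_flag or ic_flag or ebgm_flag,
    )


def analyze_table(
    table: ContingencyTable,
    drug: str = "",
    pt: str = "",
    ebgm_z: float = 1.645,
    zero_correction: bool = False,
) -> SignalResult:
    """All four algorithms plus criteria for one table."""
    work = table
    if zero_correction and table.has_zero_cell():
        work = table.corrected()
        logger.info("zero cell in (%s, %s): Haldane–Anscombe +0.5 applied", drug, pt)
    elif table.has_zero_cell():
        logger.info("zero cell in (%s, %s): affected statistics undefined", drug, pt)
    ror, ror05, ror95 = compute_ror(work)
    prr, chi2 = compute_prr_chi2(work)
    ic, ic025 = compute_ic(work)
    ebgm, ebgm05 = compute_ebgm(work, z=ebgm_z)
    result = SignalResult(
        drug=drug,
        pt=pt,
        n=int(table.a),
        ror=ror,
        ror05=ror05,
        ror95=ror95,
        prr=prr,
        chi2=chi2,
        ic=ic,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
    )
    return evaluate_criteria(result)


TOTAL_LABEL = "Total"


def run_signal_scan(
    index: CohortIndex,
    ebgm_z: float = 1.645,
    zero_correction: bool = False,
    include_grand_total: bool = True,
) -> list[SignalResult]:
    """One result per (drug, PT) cell, a pooled "Total" row per drug, and a
    grand-total row pooling all drugs and cohort PTs.

    Empty cells yield rows with n = 0 and all flags False.
    """
    results: list[SignalResult] = []
    for drug in sorted(index.drug_cases):
        for pt in index.cohort_pts(drug):
            a, b, c, d = index.counts(drug, pt)
            results.append(
                analyze_table(
                    ContingencyTable(a, b, c, d),
                    drug=drug,
                    pt=pt,
                    ebgm_z=ebgm_z,
                    zero_correction=zero_correction,
                )
            )
        a, b, c, d = index.pooled_counts(drug)
        results.append(
            analyze_table(
                ContingencyTable(a, b, c, d),
                drug=drug,
                pt=TOTAL_LABEL,
                ebgm_z=ebgm_z,
                zero_correction=zero_correction,
            )
        )
    if include_grand_total and len(index.drug_cases) > 1:
        a, b, c, d = index.pooled_counts(None)
        results.append(
            analyze_table(
                ContingencyTable(a, b, c, d),
                drug=TOTAL_LABEL,
                pt=TOTAL_LABEL,
                ebgm_z=ebgm_z,
                zero_correction=zero_correction,
            )
        )
    return results


#: Bit-exact output column order of the signals table.
SIGNAL_COLUMNS = [
    "drug", "pt", "n",
    "ror", "ror05", "ror95",
    "prr", "chi2",
    "ic", "ic025",
    "ebgm", "ebgm05",
    "ror_flag", "prr_flag", "ic_flag", "ebgm_flag", "signal",
]

_ROUNDING = {"ror": 3, "ror05": 3, "ror95": 3,
             "prr": 2, "chi2": 2, "ic": 2, "ic025": 2, "ebgm": 2, "ebgm05": 2}


def _fmt_value(name: str, value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.{_ROUNDING[name]}f}"
    return str(value)


def write_signal_table(results: Iterable[SignalResult], path: str | Path) -> None:
    """Write the scan as a TSV with the documented column order; ratios at 3
    decimals, the remaining statistics at 2, undefined values as NA."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(SIGNAL_COLUMNS) + "\n")
        for res in results:
            row = [_fmt_value(col, getattr(res, col)) for col in SIGNAL_COLUMNS]
            fh.write("\t".join(row) + "\n")
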