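"""The four disproportionality algorithms: printed-formula fidelity,
interval conventions, criteria, zero-cell policy and output format."""
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from pvsignal import (
    CohortSpec,
    ContingencyTable,
    analyze_table,
    build_cohort,
    compute_ebgm,
    compute_ic,
    compute_prr_chi2,
    compute_ror,
    evaluate_criteria,
    run_signal_scan,
    wald_se,
    write_signal_table,
)
from pvsignal.disproportionality import SignalResult

from conftest import make_record


def oracle_stats(a: int, b: int, c: int, d: int) -> dict:
    """Independent exact-rational evaluation of the four printed formulas."""
    A, B, C, D = (Fraction(x) for x in (a, b, c, d))
    T = A + B + C + D
    return {
        "ror": float(A * D / (B * C)),
        "prr": float((A / (A + B)) / (C / (C + D))),
        "chi2": float((A * D - B * C) ** 2 * T / ((A + B) * (C + D) * (A + C) * (B + D))),
        "ic": math.log2(float(A * T / ((A + C) * (A + B)))),
        "ebgm": float(A * T / ((A + C) * (A + B))),
        "se": math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
    }


class TestPointEstimates:
    def test_wald_se_unit_case(self):
        assert wald_se(ContingencyTable(4, 4, 4, 4)) == pytest.approx(1.0)

    def test_wald_se_derived_case(self):
        # sqrt(1/10 + 1/90 + 1/100 + 1/9900), frozen from the rational oracle
        assert wald_se(ContingencyTable(10, 90, 100, 9900)) == pytest.approx(
            0.3481553119, abs=1e-9
        )

    def test_wald_se_zero_cell_undefined(self):
        assert math.isnan(wald_se(ContingencyTable(0, 90, 100, 9900)))

    def test_symmetric_table_is_null(self):
        t = ContingencyTable(5, 5, 5, 5)
        ror, ror05, ror95 = compute_ror(t)
        prr, chi2 = compute_prr_chi2(t)
        assert ror == pytest.approx(1.0)
        assert ror05 < 1 < ror95
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_derived_example_table(self):
        t = ContingencyTable(10, 90, 100, 9900)
        ror, ror05, ror95 = compute_ror(t)
        assert ror == pytest.approx(11.0)
        assert ror05 == pytest.approx(5.5595, abs=5e-4)
        assert ror95 == pytest.approx(21.764, abs=5e-3)
        prr, chi2 = compute_prr_chi2(t)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.45, abs=5e-3)
        ic, _ = compute_ic(t)
        assert ic == pytest.approx(3.199, abs=5e-4)
        ebgm, _ = compute_ebgm(t)
        assert ebgm == pytest.approx(9.182, abs=5e-4)

    def test_independence_table_is_exactly_null(self):
        # a*T/((a+c)(a+b)) = 5*1000/(100*50) = 1
        t = ContingencyTable(5, 45, 95, 855)
        ic, ic025 = compute_ic(t)
        ebgm, _ = compute_ebgm(t)
        assert ic == pytest.approx(0.0)
        assert math.isnan(ic025)  # lower bound undefined at IC <= 0
        assert ebgm == pytest.approx(1.0)
        res = analyze_table(t)
        assert not res.signal


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.tuples(
        st.integers(1, 10**5), st.integers(1, 10**5),
        st.integers(1, 10**5), st.integers(1, 10**5),
    )
)
def test_matches_exact_rational_oracle(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    exp = oracle_stats(a, b, c, d)
    res = analyze_table(t)
    assert res.ror == pytest.approx(exp["ror"], rel=1e-12)
    assert res.prr == pytest.approx(exp["prr"], rel=1e-12)
    assert res.chi2 == pytest.approx(exp["chi2"], rel=1e-12)
    assert res.ebgm == pytest.approx(exp["ebgm"], rel=1e-12)
    if exp["ebgm"] != 1.0:
        assert res.ic == pytest.approx(exp["ic"], rel=1e-9)
    # exact algebraic identity of the two observed/expected forms
    assert 2 ** res.ic == pytest.approx(res.ebgm, rel=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.tuples(
        st.integers(1, 10**4), st.integers(1, 10**4),
        st.integers(1, 10**4), st.integers(1, 10**4),
    )
)
def test_chi2_matches_uncorrected_pearson(cells):
    a, b, c, d = cells
    _, chi2 = compute_prr_chi2(ContingencyTable(a, b, c, d))
    expected = chi2_contingency(np.array([[a, b], [c, d]]), correction=False).statistic
    assert chi2 == pytest.approx(expected, abs=1e-9, rel=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.tuples(
        st.integers(2, 1000), st.integers(1, 1000),
        st.integers(1, 1000), st.integers(1, 1000),
    )
)
def test_bound_ordering_and_ror_prr_monotonicity_in_a(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    res = analyze_table(t)
    assert res.ror05 < res.ror < res.ror95
    assert res.ebgm05 < res.ebgm
    if res.ic > 0:
        assert res.ic025 < res.ic
    # ROR and PRR are strictly increasing in a on every table
    bigger = analyze_table(ContingencyTable(a + 1, b, c, d))
    assert bigger.ror > res.ror
    assert bigger.prr > res.prr


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.integers(1, 100),
    st.integers(1000, 10**5), st.integers(1000, 10**5), st.integers(1000, 10**5),
)
def test_ic_ebgm_monotonicity_when_a_is_small_against_margins(a, b, c, d):
    """The observed/expected ratio increases in a only while a is small
    relative to both margins (d ln f/da = 1/a + 1/T - 1/(a+c) - 1/(a+b) > 0);
    it is not monotone on arbitrary tables."""
    res = analyze_table(ContingencyTable(a, b, c, d))
    bigger = analyze_table(ContingencyTable(a + 1, b, c, d))
    assert bigger.ic > res.ic
    assert bigger.ebgm > res.ebgm


def _result(n=10, ror=2.0, ror05=1.5, prr=2.5, chi2=10.0, ic=1.0, ic025=0.5,
            ebgm=2.5, ebgm05=2.2):
    return SignalResult(
        drug="d", pt="p", n=n, ror=ror, ror05=ror05, ror95=ror * 2,
        prr=prr, chi2=chi2, ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
    )


class TestCriteria:
    def test_all_criteria_fire(self):
        res = evaluate_criteria(_result())
        assert (res.ror_flag, res.prr_flag, res.ic_flag, res.ebgm_flag) == (True,) * 4
        assert res.signal

    def test_single_algorithm_suffices(self):
        # ROR05 just above 1 at n=5 while the MGPS bound stays under 2
        res = evaluate_criteria(_result(n=5, ror=2.808, ror05=1.165, prr=2.81,
                                        chi2=4.12, ic=1.48, ic025=0.62,
                                        ebgm=2.80, ebgm05=1.34))
        assert res.ror_flag and not res.ebgm_flag
        assert res.signal

    @pytest.mark.parametrize(
        "kwargs,flag",
        [
            (dict(ror05=1.0), "ror_flag"),          # bound not strictly > 1
            (dict(n=1), "ror_flag"),                 # N < 2
            (dict(prr=1.99), "prr_flag"),
            (dict(chi2=3.99), "prr_flag"),
            (dict(n=2), "prr_flag"),                 # N < 3
            (dict(ic025=0.0), "ic_flag"),
            (dict(ebgm05=2.0), "ebgm_flag"),
        ],
    )
    def test_threshold_edges(self, kwargs, flag):
        res = evaluate_criteria(_result(**kwargs))
        assert getattr(res, flag) is False

    def test_undefined_statistics_never_fire(self):
        nan = float("nan")
        res = evaluate_criteria(
            _result(n=0, ror=nan, ror05=nan, prr=nan, chi2=nan, ic=nan,
                    ic025=nan, ebgm=nan, ebgm05=nan)
        )
        assert not (res.ror_flag or res.prr_flag or res.ic_flag or res.ebgm_flag)
        assert not res.signal


class TestZeroCellPolicy:
    def test_default_undefined(self):
        res = analyze_table(ContingencyTable(3, 0, 10, 1000))
        assert math.isnan(res.ror)
        assert not res.ror_flag

    def test_haldane_anscombe_correction(self):
        res = analyze_table(ContingencyTable(3, 0, 10, 1000), zero_correction=True)
        assert res.ror == pytest.approx((3.5 * 1000.5) / (0.5 * 10.5), rel=1e-12)
        assert res.n == 3  # N stays the raw co-report count

    def test_ebgm_z_switch(self):
        t = ContingencyTable(10, 90, 100, 9900)
        _, one_sided = compute_ebgm(t, z=1.645)
        _, two_sided = compute_ebgm(t, z=1.96)
        assert two_sided < one_sided


class TestScanAndOutput:
    def _single_cell_index(self, meddra):
        suspect = make_record().drugs[0][1]
        records = [
            make_record(f"t{i}",
                        reactions=("confusional state", "nausea") if i < 5 else ("nausea",))
            for i in range(8)
        ] + [
            make_record(f"b{i}", drugs=(("otherdrug", suspect),),
                        reactions=("confusional state" if i < 4 else "nausea",))
            for i in range(40)
        ]
        spec = CohortSpec.create(["sorafenib"], "Psychiatric disorders")
        return build_cohort(records, spec, meddra)

    def test_single_cell_scan_gives_identical_cell_and_total_rows(self, meddra):
        index = self._single_cell_index(meddra)
        assert index.counts("sorafenib", "confusional state") == (5, 3, 4, 36)
        results = run_signal_scan(index)
        assert [(r.drug, r.pt) for r in results] == [
            ("sorafenib", "confusional state"), ("sorafenib", "Total")
        ]
        cell, total = results
        assert cell.n == total.n == 5
        assert cell.ror == pytest.approx(total.ror)
        assert cell.ic == pytest.approx(total.ic)

    def test_empty_cell_yields_flagless_row(self, meddra):
        records = [
            make_record(f"b{i}", drugs=(("otherdrug", list(make_record().drugs)[0][1]),))
            for i in range(5)
        ]
        spec = CohortSpec.create(["sorafenib"], "Psychiatric disorders")
        index = build_cohort(records, spec, meddra)
        results = run_signal_scan(index)
        assert len(results) == 1
        assert results[0].n == 0
        assert not results[0].signal

    def test_written_table_layout_and_rounding(self, meddra, tmp_path):
        results = run_signal_scan(self._single_cell_index(meddra))
        out = tmp_path / "signals.tsv"
        write_signal_table(results, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "drug", "pt", "n", "ror", "ror05", "ror95", "prr", "chi2", "ic",
            "ic025", "ebgm", "ebgm05", "ror_flag", "prr_flag", "ic_flag",
            "ebgm_flag", "signal",
        ]
        row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
        assert row["ror"] == f"{results[0].ror:.3f}"
        assert row["ic"] == f"{results[0].ic:.2f}"
        assert row["signal"] in ("true", "false")
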