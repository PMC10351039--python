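"""Duplicate detection: the 3-of-4 key-field rule, transitivity, and
agreement with the brute-force pairwise oracle."""
import datetime as dt
import random

import pytest
from scipy import stats

from pvsignal import (
    SyntheticConfig,
    dedup_rate,
    find_duplicates,
    find_duplicates_bruteforce,
    generate,
)
from pvsignal.records import Sex

from conftest import make_record

D1 = dt.date(2018, 1, 15)
D2 = dt.date(2019, 7, 1)


def test_three_of_four_match_groups_as_duplicates():
    a = make_record("a", event_date=D1, age_years=60, sex=Sex.MALE, country="US")
    b = make_record("b", event_date=D1, age_years=60, sex=Sex.MALE, country="JP")
    part = find_duplicates([a, b])
    assert len(part.kept) == 1
    assert part.groups[0].member_indices == (0, 1)


def test_two_of_four_match_is_not_a_duplicate():
    a = make_record("a", event_date=D1, age_years=60, sex=Sex.MALE, country="US")
    b = make_record("b", event_date=D2, age_years=41, sex=Sex.MALE, country="US")
    part = find_duplicates([a, b])
    assert len(part.kept) == 2
    assert part.groups == ()


def test_missing_field_never_counts_as_agreement():
    a = make_record("a", event_date=None, age_years=60, sex=Sex.MALE, country="US")
    b = make_record("b", event_date=None, age_years=60, sex=Sex.MALE, country="JP")
    # event_date missing on both: only age+sex agree -> not duplicates
    assert len(find_duplicates([a, b]).kept) == 2


def test_transitive_closure_on_six_record_fixture():
    """A~B and B~C (3 fields each) but A and C share only 2 fields: the
    group is {A, B, C} by transitivity; unrelated records stay apart."""
    a = make_record("a", event_date=D1, age_years=60, sex=Sex.MALE, country="US")
    b = make_record("b", event_date=D1, age_years=60, sex=Sex.MALE, country="JP")
    c = make_record("c", event_date=D2, age_years=60, sex=Sex.MALE, country="JP")
    others = [
        make_record("d", event_date=D2, age_years=30, sex=Sex.FEMALE, country="DE"),
        make_record("e", event_date=None, age_years=None, sex=Sex.MISSING, country=None),
        make_record("f", event_date=dt.date(2020, 2, 2), age_years=77, sex=Sex.MALE, country="BR"),
    ]
    records = [a, b, c] + others
    part = find_duplicates(records)
    oracle = find_duplicates_bruteforce(records)
    assert part.kept_indices == oracle.kept_indices
    assert len(part.groups) == 1
    assert part.groups[0].member_indices == (0, 1, 2)
    assert len(part.kept) == 4


def test_kept_record_has_fewest_missing_then_earliest_report():
    full = make_record("full", report_date=dt.date(2018, 5, 1))
    sparse = make_record("sparse", report_date=dt.date(2017, 1, 1), country=None)
    part = find_duplicates([sparse, full])
    assert [r.case_id for r in part.kept] == ["full"]


def _random_records(n: int, seed: int):
    rng = random.Random(seed)
    recs = []
    for i in range(n):
        recs.append(
            make_record(
                f"r{i}",
                report_date=dt.date(2015 + rng.randrange(5), 1 + rng.randrange(12), 5),
                event_date=rng.choice([None] + [dt.date(2018, 1, d) for d in range(1, 6)]),
                age_years=rng.choice([None, 50, 60, 70]),
                sex=rng.choice([Sex.MALE, Sex.FEMALE, Sex.MISSING]),
                country=rng.choice([None, "US", "JP", "DE"]),
            )
        )
    return recs


@pytest.mark.parametrize("n,seed", [(20, 0), (50, 1), (120, 2), (200, 3)])
def test_agreement_with_bruteforce_oracle(n, seed):
    records = _random_records(n, seed)
    fast = find_duplicates(records)
    slow = find_duplicates_bruteforce(records)
    assert fast.kept_indices == slow.kept_indices
    assert {g.member_indices for g in fast.groups} == {g.member_indices for g in slow.groups}


def test_idempotence_on_kept_set():
    records = _random_records(150, 7)
    kept = find_duplicates(records).kept
    again = find_duplicates(kept)
    assert again.groups == ()
    assert len(again.kept) == len(kept)


class TestDedupRate:
    def test_no_duplicates_is_zero(self):
        records = [make_record(f"c{i}", age_years=20 + i, event_date=None) for i in range(10)]
        assert dedup_rate(find_duplicates(records)) == 0.0

    def test_one_group_of_three_in_ten(self):
        trio = [
            make_record(f"t{i}", event_date=D1, age_years=60, sex=Sex.MALE, country=c)
            for i, c in enumerate(["US", "JP", "DE"])
        ]
        others = [
            make_record(f"o{i}", event_date=None, age_years=i, sex=Sex.FEMALE, country=None)
            for i in range(7)
        ]
        assert dedup_rate(find_duplicates(trio + others)) == pytest.approx(0.2)

    def test_empty_input_is_zero(self):
        assert dedup_rate(find_duplicates([])) == 0.0


def test_injected_duplicates_fully_recalled_and_rate_calibrated():
    """Generator clones perturb exactly one key field, so every injected
    (original, clone) pair must land in one duplicate group; the injected
    fraction itself stays inside the binomial 95% band of the configured
    rate. Coincidental demographic collisions may merge further records, so
    the measured rate is bounded below by the injected fraction."""
    cfg = SyntheticConfig(
        seed=11, n_background=30, n_cases={}, duplicate_rate=0.1, missingness={}
    )
    records, truth = generate(cfg)
    part = find_duplicates(records)
    pos = {r.case_id: i for i, r in enumerate(records)}
    roots = {}
    for g in part.groups:
        for m in g.member_indices:
            roots[m] = g.member_indices
    for orig, clones in truth.duplicate_groups.items():
        for clone in clones:
            assert pos[clone] in roots.get(pos[orig], ()), f"{orig} and {clone} not grouped"
    n_injected = sum(len(v) for v in truth.duplicate_groups.values())
    n_total = len(records)
    lo, hi = stats.binom.interval(0.95, n_total, 0.1)
    assert lo <= n_injected <= hi
    assert dedup_rate(part) >= n_injected / n_total
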