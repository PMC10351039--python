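"""Collapse probable duplicate reports with the 3-of-4 key-field rule.

Three hand-made reports describe the same clinical event through different
channels (same event date, age and sex; one differs in reporter country),
and a fourth is unrelated. Reports agreeing on at least three of
{event date, age, sex, country} are grouped transitively and one
representative — the most completely filled — is kept.
"""
import datetime as dt

from pvsignal import dedup_rate, find_duplicates
from pvsignal.records import AdrFlag, DrugRole, ICSRRecord, Sex


def report(case_id, event, age, sex, country, report_date):
    return ICSRRecord(
        case_id=case_id, report_date=report_date, event_date=event,
        age_years=age, sex=sex, country=country,
        drugs=(("sunitinib", DrugRole.PRIMARY_SUSPECT),),
        reactions=("hypersomnia",), adr_flag=AdrFlag.YES,
    )


records = [
    report("physician", dt.date(2020, 4, 2), 67, Sex.MALE, "US", dt.date(2020, 5, 1)),
    report("patient", dt.date(2020, 4, 2), 67, Sex.MALE, "CA", dt.date(2020, 5, 20)),
    report("manufacturer", dt.date(2020, 4, 2), 67, Sex.MALE, None, dt.date(2020, 6, 3)),
    report("unrelated", dt.date(2019, 11, 11), 52, Sex.FEMALE, "DE", dt.date(2019, 12, 1)),
]
partition = find_duplicates(records)

for group in partition.groups:
    ids = [records[i].case_id for i in group.member_indices]
    print(f"duplicate group: {ids}, kept: {records[group.kept_index].case_id!r}")
print(f"kept {len(partition.kept)} of {len(records)} reports "
      f"(dedup rate {dedup_rate(partition):.2f})")
print()
print("The manufacturer report (missing country) still matches the others "
      "on event date, age and sex — 3 of 4 fields — so all three collapse "
      "to the physician report, which has no missing key fields.")
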