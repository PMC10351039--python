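import datetime as dt

import pytest

from pvsignal import MedDRAMap, read_meddra_map
from pvsignal.records import AdrFlag, DrugRole, ICSRRecord, Sex
from pvsignal.reference import packaged_path


@pytest.fixture(scope="session")
def meddra() -> MedDRAMap:
    return read_meddra_map(packaged_path("pt_soc_map.tsv"))


def make_record(
    case_id: str = "c1",
    report_date=dt.date(2018, 3, 1),
    event_date=dt.date(2018, 1, 15),
    age_years=60.0,
    sex=Sex.MALE,
    country="US",
    drugs=(("sorafenib", DrugRole.PRIMARY_SUSPECT),),
    reactions=("confusional state",),
    indications=("hepatocellular carcinoma",),
    outcomes=frozenset(),
    adr_flag=AdrFlag.YES,
) -> ICSRRecord:
    """Valid ICSR with overridable fields, for terse test setup."""
    return ICSRRecord(
        case_id=case_id,
        report_date=report_date,
        event_date=event_date,
        age_years=age_years,
        sex=sex,
        country=country,
        drugs=tuple(drugs),
        reactions=tuple(reactions),
        indications=tuple(indications),
        outcomes=frozenset(outcomes),
        adr_flag=adr_flag,
    )


@pytest.fixture
def record_factory():
    return make_record
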