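import datetime as dt

import pytest

from surgcomp.records import (
    CareEvent,
    DrugClass,
    EventKind,
    InfectionStatus,
    ProcedureRecord,
    ProcedureType,
)


def make_procedure(
    pid="P1",
    animal="A1",
    date=dt.date(2020, 1, 1),
    ptype=ProcedureType.PLN,
    status=InfectionStatus.UNINFECTED,
    prophylaxis=False,
    observation=7,
):
    return ProcedureRecord(
        procedure_id=pid,
        animal_id=animal,
        surgery_date=date,
        procedure_type=ptype,
        infection_status=status,
        prophylaxis=prophylaxis,
        observation_days=observation,
    )


def make_rx(animal="A1", date=dt.date(2020, 1, 3), drug="cefazolin",
            drug_class=DrugClass.ANTIBIOTIC, indication="surgical"):
    return CareEvent(
        animal_id=animal,
        event_date=date,
        kind=EventKind.PRESCRIPTION,
        drug_name=drug,
        drug_class=drug_class,
        indication=indication,
    )


def make_note(animal="A1", date=dt.date(2020, 1, 4), text="incision clean and dry"):
    return CareEvent(
        animal_id=animal, event_date=date, kind=EventKind.NOTE, note_text=text
    )


@pytest.fixture
def procedure():
    return make_procedure()
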