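import datetime

import pytest

from opioid_its import OpioidCatalog, PatientRecord, PrescriptionRecord


@pytest.fixture(scope="session")
def catalog():
    return OpioidCatalog.default()


@pytest.fixture
def make_patient():
    def _make(pid="p1", sex="female", birth_year=1971, insurance="NHI",
              dx=("M54",)):
        return PatientRecord(pid, sex, birth_year, insurance, frozenset(dx))
    return _make


@pytest.fixture
def make_fill():
    def _make(rx="r1", pid="p1", provider="d1", inst="h1", drug="oxycodone",
              start=datetime.date(2016, 3, 1), days=10, upd=3.0, mg=10.0,
              setting="outpatient"):
        return PrescriptionRecord(rx, pid, provider, inst, drug, start, days,
                                  upd, mg, setting)
    return _make
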