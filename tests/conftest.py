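import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

from trialaudit.partialdates import PartialDate
from trialaudit.registry_io import RegistryReference, TrialRecord


@pytest.fixture
def ctgov_trial():
    """A well-behaved ClinicalTrials.gov trial inside the default cohort."""
    return TrialRecord(
        trn="NCT01234567",
        registry="ctgov",
        lead_umcs=["UMC A"],
        start_date=PartialDate(2013, 4, 10),
        completion_date=PartialDate(2015, 6, 17),
        registration_date=PartialDate(2013, 3, 2),
        status="Completed",
        study_type="interventional",
        has_structured_summary_results=False,
        references=[RegistryReference(title="Protocol", doi="10.1000/protocol")],
    )


@pytest.fixture
def drks_trial():
    return TrialRecord(
        trn="DRKS00004871",
        registry="drks",
        lead_umcs=["UMC B"],
        start_date=PartialDate(2014, 2),
        completion_date=PartialDate(2016, 9),
        registration_date=PartialDate(2014, 2),
        status="Completed",
        study_type="interventional",
    )
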