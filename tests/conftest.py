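import logging
from datetime import date

import pytest

from trialpubs.model import (
    ArticleRecord,
    OverallStatus,
    ReferenceType,
    RegistryReference,
    StudyType,
    TrialRecord,
)
from trialpubs.synth import SynthSpec, generate_corpus

logging.disable(logging.INFO)


def make_trial(nct_id="NCT04000001", **kwargs):
    defaults = dict(
        brief_title="Trial of Examplimab in Hospitalized Patients With COVID-19",
        study_type=StudyType.INTERVENTIONAL,
        overall_status=OverallStatus.RECRUITING,
        phase_labels=["Phase 3"],
        intervention_names=["Examplimab"],
        sponsor_names=["Example University"],
        location_countries=["United States"],
        start_date=date(2020, 3, 15),
        primary_completion_date=date(2021, 3, 15),
        registration_date=date(2020, 3, 1),
        version_count=4,
        condition_terms=["COVID-19"],
    )
    defaults.update(kwargs)
    return TrialRecord(nct_id=nct_id, **defaults)


def make_article(pmid="30000001", **kwargs):
    defaults = dict(
        title="Examplimab for COVID-19: a randomized trial",
        publication_date=date(2021, 1, 10),
        publication_types=["Journal Article", "Randomized Controlled Trial"],
        journal_name="Annals of Trial Medicine",
        secondary_ids=[],
    )
    defaults.update(kwargs)
    return ArticleRecord(pmid=pmid, **defaults)


def result_ref(pmid, citation="A result article."):
    return RegistryReference(
        citation_text=citation, pmid=pmid, declared_type=ReferenceType.RESULT_REFERENCE
    )


@pytest.fixture(scope="session")
def synth_corpus():
    """One seeded synthetic corpus with its ground-truth ledger."""
    return generate_corpus(SynthSpec(seed=7, n_trials=200))
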