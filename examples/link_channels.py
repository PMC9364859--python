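"""Show the two link channels and the misdated-reference filter on a tiny corpus.

Trial A cites a result article in its registry record (registry channel) and
also cites a review published before the trial started — a misclassified
result reference the date filter removes. Article 103 names trial B's NCT id
in its indexed secondary identifiers (abstract channel).
"""

from datetime import date

from trialpubs import ArticleRecord, RegistryReference, TrialRecord, run, Corpus
from trialpubs.model import ReferenceType


def result_ref(pmid):
    return RegistryReference(
        citation_text=f"PMID {pmid}", pmid=pmid,
        declared_type=ReferenceType.RESULT_REFERENCE,
    )


trial_a = TrialRecord(
    nct_id="NCT04000001",
    brief_title="Trial A of DrugA for COVID-19",
    overall_status="recruiting",
    phase_labels=["Phase 3"],
    start_date=date(2020, 6, 1),
    registry_references=[result_ref("101"), result_ref("102")],
)
trial_b = TrialRecord(
    nct_id="NCT04000002",
    brief_title="Trial B of DrugB for COVID-19",
    overall_status="completed",
    phase_labels=["Phase 2"],
    start_date=date(2020, 4, 1),
)
articles = [
    ArticleRecord(pmid="101", title="Results of trial A",
                  publication_date=date(2021, 2, 1),
                  publication_types=["Journal Article"]),
    ArticleRecord(pmid="102", title="A review of DrugA pharmacology",
                  publication_date=date(2019, 5, 1),  # predates trial start
                  publication_types=["Journal Article"]),
    ArticleRecord(pmid="103", title="Results of trial B",
                  publication_date=date(2021, 3, 1),
                  publication_types=["Journal Article"],
                  secondary_ids=["NCT04000002"]),
]

result = run(Corpus(trials=[trial_a, trial_b], articles=articles,
                    query_date=date(2022, 1, 31)))
for link in result.link_table.links:
    print(f"kept:    {link.nct_id} <-> PMID {link.pmid}  via {sorted(link.channels)}")
for link in result.link_table.removed:
    print(f"removed: {link.nct_id} <-> PMID {link.pmid}  ({link.invalidation_reason.value})")
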