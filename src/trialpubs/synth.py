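"""Synthetic registry + literature corpora with known link structure.

The generator emulates the statistical structure the pipeline assumes: a
registry of studies (phases, statuses, dates, US/non-US sites, free-text
interventions, result references — including deliberately misdated ones)
and a literature set whose articles carry trial identifiers as secondary
ids. Every planted fact is recorded in a :class:`GroundTruth` ledger, so
each pipeline stage's output can be checked exactly against construction.

Defaults are sized to roughly 200 trials / 150 planted links and follow the
structure of the real corpus where it is known: the publication lag from
trial start averages 214 days, the abstract channel carries the majority of
links, a small fraction of pairs is found by both channels, and a minority
of registry result references are misdated (article predating trial start).
Statistically realistic modeling of the true trial landscape is a non-goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional
from xml.dom import minidom
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from .classify import RegistrationTiming
from .ingest import Corpus
from .interventions import PhaseCategory
from .model import (
    ArticleRecord,
    OverallStatus,
    ReferenceType,
    RegistryReference,
    StudyType,
    TrialRecord,
)

__all__ = ["SynthSpec", "GroundTruth", "generate_corpus", "write_fixture_files"]

_CONDITION_TITLES = [
    "Efficacy of {drug} in Hospitalized Patients With COVID-19",
    "Safety and Immunogenicity of {drug} for COVID-19",
    "{drug} Versus Standard of Care for Severe Coronavirus Disease 2019",
    "A Randomized Trial of {drug} in Outpatients With COVID-19",
]
_VACCINE_TITLES = [
    "Safety of the {drug} Vaccine Candidate Against COVID-19",
    "Immunogenicity of a {drug} COVID-19 Vaccine in Adults",
]
_OFF_CONDITION_TITLES = [
    "Efficacy of {drug} in Seasonal Influenza",
    "A Trial of {drug} for Chronic Migraine",
]
_DRUGS = [
    "Adintrevimab", "Baricinol", "Cormavir", "Dexaplan", "Enzaparin",
    "Favimod", "Gravolumab", "Hydroxytide", "Imazepril", "Jasporin",
    "Kaliciclib", "Lenvomab", "Molnatrex", "Nirvastat", "Oseltravir",
    "Panzulin", "Quercivir", "Remdanavir", "Sotrovex", "Tocilizane",
]
_COUNTRIES = ["France", "Brazil", "India", "Germany", "China", "Spain", "Egypt"]
_SPONSORS = [
    "University of Westfield", "Northgate Medical Center", "Helix Therapeutics",
    "National Research Consortium", "Meridian Biotech", "Lakeside Hospital",
    "Orion Pharma", "Civic Health Alliance",
]
_JOURNALS = [
    "Journal of Clinical Investigation Reports", "Infectious Disease Letters",
    "Annals of Trial Medicine", "Global Health Research",
]
_TERMINATION_TEXTS = {
    "recruitment": "Terminated due to inability to recruit and enroll participants",
    "safety": "Stopped early because of intervention safety concerns",
    "futility": "Stopped for futility at interim analysis",
    "external_results": "Availability of results from other trials made continuation unnecessary",
    "other": "Sponsor decision following portfolio review",
    "unspecified": "",
}

_PHASE_LABEL = {
    PhaseCategory.EARLY_PHASE_1: "Early Phase 1",
    PhaseCategory.PHASE_1: "Phase 1",
    PhaseCategory.PHASE_2: "Phase 2",
    PhaseCategory.PHASE_3: "Phase 3",
    PhaseCategory.PHASE_4: "Phase 4",
    PhaseCategory.NOT_APPLICABLE: "N/A",
}


@dataclass
class SynthSpec:
    """Parameters of one synthetic corpus; all randomness flows from seed."""

    n_trials: int = 200
    study_type_mix: dict[str, float] = field(
        default_factory=lambda: {"interventional": 0.75, "observational": 0.17, "registry": 0.08}
    )
    phase_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "early_phase_1": 0.04,
            "phase_1": 0.14,
            "phase_2": 0.26,
            "phase_3": 0.28,
            "phase_4": 0.06,
            "not_applicable": 0.22,
        }
    )
    p_us_site: float = 0.30
    p_registry_link: float = 0.40  # channel assignment per planted pair
    p_abstract_link: float = 0.57
    p_dual_link: float = 0.03
    p_misdated_reference: float = 0.10  # per trial: plant a predating result ref
    p_missing_article_reference: float = 0.02
    p_off_condition: float = 0.05
    p_ineligible_status: float = 0.06
    p_vaccine: float = 0.15
    p_protocol_article: float = 0.12
    p_editorial_article: float = 0.05
    p_second_trial_on_article: float = 0.04
    p_deposited_results: float = 0.08
    mean_articles_per_trial: float = 0.75
    publication_lag_mean: float = 214.0
    publication_lag_sd: float = 90.0
    timing_mix: dict[str, float] = field(
        default_factory=lambda: {"prior": 0.45, "during": 0.42, "after": 0.13}
    )
    update_count_mean: float = 3.0  # Poisson mean for updates beyond version 1
    query_date: date = date(2022, 1, 31)
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_us_site, self.p_misdated_reference, self.p_off_condition,
            self.p_ineligible_status, self.p_vaccine, self.p_protocol_article,
            self.p_editorial_article, self.p_second_trial_on_article,
            self.p_deposited_results, self.p_missing_article_reference,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for name, mix in (
            ("study_type_mix", self.study_type_mix),
            ("phase_distribution", self.phase_distribution),
            ("timing_mix", self.timing_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        channel = self.p_registry_link + self.p_abstract_link + self.p_dual_link
        if abs(channel - 1.0) > 1e-9:
            raise ValueError("channel probabilities must sum to 1")
        if self.n_trials < 0:
            raise ValueError("n_trials must be nonnegative")


@dataclass
class GroundTruth:
    """Every planted fact, keyed so pipeline output can be recomputed exactly."""

    in_scope_ncts: set[str] = field(default_factory=set)
    registry_links: set[tuple[str, str]] = field(default_factory=set)  # valid only
    abstract_links: set[tuple[str, str]] = field(default_factory=set)
    misdated_links: set[tuple[str, str]] = field(default_factory=set)
    missing_article_links: set[tuple[str, str]] = field(default_factory=set)
    phase_by_trial: dict[str, PhaseCategory] = field(default_factory=dict)
    us_site_by_trial: dict[str, bool] = field(default_factory=dict)
    multiple_updates_by_trial: dict[str, bool] = field(default_factory=dict)
    timing_by_trial: dict[str, RegistrationTiming] = field(default_factory=dict)
    vaccine_ncts: set[str] = field(default_factory=set)
    article_type_by_pmid: dict[str, str] = field(default_factory=dict)
    lag_days: dict[tuple[str, str], int] = field(default_factory=dict)
    termination_by_trial: dict[str, str] = field(default_factory=dict)

    @property
    def all_links(self) -> set[tuple[str, str]]:
        return self.registry_links | self.abstract_links

    @property
    def dual_links(self) -> set[tuple[str, str]]:
        return self.registry_links & self.abstract_links

    def expected_shortlist(self) -> set[tuple[str, str]]:
        """Pairs meeting all four shortlist criteria, from planted facts."""
        out = set()
        for nct, pmid in self.all_links:
            if (
                self.article_type_by_pmid.get(pmid) == "result_article"
                and self.phase_by_trial.get(nct) == PhaseCategory.PHASE_3
                and self.us_site_by_trial.get(nct, False)
                and self.multiple_updates_by_trial.get(nct, False)
            ):
                out.add((nct, pmid))
        return out


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    return str(rng.choice(keys, p=[mix[k] / sum(mix.values()) for k in keys]))


def generate_corpus(spec: SynthSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a reproducible corpus and its ground-truth ledger."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    trials: list[TrialRecord] = []
    articles: list[ArticleRecord] = []
    next_pmid = 30000001

    def new_pmid() -> str:
        nonlocal next_pmid
        p = str(next_pmid)
        next_pmid += 1
        return p

    def make_article(
        pmid: str, title: str, pub: date, atype: str, ncts_in_abstract: list[str]
    ) -> ArticleRecord:
        if atype == "protocol":
            title = f"Protocol for {title}"
            ptypes = ["Journal Article", "Clinical Trial Protocol"]
        elif atype == "editorial_or_comment":
            ptypes = ["Editorial"]
        else:
            ptypes = ["Journal Article", "Randomized Controlled Trial"]
        truth.article_type_by_pmid[pmid] = atype
        return ArticleRecord(
            pmid=pmid,
            title=title,
            publication_date=pub,
            publication_types=ptypes,
            journal_name=str(rng.choice(_JOURNALS)),
            mesh_terms=["COVID-19", "Humans"],
            secondary_ids=list(ncts_in_abstract),
        )

    for i in range(spec.n_trials):
        nct = f"NCT05{i:06d}"
        drug = str(rng.choice(_DRUGS))
        study_type = StudyType(_choice(rng, spec.study_type_mix))
        off_condition = rng.random() < spec.p_off_condition
        vaccine = (
            not off_condition
            and study_type == StudyType.INTERVENTIONAL
            and rng.random() < spec.p_vaccine
        )
        if off_condition:
            title = str(rng.choice(_OFF_CONDITION_TITLES)).format(drug=drug)
        elif vaccine:
            title = str(rng.choice(_VACCINE_TITLES)).format(drug=drug)
        else:
            title = str(rng.choice(_CONDITION_TITLES)).format(drug=drug)

        if study_type == StudyType.INTERVENTIONAL:
            phase = PhaseCategory(_choice(rng, spec.phase_distribution))
            # a phase-3 trial sometimes carries the combined registry label
            if phase == PhaseCategory.PHASE_3 and rng.random() < 0.3:
                label = "Phase 2/Phase 3"
            else:
                label = _PHASE_LABEL[phase]
            phase_labels = [label]
        else:
            phase = PhaseCategory.NOT_APPLICABLE
            phase_labels = []

        start = date(2020, 1, 1) + timedelta(days=int(rng.integers(0, 540)))
        pcd = start + timedelta(days=int(rng.integers(180, 720)))
        timing = _choice(rng, spec.timing_mix)
        if timing == "prior":
            reg = start - timedelta(days=int(rng.integers(0, 60)))
        elif timing == "during":
            reg = start + timedelta(days=int(rng.integers(1, (pcd - start).days + 1)))
        else:
            reg = pcd + timedelta(days=int(rng.integers(1, 90)))

        ineligible = rng.random() < spec.p_ineligible_status
        if timing == "after":
            status = OverallStatus.COMPLETED if rng.random() < 0.8 else OverallStatus.TERMINATED
            ineligible = False
        elif ineligible:
            status = OverallStatus(
                str(rng.choice(["withdrawn", "suspended", "not_yet_recruiting"]))
            )
        else:
            status = OverallStatus(
                str(
                    rng.choice(
                        ["recruiting", "active_not_recruiting", "completed",
                         "terminated", "enrolling_by_invitation"],
                        p=[0.35, 0.2, 0.3, 0.1, 0.05],
                    )
                )
            )
        termination_reason = None
        if status == OverallStatus.TERMINATED:
            cat = str(
                rng.choice(
                    ["recruitment", "safety", "futility", "external_results",
                     "other", "unspecified"],
                    p=[0.5, 0.12, 0.12, 0.08, 0.08, 0.1],
                )
            )
            termination_reason = _TERMINATION_TEXTS[cat] or None
            truth.termination_by_trial[nct] = cat

        us = rng.random() < spec.p_us_site
        countries = ([str(c) for c in rng.choice(_COUNTRIES, size=2, replace=False)])
        if us:
            countries.insert(0, "United States")
        version_count = 1 + int(rng.poisson(spec.update_count_mean))
        interventions = [drug]
        if study_type == StudyType.INTERVENTIONAL and rng.random() < 0.5:
            interventions = [f"{drug}|Placebo"]
        sponsors = [str(rng.choice(_SPONSORS))]
        if rng.random() < 0.3:
            other = str(rng.choice(_SPONSORS))
            if other != sponsors[0]:
                sponsors.append(other)

        in_scope = not off_condition and not ineligible
        refs: list[RegistryReference] = []
        trial_articles: list[ArticleRecord] = []

        n_articles = int(rng.poisson(spec.mean_articles_per_trial)) if in_scope else 0
        for _ in range(n_articles):
            pmid = new_pmid()
            lag = max(7, int(round(rng.normal(spec.publication_lag_mean, spec.publication_lag_sd))))
            pub = start + timedelta(days=lag)
            r = rng.random()
            if r < spec.p_protocol_article:
                atype = "protocol"
            elif r < spec.p_protocol_article + spec.p_editorial_article:
                atype = "editorial_or_comment"
            else:
                atype = "result_article"
            channel = str(
                rng.choice(
                    ["registry", "abstract", "dual"],
                    p=[spec.p_registry_link, spec.p_abstract_link, spec.p_dual_link],
                )
            )
            sec_ids = [nct] if channel in ("abstract", "dual") else []
            art = make_article(pmid, title, pub, atype, sec_ids)
            trial_articles.append(art)
            truth.lag_days[(nct, pmid)] = lag
            if channel in ("registry", "dual"):
                refs.append(
                    RegistryReference(
                        citation_text=f"{art.title}. PMID {pmid}.",
                        pmid=pmid,
                        declared_type=ReferenceType.RESULT_REFERENCE,
                    )
                )
                truth.registry_links.add((nct, pmid))
            if channel in ("abstract", "dual"):
                truth.abstract_links.add((nct, pmid))

        if in_scope and rng.random() < spec.p_misdated_reference:
            pmid = new_pmid()
            pub = start - timedelta(days=int(rng.integers(30, 400)))
            art = make_article(pmid, f"Background work on {drug}", pub, "result_article", [])
            trial_articles.append(art)
            refs.append(
                RegistryReference(
                    citation_text=f"{art.title}. PMID {pmid}.",
                    pmid=pmid,
                    declared_type=ReferenceType.RESULT_REFERENCE,
                )
            )
            truth.misdated_links.add((nct, pmid))
        if in_scope and rng.random() < spec.p_missing_article_reference:
            pmid = new_pmid()  # no ArticleRecord is emitted for this one
            refs.append(
                RegistryReference(
                    citation_text=f"Unindexed report. PMID {pmid}.",
                    pmid=pmid,
                    declared_type=ReferenceType.RESULT_REFERENCE,
                )
            )
            truth.missing_article_links.add((nct, pmid))
        if rng.random() < 0.2:
            refs.append(
                RegistryReference(
                    citation_text=f"Review of {drug} pharmacology.",
                    pmid=None,
                    declared_type=ReferenceType.BACKGROUND_REFERENCE,
                )
            )

        trials.append(
            TrialRecord(
                nct_id=nct,
                brief_title=title,
                official_title=f"{title}: a {'Randomized ' if study_type == StudyType.INTERVENTIONAL else ''}Study",
                study_type=study_type,
                overall_status=status,
                phase_labels=phase_labels,
                intervention_names=interventions,
                sponsor_names=sponsors,
                location_countries=countries,
                start_date=start,
                primary_completion_date=pcd,
                registration_date=reg,
                version_count=version_count,
                registry_references=refs,
                has_deposited_results=bool(rng.random() < spec.p_deposited_results),
                termination_reason_text=termination_reason,
                condition_terms=(["COVID-19"] if not off_condition else ["Influenza"]),
            )
        )
        articles.extend(trial_articles)
        if in_scope:
            truth.in_scope_ncts.add(nct)
            truth.phase_by_trial[nct] = phase
            truth.us_site_by_trial[nct] = us
            truth.multiple_updates_by_trial[nct] = version_count - 1 >= 2
            truth.timing_by_trial[nct] = RegistrationTiming(timing)
            if vaccine:
                truth.vaccine_ncts.add(nct)

    # articles occasionally mention a second in-scope trial in the abstract
    in_scope_list = sorted(truth.in_scope_ncts)
    if in_scope_list:
        for art in articles:
            if art.secondary_ids and rng.random() < spec.p_second_trial_on_article:
                other = str(rng.choice(in_scope_list))
                if other not in art.secondary_ids:
                    art.secondary_ids.append(other)
                    truth.abstract_links.add((other, art.pmid))
    # one distractor article pointing at an out-of-scope trial, if any exist
    out_of_scope = [t.nct_id for t in trials if t.nct_id not in truth.in_scope_ncts]
    if out_of_scope:
        articles.append(
            make_article(
                new_pmid(),
                "Commentary on an unrelated study",
                spec.query_date - timedelta(days=100),
                "editorial_or_comment",
                [out_of_scope[0]],
            )
        )

    corpus = Corpus(trials=trials, articles=articles, query_date=spec.query_date)
    return corpus, truth


def _sub(parent: ET.Element, tag: str, text: Optional[str] = None, **attrs) -> ET.Element:
    e = ET.SubElement(parent, tag, attrs)
    if text is not None:
        e.text = text
    return e


def _trial_to_xml(trial: TrialRecord, parent: ET.Element) -> None:
    s = ET.SubElement(parent, "clinical_study")
    idinfo = ET.SubElement(s, "id_info")
    _sub(idinfo, "nct_id", trial.nct_id)
    _sub(s, "brief_title", trial.brief_title)
    if trial.official_title:
        _sub(s, "official_title", trial.official_title)
    sponsors = ET.SubElement(s, "sponsors")
    if trial.sponsor_names:
        lead = ET.SubElement(sponsors, "lead_sponsor")
        _sub(lead, "agency", trial.sponsor_names[0])
        for name in trial.sponsor_names[1:]:
            coll = ET.SubElement(sponsors, "collaborator")
            _sub(coll, "agency", name)
    _sub(s, "overall_status", trial.overall_status.value)
    if trial.start_date:
        _sub(s, "start_date", trial.start_date.isoformat())
    if trial.primary_completion_date:
        _sub(s, "primary_completion_date", trial.primary_completion_date.isoformat())
    if trial.registration_date:
        _sub(s, "study_first_submitted", trial.registration_date.isoformat())
    _sub(s, "study_type", trial.study_type.value)
    for label in trial.phase_labels:
        _sub(s, "phase", label)
    for cond in trial.condition_terms:
        _sub(s, "condition", cond)
    for name in trial.intervention_names:
        iv = ET.SubElement(s, "intervention")
        _sub(iv, "intervention_name", name)
    if trial.location_countries:
        lc = ET.SubElement(s, "location_countries")
        for c in trial.location_countries:
            _sub(lc, "country", c)
    for ref in trial.registry_references:
        if ref.declared_type == ReferenceType.RESULT_REFERENCE:
            r = ET.SubElement(s, "results_reference")
        elif ref.declared_type == ReferenceType.BACKGROUND_REFERENCE:
            r = ET.SubElement(s, "reference")
        else:
            r = ET.SubElement(s, "reference", {"type": ref.declared_type.value})
        _sub(r, "citation", ref.citation_text)
        if ref.pmid:
            _sub(r, "PMID", ref.pmid)
    _sub(s, "version_count", str(trial.version_count))
    _sub(s, "has_deposited_results", "true" if trial.has_deposited_results else "false")
    if trial.termination_reason_text:
        _sub(s, "termination_reason", trial.termination_reason_text)


def _article_to_xml(article: ArticleRecord, parent: ET.Element) -> None:
    pa = ET.SubElement(parent, "PubmedArticle")
    cit = ET.SubElement(pa, "MedlineCitation")
    _sub(cit, "PMID", article.pmid)
    art = ET.SubElement(cit, "Article")
    journal = ET.SubElement(art, "Journal")
    _sub(journal, "Title", article.journal_name)
    _sub(art, "ArticleTitle", article.title)
    if article.publication_date:
        ad = ET.SubElement(art, "ArticleDate")
        _sub(ad, "Year", str(article.publication_date.year))
        _sub(ad, "Month", f"{article.publication_date.month:02d}")
        _sub(ad, "Day", f"{article.publication_date.day:02d}")
    ptl = ET.SubElement(art, "PublicationTypeList")
    for t in article.publication_types:
        _sub(ptl, "PublicationType", t)
    if article.secondary_ids:
        dbl = ET.SubElement(art, "DataBankList")
        db = ET.SubElement(dbl, "DataBank")
        _sub(db, "DataBankName", "ClinicalTrials.gov")
        anl = ET.SubElement(db, "AccessionNumberList")
        for sid in article.secondary_ids:
            _sub(anl, "AccessionNumber", sid)
    if article.mesh_terms:
        mhl = ET.SubElement(cit, "MeshHeadingList")
        for term in article.mesh_terms:
            mh = ET.SubElement(mhl, "MeshHeading")
            _sub(mh, "DescriptorName", term)


def _write_xml(root: ET.Element, path: Path) -> None:
    pretty = minidom.parseString(ET.tostring(root, encoding="unicode")).toprettyxml(indent="  ")
    path.write_text(pretty, encoding="utf-8")


def write_fixture_files(corpus: Corpus, directory: str | Path, delimiter: str = "|") -> dict[str, Path]:
    """Render a corpus as registry XML, AACT-style tables, and MEDLINE XML.

    Also writes the corpus query date; reading any rendering back through
    the ingest module round-trips the records.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    root = ET.Element("clinical_studies")
    for trial in corpus.trials:
        _trial_to_xml(trial, root)
    registry_path = directory / "registry.xml"
    _write_xml(root, registry_path)

    mroot = ET.Element("PubmedArticleSet")
    for article in corpus.articles:
        _article_to_xml(article, mroot)
    medline_path = directory / "medline.xml"
    _write_xml(mroot, medline_path)

    aact_dir = directory / "aact"
    aact_dir.mkdir(exist_ok=True)
    studies_rows, iv_rows, country_rows, sponsor_rows, ref_rows = [], [], [], [], []
    for t in corpus.trials:
        studies_rows.append(
            {
                "nct_id": t.nct_id,
                "brief_title": t.brief_title,
                "official_title": t.official_title or "",
                "study_type": t.study_type.value,
                "overall_status": t.overall_status.value,
                "phase": t.phase_labels[0] if t.phase_labels else "",
                "start_date": t.start_date.isoformat() if t.start_date else "",
                "primary_completion_date": (
                    t.primary_completion_date.isoformat() if t.primary_completion_date else ""
                ),
                "study_first_submitted_date": (
                    t.registration_date.isoformat() if t.registration_date else ""
                ),
                "version_count": t.version_count,
                "has_deposited_results": "true" if t.has_deposited_results else "false",
                "why_stopped": t.termination_reason_text or "",
                "conditions": ";".join(t.condition_terms),
            }
        )
        for name in t.intervention_names:
            iv_rows.append({"nct_id": t.nct_id, "name": name})
        for c in t.location_countries:
            country_rows.append({"nct_id": t.nct_id, "name": c})
        for j, s in enumerate(t.sponsor_names):
            sponsor_rows.append(
                {"nct_id": t.nct_id, "name": s, "lead_or_collaborator": "lead" if j == 0 else "collaborator"}
            )
        for r in t.registry_references:
            ref_rows.append(
                {
                    "nct_id": t.nct_id,
                    "pmid": r.pmid or "",
                    "citation": r.citation_text,
                    "reference_type": r.declared_type.value,
                }
            )
    for name, rows, cols in (
        ("studies", studies_rows, None),
        ("interventions", iv_rows, ["nct_id", "name"]),
        ("countries", country_rows, ["nct_id", "name"]),
        ("sponsors", sponsor_rows, ["nct_id", "name", "lead_or_collaborator"]),
        ("references", ref_rows, ["nct_id", "pmid", "citation", "reference_type"]),
    ):
        df = pd.DataFrame(rows, columns=cols) if cols else pd.DataFrame(rows)
        if df.empty and cols is None:
            df = pd.DataFrame(columns=["nct_id"])
        df.to_csv(aact_dir / f"{name}.txt", sep=delimiter, index=False, encoding="utf-8")

    meta_path = directory / "meta.json"
    meta_path.write_text(
        json.dumps(
            {"query_date": corpus.query_date.isoformat() if corpus.query_date else None}
        ),
        encoding="utf-8",
    )
    return {
        "registry_xml": registry_path,
        "medline_xml": medline_path,
        "aact_dir": aact_dir,
        "meta": meta_path,
    }


def write_ledger(truth: GroundTruth, path: str | Path, delimiter: str = ",") -> Path:
    """Write the planted link-level ground truth as a delimited file."""
    rows = []
    for nct, pmid in sorted(truth.registry_links):
        rows.append({"nct_id": nct, "pmid": pmid, "kind": "registry_link"})
    for nct, pmid in sorted(truth.abstract_links):
        rows.append({"nct_id": nct, "pmid": pmid, "kind": "abstract_link"})
    for nct, pmid in sorted(truth.misdated_links):
        rows.append({"nct_id": nct, "pmid": pmid, "kind": "misdated_reference"})
    for nct, pmid in sorted(truth.missing_article_links):
        rows.append({"nct_id": nct, "pmid": pmid, "kind": "missing_article_reference"})
    path = Path(path)
    pd.DataFrame(rows, columns=["nct_id", "pmid", "kind"]).to_csv(
        path, sep=delimiter, index=False, encoding="utf-8"
    )
    return path
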