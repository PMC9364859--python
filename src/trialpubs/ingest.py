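"""Readers for registry study records and article metadata.

Three input dialects are supported and produce identical in-memory records
for the same content:

* registry-style study XML (``<clinical_study>`` elements),
* AACT-style delimited tables (studies / interventions / countries /
  sponsors / references sharing the ``nct_id`` key),
* MEDLINE-style citation XML (``<PubmedArticle>`` elements).

Every reader logs counts read and rejected, with reasons.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import (
    ArticleRecord,
    DateParseError,
    OverallStatus,
    ReferenceType,
    RegistryReference,
    StudyType,
    TrialRecord,
    parse_flexible_date,
    validate_nct_id,
)

log = logging.getLogger(__name__)

__all__ = [
    "Corpus",
    "IngestError",
    "read_registry_xml",
    "read_aact_tables",
    "read_medline_xml",
    "select_condition_studies",
    "filter_eligible",
]


class IngestError(ValueError):
    """Structured reader error (malformed file, missing table or column)."""


@dataclass
class Corpus:
    """A trial set and an article set retrieved at one query date."""

    trials: list[TrialRecord] = field(default_factory=list)
    articles: list[ArticleRecord] = field(default_factory=list)
    query_date: Optional[date] = None

    def __post_init__(self) -> None:
        ncts = [t.nct_id for t in self.trials]
        if len(ncts) != len(set(ncts)):
            dup = sorted({n for n in ncts if ncts.count(n) > 1})
            raise IngestError(f"duplicate nct_id values in corpus: {dup}")
        pmids = [a.pmid for a in self.articles]
        if len(pmids) != len(set(pmids)):
            dup = sorted({p for p in pmids if pmids.count(p) > 1})
            raise IngestError(f"duplicate pmid values in corpus: {dup}")

    def article_lookup(self) -> dict[str, ArticleRecord]:
        return {a.pmid: a for a in self.articles}

    def trial_lookup(self) -> dict[str, TrialRecord]:
        return {t.nct_id: t for t in self.trials}


def _text(elem: Optional[ET.Element], default: str = "") -> str:
    return elem.text.strip() if elem is not None and elem.text else default


def _opt_date(text: str, context: str) -> Optional[date]:
    if not text:
        return None
    try:
        d, _ = parse_flexible_date(text)
        return d
    except DateParseError:
        log.warning("unparseable date %r in %s; treated as missing", text, context)
        return None


def _trial_from_study_elem(elem: ET.Element, index: int) -> Optional[TrialRecord]:
    nct_id = _text(elem.find("id_info/nct_id")) or _text(elem.find("nct_id"))
    if not validate_nct_id(nct_id):
        log.warning("record %d rejected: missing or invalid nct_id %r", index, nct_id)
        return None
    refs: list[RegistryReference] = []
    for tag, rtype in (
        ("results_reference", ReferenceType.RESULT_REFERENCE),
        ("reference", ReferenceType.BACKGROUND_REFERENCE),
    ):
        for ref in elem.findall(tag):
            declared = ref.get("type")
            refs.append(
                RegistryReference(
                    citation_text=_text(ref.find("citation")),
                    pmid=_text(ref.find("PMID")) or None,
                    declared_type=ReferenceType.from_label(declared) if declared else rtype,
                )
            )
    sponsors = [_text(elem.find("sponsors/lead_sponsor/agency"))] if elem.find(
        "sponsors/lead_sponsor/agency"
    ) is not None else []
    sponsors += [_text(s) for s in elem.findall("sponsors/collaborator/agency")]
    return TrialRecord(
        nct_id=nct_id,
        brief_title=_text(elem.find("brief_title")),
        official_title=_text(elem.find("official_title")) or None,
        study_type=StudyType.from_label(_text(elem.find("study_type"), "Interventional")),
        overall_status=OverallStatus.from_label(_text(elem.find("overall_status"), "unknown")),
        phase_labels=[_text(p) for p in elem.findall("phase") if _text(p)],
        intervention_names=[
            _text(i.find("intervention_name")) for i in elem.findall("intervention")
        ],
        sponsor_names=[s for s in sponsors if s],
        location_countries=[_text(c) for c in elem.findall("location_countries/country")],
        start_date=_opt_date(_text(elem.find("start_date")), nct_id),
        primary_completion_date=_opt_date(
            _text(elem.find("primary_completion_date")), nct_id
        ),
        registration_date=_opt_date(
            _text(elem.find("study_first_submitted")) or _text(elem.find("registration_date")),
            nct_id,
        ),
        version_count=int(_text(elem.find("version_count"), "1")),
        registry_references=refs,
        has_deposited_results=_text(elem.find("has_deposited_results"), "false").lower()
        in ("true", "yes", "1"),
        termination_reason_text=_text(elem.find("termination_reason")) or None,
        condition_terms=[_text(c) for c in elem.findall("condition") if _text(c)],
    )


def read_registry_xml(path: str | Path) -> list[TrialRecord]:
    """Read registry-style study XML into :class:`TrialRecord` objects.

    References under a result-typed reference element get
    ``declared_type=result_reference``; records lacking a valid NCT id are
    rejected with a logged reason.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise IngestError(f"malformed registry XML {path}: {exc}") from exc
    studies = (
        [root] if root.tag == "clinical_study" else root.findall(".//clinical_study")
    )
    trials: list[TrialRecord] = []
    rejected = 0
    for i, elem in enumerate(studies):
        rec = _trial_from_study_elem(elem, i)
        if rec is None:
            rejected += 1
        else:
            trials.append(rec)
    log.info("read_registry_xml: %d read, %d rejected from %s", len(trials), rejected, path)
    return trials


_AACT_REQUIRED = {
    "studies": ["nct_id"],
    "interventions": ["nct_id", "name"],
    "countries": ["nct_id", "name"],
    "references": ["nct_id", "pmid", "citation", "reference_type"],
    "sponsors": ["nct_id", "name"],
}


def _load_table(directory: Path, name: str, delimiter: str) -> Optional[pd.DataFrame]:
    for fname in (f"{name}.txt", f"{name}.csv", f"{name}.tsv"):
        p = directory / fname
        if p.exists():
            df = pd.read_csv(p, sep=delimiter, dtype=str, keep_default_na=False)
            missing = [c for c in _AACT_REQUIRED.get(name, []) if c not in df.columns]
            if missing:
                raise IngestError(f"table {name!r} missing required columns {missing}")
            return df
    return None


def read_aact_tables(directory: str | Path, delimiter: str = "|") -> list[TrialRecord]:
    """Read AACT-style delimited tables into :class:`TrialRecord` objects.

    The directory must hold a ``studies`` table; ``interventions``,
    ``countries``, ``sponsors``, and ``references`` tables are joined on the
    ``nct_id`` key when present. Public AACT flat files are pipe-delimited,
    hence the default.
    """
    directory = Path(directory)
    studies = _load_table(directory, "studies", delimiter)
    if studies is None:
        raise IngestError(f"missing required table 'studies' in {directory}")
    if studies["nct_id"].duplicated().any():
        dup = sorted(studies.loc[studies["nct_id"].duplicated(), "nct_id"].unique())
        raise IngestError(f"duplicate nct_id rows in studies table: {dup}")

    def grouped(name: str) -> dict[str, pd.DataFrame]:
        df = _load_table(directory, name, delimiter)
        if df is None:
            return {}
        return {k: g for k, g in df.groupby("nct_id", sort=False)}

    interventions = grouped("interventions")
    countries = grouped("countries")
    sponsors = grouped("sponsors")
    references = grouped("references")

    trials: list[TrialRecord] = []
    rejected = 0
    for _, row in studies.iterrows():
        nct = row["nct_id"]
        if not validate_nct_id(nct):
            log.warning("studies row rejected: invalid nct_id %r", nct)
            rejected += 1
            continue
        refs = []
        for _, r in references.get(nct, pd.DataFrame()).iterrows():
            refs.append(
                RegistryReference(
                    citation_text=r.get("citation", ""),
                    pmid=r["pmid"] or None,
                    declared_type=ReferenceType.from_label(r["reference_type"]),
                )
            )
        spon = sponsors.get(nct)
        sponsor_names: list[str] = []
        if spon is not None:
            if "lead_or_collaborator" in spon.columns:
                spon = pd.concat(
                    [
                        spon[spon["lead_or_collaborator"] == "lead"],
                        spon[spon["lead_or_collaborator"] != "lead"],
                    ]
                )
            sponsor_names = [s for s in spon["name"].tolist() if s]
        trials.append(
            TrialRecord(
                nct_id=nct,
                brief_title=row.get("brief_title", ""),
                official_title=row.get("official_title") or None,
                study_type=StudyType.from_label(row.get("study_type", "Interventional")),
                overall_status=OverallStatus.from_label(row.get("overall_status", "unknown")),
                phase_labels=[p for p in [row.get("phase", "")] if p],
                intervention_names=(
                    interventions.get(nct, pd.DataFrame({"name": []}))["name"].tolist()
                ),
                sponsor_names=sponsor_names,
                location_countries=(
                    countries.get(nct, pd.DataFrame({"name": []}))["name"].tolist()
                ),
                start_date=_opt_date(row.get("start_date", ""), nct),
                primary_completion_date=_opt_date(
                    row.get("primary_completion_date", ""), nct
                ),
                registration_date=_opt_date(
                    row.get("study_first_submitted_date", "")
                    or row.get("registration_date", ""),
                    nct,
                ),
                version_count=int(row.get("version_count") or 1),
                registry_references=refs,
                has_deposited_results=str(row.get("has_deposited_results", "false")).lower()
                in ("true", "yes", "1", "t"),
                termination_reason_text=row.get("why_stopped")
                or row.get("termination_reason")
                or None,
                condition_terms=[
                    c.strip()
                    for c in str(row.get("conditions", "")).split(";")
                    if c.strip()
                ],
            )
        )
    log.info(
        "read_aact_tables: %d read, %d rejected from %s", len(trials), rejected, directory
    )
    return trials


def _article_from_citation(elem: ET.Element, index: int) -> Optional[ArticleRecord]:
    cit = elem.find("MedlineCitation")
    if cit is None:
        cit = elem
    pmid = _text(cit.find("PMID"))
    if not pmid.isdigit() or not pmid:
        log.warning("citation %d rejected: missing PMID", index)
        return None
    art = cit.find("Article")
    title = _text(art.find("ArticleTitle")) if art is not None else ""
    journal = _text(art.find("Journal/Title")) if art is not None else ""
    ptypes = (
        [_text(p) for p in art.findall("PublicationTypeList/PublicationType")]
        if art is not None
        else []
    )
    pub_date: Optional[date] = None
    if art is not None:
        ad = art.find("ArticleDate")
        if ad is not None:
            y, m, d = _text(ad.find("Year")), _text(ad.find("Month")), _text(ad.find("Day"))
            if y:
                pub_date = _opt_date(f"{y}-{int(m or 1):02d}-{int(d or 1):02d}", f"PMID {pmid}")
        if pub_date is None:
            pd_elem = art.find("Journal/JournalIssue/PubDate")
            if pd_elem is not None:
                y = _text(pd_elem.find("Year"))
                m = _text(pd_elem.find("Month"))
                d = _text(pd_elem.find("Day"))
                if y and m:
                    text = f"{m} {d}, {y}" if d else f"{m} {y}"
                    pub_date = _opt_date(text, f"PMID {pmid}")
                elif y:
                    pub_date = _opt_date(f"{y}-01", f"PMID {pmid}")
    secondary: list[str] = []
    if art is not None:
        for acc in art.findall("DataBankList/DataBank/AccessionNumberList/AccessionNumber"):
            if _text(acc):
                secondary.append(_text(acc))
    for oid in cit.findall("OtherID"):
        if _text(oid):
            secondary.append(_text(oid))
    mesh = [
        _text(m.find("DescriptorName"))
        for m in cit.findall("MeshHeadingList/MeshHeading")
        if _text(m.find("DescriptorName"))
    ]
    return ArticleRecord(
        pmid=pmid,
        title=title,
        publication_date=pub_date,
        publication_types=ptypes,
        journal_name=journal,
        mesh_terms=mesh,
        secondary_ids=secondary,
    )


def read_medline_xml(path: str | Path) -> list[ArticleRecord]:
    """Read MEDLINE/PubMed-style citation XML into :class:`ArticleRecord`.

    Secondary identifiers are taken from databank accession numbers (and
    ``OtherID`` fields); publication types are preserved verbatim. Citations
    lacking a PMID are rejected with a logged reason.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise IngestError(f"malformed MEDLINE XML {path}: {exc}") from exc
    citations = root.findall(".//PubmedArticle") or root.findall(".//MedlineCitation")
    articles: list[ArticleRecord] = []
    rejected = 0
    for i, elem in enumerate(citations):
        rec = _article_from_citation(elem, i)
        if rec is None:
            rejected += 1
        else:
            articles.append(rec)
    log.info("read_medline_xml: %d read, %d rejected from %s", len(articles), rejected, path)
    return articles


def select_condition_studies(
    trials: Iterable[TrialRecord], keywords: list[str]
) -> list[TrialRecord]:
    """Keep trials mentioning any keyword in a title or condition term.

    Matching is case-insensitive over brief title, official title, and the
    registry condition terms — not intervention strings or summaries, so the
    filter stays auditable against the registry's own condition indexing.
    """
    if not keywords:
        raise ValueError("keywords must be nonempty")
    lowered = [k.lower() for k in keywords]

    def hit(t: TrialRecord) -> bool:
        fields = [t.brief_title, t.official_title or "", *t.condition_terms]
        return any(k in f.lower() for f in fields for k in lowered)

    kept = [t for t in trials if hit(t)]
    log.info("select_condition_studies: kept %d trials", len(kept))
    return kept


def filter_eligible(
    trials: Iterable[TrialRecord], eligible: Iterable[OverallStatus]
) -> list[TrialRecord]:
    """Keep exactly the trials whose overall status is in ``eligible``."""
    eligible = frozenset(eligible)
    kept = [t for t in trials if t.overall_status in eligible]
    log.info("filter_eligible: kept %d trials", len(kept))
    return kept
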