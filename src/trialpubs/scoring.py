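"""Per-publication attention score, ranking, and the prioritized shortlist.

The attention score orders trial–publication pairs so the most significant
result articles surface first. It is an additive composite with configurable
weights over six components: recency of the publication, resolved trial
phase, the trial's intervention significance, registry record update count
(capped), presence of a US site, and an article-type modifier that penalizes
protocols, editorials and other non-result articles. For observational
studies and registries the phase and intervention components are omitted —
phase is not meaningful there — and everything else behaves identically.

The *prioritized shortlist* keeps result articles (not protocols) from
phase-3 trials with at least one US site and multiple registry record
updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Optional

from .interventions import (
    InterventionGroup,
    PhaseCategory,
    normalize_intervention,
    split_interventions,
    trial_phase,
)
from .linking import LinkTable
from .model import ArticleRecord, Config, StudyType, TrialRecord

log = logging.getLogger(__name__)

__all__ = [
    "ArticleType",
    "ScoredPublication",
    "classify_article_type",
    "recency_points",
    "attention_score",
    "score_publications",
    "rank_publications",
    "shortlist",
    "score_observational",
]


class ArticleType(str, Enum):
    RESULT_ARTICLE = "result_article"
    PROTOCOL = "protocol"
    EDITORIAL_OR_COMMENT = "editorial_or_comment"
    OTHER = "other"


_EDITORIAL_LABELS = ("editorial", "comment", "letter")
_RESULT_LABELS = ("clinical trial", "journal article", "randomized controlled trial")


def classify_article_type(article: ArticleRecord) -> ArticleType:
    """Classify a publication; rule order: protocol, editorial, result, other.

    Protocol if any publication type or the title contains the stem
    "protocol"; editorial/comment/letter labels next; then result article
    for clinical-trial or journal-article labels; everything else is other.
    """
    types = [t.lower() for t in article.publication_types]
    title = article.title.lower()
    if any("protocol" in t for t in types) or "protocol" in title:
        return ArticleType.PROTOCOL
    if any(lbl in t for t in types for lbl in _EDITORIAL_LABELS):
        return ArticleType.EDITORIAL_OR_COMMENT
    if any(lbl in t for t in types for lbl in _RESULT_LABELS):
        return ArticleType.RESULT_ARTICLE
    return ArticleType.OTHER


def recency_points(
    publication_date: date, query_date: date, window_days: int = 730
) -> float:
    """Linear recency in [0, 1]: 1 at the query date, 0 at the window edge.

    Publications dated after the query date clamp to 1.
    """
    age = (query_date - publication_date).days
    if age < 0:
        return 1.0
    return max(0.0, 1.0 - age / window_days)


@dataclass
class ScoredPublication:
    """One trial–publication pair with its score and display metadata."""

    nct_id: str
    pmid: str
    article_title: str
    publication_date: Optional[date]
    intervention_display: str
    trial_phase: PhaseCategory
    article_type: ArticleType
    has_us_site: bool
    has_multiple_updates: bool
    attention_score: float
    shortlisted: bool = False
    sponsor: str = ""
    journal: str = ""
    trial_has_deposited_results: bool = False
    study_type: StudyType = StudyType.INTERVENTIONAL
    flags: tuple[str, ...] = ()

    @property
    def is_result_article(self) -> bool:
        return self.article_type == ArticleType.RESULT_ARTICLE


def attention_score(
    *,
    phase_value: float,
    recency: float,
    intervention_significance: float,
    update_count: int,
    has_us_site: bool,
    article_type: ArticleType,
    weights: Mapping[str, float],
    update_cap: int = 20,
    include_phase: bool = True,
) -> float:
    """Additive attention score; deterministic for fixed inputs.

    ``include_phase=False`` drops the phase and intervention components
    (observational studies and registries).
    """
    score = (
        weights["recency"] * recency
        + weights["updates"] * min(update_count, update_cap) / update_cap
        + (weights["us_site"] if has_us_site else 0.0)
        + weights[f"type_{article_type.value}"]
    )
    if include_phase:
        score += weights["phase"] * phase_value
        score += weights["intervention"] * intervention_significance
    return score


def _trial_intervention_significance(
    trial: TrialRecord,
    groups_by_name: Mapping[str, InterventionGroup],
    config: Config,
) -> float:
    """Significance component: the trial's best non-stop-list intervention.

    With ``intervention_aggregate="mean"`` the mean over the trial's
    interventions is used instead of the maximum.
    """
    stop = {normalize_intervention(s) for s in config.intervention_stop_list}
    scores = []
    for raw in trial.intervention_names:
        for part in split_interventions(raw):
            canon = normalize_intervention(part, config.intervention_synonyms)
            if canon and canon not in stop and canon in groups_by_name:
                scores.append(groups_by_name[canon].significance_score)
    if not scores:
        return 0.0
    if config.intervention_aggregate == "mean":
        return sum(scores) / len(scores)
    return max(scores)


def has_us_site(trial: TrialRecord, us_country_name: str = "United States") -> bool:
    return any(c.strip() == us_country_name for c in trial.location_countries)


def _display_interventions(trial: TrialRecord, config: Config) -> str:
    stop = {normalize_intervention(s) for s in config.intervention_stop_list}
    parts: list[str] = []
    for raw in trial.intervention_names:
        for part in split_interventions(raw):
            if normalize_intervention(part, config.intervention_synonyms) not in stop:
                if part not in parts:
                    parts.append(part)
    return "|".join(parts)


def score_publications(
    link_table: LinkTable,
    trials: Mapping[str, TrialRecord] | Iterable[TrialRecord],
    articles: Mapping[str, ArticleRecord] | Iterable[ArticleRecord],
    intervention_groups: Iterable[InterventionGroup],
    query_date: date,
    config: Optional[Config] = None,
) -> list[ScoredPublication]:
    """Assemble and score every linked trial–publication pair.

    Missing components (no publication date, no phase) score as 0 for that
    component and the pair is flagged, never dropped.
    """
    config = config or Config()
    if not isinstance(trials, Mapping):
        trials = {t.nct_id: t for t in trials}
    if not isinstance(articles, Mapping):
        articles = {a.pmid: a for a in articles}
    groups_by_name = {g.canonical_name: g for g in intervention_groups}

    out: list[ScoredPublication] = []
    for link in link_table.links:
        trial = trials.get(link.nct_id)
        article = articles.get(link.pmid)
        if trial is None or article is None:
            log.warning("skipping link %s without metadata", link.pair)
            continue
        flags = list(link.flags)
        atype = classify_article_type(article)
        phase = trial_phase(trial)
        if article.publication_date is not None:
            rec = recency_points(
                article.publication_date, query_date, config.recency_window_days
            )
        else:
            rec = 0.0
            flags.append("missing_publication_date")
        interventional = trial.study_type == StudyType.INTERVENTIONAL
        score = attention_score(
            phase_value=config.phase_values[phase.value],
            recency=rec,
            intervention_significance=_trial_intervention_significance(
                trial, groups_by_name, config
            ),
            update_count=trial.version_count - 1,
            has_us_site=has_us_site(trial, config.us_country_name),
            article_type=atype,
            weights=config.attention_weights,
            update_cap=config.update_count_cap,
            include_phase=interventional,
        )
        multiple_updates = (
            trial.version_count - 1 >= config.multiple_updates_threshold
        )
        pub = ScoredPublication(
            nct_id=trial.nct_id,
            pmid=article.pmid,
            article_title=article.title,
            publication_date=article.publication_date,
            intervention_display=_display_interventions(trial, config),
            trial_phase=phase,
            article_type=atype,
            has_us_site=has_us_site(trial, config.us_country_name),
            has_multiple_updates=multiple_updates,
            attention_score=score,
            sponsor=trial.sponsor_names[0] if trial.sponsor_names else "",
            journal=article.journal_name,
            trial_has_deposited_results=trial.has_deposited_results,
            study_type=trial.study_type,
            flags=tuple(flags),
        )
        pub.shortlisted = (
            pub.is_result_article
            and phase == PhaseCategory.PHASE_3
            and pub.has_us_site
            and pub.has_multiple_updates
        )
        out.append(pub)
    return out


def rank_publications(pubs: Iterable[ScoredPublication]) -> list[ScoredPublication]:
    """Descending by score; ties by newer publication date, then PMID."""
    def key(p: ScoredPublication):
        d = p.publication_date or date.min
        return (-p.attention_score, -d.toordinal(), int(p.pmid))

    return sorted(pubs, key=key)


def shortlist(pubs: Iterable[ScoredPublication]) -> list[ScoredPublication]:
    """Result articles from phase-3 trials with a US site and multiple updates."""
    return [p for p in pubs if p.shortlisted]


def score_observational(
    pubs_inputs: dict,
    config: Optional[Config] = None,
) -> float:
    """Attention score for an observational study or registry publication.

    Identical to the interventional formula with the phase and intervention
    components omitted. Raises for interventional trials.
    """
    config = config or Config()
    if pubs_inputs.get("study_type", StudyType.OBSERVATIONAL) == StudyType.INTERVENTIONAL:
        raise ValueError("score_observational applies only to observational/registry studies")
    return attention_score(
        phase_value=0.0,
        recency=pubs_inputs["recency"],
        intervention_significance=0.0,
        update_count=pubs_inputs["update_count"],
        has_us_site=pubs_inputs["has_us_site"],
        article_type=pubs_inputs["article_type"],
        weights=config.attention_weights,
        update_cap=config.update_count_cap,
        include_phase=False,
    )
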