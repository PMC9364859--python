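"""Categorical analyses over trials and their linked publications.

Covers registration timing (did the study register before, during, or after
its conduct), publication lag relative to trial start, publishing before
formal completion, result-deposition categories, termination-reason
classification from free text, and the vaccine-title subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .linking import LinkTable
from .model import ArticleRecord, DEFAULT_TERMINATION_RULES, OverallStatus, TrialRecord

log = logging.getLogger(__name__)

__all__ = [
    "RegistrationTiming",
    "DepositionCategory",
    "TerminationCategory",
    "TimingClassification",
    "registration_timing",
    "days_to_publication",
    "published_before_completion",
    "deposition_category",
    "termination_category",
    "vaccine_subset",
]


class RegistrationTiming(str, Enum):
    PRIOR = "prior"
    DURING = "during"
    AFTER = "after"
    INDETERMINATE = "indeterminate"


class DepositionCategory(str, Enum):
    DEPOSIT_ONLY = "deposit_only"
    ARTICLE_ONLY = "article_only"
    BOTH = "both"
    NEITHER = "neither"


class TerminationCategory(str, Enum):
    RECRUITMENT = "recruitment"
    SAFETY = "safety"
    FUTILITY = "futility"
    EXTERNAL_RESULTS = "external_results"
    OTHER = "other"
    UNSPECIFIED = "unspecified"


@dataclass
class TimingClassification:
    nct_id: str
    registration_timing: RegistrationTiming
    days_start_to_publication: Optional[int] = None
    published_before_completion: Optional[bool] = None


def registration_timing(trial: TrialRecord) -> RegistrationTiming:
    """When the study registered relative to its start and primary completion.

    Boundary convention (ties resolve to the earlier class): registration on
    the start date is *prior*; registration on the primary completion date
    is *during*. When the completion date is missing but registration
    follows the start and the study has not ended, *during* is still
    assignable; any other missing date makes the class indeterminate.
    """
    reg, start, pcd = (
        trial.registration_date,
        trial.start_date,
        trial.primary_completion_date,
    )
    if reg is None or start is None:
        return RegistrationTiming.INDETERMINATE
    if reg <= start:
        return RegistrationTiming.PRIOR
    if pcd is None:
        if not trial.overall_status.is_ended:
            return RegistrationTiming.DURING
        return RegistrationTiming.INDETERMINATE
    return RegistrationTiming.DURING if reg <= pcd else RegistrationTiming.AFTER


def days_to_publication(trial: TrialRecord, article: ArticleRecord) -> Optional[int]:
    """Whole days from trial start to article publication (negative allowed).

    The trial start date anchors the lag because registry completion dates
    are often anticipated, not actual. Returns None if either date is
    missing.
    """
    if trial.start_date is None or article.publication_date is None:
        return None
    return (article.publication_date - trial.start_date).days


def published_before_completion(trial: TrialRecord, article: ArticleRecord) -> bool:
    """True when a result article appeared before the trial formally finished.

    A trial not yet completed or terminated has, by definition, published
    early; otherwise the article date is compared to the primary completion
    date.
    """
    if not trial.overall_status.is_ended:
        return True
    if trial.primary_completion_date is None or article.publication_date is None:
        return False
    return article.publication_date < trial.primary_completion_date


def deposition_category(trial: TrialRecord, link_table: LinkTable) -> DepositionCategory:
    """Cross of registry result deposition x having >= 1 valid article link."""
    has_article = any(
        l.is_valid_result_link for l in link_table.links if l.nct_id == trial.nct_id
    )
    if trial.has_deposited_results and has_article:
        return DepositionCategory.BOTH
    if trial.has_deposited_results:
        return DepositionCategory.DEPOSIT_ONLY
    if has_article:
        return DepositionCategory.ARTICLE_ONLY
    return DepositionCategory.NEITHER


def termination_category(
    reason_text: Optional[str],
    rules: Optional[list[tuple[str, list[str]]]] = None,
) -> TerminationCategory:
    """Keyword-rule classification of a termination reason.

    Rules are an ordered (category, stems) table; the first category whose
    stem occurs in the lowercased text wins. Empty or missing text is
    unspecified; text matching no rule is other. Total and deterministic
    over arbitrary text.
    """
    if reason_text is None or not reason_text.strip():
        return TerminationCategory.UNSPECIFIED
    text = reason_text.lower()
    for category, stems in rules if rules is not None else DEFAULT_TERMINATION_RULES:
        if any(stem in text for stem in stems):
            return TerminationCategory(category)
    return TerminationCategory.OTHER


def vaccine_subset(
    trials: Iterable[TrialRecord], term: str = "vaccine"
) -> list[TrialRecord]:
    """Trials whose brief or official title contains the term (case-insensitive).

    Title search is the operative definition because the registry does not
    capture vaccines as a distinct intervention type; an intervention string
    mentioning the term does not qualify.
    """
    t = term.lower()
    return [
        x
        for x in trials
        if t in x.brief_title.lower() or t in (x.official_title or "").lower()
    ]


def classify_trials(
    trials: Iterable[TrialRecord],
    link_table: LinkTable,
    articles_by_pmid: dict[str, ArticleRecord],
) -> list[dict]:
    """Joined per-trial classification rows for reporting."""
    rows = []
    links_by_trial: dict[str, list[str]] = {}
    for l in link_table.links:
        links_by_trial.setdefault(l.nct_id, []).append(l.pmid)
    for trial in trials:
        lags = []
        early = []
        for pmid in links_by_trial.get(trial.nct_id, []):
            art = articles_by_pmid.get(pmid)
            if art is None:
                continue
            lag = days_to_publication(trial, art)
            if lag is not None:
                lags.append(lag)
            early.append(published_before_completion(trial, art))
        rows.append(
            {
                "nct_id": trial.nct_id,
                "registration_timing": registration_timing(trial).value,
                "deposition_category": deposition_category(trial, link_table).value,
                "termination_category": (
                    termination_category(trial.termination_reason_text).value
                    if trial.overall_status == OverallStatus.TERMINATED
                    else ""
                ),
                "mean_days_to_publication": (sum(lags) / len(lags)) if lags else None,
                "any_published_before_completion": any(early) if early else False,
                "is_vaccine_trial": bool(vaccine_subset([trial])),
            }
        )
    return rows
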