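"""Trial–article link construction from the two structured channels.

A trial can point at a publication (a result-typed reference inside its
registry record: the *registry* channel) and a publication can point back at
a trial (its indexed secondary identifier naming the trial: the *abstract*
channel). This module extracts candidates from both channels, removes
registry references that are misclassified as result references (detected by
the article predating the trial's start), and merges the channels into one
link table with the three counts the analysis reports: channel
*combinations*, distinct (trial, article) *pairs*, and distinct *articles*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import ArticleRecord, InvalidationReason, LinkRecord, TrialRecord

log = logging.getLogger(__name__)

__all__ = [
    "LinkTable",
    "extract_registry_links",
    "filter_misclassified",
    "extract_abstract_links",
    "merge_links",
    "trials_with_publications",
]


@dataclass
class LinkTable:
    """Merged link table plus the registry links removed as misclassified."""

    links: list[LinkRecord] = field(default_factory=list)
    removed: list[LinkRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [l.pair for l in self.links]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (nct_id, pmid) pairs in link table")
        overlap = set(pairs) & {l.pair for l in self.removed}
        if overlap:
            raise ValueError(f"links present in both kept and removed: {overlap}")

    @property
    def combinations(self) -> int:
        """Total (pair, channel) occurrences — the per-channel counts summed."""
        return sum(len(l.channels) for l in self.links)

    @property
    def distinct_pairs(self) -> int:
        return len(self.links)

    @property
    def distinct_articles(self) -> int:
        return len({l.pmid for l in self.links})

    @property
    def dual_channel_pairs(self) -> int:
        return sum(1 for l in self.links if len(l.channels) == 2)

    def channel_count(self, channel: str) -> int:
        return sum(1 for l in self.links if channel in l.channels)

    def links_for_trial(self, nct_id: str) -> list[LinkRecord]:
        return [l for l in self.links if l.nct_id == nct_id]


def extract_registry_links(
    trials: Iterable[TrialRecord],
    articles: Mapping[str, ArticleRecord] | None = None,
) -> list[LinkRecord]:
    """Candidate links from result-typed references in the study records.

    One candidate per (trial, result reference carrying a PMID) pair,
    deduplicated within a trial; references without a PMID are counted in
    the log but produce no link. Article metadata is not required here —
    missing articles are handled by :func:`filter_misclassified`.
    """
    out: list[LinkRecord] = []
    no_pmid = 0
    for trial in trials:
        seen: set[str] = set()
        for ref in trial.registry_references:
            if ref.declared_type.value != "result_reference":
                continue
            if not ref.pmid:
                no_pmid += 1
                continue
            if ref.pmid in seen:
                continue
            seen.add(ref.pmid)
            out.append(
                LinkRecord(nct_id=trial.nct_id, pmid=ref.pmid, channels=frozenset({"registry"}))
            )
    log.info(
        "extract_registry_links: %d candidates, %d result references without PMID",
        len(out),
        no_pmid,
    )
    return out


def filter_misclassified(
    links: Iterable[LinkRecord],
    trials: Mapping[str, TrialRecord] | Iterable[TrialRecord],
    articles: Mapping[str, ArticleRecord] | Iterable[ArticleRecord],
    strictly_before: bool = True,
) -> tuple[list[LinkRecord], list[LinkRecord]]:
    """Split registry candidates into (kept, removed) by publication date.

    A registry reference declared as a result reference cannot report the
    trial's results if the article appeared before the trial started; such
    links are removed with reason ``predates_trial_start``. Links whose PMID
    has no article metadata are removed with reason ``missing_article``.
    An article published exactly on the trial start date is kept (the
    boundary is strict by default and configurable). A trial with no start
    date cannot be checked: its links are kept and flagged, never silently
    removed.
    """
    if not isinstance(trials, Mapping):
        trials = {t.nct_id: t for t in trials}
    if not isinstance(articles, Mapping):
        articles = {a.pmid: a for a in articles}
    kept: list[LinkRecord] = []
    removed: list[LinkRecord] = []
    for link in links:
        article = articles.get(link.pmid)
        if article is None:
            removed.append(
                LinkRecord(
                    nct_id=link.nct_id,
                    pmid=link.pmid,
                    channels=link.channels,
                    is_valid_result_link=False,
                    invalidation_reason=InvalidationReason.MISSING_ARTICLE,
                )
            )
            continue
        trial = trials.get(link.nct_id)
        start = trial.start_date if trial is not None else None
        if start is None:
            kept.append(
                LinkRecord(
                    nct_id=link.nct_id,
                    pmid=link.pmid,
                    channels=link.channels,
                    flags=("missing_start_date",),
                )
            )
            continue
        pub = article.publication_date
        predates = pub is not None and (
            pub < start if strictly_before else pub <= start
        )
        if predates:
            removed.append(
                LinkRecord(
                    nct_id=link.nct_id,
                    pmid=link.pmid,
                    channels=link.channels,
                    is_valid_result_link=False,
                    invalidation_reason=InvalidationReason.PREDATES_TRIAL_START,
                )
            )
        else:
            kept.append(link)
    log.info("filter_misclassified: kept %d, removed %d", len(kept), len(removed))
    return kept, removed


def extract_abstract_links(
    trials: Iterable[TrialRecord], articles: Iterable[ArticleRecord]
) -> list[LinkRecord]:
    """Links from articles whose secondary identifier names an in-scope trial.

    One link per (article, distinct NCT secondary id matching an in-scope
    trial); identifiers of out-of-scope trials produce nothing, and a trial
    listed twice in one article yields one link.
    """
    in_scope = {t.nct_id for t in trials}
    out: list[LinkRecord] = []
    for article in articles:
        for nct in article.nct_secondary_ids():
            if nct in in_scope:
                out.append(
                    LinkRecord(nct_id=nct, pmid=article.pmid, channels=frozenset({"abstract"}))
                )
    log.info("extract_abstract_links: %d links", len(out))
    return out


def merge_links(
    registry_kept: Iterable[LinkRecord], abstract: Iterable[LinkRecord]
) -> LinkTable:
    """Merge the two channels into one table, one row per (trial, article).

    Pairs found by both channels become a single record with
    ``channels={registry, abstract}``; ``combinations`` therefore equals the
    sum of the per-channel counts while ``distinct_pairs`` counts merged
    rows once.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    flags: dict[tuple[str, str], tuple[str, ...]] = {}
    for link in list(registry_kept) + list(abstract):
        merged.setdefault(link.pair, set()).update(link.channels)
        if link.flags:
            flags[link.pair] = link.flags
    links = [
        LinkRecord(
            nct_id=nct,
            pmid=pmid,
            channels=frozenset(chans),
            flags=flags.get((nct, pmid), ()),
        )
        for (nct, pmid), chans in sorted(merged.items())
    ]
    table = LinkTable(links=links)
    log.info(
        "merge_links: combinations=%d distinct_pairs=%d distinct_articles=%d dual=%d",
        table.combinations,
        table.distinct_pairs,
        table.distinct_articles,
        table.dual_channel_pairs,
    )
    return table


def trials_with_publications(table: LinkTable) -> dict[str, int]:
    """Count distinct linked articles per trial.

    Returns a mapping ``nct_id -> article count``; tallies for at-least-one,
    at-least-two, and at-least-three articles follow by summation.
    """
    counts: dict[str, set[str]] = {}
    for link in table.links:
        counts.setdefault(link.nct_id, set()).add(link.pmid)
    return {nct: len(pmids) for nct, pmids in counts.items()}


def publication_tallies(per_trial: Mapping[str, int]) -> dict[str, int]:
    """Trials with >=1, >=2, >=3 linked articles."""
    return {
        "at_least_1": sum(1 for c in per_trial.values() if c >= 1),
        "at_least_2": sum(1 for c in per_trial.values() if c >= 2),
        "at_least_3": sum(1 for c in per_trial.values() if c >= 3),
    }
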