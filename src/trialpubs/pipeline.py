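"""End-to-end driver chaining the analysis stages.

The stages are pure functions over the domain model; this module wires them
in order — select condition studies, filter by status, extract and filter
links from both channels, merge, group interventions, score and rank
publications, classify trials — and returns one result object the report
writer and the command-line interface both consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

from . import classify as _classify
from .ingest import Corpus, filter_eligible, select_condition_studies
from .interventions import InterventionGroup, build_intervention_table
from .linking import (
    LinkTable,
    extract_abstract_links,
    extract_registry_links,
    filter_misclassified,
    merge_links,
    trials_with_publications,
)
from .model import Config, TrialRecord
from .report import SummaryStats, compute_summary
from .scoring import ScoredPublication, rank_publications, score_publications

__all__ = ["PipelineResult", "run"]


@dataclass
class PipelineResult:
    config: Config
    query_date: date
    trials_in_scope: list[TrialRecord]
    link_table: LinkTable
    intervention_groups: list[InterventionGroup]
    ranked: list[ScoredPublication]
    shortlist: list[ScoredPublication]
    classification_rows: list[dict]
    stats: SummaryStats
    vaccine_trials: list[TrialRecord] = field(default_factory=list)


def run(corpus: Corpus, config: Optional[Config] = None, query_date: Optional[date] = None) -> PipelineResult:
    """Run the whole pipeline over one corpus."""
    config = config or Config()
    query_date = query_date or corpus.query_date or date.today()

    in_condition = select_condition_studies(corpus.trials, config.condition_keywords)
    in_scope = filter_eligible(in_condition, config.eligible_statuses)
    trial_map = {t.nct_id: t for t in in_scope}
    article_map = corpus.article_lookup()

    registry_candidates = extract_registry_links(in_scope, article_map)
    registry_kept, removed = filter_misclassified(
        registry_candidates,
        trial_map,
        article_map,
        strictly_before=config.misdate_strictly_before,
    )
    abstract = extract_abstract_links(in_scope, corpus.articles)
    table = merge_links(registry_kept, abstract)
    table.removed = removed

    groups = build_intervention_table(
        in_scope,
        table,
        synonyms=config.intervention_synonyms,
        phase_values=config.phase_values,
        stop_list=config.intervention_stop_list,
    )
    pubs = score_publications(table, trial_map, article_map, groups, query_date, config)
    ranked = rank_publications(pubs)
    short = [p for p in ranked if p.shortlisted]

    classification = _classify.classify_trials(in_scope, table, article_map)
    timing_counts: dict[str, int] = {}
    for row in classification:
        timing_counts[row["registration_timing"]] = (
            timing_counts.get(row["registration_timing"], 0) + 1
        )
    vaccine = _classify.vaccine_subset(in_scope, config.vaccine_title_term)
    per_trial = trials_with_publications(table)
    vaccine_with_article = sum(1 for t in vaccine if per_trial.get(t.nct_id, 0) >= 1)

    stats = compute_summary(
        trials_total=len(in_scope),
        link_table=table,
        pubs=ranked,
        timing_counts=timing_counts,
        vaccine_trials=len(vaccine),
        vaccine_trials_with_article=vaccine_with_article,
        decimals=config.percent_decimals,
        minutes_per_abstract=config.per_abstract_review_minutes,
    )
    return PipelineResult(
        config=config,
        query_date=query_date,
        trials_in_scope=in_scope,
        link_table=table,
        intervention_groups=groups,
        ranked=ranked,
        shortlist=short,
        classification_rows=classification,
        stats=stats,
        vaccine_trials=vaccine,
    )
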